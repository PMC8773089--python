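"""Minimal legacy-VTK ASCII writers/readers for meshes, fields and surfaces.

Only the subset of the legacy format the pipeline itself produces is
supported; files open directly in ParaView.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_vtk_unstructured(
    path: str | Path,
    points: np.ndarray,
    tets: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "ventriflow output",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(points)} float",
    ]
    lines += [" ".join(f"{v:.6g}" for v in p) for p in points]
    lines.append(f"CELLS {len(tets)} {5 * len(tets)}")
    lines += ["4 " + " ".join(str(i) for i in t) for t in tets]
    lines.append(f"CELL_TYPES {len(tets)}")
    lines += ["10"] * len(tets)
    if point_data:
        lines.append(f"POINT_DATA {len(points)}")
        lines += _data_block(point_data)
    if cell_data:
        lines.append(f"CELL_DATA {len(tets)}")
        lines += _data_block(cell_data)
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_polydata(
    path: str | Path,
    points: np.ndarray,
    tris: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "ventriflow surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} float",
    ]
    lines += [" ".join(f"{v:.6g}" for v in p) for p in points]
    lines.append(f"POLYGONS {len(tris)} {4 * len(tris)}")
    lines += ["3 " + " ".join(str(i) for i in t) for t in tris]
    if point_data:
        lines.append(f"POINT_DATA {len(points)}")
        lines += _data_block(point_data)
    Path(path).write_text("\n".join(lines) + "\n")


def _data_block(data: dict[str, np.ndarray]) -> list[str]:
    lines: list[str] = []
    for name, arr in data.items():
        arr = np.asarray(arr)
        if arr.ndim == 2 and arr.shape[1] == 3:
            lines.append(f"VECTORS {name} float")
            lines += [" ".join(f"{v:.6g}" for v in row) for row in arr]
        else:
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6g}" for v in arr.ravel()]
    return lines


def read_vtk_unstructured(path: str | Path):
    """Read back meshes written by :func:`write_vtk_unstructured`."""
    tok = Path(path).read_text().split("\n")
    i = tok.index(next(l for l in tok if l.startswith("POINTS")))
    npts = int(tok[i].split()[1])
    points = np.array(
        [[float(x) for x in tok[i + 1 + k].split()] for k in range(npts)]
    )
    j = i + 1 + npts
    while not tok[j].startswith("CELLS"):
        j += 1
    ncell = int(tok[j].split()[1])
    tets = np.array(
        [[int(x) for x in tok[j + 1 + k].split()[1:]] for k in range(ncell)]
    )
    data: dict[str, np.ndarray] = {}
    k = j + 1 + ncell
    section = None
    while k < len(tok):
        line = tok[k]
        if line.startswith("POINT_DATA") or line.startswith("CELL_DATA"):
            section = line.split()[0]
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            cnt = npts if section == "POINT_DATA" else ncell
            vals = [float(tok[k + 2 + m]) for m in range(cnt)]
            data[name] = np.array(vals)
            k += 1 + cnt
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            cnt = npts if section == "POINT_DATA" else ncell
            vals = [[float(x) for x in tok[k + 1 + m].split()] for m in range(cnt)]
            data[name] = np.array(vals)
            k += cnt
        k += 1
    return points, tets, data
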