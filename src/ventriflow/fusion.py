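"""Multi-series cine-MRI fusion onto an isotropic voxel grid.

A short-axis stack resolves the heart at 1 mm in plane but only 8 mm across
slices; the long-axis views are single 1 mm slices in orthogonal planes.
Fusion merges every available series into one artificial volumetric image
per frame: the target grid is the short-axis bounding box at uniform 1 mm
spacing, and each target voxel receives a distance-weighted average of the
nearest pixel of every acquired slice,

    I(v) = sum_s w(d_s) g_s / sum_s w(d_s),   w(d) = exp(-d^2 / (2 sigma_w^2)),

where g_s is the gray value of the pixel of slice s nearest (in 3D) to the
voxel center and d_s its distance; slices farther than a cutoff d_cut do
not contribute.  Voxels with no slice within d_cut are marked uncovered
(background).  The weight law and its two parameters are configuration; a
smooth positive decreasing kernel is the minimal choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import CineSeries


@dataclass
class GridSpec:
    """Axis-aligned voxel grid: world = origin + index * spacing."""

    origin: np.ndarray  # (3,) mm
    shape: tuple[int, int, int]
    spacing: float = 1.0  # mm, isotropic

    def points(self) -> np.ndarray:
        ii, jj, kk = np.meshgrid(
            *(np.arange(n) for n in self.shape), indexing="ij"
        )
        return self.origin + self.spacing * np.stack(
            [ii, jj, kk], axis=-1
        ).reshape(-1, 3)


@dataclass
class FusedImage4D:
    """Fused 1 mm isotropic image sequence with coverage mask."""

    frames: np.ndarray  # (nt, nx, ny, nz)
    coverage: np.ndarray  # (nx, ny, nz) bool — voxels reached by any slice
    grid: GridSpec
    frame_times: np.ndarray  # (nt,) s

    def __post_init__(self):
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")


def common_time_grid(
    series: list[CineSeries], frames_out: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Equispaced target times over one beat + nearest-frame map per series.

    For each series and target time the nearest-in-time source frame is
    selected; ties resolve to the earlier frame.
    """
    if not series:
        raise ValueError("no input series")
    period = max(
        s.times[-1] + (s.times[1] - s.times[0]) if len(s.times) > 1 else 0.0
        for s in series
    )
    targets = np.arange(frames_out) * period / frames_out
    maps = []
    for s in series:
        d = np.abs(s.times[None, :] - targets[:, None])
        maps.append(np.argmin(d, axis=1))  # first minimum = earlier frame
    return targets, maps


def sa_bounding_grid(series: list[CineSeries], spacing: float = 1.0) -> GridSpec:
    """Target grid covering the short-axis stack bounding box."""
    sa = [s for s in series if s.label == "short-axis"]
    if not sa:
        raise ValueError("no short-axis series to initialize the grid")
    s = sa[0]
    ni, nj = s.data.shape[2:]
    corners = []
    for isl in range(len(s.origins)):
        o = s.origins[isl]
        corners += [
            o,
            o + (ni - 1) * s.pixel_spacing * s.row_dir,
            o + (nj - 1) * s.pixel_spacing * s.col_dir,
            o + (ni - 1) * s.pixel_spacing * s.row_dir
            + (nj - 1) * s.pixel_spacing * s.col_dir,
        ]
    lo = np.min(corners, axis=0)
    hi = np.max(corners, axis=0)
    shape = tuple(int(np.floor((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    return GridSpec(origin=lo, shape=shape, spacing=spacing)


def fuse_frame(
    slices: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]],
    grid: GridSpec,
    sigma_w: float = 2.0,
    d_cut: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse oriented 2D slices into one voxel volume.

    slices: list of (pixels (ni, nj), origin, row_dir, col_dir, spacing).
    Returns (volume, coverage); uncovered voxels are 0 with coverage False.
    """
    if not slices:
        raise ValueError("no slices to fuse")
    pts = grid.points()
    wsum = np.zeros(len(pts))
    vsum = np.zeros(len(pts))
    for pix, origin, row_dir, col_dir, sp in slices:
        ni, nj = pix.shape
        nrm = np.cross(row_dir, col_dir)
        nrm = nrm / np.linalg.norm(nrm)
        rel = pts - origin
        pu = rel @ row_dir
        pv = rel @ col_dir
        pw = rel @ nrm
        iu = np.clip(np.rint(pu / sp), 0, ni - 1)
        iv = np.clip(np.rint(pv / sp), 0, nj - 1)
        d2 = pw**2 + (pu - iu * sp) ** 2 + (pv - iv * sp) ** 2
        sel = d2 <= d_cut**2
        w = np.exp(-d2[sel] / (2.0 * sigma_w**2))
        vals = pix[iu[sel].astype(np.intp), iv[sel].astype(np.intp)]
        wsum[sel] += w
        vsum[sel] += w * vals
    covered = wsum > 0
    out = np.zeros(len(pts))
    out[covered] = vsum[covered] / wsum[covered]
    if not covered.any():
        raise ValueError("no voxel is covered by any slice: geometry mismatch")
    return out.reshape(grid.shape), covered.reshape(grid.shape)


def fuse_series(
    series: list[CineSeries],
    frames_out: int = 20,
    sigma_w: float = 2.0,
    d_cut: float = 6.0,
    labels: tuple[str, ...] | None = None,
    spacing: float = 1.0,
) -> FusedImage4D:
    """Fuse all series (optionally restricted to some labels) over one beat."""
    grid = sa_bounding_grid(series, spacing)
    use = [s for s in series if labels is None or s.label in labels]
    if not use:
        raise ValueError("label selection removed all series")
    times, fmaps = common_time_grid(use, frames_out)
    frames = []
    coverage = None
    for it in range(frames_out):
        slc = []
        for s, fmap in zip(use, fmaps):
            src = fmap[it]
            for isl in range(len(s.origins)):
                slc.append(
                    (s.data[src, isl], s.origins[isl], s.row_dir, s.col_dir,
                     s.pixel_spacing)
                )
        vol, cov = fuse_frame(slc, grid, sigma_w, d_cut)
        frames.append(vol)
        coverage = cov if coverage is None else (coverage | cov)
    return FusedImage4D(
        frames=np.stack(frames), coverage=coverage, grid=grid,
        frame_times=times,
    )


def save_fused(f: FusedImage4D, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    aff[:3, :3] *= f.grid.spacing
    aff[:3, 3] = f.grid.origin
    for it, vol in enumerate(f.frames):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff),
                 out / f"fused_f{it:03d}.nii.gz")
    nib.save(nib.Nifti1Image(f.coverage.astype(np.uint8), aff),
             out / "coverage.nii.gz")
    meta = {
        "frame_times": f.frame_times.tolist(),
        "origin": np.asarray(f.grid.origin).tolist(),
        "shape": list(f.grid.shape),
        "spacing": f.grid.spacing,
    }
    (out / "fused.json").write_text(json.dumps(meta, indent=1))


def load_fused(in_dir: str | Path) -> FusedImage4D:
    p = Path(in_dir)
    meta = json.loads((p / "fused.json").read_text())
    frames = [
        np.asarray(nib.load(p / f"fused_f{it:03d}.nii.gz").dataobj)
        for it in range(len(meta["frame_times"]))
    ]
    cov = np.asarray(nib.load(p / "coverage.nii.gz").dataobj).astype(bool)
    grid = GridSpec(
        origin=np.asarray(meta["origin"]),
        shape=tuple(meta["shape"]),
        spacing=meta["spacing"],
    )
    return FusedImage4D(
        frames=np.stack(frames), coverage=cov, grid=grid,
        frame_times=np.asarray(meta["frame_times"]),
    )
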