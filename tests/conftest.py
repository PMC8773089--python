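"""Shared fixtures.

The expensive artifacts (the rendered phantom, the noiseless render, the
end-to-end desk run) are session-scoped so that every test and every
acceptance check reuses a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from ventriflow.phantom import PhantomConfig, build_phantom, render_cine
from ventriflow.meshing import OUTLET, build_swept_mesh, graded_layers
from ventriflow.solver import (
    ConstantPressure, FluidProperties, NavierStokesALE, RIISSurface,
    SolverConfig, ale_lift, riis_flux,
)


@pytest.fixture(scope="session")
def default_lv():
    return build_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def noiseless_lv():
    return build_phantom(PhantomConfig(noise_sigma=0.0))


@pytest.fixture(scope="session")
def noiseless_series(noiseless_lv):
    return render_cine(noiseless_lv)


@pytest.fixture(scope="session")
def e2e(tmp_path_factory):
    """One full desk-resolution pipeline run on the default phantom."""
    from ventriflow.pipeline import PipelineConfig, run_pipeline, run_systole
    from ventriflow.pipeline import (
        stage_fusion, stage_geometry, stage_indicators, stage_phantom,
        stage_reconstruction, stage_solver,
    )
    from pathlib import Path

    cfg = PipelineConfig(seed=1)
    run = tmp_path_factory.mktemp("e2e")
    lv, series = stage_phantom(cfg, run)
    fused = stage_fusion(cfg, run, series)
    rec = stage_reconstruction(cfg, run, fused)
    gs = stage_geometry(cfg, run, lv, rec)
    sim = stage_solver(cfg, run, lv, gs)
    summary = stage_indicators(cfg, run, lv, rec, gs, sim)
    summary["_config_hash"] = cfg.hash("full")
    import json

    (run / "summary.json").write_text(json.dumps(summary, indent=1))
    return {
        "cfg": cfg, "run": run, "lv": lv, "series": series, "fused": fused,
        "rec": rec, "gs": gs, "sim": sim, "summary": summary,
    }


@pytest.fixture(scope="session")
def poiseuille_run():
    """Steady pressure-driven pipe flow at moderate Reynolds number.

    Radius 5 mm resolved with 8 rings (h = a/8); viscosity raised so that
    the entry length stays short and the steady state is reached in a few
    large time steps.
    """
    from ventriflow.meshing import INLET, OUTLET, cylinder_mesh
    from ventriflow.solver import (
        ConstantPressure, FluidProperties, NavierStokesALE, SolverConfig,
    )

    radius, length, dp = 5.0, 20.0, 100.0
    mesh = cylinder_mesh(radius, length, 8, 10)
    props = FluidProperties(density=1000.0, viscosity=0.1)
    cfg = SolverConfig(dt=0.05, t_end=1.0)
    ns = NavierStokesALE(
        mesh, props, cfg,
        pressure_bcs=[(INLET, ConstantPressure(dp), False),
                      (OUTLET, ConstantPressure(0.0), False)],
    )
    pts = mesh.points.copy()
    energy = []
    state = None
    for k in range(16):
        state = ns.advance(pts, pts, (k + 1) * cfg.dt)
        energy.append(float(np.sum(state.u**2)))
    u_analytic = dp * (radius * 1e-3) ** 2 / (
        4.0 * props.viscosity * length * 1e-3
    )
    return {
        "mesh": mesh, "ns": ns, "state": state, "props": props,
        "radius": radius, "length": length, "dp": dp,
        "u_max_analytic": u_analytic, "energy": energy,
    }


# ---------------------------------------------------------------------------
# contracting-chamber rig with an immersed leaflet
# ---------------------------------------------------------------------------


def _chamber_mesh():
    """Small contracting chamber + outflow tube with a lateral leaflet."""
    def rf(th, z):
        r_ch = np.sqrt(np.clip(18.0**2 - (z + 12.0) ** 2 * 0.5, 36.0, None))
        s = np.clip((z - 0.0) / 10.0, 0.0, 1.0)
        s = s * s * (3 - 2 * s)
        return (1 - s) * r_ch + s * 6.0

    zl = graded_layers(-29.0, 22.0, lambda z: 2.6 if -12 < z < 12 else 3.6)
    return build_swept_mesh(rf, zl, 5, closed_bottom=True)


def _leaflet():
    phi = np.linspace(0, 2 * np.pi, 40, endpoint=False)
    ring = np.column_stack(
        [-7.0 + 6.5 * np.cos(phi), 6.5 * np.sin(phi), np.full_like(phi, -6.0)]
    )
    from ventriflow.geometry import _leaflet_surface

    return _leaflet_surface(ring, 4.0, 8, 40)


@pytest.fixture(scope="session")
def chamber_rig():
    """Runner: simulate the contracting chamber for a given valve R / dt."""
    mesh = _chamber_mesh()
    lift = ale_lift(mesh)
    bnodes = mesh.boundary_nodes()
    pts_b = mesh.points[bnodes]
    decay = 1.0 - np.clip((pts_b[:, 2] + 2.0) / 14.0, 0.0, 1.0)

    def boundary_disp(t, t_end):
        s = np.clip(t / t_end, 0, 1)
        s = s * s * (3 - 2 * s)
        d = np.zeros_like(pts_b)
        d[:, 0] = -0.12 * s * pts_b[:, 0] * decay
        d[:, 1] = -0.12 * s * pts_b[:, 1] * decay
        return d

    cache = {}

    def run(resistance, dt=4.0e-3, t_end=0.08):
        key = (resistance, dt)
        if key in cache:
            return cache[key]
        cfg = SolverConfig(dt=dt, t_end=t_end)
        riis = None
        if resistance is not None:
            lp, lt = _leaflet()
            riis = RIISSurface(lp, lt, resistance=resistance, eps=4.0)
        ns = NavierStokesALE(
            mesh, FluidProperties(), cfg, riis=riis,
            pressure_bcs=[(OUTLET, ConstantPressure(0.0), True)],
        )
        out_faces = mesh.boundary_faces[mesh.boundary_tags == OUTLET]
        x_prev = mesh.points.copy()
        n = int(round(t_end / dt))
        peak_q = 0.0
        peak_state = None
        for k in range(n):
            t1 = (k + 1) * dt
            x_new = mesh.points + lift.extend(boundary_disp(t1, t_end))
            st = ns.advance(x_new, x_prev, t1)
            q = ns.flux(out_faces, x_new, st.u)
            if abs(q) > abs(peak_q):
                peak_q, peak_state = q, st
            x_prev = x_new
        qv = riis_flux(peak_state, riis, mesh) if riis is not None else None
        out = {"peak_q": peak_q, "state": peak_state, "riis": riis,
               "valve_flux": qv, "mesh": mesh}
        cache[key] = out
        return out

    return run


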