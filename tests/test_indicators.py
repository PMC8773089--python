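"""Obstruction indicators against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventriflow import indicators as ind
from ventriflow.meshing import OUTLET, WALL, box_mesh, cylinder_mesh
from ventriflow.solver import MM, FlowState, FluidProperties


# ---------------------------------------------------------------------------
# volumetry
# ---------------------------------------------------------------------------


class TestEFMetrics:
    @pytest.mark.parametrize(
        "edv,esv,ef_round",
        [(138.0, 68.0, 51), (162.0, 94.0, 42), (102.0, 43.0, 58)],
    )
    def test_clinical_arithmetic(self, edv, esv, ef_round):
        sv, ef = ind.ef_metrics(edv, esv)
        assert sv == edv - esv
        assert round(ef) == ef_round

    @given(st.floats(50, 300), st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_algebraic_identity(self, v, f):
        """EF of (V, V(1-f)) is exactly 100 f."""
        _, ef = ind.ef_metrics(v, v * (1 - f))
        assert ef == pytest.approx(100 * f, rel=1e-9)

    def test_precondition(self):
        with pytest.raises(ValueError):
            ind.ef_metrics(60.0, 70.0)

    def test_volume_discrepancy_utility(self):
        d = ind.max_volume_discrepancy([138, 162, 102], [128, 152, 101])
        assert d == pytest.approx(10 / 128)


# ---------------------------------------------------------------------------
# U(t) and the obstruction interval
# ---------------------------------------------------------------------------


from _oracles import dense_duration


class TestObstructionDuration:
    def test_constant_series_zero(self):
        rep = ind.obstruction_duration(np.linspace(0, 1, 9), np.ones(9))
        assert rep.duration == 0.0

    def test_symmetric_ramp(self):
        t = np.arange(7) * 0.05
        U = np.array([0, 1, 2, 3, 2, 1, 0.0])
        rep = ind.obstruction_duration(t, U)
        assert rep.U_thr == 1.0
        assert rep.duration == pytest.approx(dense_duration(t, U), abs=1e-4)

    def test_triangular_pulse_closed_form(self):
        """Single pulse over a flat series: interpolated crossing width."""
        t = np.arange(9) * 0.1
        U = np.array([1, 1, 1, 1, 3, 1, 1, 1, 1.0])
        rep = ind.obstruction_duration(t, U)
        assert rep.U_thr == 1.0
        # U > 1 strictly between the two flanks of the linear pulse
        assert rep.duration == pytest.approx(0.2, abs=1e-12)

    def test_random_series_match_dense_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(5, 40)
            t = np.sort(rng.uniform(0, 0.5, n))
            t[0], t[-1] = 0.0, 0.5
            U = rng.uniform(0, 2, n)
            rep = ind.obstruction_duration(t, U)
            grid = dense_duration(t, U)
            assert abs(rep.duration - grid) <= 2 * 0.5 / (1000 * (n - 1))

    def test_threshold_within_range(self):
        rng = np.random.default_rng(1)
        U = rng.uniform(0.2, 1.8, 25)
        rep = ind.obstruction_duration(np.linspace(0, 0.4, 25), U)
        assert U.min() <= rep.U_thr <= U.max()
        assert 0 <= rep.duration <= 0.4


# ---------------------------------------------------------------------------
# pressure difference
# ---------------------------------------------------------------------------


def _tube_state(mesh, u=None, p=None):
    n = len(mesh.points)
    return FlowState(
        t=0.0,
        u=np.zeros((n, 3)) if u is None else u,
        p=np.zeros(n) if p is None else p,
        points=mesh.points.copy(),
    )


class TestPressureDifference:
    def test_uniform_pressure_zero(self):
        mesh = cylinder_mesh(4.0, 12.0, 4, 5)
        dp = ind.pressure_difference(_tube_state(mesh, p=np.full(len(mesh.points), 7.0)), mesh)
        assert np.abs(dp).max() < 1e-12

    def test_outlet_mean_is_zero(self):
        mesh = cylinder_mesh(4.0, 12.0, 4, 5)
        rng = np.random.default_rng(0)
        st_ = _tube_state(mesh, p=rng.normal(0, 100, len(mesh.points)))
        dp = ind.pressure_difference(st_, mesh)
        faces = mesh.boundary_faces[mesh.boundary_tags == OUTLET]
        area, _ = mesh.face_areas_normals(faces)
        mean_out = (area * dp[faces].mean(axis=1)).sum() / area.sum()
        assert mean_out == pytest.approx(0.0, abs=1e-10)

    def test_gauge_invariance(self):
        mesh = cylinder_mesh(4.0, 12.0, 4, 5)
        rng = np.random.default_rng(1)
        p = rng.normal(0, 50, len(mesh.points))
        d1 = ind.pressure_difference(_tube_state(mesh, p=p), mesh)
        d2 = ind.pressure_difference(_tube_state(mesh, p=p + 1234.5), mesh)
        assert np.allclose(d1, d2, atol=1e-9)

    def test_poiseuille_linear_profile(self, poiseuille_run):
        """Δp decays linearly along the tube axis within 2%."""
        mesh, st_ = poiseuille_run["mesh"], poiseuille_run["state"]
        dp = ind.pressure_difference(st_, mesh) * 133.322  # back to Pa
        z = mesh.points[:, 2]
        interior = (z > 2.0) & (z < 18.0)
        slope, icpt = np.polyfit(z[interior], dp[interior], 1)
        fit = slope * z[interior] + icpt
        assert np.abs(dp[interior] - fit).max() < 0.02 * np.abs(dp).max()


# ---------------------------------------------------------------------------
# U(t) over the aortic subdomain
# ---------------------------------------------------------------------------


class TestMaxAorticVelocity:
    def test_rest_is_zero(self):
        mesh = cylinder_mesh(4.0, 12.0, 4, 5)
        mesh.cell_tags[:] = 3  # aortic root
        times, U = ind.max_aortic_velocity([_tube_state(mesh)], mesh)
        assert U[0] == 0.0

    def test_poiseuille_centerline_peak(self, poiseuille_run):
        mesh, st_ = poiseuille_run["mesh"], poiseuille_run["state"]
        mesh.cell_tags[:] = 3
        _, U = ind.max_aortic_velocity([st_], mesh)
        assert U[0] == pytest.approx(poiseuille_run["u_max_analytic"],
                                     rel=0.05)
        mesh.cell_tags[:] = 0

    def test_rotation_invariance(self):
        mesh = cylinder_mesh(4.0, 12.0, 4, 5)
        mesh.cell_tags[:] = 4
        rng = np.random.default_rng(0)
        u = rng.normal(0, 1, (len(mesh.points), 3))
        _, U1 = ind.max_aortic_velocity([_tube_state(mesh, u=u)], mesh)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        st2 = FlowState(0.0, u @ R.T, np.zeros(len(mesh.points)),
                        mesh.points @ R.T)
        _, U2 = ind.max_aortic_velocity([st2], mesh)
        assert U1[0] == pytest.approx(U2[0], rel=1e-12)

    def test_missing_tag_rejected(self):
        mesh = cylinder_mesh(4.0, 12.0, 4, 5)
        mesh.cell_tags[:] = 0
        with pytest.raises(ValueError):
            ind.max_aortic_velocity([_tube_state(mesh)], mesh)


# ---------------------------------------------------------------------------
# WSS and Q-criterion
# ---------------------------------------------------------------------------


class TestWSS:
    def test_rest_zero(self):
        mesh = box_mesh((10.0, 6.0, 8.0), (5, 3, 4))
        nodes, w = ind.wss(_tube_state(mesh), mesh, FluidProperties())
        assert np.abs(w).max() < 1e-12

    def test_plane_couette_exact(self):
        """u = (U y / h, 0, 0): |WSS| = mu U / h on the y = 0 wall."""
        mesh = box_mesh((10.0, 6.0, 8.0), (5, 3, 4))
        props = FluidProperties(viscosity=0.01)
        Utop, h = 0.8, 6.0 * MM
        u = np.zeros((len(mesh.points), 3))
        u[:, 0] = Utop * mesh.points[:, 1] * MM / h
        nodes, w = ind.wss(_tube_state(mesh, u=u), mesh, props)
        on_wall = np.abs(mesh.points[nodes][:, 1]) < 1e-9
        # exclude edge/corner nodes whose averaged normal is oblique
        inner = on_wall & (mesh.points[nodes][:, 0] > 1) \
            & (mesh.points[nodes][:, 0] < 9) \
            & (mesh.points[nodes][:, 2] > 1) & (mesh.points[nodes][:, 2] < 7)
        mag = np.linalg.norm(w[inner], axis=1)
        assert mag == pytest.approx(props.viscosity * Utop / h, rel=1e-9)

    def test_poiseuille_tube_wss(self, poiseuille_run):
        """|WSS| = 4 mu Q / (pi a^3) at the tube wall within 10%."""
        r = poiseuille_run
        mesh, st_ = r["mesh"], r["state"]
        ns = r["ns"]
        q = ns.flux(mesh.boundary_faces[mesh.boundary_tags == OUTLET],
                    mesh.points, st_.u) * 1e-6  # m^3/s
        nodes, w = ind.wss(st_, mesh, r["props"])
        pts = mesh.points[nodes]
        mid = (pts[:, 2] > 6) & (pts[:, 2] < 14) \
            & (np.hypot(pts[:, 0], pts[:, 1]) > r["radius"] - 1e-6)
        mag = np.linalg.norm(w[mid], axis=1).mean()
        expect = 4 * r["props"].viscosity * q / (np.pi * (r["radius"] * MM) ** 3)
        assert mag == pytest.approx(expect, rel=0.10)


class TestQCriterion:
    def _state_from_field(self, mesh, fn):
        u = fn(mesh.points * MM)
        return _tube_state(mesh, u=u)

    def test_rigid_rotation(self):
        """u = omega x r gives Q = omega^2 exactly (linear field)."""
        mesh = box_mesh((8.0, 8.0, 8.0), (4, 4, 4))
        om = 3.0
        st_ = self._state_from_field(
            mesh, lambda x: np.column_stack([-om * x[:, 1], om * x[:, 0],
                                             np.zeros(len(x))])
        )
        Q = ind.q_criterion(st_, mesh)
        assert Q == pytest.approx(om**2, rel=1e-9)

    def test_simple_shear_zero(self):
        mesh = box_mesh((8.0, 8.0, 8.0), (4, 4, 4))
        st_ = self._state_from_field(
            mesh, lambda x: np.column_stack([2.0 * x[:, 1],
                                             np.zeros(len(x)),
                                             np.zeros(len(x))])
        )
        Q = ind.q_criterion(st_, mesh)
        assert np.abs(Q).max() < 1e-9

    def test_uniaxial_strain(self):
        """diag(g, -g/2, -g/2) strain gives Q = -3 g^2 / 4 < 0."""
        mesh = box_mesh((8.0, 8.0, 8.0), (4, 4, 4))
        g = 2.0
        st_ = self._state_from_field(
            mesh, lambda x: np.column_stack(
                [g * x[:, 0], -0.5 * g * x[:, 1], -0.5 * g * x[:, 2]])
        )
        Q = ind.q_criterion(st_, mesh)
        assert Q == pytest.approx(-0.75 * g**2, rel=1e-9)


class TestSeptalLine:
    def _ball_mesh(self):
        from ventriflow.meshing import build_swept_mesh, graded_layers

        def rf(th, z):
            return np.full_like(th, np.sqrt(max(100.0 - z * z, 0.25)))

        zl = graded_layers(-10.0, 9.9, lambda z: 1.0)
        return build_swept_mesh(rf, zl, 8, closed_bottom=True)

    def test_sphere_great_circle(self):
        """Plane through the center cuts a great-circle arc, s in [0, 1]."""
        mesh = self._ball_mesh()
        ostium = np.array([0.0, 0.0, 9.9])
        apex = np.array([0.0, 0.0, -10.0])
        septal = np.array([10.0, 0.0, 0.0])
        prof = ind.septal_line(mesh, mesh.points, ostium, apex, septal)
        assert prof.s[0] == 0.0 and prof.s[-1] == 1.0
        assert np.all(np.diff(prof.s) > 0)
        # arc length of the half great circle ~ pi R
        L = np.linalg.norm(np.diff(prof.points, axis=0), axis=1).sum()
        assert L == pytest.approx(np.pi * 10.0, rel=0.05)
        # the chosen branch passes through the septal marker
        assert np.min(np.linalg.norm(prof.points - septal, axis=1)) < 1.5

    def test_linear_field_sampled_exactly(self):
        """Sampling a nodal field linear in space is exact on the line."""
        mesh = self._ball_mesh()
        prof = ind.septal_line(
            mesh, mesh.points, np.array([0.0, 0, 9.9]),
            np.array([0.0, 0, -10.0]), np.array([10.0, 0, 0]),
        )
        f = mesh.points[:, 2]  # linear field: value = z
        vals = prof.sample(f)
        assert np.allclose(vals, prof.points[:, 2], atol=1e-9)
        grad = ind.intraventricular_gradient(prof, f)
        assert grad == pytest.approx(
            prof.points[:, 2].max() - prof.points[:, 2].min(), abs=1e-9
        )

    def test_uniform_field_gradient_zero(self):
        mesh = self._ball_mesh()
        prof = ind.septal_line(
            mesh, mesh.points, np.array([0.0, 0, 9.9]),
            np.array([0.0, 0, -10.0]), np.array([10.0, 0, 0]),
        )
        dp = np.full(len(mesh.points), 3.3)
        assert ind.intraventricular_gradient(prof, dp) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_landmarks_rejected(self):
        mesh = self._ball_mesh()
        with pytest.raises(ValueError):
            ind.septal_line(mesh, mesh.points, np.array([0.0, 0, 9.9]),
                            np.array([0.0, 0, -10.0]),
                            np.array([0.0, 0, 3.0]))


def test_reynolds_number():
    props = FluidProperties()
    re = ind.reynolds_number(2.0, 24.0, props)
    assert re == pytest.approx(1.06e3 * 2.0 * 0.024 / 3.5e-3, rel=1e-12)
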