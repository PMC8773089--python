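"""Annulus fitting, template attachment, meshing, displacement extension."""

import numpy as np
import pytest

from ventriflow import geometry as geo
from ventriflow.meshing import OUTLET, WALL


def ring(radius=12.0, n=64, saddle=0.0, center=(0, 0, 0), tilt=None):
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [radius * np.cos(phi), radius * np.sin(phi),
         saddle * np.cos(2 * phi)]
    )
    return pts + np.asarray(center, dtype=float)


class TestFitAnnulus:
    def test_exact_circle(self):
        fit = geo.fit_annulus(ring(12.0))
        assert fit.radius == pytest.approx(12.0, abs=1e-9)
        assert abs(fit.normal[2]) == pytest.approx(1.0, abs=1e-9)
        assert fit.plane_rms < 1e-9

    def test_saddle_height_recovered(self):
        fit = geo.fit_annulus(ring(12.0, saddle=3.0))
        assert fit.saddle_height == pytest.approx(3.0, abs=0.05)
        assert abs(fit.normal[2]) > 0.999  # mean plane

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            geo.fit_annulus(ring()[:5])

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
        with pytest.raises(ValueError):
            geo.fit_annulus(pts)


@pytest.fixture(scope="module")
def phantom_domain(default_lv):
    """Templates attached to the analytic end-systolic endocardium."""
    lv = default_lv
    t = lv.t_end_systole
    verts, faces = lv.endo_surface(t, 64, 48)
    lm = lv.landmarks(t)
    aortic = geo.fit_annulus(lm["aortic_annulus"])
    mitral = geo.fit_annulus(lm["mitral_annulus"])
    dom = geo.attach_templates(verts, faces, aortic, mitral,
                               apex_hint=lm["apex"],
                               septal_hint=lm["septal_center"])
    geo.build_mesh(dom, h_coarse=4.5, h_fine=1.8)
    return dom


class TestTemplates:
    def test_junction_ring_matches_annulus(self, phantom_domain):
        """The aortic tube meets the domain at the annulus radius."""
        d = phantom_domain
        th = np.linspace(-np.pi, np.pi, 32)
        r = d.radius_fn(th, d.z_ann)
        assert np.allclose(r, d.aortic_fit.radius, atol=0.5)

    def test_mesh_watertight_positive_volume(self, phantom_domain):
        m = phantom_domain.mesh
        assert m.volume() > 0
        assert m.min_jacobian() > 0
        area, nrm = m.face_areas_normals(m.boundary_faces)
        assert np.linalg.norm((area[:, None] * nrm).sum(axis=0)) \
            < 1e-9 * area.sum()

    def test_outlet_normal_along_axis(self, phantom_domain):
        """Sigma_out is a planar cap perpendicular to the ascending axis."""
        m = phantom_domain.mesh
        faces = m.boundary_faces[m.boundary_tags == OUTLET]
        _, nrm = m.face_areas_normals(faces)
        ang = np.degrees(np.arccos(np.clip(nrm[:, 2], -1, 1)))
        assert ang.max() < 1.0

    def test_boundary_tags_partition(self, phantom_domain):
        m = phantom_domain.mesh
        assert set(np.unique(m.boundary_tags)) == {WALL, OUTLET}

    def test_leaflet_interior_to_domain(self, phantom_domain):
        """The immersed mitral surface stays inside the fluid volume."""
        d = phantom_domain
        pts = d.leaflet_points
        th = np.arctan2(pts[:, 1], pts[:, 0])
        r = np.hypot(pts[:, 0], pts[:, 1])
        rb = d.radius_fn(th, np.clip(pts[:, 2], d.z_apex, d.z_out))
        assert np.all(r <= rb + 1e-6)
        assert np.all(pts[:, 2] > d.z_apex)

    def test_subdomain_tags_cover_mesh(self, phantom_domain):
        m = phantom_domain.mesh
        assert set(np.unique(m.cell_tags)) == {
            geo.VENTRICLE, geo.LVOT, geo.AORTIC_ROOT, geo.ASCENDING
        }

    def test_refinement_region_edge_size(self, phantom_domain):
        """Median edge in the LVOT band respects the fine size."""
        m = phantom_domain.mesh
        d = phantom_domain
        zc = m.points[m.tets].mean(axis=1)[:, 2]
        band = (zc > d.z_base) & (zc < d.z_sinus_top)
        pts = m.points
        tets = m.tets[band]
        e = []
        for i, j in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]:
            e.append(np.linalg.norm(pts[tets[:, i]] - pts[tets[:, j]], axis=1))
        assert np.median(np.concatenate(e)) <= 1.8 * 1.5


class TestExtendDisplacement:
    def test_zero_data_zero_everywhere(self, phantom_domain):
        from ventriflow.fusion import GridSpec
        from ventriflow.reconstruction import DisplacementField

        g = GridSpec(origin=np.array([-60.0, -60, -60]), shape=(8, 8, 10),
                     spacing=16.0)
        df = DisplacementField(
            disp=np.zeros((2,) + g.shape + (3,)), grid=g,
            reference_index=0, frame_times=np.array([0.0, 0.5]),
        )
        motion = geo.extend_displacement(phantom_domain, df)
        assert np.abs(motion.disp).max() < 1e-9

    def test_rigid_translation_bounded(self, phantom_domain):
        """Harmonic extension obeys the maximum principle componentwise."""
        from ventriflow.fusion import GridSpec
        from ventriflow.reconstruction import DisplacementField

        g = GridSpec(origin=np.array([-60.0, -60, -60]), shape=(8, 8, 10),
                     spacing=16.0)
        df = DisplacementField(
            disp=np.zeros((2,) + g.shape + (3,)), grid=g,
            reference_index=0, frame_times=np.array([0.0, 0.5]),
        )
        df.disp[1, ..., 0] = 2.5  # uniform endocardial shift
        motion = geo.extend_displacement(phantom_domain, df)
        d1 = motion.disp[1]
        assert d1[:, 0].max() <= 2.5 + 1e-9
        assert d1[:, 0].min() >= -1e-9
        assert np.abs(d1[:, 1:]).max() < 1e-9


class TestBuildMesh:
    def test_sphere_volume(self):
        """A ball-like closed domain meshed at fine h hits 4 pi/3 r^3."""
        from ventriflow.meshing import build_swept_mesh, graded_layers

        r0 = 10.0

        def rf(th, z):
            return np.full_like(th, np.sqrt(max(r0**2 - z * z, 1e-9)))

        zl = graded_layers(-r0, r0 * 0.999, lambda z: 0.8)
        mesh = build_swept_mesh(rf, zl, 12, closed_bottom=True)
        exact = 4.0 / 3.0 * np.pi * r0**3
        # the top cap is truncated at 0.999 r and the cross-sections are
        # polygons: stay within 1.5%
        assert mesh.volume() == pytest.approx(exact, rel=0.015)

    def test_cell_budget(self, phantom_domain):
        assert len(phantom_domain.mesh.tets) <= 100_000

    def test_cell_budget_enforced(self, phantom_domain):
        with pytest.raises(RuntimeError):
            geo.build_mesh(phantom_domain, h_coarse=4.5, h_fine=1.8,
                           max_cells=10)
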