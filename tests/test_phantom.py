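"""Phantom geometry, motion law, ground truth, and cine rendering."""

import numpy as np
import pytest

from ventriflow.phantom import (
    BLOOD, BACKGROUND, PhantomConfig, build_phantom, ground_truth,
    render_cine, render_volume,
)


def surface_volume_ml(verts, faces):
    v0, v1, v2 = (verts[faces[:, i]] for i in range(3))
    return abs(np.einsum("ij,ij->i", np.cross(v0, v1), v2).sum() / 6.0) / 1000.0


def truncated_ellipsoid_volume(a, b, c, f):
    zb = (2 * f - 1) * c
    return np.pi * a * b * (zb - zb**3 / (3 * c**2) + 2 * c / 3)


class TestGeometry:
    def test_no_bulge_matches_closed_form(self):
        cfg = PhantomConfig(septal_bulge_amplitude=0.0, target_edv_ml=None)
        lv = build_phantom(cfg)
        a, b, c = cfg.endo_semi_axes_ed
        exact = truncated_ellipsoid_volume(a, b, c, cfg.base_truncation_fraction)
        assert lv.edv == pytest.approx(exact, rel=1e-3)

    def test_default_volumes(self, default_lv):
        """EDV 138 ml / EF 51 gives ESV = EDV (1 - EF/100) = 67.6 ml."""
        v0, _, _ = ground_truth(default_lv, 0.0)
        ves, _, _ = ground_truth(default_lv, default_lv.t_end_systole)
        assert v0 == pytest.approx(138.0, abs=0.1)
        assert ves == pytest.approx(138.0 * (1 - 0.51), abs=0.2)

    def test_watertight_surface_volume(self):
        """Divergence-theorem volume of the generated surface vs analytic."""
        cfg = PhantomConfig(septal_bulge_amplitude=0.0, target_edv_ml=None)
        lv = build_phantom(cfg)
        verts, faces = lv.endo_surface(0.0, n_theta=128, n_z=128)
        a, b, c = cfg.endo_semi_axes_ed
        exact = truncated_ellipsoid_volume(a, b, c, cfg.base_truncation_fraction)
        assert surface_volume_ml(verts, faces) * 1000 == pytest.approx(
            exact, rel=0.005
        )

    def test_self_intersecting_bulge_rejected(self):
        with pytest.raises(ValueError, match="bulge"):
            build_phantom(PhantomConfig(septal_bulge_amplitude=30.0,
                                        target_edv_ml=None))

    @pytest.mark.parametrize(
        "bad",
        [
            dict(target_EF=120.0),
            dict(systole_duration=1.5),
            dict(endo_semi_axes_ed=(0.0, 24.0, 64.0)),
            dict(septal_bulge_amplitude=-1.0),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            PhantomConfig(**bad).validate()


class TestMotion:
    def test_zero_ef_is_static(self):
        lv = build_phantom(PhantomConfig(target_EF=0.0))
        v1, _ = lv.endo_surface(0.0)[0], None
        for t in (0.1, 0.25, 0.4, 0.7):
            assert np.allclose(lv.endo_surface(t)[0], v1)

    def test_displacement_zero_at_end_systole(self, default_lv):
        _, _, disp = ground_truth(default_lv, default_lv.t_end_systole)
        assert np.abs(disp).max() == 0.0

    def test_ef_from_ground_truth(self, default_lv):
        """EF from surface-integral volumes matches the configured target."""
        verts0, faces = default_lv.endo_surface(0.0, 128, 128)
        verts1, _ = default_lv.endo_surface(default_lv.t_end_systole, 128, 128)
        edv = surface_volume_ml(verts0, faces)
        esv = surface_volume_ml(verts1, faces)
        ef = 100 * (edv - esv) / edv
        assert ef == pytest.approx(default_lv.config.target_EF, abs=0.5)

    def test_volume_monotone_during_systole(self, default_lv):
        t = np.linspace(0, default_lv.t_end_systole, 41)
        v = default_lv.volume_fraction(t)
        assert np.all(np.diff(v) <= 1e-12)


class TestRendering:
    def test_pure_tissue_pixels_exact(self, noiseless_lv, noiseless_series):
        """Noise-free pixels deep inside a tissue carry its exact gray level."""
        lv = noiseless_lv
        blood, myo, bg = lv.config.intensities
        sa = noiseless_series[0]
        # voxel at the cavity center, mid-ventricle slice, frame 0
        z_slices = sa.origins[:, 2]
        isl = int(np.argmin(np.abs(z_slices - 0.5 * (lv.z_apex + lv.z_base))))
        pw = sa.pixel_world(isl)
        d = np.linalg.norm(pw[..., :2], axis=-1)
        ic = np.unravel_index(np.argmin(d), d.shape)
        assert sa.data[0, isl][ic] == blood
        corner = sa.data[0, isl][0, 0]
        assert corner == bg

    def test_seeded_render_bit_identical(self, default_lv):
        s1 = render_cine(default_lv)
        s2 = render_cine(default_lv)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.data, b.data)

    def test_series_layout(self, default_lv, noiseless_series):
        labels = {s.label for s in noiseless_series}
        assert labels == {"short-axis", "2-chamber", "3-chamber", "4-chamber"}
        sa = next(s for s in noiseless_series if s.label == "short-axis")
        assert len(sa.times) == 20
        spacing = np.diff(sa.origins[:, 2])
        assert np.allclose(np.abs(spacing), 8.0)
        la = next(s for s in noiseless_series if s.label == "2-chamber")
        assert len(la.times) == 30
        assert la.data.shape[1] == 1

    def test_sa_stack_underresolves_bulge(self, noiseless_lv):
        """The default bulge sits between two short-axis slices."""
        from ventriflow.phantom import sa_slice_positions

        zs = sa_slice_positions(noiseless_lv)
        gaps = np.abs(zs - noiseless_lv.bulge_z)
        assert gaps.min() == pytest.approx(4.0, abs=0.5)

    def test_ground_truth_labels(self, noiseless_lv):
        lv = noiseless_lv
        lab = lv.tissue(np.array([[0.0, 0.0, 0.5 * (lv.z_apex + lv.z_base)],
                                  [100.0, 100.0, 0.0]]), 0.0)
        assert lab[0] == BLOOD and lab[1] == BACKGROUND
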