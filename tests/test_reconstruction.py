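"""Segmentation, level sets, registration, and the volume curve."""

import numpy as np
import pytest

from ventriflow.fusion import GridSpec
from ventriflow.phantom import render_volume
from ventriflow.reconstruction import (
    build_levelset, dice, register_frames, segment_myocardium,
    select_reference_frame, surface_from_mask, surface_volume,
    volume_curve_from_surfaces, DisplacementField,
)


def _sphere_grid(n=48, spacing=2.0):
    origin = -spacing * (n - 1) / 2.0 * np.ones(3)
    g = GridSpec(origin=origin, shape=(n, n, n), spacing=spacing)
    ii, jj, kk = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
    pts = origin + spacing * np.stack([ii, jj, kk], -1)
    return g, np.linalg.norm(pts, axis=-1), pts


class TestSegmentation:
    def test_binary_ellipsoid_exact(self):
        """Two-intensity image: the mask equals the bright voxel set."""
        g, r, _ = _sphere_grid(32, 2.0)
        truth = r <= 20.0
        img = np.where(truth, 200.0, 20.0)
        endo, epi = segment_myocardium(img)
        assert np.array_equal(endo, truth)

    def test_phantom_frame_dice(self, noiseless_lv, noiseless_series):
        from ventriflow.fusion import fuse_series

        fused = fuse_series(noiseless_series, frames_out=1)
        endo, epi = segment_myocardium(fused.frames[0], fused.coverage)
        lab = render_volume(noiseless_lv, fused.grid.origin, fused.grid.shape,
                            fused.grid.spacing, 0.0, as_intensity=False)
        assert dice(endo, lab == 2) >= 0.95
        assert np.all(epi[endo])

    def test_external_masks_pass_through(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[1:3, 1:3, 1:3] = True
        endo, epi = segment_myocardium(np.zeros((4, 4, 4)), masks=(a, a))
        assert endo is a and epi is a

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError):
            segment_myocardium(np.zeros((8, 8, 8)))


class TestLevelSet:
    def test_concentric_spheres_signed_distance(self):
        g, r, _ = _sphere_grid(48, 2.0)
        phi = build_levelset(r <= 20, r <= 30, g.spacing)
        assert phi[r < 2].mean() == pytest.approx(20.0, abs=g.spacing)
        mid = (r > 24) & (r < 26)
        assert phi[mid].mean() == pytest.approx(-5.0, abs=g.spacing)

    def test_zero_level_matches_spheres(self):
        """Marching cubes on the shell masks reproduces the two radii."""
        g, r, pts = _sphere_grid(48, 2.0)
        endo = r <= 20
        verts, faces = surface_from_mask(endo, g)
        rv = np.linalg.norm(verts - (g.origin + 0), axis=1)
        rad = np.linalg.norm(verts, axis=1)
        assert np.abs(rad - 20.0).max() <= 2.0 * g.spacing

    def test_endo_outside_epi_rejected(self):
        g, r, _ = _sphere_grid(24, 2.0)
        with pytest.raises(ValueError):
            build_levelset(r <= 20, r <= 10, g.spacing)


class TestRegistration:
    def test_identity_is_exact(self):
        g, r, _ = _sphere_grid(40, 2.0)
        phi = build_levelset(r <= 20, r <= 30, g.spacing)
        df = register_frames(np.stack([phi, phi]), 0, g, [0.0, 0.1],
                             reg_spacing=2.0, iterations=30)
        assert np.abs(df.disp[1]).max() < 0.1
        assert np.abs(df.disp[0]).max() == 0.0

    def test_translation_recovered(self):
        """A rigid 3 mm shift of the shell is recovered within 0.3 mm."""
        n, sp = 72, 1.0
        origin = -sp * (n - 1) / 2.0 * np.ones(3)
        g = GridSpec(origin=origin, shape=(n, n, n), spacing=sp)
        ii, jj, kk = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
        pts = origin + sp * np.stack([ii, jj, kk], -1)
        r = np.linalg.norm(pts, axis=-1)
        rs = np.linalg.norm(pts - np.array([3.0, 0, 0]), axis=-1)
        phi0 = build_levelset(r <= 20, r <= 30, sp)
        phi1 = build_levelset(rs <= 20, rs <= 30, sp)
        df = register_frames(np.stack([phi0, phi1]), 0, g, [0.0, 0.1],
                             reg_spacing=1.0, iterations=150, sigma_mm=2.0)
        shell = (r >= 20.5) & (r <= 29.5)
        err = np.abs(df.disp[1][shell] - np.array([3.0, 0.0, 0.0]))
        assert err.max() < 0.3

    def test_single_frame_rejected(self):
        g, r, _ = _sphere_grid(16, 2.0)
        phi = build_levelset(r <= 10, r <= 14, g.spacing)
        with pytest.raises(ValueError):
            register_frames(phi[None], 0, g, [0.0])


class TestVolumeCurve:
    def test_unit_cube(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
             [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1.0]]
        )
        faces = np.array(
            [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
             [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
             [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]]
        )
        assert surface_volume(verts, faces) == pytest.approx(1.0)

    def test_sphere_volume(self):
        g, r, _ = _sphere_grid(64, 0.5)
        verts, faces = surface_from_mask(r <= 10.0, g)
        assert surface_volume(verts, faces) == pytest.approx(
            4188.79, rel=0.005
        )

    def test_constant_displacement_keeps_volume(self):
        g, r, _ = _sphere_grid(32, 2.0)
        verts, faces = surface_from_mask(r <= 15.0, g)
        disp = DisplacementField(
            disp=np.zeros((3,) + g.shape + (3,)), grid=g,
            reference_index=0, frame_times=np.array([0.0, 0.1, 0.2]),
        )
        disp.disp[1] = 5.0  # uniform shift
        vols, spline = volume_curve_from_surfaces(verts, faces, disp)
        assert np.allclose(vols, vols[0], rtol=1e-9)
        assert spline(0.05) == pytest.approx(vols[0], rel=1e-3)

    def test_reference_selection(self):
        masks = [np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool),
                 np.ones((4, 4, 4), bool)]
        masks[1][:2] = True
        assert select_reference_frame(masks) == 1
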