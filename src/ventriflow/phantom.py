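"""Ground-truthed moving left-ventricle phantom and cine-MRI renderer.

The phantom is a thick-walled truncated ellipsoid with a configurable
septal bulge (hypertrophy growing into the cavity), contracting through
systole with an affine motion law: in-plane scaling k(t) and long-axis
scaling l(t) = k(t)^gamma about the base plane, with the scale chosen so
that the cavity volume follows a C^1 smoothstep from EDV to
ESV = EDV (1 - EF/100).  Because the motion is affine, the volume law is
exact, and ground-truth volumes and displacements are available in closed
form for every stage of the downstream pipeline to be validated against.

The renderer produces the acquisition layout of routine cardiac cine-MRI:
one volumetric short-axis stack (8 mm slice spacing and thickness, 1 mm
in-plane, one heartbeat at 20 frames) and three single-slice long-axis
views (two-/three-/four-chamber, 20 or 30 frames), each as timed, oriented
2D slices with three tissue gray levels plus seeded Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

BACKGROUND, MYOCARDIUM, BLOOD = 0, 1, 2


@dataclass
class PhantomConfig:
    """Morphology, motion and acquisition parameters of the phantom."""

    endo_semi_axes_ed: tuple[float, float, float] = (24.0, 24.0, 64.0)  # mm
    base_truncation_fraction: float = 0.85
    wall_thickness_base: float = 10.0  # mm
    septal_bulge_amplitude: float = 12.0  # mm, hypertrophy into the cavity
    septal_bulge_theta: float = 0.0  # rad, azimuth of the septum
    septal_bulge_z: float | None = None  # mm; default: base - 16 mm
    septal_bulge_sigma_theta: float = 0.7  # rad
    septal_bulge_sigma_z: float = 9.0  # mm
    target_EF: float = 51.0  # percent
    target_edv_ml: float | None = 138.0  # autoscale semi-axes when set
    long_shortening_exponent: float = 0.7  # l(t) = k(t)^gamma
    heartbeat_period: float = 1.0  # s
    systole_duration: float = 0.4  # s
    frames_per_beat: int = 20  # short-axis temporal resolution
    la_frames_per_beat: int = 30  # long-axis temporal resolution
    pixel_spacing: float = 1.0  # mm
    sa_slice_spacing: float = 8.0  # mm (= thickness)
    slice_thickness: float = 8.0  # mm
    noise_sigma: float = 5.0  # gray levels
    intensities: tuple[float, float, float] = (200.0, 90.0, 20.0)  # blood, myo, bg
    seed: int = 0
    # landmark geometry
    aortic_annulus_radius: float = 11.0  # mm
    mitral_annulus_radius: float = 11.0  # mm
    mitral_center_offset: float = 5.5  # mm toward the lateral wall
    mitral_saddle_height: float = 2.5  # mm

    def validate(self) -> None:
        a, b, c = self.endo_semi_axes_ed
        if min(a, b, c) <= 0:
            raise ValueError("semi-axes must be positive")
        if not 0.0 < self.base_truncation_fraction < 1.0:
            raise ValueError("base_truncation_fraction must be in (0, 1)")
        if not 0.0 <= self.target_EF < 100.0:
            raise ValueError("target_EF must be in [0, 100)")
        if not self.systole_duration < self.heartbeat_period:
            raise ValueError("systole must be shorter than the heartbeat")
        if self.septal_bulge_amplitude < 0:
            raise ValueError("septal_bulge_amplitude must be >= 0")
        if self.wall_thickness_base <= 0:
            raise ValueError("wall thickness must be positive")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


class AnalyticLV:
    """Analytic moving LV: surfaces, tissue labels, landmarks, ground truth."""

    def __init__(self, config: PhantomConfig):
        config.validate()
        self.config = config
        self.a, self.b, self.c = config.endo_semi_axes_ed
        self._finalize()
        if config.target_edv_ml is not None:
            self._scale_to_edv(config.target_edv_ml * 1000.0)

    def _finalize(self) -> None:
        cfg = self.config
        self.z_base = (2.0 * cfg.base_truncation_fraction - 1.0) * self.c
        self.z_apex = -self.c
        self.wall = cfg.wall_thickness_base
        self.bulge_z = (
            cfg.septal_bulge_z
            if cfg.septal_bulge_z is not None
            else self.z_base - 16.0
        )
        if self._min_endo_radius() <= 0.5:
            raise ValueError(
                "septal bulge too large: endocardium self-intersects"
            )
        self.edv = self._cavity_volume_ed()

    def _scale_to_edv(self, target_mm3: float) -> None:
        for _ in range(6):
            s = (target_mm3 / self.edv) ** (1.0 / 3.0)
            self.a, self.b, self.c = s * self.a, s * self.b, s * self.c
            self._finalize()
            if abs(self.edv - target_mm3) < 50.0:  # 0.05 ml
                break

    # -- end-diastolic shape ----------------------------------------------
    def _ellipse_radius(self, theta, z, a, b, c):
        s2 = 1.0 - (np.asarray(z) / c) ** 2
        s = np.sqrt(np.clip(s2, 0.0, None))
        re = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        return s * re

    def endo_radius_ed(self, theta, z):
        """Cavity radius at azimuth theta, height z (ED configuration)."""
        cfg = self.config
        r = self._ellipse_radius(theta, z, self.a, self.b, self.c)
        if cfg.septal_bulge_amplitude > 0:
            dth = np.angle(np.exp(1j * (np.asarray(theta) - cfg.septal_bulge_theta)))
            bump = np.exp(
                -((dth / cfg.septal_bulge_sigma_theta) ** 2)
                - (((np.asarray(z) - self.bulge_z) / cfg.septal_bulge_sigma_z) ** 2)
            )
            r = r - cfg.septal_bulge_amplitude * bump
        return r

    def epi_radius_ed(self, theta, z):
        w = self.wall
        return self._ellipse_radius(theta, z, self.a + w, self.b + w, self.c + w)

    def _min_endo_radius(self) -> float:
        """Smallest cavity radius in the bulge band (self-intersection guard).

        The radius vanishes at the apex by construction, so only the band
        around the bulge is probed.
        """
        cfg = self.config
        if cfg.septal_bulge_amplitude == 0:
            return np.inf
        th = np.linspace(-np.pi, np.pi, 181)
        lo = max(self.z_apex + 1.0, self.bulge_z - 3 * cfg.septal_bulge_sigma_z)
        hi = min(self.z_base, self.bulge_z + 3 * cfg.septal_bulge_sigma_z)
        if hi <= lo:
            return np.inf
        z = np.linspace(lo, hi, 120)
        return float(self.endo_radius_ed(th[:, None], z[None, :]).min())

    def _cavity_volume_ed(self) -> float:
        th = np.linspace(-np.pi, np.pi, 512, endpoint=False)
        z = np.linspace(self.z_apex, self.z_base, 600)
        r = self.endo_radius_ed(th[:, None], z[None, :])
        area = 0.5 * np.trapezoid(
            np.vstack([r**2, r[:1] ** 2]), np.append(th, np.pi), axis=0
        )
        return float(np.trapezoid(area, z))

    # -- motion law --------------------------------------------------------
    def volume_fraction(self, t):
        """v(t) = V(t)/EDV along the smoothstep systole/diastole law."""
        cfg = self.config
        t = np.asarray(t, dtype=float) % cfg.heartbeat_period
        s_sys = _smoothstep(t / cfg.systole_duration)
        s_dia = _smoothstep(
            (cfg.heartbeat_period - t)
            / (cfg.heartbeat_period - cfg.systole_duration)
        )
        shape = np.where(t <= cfg.systole_duration, s_sys, s_dia)
        return 1.0 - (cfg.target_EF / 100.0) * shape

    def scales(self, t):
        """(k, l): in-plane and long-axis affine contraction factors."""
        gamma = self.config.long_shortening_exponent
        v = self.volume_fraction(t)
        k = v ** (1.0 / (2.0 + gamma))
        return k, k**gamma

    @property
    def t_end_systole(self) -> float:
        return self.config.systole_duration

    def map_points(self, pts_ed: np.ndarray, t: float) -> np.ndarray:
        """Affine motion map: ED configuration -> configuration at time t."""
        k, l = self.scales(t)
        out = np.array(pts_ed, dtype=float, copy=True)
        out[..., 0] *= k
        out[..., 1] *= k
        out[..., 2] = self.z_base + l * (out[..., 2] - self.z_base)
        return out

    def unmap_points(self, pts: np.ndarray, t: float) -> np.ndarray:
        k, l = self.scales(t)
        out = np.array(pts, dtype=float, copy=True)
        out[..., 0] /= k
        out[..., 1] /= k
        out[..., 2] = self.z_base + (out[..., 2] - self.z_base) / l
        return out

    # -- queries -----------------------------------------------------------
    def tissue(self, pts: np.ndarray, t: float) -> np.ndarray:
        """Tissue labels (BACKGROUND/MYOCARDIUM/BLOOD) at world points."""
        p = self.unmap_points(np.atleast_2d(pts), t)
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        rho = np.hypot(x, y)
        th = np.arctan2(y, x)
        lab = np.zeros(len(p), dtype=np.uint8)
        below_base = z <= self.z_base
        in_epi = below_base & (z >= -(self.c + self.wall))
        zc_epi = np.clip(z, -(self.c + self.wall) + 1e-9, self.z_base)
        r_epi = self.epi_radius_ed(th, zc_epi)
        in_epi &= rho <= r_epi
        lab[in_epi] = MYOCARDIUM
        in_cav = below_base & (z >= self.z_apex)
        zc = np.clip(z, self.z_apex + 1e-9, self.z_base)
        r_en = self.endo_radius_ed(th, zc)
        in_cav &= rho <= r_en
        lab[in_cav] = BLOOD
        return lab

    def endo_surface(self, t: float, n_theta: int = 96, n_z: int = 80):
        """Closed endocardial surface at time t: (vertices, faces)."""
        th = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
        # cluster z samples toward the apex for decent triangle shapes
        s = np.linspace(0.0, 1.0, n_z)
        z = self.z_apex + (self.z_base - self.z_apex) * np.sin(0.5 * np.pi * s) ** 2
        z[0] = self.z_apex + 1.0e-6
        r = self.endo_radius_ed(th[None, :], z[:, None].repeat(n_theta, 1))
        ring = np.stack(
            [r * np.cos(th)[None, :], r * np.sin(th)[None, :],
             np.repeat(z[:, None], n_theta, 1)], axis=-1
        )
        verts = [np.array([[0.0, 0.0, self.z_apex]])]
        verts.append(ring.reshape(-1, 3))
        verts.append(np.array([[0.0, 0.0, self.z_base]]))
        v = np.vstack(verts)
        faces = []
        for k in range(n_theta):  # apex fan
            faces.append((0, 1 + (k + 1) % n_theta, 1 + k))
        for i in range(n_z - 1):
            o0, o1 = 1 + i * n_theta, 1 + (i + 1) * n_theta
            for k in range(n_theta):
                k1 = (k + 1) % n_theta
                faces.append((o0 + k, o0 + k1, o1 + k))
                faces.append((o0 + k1, o1 + k1, o1 + k))
        top = 1 + n_z * n_theta
        o = 1 + (n_z - 1) * n_theta
        for k in range(n_theta):  # base cap fan
            faces.append((top, o + k, o + (k + 1) % n_theta))
        return self.map_points(v, t), np.asarray(faces, dtype=np.int64)

    def landmarks(self, t: float, n_ring: int = 64) -> dict:
        """Anatomical landmark points/rings at time t."""
        cfg = self.config
        phi = np.linspace(-np.pi, np.pi, n_ring, endpoint=False)
        aortic = np.column_stack(
            [cfg.aortic_annulus_radius * np.cos(phi),
             cfg.aortic_annulus_radius * np.sin(phi),
             np.full(n_ring, self.z_base)]
        )
        mc = -cfg.mitral_center_offset  # lateral side, opposite the septum
        mitral = np.column_stack(
            [mc + cfg.mitral_annulus_radius * np.cos(phi),
             cfg.mitral_annulus_radius * np.sin(phi),
             self.z_base + cfg.mitral_saddle_height * np.cos(2 * phi)]
        )
        th0 = cfg.septal_bulge_theta
        septal = np.array(
            [np.cos(th0), np.sin(th0), 0.0]
        ) * self.endo_radius_ed(th0, self.bulge_z)
        septal[2] = self.bulge_z
        # deterministic analog of the right-coronary ostium: the septal-most
        # point of the aortic annulus ring
        ostium = np.array(
            [cfg.aortic_annulus_radius * np.cos(th0),
             cfg.aortic_annulus_radius * np.sin(th0), self.z_base]
        )
        lm = {
            "apex": np.array([0.0, 0.0, self.z_apex]),
            "septal_center": septal,
            "aortic_annulus": aortic,
            "mitral_annulus": mitral,
            "rc_ostium": ostium,
        }
        return {k: self.map_points(v, t) for k, v in lm.items()}


def build_phantom(config: PhantomConfig) -> AnalyticLV:
    """Construct the analytic moving LV from its configuration."""
    return AnalyticLV(config)


def ground_truth(lv: AnalyticLV, t: float, n_sample: int = 2000):
    """Exact cavity volume [ml] and endocardial displacement at time t.

    The displacement is reported with respect to the end-systolic
    configuration (the registration reference downstream): sample points on
    the end-systolic endocardium together with their motion vectors to
    time t.  At t = end systole the displacement vanishes identically.
    """
    cfg = lv.config
    if not 0.0 <= t <= cfg.heartbeat_period:
        raise ValueError("t outside the heartbeat")
    vol_ml = lv.edv * lv.volume_fraction(t) / 1000.0
    rng = np.random.default_rng(12345)
    th = rng.uniform(-np.pi, np.pi, n_sample)
    z = rng.uniform(lv.z_apex + 1e-3, lv.z_base, n_sample)
    r = lv.endo_radius_ed(th, z)
    pts_ed = np.column_stack([r * np.cos(th), r * np.sin(th), z])
    t_es = lv.t_end_systole
    pts_es = lv.map_points(pts_ed, t_es)
    disp = lv.map_points(pts_ed, t) - pts_es
    return float(vol_ml), pts_es, disp


def render_volume(
    lv: AnalyticLV,
    origin: np.ndarray,
    shape: tuple[int, int, int],
    spacing: float,
    t: float,
    as_intensity: bool = True,
) -> np.ndarray:
    """Direct voxelization of the phantom on an axis-aligned grid.

    Serves as the resolution-limit oracle for the fusion stage and as the
    ground-truth mask for segmentation tests (``as_intensity=False`` returns
    tissue labels).
    """
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    pts = np.asarray(origin) + spacing * np.stack(
        [ii, jj, kk], axis=-1
    ).reshape(-1, 3)
    lab = lv.tissue(pts, t)
    if not as_intensity:
        return lab.reshape(shape)
    blood_i, myo_i, bg_i = lv.config.intensities
    lut = np.array([bg_i, myo_i, blood_i])
    return lut[lab].reshape(shape)


# ---------------------------------------------------------------------------
# cine-MRI rendering
# ---------------------------------------------------------------------------


@dataclass
class CineSeries:
    """Timed, oriented 2D slices from one acquisition.

    data[it, islice, i, j] is the gray level of pixel (i, j): world position
    origins[islice] + i * spacing * row_dir + j * spacing * col_dir.
    """

    label: str  # short-axis | 2-chamber | 3-chamber | 4-chamber
    times: np.ndarray  # (nt,) s
    data: np.ndarray  # (nt, ns, ni, nj)
    origins: np.ndarray  # (ns, 3) mm
    row_dir: np.ndarray  # (3,)
    col_dir: np.ndarray  # (3,)
    pixel_spacing: float  # mm
    thickness: float  # mm

    @property
    def normal(self) -> np.ndarray:
        n = np.cross(self.row_dir, self.col_dir)
        return n / np.linalg.norm(n)

    @property
    def temporal_resolution(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def pixel_world(self, islice: int) -> np.ndarray:
        """(ni, nj, 3) world coordinates of pixel centers."""
        ni, nj = self.data.shape[2:]
        ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
        return (
            self.origins[islice]
            + ii[..., None] * self.pixel_spacing * self.row_dir
            + jj[..., None] * self.pixel_spacing * self.col_dir
        )


def _render_series(lv, config, label, times, origins, row_dir, col_dir,
                   ni, nj, rng):
    blood_i, myo_i, bg_i = config.intensities
    lut = np.array([bg_i, myo_i, blood_i])
    normal = np.cross(row_dir, col_dir)
    normal = normal / np.linalg.norm(normal)
    th = config.slice_thickness
    offsets = np.array([-th / 3.0, 0.0, th / 3.0])
    data = np.empty((len(times), len(origins), ni, nj))
    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    for isl, orig in enumerate(origins):
        base_pts = (
            orig
            + ii[..., None] * config.pixel_spacing * row_dir
            + jj[..., None] * config.pixel_spacing * col_dir
        ).reshape(-1, 3)
        for it, t in enumerate(times):
            acc = np.zeros(len(base_pts))
            for off in offsets:
                acc += lut[lv.tissue(base_pts + off * normal, t)]
            data[it, isl] = (acc / len(offsets)).reshape(ni, nj)
    if config.noise_sigma > 0:
        data = data + rng.normal(0.0, config.noise_sigma, data.shape)
    return CineSeries(
        label=label,
        times=np.asarray(times, dtype=float),
        data=data,
        origins=np.asarray(origins, dtype=float),
        row_dir=np.asarray(row_dir, dtype=float),
        col_dir=np.asarray(col_dir, dtype=float),
        pixel_spacing=config.pixel_spacing,
        thickness=config.slice_thickness,
    )


def sa_slice_positions(lv: AnalyticLV) -> np.ndarray:
    """Axial positions of the short-axis stack (descending from the base)."""
    cfg = lv.config
    sp = cfg.sa_slice_spacing
    z_top = lv.z_base + sp / 2.0
    z_bot = lv.z_apex - lv.wall - sp / 2.0
    n = int(np.ceil((z_top - z_bot) / sp)) + 1
    return z_top - sp * np.arange(n)


def render_cine(lv: AnalyticLV, config: PhantomConfig | None = None) -> list[CineSeries]:
    """Render the phantom into the standard multi-view cine-MRI layout."""
    config = config or lv.config
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    T = config.heartbeat_period
    half = float(np.ceil(max(lv.a, lv.b) + lv.wall + 8.0))
    n_xy = int(2 * half / config.pixel_spacing) + 1

    series = []
    # short-axis volumetric stack
    zs = sa_slice_positions(lv)
    sa_origins = np.column_stack(
        [np.full(len(zs), -half), np.full(len(zs), -half), zs]
    )
    sa_times = np.arange(config.frames_per_beat) * T / config.frames_per_beat
    series.append(
        _render_series(
            lv, config, "short-axis", sa_times, sa_origins,
            np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]),
            n_xy, n_xy, rngs[0],
        )
    )
    # long-axis single-slice views: planes containing the LV long axis.
    # The 3-chamber plane passes through the septum (bulge azimuth).
    z_lo = lv.z_apex - lv.wall - 8.0
    z_hi = lv.z_base + 8.0
    n_z = int((z_hi - z_lo) / config.pixel_spacing) + 1
    la_times = np.arange(config.la_frames_per_beat) * T / config.la_frames_per_beat
    for rng, (label, chi) in zip(
        rngs[1:],
        [("3-chamber", config.septal_bulge_theta),
         ("4-chamber", config.septal_bulge_theta + np.pi / 3.0),
         ("2-chamber", config.septal_bulge_theta + 2.0 * np.pi / 3.0)],
    ):
        u = np.array([np.cos(chi), np.sin(chi), 0.0])
        origin = np.array([-half * u[0], -half * u[1], z_lo])
        series.append(
            _render_series(
                lv, config, label, la_times, origin[None, :],
                u, np.array([0.0, 0.0, 1.0]), n_xy, n_z, rng,
            )
        )
    return series


# ---------------------------------------------------------------------------
# on-disk layout: one NIfTI per frame + JSON sidecar per series
# ---------------------------------------------------------------------------


def save_cine(series: list[CineSeries], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in series:
        tag = s.label.replace("-", "")
        meta = {
            "label": s.label,
            "times": s.times.tolist(),
            "origins": s.origins.tolist(),
            "row_dir": s.row_dir.tolist(),
            "col_dir": s.col_dir.tolist(),
            "pixel_spacing": s.pixel_spacing,
            "thickness": s.thickness,
            "n_frames": int(len(s.times)),
        }
        (out / f"{tag}.json").write_text(json.dumps(meta, indent=1))
        normal = s.normal
        for it in range(len(s.times)):
            vol = np.transpose(s.data[it], (1, 2, 0))  # (i, j, slice)
            aff = np.eye(4)
            aff[:3, 0] = s.row_dir * s.pixel_spacing
            aff[:3, 1] = s.col_dir * s.pixel_spacing
            step = (
                s.origins[1] - s.origins[0]
                if len(s.origins) > 1
                else normal * s.thickness
            )
            aff[:3, 2] = step
            aff[:3, 3] = s.origins[0]
            nib.save(
                nib.Nifti1Image(vol.astype(np.float32), aff),
                out / f"{tag}_f{it:03d}.nii.gz",
            )


def load_cine(in_dir: str | Path) -> list[CineSeries]:
    out = []
    for meta_path in sorted(Path(in_dir).glob("*.json")):
        meta = json.loads(meta_path.read_text())
        if "n_frames" not in meta:
            continue  # not a series sidecar (e.g. a stage manifest)
        tag = meta_path.stem
        frames = []
        for it in range(meta["n_frames"]):
            img = nib.load(Path(in_dir) / f"{tag}_f{it:03d}.nii.gz")
            frames.append(np.transpose(np.asarray(img.dataobj), (2, 0, 1)))
        out.append(
            CineSeries(
                label=meta["label"],
                times=np.asarray(meta["times"]),
                data=np.stack(frames),
                origins=np.asarray(meta["origins"]),
                row_dir=np.asarray(meta["row_dir"]),
                col_dir=np.asarray(meta["col_dir"]),
                pixel_spacing=meta["pixel_spacing"],
                thickness=meta["thickness"],
            )
        )
    return out
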