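"""Two-session digital thigh phantom with known ground truth.

The generator emulates the statistical structure of a slowly progressing
neuromuscular cohort measured twice about a year apart:

* 12 thigh muscles per side, drawn as smooth convex cross-sections (a
  weighted Voronoi partition of a thigh disk) stacked over the slice
  direction;
* per-muscle baseline fat fraction from a two-component mixture -- a
  low-infiltration mode (~25%) to which the adductor longus and the short
  head of biceps femoris always belong, and a high mode (~42%);
* a fat-fraction progression applied between sessions (high-mode muscles
  progress at the nominal ~1.3%/year; low-mode muscles are static), with a
  mild cross-sectional atrophy;
* session B repositioning: a rigid transform plus a smooth b-spline warp
  and a shifted field of view, so the two sessions do not cover identical
  anatomy;
* MR signal synthesis for the three sequences (complex 4-echo Dixon with a
  multi-peak fat spectrum, 17-echo spin-echo train via the EPG model, and
  a 42-volume DWI scheme), with complex Gaussian noise on the complex
  Dixon data and Rician noise on magnitudes;
* stable clinical scores with test-retest noise only.

Image grids are scaled down from the acquisition matrix (default 64x64
in-plane at 1.5 mm instead of 320x320) to keep simulations tractable; the
slice geometry (25 Dixon / 13 T2 with 6 mm gap / 25 DWI slices, 6 mm thick)
is preserved.

A separate record-level generator (:func:`simulate_cohort_records`)
produces per-muscle summary outcomes directly -- no images -- for the
statistical power/calibration experiments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    LOW_FAT_MUSCLES,
    MUSCLES,
    MUSCLE_GROUPS,
    ComplexEchoSeries,
    DWISeries,
    MagnitudeEchoTrain,
    MuscleLabelMap,
    ScalarVolume,
    VolumeGeometry,
    write_volume,
)
from .dixon import FAT_SPECTRUM_6PEAK, FatSpectrum
from .dti import build_bscheme
from .t2epg import T1_FAT_MS, T1_MUSCLE_MS, epg_echo_train

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "build_phantom",
    "synthesize_dixon",
    "synthesize_t2_train",
    "synthesize_dwi",
    "synthesize_clinical",
    "simulate_cohort_records",
    "generate_dataset",
    "parse_label_name",
]

DIXON_ECHO_TIMES_MS = (2.6, 3.36, 4.12, 4.88)
T2_ECHO_SPACING_MS = 7.6
T2_N_ECHOES = 17


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of the synthetic cohort.

    Progression magnitudes, relaxation/diffusion means and the follow-up
    interval default to the cohort values; session repositioning defaults
    to a +-5 mm / +-3 deg rigid offset with a 2 mm smooth warp and a
    one-slice field-of-view shift.
    """

    n_subjects: int = 1
    muscles: tuple = MUSCLES
    sides: tuple = ("R",)
    # grids (scaled-down in-plane matrix, acquisition slice geometry)
    matrix: int = 96
    n_slices: int = 25
    voxel_inplane_mm: float = 1.5
    slice_thickness_mm: float = 6.0
    t2_matrix: int = 48
    t2_n_slices: int = 13
    t2_voxel_mm: float = 3.0
    t2_slice_gap_mm: float = 6.0
    dwi_matrix: int = 48
    dwi_n_slices: int = 25
    dwi_voxel_mm: float = 3.0
    # baseline fat-fraction mixture (fractions, not %)
    ff_low_mean: float = 0.25
    ff_high_mean: float = 0.42
    ff_low_sd: float = 0.05
    ff_high_sd: float = 0.07
    p_low_other: float = 0.2  # chance a non-designated muscle sits in the low mode
    # progression
    annual_ff_slope_pct: float = 1.3     # %FF per year, high-mode muscles
    low_mode_slope_pct: float = 0.0      # %FF per year, low-mode muscles
    ccsa_annual_change_cm2: float = -0.23
    followup_months: float = 13.1
    # tissue parameters
    t2_water_ms: float = 28.2
    t2_water_sd_ms: float = 1.0
    t2_fat_ms: float = 150.0
    md_mean: float = 1.35e-3
    md_sd: float = 0.03e-3
    fa_mean: float = 0.32
    fa_sd: float = 0.02
    t2star_ms: float = 25.0
    b0_amplitude_hz: float = 40.0
    b1_variation: float = 0.05
    ff_z_gradient: float = 0.06  # within-muscle proximal-distal FF span
    m0: float = 100.0
    # noise (signal units relative to m0=100)
    sigma_dixon: float = 0.0
    sigma_t2: float = 0.0
    sigma_dwi: float = 0.0
    # inter-session repositioning
    rigid_translation_mm: float = 5.0
    rigid_rotation_deg: float = 3.0
    warp_amplitude_mm: float = 2.0
    warp_spacing_mm: float = 30.0
    warp_in_plane: bool = True  # repositioning warps the thigh mostly in-plane
    fov_shift_slices: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.ff_low_mean < 1 and 0 < self.ff_high_mean < 1):
            raise ValueError("fat-fraction modes must lie in (0, 1)")
        for s in (self.sigma_dixon, self.sigma_t2, self.sigma_dwi):
            if s < 0:
                raise ValueError("noise sigma must be >= 0")


def parse_label_name(name: str) -> tuple[str, str]:
    """Split ``"<muscle>_<side>"`` into (muscle, side)."""
    muscle, side = name.rsplit("_", 1)
    return muscle, side


def _stable_hash(s: str) -> int:
    # process-independent (unlike builtin str hashing)
    return zlib.crc32(s.encode()) & 0x7FFFFFFF


def _stream_rng(spec: PhantomSpec, subject: int, *streams) -> np.random.Generator:
    ids = [spec.seed & 0x7FFFFFFF, subject]
    for s in streams:
        ids.append(_stable_hash(str(s)))
    return np.random.default_rng(ids)


@dataclass
class SessionDeformation:
    """Forward mapping A-world -> B-world: rigid followed by a smooth warp."""

    rotation: np.ndarray          # 3x3
    translation: np.ndarray       # (3,) mm
    center: np.ndarray            # (3,) mm, rotation center
    ctrl_disp: np.ndarray         # (3, nx, ny, nz) control-point displacements (mm)
    ctrl_origin: np.ndarray
    ctrl_spacing: float

    def _warp(self, pts: np.ndarray) -> np.ndarray:
        if self.ctrl_disp.size == 0:
            return np.zeros_like(pts)
        coords = (pts - self.ctrl_origin) / self.ctrl_spacing
        disp = np.empty_like(pts)
        for ax in range(3):
            disp[:, ax] = ndimage.map_coordinates(
                self.ctrl_disp[ax], coords.T, order=3, mode="nearest"
            )
        return disp

    def forward(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        rigid = (pts - self.center) @ self.rotation.T + self.center + self.translation
        return rigid + self._warp(pts)

    def inverse(self, pts: np.ndarray, n_iter: int = 25, tol: float = 1e-4) -> np.ndarray:
        """Fixed-point inversion of the composite transform."""
        pts = np.atleast_2d(pts)
        x = (pts - self.translation - self.center) @ self.rotation + self.center
        for _ in range(n_iter):
            err = self.forward(x) - pts
            if np.abs(err).max() < tol:
                break
            x = x - 0.7 * err
        return x

    @classmethod
    def identity(cls) -> "SessionDeformation":
        return cls(np.eye(3), np.zeros(3), np.zeros(3),
                   np.zeros((3, 0, 0, 0)), np.zeros(3), 1.0)


@dataclass
class PhantomTruth:
    """Everything the estimators are later asked to recover."""

    spec: PhantomSpec
    subject: int
    geometry: dict          # time -> Dixon-grid VolumeGeometry
    t2_geometry: dict
    dwi_geometry: dict
    labels: dict            # time -> MuscleLabelMap (native Dixon grid)
    maps: dict              # time -> {"ff","t2w","psi","t2star","md","fa","b1"} ScalarVolume
    principal_axis: dict    # time -> (X, Y, Z, 3) unit fibre direction
    deformation: SessionDeformation
    muscle_values: pd.DataFrame  # per muscle x side x time: true tissue values
    clinical: pd.DataFrame

    def label_ids(self) -> dict:
        return {v: k for k, v in self.labels["A"].label_names.items()}


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------


def _muscle_partition(spec: PhantomSpec, rng: np.random.Generator):
    """Weighted-Voronoi muscle layout inside a thigh disk, per side.

    Returns (seed_xy mm per side, weights, disk centre mm per side, radius mm).
    """
    n = len(spec.muscles)
    fov = spec.matrix * spec.voxel_inplane_mm
    radius = 0.42 * fov / max(len(spec.sides), 1) * (2 if len(spec.sides) == 1 else 1)
    radius = min(radius, 0.42 * fov)
    centres = []
    for i, _side in enumerate(spec.sides):
        if len(spec.sides) == 1:
            centres.append(np.array([fov / 2, fov / 2]))
        else:
            centres.append(np.array([fov * (0.27 + 0.46 * i), fov / 2]))
    ang = 2 * np.pi * (np.arange(n) + 0.5) / n + rng.uniform(-0.1, 0.1, n)
    rad = radius * (0.55 + rng.uniform(-0.05, 0.05, n))
    # larger anatomical muscles get heavier seeds (bigger cells)
    size_w = {"adductor_magnus": 1.5, "vastus_lateralis": 1.5, "semimembranosus": 1.2,
              "vastus_medialis": 1.2, "biceps_femoris_long": 1.1, "sartorius": 0.7,
              "rectus_femoris": 0.9, "gracilis": 0.8}
    weights = np.array([size_w.get(m, 1.0) for m in spec.muscles])
    seeds = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
    # muscle bellies drift and taper along the thigh: without this the
    # phantom is a near-cylinder and the through-plane alignment of two
    # sessions would be unconstrained by the image content
    drift = rng.uniform(-14.0, 14.0, (n, 2))        # mm over the full stack
    taper = rng.uniform(-0.3, 0.3, n)               # relative weight change
    return seeds, weights, centres, radius, drift, taper


def _draw_labels(spec: PhantomSpec, rng: np.random.Generator, geometry: VolumeGeometry,
                 shrink: float = 1.0, deformation: SessionDeformation | None = None):
    """Rasterise the muscle partition on a voxel grid.

    ``shrink`` scales the thigh radius (atrophy); ``deformation`` maps this
    session's world coordinates back to session-A anatomy space.
    """
    seeds, weights, centres, radius, drift, taper = _muscle_partition(spec, rng)
    shape = geometry.shape
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = geometry.voxel_to_world(pts)
    if deformation is not None:
        world = deformation.inverse(world)
    z_extent = spec.n_slices * spec.slice_thickness_mm
    zfrac = np.clip(world[:, 2] / max(z_extent, 1e-9), 0, 1)
    # the thigh narrows toward the knee: a monotone taper plus a soft bulge
    rz = radius * (1.06 - 0.12 * zfrac + 0.04 * np.sin(np.pi * zfrac))

    labels = np.zeros(len(pts), dtype=np.int16)
    names = {}
    lbl = 1
    for s_idx, side in enumerate(spec.sides):
        c = centres[s_idx]
        # atrophy contracts the whole cross-section about the limb axis
        # (muscles lose area themselves, not just the outer rim)
        d = (world[:, :2] - c) / shrink
        r2 = (d**2).sum(axis=1)
        inside = r2 <= rz**2
        zf = zfrac[inside, None]
        # seed positions and cell weights vary smoothly along the stack
        sx = seeds[None, :, 0] + drift[None, :, 0] * (zf - 0.5)
        sy = seeds[None, :, 1] + drift[None, :, 1] * (zf - 0.5)
        wz = weights[None, :] * (1.0 + taper[None, :] * (zf - 0.5))
        dist = np.hypot(d[inside, 0, None] - sx, d[inside, 1, None] - sy) / wz
        assign = dist.argmin(axis=1)
        labels[inside] = assign + lbl
        # stylised femur: a signal-free shaft whose radius and position vary
        # non-monotonically along the stack, anchoring through-plane
        # alignment the way real bony landmarks do (a monotone taper alone
        # is ambiguous between a z-shift and a scale change)
        fx = 0.18 * radius * (zf[:, 0] - 0.5)
        r_bone = radius * (0.14 + 0.06 * np.sin(2.0 * np.pi * zf[:, 0] + 0.7)
                           + 0.05 * zf[:, 0])
        bone = np.hypot(d[inside, 0] - fx, d[inside, 1]) < r_bone
        idx_inside = np.flatnonzero(inside)
        labels[idx_inside[bone]] = 0
        for m_idx, muscle in enumerate(spec.muscles):
            names[lbl + m_idx] = f"{muscle}_{side}"
        lbl += len(spec.muscles)
    return MuscleLabelMap(geometry, labels.reshape(shape), names)


def _make_deformation(spec: PhantomSpec, rng: np.random.Generator,
                      geometry: VolumeGeometry) -> SessionDeformation:
    if spec.rigid_translation_mm == 0 and spec.rigid_rotation_deg == 0 and spec.warp_amplitude_mm == 0:
        return SessionDeformation.identity()
    t = rng.uniform(-spec.rigid_translation_mm, spec.rigid_translation_mm, 3)
    t[2] *= 0.3  # smaller through-plane shift
    angles = np.deg2rad(rng.uniform(-spec.rigid_rotation_deg, spec.rigid_rotation_deg, 3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    extent = np.array(geometry.shape) * np.array(
        [geometry.voxel_size[0], geometry.voxel_size[1], geometry.slice_spacing]
    )
    centre = geometry.affine[:3, 3] + extent / 2
    n_ctrl = np.maximum((extent / spec.warp_spacing_mm).astype(int) + 3, 4)
    disp = rng.normal(0.0, spec.warp_amplitude_mm / 2.0, size=(3, *n_ctrl))
    disp = np.clip(disp, -spec.warp_amplitude_mm, spec.warp_amplitude_mm)
    if spec.warp_in_plane:
        disp[2] = 0.0
    origin = geometry.affine[:3, 3] - spec.warp_spacing_mm
    return SessionDeformation(R, t, centre, disp, origin, spec.warp_spacing_mm)


def _dixon_geometry(spec: PhantomSpec, origin=(0.0, 0.0, 0.0)) -> VolumeGeometry:
    return VolumeGeometry.from_params(
        (spec.voxel_inplane_mm, spec.voxel_inplane_mm, spec.slice_thickness_mm),
        (spec.matrix, spec.matrix, spec.n_slices),
        slice_gap=0.0, origin=origin,
    )


def _t2_geometry(spec: PhantomSpec, origin=(0.0, 0.0, 0.0)) -> VolumeGeometry:
    return VolumeGeometry.from_params(
        (spec.t2_voxel_mm, spec.t2_voxel_mm, spec.slice_thickness_mm),
        (spec.t2_matrix, spec.t2_matrix, spec.t2_n_slices),
        slice_gap=spec.t2_slice_gap_mm, origin=origin,
    )


def _dwi_geometry(spec: PhantomSpec, origin=(0.0, 0.0, 0.0)) -> VolumeGeometry:
    return VolumeGeometry.from_params(
        (spec.dwi_voxel_mm, spec.dwi_voxel_mm, spec.slice_thickness_mm),
        (spec.dwi_matrix, spec.dwi_matrix, spec.dwi_n_slices),
        slice_gap=0.0, origin=origin,
    )


def build_phantom(spec: PhantomSpec, subject: int = 0) -> PhantomTruth:
    """Construct ground truth for one subject at both time-points.

    Session B equals session A advanced by the per-muscle progression
    slopes, moved by the session deformation and re-gridded on a field of
    view shifted by ``fov_shift_slices``.  Fat fractions pushed outside
    [0, 1] by the slope are clamped.
    """
    rng_anat = _stream_rng(spec, subject, "anatomy")
    rng_tissue = _stream_rng(spec, subject, "tissue")
    interval_years = spec.followup_months / 12.0

    geomA = _dixon_geometry(spec)
    # session B: field of view shifted along the stack (and re-gridded)
    shift = spec.fov_shift_slices * spec.slice_thickness_mm
    geomB = _dixon_geometry(spec, origin=(0.0, 0.0, shift))
    deform = _make_deformation(spec, _stream_rng(spec, subject, "deformation"), geomA)

    # per muscle x side tissue truth
    rows = []
    values = {}
    for side in spec.sides:
        for muscle in spec.muscles:
            low = muscle in LOW_FAT_MUSCLES or (
                rng_tissue.uniform() < spec.p_low_other
            )
            if muscle in LOW_FAT_MUSCLES:
                low = True
            mean = spec.ff_low_mean if low else spec.ff_high_mean
            sd = spec.ff_low_sd if low else spec.ff_high_sd
            # the two designated muscles are consistently mildly infiltrated:
            # their draw is truncated at the 30% threshold
            hi = 0.30 if muscle in LOW_FAT_MUSCLES else 0.95
            ffA = float(np.clip(rng_tissue.normal(mean, sd), 0.02, hi))
            slope = spec.low_mode_slope_pct if low else spec.annual_ff_slope_pct
            ffB = float(np.clip(ffA + slope / 100.0 * interval_years, 0.0, 1.0))
            t2w = float(rng_tissue.normal(spec.t2_water_ms, spec.t2_water_sd_ms))
            md = float(rng_tissue.normal(spec.md_mean, spec.md_sd))
            fa = float(np.clip(rng_tissue.normal(spec.fa_mean, spec.fa_sd), 0.05, 0.9))
            values[(muscle, side)] = dict(ffA=ffA, ffB=ffB, t2w=t2w, md=md, fa=fa, low=low)
            for t, ff in (("A", ffA), ("B", ffB)):
                rows.append(dict(subject=subject, muscle=muscle, side=side,
                                 muscle_group=MUSCLE_GROUPS[muscle], time_point=t,
                                 low_mode=low, FF=100 * ff, T2=t2w,
                                 MD=md * 1e3, FA=fa))
    muscle_values = pd.DataFrame(rows)

    # atrophy: shrink the thigh radius so mean per-muscle CSA drops by the
    # nominal contractile-area change
    approx_csa_cm2 = np.pi * (0.42 * spec.matrix * spec.voxel_inplane_mm * 0.84) ** 2 / 100.0 / len(spec.muscles)
    rel = max(0.0, 1.0 + spec.ccsa_annual_change_cm2 * interval_years / max(approx_csa_cm2, 1e-9))
    shrinkB = float(np.sqrt(rel))

    labelsA = _draw_labels(spec, _seeded_copy(rng_anat), geomA)
    labelsB = _draw_labels(spec, _seeded_copy(rng_anat), geomB,
                           shrink=shrinkB, deformation=deform)

    # per-muscle proximal-distal FF gradient: fat infiltration varies along
    # the muscle belly, which also anchors through-plane registration
    grad_rng = _stream_rng(spec, subject, "ff_gradient")
    ff_grad = {key: grad_rng.uniform(-spec.ff_z_gradient, spec.ff_z_gradient)
               for key in values}

    def paint(labels: MuscleLabelMap, key_ff: str, use_deform: SessionDeformation | None):
        geom_l = labels.geometry
        shp = labels.geometry.shape
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shp), indexing="ij")
        pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
        world = geom_l.voxel_to_world(pts)
        if use_deform is not None:
            world = use_deform.inverse(world)
        z_extent = spec.n_slices * spec.slice_thickness_mm
        zfrac = np.clip(world[:, 2] / max(z_extent, 1e-9), 0, 1).reshape(shp)
        ff = np.zeros(shp)
        t2w = np.zeros(shp)
        md = np.zeros(shp)
        fa = np.zeros(shp)
        for lbl, name in labels.label_names.items():
            muscle, side = parse_label_name(name)
            v = values[(muscle, side)]
            m = labels.labels == lbl
            base = v[key_ff]
            vals = base + ff_grad[(muscle, side)] * (zfrac[m] - 0.5)
            # recentre so the label mean equals the reference value exactly
            vals += base - vals.mean()
            ff[m] = np.clip(vals, 0.0, 1.0)
            t2w[m] = v["t2w"]
            md[m] = v["md"]
            fa[m] = v["fa"]
        return ff, t2w, md, fa

    maps = {}
    principal = {}
    labels = {"A": labelsA, "B": labelsB}
    geoms = {"A": geomA, "B": geomB}
    for t in ("A", "B"):
        g = geoms[t]
        ff, t2w, md, fa = paint(labels[t], "ffA" if t == "A" else "ffB",
                                None if t == "A" else deform)
        shp = g.shape
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shp), indexing="ij")
        xs = (ii - shp[0] / 2) / shp[0]
        ys = (jj - shp[1] / 2) / shp[1]
        psi = spec.b0_amplitude_hz * (0.3 + 0.8 * xs + 0.5 * ys + 0.6 * (xs**2 + ys**2))
        b1 = 1.0 + spec.b1_variation * (xs + 0.5 * ys)
        t2star = np.full(shp, spec.t2star_ms)
        fg = labels[t].labels > 0
        maps[t] = {
            "ff": ScalarVolume(g, np.where(fg, ff, 0.0), name="ff"),
            "t2w": ScalarVolume(g, np.where(fg, t2w, 0.0), name="t2w"),
            "psi": ScalarVolume(g, psi, name="psi"),
            "t2star": ScalarVolume(g, t2star, name="t2star"),
            "md": ScalarVolume(g, np.where(fg, md, 0.0), name="md"),
            "fa": ScalarVolume(g, np.where(fg, fa, 0.0), name="fa"),
            "b1": ScalarVolume(g, b1, name="b1"),
        }
        # fibres run along the stack with a small in-plane tilt per muscle
        ax = np.zeros(shp + (3,))
        ax[..., 2] = 1.0
        for lbl, name in labels[t].label_names.items():
            muscle, side = parse_label_name(name)
            tilt_rng = np.random.default_rng(_stable_hash(f"{muscle}|{side}"))
            tilt = tilt_rng.uniform(-0.15, 0.15, 2)
            m = labels[t].labels == lbl
            ax[m, 0] = tilt[0]
            ax[m, 1] = tilt[1]
        ax /= np.linalg.norm(ax, axis=-1, keepdims=True)
        principal[t] = ax

    t2_geoms = {"A": _t2_geometry(spec), "B": _t2_geometry(spec, origin=(0.0, 0.0, shift))}
    dwi_geoms = {"A": _dwi_geometry(spec), "B": _dwi_geometry(spec, origin=(0.0, 0.0, shift))}
    clinical = synthesize_clinical(spec, subject)
    return PhantomTruth(
        spec=spec, subject=subject,
        geometry=geoms, t2_geometry=t2_geoms, dwi_geometry=dwi_geoms,
        labels=labels, maps=maps, principal_axis=principal,
        deformation=deform, muscle_values=muscle_values, clinical=clinical,
    )


def _seeded_copy(rng: np.random.Generator) -> np.random.Generator:
    # anatomy must be identical across sessions: clone the generator state
    return np.random.default_rng(rng.bit_generator.seed_seq)


def _sample_maps(truth: PhantomTruth, t: str, target: VolumeGeometry, names):
    """Sample session-t truth maps on another grid (piecewise-constant)."""
    src_geom = truth.geometry[t]
    shp = target.shape
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shp), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = target.voxel_to_world(pts)
    vox = src_geom.world_to_voxel(world)
    idx = np.rint(vox).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(src_geom.shape)), axis=1)
    idx_c = np.clip(idx, 0, np.array(src_geom.shape) - 1)
    out = {}
    for name in names:
        vals = truth.maps[t][name].values[idx_c[:, 0], idx_c[:, 1], idx_c[:, 2]]
        vals = np.where(inside, vals, 0.0)
        out[name] = vals.reshape(shp)
    lab = truth.labels[t].labels[idx_c[:, 0], idx_c[:, 1], idx_c[:, 2]]
    out["labels"] = np.where(inside, lab, 0).reshape(shp)
    axv = truth.principal_axis[t].reshape(-1, 3)[
        np.ravel_multi_index((idx_c[:, 0], idx_c[:, 1], idx_c[:, 2]), src_geom.shape)
    ]
    out["axis"] = np.where(inside[:, None], axv, [0, 0, 1.0]).reshape(shp + (3,))
    return out


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------


def synthesize_dixon(
    truth: PhantomTruth, t: str, sigma: float | None = None,
    fat_spectrum: FatSpectrum = FAT_SPECTRUM_6PEAK,
) -> ComplexEchoSeries:
    """Complex 4-echo gradient-echo signal of session ``t``.

    Per voxel ``S(TE) = M0 [(1-FF) + FF phi(TE)] exp(i 2 pi psi TE) exp(-TE/T2*)``
    plus complex Gaussian noise (``sigma`` per real/imaginary channel).
    """
    spec = truth.spec
    sigma = spec.sigma_dixon if sigma is None else sigma
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    geom = truth.geometry[t]
    te = np.asarray(DIXON_ECHO_TIMES_MS)
    ff = truth.maps[t]["ff"].values[..., None]
    psi = truth.maps[t]["psi"].values[..., None]
    t2s = truth.maps[t]["t2star"].values[..., None]
    fg = (truth.labels[t].labels > 0)[..., None]
    phi = fat_spectrum.modulation(te)
    m0 = spec.m0
    sig = m0 * ((1 - ff) + ff * phi[None, None, None, :])
    sig = sig * np.exp(2j * np.pi * psi * te / 1000.0) * np.exp(-te / t2s)
    sig = np.where(fg, sig, 0.0)
    if sigma > 0:
        rng = _stream_rng(spec, truth.subject, t, "dixon")
        sig = sig + rng.normal(0, sigma, sig.shape) + 1j * rng.normal(0, sigma, sig.shape)
    return ComplexEchoSeries(geom, te, sig)


def synthesize_t2_train(truth: PhantomTruth, t: str, sigma: float | None = None) -> MagnitudeEchoTrain:
    """17-echo spin-echo magnitude train on the 13-slice T2 grid.

    Signal = M0 [(1-FF) EPG(T2w, B1) + FF EPG(T2fat, B1)] with Rician noise.
    """
    spec = truth.spec
    sigma = spec.sigma_t2 if sigma is None else sigma
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    geom = truth.t2_geometry[t]
    smp = _sample_maps(truth, t, geom, ("ff", "t2w", "b1"))
    fg = smp["labels"] > 0
    ff = smp["ff"][fg]
    t2w = np.maximum(smp["t2w"][fg], 1.0)
    b1 = smp["b1"][fg]
    ew = epg_echo_train(t2w, t1_ms=T1_MUSCLE_MS, b1=b1,
                        echo_spacing_ms=T2_ECHO_SPACING_MS, n_echoes=T2_N_ECHOES)
    ef = epg_echo_train(np.full_like(t2w, spec.t2_fat_ms), t1_ms=T1_FAT_MS, b1=b1,
                        echo_spacing_ms=T2_ECHO_SPACING_MS, n_echoes=T2_N_ECHOES)
    train = spec.m0 * ((1 - ff)[:, None] * ew + ff[:, None] * ef)
    data = np.zeros(geom.shape + (T2_N_ECHOES,))
    data[fg] = train
    if sigma > 0:
        rng = _stream_rng(spec, truth.subject, t, "t2")
        data = np.abs(data + rng.normal(0, sigma, data.shape)
                      + 1j * rng.normal(0, sigma, data.shape))
    return MagnitudeEchoTrain(geom, echo_spacing=T2_ECHO_SPACING_MS, data=data)


def synthesize_dwi(truth: PhantomTruth, t: str, sigma: float | None = None) -> DWISeries:
    """42-volume DWI series: S = S0 exp(-b g'Dg) with Rician noise.

    The tensor per voxel is axially symmetric around the muscle fibre axis
    with eigenvalues matched to the true MD and FA.
    """
    spec = truth.spec
    sigma = spec.sigma_dwi if sigma is None else sigma
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    geom = truth.dwi_geometry[t]
    bvals, bvecs = build_bscheme()
    smp = _sample_maps(truth, t, geom, ("ff", "md", "fa"))
    fg = smp["labels"] > 0
    md = smp["md"][fg]
    fa = smp["fa"][fg]
    axis = smp["axis"][fg]
    lam_par, lam_perp = _axisym_eigenvalues(md, fa)
    # S/S0 = exp(-b [lam_perp + (lam_par-lam_perp) (g.axis)^2])
    dot = axis @ bvecs.T  # (V, N)
    adc = lam_perp[:, None] + (lam_par - lam_perp)[:, None] * dot**2
    sig = spec.m0 * np.exp(-bvals[None, :] * adc)
    data = np.zeros(geom.shape + (len(bvals),))
    data[fg] = sig
    if sigma > 0:
        rng = _stream_rng(spec, truth.subject, t, "dwi")
        data = np.abs(data + rng.normal(0, sigma, data.shape)
                      + 1j * rng.normal(0, sigma, data.shape))
    return DWISeries(geom, data, bvals, bvecs)


def _axisym_eigenvalues(md, fa):
    """(lam_parallel, lam_perp) of an axially symmetric tensor with given MD, FA.

    With lam_par = MD (1 + 2 d), lam_perp = MD (1 - d):
    FA = 3 d / sqrt(3 + 6 d^2), hence d = FA sqrt(3) / sqrt(9 - 6 FA^2).
    """
    fa = np.asarray(fa, dtype=float)
    md = np.asarray(md, dtype=float)
    d = fa * np.sqrt(3.0) / np.sqrt(9.0 - 6.0 * fa**2)
    return md * (1 + 2 * d), md * (1 - d)


def synthesize_clinical(spec: PhantomSpec, subject: int) -> pd.DataFrame:
    """Stable clinical scores with test-retest noise (null change by design)."""
    rng = _stream_rng(spec, subject, "clinical")
    hfmse = rng.integers(5, 55)
    mrc = rng.normal(142, 35)
    mrc_thigh = rng.normal(16, 5)
    hhd = {"adductors": rng.normal(39, 15), "hamstrings": rng.normal(47, 20),
           "quadriceps": rng.normal(16, 10)}
    rows = []
    for t in ("A", "B"):
        row = dict(
            subject=subject, time_point=t,
            HFMSE=int(np.clip(hfmse + rng.normal(0, 2), 0, 66)),
            MRC_sum=float(np.clip(mrc + rng.normal(0, 3), 44, 210)),
            MRC_thigh=float(np.clip(mrc_thigh + rng.normal(0, 1), 6, 30)),
        )
        for g, v in hhd.items():
            for side in ("R", "L"):
                row[f"HHD_{g}_{side}"] = max(0.0, v + rng.normal(0, 4))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# record-level cohort simulation (no images)
# ---------------------------------------------------------------------------


def simulate_cohort_records(
    rng: np.random.Generator,
    n_subjects: int = 10,
    muscles: tuple = MUSCLES,
    sides: tuple = ("R", "L"),
    slope_pct: float = 1.28,
    low_mode_slope_pct: float | None = None,
    low_slope_muscles: tuple | None = None,
    subject_sd: float = 0.6,
    group_sd: float = 0.5,
    residual_sd: float = 2.5,
    ff_low_mean: float = 25.0,
    ff_high_mean: float = 42.0,
    ff_low_sd: float = 5.0,
    ff_high_sd: float = 7.0,
    p_low_other: float = 0.2,
    snr_mean: float = 17.3,
    snr_sd: float = 4.0,
    outcome: str = "FF",
) -> pd.DataFrame:
    """Per-muscle outcome records for the statistical experiments.

    Generative model (units: %FF):

        y_A = baseline_sm + e_A
        y_B = baseline_sm + slope_m + u_s + v_g + e_B

    with baseline from the bimodal muscle mixture, slope ``slope_pct`` for
    high-mode muscles and ``low_mode_slope_pct`` (default: the same) for the
    low-mode muscles, subject- and muscle-group-level change offsets
    (SD ``subject_sd`` / ``group_sd``) and i.i.d. measurement noise
    (SD ``residual_sd``, sized so the model SE of the time effect matches
    the cohort table's 0.39 at the default design: SE^2 =
    subject_sd^2/10 + group_sd^2/4 + 2 residual_sd^2/240).

    ``low_slope_muscles``, when given, pins the reduced slope to exactly
    those muscles (independent of the random mode draw); other muscles get
    the full slope.
    """
    if low_mode_slope_pct is None:
        low_mode_slope_pct = slope_pct
    groups = sorted(set(MUSCLE_GROUPS[m] for m in muscles))
    rows = []
    for s in range(n_subjects):
        u_s = rng.normal(0, subject_sd)
        v_g = {g: rng.normal(0, group_sd) for g in groups}
        snr = max(rng.normal(snr_mean, snr_sd), 1.0)
        for m in muscles:
            low = m in LOW_FAT_MUSCLES or rng.uniform() < p_low_other
            if m in LOW_FAT_MUSCLES:
                low = True
            mean = ff_low_mean if low else ff_high_mean
            sd = ff_low_sd if low else ff_high_sd
            if low_slope_muscles is not None:
                slope = low_mode_slope_pct if m in low_slope_muscles else slope_pct
            else:
                slope = low_mode_slope_pct if low else slope_pct
            g = MUSCLE_GROUPS[m]
            hi = 30.0 if m in LOW_FAT_MUSCLES else 95.0
            for side in sides:
                base = np.clip(rng.normal(mean, sd), 2.0, hi)
                y_a = base + rng.normal(0, residual_sd)
                y_b = base + slope + u_s + v_g[g] + rng.normal(0, residual_sd)
                for t, y in (("A", y_a), ("B", y_b)):
                    rows.append(dict(subject=s, muscle=m, side=side,
                                     muscle_group=g, time_point=t,
                                     value=y, outcome=outcome, SNR=snr,
                                     low_mode=low))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------


def generate_dataset(spec: PhantomSpec, out_dir) -> dict:
    """Write the full two-session dataset (plus ground truth) to disk.

    Layout: ``sub-XX/ses-{A,B}/{dixon,t2,dwi,labels}`` NIfTI files, a
    ``truth/`` directory with the ground-truth maps and per-muscle values,
    and a manifest; returns the manifest dictionary.
    """
    out = Path(out_dir)
    manifest = {"n_subjects": spec.n_subjects, "seed": spec.seed, "subjects": []}
    for s in range(spec.n_subjects):
        truth = build_phantom(spec, subject=s)
        sub = out / f"sub-{s:02d}"
        entry = {"subject": s, "sessions": {}}
        for t in ("A", "B"):
            ses = sub / f"ses-{t}"
            write_volume(synthesize_dixon(truth, t), ses / "dixon.nii.gz")
            write_volume(synthesize_t2_train(truth, t), ses / "t2_train.nii.gz")
            write_volume(synthesize_dwi(truth, t), ses / "dwi.nii.gz")
            write_volume(truth.labels[t], ses / "labels.nii.gz")
            for name, vol in truth.maps[t].items():
                write_volume(vol, sub / "truth" / f"{name}_{t}.nii.gz")
            entry["sessions"][t] = str(ses)
        truth.muscle_values.to_csv(sub / "truth" / "muscle_values.csv", index=False)
        truth.clinical.to_csv(sub / "clinical.csv", index=False)
        manifest["subjects"].append(entry)
    return manifest
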