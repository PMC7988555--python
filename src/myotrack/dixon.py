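"""IDEAL fat-water separation from 4-echo complex Dixon data.

Per voxel the gradient-echo signal at echo time ``t`` (ms) is modelled as

    S(t) = (W + F * phi(t)) * exp(i*2*pi*psi*t/1000) * exp(-R2s*t)

with complex water/fat amplitudes ``W``, ``F``, field offset ``psi`` (Hz),
common effective decay ``R2s`` (1/ms; four echoes cannot support separate
water and fat decays), and the multi-peak fat modulation

    phi(t) = sum_k c_k * exp(i*2*pi*f_k*t/1000),   sum_k c_k = 1.

Estimation is variable projection (VARPRO): for a candidate ``(psi, R2s)``
the amplitudes solve a linear least-squares, so only the two nonlinear
parameters are searched -- a coarse grid, a quality-guided region-growing
choice among the candidate field-map minima (which suppresses water-fat
swaps from psi aliasing), then per-voxel grid zooming to convergence.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .core import ComplexEchoSeries, ScalarVolume

__all__ = ["FatSpectrum", "FAT_SPECTRUM_6PEAK", "DixonFit", "ideal_fit", "fat_fraction"]

GAMMA_MHZ_PER_T = 42.5774785
FIELD_T = 3.0


@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak fat spectrum: frequency offsets from water and weights."""

    freqs_hz: tuple
    weights: tuple

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("fat spectrum weights must sum to 1")

    def modulation(self, echo_times_ms: np.ndarray) -> np.ndarray:
        """phi(t): complex fat modulation at the given echo times."""
        t = np.asarray(echo_times_ms, dtype=float) / 1000.0  # s
        f = np.asarray(self.freqs_hz)[:, None]
        c = np.asarray(self.weights)[:, None]
        return (c * np.exp(2j * np.pi * f * t)).sum(axis=0)


# Standard six-peak muscle/fat spectrum at 3 T: chemical shifts relative to
# water (ppm) and relative amplitudes (normalised to 1).
_PPM = (-3.80, -3.40, -2.60, -1.94, -0.39, 0.60)
_AMP = (0.087, 0.693, 0.128, 0.004, 0.039, 0.048)
FAT_SPECTRUM_6PEAK = FatSpectrum(
    freqs_hz=tuple(p * GAMMA_MHZ_PER_T * FIELD_T for p in _PPM),
    weights=tuple(a / sum(_AMP) for a in _AMP),
)


@dataclass
class DixonFit:
    """Water/fat amplitudes and nuisance maps from the IDEAL fit."""

    water: ScalarVolume      # |W|
    fat: ScalarVolume        # |F|
    psi: ScalarVolume        # field offset (Hz); NaN in background
    r2star: ScalarVolume     # effective decay (1/ms); >= 0
    residual: ScalarVolume   # per-voxel fit residual norm
    background: np.ndarray = None  # bool mask of excluded voxels


def _coarse_profiles(y, te_ms, phi, psi_grid, r2s_grid, chunk_vox=2000):
    """Field-map residual profiles on the coarse (psi, R2s) grid.

    For each voxel returns ``prof`` (residual minimised over R2s, per psi
    candidate) and ``r2s_arg`` (the minimising R2s index).  Uses the VARPRO
    projection identity ``res = ||y||^2 - c^H G^{-1} c`` evaluated in real
    arithmetic; voxels are chunked to bound memory.
    """
    t = te_ms[None, :]
    P, R = np.meshgrid(psi_grid, r2s_grid, indexing="ij")
    psi, r2s = P.ravel(), R.ravel()
    w = np.exp((2j * np.pi * psi[:, None] / 1000.0 - r2s[:, None]) * t)  # (C, E)
    b1 = w
    b2 = w * phi[None, :]
    g11 = np.einsum("ce,ce->c", b1.conj(), b1).real
    g12 = np.einsum("ce,ce->c", b1.conj(), b2)
    g22 = np.einsum("ce,ce->c", b2.conj(), b2).real
    det = g11 * g22 - np.abs(g12) ** 2
    det = np.where(det <= 1e-30, np.nan, det)
    b1c, b2c = b1.conj().T.copy(), b2.conj().T.copy()  # (E, C)
    g12r, g12i = g12.real, g12.imag

    n_vox = y.shape[0]
    n_psi, n_r2s = len(psi_grid), len(r2s_grid)
    prof = np.empty((n_vox, n_psi))
    r2s_arg = np.empty((n_vox, n_psi), dtype=np.intp)
    for start in range(0, n_vox, chunk_vox):
        sl = slice(start, min(start + chunk_vox, n_vox))
        c1 = y[sl] @ b1c  # (v, C)
        c2 = y[sl] @ b2c
        a11 = c1.real**2 + c1.imag**2
        a22 = c2.real**2 + c2.imag**2
        cr = c1.real * c2.real + c1.imag * c2.imag
        ci = c1.imag * c2.real - c1.real * c2.imag
        proj = (g22 * a11 + g11 * a22 - 2.0 * (g12r * cr + g12i * ci)) / det
        yy = np.einsum("ve,ve->v", y[sl].conj(), y[sl]).real[:, None]
        res = np.maximum(yy - proj, 0.0).reshape(-1, n_psi, n_r2s)
        r2s_arg[sl] = res.argmin(axis=2)
        prof[sl] = res.min(axis=2)
    return prof, r2s_arg


def _local_minima_1d(profile):
    """Indices of strict local minima of a 1-D array (ends included)."""
    v = profile
    idx = []
    n = len(v)
    for i in range(n):
        left = v[i - 1] if i > 0 else np.inf
        right = v[i + 1] if i < n - 1 else np.inf
        if v[i] <= left and v[i] <= right:
            idx.append(i)
    return idx


def ideal_fit(
    series: ComplexEchoSeries,
    fat_spectrum: FatSpectrum = FAT_SPECTRUM_6PEAK,
    psi_range_hz: tuple = (-200.0, 200.0),
    psi_step_hz: float = 5.0,
    r2s_range: tuple = (0.0, 0.2),
    r2s_step: float = 0.01,
    n_zoom: int = 3,
    region_growing: bool = True,
) -> DixonFit:
    """Variable-projection IDEAL fit of a complex multi-echo series.

    The coarse ``(psi, R2s)`` grid gives each voxel a field-map residual
    profile; candidate field values are its local minima.  A quality-guided
    region growing (quality = depth of the best minimum relative to the
    runner-up) assigns each voxel the candidate most consistent with its
    already-assigned neighbours, then ``n_zoom`` rounds of 10x grid
    refinement polish the estimate.  All-zero voxels are marked background
    and excluded.
    """
    geom = series.geometry
    te = np.asarray(series.echo_times, dtype=float)
    if len(te) < 4:
        raise ValueError("IDEAL needs at least 4 echoes")
    phi = fat_spectrum.modulation(te)
    flat = series.data.reshape(-1, len(te))
    fg = np.abs(flat).max(axis=1) > 0
    y = flat[fg]
    n_vox = y.shape[0]

    psi_grid = np.arange(psi_range_hz[0], psi_range_hz[1] + 1e-9, psi_step_hz)
    r2s_grid = np.arange(r2s_range[0], r2s_range[1] + 1e-9, r2s_step)
    prof, r2s_arg = _coarse_profiles(y, te, phi, psi_grid, r2s_grid)

    if region_growing and n_vox > 1:
        psi_idx = _region_grow_psi(prof, fg.reshape(geom.shape))
    else:
        psi_idx = prof.argmin(axis=1)

    psi_hat = psi_grid[psi_idx]
    r2s_hat = r2s_grid[r2s_arg[np.arange(n_vox), psi_idx]]

    # per-voxel zoom refinement around the selected minimum: each level
    # searches +-1 previous step at 5x finer resolution
    dpsi, dr2s = psi_step_hz, r2s_step
    for _ in range(n_zoom):
        off_p = np.linspace(-dpsi, dpsi, 11)
        off_r = np.linspace(-dr2s, dr2s, 11)
        dpsi /= 5.0
        dr2s /= 5.0
        OP, OR = np.meshgrid(off_p, off_r, indexing="ij")
        op, orr = OP.ravel(), OR.ravel()
        chunk = max(1, int(2e6 // (len(op) * len(te))))
        for start in range(0, n_vox, chunk):
            sl = slice(start, min(start + chunk, n_vox))
            pv = psi_hat[sl][:, None] + op[None, :]
            rv = np.clip(r2s_hat[sl][:, None] + orr[None, :], r2s_range[0], None)
            # evaluate candidates voxel-wise (designs differ per voxel)
            t = te[None, None, :]
            w = np.exp((2j * np.pi * pv[..., None] / 1000.0 - rv[..., None]) * t)
            b1, b2 = w, w * phi[None, None, :]
            g11 = np.einsum("vce,vce->vc", b1.conj(), b1).real
            g12 = np.einsum("vce,vce->vc", b1.conj(), b2)
            g22 = np.einsum("vce,vce->vc", b2.conj(), b2).real
            det = np.where(g11 * g22 - np.abs(g12) ** 2 <= 1e-30, np.nan,
                           g11 * g22 - np.abs(g12) ** 2)
            c1 = np.einsum("ve,vce->vc", y[sl], b1.conj())
            c2 = np.einsum("ve,vce->vc", y[sl], b2.conj())
            a11 = c1.real**2 + c1.imag**2
            a22 = c2.real**2 + c2.imag**2
            cr = c1.real * c2.real + c1.imag * c2.imag
            ci = c1.imag * c2.real - c1.real * c2.imag
            proj = (g22 * a11 + g11 * a22 - 2.0 * (g12.real * cr + g12.imag * ci)) / det
            yy = np.einsum("ve,ve->v", y[sl].conj(), y[sl]).real[:, None]
            rloc = np.maximum(yy - proj, 0.0)
            j = np.nanargmin(rloc, axis=1)
            rows = np.arange(rloc.shape[0])
            psi_hat[sl] = pv[rows, j]
            r2s_hat[sl] = rv[rows, j]

    res_fin, Wc, Fc = _final_amplitudes(y, te, phi, psi_hat, r2s_hat)

    shape = geom.shape
    n_total = flat.shape[0]

    def full(vals, fill=np.nan):
        out = np.full(n_total, fill, dtype=float)
        out[fg] = vals
        return out.reshape(shape)

    return DixonFit(
        water=ScalarVolume(geom, full(np.abs(Wc), 0.0), name="water"),
        fat=ScalarVolume(geom, full(np.abs(Fc), 0.0), name="fat"),
        psi=ScalarVolume(geom, full(psi_hat), name="psi"),
        r2star=ScalarVolume(geom, full(r2s_hat), name="R2star"),
        residual=ScalarVolume(geom, full(np.sqrt(res_fin)), name="residual"),
        background=~fg.reshape(shape),
    )


def _final_amplitudes(y, te, phi, psi_hat, r2s_hat):
    t = te[None, :]
    w = np.exp((2j * np.pi * psi_hat[:, None] / 1000.0 - r2s_hat[:, None]) * t)
    b1, b2 = w, w * phi[None, :]
    g11 = np.einsum("ve,ve->v", b1.conj(), b1).real
    g12 = np.einsum("ve,ve->v", b1.conj(), b2)
    g22 = np.einsum("ve,ve->v", b2.conj(), b2).real
    det = np.where(g11 * g22 - np.abs(g12) ** 2 <= 1e-30, np.nan,
                   g11 * g22 - np.abs(g12) ** 2)
    c1 = np.einsum("ve,ve->v", y, b1.conj())
    c2 = np.einsum("ve,ve->v", y, b2.conj())
    W = (g22 * c1 - g12 * c2) / det
    F = (g11 * c2 - np.conj(g12) * c1) / det
    yy = np.einsum("ve,ve->v", y.conj(), y).real
    res = np.maximum(yy - (np.conj(c1) * W + np.conj(c2) * F).real, 0.0)
    return res, W, F


def _region_grow_psi(prof, fg_mask):
    """Quality-guided region growing over the field-map residual profiles.

    ``prof``: (n_fg_voxels, n_psi) residual vs field-offset candidate;
    ``fg_mask``: 3-D foreground mask locating those voxels.  Each voxel's
    candidates are the local minima of its profile; growth starts at the
    least ambiguous voxel and neighbours adopt the candidate closest to the
    mean field of their already-assigned neighbourhood.
    """
    shape = fg_mask.shape
    fg_lin = np.flatnonzero(fg_mask.ravel())
    pos = {lin: i for i, lin in enumerate(fg_lin)}
    n = len(fg_lin)

    # vectorised local-minima detection over all residual profiles
    pad = np.pad(prof, ((0, 0), (1, 1)), constant_values=np.inf)
    is_min = (prof <= pad[:, :-2]) & (prof <= pad[:, 2:])
    spread = prof.max(axis=1) - prof.min(axis=1) + 1e-30
    candidates = []
    quality = np.empty(n)
    for i in range(n):
        mins = np.flatnonzero(is_min[i])
        vals = prof[i][mins]
        order = np.argsort(vals)
        mins = mins[order].tolist()
        candidates.append(mins)
        if len(mins) > 1:
            quality[i] = (vals[order[1]] - vals[order[0]]) / spread[i]
        else:
            quality[i] = 1.0

    assigned = np.full(n, -1, dtype=int)
    seed = int(np.argmax(quality))
    heap = [(-quality[seed], seed, candidates[seed][0])]
    strides = np.array([shape[1] * shape[2], shape[2], 1])

    def neighbours(lin):
        ijk = np.array(np.unravel_index(lin, shape))
        for ax in range(3):
            for d in (-1, 1):
                nb = ijk.copy()
                nb[ax] += d
                if 0 <= nb[ax] < shape[ax]:
                    yield int(nb @ strides)

    while heap:
        _, i, cand = heapq.heappop(heap)
        if assigned[i] >= 0:
            continue
        assigned[i] = cand
        for nb_lin in neighbours(fg_lin[i]):
            j = pos.get(nb_lin)
            if j is None or assigned[j] >= 0:
                continue
            # choose the neighbour's candidate closest to this voxel's field
            cands = candidates[j]
            best = min(cands, key=lambda c: abs(c - cand))
            heapq.heappush(heap, (-quality[j], j, best))

    # disconnected foreground components fall back to their global minimum
    left = assigned < 0
    if np.any(left):
        assigned[left] = prof[left].argmin(axis=1)
    return assigned


def fat_fraction(fit: DixonFit) -> ScalarVolume:
    """FF = |F| / (|W| + |F|), NaN where there is no signal."""
    w = fit.water.values
    f = fit.fat.values
    denom = w + f
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(denom > 0, f / denom, np.nan)
    if fit.background is not None:
        ff = np.where(fit.background, np.nan, ff)
    return ScalarVolume(fit.water.geometry, ff, name="FF")
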