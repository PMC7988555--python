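"""Diffusion pipeline: MP-PCA denoising, motion/eddy correction and robust
tensor estimation.

The tensor is estimated from the log-linear model ``ln S = ln S0 - b g'Dg``
by iteratively weighted linear least squares (iWLLS, weights = predicted
squared signal) wrapped in REKINDLE-style robust reweighting: Geman-McClure
IRLS identifies signal dropouts/artefacts, observations whose standardized
residual exceeds ``kappa`` (default 6) are excluded, and the final iWLLS runs
on inliers only.  The kurtosis term is omitted -- the maximum b-value of the
muscle protocol (600 s/mm^2) is too low to support it -- so REKINDLE serves
purely as outlier machinery.

Noise is estimated alongside denoising: local PCA with the Marchenko-Pastur
law separating noise from signal eigenvalues yields both the denoised series
and a sigma map, from which the SNR map (mean low-b signal / sigma) used as
a covariate in the statistics is derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core import DWISeries, ScalarVolume

__all__ = [
    "DWI_SCHEME",
    "build_bscheme",
    "electrostatic_directions",
    "NoiseEstimate",
    "TensorMap",
    "mp_denoise",
    "correct_motion_eddy",
    "fit_tensor_iwlls_rekindle",
    "tensor_metrics",
]

#: The study's b-value scheme: (b in s/mm^2, number of volumes); 42 total.
DWI_SCHEME = ((0, 1), (1, 6), (10, 3), (25, 3), (100, 3), (200, 6), (400, 8), (600, 12))

EIG_CLIP = 1e-7  # mm^2/s; floor applied to eigenvalues for FA stability


@lru_cache(maxsize=32)
def electrostatic_directions(n: int, n_iter: int = 400) -> np.ndarray:
    """``n`` unit vectors spread by electrostatic repulsion (antipodal pairs).

    Deterministic: starts from a Fibonacci hemisphere and relaxes the
    Coulomb energy of the +-pair ensemble by projected gradient descent.
    """
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = (i + 0.5) / n  # hemisphere
    r = np.sqrt(1 - z**2)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    step = 0.05
    for _ in range(n_iter):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]
            d2 = (diff**2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            d2 = np.maximum(d2, 1e-12)
            force += (diff / d2[..., None] ** 1.5).sum(axis=1)
        pts = pts + step * force / n
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # canonical hemisphere orientation
    flip = pts[:, 2] < 0
    pts[flip] *= -1
    return pts


def build_bscheme(scheme=DWI_SCHEME) -> tuple[np.ndarray, np.ndarray]:
    """Expand a (b, count) scheme into bvals and repulsion-optimised bvecs."""
    bvals, bvecs = [], []
    for b, count in scheme:
        dirs = electrostatic_directions(count) if b > 0 else np.zeros((count, 3))
        for d in dirs:
            bvals.append(float(b))
            bvecs.append(d)
    return np.asarray(bvals), np.asarray(bvecs)


@dataclass
class NoiseEstimate:
    """Noise level and derived SNR of a DWI series."""

    sigma: ScalarVolume  # noise sigma in signal units
    snr: ScalarVolume    # mean b<=25 signal / sigma


@dataclass
class TensorMap:
    """Voxelwise diffusion tensors (lower-triangular order) and S0."""

    geometry: object
    tensor: np.ndarray   # (X, Y, Z, 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    s0: np.ndarray
    valid: np.ndarray
    outlier_fraction: np.ndarray | None = None

    def as_matrices(self) -> np.ndarray:
        d = self.tensor
        out = np.empty(d.shape[:-1] + (3, 3))
        out[..., 0, 0] = d[..., 0]
        out[..., 1, 1] = d[..., 1]
        out[..., 2, 2] = d[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = d[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = d[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = d[..., 5]
        return out


# ---------------------------------------------------------------------------
# MP-PCA denoising
# ---------------------------------------------------------------------------


def _mp_window(X):
    """Denoise one local window (N voxels x M volumes); returns (Xhat, sigma2, p)."""
    N, M = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    vals = (s**2) / N  # descending eigenvalues of X'X/N
    asc = vals[::-1]
    sigma2 = 0.0
    p = 0
    for r in range(1, len(asc) + 1):
        # hypothesis: the r smallest eigenvalues are pure noise
        sig2 = asc[:r].sum() / r
        gamma = r / N
        if asc[r - 1] - asc[0] < 4.0 * np.sqrt(gamma) * sig2:
            sigma2 = sig2
            p = len(asc) - r
        else:
            break
    keep = np.zeros(len(s), dtype=bool)
    keep[:p] = True
    Xhat = (U[:, keep] * s[keep]) @ Vt[keep]
    return Xhat, sigma2, p


def mp_denoise(dwi: DWISeries, window: int = 5, stride: int | None = None):
    """Local-PCA denoising with Marchenko-Pastur eigenvalue thresholding.

    A sliding ``window``^3 patch is unfolded to (voxels x volumes), its
    eigen-spectrum split into signal and MP-distributed noise components,
    the noise components removed, and sigma estimated from the MP fit.
    Overlapping estimates are averaged.  ``stride`` > 1 trades accuracy at
    patch seams for speed (default 2).

    Returns ``(denoised DWISeries, NoiseEstimate)``.
    """
    shape = dwi.geometry.shape
    if any(w > s for w, s in zip((window,) * 3, shape)):
        raise ValueError("window larger than volume")
    if stride is None:
        stride = 2
    data = dwi.data
    M = data.shape[-1]
    acc = np.zeros_like(data)
    cnt = np.zeros(shape)
    sig_acc = np.zeros(shape)

    xs = _window_starts(shape[0], window, stride)
    ys = _window_starts(shape[1], window, stride)
    zs = _window_starts(shape[2], window, stride)
    for x0 in xs:
        for y0 in ys:
            for z0 in zs:
                sl = (slice(x0, x0 + window), slice(y0, y0 + window), slice(z0, z0 + window))
                X = data[sl].reshape(-1, M)
                Xhat, sigma2, _ = _mp_window(X)
                acc[sl] += Xhat.reshape(window, window, window, M)
                cnt[sl] += 1
                sig_acc[sl] += np.sqrt(max(sigma2, 0.0))
    den = acc / cnt[..., None]
    sigma = sig_acc / cnt
    lowb = dwi.bvals <= 25
    mean_lowb = den[..., lowb].mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        snr = np.where(sigma > 0, mean_lowb / sigma, np.nan)
    out = DWISeries(dwi.geometry, np.clip(den, 0, None), dwi.bvals, dwi.bvecs)
    noise = NoiseEstimate(
        sigma=ScalarVolume(dwi.geometry, sigma, name="sigma"),
        snr=ScalarVolume(dwi.geometry, snr, name="SNR"),
    )
    return out, noise


def _window_starts(size, window, stride):
    starts = list(range(0, size - window + 1, stride))
    if starts[-1] != size - window:
        starts.append(size - window)
    return starts


# ---------------------------------------------------------------------------
# Motion / eddy-current correction
# ---------------------------------------------------------------------------


def correct_motion_eddy(dwi: DWISeries, max_iterations: int = 100):
    """Affine registration of every volume to the mean b<=25 volume.

    The rigid (rotation) part of each recovered affine also rotates the
    corresponding b-vector.  Volumes whose registration fails are flagged
    and excluded from the returned series.

    Returns ``(corrected DWISeries, list of 4x4 voxel-space affines)``.
    """
    import SimpleITK as sitk

    lowb = dwi.bvals <= 25
    if not np.any(lowb):
        raise ValueError("need at least one b<=25 volume as reference")
    ref_arr = dwi.data[..., lowb].mean(axis=-1)
    spacing = (dwi.geometry.voxel_size[0], dwi.geometry.voxel_size[1], dwi.geometry.slice_spacing)

    def to_img(a):
        img = sitk.GetImageFromArray(np.ascontiguousarray(a.T, dtype=np.float64))
        img.SetSpacing(spacing)
        return img

    ref = to_img(ref_arr)
    out = np.empty_like(dwi.data)
    bvecs = dwi.bvecs.copy()
    transforms = []
    kept = np.ones(dwi.n_volumes, dtype=bool)
    for v in range(dwi.n_volumes):
        mov = to_img(dwi.data[..., v])
        try:
            reg = sitk.ImageRegistrationMethod()
            reg.SetMetricAsCorrelation()
            reg.SetInterpolator(sitk.sitkLinear)
            reg.SetOptimizerAsRegularStepGradientDescent(
                learningRate=1.0, minStep=1e-4, numberOfIterations=max_iterations,
                relaxationFactor=0.6,
            )
            reg.SetOptimizerScalesFromPhysicalShift()
            tx0 = sitk.CenteredTransformInitializer(
                ref, mov, sitk.AffineTransform(3),
                sitk.CenteredTransformInitializerFilter.GEOMETRY,
            )
            reg.SetInitialTransform(tx0, inPlace=True)
            reg.SetShrinkFactorsPerLevel([2, 1])
            reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
            tx = reg.Execute(ref, mov)
            res = sitk.Resample(mov, ref, tx, sitk.sitkLinear, 0.0)
            out[..., v] = sitk.GetArrayFromImage(res).T
            A = np.array(sitk.AffineTransform(tx.GetNthTransform(0)
                         if isinstance(tx, sitk.CompositeTransform) else tx).GetMatrix()).reshape(3, 3)
            # rigid part via polar decomposition; rotate the gradient direction
            Uq, _, Vtq = np.linalg.svd(A)
            Rrot = Uq @ Vtq
            if np.linalg.det(Rrot) < 0:
                Rrot = Uq @ np.diag([1, 1, -1]) @ Vtq
            if dwi.bvals[v] > 0:
                bvecs[v] = Rrot.T @ bvecs[v]
                bvecs[v] /= np.linalg.norm(bvecs[v])
            M4 = np.eye(4)
            M4[:3, :3] = A
            M4[:3, 3] = np.array(tx.GetParameters()[9:12]) if not isinstance(tx, sitk.CompositeTransform) else 0
            transforms.append(M4)
        except Exception:
            kept[v] = False
            out[..., v] = dwi.data[..., v]
            transforms.append(None)
    corrected = DWISeries(
        dwi.geometry, out[..., kept], dwi.bvals[kept], bvecs[kept]
    )
    return corrected, transforms


# ---------------------------------------------------------------------------
# Tensor fitting
# ---------------------------------------------------------------------------


def _design(bvals, bvecs):
    g = bvecs
    b = bvals
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def _batched_wlls(X, Y, W):
    """Weighted LS solve per voxel; X (N,7), Y (V,N), W (V,N) -> beta (V,7)."""
    XtW = X[None, :, :] * W[:, :, None]          # (V, N, 7)
    A = np.einsum("vni,nj->vij", XtW, X)         # (V, 7, 7)
    rhs = np.einsum("vni,vn->vi", XtW, Y)
    return np.linalg.solve(A, rhs[..., None])[..., 0]


def fit_tensor_iwlls_rekindle(
    dwi: DWISeries,
    noise: NoiseEstimate | None = None,
    mask: np.ndarray | None = None,
    kappa: float = 6.0,
    max_iter: int = 10,
    tol: float = 1e-6,
    rekindle: bool = True,
    drop_b_below: float | None = None,
) -> TensorMap:
    """iWLLS tensor fit with REKINDLE outlier rejection.

    ``drop_b_below`` optionally removes low-b volumes (IVIM contamination)
    but keeps b=0; by default all volumes enter the fit.  Voxels with fewer
    inliers than parameters are marked invalid.
    """
    keep = np.ones(dwi.n_volumes, dtype=bool)
    if drop_b_below is not None:
        keep = (dwi.bvals == 0) | (dwi.bvals >= drop_b_below)
    bvals, bvecs, data = dwi.bvals[keep], dwi.bvecs[keep], dwi.data[..., keep]
    N = keep.sum()
    if N < 7:
        raise ValueError("need >= 7 acquisitions for a tensor fit")
    X = _design(bvals, bvecs)
    shape = dwi.geometry.shape
    flat = data.reshape(-1, N)
    if mask is None:
        fg = flat.min(axis=1) > 0
    else:
        fg = np.asarray(mask, dtype=bool).ravel() & (flat.min(axis=1) > 0)
    S = flat[fg]
    V = S.shape[0]
    Y = np.log(np.maximum(S, 1e-12))

    # OLS start, then iWLLS with weights = predicted squared signal
    beta = _batched_wlls(X, Y, np.ones_like(Y))
    for _ in range(max_iter):
        W = np.exp(2.0 * (beta @ X.T))
        W = np.clip(W, 1e-12, None)
        new = _batched_wlls(X, Y, W)
        if np.nanmax(np.abs(new - beta)) < tol * max(1.0, np.nanmax(np.abs(beta))):
            beta = new
            break
        beta = new

    inliers = np.ones((V, N), dtype=bool)
    if rekindle and kappa is not None:
        # robust Geman-McClure IRLS on the weighted log-linear problem
        for _ in range(max_iter):
            pred = beta @ X.T
            e = (Y - pred) * np.exp(pred)  # approx signal-domain residuals
            scale = 1.4826 * np.median(np.abs(e - np.median(e, axis=1, keepdims=True)), axis=1)
            scale = np.maximum(scale, 1e-12)[:, None]
            r = e / scale
            w_rob = 1.0 / (1.0 + r**2) ** 2
            W = np.clip(np.exp(2.0 * pred), 1e-12, None) * w_rob
            new = _batched_wlls(X, Y, W)
            if np.nanmax(np.abs(new - beta)) < tol * max(1.0, np.nanmax(np.abs(beta))):
                beta = new
                break
            beta = new
        pred = beta @ X.T
        e = (Y - pred) * np.exp(pred)
        scale = 1.4826 * np.median(np.abs(e - np.median(e, axis=1, keepdims=True)), axis=1)
        scale = np.maximum(scale, 1e-12)[:, None]
        inliers = np.abs(e / scale) <= kappa
        # final iWLLS restricted to inliers
        W = np.clip(np.exp(2.0 * pred), 1e-12, None) * inliers
        enough = inliers.sum(axis=1) >= 7
        beta_in = _batched_wlls(X, np.where(inliers, Y, 0.0), W)
        beta = np.where(enough[:, None], beta_in, beta)
    else:
        enough = np.ones(V, dtype=bool)

    n_total = flat.shape[0]
    tensor = np.zeros((n_total, 6))
    s0 = np.zeros(n_total)
    valid = np.zeros(n_total, dtype=bool)
    outfrac = np.zeros(n_total)
    tensor[fg] = beta[:, 1:]
    s0[fg] = np.exp(beta[:, 0])
    valid[fg] = enough & np.isfinite(beta).all(axis=1)
    outfrac[fg] = 1.0 - inliers.mean(axis=1)
    return TensorMap(
        geometry=dwi.geometry,
        tensor=tensor.reshape(shape + (6,)),
        s0=s0.reshape(shape),
        valid=valid.reshape(shape),
        outlier_fraction=outfrac.reshape(shape),
    )


def tensor_metrics(tensors: TensorMap) -> tuple[ScalarVolume, ScalarVolume]:
    """MD and FA maps from closed-form eigen-decomposition.

    Eigenvalues are floored at ``EIG_CLIP`` mm^2/s before the FA formula to
    keep it stable for near-degenerate tensors; non-finite tensors are
    masked to NaN.
    """
    D = tensors.as_matrices()
    finite = np.isfinite(D).all(axis=(-2, -1)) & tensors.valid
    Dsafe = np.where(finite[..., None, None], D, np.eye(3))
    evals = np.linalg.eigvalsh(Dsafe)
    evals = np.clip(evals, EIG_CLIP, None)
    md = evals.mean(axis=-1)
    num = ((evals - md[..., None]) ** 2).sum(axis=-1)
    den = (evals**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(num / den)
    fa = np.clip(fa, 0.0, 1.0)
    md = np.where(finite, md, np.nan)
    fa = np.where(finite, fa, np.nan)
    geom = tensors.geometry
    return ScalarVolume(geom, md, name="MD"), ScalarVolume(geom, fa, name="FA")
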