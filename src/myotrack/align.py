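"""Longitudinal mask alignment between two scan sessions.

Baseline (A) and follow-up (B) scans never cover identical anatomy: the leg
is repositioned and the field of view re-planned.  To compare muscles over
exactly the same anatomy, the Dixon water image of session A is registered
to session B (rigid, then affine, then b-spline; normalised correlation,
multi-resolution), the segmentations are propagated in both directions with
nearest-neighbour interpolation, and each session's native masks are
restricted to the voxels whose propagated counterpart agrees -- voxelwise
intersection.  Quantitative maps themselves are never resampled: analysis
always happens in the native space of each dataset, only masks move.

The restriction defaults to intersection (removing non-corresponding
regions); ``combine="union"`` is available for sensitivity analysis.
Muscles left with fewer matched voxels than a floor are dropped from the
analysis; the retained set is identical in the two spaces by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import MuscleLabelMap, ScalarVolume, VolumeGeometry

__all__ = [
    "SessionTransform",
    "MatchedSegmentations",
    "register_sessions",
    "propagate_and_match",
    "alignment_qc",
    "RegistrationError",
]

DEFAULT_VOXEL_FLOOR = 50  # matched voxels per muscle per space


class RegistrationError(RuntimeError):
    """Raised when the metric fails or the transform is implausible."""


def _to_sitk(vol) -> sitk.Image:
    """Convert a volume with an axis-aligned affine to a SimpleITK image."""
    if isinstance(vol, ScalarVolume):
        arr, geom = vol.values, vol.geometry
    elif isinstance(vol, MuscleLabelMap):
        arr, geom = vol.labels, vol.geometry
    else:
        arr, geom = vol[0], vol[1]
    off = np.abs(geom.affine[:3, :3] - np.diag(np.diag(geom.affine[:3, :3]))).max()
    if off > 1e-6:
        raise ValueError("only axis-aligned geometries are supported here")
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T.astype(np.float64)))
    img.SetSpacing((geom.affine[0, 0], geom.affine[1, 1], geom.affine[2, 2]))
    img.SetOrigin(tuple(geom.affine[:3, 3]))
    return img


def _from_sitk(img: sitk.Image, geom: VolumeGeometry) -> np.ndarray:
    return sitk.GetArrayFromImage(img).T


@dataclass
class SessionTransform:
    """Composite spatial mapping between the two session spaces.

    ``to_A`` maps session-B world points into session-A space (this is the
    transform SimpleITK estimates with B fixed and A moving, and the one
    used to resample A-space images onto the B grid).  ``to_B`` is its
    fixed-point-inverted counterpart.  ``metric_trace`` records the final
    metric value per registration stage.
    """

    to_A: sitk.Transform
    to_B: sitk.Transform
    geometry_A: VolumeGeometry
    geometry_B: VolumeGeometry
    metric_trace: dict = field(default_factory=dict)

    def map_points_AB(self, pts: np.ndarray) -> np.ndarray:
        """Forward mapping: space-A physical coords -> space-B."""
        pts = np.atleast_2d(pts)
        return np.array([self.to_B.TransformPoint(tuple(p)) for p in pts])

    def map_points_BA(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return np.array([self.to_A.TransformPoint(tuple(p)) for p in pts])

    def roundtrip_residual(self, pts: np.ndarray) -> np.ndarray:
        """|T^-1(T(x)) - x| per point (mm); invertibility QC."""
        fwd = self.map_points_AB(pts)
        back = np.array([self.to_A.TransformPoint(tuple(p)) for p in fwd])
        return np.linalg.norm(back - np.atleast_2d(pts), axis=1)


@dataclass
class MatchedSegmentations:
    """Per-session masks restricted to the common anatomy."""

    maskA_matched: MuscleLabelMap
    maskB_matched: MuscleLabelMap
    counts: pd.DataFrame          # per muscle: matched voxels per space
    dropped: list                 # label names below the voxel floor
    propagated_A_in_B: MuscleLabelMap = None
    propagated_B_in_A: MuscleLabelMap = None


def register_sessions(
    waterA: ScalarVolume,
    waterB: ScalarVolume,
    bspline_spacing_mm: float = 30.0,
    rigid_only: bool = False,
    sampling_fraction: float = 0.25,
    seed: int = 12345,
    metric: str = "correlation",
) -> SessionTransform:
    """Three-stage registration of the session water images.

    Session A's water image is moved into session B's frame with a rigid,
    then affine, then b-spline stage (multi-resolution pyramid, linear
    interpolation).  The metric defaults to normalised cross-correlation --
    the two water images are the same modality -- with Mattes mutual
    information available (``metric="mi"``).  Raises
    :class:`RegistrationError` if the affine stage produces an implausible
    scaling (outside [0.8, 1.25]).
    """
    # single-threaded metric evaluation: multi-threaded reductions change
    # summation order and break run-to-run reproducibility
    prev_threads = sitk.ProcessObject.GetGlobalDefaultNumberOfThreads()
    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)
    try:
        return _register_sessions_impl(
            waterA, waterB, bspline_spacing_mm, rigid_only,
            sampling_fraction, seed, metric)
    finally:
        sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(prev_threads)


def _overlap_mask(geomB: VolumeGeometry, geomA: VolumeGeometry) -> "sitk.Image":
    """Fixed-image mask limited to the z-range both fields of view cover.

    The stack positions are known in world coordinates; slices of B that A
    cannot contain would otherwise let the optimiser 'improve' the metric
    by shifting them out of the moving domain (overlap shrinkage), which
    biases the through-plane alignment.
    """
    zA = geomA.affine[2, 3] + geomA.affine[2, 2] * np.arange(geomA.shape[2])
    zB = geomB.affine[2, 3] + geomB.affine[2, 2] * np.arange(geomB.shape[2])
    # a two-slice guard margin: masked points must stay inside the moving
    # domain for any plausible shift, otherwise the optimiser can still
    # 'improve' the metric by dropping end slices out of the overlap
    margin = 2.0 * abs(geomB.affine[2, 2])
    keep = (zB >= zA.min() + margin) & (zB <= zA.max() - margin)
    if not keep.any():
        keep = (zB >= zA.min()) & (zB <= zA.max())
    mask = np.zeros(geomB.shape, dtype=np.uint8)
    mask[:, :, keep] = 1
    img = sitk.GetImageFromArray(np.ascontiguousarray(mask.T))
    img.SetSpacing((geomB.affine[0, 0], geomB.affine[1, 1], geomB.affine[2, 2]))
    img.SetOrigin(tuple(geomB.affine[:3, 3]))
    return img


def _register_sessions_impl(waterA, waterB, bspline_spacing_mm, rigid_only,
                            sampling_fraction, seed, metric):
    fixed = _to_sitk(waterB)
    moving = _to_sitk(waterA)
    fixed_mask = _overlap_mask(waterB.geometry, waterA.geometry)
    trace = {}

    def _new_method():
        reg = sitk.ImageRegistrationMethod()
        if metric == "mi":
            reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
        elif metric == "correlation":
            reg.SetMetricAsCorrelation()
        else:
            raise ValueError("metric must be 'correlation' or 'mi'")
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(sampling_fraction, seed)
        reg.SetMetricFixedMask(fixed_mask)
        reg.SetInterpolator(sitk.sitkLinear)
        return reg

    # stage 1: similarity (rigid + uniform scale), initialised at identity.
    # Both sessions live in scanner world coordinates, so grid centres must
    # not be forcibly aligned (the field of view is re-planned between
    # visits), and the scale degree of freedom absorbs limb atrophy, which
    # would otherwise alias into a spurious shift along the thigh taper.
    reg = _new_method()
    init = sitk.Similarity3DTransform()
    centre = fixed.TransformContinuousIndexToPhysicalPoint(
        [(sz - 1) / 2.0 for sz in fixed.GetSize()])
    init.SetCenter(centre)
    reg.SetInitialTransform(init, inPlace=True)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=300,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-9)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    rigid = reg.Execute(fixed, moving)
    trace["rigid"] = reg.GetMetricValue()

    composite = sitk.CompositeTransform([rigid])
    if not rigid_only:
        # affine, initialised at the rigid solution
        reg = _new_method()
        aff = sitk.AffineTransform(3)
        aff.SetCenter(sitk.Similarity3DTransform(rigid).GetCenter())
        reg.SetInitialTransform(aff, inPlace=True)
        reg.SetMovingInitialTransform(rigid)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=0.5, minStep=1e-6, numberOfIterations=300,
            relaxationFactor=0.6, gradientMagnitudeTolerance=1e-9)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel([2, 1])
        reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
        aff = reg.Execute(fixed, moving)
        trace["affine"] = reg.GetMetricValue()
        sv = np.linalg.svd(np.array(aff.GetMatrix()).reshape(3, 3), compute_uv=False)
        if sv.min() < 0.8 or sv.max() > 1.25:
            raise RegistrationError(
                f"implausible affine scaling {sv}; check session images"
            )
        composite = sitk.CompositeTransform([rigid, aff])

        # b-spline; scaled gradient descent is more robust here than LBFGSB,
        # whose line search aborts on this sampled metric
        reg = _new_method()
        phys = [sz * sp for sz, sp in zip(fixed.GetSize(), fixed.GetSpacing())]
        mesh = [max(1, int(round(p / bspline_spacing_mm))) for p in phys]
        bsp = sitk.BSplineTransformInitializer(fixed, mesh)
        reg.SetInitialTransform(bsp, inPlace=True)
        reg.SetMovingInitialTransform(composite)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=2.0, minStep=1e-5, numberOfIterations=200,
            relaxationFactor=0.6, gradientMagnitudeTolerance=1e-9)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel([2, 1])
        reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
        bsp = reg.Execute(fixed, moving)
        trace["bspline"] = reg.GetMetricValue()
        composite = sitk.CompositeTransform([rigid, aff, bsp])

    to_A = composite  # maps B-space points to A-space
    to_B = _invert(composite, fixed)
    return SessionTransform(
        to_A=to_A, to_B=to_B,
        geometry_A=waterA.geometry, geometry_B=waterB.geometry,
        metric_trace=trace,
    )


def _invert(transform: sitk.Transform, reference: sitk.Image) -> sitk.Transform:
    """Invert a composite transform via displacement-field fixed-point iteration.

    The field domain is padded beyond the reference grid so that points
    near the field-of-view edge still fall inside it after the forward
    mapping (outside the field the transform degenerates to identity).
    """
    pad_xy, pad_z = 8, 3
    size = [int(s) for s in reference.GetSize()]
    spacing = list(reference.GetSpacing())
    origin = list(reference.GetOrigin())
    # halve the through-plane sampling: slices are thick and the field is
    # interpolated between them during inversion
    z_spacing = spacing[2] / 2.0
    nz = (size[2] + 2 * pad_z) * 2
    padded = sitk.Image(size[0] + 2 * pad_xy, size[1] + 2 * pad_xy,
                        nz, sitk.sitkFloat32)
    padded.SetSpacing((spacing[0], spacing[1], z_spacing))
    padded.SetOrigin((origin[0] - pad_xy * spacing[0],
                      origin[1] - pad_xy * spacing[1],
                      origin[2] - pad_z * spacing[2]))
    f = sitk.TransformToDisplacementFieldFilter()
    f.SetReferenceImage(padded)
    df = f.Execute(transform)
    inv = sitk.InvertDisplacementField(
        df, maximumNumberOfIterations=300,
        meanErrorToleranceThreshold=0.0005, maxErrorToleranceThreshold=0.01,
        enforceBoundaryCondition=False,
    )
    return sitk.DisplacementFieldTransform(inv)


def _resample_labels(labels: MuscleLabelMap, target_geom: VolumeGeometry,
                     transform: sitk.Transform) -> MuscleLabelMap:
    src = _to_sitk(labels)
    ref = _to_sitk(ScalarVolume(target_geom, np.zeros(target_geom.shape)))
    res = sitk.Resample(src, ref, transform, sitk.sitkNearestNeighbor, 0.0)
    arr = np.rint(_from_sitk(res, target_geom)).astype(labels.labels.dtype)
    return MuscleLabelMap(target_geom, arr, dict(labels.label_names))


def propagate_and_match(
    segA: MuscleLabelMap,
    segB: MuscleLabelMap,
    transform: SessionTransform,
    combine: str = "intersection",
    voxel_floor: int = DEFAULT_VOXEL_FLOOR,
) -> MatchedSegmentations:
    """Bidirectional propagation and per-muscle restriction to common anatomy.

    In space B each muscle's matched mask is ``(segA propagated to B)``
    combined with native ``segB`` (intersection by default); symmetrically
    in space A with the inverse transform.  Muscles whose matched voxel
    count falls below ``voxel_floor`` in either space are dropped from both.
    """
    if combine not in ("intersection", "union"):
        raise ValueError("combine must be 'intersection' or 'union'")
    propA_in_B = _resample_labels(segA, transform.geometry_B, transform.to_A)
    propB_in_A = _resample_labels(segB, transform.geometry_A, transform.to_B)

    names = dict(segA.label_names)
    outA = np.zeros_like(segA.labels)
    outB = np.zeros_like(segB.labels)
    rows = []
    for lbl, name in names.items():
        natA = segA.labels == lbl
        natB = segB.labels == lbl
        pA = propA_in_B.labels == lbl
        pB = propB_in_A.labels == lbl
        if combine == "intersection":
            commonB = pA & natB
            commonA = pB & natA
        else:
            commonB = pA | natB
            commonA = pB | natA
        rows.append(dict(label=lbl, name=name,
                         n_matched_A=int(commonA.sum()),
                         n_matched_B=int(commonB.sum()),
                         n_native_A=int(natA.sum()),
                         n_native_B=int(natB.sum())))
        outA[commonA] = lbl
        outB[commonB] = lbl
    counts = pd.DataFrame(rows)
    keep = (counts.n_matched_A >= voxel_floor) & (counts.n_matched_B >= voxel_floor)
    dropped = counts.loc[~keep, "name"].tolist()
    for lbl in counts.loc[~keep, "label"]:
        outA[outA == lbl] = 0
        outB[outB == lbl] = 0
    if keep.sum() == 0:
        raise RegistrationError("no common anatomy: every muscle fell below the voxel floor")
    return MatchedSegmentations(
        maskA_matched=MuscleLabelMap(segA.geometry, outA, names),
        maskB_matched=MuscleLabelMap(segB.geometry, outB, names),
        counts=counts,
        dropped=dropped,
        propagated_A_in_B=propA_in_B,
        propagated_B_in_A=propB_in_A,
    )


def alignment_qc(matched: MatchedSegmentations, segB: MuscleLabelMap | None = None) -> pd.DataFrame:
    """Per-muscle overlap report: Dice of propagated vs native masks,
    matched voxel counts per space, and the dropped-muscle flag.

    Dice is evaluated over the part of space B that space A's field of
    view covers at all (known from the stack geometries): outside it the
    propagated mask is undefined by construction, which is precisely the
    non-corresponding anatomy the matching step removes.
    """
    rows = []
    retained = set(np.unique(matched.maskB_matched.labels)) - {0}
    in_fov = None
    if segB is not None:
        gA = matched.maskA_matched.geometry
        gB = segB.geometry
        zA = gA.affine[2, 3] + gA.affine[2, 2] * np.arange(gA.shape[2])
        zB = gB.affine[2, 3] + gB.affine[2, 2] * np.arange(gB.shape[2])
        half = 0.5 * abs(gB.affine[2, 2])
        keep = (zB >= zA.min() - half) & (zB <= zA.max() + half)
        in_fov = np.zeros(gB.shape, dtype=bool)
        in_fov[:, :, keep] = True
    for _, r in matched.counts.iterrows():
        lbl = r.label
        row = dict(label=lbl, name=r["name"],
                   n_matched_A=r.n_matched_A, n_matched_B=r.n_matched_B,
                   dropped=r["name"] in matched.dropped)
        if segB is not None and matched.propagated_A_in_B is not None:
            a = (matched.propagated_A_in_B.labels == lbl) & in_fov
            b = (segB.labels == lbl) & in_fov
            denom = a.sum() + b.sum()
            row["dice"] = 2.0 * np.logical_and(a, b).sum() / denom if denom else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[df.label.isin(retained) | df.dropped]
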