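"""Session registration, bidirectional mask propagation and QC."""

import numpy as np
import pytest

from myotrack.align import (
    RegistrationError,
    alignment_qc,
    propagate_and_match,
    register_sessions,
)
from myotrack.core import MuscleLabelMap, ScalarVolume, VolumeGeometry


def test_identity_registration_on_identical_images(default_phantom, water_images):
    """waterB = waterA exactly: displacements stay below 0.15 mm."""
    wA = water_images["A"]
    T = register_sessions(wA, wA, rigid_only=True)
    fg = default_phantom.labels["A"].labels > 0
    rng = np.random.default_rng(0)
    sel = np.argwhere(fg)[rng.choice(fg.sum(), 100, replace=False)]
    pts = default_phantom.geometry["A"].voxel_to_world(sel.astype(float))
    moved = T.map_points_BA(pts)
    assert np.linalg.norm(moved - pts, axis=1).max() < 0.15


def test_known_translation_recovered(water_images):
    """A 9 mm shift between sessions is recovered within 0.3 mm."""
    wA = water_images["A"]
    shift_vox = 6  # 9 mm at 1.5 mm in-plane
    vals = np.zeros_like(wA.values)
    vals[shift_vox:] = wA.values[:-shift_vox]
    wB = ScalarVolume(wA.geometry, vals)
    T = register_sessions(wA, wB, rigid_only=True)
    p = np.array([[48.0, 48.0, 72.0]])
    back = T.map_points_BA(p)  # B-space point mapped into A-space
    assert back[0, 0] == pytest.approx(48.0 - 9.0, abs=0.3)
    assert back[0, 1] == pytest.approx(48.0, abs=0.3)


def test_default_phantom_warp_recovered(default_phantom, session_transform):
    """Rigid + 2 mm b-spline session repositioning: residual target-
    registration error at most the voxel size per axis on average —
    1.5 mm in-plane, half the 6 mm slice through-plane."""
    truth = default_phantom
    rng = np.random.default_rng(0)
    fg = truth.labels["A"].labels > 0
    sel = np.argwhere(fg)[rng.choice(fg.sum(), 300, replace=False)]
    pts = truth.geometry["A"].voxel_to_world(sel.astype(float))
    true_fwd = truth.deformation.forward(pts)
    back = session_transform.map_points_BA(true_fwd)
    err = back - pts
    assert np.linalg.norm(err[:, :2], axis=1).mean() <= 1.5
    assert np.abs(err[:, 2]).mean() <= 3.0


def test_transform_roundtrip_invertibility(default_phantom, session_transform):
    """T^-1(T(x)) within 0.1 mm for 99% of in-mask points."""
    truth = default_phantom
    fg = truth.labels["A"].labels > 0
    rng = np.random.default_rng(1)
    sel = np.argwhere(fg)[rng.choice(fg.sum(), 300, replace=False)]
    pts = truth.geometry["A"].voxel_to_world(sel.astype(float))
    res = session_transform.roundtrip_residual(pts)
    assert np.percentile(res, 99) < 0.1


def test_propagation_dice_and_matching(default_phantom, session_transform):
    """Propagated masks overlap the native follow-up segmentations well on
    the default phantom: high mean Dice, no dropped muscles, and at most
    the thinnest muscle below 0.90 (sartorius' wedge is a few voxels wide,
    where a ~1 mm residual warp costs disproportionate Dice)."""
    truth = default_phantom
    matched = propagate_and_match(truth.labels["A"], truth.labels["B"],
                                  session_transform)
    assert matched.dropped == []
    qc = alignment_qc(matched, truth.labels["B"])
    assert len(qc) == 12
    assert qc.dice.mean() >= 0.92
    assert qc.dice.min() >= 0.85
    below = qc[qc.dice < 0.90]
    assert len(below) <= 1


def test_containment_and_symmetry(default_phantom, session_transform):
    """Matched masks are subsets of the native segmentations, and the
    retained muscle set is the same in both spaces."""
    truth = default_phantom
    matched = propagate_and_match(truth.labels["A"], truth.labels["B"],
                                  session_transform)
    for m, native in ((matched.maskA_matched, truth.labels["A"]),
                      (matched.maskB_matched, truth.labels["B"])):
        inside = m.labels > 0
        assert np.array_equal(m.labels[inside], native.labels[inside])
    kept_A = set(np.unique(matched.maskA_matched.labels)) - {0}
    kept_B = set(np.unique(matched.maskB_matched.labels)) - {0}
    assert kept_A == kept_B


def test_union_mode_adds_voxels(default_phantom, session_transform):
    truth = default_phantom
    inter = propagate_and_match(truth.labels["A"], truth.labels["B"],
                                session_transform, combine="intersection")
    union = propagate_and_match(truth.labels["A"], truth.labels["B"],
                                session_transform, combine="union")
    assert (union.maskB_matched.labels > 0).sum() > (inter.maskB_matched.labels > 0).sum()
    with pytest.raises(ValueError):
        propagate_and_match(truth.labels["A"], truth.labels["B"],
                            session_transform, combine="nope")


def _identity_transform(geom):
    import SimpleITK as sitk

    from myotrack.align import SessionTransform

    t = sitk.Euler3DTransform()
    return SessionTransform(to_A=t, to_B=t, geometry_A=geom, geometry_B=geom)


def test_identical_sessions_identity_transform_keeps_everything():
    geom = VolumeGeometry.from_params((1.5, 1.5, 6.0), (16, 16, 4))
    labels = np.zeros((16, 16, 4), np.int16)
    labels[2:9, 2:14, :] = 1
    labels[9:14, 2:14, :] = 2
    lm = MuscleLabelMap(geom, labels, {1: "gracilis_R", 2: "sartorius_R"})
    matched = propagate_and_match(lm, lm, _identity_transform(geom), voxel_floor=10)
    assert np.array_equal(matched.maskA_matched.labels, labels)
    assert np.array_equal(matched.maskB_matched.labels, labels)
    assert matched.dropped == []
    qc = alignment_qc(matched, lm)
    assert np.allclose(qc.dice, 1.0)


def test_cropped_session_excludes_out_of_fov_voxels():
    """Session B missing the last two slices: matched masks exclude exactly
    the voxels whose counterpart falls outside B's field of view."""
    geom = VolumeGeometry.from_params((1.5, 1.5, 6.0), (16, 16, 6))
    labels = np.zeros((16, 16, 6), np.int16)
    labels[3:13, 3:13, :] = 1
    lmA = MuscleLabelMap(geom, labels, {1: "gracilis_R"})
    labelsB = labels.copy()
    labelsB[:, :, 4:] = 0  # cropped coverage
    lmB = MuscleLabelMap(geom, labelsB, {1: "gracilis_R"})
    matched = propagate_and_match(lmA, lmB, _identity_transform(geom), voxel_floor=10)
    assert np.array_equal(matched.maskA_matched.labels, labelsB)
    assert np.array_equal(matched.maskB_matched.labels, labelsB)


def test_muscle_absent_in_one_session_dropped():
    geom = VolumeGeometry.from_params((1.5, 1.5, 6.0), (16, 16, 4))
    labels = np.zeros((16, 16, 4), np.int16)
    labels[2:9, 2:14, :] = 1
    labels[9:14, 2:14, :] = 2
    lmA = MuscleLabelMap(geom, labels, {1: "gracilis_R", 2: "sartorius_R"})
    labelsB = labels.copy()
    labelsB[labelsB == 2] = 0
    lmB = MuscleLabelMap(geom, labelsB, {1: "gracilis_R", 2: "sartorius_R"})
    matched = propagate_and_match(lmA, lmB, _identity_transform(geom), voxel_floor=10)
    assert matched.dropped == ["sartorius_R"]
    qc = alignment_qc(matched, lmB)
    assert bool(qc[qc.name == "sartorius_R"].dropped.iloc[0])


def test_no_common_anatomy_raises():
    geom = VolumeGeometry.from_params((1.5, 1.5, 6.0), (16, 16, 4))
    labels = np.zeros((16, 16, 4), np.int16)
    labels[2:8, 2:8, :] = 1
    lmA = MuscleLabelMap(geom, labels, {1: "gracilis_R"})
    other = np.zeros_like(labels)
    other[10:15, 10:15, :] = 1
    lmB = MuscleLabelMap(geom, other, {1: "gracilis_R"})
    with pytest.raises(RegistrationError, match="no common anatomy"):
        propagate_and_match(lmA, lmB, _identity_transform(geom), voxel_floor=10)
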