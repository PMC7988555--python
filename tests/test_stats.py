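"""Mixed model, subset analyses and paired tests.

The independent oracle for the mixed model is closed-form generalised least
squares with the true variance components: for known covariance V the fixed
effects are (X' V^-1 X)^-1 X' V^-1 y.
"""

import numpy as np
import pandas as pd
import pytest

from myotrack.core import LOW_FAT_MUSCLES, MUSCLE_GROUPS, MUSCLES
from myotrack.phantom import simulate_cohort_records
from myotrack.stats import LMMSpec, fit_lmm, paired_tests, subset_analysis, type1_check


def long_from_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Helper: wide per-unit (yA, yB) frame to long records."""
    rows = []
    for _, r in pairs.iterrows():
        for t, y in (("A", r.yA), ("B", r.yB)):
            rows.append(dict(subject=r.subject, muscle=r.muscle, side=r.side,
                             muscle_group=MUSCLE_GROUPS.get(r.muscle, "other"),
                             time_point=t, value=y))
    return pd.DataFrame(rows)


def test_no_change_gives_zero_time_effect():
    rng = np.random.default_rng(0)
    rows = []
    for s in range(6):
        for m in MUSCLES:
            y = rng.uniform(20, 60)
            rows.append(dict(subject=s, muscle=m, side="R", yA=y, yB=y))
    res = fit_lmm(long_from_pairs(pd.DataFrame(rows)))
    assert res.time_effect == pytest.approx(0.0, abs=1e-8)
    assert res.time_p > 0.99


def test_balanced_single_group_equals_mean_paired_difference():
    """With one muscle group and complete pairs, the LMM time effect equals
    the mean paired difference and Wald agrees with the paired t direction."""
    rng = np.random.default_rng(5)
    rows = []
    for s in range(8):
        for m in ("rectus_femoris", "vastus_lateralis", "vastus_medialis"):
            yA = rng.normal(40, 8)
            rows.append(dict(subject=s, muscle=m, side="R", yA=yA,
                             yB=yA + rng.normal(1.0, 2.0)))
    df = long_from_pairs(pd.DataFrame(rows))
    res = fit_lmm(df, LMMSpec(baseline_covariate=False))
    wide = pd.DataFrame(rows)
    d = (wide.yB - wide.yA)
    assert res.time_effect == pytest.approx(d.mean(), abs=1e-6)
    assert "single muscle group" in " ".join(res.flags)
    tests = paired_tests(df.rename(columns={"value": "score"}).pivot_table(
        index=["subject", "muscle"], columns="time_point", values="score")
        .reset_index().melt(id_vars=["subject", "muscle"], var_name="time_point",
                            value_name="score")
        .pivot_table(index="subject", columns="time_point", values="score")
        .reset_index().melt(id_vars="subject", var_name="time_point", value_name="score"))
    assert np.sign(tests.iloc[0].mean_diff) == np.sign(res.time_effect)


def test_fixed_effects_match_gls_oracle():
    """Known variance components: the REML fit's fixed effects agree with
    closed-form GLS using the true covariance."""
    rng = np.random.default_rng(9)
    n_sub, n_grp, per = 8, 4, 6
    sub_sd, grp_sd, res_sd = 1.5, 1.0, 2.0
    rows = []
    for s in range(n_sub):
        us = rng.normal(0, sub_sd)
        for g in range(n_grp):
            vg_key = f"g{g}"
            for k in range(per):
                base = rng.normal(40, 6)
                rows.append(dict(subject=s, grp=vg_key, baseline=base,
                                 change=1.0 + us + 0.1 * (base - 40) + rng.normal(0, res_sd)))
    # the group effects are shared across subjects (crossed): add afterwards
    df = pd.DataFrame(rows)
    vg = {f"g{g}": rng.normal(0, grp_sd) for g in range(n_grp)}
    df["change"] += df.grp.map(vg)

    # GLS oracle with the TRUE components
    Zs = pd.get_dummies(df.subject).to_numpy(float)
    Zg = pd.get_dummies(df.grp).to_numpy(float)
    V = (sub_sd**2 * Zs @ Zs.T + grp_sd**2 * Zg @ Zg.T
         + res_sd**2 * np.eye(len(df)))
    X = np.column_stack([np.ones(len(df)), df.baseline - df.baseline.mean()])
    Vi = np.linalg.inv(V)
    beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df.change.to_numpy())

    # the package fit (REML estimates the components from these data)
    long = []
    for i, r in df.iterrows():
        long.append(dict(subject=r.subject, muscle=f"m{i}", side="R",
                         muscle_group=r.grp, time_point="A", value=r.baseline))
        long.append(dict(subject=r.subject, muscle=f"m{i}", side="R",
                         muscle_group=r.grp, time_point="B", value=r.baseline + r.change))
    res = fit_lmm(pd.DataFrame(long))
    # agreement within a fraction of the SE (components are estimated, not known)
    assert res.time_effect == pytest.approx(beta_gls[0], abs=0.3 * res.time_se)


def test_slope_recovery_within_tolerance():
    """Cohorts generated at the published all-muscle slope: the mean
    estimate over 40 replicates recovers it."""
    rng = np.random.default_rng(21)
    ests = [fit_lmm(simulate_cohort_records(rng, slope_pct=1.28,
                                            low_mode_slope_pct=1.28)).time_effect
            for _ in range(40)]
    assert np.mean(ests) == pytest.approx(1.28, abs=0.2)


def test_empty_exclusion_identical_to_full_fit():
    rng = np.random.default_rng(3)
    df = simulate_cohort_records(rng)
    full = fit_lmm(df)
    sub = subset_analysis(df, exclude=())
    assert sub.time_effect == pytest.approx(full.time_effect, abs=1e-12)


def test_subset_estimate_exceeds_full_when_excluded_muscles_are_static():
    """If the excluded muscles truly have zero slope, removing them raises
    the estimated slope (averaged over replicates)."""
    rng = np.random.default_rng(17)
    d_full, d_sub = [], []
    for _ in range(25):
        df = simulate_cohort_records(rng, slope_pct=1.59, low_mode_slope_pct=0.0,
                                     low_slope_muscles=LOW_FAT_MUSCLES)
        d_full.append(fit_lmm(df).time_effect)
        d_sub.append(subset_analysis(df, exclude=LOW_FAT_MUSCLES).time_effect)
    assert np.mean(d_sub) > np.mean(d_full)
    assert np.mean(d_sub) == pytest.approx(1.59, abs=0.2)


def test_stratification_splits_by_baseline():
    rng = np.random.default_rng(8)
    df = simulate_cohort_records(rng)
    out = subset_analysis(df, stratify_ff_threshold=30.0)
    assert set(out) == {"low", "high"}
    assert out["high"].n_pairs > out["low"].n_pairs  # high-FF mode dominates


def test_paired_t_matches_closed_form():
    """Pairs with differences (1, 1, 2): t = mean/ (sd/sqrt(3)) exactly."""
    tab = pd.DataFrame(dict(subject=[1, 2, 3] * 2,
                            time_point=["A"] * 3 + ["B"] * 3,
                            score=[1.0, 2.0, 3.0, 2.0, 3.0, 5.0]))
    out = paired_tests(tab)
    d = np.array([1.0, 1.0, 2.0])
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
    assert out.iloc[0].t == pytest.approx(t_hand, abs=1e-12)
    assert out.iloc[0].n == 3
    assert out.iloc[0].df == 2


def test_pairwise_deletion_reports_reduced_n():
    """One of 10 subjects missing follow-up: n = 9."""
    rows = [dict(subject=s, time_point="A", score=float(s)) for s in range(10)]
    rows += [dict(subject=s, time_point="B", score=float(s) + 1) for s in range(9)]
    out = paired_tests(pd.DataFrame(rows))
    assert out.iloc[0].n == 9


def test_zero_variance_and_too_few_pairs_flagged():
    tab = pd.DataFrame(dict(subject=[1, 2, 1, 2], time_point=list("AABB"),
                            score=[3.0, 4.0, 3.0, 4.0]))
    out = paired_tests(tab)
    assert out.iloc[0].flag == "zero variance of differences"
    assert np.isnan(out.iloc[0].p)
    tab1 = pd.DataFrame(dict(subject=[1, 1], time_point=["A", "B"], score=[1.0, 2.0]))
    out1 = paired_tests(tab1)
    assert out1.iloc[0].flag == "fewer than 2 complete pairs"


def test_estimates_invariant_to_record_order_and_group_labels():
    rng = np.random.default_rng(30)
    df = simulate_cohort_records(rng)
    res1 = fit_lmm(df)
    shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
    res2 = fit_lmm(shuffled)
    assert res2.time_effect == pytest.approx(res1.time_effect, abs=1e-8)
    relabel = df.copy()
    relabel["muscle_group"] = relabel.muscle_group.map(
        lambda g: {"adductors": "g1", "hamstrings": "g2", "quadriceps": "g3",
                   "sartorius": "g4"}[g])
    res3 = fit_lmm(relabel)
    assert res3.time_effect == pytest.approx(res1.time_effect, abs=1e-8)


def test_huge_effect_always_detected():
    rate = type1_check(seed=99, n_replicates=10, slope_pct=10.0, residual_sd=0.5,
                       subject_sd=0.1, group_sd=0.1)
    assert rate == 1.0


def test_snr_covariate_requires_column():
    rng = np.random.default_rng(2)
    df = simulate_cohort_records(rng).drop(columns=["SNR"])
    with pytest.raises(ValueError, match="SNR"):
        fit_lmm(df, LMMSpec(include_snr=True))
    df2 = simulate_cohort_records(rng)
    res = fit_lmm(df2, LMMSpec(include_snr=True))
    assert "snr_c" in res.params.index
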