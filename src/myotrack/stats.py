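"""Statistical layer: paired t-tests and the longitudinal mixed-effects model.

The change in a qMRI outcome over the follow-up interval is modelled with a
linear mixed-effects model with crossed random intercepts for *subjects*
and *muscle groups*, the subject's baseline level of the outcome as a fixed
covariate, and -- for the diffusion outcomes -- the per-muscle SNR as an
additional covariate.  Inference on the time effect uses the Wald statistic
with a normal reference; the significance threshold is 0.05.

A note on the design.  With one baseline and one follow-up measurement per
muscle, conditioning on the observed baseline value makes the baseline rows
deterministic, so the model is estimated on the paired changes:

    change_sm = beta_t + beta_b * baseline_c + u_subject + v_group + e_sm

This is the well-posed reduction of the two-time-point formulation
(outcome ~ time + baseline): the time coefficient ``beta_t`` equals the
baseline-adjusted mean change, reduces to the mean paired difference in the
balanced single-group case, and its Wald test is correctly calibrated
(which a literal both-rows fit with the muscle's own baseline as covariate
is not -- the duplicated rows halve the residual variance estimate).
Time-point marginal means are reported alongside: mean(A) with a
subject-clustered standard error, and mean(B) = mean(A) + beta_t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .core import MUSCLE_GROUPS

__all__ = [
    "LMMSpec",
    "LMMResult",
    "fit_lmm",
    "subset_analysis",
    "paired_tests",
    "type1_check",
]

ALPHA = 0.05
Z95 = 1.959963984540054


@dataclass(frozen=True)
class LMMSpec:
    """Configuration of the longitudinal mixed model."""

    outcome: str = "FF"
    include_snr: bool = False
    alpha: float = ALPHA
    reml: bool = True
    group_level: str = "functional"  # random intercept over functional groups
    baseline_covariate: bool = True


@dataclass
class LMMResult:
    """Fixed effects, Wald inference and variance components of one fit."""

    outcome: str
    params: pd.Series
    bse: pd.Series
    wald_z: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    time_effect: float
    time_se: float
    time_p: float
    time_ci: tuple
    mean_A: float
    mean_A_se: float
    mean_B: float
    mean_B_se: float
    variance_components: dict
    n_pairs: int
    n_subjects: int
    flags: list = field(default_factory=list)

    def significant(self, alpha: float = ALPHA) -> bool:
        return self.time_p < alpha

    def summary_row(self) -> dict:
        """One row in the layout of the cohort's outcome table."""
        return dict(
            outcome=self.outcome, n=self.n_pairs,
            mean_A=self.mean_A, se_A=self.mean_A_se,
            mean_B=self.mean_B, se_B=self.mean_B_se,
            difference=self.time_effect, difference_se=self.time_se,
            ci_low=self.time_ci[0], ci_high=self.time_ci[1],
            p=self.time_p,
        )


def _paired_frame(records: pd.DataFrame, outcome_col: str) -> pd.DataFrame:
    """Wide per-unit frame: one row per (subject, muscle, side) with both
    time-points present (pairwise deletion feeds the varying N)."""
    df = records.copy()
    if "muscle_group" not in df.columns:
        df["muscle_group"] = df["muscle"].map(MUSCLE_GROUPS)
    if "side" not in df.columns:
        df["side"] = "R"
    keys = ["subject", "muscle", "side", "muscle_group"]
    agg = {"value": "mean"}
    if "SNR" in df.columns:
        agg["SNR"] = "mean"
    wide = df.pivot_table(index=keys, columns="time_point",
                          values=outcome_col, aggfunc="mean")
    if "A" not in wide.columns or "B" not in wide.columns:
        raise ValueError("both time-points must be represented")
    wide = wide.dropna(subset=["A", "B"]).reset_index()
    wide["change"] = wide["B"] - wide["A"]
    wide["baseline_c"] = wide["A"] - wide["A"].mean()
    if "SNR" in df.columns:
        snr = df.groupby(keys)["SNR"].mean().reset_index()
        wide = wide.merge(snr, on=keys, how="left")
        wide["snr_c"] = wide["SNR"] - wide["SNR"].mean()
    return wide


def fit_lmm(records: pd.DataFrame, spec: LMMSpec = LMMSpec(),
            outcome_col: str = "value") -> LMMResult:
    """REML fit of the longitudinal mixed model on one outcome.

    ``records`` is a long table with columns ``subject``, ``muscle``,
    ``side`` (optional), ``muscle_group`` (derived from the muscle name if
    absent), ``time_point`` in {"A", "B"} and the outcome in
    ``outcome_col`` (plus ``SNR`` when the spec asks for it).
    """
    wide = _paired_frame(records, outcome_col)
    n_sub = wide.subject.nunique()
    n_grp = wide.muscle_group.nunique()
    if n_sub < 2:
        raise ValueError("need at least two subjects")
    flags = []

    fixed = "change ~ 1"
    if spec.baseline_covariate:
        fixed += " + baseline_c"
    if spec.include_snr:
        if "snr_c" not in wide.columns:
            raise ValueError("SNR covariate requested but no SNR column present")
        fixed += " + snr_c"

    vc = {"subject": "0 + C(subject)"}
    if n_grp >= 2:
        vc["muscle_group"] = "0 + C(muscle_group)"
    else:
        flags.append("single muscle group: subject-only random intercept")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(fixed, wide, groups=np.ones(len(wide)), vc_formula=vc)
        fit = model.fit(reml=spec.reml, method=["lbfgs", "cg", "powell"], maxiter=200)

    if not fit.converged:
        flags.append("optimizer did not report convergence")
    vcomp = {name: float(v) for name, v in zip(model.exog_vc.names, fit.vcomp)}
    vcomp["residual"] = float(fit.scale)
    for name, v in vcomp.items():
        if name != "residual" and v < 1e-8:
            flags.append(f"variance component '{name}' pinned at 0 (singular fit)")

    params = fit.params[fit.params.index != "Group Var"]
    bse = fit.bse[params.index]
    zvals = params / bse
    pvals = pd.Series(2 * sps.norm.sf(np.abs(zvals)), index=params.index)
    ci = pd.DataFrame({"low": params - Z95 * bse, "high": params + Z95 * bse})

    te = float(params["Intercept"])
    tse = float(bse["Intercept"])
    if vcomp["residual"] < 1e-12 and all(v < 1e-12 for v in vcomp.values()):
        # perfect fit (e.g. follow-up identical to baseline): the Wald
        # statistic is 0/0; report certainty about the point estimate
        flags.append("degenerate: zero residual variance")
        tse = 0.0
        pvals[:] = np.where(np.abs(params) < 1e-10, 1.0, 0.0)
    mean_a = float(wide["A"].mean())
    sub_means = wide.groupby("subject")["A"].mean()
    mean_a_se = float(sub_means.std(ddof=1) / np.sqrt(n_sub))
    return LMMResult(
        outcome=spec.outcome,
        params=params, bse=bse, wald_z=zvals, pvalues=pvals, conf_int=ci,
        time_effect=te, time_se=tse,
        time_p=float(pvals["Intercept"]),
        time_ci=(te - Z95 * tse, te + Z95 * tse),
        mean_A=mean_a, mean_A_se=mean_a_se,
        mean_B=mean_a + te, mean_B_se=mean_a_se,
        variance_components=vcomp,
        n_pairs=len(wide), n_subjects=n_sub,
        flags=flags,
    )


def subset_analysis(
    records: pd.DataFrame,
    spec: LMMSpec = LMMSpec(),
    exclude: tuple = (),
    restrict_to: tuple = (),
    stratify_ff_threshold: float | None = None,
    outcome_col: str = "value",
):
    """Re-fit the mixed model on muscle subsets.

    ``exclude`` drops the named muscles; ``restrict_to`` keeps only them;
    ``stratify_ff_threshold`` instead splits units by baseline value
    (<= threshold vs >) and returns a dict of two fits.  An empty exclusion
    reproduces the full fit.
    """
    df = records.copy()
    if exclude and restrict_to:
        raise ValueError("use either exclude or restrict_to")
    if exclude:
        df = df[~df.muscle.isin(exclude)]
    if restrict_to:
        df = df[df.muscle.isin(restrict_to)]
    if df.empty:
        raise ValueError("subset is empty")
    if stratify_ff_threshold is None:
        return fit_lmm(df, spec, outcome_col)
    wide = _paired_frame(df, outcome_col)
    units_low = wide[wide["A"] <= stratify_ff_threshold][["subject", "muscle", "side"]]
    out = {}
    for name, unit_sel in (("low", units_low),
                           ("high", wide[wide["A"] > stratify_ff_threshold][["subject", "muscle", "side"]])):
        sel = df.merge(unit_sel, on=["subject", "muscle", "side"])
        if sel.empty:
            out[name] = None
            continue
        out[name] = fit_lmm(sel, spec, outcome_col)
    return out


def paired_tests(table: pd.DataFrame, score_columns=None,
                 subject_col: str = "subject", time_col: str = "time_point") -> pd.DataFrame:
    """Paired t-tests baseline vs follow-up with pairwise deletion.

    ``table`` is wide per (subject, time_point); every column in
    ``score_columns`` (default: all numeric score columns) is tested.
    Subjects missing either time-point for a score are dropped from that
    score's test; ``n`` reports the complete pairs used.  Degenerate cases
    are flagged: fewer than 2 complete pairs -> NA; zero variance of the
    differences -> NA with a flag.
    """
    if score_columns is None:
        score_columns = [c for c in table.columns
                         if c not in (subject_col, time_col)
                         and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for col in score_columns:
        wide = table.pivot_table(index=subject_col, columns=time_col, values=col,
                                 aggfunc="mean")
        if "A" not in wide.columns or "B" not in wide.columns:
            rows.append(dict(score=col, n=0, mean_A=np.nan, mean_B=np.nan,
                             mean_diff=np.nan, t=np.nan, df=np.nan, p=np.nan,
                             flag="missing time-point"))
            continue
        pairs = wide.dropna(subset=["A", "B"])
        n = len(pairs)
        if n < 2:
            rows.append(dict(score=col, n=n, mean_A=np.nan, mean_B=np.nan,
                             mean_diff=np.nan, t=np.nan, df=np.nan, p=np.nan,
                             flag="fewer than 2 complete pairs"))
            continue
        d = pairs["B"] - pairs["A"]
        flag = ""
        if d.std(ddof=1) < 1e-12:
            t = np.nan
            p = np.nan
            flag = "zero variance of differences"
        else:
            t, p = sps.ttest_rel(pairs["B"], pairs["A"])
        rows.append(dict(score=col, n=n,
                         mean_A=pairs["A"].mean(), mean_B=pairs["B"].mean(),
                         mean_diff=d.mean(), t=t, df=n - 1, p=p, flag=flag))
    return pd.DataFrame(rows)


def type1_check(
    seed: int,
    n_replicates: int = 1000,
    alpha: float = ALPHA,
    slope_pct: float = 0.0,
    lmm_spec: LMMSpec = LMMSpec(),
    **cohort_kwargs,
) -> float:
    """Empirical rejection rate of the Wald time-effect test.

    Simulates ``n_replicates`` cohorts with the given true slope (zero for
    a null calibration) via :func:`myotrack.phantom.simulate_cohort_records`
    and returns the fraction with time-effect p < ``alpha``.
    """
    from .phantom import simulate_cohort_records

    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_replicates):
        df = simulate_cohort_records(rng, slope_pct=slope_pct,
                                     low_mode_slope_pct=slope_pct, **cohort_kwargs)
        res = fit_lmm(df, lmm_spec)
        rej += res.time_p < alpha
    return rej / n_replicates
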