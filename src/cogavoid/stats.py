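"""Statistical layer: condition aggregation, paired effect sizes with
noncentral-t confidence intervals, the within- and cross-phase linear
mixed-effects models, and sensitivity power analysis.

The primary contrast throughout is CS+ versus CS- within a phase, summarised
per participant and expressed as Cohen's d_z (mean difference over the SD of
differences) with Hedges' small-sample correction
``g = d * J``, ``J = 1 - 3 / (4*df - 1)``, ``df = n - 1``.  Confidence
intervals for g invert the noncentral-t distribution of the paired
t statistic.  Mixed models follow the two published structures
``DV ~ CS * trial_num + (1 | ppid)`` (within phase) and
``DV ~ CS * phase + trial_num + (1 | ppid)`` (across two phases), estimated
with statsmodels' MixedLM; trial number enters as a linear numeric predictor.
p-values are descriptive (no multiplicity correction is applied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "EffectSizeResult",
    "ModelResult",
    "cohort_trial_table",
    "aggregate_by_condition",
    "paired_effect_size",
    "effect_size_table",
    "fit_within_phase_model",
    "fit_cross_phase_model",
    "power_paired_t",
    "sensitivity_dz",
]

CS_PLUS = "CS+"
CS_MINUS = "CS-"

DV_COLUMNS = [
    "mean_dist_m", "max_dist_m", "min_dist_m", "path_len_m",
    "max_speed_mps", "head_angle_deg", "rt_s",
]


@dataclass
class EffectSizeResult:
    """Paired standardized mean difference for the CS+/CS- contrast."""

    cohens_d: float
    hedges_g: float
    ci_low: float
    ci_high: float
    n_pairs: int
    variant: str = "dz"

    def __str__(self) -> str:
        return (
            f"g = {self.hedges_g:.2f} [{self.ci_low:.2f}, {self.ci_high:.2f}] "
            f"(d = {self.cohens_d:.2f}, n = {self.n_pairs})"
        )


@dataclass
class ModelResult:
    """Fixed-effect estimates of one mixed model (or its fallback contrast)."""

    params: pd.DataFrame  # index term; columns estimate, se, stat, p
    random_intercept_var: float
    resid_var: float
    df_resid: float
    converged: bool
    method: str = "lmm"  # "lmm" or "rm_fallback"

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.params.loc[term, "se"])

    def pvalue(self, term: str) -> float:
        return float(self.params.loc[term, "p"])

    def summary(self) -> str:
        lines = [f"Mixed model ({self.method}); converged={self.converged}; "
                 f"random-intercept var={self.random_intercept_var:.4g}; "
                 f"residual var={self.resid_var:.4g}; df_resid={self.df_resid:.0f}"]
        lines.append(self.params.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# tables and aggregation


def cohort_trial_table(sessions) -> pd.DataFrame:
    """Long trial table (one row per trial per participant) from SessionLogs."""
    frames = [s.trial_table() for s in sessions]
    return pd.concat(frames, ignore_index=True)


def aggregate_by_condition(
    table: pd.DataFrame, dv: str, phase: str
) -> pd.DataFrame:
    """Per-participant CS+ and CS- means of ``dv`` within ``phase``.

    Participants missing a condition (e.g. all reaction times censored) are
    dropped with a warning; the result has columns ppid, cs_plus, cs_minus.
    """
    sub = table[(table["phase"] == phase) & table["condition"].isin([CS_PLUS, CS_MINUS])]
    if sub.empty:
        raise ValueError(f"no trials for phase {phase!r}")
    means = (
        sub.groupby(["ppid", "condition"], sort=True)[dv]
        .mean()
        .unstack("condition")
        .rename(columns={CS_PLUS: "cs_plus", CS_MINUS: "cs_minus"})
    )
    for col in ("cs_plus", "cs_minus"):
        if col not in means.columns:
            means[col] = np.nan
    complete = means.dropna(subset=["cs_plus", "cs_minus"])
    dropped = sorted(set(means.index) - set(complete.index))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} participant(s) missing a condition mean "
            f"for {dv} in {phase}: {dropped}",
            stacklevel=2,
        )
    return complete[["cs_plus", "cs_minus"]].reset_index()


# ---------------------------------------------------------------------------
# paired effect sizes


def _hedges_j(df: int) -> float:
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def _safe_nct_cdf(t: float, df: int, nc: float) -> float:
    """nct.cdf with far-tail underflow (NaN) resolved by the tail side."""
    v = sps.nct.cdf(t, df, nc)
    if np.isnan(v):
        return 0.0 if t < nc else 1.0
    return float(v)


def _nct_ci_on_d(t_obs: float, df: int, n: int, conf: float) -> tuple[float, float]:
    """CI on d by inverting the noncentral-t distribution of the paired t."""
    alpha = 1.0 - conf

    def solve(target_p: float) -> float:
        f = lambda nc: _safe_nct_cdf(t_obs, df, nc) - target_p
        lo, hi = t_obs - 50 - 10 * abs(t_obs), t_obs + 50 + 10 * abs(t_obs)
        if f(lo) < 0:  # cdf at lo below target even for tiny nc
            return lo
        if f(hi) > 0:
            return hi
        return optimize.brentq(f, lo, hi, xtol=1e-10)

    nc_low = solve(1.0 - alpha / 2.0)
    nc_high = solve(alpha / 2.0)
    return nc_low / np.sqrt(n), nc_high / np.sqrt(n)


def paired_effect_size(
    cs_plus: Sequence[float],
    cs_minus: Optional[Sequence[float]] = None,
    conf: float = 0.95,
    variant: str = "dz",
) -> EffectSizeResult:
    """Cohen's d and Hedges' g for paired condition means, with a CI on g.

    With one argument the input is taken as the vector of paired differences.
    ``variant='dz'`` (default) standardises by the SD of the differences;
    ``variant='dav'`` by the mean of the two condition SDs.
    """
    if cs_minus is None:
        diffs = np.asarray(cs_plus, dtype=float)
    else:
        plus = np.asarray(cs_plus, dtype=float)
        minus = np.asarray(cs_minus, dtype=float)
        if plus.shape != minus.shape:
            raise ValueError("condition vectors must have equal length")
        diffs = plus - minus
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd_diff = float(np.std(diffs, ddof=1))
    if sd_diff == 0:
        raise ValueError("zero-variance differences: effect size undefined")
    mean_diff = float(np.mean(diffs))
    if variant == "dz":
        d = mean_diff / sd_diff
    elif variant == "dav":
        if cs_minus is None:
            raise ValueError("d_av needs both condition vectors")
        sd_av = (np.std(plus, ddof=1) + np.std(minus, ddof=1)) / 2.0
        if sd_av == 0:
            raise ValueError("zero-variance conditions: effect size undefined")
        d = mean_diff / float(sd_av)
    else:
        raise ValueError(f"unknown d variant {variant!r}")

    df = n - 1
    j = _hedges_j(df)
    g = d * j
    # CI via the noncentral-t pivot of the paired t statistic (d_z scale)
    t_obs = (mean_diff / sd_diff) * np.sqrt(n)
    d_lo, d_hi = _nct_ci_on_d(t_obs, df, n, conf)
    return EffectSizeResult(
        cohens_d=d, hedges_g=g, ci_low=d_lo * j, ci_high=d_hi * j,
        n_pairs=n, variant=variant,
    )


def effect_size_table(
    table: pd.DataFrame,
    dvs: Sequence[str] = DV_COLUMNS,
    phases: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Tidy table of paired effect sizes per DV per phase."""
    if phases is None:
        phases = [p for p in table["phase"].unique() if p != "practice"]
    rows = []
    for phase in phases:
        for dv in dvs:
            if dv not in table.columns:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pairs = aggregate_by_condition(table, dv, phase)
                    res = paired_effect_size(pairs["cs_plus"], pairs["cs_minus"])
            except ValueError:
                continue
            rows.append(
                {"phase": phase, "dv": dv, "cohens_d": res.cohens_d,
                 "hedges_g": res.hedges_g, "ci_low": res.ci_low,
                 "ci_high": res.ci_high, "n_pairs": res.n_pairs}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed models


def _prepare(table: pd.DataFrame, dv: str, phase: Optional[str]) -> pd.DataFrame:
    sub = table[table["condition"].isin([CS_PLUS, CS_MINUS])].copy()
    if phase is not None:
        sub = sub[sub["phase"] == phase]
    sub = sub.dropna(subset=[dv])
    if sub.empty:
        raise ValueError(f"no usable rows for {dv}" + (f" in {phase}" if phase else ""))
    if sub["ppid"].nunique() < 2:
        raise ValueError("mixed model needs >= 2 participants (random intercept)")
    sub["cs"] = (sub["condition"] == CS_PLUS).astype(float)
    sub["trial_num"] = sub["trial_num"].astype(float)
    return sub


def _fit_mixedlm(data: pd.DataFrame, formula: str) -> ModelResult:
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data["ppid"])
        fit = None
        last_err: Exception = ValueError("mixed model fit failed")
        for method in ("lbfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_err = exc
        if fit is None:
            raise last_err
    fe = fit.fe_params
    terms = list(fe.index)
    params = pd.DataFrame(
        {
            "estimate": fe.values,
            "se": fit.bse_fe.values,
            "stat": fit.tvalues[terms].values,
            "p": fit.pvalues[terms].values,
        },
        index=terms,
    )
    df_resid = float(len(data) - len(terms) - 1)
    return ModelResult(
        params=params,
        random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
        resid_var=float(fit.scale),
        df_resid=df_resid,
        converged=bool(getattr(fit, "converged", True)),
        method="lmm",
    )


def _rm_fallback(data: pd.DataFrame, dv: str) -> ModelResult:
    """Repeated-measures contrast used when the mixed model fails to fit:
    paired t-test on per-participant condition means (CS effect only)."""
    means = data.groupby(["ppid", "cs"])[dv].mean().unstack("cs")
    diffs = (means[1.0] - means[0.0]).dropna()
    t, p = sps.ttest_rel(means[1.0].dropna(), means[0.0].dropna())
    est = float(diffs.mean())
    se = float(diffs.std(ddof=1) / np.sqrt(len(diffs)))
    params = pd.DataFrame(
        {"estimate": [est], "se": [se], "stat": [float(t)], "p": [float(p)]},
        index=["cs"],
    )
    return ModelResult(
        params=params, random_intercept_var=np.nan, resid_var=np.nan,
        df_resid=float(len(diffs) - 1), converged=False, method="rm_fallback",
    )


def fit_within_phase_model(
    table: pd.DataFrame, dv: str, phase: Optional[str] = None
) -> ModelResult:
    """``DV ~ CS * trial_num + (1 | ppid)`` within one phase.

    ``cs`` is coded 1 for CS+ and 0 for CS-; ``trial_num`` is the within-phase
    trial index across conditions, entered linearly.  Falls back to the
    repeated-measures paired contrast when the mixed model fails.
    """
    data = _prepare(table, dv, phase)
    if data["trial_num"].nunique() < 2:
        raise ValueError("need >= 2 trials for the trial_num predictor")
    formula = f"{dv} ~ cs * trial_num"
    try:
        return _fit_mixedlm(data, formula)
    except (np.linalg.LinAlgError, ValueError):
        return _rm_fallback(data, dv)


def fit_cross_phase_model(
    table: pd.DataFrame, dv: str, phases: Sequence[str]
) -> ModelResult:
    """``DV ~ CS * phase + trial_num + (1 | ppid)`` across exactly two phases.

    The CS-by-phase interaction is the criterion for extinction (avoidance vs
    extinction) and reinstatement (extinction vs reinstatement); ``phase`` is
    coded 0 for the first phase supplied and 1 for the second, so the
    interaction's sign follows the supplied order.
    """
    if len(phases) != 2:
        raise ValueError("fit_cross_phase_model needs exactly 2 phases")
    data = _prepare(table[table["phase"].isin(phases)], dv, None)
    if set(data["phase"].unique()) != set(phases):
        raise ValueError(f"both phases must have data: {phases}")
    data["phase_code"] = (data["phase"] == phases[1]).astype(float)
    formula = f"{dv} ~ cs * phase_code + trial_num"
    try:
        res = _fit_mixedlm(data, formula)
    except (np.linalg.LinAlgError, ValueError):
        return _rm_fallback(data, dv)
    return res


# ---------------------------------------------------------------------------
# sensitivity power analysis


def power_paired_t(
    d: float, n: int, alpha: float = 0.05, tails: str = "one"
) -> float:
    """Power of the paired t-test for a true standardized effect ``d``.

    Uses the exact noncentral-t distribution with df = n - 1 and
    noncentrality ``d * sqrt(n)``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == "one":
        t_crit = sps.t.ppf(1 - alpha, df)
        return 1.0 - _safe_nct_cdf(t_crit, df, nc)
    if tails == "two":
        t_crit = sps.t.ppf(1 - alpha / 2, df)
        return (
            1.0 - _safe_nct_cdf(t_crit, df, nc) + _safe_nct_cdf(-t_crit, df, nc)
        )
    raise ValueError("tails must be 'one' or 'two'")


def sensitivity_dz(
    n: int, power: float = 0.80, alpha: float = 0.05, tails: str = "one"
) -> float:
    """Smallest standardized paired effect detectable at the target power.

    Solves ``power_paired_t(d, n) = power`` for d to 1e-6 (noncentral-t
    throughout; the classic normal approximation is
    ``(z_{1-alpha} + z_{power}) / sqrt(n)``).
    """
    if not (0 < power < 1):
        raise ValueError("power must be in (0, 1)")
    f = lambda d: power_paired_t(d, n, alpha, tails) - power
    hi = 10.0
    if f(hi) < 0:
        raise ValueError("requested power unattainable for d <= 10")
    return float(optimize.brentq(f, 1e-9, hi, xtol=1e-6))
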