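"""Duration and factor statistics for treatment-pattern cohorts.

Four analyses are provided:

* Kaplan–Meier product-limit curves for the time from the first to the
  second treatment pattern, with right censoring at observation end.
* Logistic regression of a binary prescribing-pattern outcome (levodopa
  monotherapy vs other first pattern) on patient covariates, reported as
  odds ratios with 95% Wald intervals.
* Cox proportional-hazards regression of monotherapy duration, reported
  as hazard ratios with 95% intervals.
* Two-group comparisons: Wilcoxon rank-sum for continuous variables and
  chi-square for categorical ones, switching to Fisher's exact test when
  any expected cell count is < 5.

Significance is assessed two-sided at 0.05 with no multiplicity
adjustment; this is recorded in the output metadata of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError


@dataclass
class KMCurve:
    times: np.ndarray  # event/censor times where the curve is defined
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray
    censor_times: np.ndarray
    median: Optional[float]
    q25: Optional[float]  # time at which S drops to/below 0.75
    q75: Optional[float]  # ... 0.25

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class FactorEstimate:
    variable: str
    estimate: float  # odds ratio or hazard ratio
    ci_low: float
    ci_high: float
    p_value: float
    flag: str = ""  # non-empty for diagnostics (e.g. separation)


@dataclass
class GroupTestResult:
    variable: str
    test_name: str  # "wilcoxon_rank_sum" | "chi_square" | "fisher_exact"
    statistic: float
    p_value: float
    note: str = ""


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------


def km_estimate(durations_days: Sequence[float], event_flags: Sequence[bool]) -> KMCurve:
    """Product-limit estimate with ties handled as simultaneous events
    followed by censorings (the standard convention)."""
    durations = np.asarray(durations_days, dtype=float)
    events = np.asarray(event_flags, dtype=bool)
    if durations.size == 0:
        raise ValueError("km_estimate requires at least one observation")
    if np.any(durations < 0):
        raise ValueError("durations must be non-negative")

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    times = surv.index.to_numpy(dtype=float)
    values = surv.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).to_numpy(dtype=float)

    def _quantile(level: float) -> Optional[float]:
        below = times[values <= level]
        return float(below[0]) if below.size else None

    return KMCurve(
        times=times,
        survival=values,
        at_risk=at_risk,
        censor_times=np.sort(durations[~events]),
        median=_quantile(0.5),
        q25=_quantile(0.75),
        q75=_quantile(0.25),
    )


def km_frame(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {"time_days": curve.times, "survival": curve.survival, "at_risk": curve.at_risk}
    )


# ---------------------------------------------------------------------------
# Logistic factors
# ---------------------------------------------------------------------------


def screen_collinearity(table: pd.DataFrame, covariates: Sequence[str], threshold: float = 0.9) -> list[str]:
    """Pairs of covariates with |Pearson r| above the threshold (pre-fit screen)."""
    notes = []
    sub = table[list(covariates)].astype(float)
    corr = sub.corr().to_numpy()
    for i, a in enumerate(covariates):
        for j in range(i + 1, len(covariates)):
            if abs(corr[i, j]) > threshold:
                notes.append(f"{a}~{covariates[j]} (r={corr[i, j]:.2f})")
    return notes


def fit_monotherapy_factors(
    table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
) -> list[FactorEstimate]:
    """Logistic regression of a binary prescribing-pattern outcome.

    Returns one odds-ratio estimate with a 95% Wald interval per
    covariate. Complete or quasi-complete separation is flagged on the
    affected estimate rather than raised.
    """
    y = table[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("degenerate outcome: all observations identical")
    X = sm.add_constant(table[list(covariates)].astype(float), has_constant="add")
    collinear = screen_collinearity(table, covariates)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            # complete/quasi-complete separation: report a penalized point
            # estimate, flagged, with undefined inference
            separated = True
            result = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=False, maxiter=200)
    if separated:
        return [
            FactorEstimate(
                variable=name,
                estimate=float(np.exp(result.params[name])),
                ci_low=0.0,
                ci_high=float("inf"),
                p_value=float("nan"),
                flag="complete separation; penalized estimate, CI undefined",
            )
            for name in covariates
        ]
    conf = result.conf_int()
    estimates = []
    for name in covariates:
        beta = result.params[name]
        se = result.bse[name]
        flag = ""
        if not np.isfinite(se) or se > 50 or abs(beta) > 15:
            flag = "possible separation"
        if collinear:
            flag = (flag + "; " if flag else "") + "collinear: " + ", ".join(collinear)
        estimates.append(
            FactorEstimate(
                variable=name,
                estimate=float(np.exp(beta)),
                ci_low=float(np.exp(conf.loc[name, 0])),
                ci_high=float(np.exp(conf.loc[name, 1])),
                p_value=float(result.pvalues[name]),
                flag=flag,
            )
        )
    return estimates


# ---------------------------------------------------------------------------
# Cox factors
# ---------------------------------------------------------------------------


def fit_duration_factors(
    table: pd.DataFrame,
    duration: str,
    event: str,
    covariates: Sequence[str],
) -> list[FactorEstimate]:
    """Cox proportional-hazards fit; hazard ratios with 95% intervals."""
    if len(table) < 2:
        raise ValueError("need at least two observations for a Cox fit")
    if table[event].astype(bool).sum() == 0:
        raise ValueError("no events observed; hazard ratios are not identified")
    cols = [duration, event, *covariates]
    cph = CoxPHFitter()
    df = table[cols].astype(float)
    df = df[df[duration] > 0]
    cph.fit(df, duration_col=duration, event_col=event)
    summary = cph.summary
    return [
        FactorEstimate(
            variable=name,
            estimate=float(summary.loc[name, "exp(coef)"]),
            ci_low=float(summary.loc[name, "exp(coef) lower 95%"]),
            ci_high=float(summary.loc[name, "exp(coef) upper 95%"]),
            p_value=float(summary.loc[name, "p"]),
        )
        for name in covariates
    ]


def factors_frame(estimates: Sequence[FactorEstimate], measure: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": e.variable,
                measure: e.estimate,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_value": e.p_value,
                "flag": e.flag,
            }
            for e in estimates
        ]
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def choose_categorical_test(contingency: np.ndarray) -> str:
    """Pure decision rule: Fisher's exact when any expected count < 5 (2x2),
    chi-square otherwise."""
    expected = stats.contingency.expected_freq(contingency)
    if (expected < 5).any() and contingency.shape == (2, 2):
        return "fisher_exact"
    return "chi_square"


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    group_col: str,
    kind: str,
) -> GroupTestResult:
    """Two-group comparison of one variable.

    ``kind`` is ``"continuous"`` (Wilcoxon rank-sum) or ``"categorical"``
    (chi-square, or Fisher's exact when expected frequencies are small).
    """
    groups = [g for _, g in table.groupby(group_col, observed=True)]
    if len(groups) != 2:
        raise ValueError("compare_groups requires exactly two groups")
    a, b = (g[variable] for g in groups)
    if kind == "continuous":
        if table[variable].nunique() < 2:
            return GroupTestResult(variable, "wilcoxon_rank_sum", float("nan"), 1.0, "constant variable")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupTestResult(variable, "wilcoxon_rank_sum", float(stat), float(p))
    if kind == "categorical":
        contingency = pd.crosstab(table[group_col], table[variable]).to_numpy()
        if contingency.shape[1] < 2:
            return GroupTestResult(variable, "chi_square", float("nan"), 1.0, "constant variable")
        test = choose_categorical_test(contingency)
        if test == "fisher_exact":
            stat, p = stats.fisher_exact(contingency)
        else:
            stat, p, _, _ = stats.chi2_contingency(contingency)
        return GroupTestResult(variable, test, float(stat), float(p))
    raise ValueError(f"unknown variable kind {kind!r}")
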