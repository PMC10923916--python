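"""Survival estimation and testing for tertile-stratified cohorts.

Kaplan-Meier curves, the log-rank test, Cox proportional hazards (Efron
tie handling) and a Schoenfeld-residual check of the proportional-hazards
assumption, all delegated to lifelines; this module adapts them to the
pipeline's tertile-group semantics (top vs bottom tertile hazard ratio).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

from .containers import StratificationResult

logger = logging.getLogger("dspsig")


@dataclass
class KMCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    variance: np.ndarray  # Greenwood


@dataclass
class SurvivalFit:
    log_hr: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    converged: bool
    covariates: pd.DataFrame | None = None


def kaplan_meier(
    time: pd.Series, event: pd.Series, groups: pd.Series
) -> dict[str, KMCurve]:
    """Product-limit survival estimate per group, with Greenwood variance."""
    time, event, groups = _align(time, event, groups)
    out = {}
    for g, idx in groups.groupby(groups).groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {g!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(time.loc[idx], event.loc[idx])
        surv = kmf.survival_function_.iloc[:, 0]
        table = kmf.event_table
        d = table["observed"].reindex(surv.index).fillna(0).to_numpy(dtype=float)
        n = table["at_risk"].reindex(surv.index).to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(n > d, d / (n * (n - d)), 0.0)
        greenwood = surv.to_numpy() ** 2 * np.cumsum(term)
        out[str(g)] = KMCurve(
            group=str(g),
            times=surv.index.to_numpy(),
            survival=surv.to_numpy(),
            at_risk=table["at_risk"].reindex(surv.index).to_numpy(),
            censor_times=time.loc[idx][event.loc[idx] == 0].to_numpy(),
            variance=greenwood,
        )
    return out


def logrank_test(
    time: pd.Series, event: pd.Series, groups: pd.Series
) -> tuple[float, int, float]:
    """Observed-minus-expected chi-square log-rank test across groups.

    Returns (statistic, df, p)."""
    time, event, groups = _align(time, event, groups)
    if groups.nunique() < 2:
        raise ValueError("log-rank test needs >=2 groups")
    if event.sum() == 0:
        raise ValueError("log-rank test needs >=1 event")
    res = multivariate_logrank_test(time, groups, event)
    df = groups.nunique() - 1
    return float(res.test_statistic), df, float(res.p_value)


def cox_ph(
    time: pd.Series,
    event: pd.Series,
    covariates: pd.DataFrame | pd.Series,
    tie_method: str = "efron",
) -> SurvivalFit:
    """Cox proportional-hazards fit with Efron tie handling.

    The first covariate column is reported as the headline hazard ratio
    with a Wald 95% CI.
    """
    if tie_method != "efron":
        raise ValueError("only Efron tie handling is implemented")
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    time, event, covariates = _align(time, event, covariates)
    const = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if const:
        raise ValueError(f"non-identifiable: constant covariates {const}")
    if int(event.sum()) < 5:
        raise ValueError("cox_ph: need >=5 events")
    df = covariates.copy()
    df["time"], df["event"] = time, event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError on separation
        raise ValueError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    first = summary.index[0]
    return SurvivalFit(
        log_hr=float(summary.loc[first, "coef"]),
        hr=float(summary.loc[first, "exp(coef)"]),
        ci_low=float(summary.loc[first, "exp(coef) lower 95%"]),
        ci_high=float(summary.loc[first, "exp(coef) upper 95%"]),
        p=float(summary.loc[first, "p"]),
        n=len(df),
        n_events=int(event.sum()),
        converged=True,
        covariates=summary[["coef", "se(coef)", "exp(coef)", "p"]].copy(),
    )


def ph_assumption_check(
    time: pd.Series,
    event: pd.Series,
    covariates: pd.DataFrame | pd.Series,
) -> pd.Series:
    """Score test of scaled Schoenfeld residuals against Kaplan-Meier
    transformed time; one advisory p-value per covariate."""
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    time, event, covariates = _align(time, event, covariates)
    if int(event.sum()) < 3:
        raise ValueError("ph_assumption_check: need >=3 events")
    df = covariates.copy()
    df["time"], df["event"] = time, event
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    res = proportional_hazard_test(cph, df, time_transform="km")
    p = res.summary["p"]
    p.index = p.index.get_level_values(0)
    return p


def compare_extreme_tertiles(
    strat: StratificationResult,
    survival: pd.DataFrame,
    extra_covariates: pd.DataFrame | None = None,
    tie_method: str = "efron",
) -> dict:
    """Top-vs-bottom tertile survival comparison.

    Fits a Cox model on the high-vs-low indicator (optionally adjusted for
    supplied covariates, e.g. an IPI risk score), runs the log-rank test on
    the extreme groups, and returns KM curves for all three groups.
    """
    table = strat.table
    extremes = table[table["group"].isin(["low", "high"])]
    surv = survival.loc[extremes.index]
    indicator = (extremes["group"] == "high").astype(float).rename("high_vs_low")
    covs: pd.DataFrame = indicator.to_frame()
    if extra_covariates is not None:
        covs = covs.join(extra_covariates.loc[extremes.index])
    fit = cox_ph(surv["time"], surv["event"], covs, tie_method=tie_method)
    stat, df, p = logrank_test(surv["time"], surv["event"], extremes["group"])
    km = kaplan_meier(
        survival.loc[table.index, "time"],
        survival.loc[table.index, "event"],
        table["group"],
    )
    try:
        ph_p = ph_assumption_check(surv["time"], surv["event"], covs)
    except ValueError:
        ph_p = pd.Series(dtype=float)
    return {
        "cox": fit,
        "logrank_statistic": stat,
        "logrank_df": df,
        "logrank_p": p,
        "km": km,
        "ph_assumption_p": ph_p,
    }


def _align(time, event, other):
    time = pd.Series(time).astype(float)
    event = pd.Series(event).reindex(time.index).astype(int)
    if (time <= 0).any():
        raise ValueError("survival times must be > 0")
    if isinstance(other, pd.DataFrame):
        other = other.reindex(time.index)
    else:
        other = pd.Series(other).reindex(time.index)
    return time, event, other
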