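"""Kaplan-Meier estimation, log-rank comparison, and Cox regression for
HRD-score-stratified survival endpoints.

Endpoints are CRPC-free survival (CFS), metastasis-free survival (MFS) and
overall survival (OS), all in months from diagnosis.  Median survival is the
smallest time with S(t) <= 0.5 and is reported as "not reached" when the
curve never crosses 0.5.  Cox fits use Efron tie handling (months-resolution
times tie heavily) and 95% confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, exceptions
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

__all__ = [
    "SurvivalCurve",
    "CoxResult",
    "km_fit",
    "logrank",
    "cox_fit",
    "endpoint_analysis",
    "ENDPOINT_COLUMNS",
]

ENDPOINT_COLUMNS = {
    "CFS": ("cfs_months", "cfs_event"),
    "MFS": ("mfs_months", "mfs_event"),
    "OS": ("os_months", "os_event"),
}


@dataclass(frozen=True)
class SurvivalCurve:
    """A product-limit curve: S(t) at each event time plus the median."""

    grouping: str
    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    median_survival: float  # inf when the curve never crosses 0.5

    @property
    def median_label(self) -> str:
        return "not reached" if math.isinf(self.median_survival) else f"{self.median_survival:g}"


@dataclass(frozen=True)
class CoxResult:
    covariates: tuple[str, ...]
    coefficients: tuple[float, ...]
    hazard_ratios: tuple[float, ...]
    ci_lower: tuple[float, ...]
    ci_upper: tuple[float, ...]
    p_values: tuple[float, ...]


def km_fit(
    times: Sequence[float], events: Sequence[bool], grouping: str = "all"
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    At tied times, events are processed before censorings (the standard
    convention).  Median survival is the smallest observed time with
    S(t) <= 0.5, or ``inf`` ("not reached").
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("cannot fit a survival curve on an empty sample")
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    event_times = np.unique(t[e])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    table = kmf.event_table
    at_risk = table.loc[event_times, "at_risk"].to_numpy().astype(int)
    return SurvivalCurve(
        grouping=grouping,
        times=tuple(float(x) for x in event_times),
        survival=tuple(float(x) for x in surv),
        at_risk=tuple(int(x) for x in at_risk),
        median_survival=float(kmf.median_survival_time_),
    )


def logrank(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
) -> tuple[float, float]:
    """Two-group ordinary (unweighted) log-rank test (chi-square, df 1)."""
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], bool)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (ea.any() or eb.any()):
        warnings.warn("no events in either group; log-rank p = 1 by convention")
        return (0.0, 1.0)
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return (float(res.test_statistic), float(res.p_value))


def cox_fit(
    cohort: pd.DataFrame,
    endpoint: str,
    covariates: Sequence[str],
    ci_level: float = 0.95,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, Wald p per covariate).

    Covariates must be numeric or binary-encoded columns of ``cohort``.
    Monotone-likelihood/separation problems surface as an explicit
    convergence error rather than silent output.
    """
    if endpoint not in ENDPOINT_COLUMNS:
        raise KeyError(f"unknown endpoint {endpoint!r}; expected one of {list(ENDPOINT_COLUMNS)}")
    tcol, ecol = ENDPOINT_COLUMNS[endpoint]
    df = cohort[[tcol, ecol, *covariates]].dropna()
    if df[ecol].sum() < 1:
        raise ValueError(f"no events for endpoint {endpoint}")
    cph = CoxPHFitter(alpha=1.0 - ci_level)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col=tcol, event_col=ecol)
    except ConvergenceError as err:
        raise ConvergenceError(
            f"Cox fit for {endpoint} did not converge (possible separation): {err}"
        ) from err
    convergence_issues = [
        w for w in caught if issubclass(w.category, exceptions.ConvergenceWarning)
    ]
    if convergence_issues:
        raise ConvergenceError(
            f"Cox fit for {endpoint} is unreliable (possible separation or "
            f"monotone likelihood): {convergence_issues[0].message}"
        )
    summ = cph.summary
    return CoxResult(
        covariates=tuple(summ.index),
        coefficients=tuple(float(x) for x in summ["coef"]),
        hazard_ratios=tuple(float(x) for x in summ["exp(coef)"]),
        ci_lower=tuple(float(np.exp(x)) for x in summ[f"coef lower {ci_level * 100:g}%"]),
        ci_upper=tuple(float(np.exp(x)) for x in summ[f"coef upper {ci_level * 100:g}%"]),
        p_values=tuple(float(x) for x in summ["p"]),
    )


def endpoint_analysis(
    cohort: pd.DataFrame,
    stratum: str = "total",
    cutoff: int = 21,
    score_col: str = "hrd_score",
) -> dict:
    """Per-stratum survival report split at ``score >= cutoff``.

    Endpoints per stratum follow the cohort's event structure: the total and
    M1 strata use CFS and OS; the M0 stratum uses CFS and MFS (too few deaths
    among localized patients for OS to be informative).
    """
    if stratum == "total":
        df = cohort
        endpoints = ("CFS", "OS")
    elif stratum in ("M0", "M1"):
        df = cohort[cohort["m_stage"] == stratum]
        endpoints = ("CFS", "MFS") if stratum == "M0" else ("CFS", "OS")
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    if df.empty:
        raise ValueError(f"stratum {stratum!r} is empty")

    high = df[score_col] >= cutoff
    report: dict = {"stratum": stratum, "cutoff": cutoff, "n": int(len(df)),
                    "n_high": int(high.sum()), "endpoints": {}}
    single_group = int(high.sum()) in (0, len(df))
    if single_group:
        warnings.warn(
            f"cutoff {cutoff} yields a single group in stratum {stratum}; "
            "log-rank and Cox comparisons skipped"
        )
    for ep in endpoints:
        tcol, ecol = ENDPOINT_COLUMNS[ep]
        entry: dict = {}
        km_all = {}
        for label, mask in (("high", high), ("low", ~high)):
            if mask.any():
                km_all[label] = km_fit(df.loc[mask, tcol], df.loc[mask, ecol].astype(bool), label)
        entry["median_high"] = km_all["high"].median_label if "high" in km_all else None
        entry["median_low"] = km_all["low"].median_label if "low" in km_all else None
        if not single_group:
            stat, p = logrank(
                (df.loc[high, tcol], df.loc[high, ecol].astype(bool)),
                (df.loc[~high, tcol], df.loc[~high, ecol].astype(bool)),
            )
            entry["logrank_statistic"] = stat
            entry["logrank_p"] = p
            sub = df[[tcol, ecol]].copy()
            sub["hrd_high"] = high.astype(int)
            cox = cox_fit(sub, ep, ["hrd_high"])
            entry["cox_hr"] = cox.hazard_ratios[0]
            entry["cox_ci"] = (cox.ci_lower[0], cox.ci_upper[0])
            entry["cox_p"] = cox.p_values[0]
        report["endpoints"][ep] = entry
    return report


def plot_km(
    cohort: pd.DataFrame,
    endpoint: str,
    cutoff: int = 21,
    score_col: str = "hrd_score",
    ax=None,
):
    """Optional Kaplan-Meier plot for one endpoint split at the cutoff."""
    import matplotlib.pyplot as plt

    tcol, ecol = ENDPOINT_COLUMNS[endpoint]
    if ax is None:
        _, ax = plt.subplots()
    for label, mask in (
        (f"HRD >= {cutoff}", cohort[score_col] >= cutoff),
        (f"HRD < {cutoff}", cohort[score_col] < cutoff),
    ):
        if mask.any():
            kmf = KaplanMeierFitter()
            kmf.fit(cohort.loc[mask, tcol], cohort.loc[mask, ecol], label=label)
            kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel(f"{endpoint} probability")
    return ax
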