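"""Survival analysis for methylation-stratified overall survival.

Kaplan-Meier product-limit curves, the log-rank test, and Cox
proportional-hazards regression (Efron tie handling), plus administrative
truncation to a fixed follow-up horizon (e.g. 10-year overall survival).
Estimation is delegated to lifelines behind this module's surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


__all__ = [
    "km_estimate",
    "logrank_test",
    "cox_ph",
    "truncate_followup",
    "CoxResult",
]


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with 95% Wald intervals and p-values."""

    summary: pd.DataFrame  # index covariate; hr, ci_lower, ci_upper, coef, se, p
    n: int
    n_events: int


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a DataFrame with one row per distinct observed time: columns
    ``time``, ``at_risk``, ``events``, ``censored``, ``survival``.  S(0)=1,
    nonincreasing; at tied times events are processed before censorings.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one record")
    if np.any(time < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tbl = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": tbl.index.to_numpy(dtype=float),
            "at_risk": tbl["at_risk"].to_numpy(dtype=int),
            "events": tbl["observed"].to_numpy(dtype=int),
            "censored": tbl["censored"].to_numpy(dtype=int),
            "survival": surv.reindex(tbl.index).to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    return out


def logrank_test(time_a, event_a, time_b, event_b):
    """Two-group log-rank test: O-E over event times with hypergeometric variance.

    Returns ``(chi2_statistic, p_value)`` on 1 degree of freedom.  Raises if
    the pooled sample has no events (the statistic is undefined).
    """
    ea = np.asarray(event_a, dtype=int)
    eb = np.asarray(event_b, dtype=int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group: log-rank undefined")
    res = _ll_logrank(time_a, time_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_ph(
    records: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_months",
    event_col: str = "event",
) -> CoxResult:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    ``records`` holds one row per subject with numeric covariate codings
    (categoricals pre-coded as reference-level indicators).  Returns hazard
    ratios exp(coef) with 95% CIs exp(coef +/- 1.96 SE) and Wald p-values.
    """
    df = records[[duration_col, event_col, *covariates]].copy()
    if df[event_col].sum() == 0:
        raise ValueError("no events: Cox model undefined")
    for cov in covariates:
        if df[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # convergence failure / separation
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "hr": np.exp(s["coef"]),
            "ci_lower": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
            "ci_upper": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
            "coef": s["coef"],
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )
    return CoxResult(summary=summary, n=len(df), n_events=int(df[event_col].sum()))


def truncate_followup(
    records: pd.DataFrame,
    horizon: float = 120.0,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Administratively censor follow-up at ``horizon`` months.

    Times are capped at the horizon and events occurring beyond it become
    censorings; records at or before the horizon are unchanged.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    out = records.copy()
    late = out[duration_col] > horizon
    out.loc[late, duration_col] = horizon
    out.loc[late, event_col] = 0
    return out
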