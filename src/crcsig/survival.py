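"""Kaplan-Meier estimation and log-rank comparisons.

Overall survival is stratified either by signature-score quartile or by CMS
class; estimation is the product-limit estimator with Greenwood variance
(events processed before censorings at tied times, the standard
convention), and groups are compared with the k-sample log-rank chi-square.
Fitting is delegated to ``lifelines``; this module shapes inputs/outputs
and adds the quartile plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .scoring import assign_quartiles, QUARTILE_LABELS
from .stats import ClinicalTable

__all__ = ["SurvivalCurve", "SurvivalError", "km_fit", "logrank", "quartile_survival"]


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier step function.

    ``times`` are the ordered distinct event/censor times, ``survival`` the
    product-limit estimate after each, ``at_risk`` the risk-set size just
    before each, ``variance`` the Greenwood variance of the estimate.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    variance: np.ndarray
    group_label: str = ""

    def survival_at(self, t: float) -> float:
        """Step-function evaluation (right-continuous), S(t<first time)=1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median_time(self) -> float:
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if len(below) else float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "variance": self.variance,
                "group": self.group_label,
            }
        )


def km_fit(times, events, label: str = "") -> SurvivalCurve:
    """Product-limit survival estimate.

    ``times`` are non-negative durations; ``events`` True for deaths, False
    for right-censoring. With no censoring the estimate equals the
    empirical survival function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise SurvivalError("times and events must have equal length")
    if (times < 0).any():
        raise SurvivalError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    et = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and (
        kmf.event_table.iloc[0][["observed", "censored"]].sum() == 0
    ) else kmf.event_table
    t = et.index.to_numpy(dtype=float)
    d = et["observed"].to_numpy(dtype=float)
    n = et["at_risk"].to_numpy(dtype=float)
    surv = np.cumprod(np.where(n > 0, 1.0 - d / n, 1.0))
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((n - d) > 0, d / (n * (n - d)), 0.0)
    var = surv**2 * np.cumsum(terms)
    return SurvivalCurve(times=t, survival=surv, at_risk=n, variance=var, group_label=label)


def logrank(times, events, groups) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square on k-1 df, p).

    Invariant to group ordering; requires at least two non-empty groups.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise SurvivalError("log-rank needs at least 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def quartile_survival(
    scores: pd.Series, clinical: ClinicalTable | pd.DataFrame
) -> dict:
    """KM curves and log-rank tests across score quartiles.

    Samples without overall-survival data are dropped (their count is
    reported); quartiles are formed on the remaining scores with the
    boundary-low convention. Returns a dict with the four curves, the
    overall log-rank (statistic, p), the Q4-vs-Q1 pairwise log-rank, and
    ``n_dropped``.
    """
    df = clinical.df if isinstance(clinical, ClinicalTable) else clinical
    merged = pd.DataFrame({"score": scores}).join(df[["os_time", "os_event"]], how="inner")
    kept = merged.dropna(subset=["os_time", "os_event"])
    n_dropped = len(scores) - len(kept)
    quart = assign_quartiles(kept["score"])
    curves = {}
    for q in QUARTILE_LABELS:
        mask = quart == q
        if mask.sum():
            curves[q] = km_fit(
                kept.loc[mask, "os_time"], kept.loc[mask, "os_event"].astype(bool), label=q
            )
    overall = logrank(kept["os_time"], kept["os_event"].astype(bool), quart.astype(str))
    q41_mask = quart.isin(["Q1", "Q4"])
    q4_vs_q1 = logrank(
        kept.loc[q41_mask, "os_time"],
        kept.loc[q41_mask, "os_event"].astype(bool),
        quart[q41_mask].astype(str),
    )
    return {
        "curves": curves,
        "logrank": overall,
        "q4_vs_q1": q4_vs_q1,
        "n_dropped": int(n_dropped),
        "quartiles": quart,
    }
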