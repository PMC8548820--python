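"""Survival-analysis layer: Kaplan-Meier curves, recurrence-fraction
quantile points, the log-SSR discrepancy and the two-sample log-rank
test.

Kaplan-Meier estimation and the log-rank test are delegated to
lifelines; the quantile extraction and log-SSR objective — the pieces
specific to the fitting procedure — are implemented here.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalCurve",
    "QuantilePoints",
    "km_estimate",
    "event_quantiles",
    "log_ssr",
    "logrank_test",
]

QUANTILE_FRACTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclasses.dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with at-risk / event bookkeeping.

    Arrays are aligned per distinct event time (censoring-only times do
    not get a row; they deplete the at-risk counts between rows).
    """

    times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def probability_at(self, t: float) -> float:
        """Step-function evaluation S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclasses.dataclass(frozen=True)
class QuantilePoints:
    """Event times at which 20/40/60/80/100% of event patients have
    recurred; the last point is the maximum event time."""

    times: tuple[float, float, float, float, float]

    def __iter__(self):
        return iter(self.times)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Ties are grouped; observations censored exactly at an event time
    count as at risk for that time (the standard convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("km_estimate requires at least one observation")
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1 indicators")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table  # indexed by time, includes t=0 row
    tbl = tbl[tbl["observed"] > 0]
    surv = np.array([kmf.predict(x) for x in tbl.index], dtype=float)
    return SurvivalCurve(
        times=tbl.index.to_numpy(dtype=float),
        n_at_risk=tbl["at_risk"].to_numpy(dtype=np.int64),
        n_events=tbl["observed"].to_numpy(dtype=np.int64),
        survival=surv,
    )


def event_quantiles(event_times: Sequence[float]) -> QuantilePoints:
    """The five recurrence-fraction time points among event patients.

    For K sorted event times t(1..K), the point at fraction q is
    t(ceil(q K)); the 100% point is therefore exactly the largest
    event time.
    """
    t = np.sort(np.asarray(event_times, dtype=float))
    if t.size == 0:
        raise ValueError("event_quantiles requires at least one event")
    k = t.size
    idx = [int(math.ceil(q * k)) - 1 for q in QUANTILE_FRACTIONS]
    return QuantilePoints(times=tuple(float(t[j]) for j in idx))


def log_ssr(
    sim_points: QuantilePoints | Sequence[float],
    clin_points: QuantilePoints | Sequence[float],
    base: float = 10.0,
) -> float:
    """Sum of squared logarithmic residuals over the five matched
    quantile points (default base 10); symmetric and >= 0."""
    a = np.asarray(list(sim_points), dtype=float)
    b = np.asarray(list(clin_points), dtype=float)
    if a.shape != b.shape:
        raise ValueError("point sets must have equal length")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("all times must be positive")
    r = (np.log(a) - np.log(b)) / np.log(base)
    return float(np.sum(r * r))


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Standard two-sample log-rank test (chi-square, 1 df; ties via
    the hypergeometric variance).  Returns (statistic, p_value)."""
    ta, tb = np.asarray(times_a, dtype=float), np.asarray(times_b, dtype=float)
    ea, eb = np.asarray(events_a), np.asarray(events_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test undefined with no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)
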