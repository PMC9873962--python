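"""Kaplan–Meier survival comparison between expression groups.

Patients are split at the median of a target-gene expression level
(strictly above the median → high group; the median itself and below →
low), each group gets a product-limit survival estimate, and the groups
are compared with the standard log-rank chi-square test on one degree of
freedom. Ties between an event and a censoring at the same time are
resolved events-first, the usual convention. Follow-up time units are
abstract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "split_by_expression",
    "km_estimate",
    "logrank_test",
    "os_summary",
]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float
    event: bool  # True = death observed, False = censored
    expression: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.expression < 0:
            raise ValueError("expression must be >= 0")


@dataclass
class KMCurve:
    """Product-limit estimate: step down by (1 - d/n) at each event time."""

    times: list[float]      # distinct event times, increasing
    survival: list[float]   # S(t) just after each event time
    at_risk: list[int]      # risk-set size just before each event time
    n_events: list[int]     # deaths at each event time

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function starting at 1."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def split_by_expression(
    records: list[SurvivalRecord],
) -> tuple[list[SurvivalRecord], list[SurvivalRecord]]:
    """Median split into (high, low) expression groups; ties go low."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    expr = np.array([r.expression for r in records])
    if np.all(expr == expr[0]):
        raise ValueError("all expression values identical; no split possible")
    med = float(np.median(expr))
    high = [r for r in records if r.expression > med]
    low = [r for r in records if r.expression <= med]
    return high, low


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    At each distinct event time t_i with d_i deaths and n_i at risk the
    survival drops by the factor (1 − d_i/n_i); censored patients leave
    the risk set without producing a step. With no censoring the curve
    equals the empirical survival function.
    """
    if not records:
        raise ValueError("need at least 1 record")
    order = sorted(records, key=lambda r: (r.time, not r.event))
    times: list[float] = []
    survival: list[float] = []
    at_risk: list[int] = []
    n_events: list[int] = []
    total = len(order)
    n = total  # risk-set size just before the current time
    s = 1.0
    i = 0
    while i < total:
        t = order[i].time
        d = 0
        c = 0
        while i < total and order[i].time == t:
            if order[i].event:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            times.append(t)
            at_risk.append(n)
            n_events.append(d)
            s *= 1.0 - d / n
            survival.append(s)
        n -= d + c
    return KMCurve(times=times, survival=survival, at_risk=at_risk,
                   n_events=n_events)


def logrank_test(
    a: list[SurvivalRecord], b: list[SurvivalRecord]
) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p-value).

    Symmetric in its arguments. Raises if neither group has any event.
    """
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in a) and not any(r.event for r in b):
        raise ValueError("no events in either group")
    recs = [(r.time, r.event, 0) for r in a] + [(r.time, r.event, 1) for r in b]
    event_times = sorted({t for t, e, _ in recs if e})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = sum(1 for ti, _, g in recs if ti >= t and g == 0)
        n2 = sum(1 for ti, _, g in recs if ti >= t and g == 1)
        d1 = sum(1 for ti, e, g in recs if ti == t and e and g == 0)
        d2 = sum(1 for ti, e, g in recs if ti == t and e and g == 1)
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e * o_minus_e / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def os_summary(curve: KMCurve) -> float | None:
    """Median overall survival: smallest time with S(t) <= 0.5.

    Returns ``None`` when the curve never reaches 0.5 (median undefined).
    """
    for t, s in zip(curve.times, curve.survival):
        if s <= 0.5:
            return t
    return None
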