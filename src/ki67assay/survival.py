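"""Kaplan-Meier estimation, two-group log-rank test and median follow-up.

Time unit is months. Ties between events and censorings at the same time use
the standard convention: censored subjects remain in the risk set at that
time. Median follow-up is the reverse Kaplan-Meier median (censoring treated
as the event of interest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); survival is constant between event times."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    df: int = 1


def _validate(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have the same length")
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    return times, events


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance."""
    times, events = _validate(times, events)
    event_times = np.unique(times[events])
    n_at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    n_events = np.array([((times == t) & events).sum() for t in event_times], dtype=int)
    if event_times.size == 0:
        return KMCurve(
            times=event_times,
            n_at_risk=n_at_risk,
            n_events=n_events,
            survival=np.array([]),
            variance=np.array([]),
            n=times.size,
        )
    surv = np.cumprod(1.0 - n_events / n_at_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.cumsum(
            np.where(
                n_at_risk > n_events,
                n_events / (n_at_risk * (n_at_risk - n_events)),
                np.inf,
            )
        )
        variance = np.where(surv > 0, surv**2 * g, 0.0)
    return KMCurve(
        times=event_times,
        n_at_risk=n_at_risk,
        n_events=n_events,
        survival=surv,
        variance=variance,
        n=times.size,
    )


def km_median(curve: KMCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None when the median is not reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.times[below[0]])


def logrank(times, events, groups) -> LogrankResult:
    """Standard two-group log-rank test (hypergeometric variance, no correction)."""
    times, events = _validate(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two non-empty groups are required")
    g1 = groups == labels[0]

    observed = expected = variance = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_j = at_risk.sum()
        d_j = (events & (times == t)).sum()
        n1_j = (at_risk & g1).sum()
        d1_j = (events & (times == t) & g1).sum()
        observed += d1_j
        expected += d_j * n1_j / n_j
        if n_j > 1:
            variance += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    if variance == 0:
        return LogrankResult(statistic=0.0, p_value=1.0)
    chi2 = (observed - expected) ** 2 / variance
    return LogrankResult(statistic=float(chi2), p_value=float(stats.chi2.sf(chi2, 1)))


def median_followup(times, events) -> float | None:
    """Reverse Kaplan-Meier median: censoring is the event, events are censored.

    Returns None (not reached) when reverse survival never drops to 0.5,
    e.g. when every subject had an event and none were censored.
    """
    times, events = _validate(times, events)
    return km_median(km_estimate(times, ~events))
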