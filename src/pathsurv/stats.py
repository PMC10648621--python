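"""Censored-data statistics used throughout the package.

The negative log Cox partial likelihood (the training loss) and the
concordance index are implemented here; Kaplan–Meier estimation and the
two-group log-rank test delegate to lifelines.

Conventions:

* The partial likelihood uses the inclusive risk set {j : T_j ≥ T_i}, i.e. the
  Breslow handling of tied event times, and is a **sum** over events (a mean
  over events is available via ``mean=True``).
* The concordance index counts ordered pairs (i, j) with T_j < T_i and
  δ_j = 1; a pair is concordant when r_j > r_i. Risk ties receive 0.5 credit
  by default (``ties="credit"``); ``ties="strict"`` scores ties as 0, which is
  the literal indicator-function definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "neg_log_partial_likelihood",
    "concordance_index",
    "SurvivalCurve",
    "kaplan_meier",
    "logrank_test",
    "median_split",
]


def _validate(risk, time, event):
    risk = np.asarray(risk, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=float).ravel()
    if not (risk.shape == time.shape == event.shape):
        raise ValueError("risk, time and event must have equal length")
    if not np.isfinite(risk).all():
        raise ValueError("non-finite risk score")
    return risk, time, event


def neg_log_partial_likelihood(
    risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    mean: bool = False,
) -> float:
    """−Σ_{i: δ_i=1} [ r_i − log Σ_{j: T_j ≥ T_i} exp(r_j) ].

    Computed with a max-shift inside the log-sum-exp for overflow safety.
    ``mean=True`` divides by the number of events.
    """
    risk, time, event = _validate(risk, time, event)
    events = np.flatnonzero(event == 1)
    if events.size == 0:
        raise ValueError("no events: the partial likelihood is undefined")
    # risk-set membership: R[i, j] = 1[T_j >= T_i], rows restricted to events
    at_risk = time[None, :] >= time[events, None]
    shift = risk.max()
    log_denoms = shift + np.log((np.exp(risk - shift)[None, :] * at_risk).sum(axis=1))
    value = -float(np.sum(risk[events] - log_denoms))
    return value / events.size if mean else value


def concordance_index(
    risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "credit",
) -> float:
    """Concordance between predicted risk and observed survival ordering.

    C = Σ_{i,j} 1[T_j < T_i] δ_j h(r_j, r_i) / Σ_{i,j} 1[T_j < T_i] δ_j with
    h = 1[r_j > r_i] (+ 0.5·1[r_j = r_i] under ``ties="credit"``).
    """
    if ties not in ("credit", "strict"):
        raise ValueError(f"unknown tie handling {ties!r}")
    risk, time, event = _validate(risk, time, event)
    # comparable[i, j] = 1 iff T_j < T_i and sample j had an event
    comparable = (time[None, :] < time[:, None]) & (event[None, :] == 1)
    denom = comparable.sum()
    if denom == 0:
        raise ValueError("no comparable pairs")
    higher = risk[None, :] > risk[:, None]
    num = float((comparable & higher).sum())
    if ties == "credit":
        tied = risk[None, :] == risk[:, None]
        num += 0.5 * float((comparable & tied).sum())
    return num / float(denom)


@dataclass
class SurvivalCurve:
    """A right-continuous Kaplan–Meier step function.

    ``survival[k]`` is Ŝ(t) for t in [event_times[k], event_times[k+1]).
    """

    event_times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def at(self, t: float) -> float:
        """Ŝ(t)."""
        k = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if k == 0 else float(self.survival[k - 1])


def kaplan_meier(time: np.ndarray, event: np.ndarray) -> SurvivalCurve:
    """Product-limit estimator over the distinct observed event times."""
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=float).ravel()
    if time.size == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_.iloc[:, 0]
    # keep only true event times (the estimator is flat elsewhere)
    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        return SurvivalCurve(np.array([]), np.array([]))
    surv = np.array([sf[sf.index <= t].iloc[-1] for t in event_times])
    return SurvivalCurve(event_times, surv)


def logrank_test(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail p-value."""
    time_a = np.asarray(time_a, dtype=float).ravel()
    time_b = np.asarray(time_b, dtype=float).ravel()
    event_a = np.asarray(event_a, dtype=float).ravel()
    event_b = np.asarray(event_b, dtype=float).ravel()
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if event_a.sum() + event_b.sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def median_split(values: np.ndarray) -> np.ndarray:
    """Boolean high-expression labels: strictly above the median is high.

    Ties at the median go to the low group, so the high group holds the top
    half of the expression levels (up to ties).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least two samples to split")
    med = np.median(values)
    high = values > med
    if not high.any() or high.all():
        raise ValueError("no split possible: expression is constant at the median")
    return high
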