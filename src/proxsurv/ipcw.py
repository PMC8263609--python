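"""Kaplan-Meier estimation and inverse-probability-of-censoring weights.

Right-censored outcomes are converted into a weighted binary classification
problem at a fixed horizon (default 60 months = 5 years):

* event observed before the horizon      -> label 1, weight 1 / G(T-)
* followed event-free past the horizon   -> label 0, weight 1 / G(horizon)
* censored event-free before the horizon -> no label, weight 0

where G is the Kaplan-Meier estimate of the *censoring* survival function
(the product-limit estimator with the event indicator flipped).  Evaluating
G just before an event time avoids counting a patient's own censoring risk.
Weights are capped (default 20) to bound the variance contributed by
near-zero G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["StepSurvival", "HorizonOutcome", "km_estimator", "censoring_survival", "ipcw_weights"]

logger = logging.getLogger(__name__)

DEFAULT_HORIZON_MONTHS = 60.0
DEFAULT_WEIGHT_CAP = 20.0


@dataclass
class StepSurvival:
    """Right-continuous step survival function, S = 1 before the first jump."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be aligned 1-d arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.values) > 1e-12):
            raise ValueError("survival values must be non-increasing")

    def evaluate(self, t) -> np.ndarray:
        """S(t), right-continuous."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)

    def evaluate_left(self, t) -> np.ndarray:
        """S(t-), the left limit."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)


@dataclass
class HorizonOutcome:
    """IPCW-weighted binary outcome at a fixed horizon.

    ``label`` is only meaningful where ``weight > 0``; ``observable`` marks
    those patients.  Early-censored event-free patients have weight exactly 0.
    """

    horizon_months: float
    label: np.ndarray
    weight: np.ndarray
    observable: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.weight < 0):
            raise ValueError("weights must be non-negative")
        if np.any((self.weight > 0) != self.observable):
            raise ValueError("observable mask must equal weight > 0")

    def to_frame(self, patient_ids=None):
        """Audit table with columns patient_id, label, weight."""
        import pandas as pd

        ids = range(len(self.label)) if patient_ids is None else patient_ids
        return pd.DataFrame(
            {"patient_id": list(ids), "label": self.label, "weight": self.weight}
        ).set_index("patient_id")


def _check_inputs(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("event must be 0/1")
    return t, e.astype(int)


def km_estimator(time, event) -> StepSurvival:
    """Product-limit estimator over distinct event times.

    At tied times, censored observations are treated as leaving the risk set
    after the events (the standard convention).
    """
    t, e = _check_inputs(time, event)
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return StepSurvival(times=np.array([np.max(t)]), values=np.array([1.0]))
    # risk set Y_k = #{t_i >= tau_k}; d_k = events at tau_k
    at_risk = (t[:, None] >= event_times[None, :]).sum(axis=0)
    deaths = ((t[:, None] == event_times[None, :]) & (e[:, None] == 1)).sum(axis=0)
    surv = np.cumprod(1.0 - deaths / at_risk)
    return StepSurvival(times=event_times, values=surv)


def censoring_survival(time, event) -> StepSurvival:
    """Kaplan-Meier estimate G of the censoring distribution (flipped indicator)."""
    t, e = _check_inputs(time, event)
    return km_estimator(t, 1 - e)


def ipcw_weights(
    time,
    event,
    horizon: float = DEFAULT_HORIZON_MONTHS,
    weight_cap: float = DEFAULT_WEIGHT_CAP,
) -> HorizonOutcome:
    """Labels and censoring weights at ``horizon`` (see module docstring)."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t, e = _check_inputs(time, event)
    G = censoring_survival(t, e)

    n = t.size
    label = np.zeros(n, dtype=int)
    weight = np.zeros(n, dtype=float)

    is_event = (e == 1) & (t < horizon)
    is_survivor = t >= horizon

    g_event = np.asarray(G.evaluate_left(t[is_event]))
    g_surv = float(np.asarray(G.evaluate(horizon)))

    capped = 0
    w_event = np.empty(g_event.shape)
    zero = g_event <= 0
    w_event[~zero] = np.minimum(1.0 / g_event[~zero], weight_cap)
    w_event[zero] = weight_cap
    capped += int(zero.sum() + (1.0 / np.maximum(g_event, 1e-300) > weight_cap).sum())

    if g_surv <= 0:
        w_surv = weight_cap
        capped += int(is_survivor.sum())
    else:
        w_surv = min(1.0 / g_surv, weight_cap)

    label[is_event] = 1
    weight[is_event] = w_event
    weight[is_survivor] = w_surv
    if capped:
        logger.warning("IPCW weight cap (%.1f) active for %d evaluation(s)", weight_cap, capped)

    return HorizonOutcome(
        horizon_months=float(horizon),
        label=label,
        weight=weight,
        observable=weight > 0,
    )
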