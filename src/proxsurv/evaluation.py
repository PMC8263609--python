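"""Discrimination metrics and group stratification tests.

Harrell's C-index over comparable pairs, an (optionally IPCW-weighted)
Mann-Whitney AUC at a fixed horizon, the k-group log-rank test, and
Kaplan-Meier tables per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ipcw import HorizonOutcome, StepSurvival, km_estimator

__all__ = [
    "harrell_c_index",
    "auc_horizon",
    "logrank_test",
    "km_curves_by_group",
    "EvaluationReport",
]


def harrell_c_index(risk, time, event) -> float:
    """Concordance over comparable pairs.

    A pair (i, j) is comparable when ``T_i < T_j`` and patient i had the
    event, or when ``T_i == T_j`` with an event for i only (the event is
    treated as the earlier observation).  Concordant pairs have
    ``risk_i > risk_j``; tied risks count one half.
    """
    r = np.asarray(risk, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    if not (r.shape == t.shape == e.shape):
        raise ValueError("risk, time and event must be aligned")
    earlier = (t[:, None] < t[None, :]) | ((t[:, None] == t[None, :]) & (e[None, :] == 0))
    comparable = earlier & (e[:, None] == 1)
    np.fill_diagonal(comparable, False)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    conc = (r[:, None] > r[None, :]) & comparable
    ties = (r[:, None] == r[None, :]) & comparable
    return float((conc.sum() + 0.5 * ties.sum()) / n_comp)


def auc_horizon(risk, outcome: HorizonOutcome) -> float:
    """IPCW-weighted Mann-Whitney AUC among patients with positive weight."""
    r = np.asarray(risk, dtype=float)
    mask = outcome.observable
    r, y, w = r[mask], outcome.label[mask], outcome.weight[mask]
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"degenerate classes: {n_pos} positives, {n_neg} negatives")
    rp, wp = r[y == 1], w[y == 1]
    rn, wn = r[y == 0], w[y == 0]
    ww = wp[:, None] * wn[None, :]
    wins = (rp[:, None] > rn[None, :]) * 1.0 + 0.5 * (rp[:, None] == rn[None, :])
    return float((ww * wins).sum() / ww.sum())


def logrank_test(labels, time, event) -> tuple[float, float]:
    """k-group log-rank test; returns (chi2, p) with k-1 degrees of freedom."""
    g = np.asarray(labels)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    groups = np.unique(g)
    k = groups.size
    if k < 2:
        raise ValueError("log-rank needs at least 2 non-empty groups")
    event_times = np.unique(t[e == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for tau in event_times:
        at_risk = t >= tau
        Y = at_risk.sum()
        d = int(((t == tau) & (e == 1)).sum())
        Yg = np.array([(at_risk & (g == grp)).sum() for grp in groups], dtype=float)
        dg = np.array([((t == tau) & (e == 1) & (g == grp)).sum() for grp in groups], dtype=float)
        observed += dg
        expected += Yg * d / Y
        if Y > 1:
            frac = Yg / Y
            mult = d * (Y - d) / (Y - 1)
            cov += mult * (np.diag(frac) - np.outer(frac, frac))
    o_minus_e = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    chi2 = float(o_minus_e @ np.linalg.pinv(v) @ o_minus_e) if v.size else 0.0
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


def km_curves_by_group(labels, time, event, grid_step: float = 1.0) -> dict:
    """Per-group Kaplan-Meier curves plus at-risk counts on a monthly grid.

    Returns ``{group: {"curve": StepSurvival, "table": DataFrame}}`` where the
    table has columns month, survival, at_risk.
    """
    g = np.asarray(labels)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    out: dict = {}
    grid = np.arange(0.0, np.max(t) + grid_step, grid_step)
    for grp in np.unique(g):
        m = g == grp
        curve = km_estimator(t[m], e[m])
        at_risk = (t[m][:, None] >= grid[None, :]).sum(axis=0)
        table = pd.DataFrame(
            {"month": grid, "survival": np.asarray(curve.evaluate(grid)), "at_risk": at_risk}
        )
        out[grp] = {"curve": curve, "table": table}
    return out


@dataclass
class EvaluationReport:
    """Metrics for one covariate mode: C-index and 5-year AUC, train and test."""

    c_index_train: float
    c_index_test: float
    auc_train: float
    auc_test: float
    auc_train_unweighted: float | None = None
    auc_test_unweighted: float | None = None
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "c_index_train": self.c_index_train,
            "c_index_test": self.c_index_test,
            "auc_train": self.auc_train,
            "auc_test": self.auc_test,
        }
        if self.auc_train_unweighted is not None:
            d["auc_train_unweighted"] = self.auc_train_unweighted
        if self.auc_test_unweighted is not None:
            d["auc_test_unweighted"] = self.auc_test_unweighted
        if self.logrank_chi2 is not None:
            d["logrank_chi2"] = self.logrank_chi2
            d["logrank_p"] = self.logrank_p
        d.update(self.extras)
        return d
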