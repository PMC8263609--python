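"""Random survival forest with log-rank splitting.

Each tree is grown on a bootstrap sample (n draws with replacement).  At
every node ``mtry`` candidate features are drawn without replacement and the
chosen split maximizes the absolute standardized log-rank statistic between
the two daughters,

    num = sum_k ( d_kL - Y_kL * d_k / Y_k )
    var = sum_k ( Y_kL / Y_k ) (1 - Y_kL / Y_k) ((Y_k - d_k) / (Y_k - 1)) d_k

over the distinct event times ``t_k`` in the node; candidate thresholds are
midpoints between sorted distinct in-bag values and both daughters must keep
at least ``min_node_size`` in-bag samples.  Terminal nodes carry a
Nelson-Aalen cumulative hazard evaluated on the forest-wide event-time grid.

Unlike off-the-shelf forests, trees expose per-sample terminal-node ids and
bootstrap in-bag counts: those are the raw material for the in-bag proximity
matrix used to cluster patients, and for frequency-based variable importance.

The split search is vectorized: for one feature, a single pass of cumulative
sums over the (sample x event-time) at-risk matrix scores every candidate
threshold at once.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalTree",
    "SurvivalForest",
    "fit_survival_forest",
    "terminal_node_ids",
    "variable_importance_frequency",
    "variable_importance_repeated",
    "predict_forest_risk",
    "CLUSTERING_PRESET",
    "FEATURE_SELECTION_PRESET",
]

# Forest presets: patient-clustering forest and feature-selection forest.
CLUSTERING_PRESET = {"n_trees": 1000, "min_node_size": 5}
FEATURE_SELECTION_PRESET = {"n_trees": 1000, "min_node_size": 2}

_VAR_EPS = 1e-12


@dataclass
class SurvivalTree:
    """Array-encoded binary tree; ``feature[i] == -1`` marks a terminal node."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_row: np.ndarray  # node id -> row in chf (or -1 for internal nodes)
    chf: np.ndarray  # (n_leaves, n_grid) Nelson-Aalen cumulative hazard
    inbag_counts: np.ndarray  # (n_train,) bootstrap multiplicity

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Terminal node id reached by each row of ``X``."""
        node = np.zeros(X.shape[0], dtype=np.int32)
        active = np.flatnonzero(self.feature[node] >= 0)
        while active.size:
            nd = node[active]
            go_left = X[active, self.feature[nd]] <= self.threshold[nd]
            node[active] = np.where(go_left, self.left[nd], self.right[nd])
            active = active[self.feature[node[active]] >= 0]
        return node

    def leaf_chf(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_grid) cumulative hazard of the reached leaves."""
        return self.chf[self.leaf_row[self.apply(X)]]


@dataclass
class SurvivalForest:
    trees: list[SurvivalTree]
    n_trees: int
    mtry: int
    min_node_size: int
    seed: int
    feature_names: list[str]
    event_time_grid: np.ndarray
    n_train: int
    training_node_ids: np.ndarray = field(repr=False)  # (n_train, n_trees)

    @property
    def inbag_matrix(self) -> np.ndarray:
        """(n_train, n_trees) bootstrap counts."""
        return np.stack([t.inbag_counts for t in self.trees], axis=1)

    def _matrix(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in features.columns]
            if missing:
                raise ValueError(f"feature columns missing: {missing[:5]}")
            return features[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix does not match training schema")
        return X

    def predict_cumulative_hazard(self, features) -> np.ndarray:
        """Tree-averaged Nelson-Aalen CHF on the event-time grid."""
        X = self._matrix(features)
        acc = np.zeros((X.shape[0], self.event_time_grid.size))
        for tree in self.trees:
            acc += tree.leaf_chf(X)
        return acc / self.n_trees

    def predict_survival_at(self, features, horizon: float) -> np.ndarray:
        """exp(-CHF(horizon)) with the step CHF evaluated right-continuously."""
        chf = self.predict_cumulative_hazard(features)
        idx = np.searchsorted(self.event_time_grid, horizon, side="right") - 1
        h = chf[:, idx] if idx >= 0 else np.zeros(chf.shape[0])
        return np.exp(-h)


def _grow_tree(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    grid: np.ndarray,
    mtry: int,
    min_node_size: int,
    rng: np.random.Generator,
) -> SurvivalTree:
    n, p = X.shape
    boot = rng.integers(0, n, size=n)
    inbag_counts = np.bincount(boot, minlength=n)

    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    leaf_samples: dict[int, np.ndarray] = {}

    stack: list[tuple[int, np.ndarray]] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        return len(feature) - 1

    root = new_node()
    stack.append((root, boot))

    while stack:
        node_id, samples = stack.pop()
        best = _best_split(X, time, event, samples, mtry, min_node_size, rng)
        if best is None:
            leaf_samples[node_id] = samples
            continue
        f, thr = best
        go_left = X[samples, f] <= thr
        feature[node_id] = f
        threshold[node_id] = thr
        lid, rid = new_node(), new_node()
        left[node_id], right[node_id] = lid, rid
        stack.append((rid, samples[~go_left]))
        stack.append((lid, samples[go_left]))

    # Nelson-Aalen CHF per leaf on the forest grid
    n_nodes = len(feature)
    leaf_row = np.full(n_nodes, -1, dtype=np.int32)
    chf_rows = []
    for row, (node_id, samples) in enumerate(sorted(leaf_samples.items())):
        leaf_row[node_id] = row
        chf_rows.append(_nelson_aalen_on_grid(time[samples], event[samples], grid))
    return SurvivalTree(
        feature=np.asarray(feature, dtype=np.int32),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int32),
        right=np.asarray(right, dtype=np.int32),
        leaf_row=leaf_row,
        chf=np.asarray(chf_rows, dtype=float),
        inbag_counts=inbag_counts.astype(np.int32),
    )


def _nelson_aalen_on_grid(t: np.ndarray, e: np.ndarray, grid: np.ndarray) -> np.ndarray:
    taus = np.unique(t[e == 1])
    if taus.size == 0:
        return np.zeros(grid.size)
    Y = (t[:, None] >= taus[None, :]).sum(axis=0)
    d = ((t[:, None] == taus[None, :]) & (e[:, None] == 1)).sum(axis=0)
    H = np.cumsum(d / Y)
    idx = np.searchsorted(taus, grid, side="right") - 1
    out = np.zeros(grid.size)
    pos = idx >= 0
    out[pos] = H[idx[pos]]
    return out


def _best_split(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    samples: np.ndarray,
    mtry: int,
    min_node_size: int,
    rng: np.random.Generator,
) -> tuple[int, float] | None:
    m = samples.size
    if m < 2 * min_node_size:
        return None
    t = time[samples]
    e = event[samples]
    taus = np.unique(t[e == 1])
    if taus.size == 0:
        return None

    # node-level at-risk / event matrices over the node's own event times
    A = (t[:, None] >= taus[None, :]).astype(np.float64)
    Y = A.sum(axis=0)
    E = ((t[:, None] == taus[None, :]) & (e[:, None] == 1)).astype(np.float64)
    d = E.sum(axis=0)
    r = d / Y
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(Y > 1, d * (Y - d) / (Y - 1), 0.0)
    v1 = c / Y
    v2 = c / (Y * Y)

    candidates = rng.choice(X.shape[1], size=mtry, replace=False)
    candidates.sort()

    best_score = 0.0
    best: tuple[int, float] | None = None
    lo, hi = min_node_size, m - min_node_size  # admissible prefix sizes
    for f in candidates:
        x = X[samples, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        if xs[0] == xs[-1]:
            continue  # in-bag constant feature: never split
        cumA = np.cumsum(A[order], axis=0)
        cum_events = np.cumsum(e[order].astype(np.float64))
        num = cum_events - cumA @ r
        var = cumA @ v1 - (cumA * cumA) @ v2
        # prefix of size j uses row j-1; split requires xs[j-1] < xs[j]
        j = np.arange(1, m)
        ok = (j >= lo) & (j <= hi) & (xs[:-1] < xs[1:])
        if not ok.any():
            continue
        score = np.full(m - 1, -np.inf)
        vv = var[: m - 1]
        good = ok & (vv > _VAR_EPS)
        score[good] = np.abs(num[: m - 1][good]) / np.sqrt(vv[good])
        jbest = int(np.argmax(score))
        if score[jbest] > best_score:
            best_score = float(score[jbest])
            best = (int(f), float((xs[jbest] + xs[jbest + 1]) / 2.0))
    return best


def fit_survival_forest(
    features,
    time,
    event,
    n_trees: int = 1000,
    mtry: int | None = None,
    min_node_size: int = 5,
    seed: int = 0,
) -> SurvivalForest:
    """Fit the forest; bit-reproducible given ``seed`` (per-tree sub-seeds are
    spawned from a forest-level seed sequence)."""
    if isinstance(features, pd.DataFrame):
        names = [str(c) for c in features.columns]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    n, p = X.shape
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds number of features ({p})")
    if np.unique(t[e == 1]).size < 2:
        raise ValueError("need at least 2 distinct event times")

    grid = np.unique(t[e == 1])
    child_seeds = np.random.SeedSequence(seed).spawn(n_trees)
    trees = [
        _grow_tree(X, t, e, grid, mtry, min_node_size, np.random.default_rng(s))
        for s in child_seeds
    ]
    training_ids = np.stack([tree.apply(X) for tree in trees], axis=1)
    return SurvivalForest(
        trees=trees,
        n_trees=n_trees,
        mtry=mtry,
        min_node_size=min_node_size,
        seed=seed,
        feature_names=names,
        event_time_grid=grid,
        n_train=n,
        training_node_ids=training_ids,
    )


def terminal_node_ids(forest: SurvivalForest, features) -> np.ndarray:
    """(n_samples, n_trees) terminal node reached in every tree."""
    X = forest._matrix(features)
    return np.stack([tree.apply(X) for tree in forest.trees], axis=1)


def variable_importance_frequency(forest: SurvivalForest) -> list[tuple[str, float]]:
    """Features ranked by split frequency (internal-node counts), descending;
    ties broken alphabetically."""
    counts: Counter[str] = Counter({name: 0 for name in forest.feature_names})
    for tree in forest.trees:
        for f in tree.feature[tree.feature >= 0]:
            counts[forest.feature_names[int(f)]] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def variable_importance_repeated(
    features,
    time,
    event,
    n_repeats: int = 10,
    seed: int = 0,
    **forest_params,
) -> list[tuple[str, float]]:
    """Average split-frequency ranking over repeated forest fits.

    The forest is refit ``n_repeats`` times with distinct sub-seeds and the
    per-feature split counts are averaged (mean count), smoothing out the
    forest's own randomness before the top-k cut.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_repeats)
    total: Counter[str] = Counter()
    for s in seeds:
        forest = fit_survival_forest(
            features, time, event, seed=int(s.generate_state(1)[0] % (2**31)), **forest_params
        )
        for name, cnt in variable_importance_frequency(forest):
            total[name] += cnt
    mean = {name: cnt / n_repeats for name, cnt in total.items()}
    return sorted(mean.items(), key=lambda kv: (-kv[1], kv[0]))


def predict_forest_risk(forest: SurvivalForest, features) -> np.ndarray:
    """Ensemble mortality: the tree-averaged CHF summed over the event-time
    grid; higher values mean higher risk."""
    return forest.predict_cumulative_hazard(features).sum(axis=1)


# ---------------------------------------------------------------------------
# JSON persistence


def forest_to_json(forest: SurvivalForest, path: str | Path | None = None) -> dict:
    doc = {
        "n_trees": forest.n_trees,
        "mtry": forest.mtry,
        "min_node_size": forest.min_node_size,
        "seed": forest.seed,
        "feature_names": forest.feature_names,
        "event_time_grid": forest.event_time_grid.tolist(),
        "n_train": forest.n_train,
        "training_node_ids": forest.training_node_ids.tolist(),
        "trees": [
            {
                "feature": t.feature.tolist(),
                "threshold": [None if np.isnan(v) else v for v in t.threshold],
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "leaf_row": t.leaf_row.tolist(),
                "chf": t.chf.tolist(),
                "inbag_counts": t.inbag_counts.tolist(),
            }
            for t in forest.trees
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc))
    return doc


def forest_from_json(doc: dict | str | Path) -> SurvivalForest:
    if not isinstance(doc, dict):
        doc = json.loads(Path(doc).read_text())
    trees = [
        SurvivalTree(
            feature=np.asarray(t["feature"], dtype=np.int32),
            threshold=np.asarray(
                [np.nan if v is None else v for v in t["threshold"]], dtype=float
            ),
            left=np.asarray(t["left"], dtype=np.int32),
            right=np.asarray(t["right"], dtype=np.int32),
            leaf_row=np.asarray(t["leaf_row"], dtype=np.int32),
            chf=np.asarray(t["chf"], dtype=float),
            inbag_counts=np.asarray(t["inbag_counts"], dtype=np.int32),
        )
        for t in doc["trees"]
    ]
    return SurvivalForest(
        trees=trees,
        n_trees=doc["n_trees"],
        mtry=doc["mtry"],
        min_node_size=doc["min_node_size"],
        seed=doc["seed"],
        feature_names=list(doc["feature_names"]),
        event_time_grid=np.asarray(doc["event_time_grid"], dtype=float),
        n_train=doc["n_train"],
        training_node_ids=np.asarray(doc["training_node_ids"], dtype=np.int32),
    )
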