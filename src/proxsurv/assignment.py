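"""Propagating training cluster labels to unseen patients.

A multinomial log-linear model is trained on the training patients with the
cluster label as response and the top forest-frequency radiomic features
(z-scored with training statistics) as covariates.  Held-out patients are
then assigned by softmax argmax.  The multinomial form is kept even for two
clusters so the same code path covers 2-4 groups; with two classes it
coincides with binary logistic regression.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .clustering import ClusterLabels
from .preprocessing import Scaler

__all__ = ["AssignmentModel", "fit_assignment_model", "assign_clusters"]

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 10
MAX_ITER = 500
GRADIENT_TOL = 1e-6
_COEF_EXPLOSION = 1e4
_RIDGE_C = 100.0


@dataclass
class AssignmentModel:
    """Fitted multinomial assigner.

    ``coefficients`` has one row per non-reference cluster (reference =
    cluster 1) and columns ``[intercept, features...]`` on z-scored inputs.
    """

    feature_subset: list[str]
    classes: np.ndarray  # sorted cluster ids, classes[0] == 1
    coefficients: np.ndarray  # (k - 1, n_features + 1) relative to cluster 1
    scaler: Scaler
    converged: bool
    ridge_fallback: bool = False

    def _logits(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_subset if c not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        z = self.scaler.transform(features[self.feature_subset]).to_numpy(dtype=float)
        k = self.classes.size
        logits = np.zeros((z.shape[0], k))
        logits[:, 1:] = self.coefficients[:, 0][None, :] + z @ self.coefficients[:, 1:].T
        return logits

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        logits = self._logits(features)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def to_dict(self) -> dict:
        return {
            "feature_subset": self.feature_subset,
            "classes": self.classes.tolist(),
            "coefficients": self.coefficients.tolist(),
            "scaler": self.scaler.to_dict(),
            "converged": bool(self.converged),
            "ridge_fallback": bool(self.ridge_fallback),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssignmentModel":
        return cls(
            feature_subset=list(d["feature_subset"]),
            classes=np.asarray(d["classes"], dtype=int),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            scaler=Scaler.from_dict(d["scaler"]),
            converged=d["converged"],
            ridge_fallback=d.get("ridge_fallback", False),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "AssignmentModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _reference_coefficients(clf: LogisticRegression, k: int) -> np.ndarray:
    """sklearn coefficients -> (k-1, p+1) matrix relative to the first class."""
    coef = np.asarray(clf.coef_)
    intercept = np.asarray(clf.intercept_)
    if k == 2 and coef.shape[0] == 1:
        full = np.vstack([np.zeros_like(coef[0]), coef[0]])
        ints = np.array([0.0, float(intercept[0])])
    else:
        full = coef
        ints = intercept
    rel = full[1:] - full[0]
    rel_int = ints[1:] - ints[0]
    return np.hstack([rel_int[:, None], rel])


def fit_assignment_model(
    features: pd.DataFrame,
    labels: ClusterLabels,
    importance_ranking: list[tuple[str, float]],
    top_k: int = DEFAULT_TOP_K,
) -> AssignmentModel:
    """Maximum-likelihood multinomial fit on the ``top_k`` ranked features.

    Quasi-Newton (lbfgs) on the unpenalized likelihood; if the optimizer
    fails to converge or the coefficients explode (separation), the model is
    refit with a light L2 ridge and the fallback is recorded.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    y = labels.labels
    if np.unique(y).size < 2:
        raise ValueError("cluster labels contain a single class")
    subset = [name for name, _ in importance_ranking if name in features.columns][:top_k]
    if not subset:
        raise ValueError("no ranked features present in the feature table")
    x = features[subset]
    scaler = Scaler.fit(x)
    z = scaler.transform(x).to_numpy(dtype=float)

    def _fit(penalty):
        clf = LogisticRegression(
            C=_RIDGE_C if penalty else np.inf,
            solver="lbfgs",
            max_iter=MAX_ITER,
            tol=GRADIENT_TOL,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(z, y)
        converged = bool(np.all(clf.n_iter_ < MAX_ITER))
        return clf, converged

    clf, converged = _fit(penalty=False)
    ridge = False
    if not converged or np.abs(clf.coef_).max() > _COEF_EXPLOSION:
        logger.warning("assignment model unstable (separation?); refitting with L2 ridge")
        clf, converged = _fit(penalty=True)
        ridge = True

    k = int(np.unique(y).size)
    return AssignmentModel(
        feature_subset=subset,
        classes=np.asarray(sorted(np.unique(y)), dtype=int),
        coefficients=_reference_coefficients(clf, k),
        scaler=scaler,
        converged=converged,
        ridge_fallback=ridge,
    )


def assign_clusters(
    model: AssignmentModel, features: pd.DataFrame
) -> tuple[ClusterLabels, np.ndarray]:
    """Softmax argmax assignment; ties go to the lower cluster index.

    Returns the labels and the (n, k) probability matrix.
    """
    proba = model.predict_proba(features)
    labels = model.classes[np.argmax(proba, axis=1)]  # argmax -> first (lowest) index
    present = np.unique(labels)
    k = int(model.classes.size)
    if set(present) != set(model.classes.tolist()):
        # degenerate assignment (some cluster empty on this set) is allowed;
        # keep original numbering by reporting labels as-is
        return DegenerateLabels(k=k, labels=labels), proba
    return ClusterLabels(k=k, labels=labels), proba


@dataclass
class DegenerateLabels:
    """Cluster labels where some clusters may be unoccupied (test-set edge case)."""

    k: int
    labels: np.ndarray

    def sizes(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in range(1, self.k + 1)}
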