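"""IPCW-weighted, NNLS-stacked survival-prediction ensemble.

Five base risk models are fit on a design matrix of clinical covariates plus
optional radiomic covariates or the cluster label:

* Cox proportional hazards (partial likelihood; handles censoring directly)
* random survival forest (this package's implementation)
* random forest classifier, logistic regression and logistic elastic net on
  the IPCW-weighted binary 5-year outcome (zero-weight patients excluded)

Survival-model outputs are harmonized to the classifiers' scale as the
horizon event probability ``1 - S_i(60)``, so all five stacked columns are
5-year risks.  Stacking weights are learned on 5-fold out-of-fold
predictions by weighted non-negative least squares and normalized to sum to
one (super-learner convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from . import forest as _forest
from .ipcw import HorizonOutcome, ipcw_weights, km_estimator
from .preprocessing import Scaler

__all__ = [
    "MODEL_NAMES",
    "BaseModels",
    "StackedEnsemble",
    "fit_base_models",
    "out_of_fold_predictions",
    "nnls_stack",
    "fit_stacked_ensemble",
    "ensemble_predict",
    "coxnet_select",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = ("cox", "rsf", "rf", "logistic", "elastic_net")

DEFAULT_RSF_TREES = 300
DEFAULT_RF_TREES = 500
_ENET_C_GRID = np.logspace(-2.0, 2.0, 7)


def _marginal_risk(time, event, horizon) -> float:
    """Kaplan-Meier 1 - S(horizon), the constant fallback prediction."""
    km = km_estimator(time, event)
    return float(1.0 - np.asarray(km.evaluate(horizon)))


@dataclass
class BaseModels:
    """Fitted base models plus the shared preprocessing state."""

    columns: list[str]
    horizon: float
    constant_risk: float
    cox: object | None = None
    rsf: object | None = None
    rf: object | None = None
    logistic: object | None = None
    elastic_net: object | None = None
    scaler: Scaler | None = None
    notes: dict = field(default_factory=dict)

    def predict_risk(self, design: pd.DataFrame) -> pd.DataFrame:
        """(n, 5) horizon event probabilities, columns ordered as MODEL_NAMES."""
        missing = [c for c in self.columns if c not in design.columns]
        if missing:
            raise ValueError(f"design columns missing: {missing}")
        x = design[self.columns]
        n = x.shape[0]
        out = {}
        if not self.columns:  # null design: every model is the marginal constant
            for m in MODEL_NAMES:
                out[m] = np.full(n, self.constant_risk)
            return pd.DataFrame(out, index=design.index)
        xz = self.scaler.transform(x).to_numpy(dtype=float)
        out["cox"] = 1.0 - self._cox_survival(x)
        out["rsf"] = 1.0 - self.rsf.predict_survival_at(x.to_numpy(dtype=float), self.horizon)
        out["rf"] = self._proba(self.rf, x.to_numpy(dtype=float))
        out["logistic"] = self._proba(self.logistic, xz)
        out["elastic_net"] = self._proba(self.elastic_net, xz)
        return pd.DataFrame(out, index=design.index)

    def _cox_survival(self, x: pd.DataFrame) -> np.ndarray:
        sf = self.cox.predict_survival_function(x, times=[self.horizon])
        return sf.to_numpy()[0]

    @staticmethod
    def _proba(clf, x: np.ndarray) -> np.ndarray:
        if len(getattr(clf, "classes_", [0, 1])) == 1:
            return np.full(x.shape[0], float(clf.classes_[0]))
        return clf.predict_proba(x)[:, 1]


def _fit_cox(design: pd.DataFrame, time, event):
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = design.copy()
    df["__time"] = np.asarray(time, dtype=float)
    df["__event"] = np.asarray(event).astype(int)
    for penalizer in (0.0, 0.1):
        try:
            cph = CoxPHFitter(penalizer=penalizer)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="__time", event_col="__event")
            if penalizer > 0:
                logger.warning("Cox model ridge-stabilized (penalizer=%.2f)", penalizer)
            return cph
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            continue
    cph = CoxPHFitter(penalizer=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="__time", event_col="__event")
    logger.warning("Cox model required strong ridge stabilization")
    return cph


def _fit_weighted_logistic(xz, y, w, penalty=None, seed=0, l1_ratio=None, C=1.0):
    kwargs = dict(max_iter=2000, tol=1e-7)
    if penalty == "elasticnet":
        clf = LogisticRegression(
            solver="saga", l1_ratio=l1_ratio, C=C, random_state=seed, **kwargs
        )
    elif penalty == "l2":
        clf = LogisticRegression(C=C, solver="lbfgs", **kwargs)
    else:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(xz, y, sample_weight=w)
    return clf


def _select_enet_C(xz, y, w, l1_ratio, n_folds, seed) -> float:
    """Weighted CV deviance (log loss) over a small C grid."""
    if np.unique(y).size < 2 or xz.shape[0] < 2 * n_folds:
        return 1.0
    kf = KFold(n_splits=min(n_folds, xz.shape[0]), shuffle=True, random_state=seed)
    best_C, best_loss = 1.0, np.inf
    for C in _ENET_C_GRID:
        losses = []
        for tr, te in kf.split(xz):
            if np.unique(y[tr]).size < 2:
                continue
            clf = _fit_weighted_logistic(
                xz[tr], y[tr], w[tr], penalty="elasticnet", seed=seed, l1_ratio=l1_ratio, C=C
            )
            p = np.clip(clf.predict_proba(xz[te])[:, 1], 1e-12, 1 - 1e-12)
            ll = -(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
            losses.append(np.average(ll, weights=w[te]) if w[te].sum() > 0 else np.mean(ll))
        if losses and np.mean(losses) < best_loss:
            best_loss, best_C = float(np.mean(losses)), float(C)
    return best_C


def fit_base_models(
    design: pd.DataFrame,
    time,
    event,
    horizon: float,
    outcome: HorizonOutcome,
    seed: int = 0,
    rsf_trees: int = DEFAULT_RSF_TREES,
    rf_trees: int = DEFAULT_RF_TREES,
    enet_l1_ratio: float = 0.5,
    enet_cv_folds: int = 5,
) -> BaseModels:
    """Fit the five base models on training data.

    The three binary learners use the IPCW labels/weights with zero-weight
    patients excluded; the elastic-net penalty is chosen by weighted CV.
    """
    if design.isna().any().any():
        raise ValueError("design matrix contains missing values")
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    cols = [str(c) for c in design.columns]
    const = _marginal_risk(t, e, horizon)
    models = BaseModels(columns=cols, horizon=horizon, constant_risk=const)
    if not cols:
        return models

    seeds = np.random.SeedSequence(seed).spawn(4)
    s_rsf, s_rf, s_log, s_enet = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    models.cox = _fit_cox(design, t, e)
    models.rsf = _forest.fit_survival_forest(
        design.to_numpy(dtype=float), t, e, n_trees=rsf_trees, min_node_size=5, seed=s_rsf
    )

    m = outcome.observable
    y, w = outcome.label[m], outcome.weight[m]
    x = design.loc[m]
    models.scaler = Scaler.fit(design)
    xz_all = models.scaler.transform(design).to_numpy(dtype=float)
    xz = xz_all[m]

    models.rf = RandomForestClassifier(n_estimators=rf_trees, random_state=s_rf)
    models.rf.fit(x.to_numpy(dtype=float), y, sample_weight=w)

    clf = _fit_weighted_logistic(xz, y, w, penalty=None, seed=s_log)
    if np.abs(clf.coef_).max() > 1e4:
        logger.warning("logistic base model unstable; refitting with L2 ridge")
        clf = _fit_weighted_logistic(xz, y, w, penalty="l2", C=100.0, seed=s_log)
        models.notes["logistic_ridge_fallback"] = True
    models.logistic = clf

    C = _select_enet_C(xz, y, w, enet_l1_ratio, enet_cv_folds, s_enet)
    models.elastic_net = _fit_weighted_logistic(
        xz, y, w, penalty="elasticnet", seed=s_enet, l1_ratio=enet_l1_ratio, C=C
    )
    models.notes["elastic_net_C"] = C
    return models


def out_of_fold_predictions(
    design: pd.DataFrame,
    time,
    event,
    horizon: float,
    n_folds: int = 5,
    seed: int = 0,
    max_refolds: int = 20,
    **model_kwargs,
) -> pd.DataFrame:
    """(n, 5) matrix of cross-validated 5-year risks, rows aligned to patients.

    Each fold's models are fit on the complement, with censoring weights
    re-estimated inside the complement; folds whose complement lacks events
    trigger a reseeded refold (logged).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    n = design.shape[0]
    n_folds = min(n_folds, n)

    current = seed
    for attempt in range(max_refolds):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=current)
        splits = list(kf.split(np.arange(n)))
        ok = all(np.unique(t[tr][e[tr] == 1]).size >= 2 for tr, _ in splits)
        if ok:
            break
        logger.warning("fold without enough events; refolding with a new seed")
        current += 1
    else:
        raise ValueError("could not build folds with events in every training part")

    Z = np.empty((n, len(MODEL_NAMES)))
    for tr, te in splits:
        out_tr = ipcw_weights(t[tr], e[tr], horizon)
        base = fit_base_models(
            design.iloc[tr], t[tr], e[tr], horizon, out_tr, seed=current, **model_kwargs
        )
        Z[te] = base.predict_risk(design.iloc[te]).to_numpy()
    return pd.DataFrame(Z, index=design.index, columns=list(MODEL_NAMES))


def nnls_stack(Z: pd.DataFrame | np.ndarray, outcome: HorizonOutcome) -> np.ndarray:
    """Weighted Lawson-Hanson NNLS of the labels on the base predictions.

    Rows with zero censoring weight are excluded (they carry zero loss);
    weights are normalized to sum to one when any is positive, otherwise the
    uniform fallback is returned with a warning.
    """
    z = np.asarray(Z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("Z contains non-finite values")
    m = outcome.observable
    zw = z[m] * np.sqrt(outcome.weight[m])[:, None]
    yw = outcome.label[m] * np.sqrt(outcome.weight[m])
    beta, _ = _nnls(zw, yw)
    if beta.sum() <= 0:
        logger.warning("NNLS returned the zero vector; falling back to uniform weights")
        return np.full(z.shape[1], 1.0 / z.shape[1])
    return beta / beta.sum()


@dataclass
class StackedEnsemble:
    base_models: BaseModels
    stack_weights: np.ndarray
    cv_seed: int
    horizon: float
    oof_predictions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if np.any(self.stack_weights < 0) or not np.any(self.stack_weights > 0):
            raise ValueError("stack weights must be non-negative with at least one positive")

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        return ensemble_predict(self, design)

    def weights_dict(self) -> dict[str, float]:
        return {m: float(w) for m, w in zip(MODEL_NAMES, self.stack_weights)}


def fit_stacked_ensemble(
    design: pd.DataFrame,
    time,
    event,
    horizon: float = 60.0,
    n_folds: int = 5,
    seed: int = 0,
    **model_kwargs,
) -> StackedEnsemble:
    """Learn NNLS stacking weights on out-of-fold predictions, then refit the
    base models on the full training data."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    outcome = ipcw_weights(t, e, horizon)
    Z = out_of_fold_predictions(design, t, e, horizon, n_folds=n_folds, seed=seed, **model_kwargs)
    weights = nnls_stack(Z, outcome)
    base = fit_base_models(design, t, e, horizon, outcome, seed=seed, **model_kwargs)
    return StackedEnsemble(
        base_models=base, stack_weights=weights, cv_seed=seed, horizon=horizon, oof_predictions=Z
    )


def ensemble_predict(model: StackedEnsemble, design: pd.DataFrame) -> np.ndarray:
    """Convex-ish combination of base 5-year risks, clipped to [0, 1]."""
    risks = model.base_models.predict_risk(design).to_numpy()
    return np.clip(risks @ model.stack_weights, 0.0, 1.0)


def coxnet_select(
    features: pd.DataFrame,
    time,
    event,
    n_folds: int = 5,
    seed: int = 0,
    l1_ratio: float = 1.0,
    n_alphas: int = 40,
) -> list[str]:
    """L1-penalized Cox feature selection over a regularization path.

    The penalty is chosen by cross-validated concordance on held-out folds;
    the model is refit on the full training data at that penalty and the
    features with non-zero coefficients are returned (possibly none).
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    if e.sum() < 2:
        raise ValueError("need at least 2 events")
    scaler = Scaler.fit(features)
    xz = scaler.transform(features).to_numpy(dtype=float)
    y = Surv.from_arrays(event=e.astype(bool), time=t)

    path = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio, n_alphas=n_alphas, alpha_min_ratio=0.01, fit_baseline_model=False
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path.fit(xz, y)
    alphas = np.asarray(path.alphas_)

    from .evaluation import harrell_c_index

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros(alphas.size)
    counts = np.zeros(alphas.size)
    for tr, te in kf.split(xz):
        if e[tr].sum() < 2 or e[te].sum() < 1:
            continue
        fold = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fold.fit(xz[tr], y[tr])
            except Exception:
                continue
        fold_alphas = np.asarray(fold.alphas_)
        for i, a in enumerate(alphas):
            j = int(np.argmin(np.abs(fold_alphas - a)))
            lp = xz[te] @ fold.coef_[:, j]
            if np.unique(lp).size < 2:
                continue
            try:
                scores[i] += harrell_c_index(lp, t[te], e[te])
                counts[i] += 1
            except ValueError:
                continue
    valid = counts > 0
    if not valid.any():
        logger.warning("coxnet CV produced no valid scores; selecting nothing")
        return []
    mean_scores = np.where(valid, scores / np.maximum(counts, 1), -np.inf)
    # ties toward larger alpha (sparser model); alphas are sorted descending
    best = int(np.min(np.flatnonzero(mean_scores == mean_scores.max())))

    coefs = path.coef_[:, best]
    selected = [c for c, b in zip(features.columns, coefs) if b != 0.0]
    if not selected:
        logger.warning("coxnet selected no features at the CV-optimal penalty")
    return selected
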