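"""End-to-end risk-stratification pipeline.

Stages: preprocess (feature filters + clinical categorization) -> clustering
forest -> in-bag proximity -> Ward dendrogram -> cut at k -> multinomial
cluster assignment for test patients -> per-covariate-mode stacked ensembles
-> discrimination metrics on the held-out test set.

Test patients never reach a fitting routine: filter statistics, the forest,
the dendrogram, the assignment model, cross-validation folds and the NNLS
stack all see training rows only; test rows are only transformed and scored.

All randomness flows from one master seed, expanded in a fixed order
(simulation, clustering forest, feature-selection forest, coxnet, ensemble,
auxiliary), so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import clustering as _clust
from . import ensemble as _ens
from . import forest as _forest
from ._seeds import spawn_seeds
from .assignment import assign_clusters, fit_assignment_model
from .cohort import ANCHOR_FEATURES, Cohort, CohortConfig, generate_cohort, read_cohort
from .evaluation import auc_horizon, harrell_c_index, km_curves_by_group, logrank_test
from .ipcw import HorizonOutcome, ipcw_weights
from .preprocessing import categorize_clinical, encode_design, filter_features

__all__ = ["PipelineConfig", "run_pipeline", "CLINICAL_COVARIATES"]

logger = logging.getLogger(__name__)

# the six baseline clinical covariates; AJCC stage enters only in +ajcc modes
CLINICAL_COVARIATES = [
    "age",
    "hpv_status",
    "smoking_status",
    "t_category",
    "n_category",
    "therapeutic_combination",
]

SMALL_CLUSTER_FRACTION = 0.05


@dataclass
class PipelineConfig:
    """Configuration of :func:`run_pipeline`.

    Exactly one of ``simulate`` (a :class:`CohortConfig`) or ``data_dir``
    (a directory written by :func:`proxsurv.cohort.write_cohort`) must be
    set.  Tree counts default to desk-scale values that keep a full run in
    the low minutes; raise them for production-quality variance reduction.
    """

    simulate: CohortConfig | None = None
    data_dir: str | None = None
    outcome: str = "os"
    covariate_modes: tuple[str, ...] = ("clinical", "clinical+clusters_2")
    horizon: float = 60.0
    folds: int = 5
    top_k: int = 10
    clustering_trees: int = 300
    clustering_min_node_size: int = 5
    fs_trees: int = 300
    fs_min_node_size: int = 2
    ensemble_rsf_trees: int = 200
    ensemble_rf_trees: int = 300
    ward_dialect: str = "ward.D"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.data_dir is None):
            raise ValueError("exactly one of simulate or data_dir must be set")
        self.covariate_modes = tuple(self.covariate_modes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = CohortConfig.from_dict(raw["simulate"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = None if self.simulate is None else self.simulate.to_dict()
        d["covariate_modes"] = list(self.covariate_modes)
        return d


def _parse_mode(mode: str) -> tuple[str, int | None]:
    """'clinical' / 'clinical+ajcc' / 'clinical+cox' / 'clinical+rsf_top_N' /
    'clinical+clusters_K' -> (kind, parameter)."""
    if mode == "clinical":
        return "clinical", None
    if mode == "clinical+ajcc":
        return "ajcc", None
    if mode == "clinical+cox":
        return "cox", None
    if mode.startswith("clinical+rsf_top_"):
        return "rsf_top", int(mode.rsplit("_", 1)[1])
    if mode.startswith("clinical+clusters_"):
        k = int(mode.rsplit("_", 1)[1])
        if not 2 <= k <= 4:
            raise ValueError("cluster modes support k in 2..4")
        return "clusters", k
    raise ValueError(f"unknown covariate mode: {mode}")


def _evaluate_mode(
    model: _ens.StackedEnsemble,
    design_train: pd.DataFrame,
    design_test: pd.DataFrame,
    train: Cohort,
    test: Cohort,
    horizon: float,
) -> dict:
    risk_train = model.predict(design_train)
    risk_test = model.predict(design_test)
    out_train = ipcw_weights(train.time_months, train.event, horizon)
    out_test = ipcw_weights(test.time_months, test.event, horizon)
    unit_train = HorizonOutcome(
        horizon, out_train.label, out_train.observable.astype(float), out_train.observable
    )
    unit_test = HorizonOutcome(
        horizon, out_test.label, out_test.observable.astype(float), out_test.observable
    )
    return {
        "c_index_train": harrell_c_index(risk_train, train.time_months, train.event),
        "c_index_test": harrell_c_index(risk_test, test.time_months, test.event),
        "auc_train": auc_horizon(risk_train, out_train),
        "auc_test": auc_horizon(risk_test, out_test),
        "auc_train_unweighted": auc_horizon(risk_train, unit_train),
        "auc_test_unweighted": auc_horizon(risk_test, unit_test),
        "stack_weights": model.weights_dict(),
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return (and optionally write) the report."""
    seeds = spawn_seeds(config.seed, 6)
    s_sim, s_cforest, s_fs, s_cox, s_ens, s_aux = seeds

    stage = "load"
    try:
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=s_sim)
            cohort = generate_cohort(sim_cfg)
        else:
            cohort = read_cohort(config.data_dir)
        cohort.clinical = categorize_clinical(cohort.clinical)
        train, test = cohort.subset("train"), cohort.subset("test")
        logger.info("cohort: %d train / %d test patients", train.n_patients, test.n_patients)

        stage = "preprocess"
        anchors = [a for a in ANCHOR_FEATURES if a in cohort.features.columns]
        feats_train, filter_report = filter_features(
            train.features, np.ones(train.n_patients, dtype=bool), anchors=anchors
        )
        feats_test = test.features[feats_train.columns]
        logger.info(
            "features: %d -> %d after filtering", filter_report.n_input, filter_report.n_output
        )

        cluster_ks = sorted(
            {p for m in config.covariate_modes if _parse_mode(m)[0] == "clusters" for p in [_parse_mode(m)[1]]}
        )
        need_clustering = bool(cluster_ks)

        clusters: dict[int, dict] = {}
        train_labels_by_k: dict[int, np.ndarray] = {}
        test_labels_by_k: dict[int, np.ndarray] = {}
        proximity = dendro = None
        ranking = None
        if need_clustering:
            stage = "clustering_forest"
            cforest = _forest.fit_survival_forest(
                feats_train,
                train.time_months,
                train.event,
                n_trees=config.clustering_trees,
                min_node_size=config.clustering_min_node_size,
                seed=s_cforest,
            )
            ranking = _forest.variable_importance_frequency(cforest)

            stage = "proximity"
            proximity = _clust.inbag_proximity(cforest)
            D = _clust.proximity_to_dissimilarity(proximity)

            stage = "ward"
            dendro = _clust.ward_agglomerate(D, dialect=config.ward_dialect)

            for k in cluster_ks:
                stage = f"clusters_k{k}"
                labels = _clust.cut_dendrogram(dendro, k)
                sizes = labels.sizes()
                if min(sizes.values()) < SMALL_CLUSTER_FRACTION * train.n_patients:
                    logger.warning(
                        "k=%d: smallest cluster has %d patients (<%.0f%% of training set); "
                        "possible overfitting",
                        k,
                        min(sizes.values()),
                        100 * SMALL_CLUSTER_FRACTION,
                    )
                assigner = fit_assignment_model(feats_train, labels, ranking, top_k=config.top_k)
                assigned, _proba = assign_clusters(assigner, feats_test)
                train_labels_by_k[k] = labels.labels
                test_labels_by_k[k] = assigned.labels
                entry: dict = {
                    "train_sizes": sizes,
                    "test_sizes": assigned.sizes(),
                    "assignment_converged": bool(assigner.converged),
                }
                chi2, p = logrank_test(labels.labels, train.time_months, train.event)
                entry["logrank_train"] = {"chi2": chi2, "p": p}
                if np.unique(assigned.labels).size >= 2:
                    chi2, p = logrank_test(assigned.labels, test.time_months, test.event)
                    entry["logrank_test"] = {"chi2": chi2, "p": p}
                if train.latent_group is not None:
                    entry["ari_train"] = float(
                        adjusted_rand_score(train.latent_group.to_numpy(), labels.labels)
                    )
                if test.latent_group is not None and np.unique(assigned.labels).size >= 2:
                    entry["ari_test"] = float(
                        adjusted_rand_score(test.latent_group.to_numpy(), assigned.labels)
                    )
                clusters[k] = entry
                if out_dir is not None:
                    _write_cluster_artifacts(out_dir, k, train, test, labels.labels, assigned.labels, assigner)

        stage = "feature_selection"
        rsf_top_ns = [p for m in config.covariate_modes if _parse_mode(m)[0] == "rsf_top" for p in [_parse_mode(m)[1]]]
        fs_ranking = None
        if rsf_top_ns:
            fs_forest = _forest.fit_survival_forest(
                feats_train,
                train.time_months,
                train.event,
                n_trees=config.fs_trees,
                min_node_size=config.fs_min_node_size,
                seed=s_fs,
            )
            fs_ranking = _forest.variable_importance_frequency(fs_forest)
        cox_selected = None
        if any(_parse_mode(m)[0] == "cox" for m in config.covariate_modes):
            cox_selected = _ens.coxnet_select(
                feats_train, train.time_months, train.event, n_folds=config.folds, seed=s_cox
            )
            logger.info("coxnet selected %d feature(s)", len(cox_selected))

        stage = "ensemble"
        modes_report: dict[str, dict] = {}
        ens_seeds = spawn_seeds(s_ens, len(config.covariate_modes))
        for mode, mode_seed in zip(config.covariate_modes, ens_seeds):
            kind, param = _parse_mode(mode)
            clin_cols = list(CLINICAL_COVARIATES)
            extra_tr = extra_te = None
            clin_tr, clin_te = train.clinical.copy(), test.clinical.copy()
            if kind == "ajcc":
                clin_cols.append("ajcc_stage")
            elif kind == "clusters":
                clin_cols.append("cluster")
                clin_tr["cluster"] = train_labels_by_k[param].astype(str)
                clin_te["cluster"] = test_labels_by_k[param].astype(str)
            elif kind == "rsf_top":
                top = [name for name, _ in fs_ranking[:param]]
                extra_tr, extra_te = feats_train[top], feats_test[top]
            elif kind == "cox":
                if cox_selected:
                    extra_tr, extra_te = feats_train[cox_selected], feats_test[cox_selected]
                else:
                    logger.warning("coxnet selected nothing; %s falls back to clinical-only", mode)
            design_tr = encode_design(clin_tr, clin_cols, extra_numeric=extra_tr)
            design_te = encode_design(clin_te, clin_cols, extra_numeric=extra_te)
            design_te = design_te.reindex(columns=design_tr.columns, fill_value=0.0)
            model = _ens.fit_stacked_ensemble(
                design_tr,
                train.time_months,
                train.event,
                horizon=config.horizon,
                n_folds=config.folds,
                seed=mode_seed,
                rsf_trees=config.ensemble_rsf_trees,
                rf_trees=config.ensemble_rf_trees,
            )
            modes_report[mode] = _evaluate_mode(
                model, design_tr, design_te, train, test, config.horizon
            )
            logger.info(
                "%s: test AUC %.3f, test C-index %.3f",
                mode,
                modes_report[mode]["auc_test"],
                modes_report[mode]["c_index_test"],
            )
            if out_dir is not None:
                safe = mode.replace("+", "_")
                _write_json(Path(out_dir) / f"ensemble_{safe}.json", modes_report[mode])
    except Exception as exc:  # noqa: BLE001 - abort with the failing stage name
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    report = {
        "seed": config.seed,
        "config": config.to_dict(),
        "n_train": train.n_patients,
        "n_test": test.n_patients,
        "event_rate": float(np.mean(cohort.event)),
        "filter": filter_report.to_dict(),
        "clusters": {str(k): v for k, v in clusters.items()},
        "modes": modes_report,
    }
    if cox_selected is not None:
        report["coxnet_selected"] = cox_selected

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(out / "filter_report.json", filter_report.to_dict())
        if proximity is not None:
            pd.DataFrame(
                proximity.values, index=train.patient_ids, columns=train.patient_ids
            ).to_csv(out / "proximity.csv")
            _write_json(out / "dendrogram.json", dendro.to_dict())
        _write_json(out / "report.json", report)
    return report


def _write_json(path: Path, obj: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_cluster_artifacts(out_dir, k, train, test, train_labels, test_labels, assigner) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = pd.DataFrame(
        {
            "patient_id": list(train.patient_ids) + list(test.patient_ids),
            "split": ["train"] * train.n_patients + ["test"] * test.n_patients,
            "cluster": list(train_labels) + list(test_labels),
        }
    )
    rows.to_csv(out / f"clusters_k{k}.csv", index=False)
    assigner.save(out / f"assignment_model_k{k}.json")
    for split_name, cohort_part, labels in (
        ("train", train, train_labels),
        ("test", test, test_labels),
    ):
        curves = km_curves_by_group(labels, cohort_part.time_months, cohort_part.event)
        for grp, data in curves.items():
            data["table"].to_csv(out / f"km_k{k}_{split_name}_cluster{grp}.csv", index=False)
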