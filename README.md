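# proxsurv

Risk stratification for right-censored patient cohorts with high-dimensional
tumor-imaging features, via **random survival forest proximity clustering**
and an **IPCW-weighted, NNLS-stacked prediction ensemble**.

## The problem

Radiomic panels extract hundreds to thousands of continuous intensity,
shape and texture features from a segmented tumor volume. For survival
modelling in mid-size cohorts (a few hundred patients, ~20% observed
events) this feature space is far too wide and too redundant to enter a
risk model directly. `proxsurv` implements a supervised
dimensionality-reduction strategy: compress the whole radiomic block into a
*single categorical covariate* — a cluster label — obtained by clustering
patients through the lens of a random survival forest, then measure whether
that label improves risk prediction over clinical covariates alone.

The package is aimed at biostatisticians and imaging researchers who want a
reproducible, fully inspectable implementation of this pipeline, together
with a synthetic-cohort generator for validation under known ground truth.

## Method

1. **Feature reduction** (training statistics only): drop zero-variance
   columns, drop one member of every pair with |r| > 0.99, drop columns
   with |r| > 0.80 to two anchor features (tumor volume, global mean
   intensity).
2. **Survival forest**: log-rank splitting; at each node the split
   maximizes the standardized statistic
   `|Σ_k (d_kL − Y_kL d_k / Y_k)| / sqrt(Σ_k (Y_kL/Y_k)(1 − Y_kL/Y_k) ((Y_k − d_k)/(Y_k − 1)) d_k)`
   over the node's distinct event times `t_k`.
3. **In-bag proximity**: `P_ij` = fraction of trees, among those where
   patients i and j are both in the bootstrap sample, in which they share a
   terminal node; dissimilarity `D = 1 − P`.
4. **Ward agglomeration** on `D` via the Lance–Williams recurrence, merge
   cost `δ(c1, c2) = |c1||c2| / (|c1| + |c2|) · ‖c̄1 − c̄2‖²`; cut at
   k ∈ {2, 3, 4} clusters.
5. **Assignment**: a multinomial log-linear model on the top-10
   split-frequency features labels held-out patients.
6. **Ensemble**: Cox PH, survival forest, random-forest classifier,
   logistic regression and logistic elastic net, the binary learners
   trained on the 5-year outcome with inverse-probability-of-censoring
   weights (`1/Ĝ(T−)` for events, `1/Ĝ(60)` for survivors, 0 for the
   early-censored); stacked by non-negative least squares on 5-fold
   out-of-fold predictions.
7. **Evaluation**: Harrell's C-index, IPCW-weighted 5-year AUC,
   Kaplan–Meier curves and k-group log-rank tests per cluster.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
import numpy as np
import proxsurv as ps
from proxsurv.cohort import ANCHOR_FEATURES, CohortConfig, generate_cohort
from sklearn.metrics import adjusted_rand_score

cohort = generate_cohort(CohortConfig(seed=0))      # 500 patients, 300 features
train, test = cohort.subset("train"), cohort.subset("test")

feats, report = ps.filter_features(
    train.features, np.ones(train.n_patients, bool), anchors=list(ANCHOR_FEATURES)
)
print(f"features retained: {report.n_output} of {report.n_input}")

forest = ps.fit_survival_forest(
    feats, train.time_months, train.event, n_trees=250, min_node_size=5, seed=100
)
prox = ps.inbag_proximity(forest)
dendrogram = ps.ward_agglomerate(ps.proximity_to_dissimilarity(prox))
clusters = ps.cut_dendrogram(dendrogram, k=2)
print(f"cluster sizes: {clusters.sizes()}")
print(f"ARI vs latent groups: "
      f"{adjusted_rand_score(train.latent_group, clusters.labels):.3f}")

ranking = ps.variable_importance_frequency(forest)
assigner = ps.fit_assignment_model(feats, clusters, ranking, top_k=10)
assigned, _ = ps.assign_clusters(assigner, test.features[feats.columns])
chi2, p = ps.logrank_test(assigned.labels, test.time_months, test.event)
print(f"test-set log-rank: chi2={chi2:.1f}, p={p:.2e}")
```

Output:

```
features retained: 300 of 300
cluster sizes: {1: 218, 2: 182}
ARI vs latent groups: 0.846
test-set log-rank: chi2=12.6, p=3.84e-04
```

The two recovered clusters align closely with the generator's latent risk
groups (adjusted Rand index 0.85), split the training cohort roughly
55/45, and the labels propagated to the 100 held-out patients stratify
their survival (log-rank p < 0.001). On this cohort, adding the cluster
label to a clinical-covariate ensemble raises the held-out 5-year AUC from
0.55 to 0.77 (the clinical covariates are pure noise in the generator, so
the clinical-only ensemble hovers near chance).

## Command line

```bash
proxsurv simulate --out data/ --seed 7            # write a synthetic cohort
proxsurv preprocess --features data/features.csv --outcomes data/outcomes.csv --out work/
proxsurv run --config pipeline.yaml --out results/   # full pipeline
proxsurv assign --model results/assignment_model_k2.json --features new_patients.csv
```

A minimal `pipeline.yaml`:

```yaml
simulate: {n_patients: 500, n_features: 300, seed: 0}
covariate_modes: [clinical, clinical+clusters_2]
seed: 11
```

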