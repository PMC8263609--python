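# Methods

## Problem setting

`proxsurv` stratifies patients with right-censored survival outcomes using a
high-dimensional block of continuous tumor-imaging ("radiomic") features
alongside a handful of clinical covariates. The package implements a
supervised dimensionality-reduction idea: instead of selecting individual
radiomic features, it compresses the whole feature block into a single
categorical risk label obtained by clustering patients through the lens of a
random survival forest, and then asks whether that label adds predictive
value over clinical covariates alone.

## Pipeline

1. **Feature reduction.** On training rows only: drop zero-variance columns;
   drop the later member of any pair with |Pearson r| > 0.99 (greedy scan in
   column order, keep-first); drop non-anchor columns with |r| > 0.80 to
   either of two anchor features (a tumor-volume and a global-intensity
   column), keeping the anchors. The thresholds are strict inequalities.
   Test rows are subset to the surviving columns and never inspected.
2. **Clustering forest.** A random survival forest with log-rank splitting
   (1000 trees and minimum node size 5 by library default; desk-scale runs
   use fewer trees, see *Problem sizes*). Each tree is grown on a bootstrap
   sample; at each node `mtry = ceil(sqrt(p))` candidate features are drawn
   and the split maximizes the absolute standardized log-rank statistic over
   midpoints between sorted distinct in-bag values, with both daughters
   required to keep `min_node_size` in-bag samples.
3. **In-bag proximity.** For a pair of training patients, proximity is the
   fraction of trees — among trees where both are in the bootstrap sample —
   in which they share a terminal node. In-bag (rather than out-of-bag)
   proximity is used because the forest serves as a similarity engine here,
   not as a predictive model. The dissimilarity is `D = 1 - P`.
4. **Ward agglomeration.** Hierarchical clustering on the precomputed `D`
   via the Lance–Williams recurrence for Ward's criterion, with recorded
   merge heights equal to the merge cost
   `|c1||c2|/(|c1|+|c2|) * ||mean(c1) - mean(c2)||^2` when `D` entries are
   read as squared distances ("ward.D" dialect, the default; a "ward.D2"
   switch squares the entries first). Ward on a forest dissimilarity is a
   heuristic — the matrix is not Euclidean — but it is well defined, tends
   to produce balanced clusters, and is exactly testable against a
   coordinate-based oracle on Euclidean inputs. The tree is cut at
   k in {2, 3, 4}; clusters are numbered by decreasing size so "cluster 1"
   is stable across reruns.
5. **Test-set assignment.** A multinomial log-linear model (softmax link,
   quasi-Newton on the unpenalized likelihood, max 500 iterations, gradient
   tolerance 1e-6) is trained on the top-10 features ranked by forest split
   frequency, z-scored with training statistics, with the training cluster
   label as response. The multinomial form is kept even for two clusters so
   the same path covers k up to 4. On detected separation or
   non-convergence the model is refit with a light L2 ridge (logged).
   Held-out patients are assigned by probability argmax, ties toward the
   lower cluster index.
6. **Stacked ensemble.** Five base risk models per covariate mode: Cox
   proportional hazards and a random survival forest (both consume the
   censored outcome directly), plus a random-forest classifier, logistic
   regression and logistic elastic net (mixing parameter 0.5, penalty by
   weighted 5-fold CV deviance) trained on the binary 5-year outcome with
   inverse-probability-of-censoring weights; zero-weight patients are
   excluded from the binary learners. Survival-model outputs enter the
   stack as `1 - S_i(60)` so all five columns are horizon event
   probabilities. Stacking weights are learned by weighted non-negative
   least squares (Lawson–Hanson) on 5-fold out-of-fold predictions, with
   censoring weights re-estimated inside each fold's training part, and are
   normalized to sum to one (super-learner convention).
7. **Evaluation.** Harrell's C-index (comparable pairs: earlier observed
   event; tied times with a single event treat the event as earlier; tied
   risks count one half) and the 5-year AUC as an IPCW-weighted
   Mann–Whitney statistic (an unweighted AUC is reported alongside for
   transparency). Cluster stratification is tested with the k-group
   log-rank statistic, and Kaplan–Meier tables per cluster are exported.

## Censoring weights

With `G` the Kaplan–Meier estimate of the censoring survival function
(indicator flipped), a patient contributes at the 60-month horizon as:
label 1 with weight `1/G(T-)` if the event occurred before 60 months
(left limit avoids self-inclusion); label 0 with weight `1/G(60)` if
followed event-free to 60 months; weight exactly 0 if censored event-free
earlier. Weights are capped at 20 to bound the variance from near-zero `G`;
the cap is logged whenever active. Because the synthetic generator uses
exponential survival and censoring, the true horizon event probability has
the closed form `1 - exp(-lambda * HR * 60)` per group, which the
calibration tests compare against the weighted event frequency.

## Synthetic cohort generator

The generator emulates the structure of a mid-size oncology cohort: 500
patients split 80/20, 300 continuous features in equicorrelated blocks of
10 (within-block r = 0.5) mimicking redundant radiomic families, and
clinical covariates (age; HPV, smoking, T/N category, therapy combination,
AJCC stage) drawn with realistic marginal frequencies. Each patient belongs
to one of 2–4 latent risk groups (equiprobable); the group adds
`feature_shift` (default 2) standard deviations per group step to the first
`n_informative` feature columns and multiplies the baseline exponential
hazard (0.002/month) by the group hazard ratio (default 1 vs 3). Random
censoring is exponential (0.012/month) truncated by administrative
censoring at 120 months; these rates are calibrated, via the closed form
`h/(h+c) * (1 - exp(-(h+c)A))`, to an observed event fraction of ~0.20.

`n_informative = 100` of 300 reflects how broadly phenotype structure is
expressed in real radiomic panels: features are massively redundant, and a
risk-relevant phenotype (e.g. tumor volume) co-varies with a large share of
the intensity/texture families rather than with a sparse handful. This
breadth is also what makes the latent groups "well separated" in feature
space: with a sparse informative set (say 30/300), the per-node log-rank
signal available from ~80 training events is too weak for any
outcome-supervised forest to key on the informative columns, and proximity
clustering cannot recover the groups.

What the generator does **not** emulate: covariate-dependent censoring,
clinical covariates that carry prognostic signal (they are independent
noise by default, so "clinical-only" models hover near AUC 0.5; a
confounding knob linking T-category to the latent group exists but is off),
non-proportional hazards, measurement batch effects, or any imaging-level
structure. Passing tests therefore demonstrate the machinery's correctness
and the method's behavior under a favorable, known truth — not performance
on real radiomic data.

The latent group label is carried on the `Cohort` object for evaluation
only; the modelling export schema omits it, so no fitting routine can read
it.

## Numerical and design choices

- **Correlation filters:** Pearson on training rows (the standard choice
  for continuous radiomics); drop iff |r| strictly exceeds the threshold;
  keep-first tie-breaking by column order makes the reduction deterministic
  and idempotent. Order: zero-variance, pairwise, anchor.
- **Forest:** `mtry = ceil(sqrt(p))` by default; candidate thresholds are
  midpoints between sorted distinct in-bag values; split-score ties keep
  the lowest threshold of the earliest candidate feature; all-censored
  nodes become terminal; terminal nodes store a Nelson–Aalen cumulative
  hazard on the forest-wide event-time grid. Per-tree seeds are spawned
  from the forest seed by a counter, so forests are bit-reproducible.
  Presets: clustering forest (min node size 5), feature-selection forest
  (min node size 2); a repeat-and-average utility aggregates split counts
  over repeated fits by their mean.
- **Proximity:** pairs never co-in-bag (probability ~(1 - 0.632^2)^T)
  receive proximity 0 — maximally dissimilar rather than missing — with a
  logged warning.
- **Ward dialects:** whether the forest dissimilarity should enter the
  recurrence raw or squared is not decidable a priori; both are exposed,
  `ward.D` (raw entries treated as squared distances) being the default.
  Merge ties are broken by the smallest cluster-id pair.
- **Scaling:** z-scoring with training means/SDs is applied only to the
  regression-based learners (multinomial assigner, logistic, elastic net,
  coxnet); forests are invariant to monotone transforms and receive raw
  features.
- **Reference levels** for one-hot encoding are fixed (HPV Positive,
  Smoking Never, T1-2, N0-1, therapy CC, Stage I, cluster 1).
- **Coxnet selection:** lasso path (40 penalties down to 1% of the maximal
  one) with the penalty chosen by cross-validated concordance; ties prefer
  the sparser model; an empty selection falls back to clinical-only and is
  logged.
- **Degenerate inputs:** an empty design matrix yields constant marginal
  predictions from every base model; a zero NNLS solution falls back to
  uniform weights; folds whose training part lacks two distinct event
  times trigger a reseeded refold; Cox non-convergence triggers a
  ridge-stabilized refit. All fallbacks log a warning.

## Problem sizes

Library defaults follow the 1000-tree convention for the clustering and
feature-selection forests. The pipeline's default configuration, the test
suite and the acceptance script run at desk scale so a full experiment
completes in minutes on one CPU: 250–300 trees for the clustering forest,
200 trees for the in-ensemble survival forest and 300 for the
random-forest classifier. At 250+ trees the proximity matrix is already
well resolved for n = 400 training patients (pair counts of ~100 trees per
pair); tree counts beyond that mainly polish the dendrogram's lower
levels.

## Known limitations

- With a ~20% event rate, a 100-patient test split carries only ~18
  events. The log-rank test on assigned test clusters then has limited
  power, and its p-value varies widely across cohort draws (from ~1e-4 to
  ~0.1 under identical generator settings). Training-set stratification is
  essentially always highly significant; the test-set p-value should be
  read with its event count in mind.
- On occasional cohort draws the k = 2 dendrogram's top split separates a
  structure other than the latent groups (the groups then emerge at
  k = 3). This mirrors the general instability of choosing k; the package
  deliberately offers k in {2, 3, 4} and no automatic selection.
- Ward on a non-Euclidean forest dissimilarity has no variance
  interpretation; it is used as a robust, deterministic agglomeration
  heuristic.
- The binary 5-year cluster label has a ceiling on achievable AUC (a
  two-level predictor cannot rank within groups); gains over clinical-only
  covariates reflect the label capturing the latent hazard structure, not
  a universally optimal risk score.
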