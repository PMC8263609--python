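"""Synthetic cohorts with latent risk groups, radiomic-style features and
right-censored follow-up.

The generator emulates the structure of a single-institution head-and-neck
cancer cohort: ~500 patients, a few hundred continuous tumor-imaging
("radiomic") features organised in redundant correlated families, a small set
of clinical covariates, and an overall-survival-like outcome with roughly 20%
observed events under random plus administrative censoring.

Latent structure
----------------
Each patient belongs to one of ``n_latent_groups`` hidden risk groups.  The
group shifts the mean of the first ``n_informative`` feature columns (by
``feature_shift`` standard deviations per group step) and multiplies the
baseline exponential hazard by the group's hazard ratio.  Survival and
censoring times are exponential, so horizon event probabilities have closed
forms: ``P(T <= h) = 1 - exp(-lambda * HR * h)`` before censoring, which is
what the censoring-weight calibration tests lean on.

The latent group is carried on the :class:`Cohort` for evaluation but is
deliberately excluded from every exported modelling table.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "sample_clinical_categories",
    "split_cohort",
    "feature_names",
    "write_cohort",
    "read_cohort",
]

# Marginal frequencies of the clinical covariates in the emulated training
# cohort (fractions; renormalised at sampling time).
CLINICAL_FREQUENCIES: dict[str, dict[str, float]] = {
    "sex": {"Male": 0.878, "Female": 0.122},
    "hpv_status": {"Positive": 0.61, "Negative": 0.09, "Unknown": 0.29},
    "smoking_status": {"Former": 0.358, "Current": 0.208, "Never": 0.434},
    "t_category": {"T1-2": 0.627, "T3-4": 0.373},
    "n_category": {"N0-1": 0.511, "N2-3": 0.489},
    "therapeutic_combination": {"CC": 0.516, "IC+CC": 0.269, "IC+RT": 0.100, "RT": 0.115},
    "ajcc_stage": {"I": 0.346, "II": 0.186, "III": 0.129, "IV": 0.339},
}

# Age: normal truncated to [25, 90], located to match a median near 58 with
# inter-quartile range (52.5, 65.8).
AGE_LOC = 58.2
AGE_SCALE = 9.86
AGE_BOUNDS = (25.0, 90.0)

# Radiomic family stems used to build feature names; positions 4 and 8 are
# chosen so that columns 25 and 29 (1-based) carry the conventional volume
# and global-mean anchor names used by the anchor-correlation filter.
_FEATURE_STEMS = [
    "IntensityDirectLocalRangeMax",
    "IntensityDirectKurtosis",
    "IntensityDirectSkewness",
    "IntensityDirectGlobalMax",
    "ShapeVolume",
    "GrayLevelCooccurenceMatrix25.Contrast",
    "GrayLevelCooccurenceMatrix25.ClusterProminence",
    "GrayLevelRunLengthMatrix25.ShortRunEmphasis",
    "IntensityDirectGlobalMean",
    "GrayLevelRunLengthMatrix25.RunLengthNonuniformity",
]

ANCHOR_FEATURES = ("F25.ShapeVolume", "F29.IntensityDirectGlobalMean")

BLOCK_SIZE = 10  # equicorrelated feature family size


def feature_names(n_features: int) -> list[str]:
    """Radiomic-style names ``F<i>.<family>`` for ``n_features`` columns."""
    return [f"F{i + 1}.{_FEATURE_STEMS[i % len(_FEATURE_STEMS)]}" for i in range(n_features)]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are calibrated so that, at ``n_patients=500``, the marginal
    observed event fraction is approximately 0.20 (closed form:
    ``h/(h+c) * (1 - exp(-(h+c) * A))`` per group with ``h = baseline *
    HR``, ``c = censor_rate``, ``A = admin_censor_months``).
    """

    n_patients: int = 500
    n_features: int = 300
    n_latent_groups: int = 2
    feature_shift: float = 2.0
    n_informative: int = 100
    block_correlation: float = 0.5
    baseline_hazard: float = 0.002  # events per month in the reference group
    group_hazard_ratios: tuple[float, ...] = (1.0, 3.0)
    censor_rate: float = 0.012  # random-censoring rate per month
    admin_censor_months: float = 120.0
    train_fraction: float = 0.8
    confound_t_category: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_features <= 0:
            raise ValueError("n_patients and n_features must be positive")
        if self.n_latent_groups not in (2, 3, 4):
            raise ValueError("n_latent_groups must be in {2, 3, 4}")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must not exceed n_features")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must be in [0, 1)")
        if self.feature_shift < 0:
            raise ValueError("feature_shift must be non-negative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if self.admin_censor_months <= 0:
            raise ValueError("admin_censor_months must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        hrs = tuple(float(h) for h in self.group_hazard_ratios)
        object.__setattr__(self, "group_hazard_ratios", hrs)
        if len(hrs) != self.n_latent_groups:
            raise ValueError("group_hazard_ratios must have one entry per latent group")
        if any(h <= 0 for h in hrs):
            raise ValueError("hazard ratios must be positive")
        if not math.isclose(hrs[0], 1.0):
            raise ValueError("first hazard ratio is the reference group and must be 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_hazard_ratios"] = list(d["group_hazard_ratios"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "group_hazard_ratios" in d:
            d["group_hazard_ratios"] = tuple(d["group_hazard_ratios"])
        return cls(**d)


@dataclass
class Cohort:
    """A simulated patient cohort.

    ``latent_group`` is simulation ground truth; :meth:`modelling_frames`
    never exposes it, so downstream fitting code cannot read it by accident.
    """

    patient_ids: list[str]
    features: pd.DataFrame
    clinical: pd.DataFrame
    time_months: pd.Series
    event: pd.Series
    split: pd.Series
    latent_group: pd.Series | None = None
    config: CohortConfig | None = None

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise ValueError("features contain missing values")
        if (self.time_months <= 0).any():
            raise ValueError("time_months must be strictly positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event must be 0/1")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def train_mask(self) -> pd.Series:
        return self.split == "train"

    def subset(self, which: str) -> "Cohort":
        """Return the ``'train'`` or ``'test'`` portion of the cohort."""
        m = (self.split == which).to_numpy()
        ids = [p for p, keep in zip(self.patient_ids, m) if keep]
        return Cohort(
            patient_ids=ids,
            features=self.features.loc[m],
            clinical=self.clinical.loc[m],
            time_months=self.time_months.loc[m],
            event=self.event.loc[m],
            split=self.split.loc[m],
            latent_group=None if self.latent_group is None else self.latent_group.loc[m],
            config=self.config,
        )

    def modelling_frames(self) -> dict[str, pd.DataFrame | pd.Series]:
        """Tables visible to models: features, clinical, outcomes, split."""
        return {
            "features": self.features,
            "clinical": self.clinical,
            "time_months": self.time_months,
            "event": self.event,
            "split": self.split,
        }

    def outcomes_frame(self, include_latent: bool = False) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "time_months": self.time_months.to_numpy(),
                "event": self.event.to_numpy(),
                "split": self.split.to_numpy(),
            }
        ).set_index("patient_id")
        if include_latent and self.latent_group is not None:
            out["latent_group"] = self.latent_group.to_numpy()
        return out


def sample_clinical_categories(n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` clinical rows with the cohort's marginal frequencies.

    Categories are sampled independently per column; age comes from a
    truncated normal on [25, 90] years.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    a, b = (AGE_BOUNDS[0] - AGE_LOC) / AGE_SCALE, (AGE_BOUNDS[1] - AGE_LOC) / AGE_SCALE
    cols["age"] = stats.truncnorm.rvs(
        a, b, loc=AGE_LOC, scale=AGE_SCALE, size=n, random_state=rng
    ).round(1)
    for name, freq in CLINICAL_FREQUENCIES.items():
        levels = list(freq)
        p = np.array([freq[lv] for lv in levels], dtype=float)
        p /= p.sum()
        cols[name] = rng.choice(levels, size=n, p=p)
    return pd.DataFrame(cols)


def _split_labels(n: int, train_fraction: float, seed: int) -> np.ndarray:
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1) if n > 1 else n_train
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.full(n, "test", dtype=object)
    labels[perm[:n_train]] = "train"
    return labels


def split_cohort(cohort: Cohort, train_fraction: float, seed: int) -> Cohort:
    """Assign a random disjoint train/test split, reproducible from ``seed``."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if cohort.n_patients == 0:
        raise ValueError("cannot split an empty cohort")
    labels = _split_labels(cohort.n_patients, train_fraction, seed)
    new = dataclasses.replace(cohort)
    new.split = pd.Series(labels, index=cohort.features.index, name="split")
    return new


def generate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a cohort under ``config``; deterministic given ``config.seed``."""
    n, p = config.n_patients, config.n_features
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_group = np.random.default_rng(streams[0])
    rng_feat = np.random.default_rng(streams[1])
    rng_surv = np.random.default_rng(streams[2])
    rng_cens = np.random.default_rng(streams[3])
    seed_clin = int(streams[4].generate_state(1)[0] % (2**31))
    seed_split = int(streams[5].generate_state(1)[0] % (2**31))

    group = rng_group.integers(1, config.n_latent_groups + 1, size=n)

    # Block-equicorrelated Gaussian features: shared factor per 10-column
    # family plus independent noise, unit marginal variance.
    rho = config.block_correlation
    n_blocks = math.ceil(p / BLOCK_SIZE)
    factors = rng_feat.standard_normal((n, n_blocks))
    noise = rng_feat.standard_normal((n, p))
    block_of = np.arange(p) // BLOCK_SIZE
    X = math.sqrt(rho) * factors[:, block_of] + math.sqrt(1.0 - rho) * noise
    if config.n_informative > 0 and config.feature_shift > 0:
        X[:, : config.n_informative] += config.feature_shift * (group - 1)[:, None]

    hr = np.asarray(config.group_hazard_ratios)[group - 1]
    hazard = config.baseline_hazard * hr
    t_event = rng_surv.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        t_cens = rng_cens.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.admin_censor_months)
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-6)  # guard strictly-positive invariant

    clinical = sample_clinical_categories(n, seed_clin)
    if config.confound_t_category:
        # optional confounding knob: higher-risk groups skew toward T3-4
        p_t34 = np.clip(0.2 + 0.3 * (group - 1), 0.0, 0.95)
        draw = np.random.default_rng(streams[4]).random(n)
        clinical["t_category"] = np.where(draw < p_t34, "T3-4", "T1-2")

    ids = [f"P{i + 1:04d}" for i in range(n)]
    idx = pd.Index(ids, name="patient_id")
    clinical.index = idx
    cohort = Cohort(
        patient_ids=ids,
        features=pd.DataFrame(X, index=idx, columns=feature_names(p)),
        clinical=clinical,
        time_months=pd.Series(time, index=idx, name="time_months"),
        event=pd.Series(event, index=idx, name="event"),
        split=pd.Series("train", index=idx, name="split"),
        latent_group=pd.Series(group, index=idx, name="latent_group"),
        config=config,
    )
    return split_cohort(cohort, config.train_fraction, seed_split)


def horizon_event_probability(config: CohortConfig, horizon_months: float = 60.0) -> float:
    """Closed-form marginal ``P(T <= horizon)`` before censoring (groups equiprobable)."""
    probs = [
        1.0 - math.exp(-config.baseline_hazard * hr * horizon_months)
        for hr in config.group_hazard_ratios
    ]
    return float(np.mean(probs))


def expected_event_fraction(config: CohortConfig) -> float:
    """Closed-form marginal probability that the event is observed."""
    c, a = config.censor_rate, config.admin_censor_months
    vals = []
    for hr in config.group_hazard_ratios:
        h = config.baseline_hazard * hr
        vals.append(h / (h + c) * (1.0 - math.exp(-(h + c) * a)))
    return float(np.mean(vals))


def write_cohort(cohort: Cohort, out_dir: str | Path, include_latent: bool = False) -> None:
    """Write features.csv, clinical.csv, outcomes.csv and a config sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.features.to_csv(out / "features.csv")
    cohort.clinical.to_csv(out / "clinical.csv")
    cohort.outcomes_frame(include_latent=include_latent).to_csv(out / "outcomes.csv")
    sidecar = {"config": None if cohort.config is None else cohort.config.to_dict()}
    (out / "cohort_config.json").write_text(json.dumps(sidecar, indent=2))


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    d = Path(in_dir)
    features = pd.read_csv(d / "features.csv", index_col="patient_id")
    clinical = pd.read_csv(d / "clinical.csv", index_col="patient_id")
    outcomes = pd.read_csv(d / "outcomes.csv", index_col="patient_id")
    config = None
    sidecar = d / "cohort_config.json"
    if sidecar.exists():
        raw = json.loads(sidecar.read_text()).get("config")
        if raw is not None:
            config = CohortConfig.from_dict(raw)
    latent = None
    if "latent_group" in outcomes.columns:
        latent = outcomes["latent_group"]
    return Cohort(
        patient_ids=list(features.index),
        features=features,
        clinical=clinical,
        time_months=outcomes["time_months"],
        event=outcomes["event"].astype(int),
        split=outcomes["split"],
        latent_group=latent,
        config=config,
    )
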