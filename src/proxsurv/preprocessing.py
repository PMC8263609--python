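"""Feature-reduction filters and clinical covariate encoding.

The radiomic feature table is reduced in three train-statistics-only steps,
in this order: drop zero-variance columns, drop the later member of any pair
with absolute Pearson correlation above 0.99, then drop non-anchor columns
correlated above 0.80 with either of two anchor features (a tumor-volume and
a global-intensity column).  All correlations are computed on training rows
only; test rows are subset to the surviving columns, never inspected.

Thresholds are strict: a column is dropped iff |r| > threshold.  Pair
scanning is greedy in column order, keeping the earlier column, which makes
the result deterministic and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "drop_zero_variance",
    "drop_pairwise_correlated",
    "drop_anchor_correlated",
    "filter_features",
    "categorize_clinical",
    "encode_design",
    "Scaler",
]

PAIRWISE_THRESHOLD = 0.99
ANCHOR_THRESHOLD = 0.80

# One-hot reference levels, fixed for reproducibility.
REFERENCE_LEVELS = {
    "hpv_status": "Positive",
    "smoking_status": "Never",
    "t_category": "T1-2",
    "n_category": "N0-1",
    "therapeutic_combination": "CC",
    "ajcc_stage": "I",
    "sex": "Male",
    "cluster": "1",
}

_T_MAP = {"T1": "T1-2", "T2": "T1-2", "T3": "T3-4", "T4": "T3-4", "T1-2": "T1-2", "T3-4": "T3-4"}
_N_MAP = {"N0": "N0-1", "N1": "N0-1", "N2": "N2-3", "N3": "N2-3", "N0-1": "N0-1", "N2-3": "N2-3"}


@dataclass
class FilterReport:
    """Audit trail of the feature filters."""

    n_input: int
    dropped_zero_variance: list[str] = field(default_factory=list)
    dropped_pairwise: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_anchor: list[tuple[str, str, float]] = field(default_factory=list)
    n_output: int = 0

    def validate(self) -> None:
        dropped = (
            list(self.dropped_zero_variance)
            + [d for _, d, _ in self.dropped_pairwise]
            + [d for _, d, _ in self.dropped_anchor]
        )
        if len(set(dropped)) != len(dropped):
            raise ValueError("a feature appears in two drop lists")
        if self.n_output != self.n_input - len(dropped):
            raise ValueError("FilterReport counts are inconsistent")

    def merged_with(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            n_input=self.n_input,
            dropped_zero_variance=self.dropped_zero_variance + other.dropped_zero_variance,
            dropped_pairwise=self.dropped_pairwise + other.dropped_pairwise,
            dropped_anchor=self.dropped_anchor + other.dropped_anchor,
            n_output=other.n_output,
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "dropped_zero_variance": list(self.dropped_zero_variance),
            "dropped_pairwise": [[k, d, float(r)] for k, d, r in self.dropped_pairwise],
            "dropped_anchor": [[a, d, float(r)] for a, d, r in self.dropped_anchor],
            "n_output": self.n_output,
        }


def _as_mask(train_mask, index) -> np.ndarray:
    m = np.asarray(pd.Series(train_mask).to_numpy() if not isinstance(train_mask, np.ndarray) else train_mask)
    if m.dtype != bool:
        m = m.astype(bool)
    if m.shape[0] != len(index):
        raise ValueError("train_mask length does not match number of rows")
    return m


def drop_zero_variance(features: pd.DataFrame, train_mask) -> tuple[pd.DataFrame, FilterReport]:
    """Remove columns constant on the training rows."""
    m = _as_mask(train_mask, features.index)
    if m.sum() < 2:
        raise ValueError("need at least 2 training rows")
    train = features.loc[m]
    var = train.to_numpy(dtype=float).var(axis=0)
    drop = [c for c, v in zip(features.columns, var) if v == 0.0]
    kept = features.drop(columns=drop)
    if kept.shape[1] == 0:
        raise ValueError("zero-variance filter dropped every column")
    rep = FilterReport(n_input=features.shape[1], dropped_zero_variance=drop, n_output=kept.shape[1])
    rep.validate()
    return kept, rep


def _train_corr(features: pd.DataFrame, m: np.ndarray) -> np.ndarray:
    x = features.loc[m].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    if not np.isfinite(r).all():
        raise ValueError("non-finite correlation encountered; run the zero-variance filter first")
    return r


def drop_pairwise_correlated(
    features: pd.DataFrame, train_mask, threshold: float = PAIRWISE_THRESHOLD
) -> tuple[pd.DataFrame, FilterReport]:
    """Greedy keep-first scan: drop the later column of any pair with |r| > threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    m = _as_mask(train_mask, features.index)
    r = np.abs(_train_corr(features, m))
    cols = list(features.columns)
    kept_idx: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(len(cols)):
        offender = next((k for k in kept_idx if r[k, j] > threshold), None)
        if offender is None:
            kept_idx.append(j)
        else:
            dropped.append((cols[offender], cols[j], float(r[offender, j])))
    kept = features.iloc[:, kept_idx]
    rep = FilterReport(n_input=features.shape[1], dropped_pairwise=dropped, n_output=kept.shape[1])
    rep.validate()
    return kept, rep


def drop_anchor_correlated(
    features: pd.DataFrame,
    train_mask,
    anchors: list[str],
    threshold: float = ANCHOR_THRESHOLD,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop non-anchor columns with |r| > threshold to any anchor; keep anchors."""
    missing = [a for a in anchors if a not in features.columns]
    if missing:
        raise ValueError(f"anchor feature(s) not present: {missing}")
    m = _as_mask(train_mask, features.index)
    r = np.abs(_train_corr(features, m))
    cols = list(features.columns)
    anchor_idx = [cols.index(a) for a in anchors]
    dropped: list[tuple[str, str, float]] = []
    keep: list[int] = []
    for j in range(len(cols)):
        if j in anchor_idx:
            keep.append(j)
            continue
        hit = next((a for a in anchor_idx if r[a, j] > threshold), None)
        if hit is None:
            keep.append(j)
        else:
            dropped.append((cols[hit], cols[j], float(r[hit, j])))
    kept = features.iloc[:, keep]
    rep = FilterReport(n_input=features.shape[1], dropped_anchor=dropped, n_output=kept.shape[1])
    rep.validate()
    return kept, rep


def filter_features(
    features: pd.DataFrame,
    train_mask,
    anchors: list[str] | None = None,
    pairwise_threshold: float = PAIRWISE_THRESHOLD,
    anchor_threshold: float = ANCHOR_THRESHOLD,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full reduction: zero variance -> pairwise 0.99 -> anchor 0.80.

    Anchors missing from the table (e.g. already removed as duplicates) are
    silently skipped when ``anchors`` is None-like default usage; an explicit
    list with a missing name still raises via :func:`drop_anchor_correlated`.
    """
    x1, r1 = drop_zero_variance(features, train_mask)
    x2, r2 = drop_pairwise_correlated(x1, train_mask, pairwise_threshold)
    report = r1.merged_with(r2)
    if anchors:
        present = [a for a in anchors if a in x2.columns]
        if present:
            x3, r3 = drop_anchor_correlated(x2, train_mask, present, anchor_threshold)
            report = report.merged_with(r3)
            x2 = x3
    report.validate()
    return x2, report


def categorize_clinical(raw_clinical: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw staging categories into the binary groups used downstream.

    T1..T4 -> {T1-2, T3-4}; N0..N3 -> {N0-1, N2-3}.  HPV ``Unknown`` is kept
    as its own level, never imputed.  Already-grouped values pass through.
    """
    out = raw_clinical.copy()
    for col, mapping in (("t_category", _T_MAP), ("n_category", _N_MAP)):
        if col in out.columns:
            vals = out[col].astype(str)
            bad = sorted(set(vals) - set(mapping))
            if bad:
                raise ValueError(f"unknown {col} value(s): {bad}")
            out[col] = vals.map(mapping)
    for col, freq in (
        ("hpv_status", ("Positive", "Negative", "Unknown")),
        ("smoking_status", ("Current", "Former", "Never")),
    ):
        if col in out.columns:
            bad = sorted(set(out[col].astype(str)) - set(freq))
            if bad:
                raise ValueError(f"unknown {col} value(s): {bad}")
    return out


def encode_design(
    clinical: pd.DataFrame,
    columns: list[str] | None = None,
    extra_numeric: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One-hot encode categoricals with declared reference levels.

    ``columns`` selects clinical covariates (default: all present).
    ``extra_numeric`` columns (e.g. selected radiomic features) are appended
    unchanged.  The cluster label, if present as a ``cluster`` column, is
    treated as categorical with cluster 1 as reference.
    """
    cols = list(clinical.columns) if columns is None else list(columns)
    parts: list[pd.DataFrame] = []
    for col in cols:
        if col not in clinical.columns:
            raise ValueError(f"clinical column missing: {col}")
        series = clinical[col]
        if pd.api.types.is_numeric_dtype(series) and col != "cluster":
            parts.append(series.to_frame(col).astype(float))
            continue
        vals = series.astype(str)
        ref = REFERENCE_LEVELS.get(col)
        levels = sorted(vals.unique())
        if ref in levels:
            levels = [ref] + [lv for lv in levels if lv != ref]
        for lv in levels[1:]:
            parts.append((vals == lv).astype(float).to_frame(f"{col}[{lv}]"))
    if extra_numeric is not None:
        parts.append(extra_numeric.astype(float))
    if not parts:
        return pd.DataFrame(index=clinical.index)
    out = pd.concat(parts, axis=1)
    out.index = clinical.index
    return out


@dataclass
class Scaler:
    """Train-statistics z-scaler for regression-based models."""

    mean: pd.Series
    std: pd.Series

    @classmethod
    def fit(cls, x: pd.DataFrame) -> "Scaler":
        mean = x.mean(axis=0)
        std = x.std(axis=0, ddof=0).replace(0.0, 1.0)
        return cls(mean=mean, std=std)

    def transform(self, x: pd.DataFrame) -> pd.DataFrame:
        return (x[self.mean.index] - self.mean) / self.std

    def to_dict(self) -> dict:
        return {"mean": self.mean.to_dict(), "std": self.std.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(mean=pd.Series(d["mean"]), std=pd.Series(d["std"]))
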