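"""Feature filters (train-statistics only) and clinical categorization."""

import numpy as np
import pandas as pd
import pytest

from proxsurv.preprocessing import (
    Scaler,
    categorize_clinical,
    drop_anchor_correlated,
    drop_pairwise_correlated,
    drop_zero_variance,
    encode_design,
    filter_features,
)


def _frame(arr, names=None):
    arr = np.asarray(arr, dtype=float)
    names = names or [f"f{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=names)


def test_constant_column_dropped(rng):
    x = _frame(np.column_stack([rng.normal(size=30), np.full(30, 3.0)]))
    kept, rep = drop_zero_variance(x, np.ones(30, bool))
    assert rep.dropped_zero_variance == ["f1"]
    assert list(kept.columns) == ["f0"]


def test_no_constant_no_drops(rng):
    x = _frame(rng.normal(size=(20, 5)))
    kept, rep = drop_zero_variance(x, np.ones(20, bool))
    assert rep.dropped_zero_variance == [] and kept.shape[1] == 5


def test_zero_variance_uses_train_rows_only(rng):
    """A column constant on train but varying on test must still be dropped."""
    col = np.concatenate([np.full(15, 1.0), rng.normal(size=5)])
    x = _frame(np.column_stack([rng.normal(size=20), col]))
    mask = np.array([True] * 15 + [False] * 5)
    kept, rep = drop_zero_variance(x, mask)
    assert rep.dropped_zero_variance == ["f1"]
    assert kept.shape[0] == 20  # test rows retained, columns aligned


def test_duplicate_column_later_copy_dropped(rng):
    a = rng.normal(size=40)
    x = _frame(np.column_stack([a, rng.normal(size=40), a]))
    kept, rep = drop_pairwise_correlated(x, np.ones(40, bool))
    assert [d for _, d, _ in rep.dropped_pairwise] == ["f2"]
    assert "f0" in kept.columns


def test_three_mutual_duplicates_keep_first(rng):
    a = rng.normal(size=25)
    x = _frame(np.column_stack([a, a, a]))
    kept, rep = drop_pairwise_correlated(x, np.ones(25, bool))
    assert list(kept.columns) == ["f0"]
    assert sorted(d for _, d, _ in rep.dropped_pairwise) == ["f1", "f2"]


def test_independent_gaussians_kept(rng):
    x = _frame(rng.normal(size=(1000, 2)))
    kept, _ = drop_pairwise_correlated(x, np.ones(1000, bool))
    assert kept.shape[1] == 2


def test_anchor_multiple_of_anchor_dropped(rng):
    a = rng.normal(size=50)
    x = _frame(np.column_stack([a, 2 * a, rng.normal(size=50)]), ["anchor", "double", "noise"])
    kept, rep = drop_anchor_correlated(x, np.ones(50, bool), anchors=["anchor"])
    assert [d for _, d, _ in rep.dropped_anchor] == ["double"]
    assert "anchor" in kept.columns and "noise" in kept.columns


def test_correlated_anchors_mutually_retained(rng):
    a = rng.normal(size=50)
    x = _frame(np.column_stack([a, a + 0.01 * rng.normal(size=50)]), ["a1", "a2"])
    kept, _ = drop_anchor_correlated(x, np.ones(50, bool), anchors=["a1", "a2"])
    assert list(kept.columns) == ["a1", "a2"]


def test_shared_factor_block_dropped_by_anchor(rng):
    """10 columns built from a shared factor at r ~ 0.9 to the anchor all go."""
    n = 2000
    factor = rng.normal(size=n)
    anchor = factor + 0.1 * rng.normal(size=n)
    block = factor[:, None] + 0.45 * rng.normal(size=(n, 10))
    x = _frame(np.column_stack([anchor, block]), ["anchor"] + [f"b{i}" for i in range(10)])
    corr = [abs(np.corrcoef(anchor, block[:, i])[0, 1]) for i in range(10)]
    assert min(corr) > 0.80  # construction check
    kept, rep = drop_anchor_correlated(x, np.ones(n, bool), anchors=["anchor"])
    assert len(rep.dropped_anchor) == 10
    assert list(kept.columns) == ["anchor"]


def test_missing_anchor_raises(rng):
    x = _frame(rng.normal(size=(10, 2)))
    with pytest.raises(ValueError, match="nope"):
        drop_anchor_correlated(x, np.ones(10, bool), anchors=["nope"])


def test_filter_pipeline_idempotent_and_train_test_aligned(rng):
    n = 60
    a = rng.normal(size=n)
    x = _frame(np.column_stack([a, a, np.full(n, 2.0), rng.normal(size=n)]))
    mask = np.array([True] * 40 + [False] * 20)
    kept, rep = filter_features(x, mask)
    again, rep2 = filter_features(kept, mask)
    assert list(again.columns) == list(kept.columns)
    assert rep2.n_input == rep2.n_output
    assert kept.shape[0] == n


def test_equicorrelated_blocks_collapse(rng):
    """Blocks at r = 0.995 collapse to one representative each (pairwise 0.99)."""
    n, n_blocks = 4000, 3
    cols = []
    for _ in range(n_blocks):
        z = rng.normal(size=n)
        for _ in range(10):
            cols.append(np.sqrt(0.995) * z + np.sqrt(0.005) * rng.normal(size=n))
    x = _frame(np.column_stack(cols))
    kept, rep = drop_pairwise_correlated(x, np.ones(n, bool))
    # oracle: exhaustive pairwise check on the survivors
    r = np.abs(np.corrcoef(kept.to_numpy(), rowvar=False))
    np.fill_diagonal(r, 0.0)
    assert r.max() <= 0.99
    assert kept.shape[1] == n_blocks


def test_categorize_t_and_n():
    raw = pd.DataFrame(
        {"t_category": ["T1", "T2", "T3", "T4"], "n_category": ["N0", "N1", "N2", "N3"]}
    )
    out = categorize_clinical(raw)
    assert list(out["t_category"]) == ["T1-2", "T1-2", "T3-4", "T3-4"]
    assert list(out["n_category"]) == ["N0-1", "N0-1", "N2-3", "N2-3"]


def test_categorize_unknown_value_raises():
    with pytest.raises(ValueError, match="T9"):
        categorize_clinical(pd.DataFrame({"t_category": ["T9"]}))


def test_hpv_unknown_is_a_level_not_imputed():
    raw = pd.DataFrame({"hpv_status": ["Positive", "Unknown", "Negative"]})
    out = categorize_clinical(raw)
    assert list(out["hpv_status"]) == ["Positive", "Unknown", "Negative"]
    design = encode_design(out, ["hpv_status"])
    assert "hpv_status[Unknown]" in design.columns
    assert "hpv_status[Positive]" not in design.columns  # reference level


def test_encode_design_reference_levels_and_numeric_passthrough():
    clin = pd.DataFrame(
        {
            "age": [50.0, 60.0],
            "t_category": ["T1-2", "T3-4"],
            "cluster": ["1", "2"],
        }
    )
    d = encode_design(clin, ["age", "t_category", "cluster"])
    assert list(d.columns) == ["age", "t_category[T3-4]", "cluster[2]"]
    assert d["cluster[2]"].tolist() == [0.0, 1.0]


def test_scaler_roundtrip(rng):
    x = pd.DataFrame(rng.normal(5, 3, size=(50, 3)), columns=list("abc"))
    s = Scaler.fit(x)
    z = s.transform(x)
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-12)
    s2 = Scaler.from_dict(s.to_dict())
    pd.testing.assert_frame_equal(s.transform(x), s2.transform(x))
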