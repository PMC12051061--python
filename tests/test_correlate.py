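"""Correlation engine: filtering, imputation, segment enumeration, the
normality gate, retention, top-rank refinement and pipeline bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import sensomics as sm
from sensomics.correlate import (
    CorrelationConfig,
    FeatureTable,
    Segment,
    correlate_segment,
    enumerate_segments,
    filter_features,
    impute_half_min,
    refine_top_rank,
    retain,
    run_correlation,
)


def _ft(matrix, fractions=None):
    matrix = np.asarray(matrix, dtype=float)
    fracs = fractions or [f"F{j + 1:02d}" for j in range(matrix.shape[1])]
    ids = [f"M{i + 1:03d}" for i in range(matrix.shape[0])]
    feats = pd.DataFrame(
        {"mz": 100.0 + np.arange(len(ids)), "rt": 1.0, "annotation": ""},
        index=pd.Index(ids, name="feature_id"),
    )
    return FeatureTable(feats, pd.DataFrame(matrix, index=feats.index, columns=fracs))


# --- filtering and imputation ---------------------------------------------


def test_filter_detection_boundary():
    nan = np.nan
    ft = _ft(
        [
            [1, 2, 3, 4, nan, nan, nan, nan],  # 4 observed -> dropped
            [1, 2, 3, 4, 5, nan, nan, nan],  # 5 observed -> kept
        ]
    )
    kept = filter_features(ft, min_fractions=5)
    assert list(kept.features.index) == ["M002"]


def test_filter_empty_table():
    ft = _ft(np.empty((0, 6)))
    assert filter_features(ft).n_features == 0


def test_impute_half_of_feature_minimum():
    ft = _ft([[10, 4, np.nan]])
    out = impute_half_min(ft)
    np.testing.assert_allclose(out.intensities.iloc[0], [10, 4, 2])


def test_impute_identity_without_missing():
    ft = _ft([[3, 2, 1]])
    assert impute_half_min(ft).intensities.equals(ft.intensities)


def test_impute_below_observed_minimum_property(rng):
    x = rng.uniform(1, 100, size=(10, 12))
    mask = rng.random((10, 12)) < 0.3
    x[mask] = np.nan
    x[:, 0] = rng.uniform(1, 100, 10)  # at least one observed per feature
    ft = _ft(x)
    out = impute_half_min(ft)
    for i in range(10):
        observed = ft.intensities.iloc[i].dropna()
        filled = out.intensities.iloc[i][ft.intensities.iloc[i].isna()]
        assert (filled < observed.min()).all()


def test_impute_all_missing_feature_errors():
    ft = _ft([[np.nan, np.nan, np.nan]])
    with pytest.raises(ValueError):
        impute_half_min(ft)


def test_impute_global_mode():
    ft = _ft([[10, np.nan], [4, np.nan]])
    out = impute_half_min(ft, mode="global")
    np.testing.assert_allclose(out.intensities.to_numpy(), [[10, 2], [4, 2]])


# --- segments --------------------------------------------------------------


@pytest.mark.parametrize("n,expected", [(5, 1), (10, 20), (53, 235), (4, 0)])
def test_segment_counts(n, expected):
    assert len(enumerate_segments(n)) == expected


@given(hst.integers(5, 80))
@settings(max_examples=40, deadline=None)
def test_segment_count_formula(n):
    segs = enumerate_segments(n)
    assert len(segs) == sum(max(0, n - length + 1) for length in range(5, 10))
    assert len(set(segs)) == len(segs)
    assert all(5 <= s.length <= 9 and s.end < n for s in segs)


# --- the normality gate ----------------------------------------------------


def test_gate_normal_pair_uses_pearson(rng):
    x = np.array([10.0, 12.0, 11.5, 13.0, 12.5, 14.0, 13.5, 15.0, 14.5])
    y = 2 * x + rng.normal(0, 0.3, 9)
    rec = correlate_segment(x, y, Segment(0, 8))
    assert rec.method == "pearson"
    assert rec.coefficient > 0.9


def test_gate_skewed_intensities_use_kendall():
    x = np.array([1.0, 1.1, 1.05, 1.2, 500.0, 1.15, 1.08, 1.12, 1.03])
    y = np.arange(9.0)
    rec = correlate_segment(x, y, Segment(0, 8))
    assert rec.method == "kendall"


def test_gate_constant_vector_skipped():
    rec = correlate_segment(np.ones(9), np.arange(9.0), Segment(0, 8))
    assert rec is None


def test_gate_both_mode_requires_both_non_normal(rng):
    x = np.array([1.0, 1.1, 1.05, 1.2, 500.0, 1.15, 1.08, 1.12, 1.03])
    y = rng.normal(10, 1, 9)
    either = correlate_segment(x, y, Segment(0, 8), gate_mode="either")
    both = correlate_segment(x, y, Segment(0, 8), gate_mode="both")
    assert either.method == "kendall"
    assert both.method == "pearson"


def test_monotone_association_sign_preserved_across_methods():
    x = np.exp(np.linspace(0, 4, 9))
    y = np.log(x + 1.0)
    k = correlate_segment(x, y, Segment(0, 8), gate_mode="either")
    p = correlate_segment(x, y, Segment(0, 8), gate_mode="both")
    assert np.sign(k.coefficient) == np.sign(p.coefficient) == 1.0


# --- retention and refinement ---------------------------------------------


def _records_df(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "category", "seg_start", "seg_end", "length",
            "method", "coefficient", "p_raw", "p_adj", "retained",
            "refined", "n_observed",
        ],
    )


def test_retain_truth_table():
    rows = [
        ("M1", "c", 0, 4, 5, "pearson", 0.97, 0.001, 0.01, False, False, 5),
        ("M1", "c", 1, 5, 5, "pearson", 0.90, 0.001, 0.01, False, False, 5),
        ("M1", "c", 2, 6, 5, "pearson", 0.99, 0.02, 0.06, False, False, 5),
        ("M1", "c", 3, 7, 5, "pearson", -0.99, 0.0001, 0.001, False, False, 5),
    ]
    out = retain(_records_df(rows))
    assert list(out["retained"]) == [True, False, False, False]
    unsigned = retain(_records_df(rows), signed=False)
    assert list(unsigned["retained"]) == [True, False, False, True]
    raw = retain(_records_df(rows), use_adjusted=False)
    assert list(raw["retained"]) == [True, False, True, False]


def test_refine_requires_four_top_fractions_inside_segment():
    # feature peaking in fractions 5..9 (0-based 4..8)
    x = np.array([[1, 2, 3, 4, 50, 60, 70, 80, 90, 4, 3, 2]], dtype=float)
    ft = impute_half_min(_ft(x))
    rows = [
        ("M001", "c", 3, 9, 7, "pearson", 0.99, 1e-6, 1e-5, True, False, 7),
        ("M001", "c", 0, 5, 6, "pearson", 0.99, 1e-6, 1e-5, True, False, 6),
    ]
    out = refine_top_rank(_records_df(rows), ft)
    assert list(out["refined"]) == [True, False]  # 5 vs 2 top-5 fractions inside


def test_refine_tie_at_fifth_rank_includes_both():
    # ranks: 90,80,70,60 then a tie 50,50 at the 5th value -> top set has 6
    x = np.array([[50, 50, 60, 70, 80, 90, 1, 1, 1, 1]], dtype=float)
    ft = impute_half_min(_ft(x))
    rows = [("M001", "c", 0, 4, 5, "pearson", 0.99, 1e-6, 1e-5, True, False, 5)]
    out = refine_top_rank(_records_df(rows), ft, top_k=5, min_count=4)
    # fractions 0..4 hold values 50,50,60,70,80 -- all in the tied top set
    assert bool(out["refined"].iloc[0])
    # brute-force check of the tie rule
    thresh = np.sort(x[0])[-5]
    assert (x[0] >= thresh).sum() == 6


def test_refined_implies_retained(default_report):
    rec = default_report.records
    assert (rec.loc[rec["refined"], "retained"]).all()
    assert (rec["p_adj"] >= rec["p_raw"] - 1e-15).all()


# --- full pipeline ---------------------------------------------------------


def _small_world(rng, n_feat=4, n_frac=12, n_cat=2):
    x = rng.uniform(1, 100, size=(n_feat, n_frac))
    x[rng.random((n_feat, n_frac)) < 0.2] = np.nan
    x[:, 0] = rng.uniform(1, 100, n_feat)
    ft = _ft(x)
    taste = pd.DataFrame(
        rng.integers(0, 30, size=(n_frac, n_cat)).astype(float),
        index=ft.fractions,
        columns=[f"cat{k}" for k in range(n_cat)],
    )
    return ft, taste


def test_run_bookkeeping_identity(rng):
    ft, taste = _small_world(rng)
    rep = run_correlation(ft, taste)
    m = rep.meta
    assert m["n_tested"] + m["n_skipped"] == m["n_triples"]
    assert m["n_refined"] == int(rep.records["refined"].sum())
    assert m["n_retained"] == int(rep.records["retained"].sum())


def test_run_deterministic(rng):
    ft, taste = _small_world(rng)
    r1 = run_correlation(ft, taste)
    r2 = run_correlation(ft, taste)
    pd.testing.assert_frame_equal(r1.records, r2.records)


def test_run_fraction_mismatch_errors(rng):
    ft, taste = _small_world(rng)
    taste = taste.iloc[::-1]
    with pytest.raises(ValueError, match="fraction order"):
        run_correlation(ft, taste)


def test_run_matches_scalar_segment_api(rng):
    """The vectorized batch path agrees with the one-segment scalar API."""
    ft, taste = _small_world(rng, n_feat=3, n_frac=10, n_cat=2)
    cfg = CorrelationConfig()
    rep = run_correlation(ft, taste, cfg)
    kept = filter_features(ft, cfg.min_fractions)
    imputed = impute_half_min(kept)
    for _, row in rep.records.iterrows():
        rec = correlate_segment(
            imputed.intensities.loc[row["feature_id"]].to_numpy(),
            taste[row["category"]].to_numpy(),
            Segment(int(row["seg_start"]), int(row["seg_end"])),
        )
        assert rec.method == row["method"]
        assert rec.coefficient == pytest.approx(row["coefficient"], abs=1e-12)
        assert rec.p_raw == pytest.approx(row["p_raw"], abs=1e-12)


def test_n_observed_counts_non_imputed_points(rng):
    ft, taste = _small_world(rng)
    rep = run_correlation(ft, taste)
    obs = filter_features(ft).intensities.notna().to_numpy()
    idx = {fid: i for i, fid in enumerate(filter_features(ft).features.index)}
    for _, row in rep.records.head(50).iterrows():
        i = idx[row["feature_id"]]
        expect = obs[i, int(row["seg_start"]) : int(row["seg_end"]) + 1].sum()
        assert row["n_observed"] == expect
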