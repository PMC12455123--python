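"""Imputation: mechanism assignment, k-NN/min/MinDet oracles, mixed flow."""

import numpy as np
import pandas as pd
import pytest

from dialop import ImputationConfig, ValidationError, classify_missingness
from dialop.imputation import (
    COMPLETE,
    MAR,
    MNAR,
    impute,
    impute_knn,
    impute_min,
    impute_mindet,
    impute_mixed,
)

from conftest import make_matrix, random_missing_matrix

NA = np.nan


class TestClassifyMissingness:
    def test_count_rule_on_ten_fractions(self):
        rows = [
            [1.0] * 7 + [NA] * 3,  # 3 missing -> MNAR
            [1.0] * 8 + [NA] * 2,  # 2 missing -> MAR
            [1.0] * 10,  # COMPLETE
        ]
        labels = classify_missingness(make_matrix(rows), ImputationConfig())
        assert labels.tolist() == [MNAR, MAR, COMPLETE]

    def test_proportion_rule_scales_with_fraction_count(self):
        row = [[1.0] * 4 + [NA]]  # 1 of 5 missing = 0.2, not > 0.2
        cfg = ImputationConfig(mnar_rule="proportion", mnar_missing_frac_threshold=0.2)
        assert classify_missingness(make_matrix(row), cfg).iloc[0] == MAR
        row = [[1.0] * 3 + [NA, NA]]  # 0.4 > 0.2
        assert classify_missingness(make_matrix(row), cfg).iloc[0] == MNAR


class TestKnn:
    def test_unique_nearest_neighbour_donates_its_value(self):
        m = make_matrix([[1, 2, 3], [1, 2, NA]])
        out = impute_knn(m, cfg=ImputationConfig(knn_k=1))
        assert out.values.iloc[1, 2] == 3.0

    def test_equidistant_donors_are_averaged(self):
        m = make_matrix([[1, 2, 3], [1, 2, 5], [1, 2, NA]])
        out = impute_knn(m, cfg=ImputationConfig(knn_k=2))
        assert out.values.iloc[2, 2] == 4.0

    def test_complete_matrix_is_identity(self):
        m = make_matrix([[1, 2], [3, 4]])
        out = impute_knn(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_row_subset_restricts_imputation(self):
        m = make_matrix([[1, 2, 3], [1, 2, NA], [4, 5, NA]])
        out = impute_knn(m, rows=["prec1"], cfg=ImputationConfig(knn_k=1))
        assert not np.isnan(out.values.iloc[1, 2])
        assert np.isnan(out.values.iloc[2, 2])

    def test_fully_missing_column_raises(self):
        m = make_matrix([[1, NA], [2, NA]])
        with pytest.raises(ValidationError, match="column"):
            impute_knn(m)


class TestMin:
    def test_global_minimum_matches_bruteforce(self):
        m = random_missing_matrix(4)
        expected = float(np.nanmin(m.values.to_numpy()))
        out = impute_min(m)
        filled = out.values.to_numpy()[m.values.isna().to_numpy()]
        assert (filled == expected).all()

    def test_no_missing_in_selected_rows_is_identity(self):
        m = make_matrix([[1, 2], [NA, 4]])
        out = impute_min(m, rows=["prec0"])
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_column_scope_uses_column_minima(self):
        m = make_matrix([[1, 10], [2, NA]])
        out = impute_min(m, scope="column")
        assert out.values.iloc[1, 1] == 10.0


class TestMinDet:
    def test_quantile_convention_on_1_to_100(self):
        # column 0: observed values 1..100 plus one missing cell; the
        # linear-interpolation 1% quantile of 1..100 is 1.99.
        col0 = list(range(1, 101)) + [NA]
        col1 = [5.0] * 101
        m = make_matrix(np.column_stack([col0, col1]))
        out = impute_mindet(m, ImputationConfig(mindet_quantile=0.01))
        assert np.isclose(out.values.iloc[100, 0], 1.99)

    def test_tiny_quantile_approaches_column_minimum(self):
        m = random_missing_matrix(9)
        out = impute_mindet(m, ImputationConfig(mindet_quantile=1e-9))
        mins = m.values.min(axis=0)
        mask = m.values.isna()
        for col in m.values.columns:
            filled = out.values.loc[mask[col], col]
            assert np.allclose(filled, mins[col])

    def test_no_missing_is_identity(self):
        m = make_matrix([[1, 2], [3, 4]])
        pd.testing.assert_frame_equal(impute_mindet(m).values, m.values)


class TestMixed:
    def test_composes_min_and_knn_oracles(self):
        rows = [
            [10.0, 11.0, 12.0, 13.0],
            [10.0, 11.0, 12.0, NA],  # 1 missing -> MAR -> k-NN
            [2.0, NA, NA, NA],  # 3 missing -> MNAR -> global min
        ]
        cfg = ImputationConfig(knn_k=1)
        out, labels = impute_mixed(make_matrix(rows), cfg)
        assert labels.tolist() == [COMPLETE, MAR, MNAR]
        knn_oracle = impute_knn(make_matrix(rows), cfg=cfg).values.iloc[1, 3]
        assert out.values.iloc[1, 3] == knn_oracle
        assert (out.values.iloc[2, 1:] == 2.0).all()  # global observed min
        assert out.n_missing == 0

    def test_all_complete_is_identity(self):
        m = make_matrix([[1, 2], [3, 4]])
        out, labels = impute_mixed(m, ImputationConfig())
        pd.testing.assert_frame_equal(out.values, m.values)
        assert (labels == COMPLETE).all()

    def test_threshold_at_fraction_count_degenerates_to_knn(self):
        m = random_missing_matrix(6)
        cfg = ImputationConfig(mnar_missing_count_threshold=m.values.shape[1])
        out, labels = impute_mixed(m, cfg)
        assert MNAR not in labels.values
        knn = impute_knn(m, cfg=cfg)
        pd.testing.assert_frame_equal(out.values, knn.values)


@pytest.mark.parametrize("mode", ["mixed", "knn_global", "mindet_global", "min_global"])
@pytest.mark.parametrize("seed", [0, 1])
def test_observed_cells_never_change_and_output_complete(mode, seed):
    m = random_missing_matrix(seed)
    out, _ = impute(m, ImputationConfig(mode=mode))
    observed = m.values.notna()
    pd.testing.assert_frame_equal(out.values[observed], m.values[observed])
    assert out.n_missing == 0


def test_replicate_processing_order_is_irrelevant(small_sim):
    """Imputation is per-replicate; the order replicates are handled in must
    not leak information between them."""
    from dialop import pivot_replicate
    from dialop.qc import QcConfig, run_dia_qc

    table = small_sim.combined_table()
    cfg = ImputationConfig()
    results = {}
    for order in ([1, 2], [2, 1]):
        for rep in order:
            m = pivot_replicate(table, small_sim.design, rep)
            m, _ = run_dia_qc(m, QcConfig())
            out, _ = impute_mixed(m, cfg)
            results.setdefault(rep, []).append(out.values)
    for rep, (first, second) in results.items():
        pd.testing.assert_frame_equal(first, second)


def test_left_censoring_sanity_on_synthetic_truth(small_sim):
    """Min-imputed (MNAR) rows receive lower values on average than k-NN
    imputed (MAR) rows, reflecting left censoring."""
    from dialop import pivot_replicate
    from dialop.qc import QcConfig, run_dia_qc

    m = pivot_replicate(small_sim.combined_table(), small_sim.design, 1)
    m, _ = run_dia_qc(m, QcConfig())
    cfg = ImputationConfig()
    labels = classify_missingness(m, cfg)
    out, _ = impute_mixed(m, cfg)
    imputed_mask = m.values.isna()
    mnar_vals = out.values[imputed_mask].loc[labels == MNAR].stack()
    mar_vals = out.values[imputed_mask].loc[labels == MAR].stack()
    assert len(mnar_vals) and len(mar_vals)
    assert mnar_vals.mean() <= mar_vals.mean()
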