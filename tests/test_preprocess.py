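"""Cleaning, balancing, importance ranking, selection and grid encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from convbag.errors import (ConfigurationError, DegenerateLabelError,
                            EmptyOutputError)
from convbag.preprocess import (CleaningPolicy, GridEncoder, balance_classes,
                                clean_table, encode_grid,
                                rank_feature_importance, select_features)
from convbag.tables import FeatureTable


def table_from(matrix, label, names=None):
    matrix = np.asarray(matrix, dtype=float)
    names = names or [f"x{j:02d}" for j in range(matrix.shape[1])]
    return FeatureTable(pd.DataFrame(matrix, columns=names), np.asarray(label, float))


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

class TestCleaning:
    def test_clean_table_is_identity_without_missing(self):
        t = table_from([[1, 2], [3, 4]], [0, 1])
        out, log = clean_table(t)
        assert out.equals(t)
        assert log.n_dropped_missing_label == 0
        assert log.n_dropped_sparse_rows == 0
        assert log.n_imputed_cells == 0

    def test_sparse_rows_beyond_half_missing_are_dropped(self):
        m = np.ones((10, 5))
        m[0, :3] = np.nan              # 60% missing -> dropped
        m[1, :2] = np.nan              # 40% missing -> kept, imputed
        out, log = clean_table(table_from(m, [0, 1] * 5))
        assert out.n_rows == 9
        assert log.n_dropped_sparse_rows == 1
        assert log.n_imputed_cells == 2
        assert not out.features.isna().any().any()

    def test_class_conditional_median_imputation(self):
        # one class holds {1, missing, 3}: the missing cell becomes 2
        m = [[1.0, 0], [np.nan, 0], [3.0, 0], [100.0, 0], [100.0, 0]]
        t = table_from(m, [1, 1, 1, 0, 0])
        out, _ = clean_table(t)
        assert out.features.iloc[1, 0] == 2.0

    def test_missing_label_rows_are_dropped(self):
        t = table_from([[1, 2], [3, 4], [5, 6]], [0, np.nan, 1])
        out, log = clean_table(t)
        assert out.n_rows == 2
        assert log.n_dropped_missing_label == 1

    def test_all_rows_dropped_raises(self):
        t = table_from([[np.nan, np.nan]], [1])
        with pytest.raises(EmptyOutputError):
            clean_table(t, CleaningPolicy(max_missing_fraction=0.4))


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

class TestBalancing:
    def test_already_balanced_is_a_no_op(self):
        t = table_from([[1], [2], [3], [4]], [0, 0, 1, 1])
        out = balance_classes(t, "random_oversample", seed=0)
        assert out.equals(t)

    @pytest.mark.parametrize("method", ["random_oversample", "smote"])
    def test_counts_become_exactly_equal_and_originals_survive(self, method, rng):
        n_maj, n_min = 800, 200
        X = np.vstack([rng.normal(0, 1, (n_maj, 3)),
                       rng.normal(3, 1, (n_min, 3))])
        t = table_from(X, [0] * n_maj + [1] * n_min)
        out = balance_classes(t, method, seed=3)
        assert out.class_counts() == (800, 800)
        # original rows occupy the head, unmodified
        assert np.array_equal(out.values()[:1000], t.values())

    def test_smote_rows_lie_in_minority_bounding_box(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 4)), rng.uniform(5, 6, (10, 4))])
        t = table_from(X, [0] * 50 + [1] * 10)
        out = balance_classes(t, "smote", seed=1)
        synth = out.values()[60:]
        assert synth.min() >= 5.0 - 1e-9 and synth.max() <= 6.0 + 1e-9
        assert (out.label[60:] == 1).all()

    def test_single_class_raises(self):
        t = table_from([[1], [2]], [1, 1])
        with pytest.raises(DegenerateLabelError):
            balance_classes(t, "random_oversample", seed=0)

    def test_smote_with_single_minority_row_raises(self):
        t = table_from([[1], [2], [3]], [0, 0, 1])
        with pytest.raises(DegenerateLabelError):
            balance_classes(t, "smote", seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n_min=st.integers(2, 30), n_maj=st.integers(31, 80),
           seed=st.integers(0, 10**6))
    def test_balance_exactness_property(self, n_min, n_maj, seed):
        """Counts end exactly equal and no original row is deleted."""
        gen = np.random.default_rng(seed)
        X = gen.normal(size=(n_min + n_maj, 2))
        t = table_from(X, [1] * n_min + [0] * n_maj)
        out = balance_classes(t, "random_oversample", seed=seed)
        assert out.class_counts() == (n_maj, n_maj)
        assert np.array_equal(out.values()[: n_min + n_maj], X)


# ---------------------------------------------------------------------------
# ranking / selection
# ---------------------------------------------------------------------------

class TestRanking:
    def test_predictive_feature_ranks_first(self, rng):
        n = 300
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 6))
        X[:, 2] = y * 4.0 + rng.normal(0, 0.1, n)     # the lone signal column
        t = table_from(X, y)
        ranking = rank_feature_importance(t, seed=1, n_trees=30, n_repeats=1)
        assert ranking.ordering[0] == "x02"

    def test_constant_columns_tie_and_keep_column_order(self):
        t = table_from(np.ones((40, 5)), [0, 1] * 20)
        ranking = rank_feature_importance(t, seed=0, n_trees=10)
        assert all(v == 0.0 for v in ranking.scores.values())
        assert ranking.ordering == t.column_names

    def test_noise_features_score_near_zero(self, separable_small):
        ds = separable_small
        ranking = rank_feature_importance(ds.table, seed=4, n_trees=50, n_repeats=1)
        noise = set(ds.table.column_names) - set(ds.informative_feature_names)
        assert max(ranking.scores[c] for c in noise) < 0.05

    def test_informative_features_outrank_noise_over_many_seeds(self, separable_small):
        """The injected signal columns all rank above every pure-noise column."""
        ds = separable_small
        informative = set(ds.informative_feature_names)
        k = len(informative)
        failures = 0
        for seed in range(50):
            ranking = rank_feature_importance(ds.table, seed=seed)
            if set(ranking.ordering[:k]) != informative:
                failures += 1
        assert failures == 0

    def test_degenerate_label_raises(self):
        t = table_from(np.random.default_rng(0).normal(size=(20, 3)), [1] * 20)
        with pytest.raises(DegenerateLabelError):
            rank_feature_importance(t, seed=0)


class TestSelection:
    @pytest.fixture(scope="class")
    def ranked(self, separable_small):
        ranking = rank_feature_importance(separable_small.table, seed=2,
                                          n_trees=30, n_repeats=1)
        return separable_small.table, ranking

    def test_top_36_of_49(self, ranked):
        table, ranking = ranked
        out = select_features(table, ranking, k=36)
        assert out.n_features == 36
        assert out.column_names == ranking.ordering[:36]

    def test_k_equal_p_is_a_reordering(self, ranked):
        table, ranking = ranked
        out = select_features(table, ranking, k=49)
        assert sorted(out.column_names) == sorted(table.column_names)
        assert out.column_names == ranking.ordering

    def test_k_one_keeps_the_top_column(self, ranked):
        table, ranking = ranked
        out = select_features(table, ranking, k=1)
        assert out.column_names == [ranking.ordering[0]]

    def test_k_beyond_p_raises(self, ranked):
        table, ranking = ranked
        with pytest.raises(ConfigurationError):
            select_features(table, ranking, k=50)

    def test_keep_list_overrides_the_tail(self, ranked):
        table, ranking = ranked
        pinned = ranking.ordering[-1]        # least important column
        out = select_features(table, ranking, k=36, keep=[pinned])
        assert pinned in out.column_names
        assert out.n_features == 36


# ---------------------------------------------------------------------------
# grid encoding
# ---------------------------------------------------------------------------

class TestGridEncoding:
    @pytest.fixture(scope="class")
    def selected36(self, separable_small):
        ranking = rank_feature_importance(separable_small.table, seed=2,
                                          n_trees=30, n_repeats=1)
        return select_features(separable_small.table, ranking, k=36)

    def test_shape_is_n_by_6_by_6_by_1(self, selected36):
        batch = encode_grid(selected36)
        assert batch.data.shape == (selected36.n_rows, 6, 6, 1)

    def test_grid_cell_holds_feature_at_rank_6r_plus_c(self, selected36):
        enc = GridEncoder().fit(selected36)
        batch = enc.transform(selected36)
        Z = (selected36.values() - enc.mean_) / enc.sd_
        for r in range(6):
            for c in range(6):
                np.testing.assert_array_equal(batch.data[:, r, c, 0], Z[:, 6 * r + c])

    def test_decode_inverts_the_layout_exactly(self, selected36):
        enc = GridEncoder()
        batch = enc.fit_transform(selected36)
        Z = (selected36.values() - enc.mean_) / enc.sd_
        np.testing.assert_array_equal(enc.decode(batch), Z)

    def test_constant_column_encodes_to_zeros_with_warning(self, selected36):
        feats = selected36.features.copy()
        feats[feats.columns[0]] = 7.0
        t = FeatureTable(feats, selected36.label.copy())
        with pytest.warns(UserWarning, match="zero-variance"):
            batch = encode_grid(t)
        assert np.array_equal(batch.data[:, 0, 0, 0], np.zeros(t.n_rows))

    def test_wrong_column_count_raises(self, separable_small):
        with pytest.raises(ConfigurationError):
            encode_grid(separable_small.table)        # 49 columns

    def test_transform_reuses_training_statistics(self, selected36):
        enc = GridEncoder().fit(selected36)
        half = FeatureTable(selected36.features.iloc[:50].copy(),
                            selected36.label[:50].copy())
        batch = enc.transform(half)
        Z = (half.values() - enc.mean_) / enc.sd_
        np.testing.assert_array_equal(enc.decode(batch), Z)
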