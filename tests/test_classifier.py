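"""Univariate AUC, greedy correlation-pruned selection, repeated CV."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nephrotex.classifier import (ClassifierError, CVResult, auc_grid,
                                  folded_auc, grid_to_frame, repeated_cv_auc,
                                  select_features, univariate_auc)
from nephrotex.features.names import FEATURE_NAMES

F = list(FEATURE_NAMES)


class TestUnivariateAUC:
    def test_concordant_pair_hand_example(self):
        values = np.array([3.0, 5.0, 1.0, 2.0, 4.0])
        labels = np.array([1, 1, 0, 0, 0])
        # pairs: (3 vs 1,2,4) -> 2 wins of 3; (5 vs 1,2,4) -> 3 of 3
        assert univariate_auc(values, labels) == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        assert univariate_auc(np.array([1, 2, 10, 11.0]),
                              np.array([0, 0, 1, 1])) == 1.0

    def test_all_ties_give_half(self):
        assert univariate_auc(np.ones(6), np.array([0, 1] * 3)) == 0.5

    def test_one_class_absent_rejected(self):
        with pytest.raises(ClassifierError):
            univariate_auc(np.arange(4.0), np.ones(4, int))

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_normalized_rank_sum(self, seed):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        labels = np.zeros(n, int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        values = np.round(rng.standard_normal(n), 1)  # induce ties
        u = mannwhitneyu(values[labels == 1], values[labels == 0]).statistic
        expected = u / (labels.sum() * (n - labels.sum()))
        assert univariate_auc(values, labels) == pytest.approx(expected)

    def test_folding(self):
        values = np.array([1, 2, 10, 11.0])
        labels = np.array([1, 1, 0, 0])
        assert univariate_auc(values, labels) == 0.0
        assert folded_auc(values, labels) == 1.0


def _table(cols: dict) -> pd.DataFrame:
    return pd.DataFrame({F[i]: v for i, v in enumerate(cols.values())})


class TestSelectFeatures:
    def test_duplicated_column_admitted_once(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 10)
        sig = y + 0.1 * rng.standard_normal(20)
        t = _table({"a": sig, "b": sig.copy(), "c": rng.standard_normal(20)})
        kept = select_features(t, y, k_top=3)
        assert not {F[0], F[1]} <= set(kept)  # |r| = 1 pair never both kept

    def test_orthogonal_features_fill_k_top(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 20)
        t = pd.DataFrame({F[i]: rng.standard_normal(40) for i in range(12)})
        kept = select_features(t, y, k_top=10)
        assert len(kept) == 10

    def test_greedy_admission_matches_bruteforce(self):
        """Constructed 5-feature table: the greedy AUC-ordered admission
        with |r| < 0.7 must equal an exhaustive re-simulation."""
        rng = np.random.default_rng(5)
        y = np.array([0] * 15 + [1] * 15)
        cols = {}
        base = y + 0.3 * rng.standard_normal(30)
        cols["f0"] = base
        cols["f1"] = base + 0.05 * rng.standard_normal(30)   # r ~ 1 with f0
        cols["f2"] = y + 0.8 * rng.standard_normal(30)
        cols["f3"] = rng.standard_normal(30)
        cols["f4"] = -base + 0.9 * rng.standard_normal(30)
        t = _table(cols)
        kept = select_features(t, y, k_top=3)

        # independent oracle: sort by folded AUC desc/name asc, then greedy
        names = list(t.columns)
        scored = sorted(
            names, key=lambda n: (-folded_auc(t[n].to_numpy(), y), n))
        expected = []
        for n in scored:
            if len(expected) == 3:
                break
            if all(abs(np.corrcoef(t[n], t[m])[0, 1]) < 0.7
                   for m in expected):
                expected.append(n)
        assert kept == expected

    def test_constant_feature_skipped(self):
        y = np.array([0, 1] * 8)
        t = _table({"a": np.ones(16), "b": y.astype(float)})
        kept = select_features(t, y, k_top=2)
        assert F[0] not in kept


def _labeled_noise_table(n=40, n_feats=20, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    t = pd.DataFrame({F[i]: rng.standard_normal(n) for i in range(n_feats)})
    return t, y


class TestRepeatedCV:
    def test_deterministic_given_seed(self):
        t, y = _labeled_noise_table()
        a = repeated_cv_auc(t, y, folds=4, repeats=2, seed=9)
        b = repeated_cv_auc(t, y, folds=4, repeats=2, seed=9)
        assert a.fold_aucs == b.fold_aucs
        assert a.selection_counts == b.selection_counts
        c = repeated_cv_auc(t, y, folds=4, repeats=2, seed=10)
        assert a.fold_aucs != c.fold_aucs

    def test_partition_count_and_interval(self):
        t, y = _labeled_noise_table()
        res = repeated_cv_auc(t, y, folds=4, repeats=3, seed=1)
        assert res.n_partitions == 12
        assert res.interval[0] <= res.mean_auc <= res.interval[1]

    def test_label_copy_feature_classifies_perfectly(self):
        t, y = _labeled_noise_table(seed=3)
        t[F[0]] = y.astype(float)
        res = repeated_cv_auc(t, y, folds=4, repeats=2, seed=2)
        assert res.mean_auc > 0.99
        assert res.selection_counts[F[0]] == 8  # picked in every partition

    def test_no_leakage_from_test_only_signal(self):
        """A feature equal to the label on held-out rows but noise on
        training rows must not help: selection/standardization see only
        the training partition, so held-out AUC stays near chance."""
        from sklearn.model_selection import StratifiedKFold
        t, y = _labeled_noise_table(n=60, seed=4)
        rng = np.random.default_rng(7)
        leak = rng.standard_normal(60)
        # plant label-copies exactly on the test rows of the first split
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        _, test_idx = next(iter(skf.split(t, y)))
        leak[test_idx] = y[test_idx] * 10.0
        t[F[0]] = leak
        res = repeated_cv_auc(t, y, folds=5, repeats=2, seed=11)
        assert res.mean_auc < 0.75

    def test_stratified_folds_balanced(self):
        from sklearn.model_selection import StratifiedKFold
        y = np.array([0] * 13 + [1] * 13)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=1)
        for _, test in skf.split(np.zeros((26, 1)), y):
            c = np.bincount(y[test], minlength=2)
            assert abs(c[0] - c[1]) <= 1

    def test_too_few_per_class_rejected(self):
        t, y = _labeled_noise_table(n=8)
        with pytest.raises(ClassifierError):
            repeated_cv_auc(t, y, folds=5, repeats=1, seed=0)


class TestAUCGrid:
    def test_72_cell_grid_arithmetic(self):
        t, y = _labeled_noise_table(n=20, n_feats=8, seed=6)
        keys = list(itertools.product(
            ("noncystic", "entire_kidney"),
            ("original", "zscore", "reference"),
            ("up_1.0mm", "down_2.0mm"),
            (8, 16, 32, 64, 128, 256),
        ))
        cells = {k: (t, y) for k in keys}
        results = auc_grid(cells, folds=2, repeats=1, seed=0)
        assert len(results) == 72
        frame = grid_to_frame(results)
        assert len(frame) == 72
        assert set(frame["n_gray_levels"]) == {8, 16, 32, 64, 128, 256}

    def test_missing_cell_named(self):
        with pytest.raises(ClassifierError, match="missing"):
            auc_grid({("noncystic", "zscore", "up_1.0mm", 8): (None, None)})
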