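"""Split stratification, L1-path ranking, SRC, forward selection."""

import numpy as np
import pandas as pd
import pytest

from synthrad.selection import (
    SelectionResult, forward_select, make_split, select_features,
    sparse_rank, src_classify,
)


def _labels(n_soft, n_fib):
    return pd.Series({f"s{i}": "soft" for i in range(n_soft)}
                     | {f"f{i}": "fibrous" for i in range(n_fib)})


class TestSplit:
    def test_study_sized_cohort(self):
        plan = make_split(_labels(88, 64), seed=1)
        assert len(plan.train_ids) == 101
        assert len(plan.test_ids) == 51

    def test_three_case_edge_keeps_both_classes_in_train(self):
        with pytest.warns(UserWarning, match="single member"):
            plan = make_split(_labels(2, 2).iloc[:3], seed=0)
        labels = _labels(2, 2).iloc[:3]
        train_classes = set(labels[plan.train_ids])
        assert len(plan.train_ids) == 2 and len(plan.test_ids) == 1
        assert train_classes == {"soft", "fibrous"}

    def test_deterministic_per_seed(self):
        a = make_split(_labels(20, 10), seed=5)
        b = make_split(_labels(20, 10), seed=5)
        c = make_split(_labels(20, 10), seed=6)
        assert a.train_ids == b.train_ids
        assert a.train_ids != c.train_ids

    def test_stratification_preserves_prevalence(self):
        labels = _labels(60, 30)
        plan = make_split(labels, seed=2)
        frac_train = (labels[plan.train_ids] == "fibrous").mean()
        assert frac_train == pytest.approx(1 / 3, abs=0.02)

    def test_singleton_class_forced_into_train(self):
        with pytest.warns(UserWarning, match="single member"):
            plan = make_split(_labels(5, 1), seed=0)
        assert "f0" in plan.train_ids

    def test_single_class_cohort_rejected(self):
        with pytest.raises(ValueError, match="two non-empty classes"):
            make_split(_labels(5, 0))


def _standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


class TestSparseRank:
    def test_perfect_predictor_ranked_first(self, rng):
        n, p = 60, 10
        y = np.where(rng.uniform(size=n) > 0.5, 1.0, -1.0)
        X = rng.standard_normal((n, p))
        X[:, 4] = y
        ranking = sparse_rank(_standardize(X), y)
        assert ranking[0] == 4

    @pytest.mark.parametrize("seed", [1234, 7, 99])
    def test_duplicated_informative_signal_occupies_top_two(self, seed):
        """Two independent noisy copies of the class signal both activate
        early on the path.  (An exact duplicate would instead be suppressed
        once its twin is active -- a well-known property of the lasso.)"""
        r = np.random.default_rng(seed)
        n = 80
        y = np.where(r.uniform(size=n) > 0.5, 1.0, -1.0)
        X = r.standard_normal((n, 8))
        X[:, 2] = y + 0.3 * r.standard_normal(n)
        X[:, 6] = y + 0.3 * r.standard_normal(n)
        ranking = sparse_rank(_standardize(X), y)
        assert set(ranking[:2]) == {2, 6}

    def test_pure_noise_no_spuriously_stable_winner(self):
        """Across 50 reseeds of an all-noise design, no feature should top
        the ranking much more often than the uniform rate."""
        p = 20
        wins = np.zeros(p)
        for seed in range(50):
            r = np.random.default_rng(seed)
            X = r.standard_normal((40, p))
            y = np.where(r.uniform(size=40) > 0.5, 1.0, -1.0)
            ranking = sparse_rank(_standardize(X), y)
            wins[ranking[0]] += 1
        assert wins.max() <= 0.3 * 50  # uniform would be 2.5 wins/feature

    def test_unstandardized_input_rejected(self, rng):
        X = rng.standard_normal((30, 5)) * 7 + 3
        with pytest.raises(ValueError, match="not standardized"):
            sparse_rank(X, np.sign(rng.standard_normal(30)))

    def test_constant_column_ranked_last_with_warning(self, rng):
        X = _standardize(rng.standard_normal((40, 5)))
        X[:, 3] = 0.0
        y = np.sign(rng.standard_normal(40))
        with pytest.warns(UserWarning, match="constant"):
            ranking = sparse_rank(X, y)
        assert ranking[-1] == 3

    def test_dataframe_names_preserved(self, rng):
        X = pd.DataFrame(_standardize(rng.standard_normal((30, 3))),
                         columns=["a", "b", "c"])
        y = np.sign(rng.standard_normal(30))
        assert set(sparse_rank(X, y)) == {"a", "b", "c"}


class TestSRC:
    def test_training_sample_reconstructs_itself(self, rng):
        X = rng.standard_normal((20, 6))
        y = np.array(["A"] * 10 + ["B"] * 10)
        label, residuals = src_classify(X, y, X[3], lam_frac=0.01)
        assert label == "A"
        assert residuals["A"] < 0.15
        assert residuals["A"] < residuals["B"]

    def test_separated_gaussians_holdout_accuracy(self):
        r = np.random.default_rng(42)
        mu = np.zeros(5)
        mu2 = np.full(5, 3.0)
        Xtr = np.vstack([r.standard_normal((20, 5)) + mu,
                         r.standard_normal((20, 5)) + mu2])
        ytr = np.array(["A"] * 20 + ["B"] * 20)
        Xte = np.vstack([r.standard_normal((20, 5)) + mu,
                         r.standard_normal((20, 5)) + mu2])
        yte = np.array(["A"] * 20 + ["B"] * 20)
        correct = sum(src_classify(Xtr, ytr, q)[0] == t for q, t in zip(Xte, yte))
        assert correct / 40 >= 0.9

    def test_label_permutation_gives_chance(self):
        r = np.random.default_rng(43)
        X = np.vstack([r.standard_normal((20, 5)),
                       r.standard_normal((20, 5)) + 3.0])
        y = np.array(["A"] * 20 + ["B"] * 20)
        yperm = r.permutation(y)
        Xte = np.vstack([r.standard_normal((10, 5)),
                         r.standard_normal((10, 5)) + 3.0])
        yte = np.array(["A"] * 10 + ["B"] * 10)
        acc = np.mean([src_classify(X, yperm, q)[0] == t
                       for q, t in zip(Xte, yte)])
        assert 0.3 <= acc <= 0.7

    def test_zero_variance_query_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        y = np.array(["A"] * 5 + ["B"] * 5)
        with pytest.raises(ValueError, match="zero-variance"):
            src_classify(X, y, np.full(4, 2.0))


def _planted_dataset(seed, n=80, p=40, informative=(0,)):
    r = np.random.default_rng(seed)
    y = np.where(r.uniform(size=n) > 0.5, 1.0, -1.0)
    X = r.standard_normal((n, p))
    for j in informative:
        X[:, j] = 1.2 * y + 0.8 * r.standard_normal(n)
    return _standardize(X), np.where(y > 0, "fibrous", "soft")


class TestForwardSelect:
    def test_single_informative_among_noise(self):
        X, y = _planted_dataset(seed=11, p=100, informative=(7,))
        ranking = sparse_rank(X, np.where(y == "fibrous", 1.0, -1.0))
        res = forward_select(ranking, X, y, k_max=10, folds=5, seed=11)
        assert res.chosen_subset[0] == 7
        assert max(res.cv_curve) > 0.8

    def test_kmax_one(self):
        X, y = _planted_dataset(seed=3)
        ranking = sparse_rank(X, np.where(y == "fibrous", 1.0, -1.0))
        res = forward_select(ranking, X, y, k_max=1, folds=5, seed=3)
        assert len(res.cv_curve) == 1
        assert len(res.chosen_subset) == 1

    def test_xor_pair_needs_both_features(self):
        """Two features informative only jointly (XOR) are both kept when
        they sit at the top of the ranking."""
        r = np.random.default_rng(21)
        n = 120
        a = np.sign(r.standard_normal(n))
        b = np.sign(r.standard_normal(n))
        y = np.where(a * b > 0, "fibrous", "soft")
        X = np.column_stack([a + 0.1 * r.standard_normal(n),
                             b + 0.1 * r.standard_normal(n),
                             r.standard_normal((n, 3))])
        Xs = _standardize(X)
        res = forward_select([0, 1, 2, 3, 4], Xs, y, k_max=5, folds=5, seed=21)
        assert set(res.chosen_subset) >= {0, 1}
        assert res.cv_curve[1] > res.cv_curve[0]

    def test_curve_bounds_and_prefix_invariant(self):
        X, y = _planted_dataset(seed=5)
        ranking = sparse_rank(X, np.where(y == "fibrous", 1.0, -1.0))
        res = forward_select(ranking, X, y, k_max=6, folds=5, seed=5)
        assert all(0.0 <= v <= 1.0 for v in res.cv_curve)
        assert max(res.cv_curve) == res.cv_curve[len(res.chosen_subset) - 1]
        assert res.chosen_subset == res.ranking[:len(res.chosen_subset)]

    def test_too_many_folds_rejected(self):
        X, y = _planted_dataset(seed=6, n=12)
        with pytest.raises(ValueError, match="folds"):
            forward_select(list(range(5)), X, y, k_max=3, folds=11, seed=0)


class TestLeakageGuard:
    def test_selection_pure_function_of_training_rows(self):
        """Replacing held-out rows with noise leaves selection unchanged."""
        rng_a = np.random.default_rng(31)
        n, p = 90, 30
        y = np.where(rng_a.uniform(size=n) > 0.5, "fibrous", "soft")
        X = rng_a.standard_normal((n, p))
        X[:, 4] += np.where(y == "fibrous", 1.5, -1.5)
        cols = [f"feat_{i:02d}" for i in range(p)]
        full = pd.DataFrame(X, columns=cols)
        full["label"] = y
        full["case_id"] = [f"c{i:03d}" for i in range(n)]
        train_ids = set(full.case_id[:60])

        def run(cohort):
            train = cohort[cohort.case_id.isin(train_ids)].reset_index(drop=True)
            return select_features(train, k_max=5, folds=5, seed=31)

        res_a = run(full)
        corrupted = full.copy()
        noise = np.random.default_rng(99).standard_normal((n - 60, p)) * 100
        corrupted.loc[~corrupted.case_id.isin(train_ids), cols] = noise
        res_b = run(corrupted)
        assert res_a.ranking == res_b.ranking
        assert res_a.chosen_subset == res_b.chosen_subset
        assert res_a.cv_curve == res_b.cv_curve

    def test_result_json_round_trip(self, tmp_path):
        res = SelectionResult(ranking=["a", "b", "c"], chosen_subset=["a"],
                              cv_curve=[0.8, 0.7, 0.6], seed=1)
        path = res.to_json(tmp_path / "sel.json")
        back = SelectionResult.from_json(path)
        assert back.chosen_subset == ["a"]
        assert back.cv_curve == [0.8, 0.7, 0.6]

    def test_chosen_subset_must_be_prefix(self):
        with pytest.raises(ValueError, match="prefix"):
            SelectionResult(ranking=["a", "b"], chosen_subset=["b"],
                            cv_curve=[0.5, 0.6], seed=0)
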