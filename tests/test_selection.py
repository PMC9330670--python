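"""Stratified splitting, AUC, the genetic algorithm, incidence aggregation
and permutation inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import erpstrat as es
from erpstrat import selection as sel


def brute_force_auc(scores, labels):
    """Pair-enumeration oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _binary_table(n=144, n_pos=33, seed=0):
    rng = np.random.default_rng(seed)
    tab = pd.DataFrame({"x": rng.normal(size=n)})
    tab["diagnosis"] = np.r_[np.ones(n_pos, int), np.zeros(n - n_pos, int)]
    return tab


class TestStratifiedSplit:
    def test_study_sizes(self):
        main, hold = sel.stratified_split(_binary_table(), 0.70, seed=1)
        assert (len(main), len(hold)) == (101, 43)
        assert main["diagnosis"].sum() == 23 and hold["diagnosis"].sum() == 10

    def test_same_seed_same_membership(self):
        tab = _binary_table(seed=3)
        a1, _ = sel.stratified_split(tab, 0.70, seed=9)
        a2, _ = sel.stratified_split(tab, 0.70, seed=9)
        assert list(a1.index) == list(a2.index)

    @pytest.mark.parametrize("frac", [0.0, 1.0, 1.2])
    def test_degenerate_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            sel.stratified_split(_binary_table(), frac, seed=0)

    def test_tiny_class_rejected(self):
        tab = _binary_table(n=20, n_pos=1)
        with pytest.raises(ValueError):
            sel.stratified_split(tab, 0.70, seed=0)

    @pytest.mark.parametrize("n,n_pos", [(50, 10), (81, 27), (200, 60)])
    def test_class_ratio_preserved_within_one_subject(self, n, n_pos):
        main, hold = sel.stratified_split(_binary_table(n, n_pos, seed=5),
                                          0.70, seed=2)
        expected = round(0.70 * n_pos)
        assert main["diagnosis"].sum() == expected


class TestAUC:
    def test_perfect_separation(self):
        assert sel.auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert sel.auc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_hand_worked_example(self):
        # pos {3, 2}, neg {1, 2}: (1 + 1 + 1 + 0.5) / 4
        assert sel.auc([3, 2, 1, 2], [1, 1, 0, 0]) == 0.875

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sel.auc([1, 2], [1, 1])

    @given(st.lists(st.tuples(st.integers(-3, 3), st.booleans()),
                    min_size=2, max_size=12))
    @settings(max_examples=300, deadline=None)
    def test_matches_pair_enumeration_oracle(self, pairs):
        scores = [s for s, _ in pairs]
        labels = [int(l) for _, l in pairs]
        if len(set(labels)) < 2:
            return
        assert sel.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels))


class TestLinearSVM:
    def test_dcd_matches_libsvm_decisions(self, rng):
        X = rng.normal(size=(150, 8))
        y = (rng.random(150) < 0.3).astype(int)
        X[y == 1, :3] += 0.8
        from sklearn.svm import SVC

        ref = SVC(kernel="linear", C=1.0).fit(X, y).decision_function(X)
        ours = sel.linear_svm_decision(X, y, X, C=1.0)
        assert np.corrcoef(ref, ours)[0, 1] > 0.999

    def test_cv_auc_solvers_agree(self, rng):
        X = rng.normal(size=(120, 6))
        y = (rng.random(120) < 0.4).astype(int)
        X[y == 1, 0] += 1.0
        a = sel.cv_auc(X, y, k=5, seed=3, solver="svc")
        b = sel.cv_auc(X, y, k=5, seed=3, solver="dcd")
        assert abs(a - b) < 0.02


class TestCvAuc:
    def test_strong_single_feature(self, rng):
        n = 200
        y = (rng.random(n) < 0.5).astype(int)
        X = rng.normal(size=(n, 1))
        X[y == 1] += 3.0  # theoretical AUC = Phi(3/sqrt(2)) ~ 0.983
        assert sel.cv_auc(X, y, k=10, seed=0) > 0.95

    def test_null_features_near_chance(self, rng):
        aucs = []
        for s in range(40):
            r = np.random.default_rng(s)
            X = r.normal(size=(60, 5))
            y = (r.random(60) < 0.5).astype(int)
            if y.sum() < 5 or y.sum() > 55:
                continue
            aucs.append(sel.cv_auc(X, y, k=5, seed=s, solver="dcd"))
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_row_duplication_invariance(self, rng):
        X = rng.normal(size=(60, 3))
        y = (rng.random(60) < 0.4).astype(int)
        X[y == 1, 0] += 1.5
        a = sel.cv_auc(X, y, k=5, seed=1)
        b = sel.cv_auc(np.vstack([X, X]), np.r_[y, y], k=5, seed=1)
        assert abs(a - b) < 0.06

    def test_empty_mask_rejected(self, rng):
        X = rng.normal(size=(30, 4))
        y = (rng.random(30) < 0.5).astype(int)
        with pytest.raises(ValueError):
            sel.cv_auc(X, y, np.zeros(4, bool), k=3)


class TestGeneticAlgorithm:
    def _problem(self, seed=0, n=150, p=12, d=1.5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = (rng.random(n) < 0.4).astype(int)
        X[y == 1, 0] += d
        X[y == 1, 1] += d
        return X, y

    def test_zero_generations_returns_best_initial(self):
        X, y = self._problem()
        best = sel.ga_evolve(X, y, seed=5, pop_size=8, generations=0, k=5)
        assert best.fitness is not None and best.mask.any()

    def test_elitism_never_loses_fitness(self):
        X, y = self._problem(seed=2)
        init = sel.ga_evolve(X, y, seed=7, pop_size=8, generations=0, k=5)
        evolved = sel.ga_evolve(X, y, seed=7, pop_size=8, generations=6, k=5)
        assert evolved.fitness >= init.fitness

    def test_informative_bits_found(self):
        hits = 0
        for s in range(5):
            X, y = self._problem(seed=10 + s)
            best = sel.ga_evolve(X, y, seed=s, pop_size=14, generations=10,
                                 k=5, init_p=0.15)
            hits += bool(best.mask[0] and best.mask[1])
        assert hits >= 4

    def test_all_zero_chromosome_repaired(self):
        X, y = self._problem()
        best = sel.ga_evolve(X, y, seed=1, pop_size=4, generations=1,
                             init_p=0.0, k=5)
        assert best.mask.any()

    def test_same_seed_reproducible(self):
        X, y = self._problem(seed=4)
        a = sel.ga_evolve(X, y, seed=11, pop_size=8, generations=3, k=5)
        b = sel.ga_evolve(X, y, seed=11, pop_size=8, generations=3, k=5)
        assert np.array_equal(a.mask, b.mask) and a.fitness == b.fitness


class TestIncidenceAggregation:
    def _archive(self, masks, fits):
        arch = sel.EvolutionArchive()
        for m, f in zip(masks, fits):
            arch.append(sel.FeatureMask(np.array(m, bool), f))
        return arch

    def test_unanimous_feature_included(self):
        arch = self._archive([[1, 0]] * 5, [0.9] * 5)
        mask, inc, nq = sel.aggregate_incidence(arch)
        assert nq == 5 and mask.mask.tolist() == [True, False]
        assert inc[0] == 1.0

    def test_exact_80_percent_excluded(self):
        masks = [[1, 1]] * 8 + [[0, 1]] * 2
        mask, inc, _ = sel.aggregate_incidence(self._archive(masks, [0.9] * 10))
        assert inc[0] == pytest.approx(0.80)
        assert not mask.mask[0] and mask.mask[1]

    def test_no_qualifying_runs_empty_flag(self):
        mask, inc, nq = sel.aggregate_incidence(
            self._archive([[1, 1]] * 4, [0.5] * 4))
        assert nq == 0 and not mask.mask.any() and np.isnan(inc).all()

    def test_output_subset_of_qualifying_union(self, rng):
        masks = (rng.random((30, 10)) < 0.4)
        fits = rng.uniform(0.7, 1.0, 30)
        arch = self._archive(masks.tolist(), fits.tolist())
        mask, _, _ = sel.aggregate_incidence(arch)
        union = masks[np.array(arch.fitnesses) > 0.85].any(axis=0)
        assert not np.any(mask.mask & ~union)

    def test_optimal_mask_tie_breaks_to_fewest_features(self):
        arch = self._archive([[1, 1, 1], [1, 0, 0]], [0.9, 0.9])
        assert sel.optimal_mask(arch).mask.tolist() == [True, False, False]


class TestTopdownSets:
    def test_visual_noise_mask(self, inventory):
        masks = sel.topdown_sets(inventory)
        n_mask = masks["condition:N"]
        assert n_mask.sum() == 6
        assert all(name.endswith("_N") for name, m in zip(inventory, n_mask) if m)

    def test_stimulus_masks_union_is_averaged_block(self, inventory):
        masks = sel.topdown_sets(inventory)
        union = np.zeros(len(inventory), bool)
        for cond in ("FD", "FA", "F", "N", "SD", "SA"):
            union |= masks[f"condition:{cond}"]
        assert union.sum() == 36
        assert all(union[:36]) and not any(union[36:])

    def test_latency_mask_has_27_bits(self, inventory):
        assert sel.topdown_sets(inventory)["measure:lat"].sum() == 27


class TestHoldoutEvaluation:
    def test_confusion_arithmetic(self):
        pred = np.r_[np.ones(25), np.zeros(9), np.zeros(7), np.ones(2)].astype(int)
        ytrue = np.r_[np.ones(34), np.zeros(9)].astype(int)
        m = sel._confusion_metrics(pred, ytrue)
        assert m["sensitivity"] == pytest.approx(25 / 34)
        assert m["specificity"] == pytest.approx(7 / 9)
        assert m["accuracy"] == pytest.approx(32 / 43)

    def test_perfect_separation_degenerate_cis(self, rng):
        n = 60
        y = np.r_[np.ones(20, int), np.zeros(40, int)]
        X = rng.normal(size=(n, 2)) * 0.01
        X[y == 1, 0] += 10.0
        rep = sel.evaluate_holdout(X, y, X, y, np.ones(2, bool), n_boot=200,
                                   seed=0)
        for key in ("auc", "sensitivity", "specificity", "accuracy"):
            point, lo, hi = rep.metrics[key]
            assert point == 1.0
            assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_single_class_holdout_flagged(self, rng):
        X = rng.normal(size=(40, 2))
        y = (rng.random(40) < 0.5).astype(int)
        Xh = rng.normal(size=(5, 2))
        yh = np.ones(5, int)
        rep = sel.evaluate_holdout(X, y, Xh, yh, np.ones(2, bool), n_boot=50,
                                   seed=0)
        assert "auc" in rep.flags and np.isnan(rep.metrics["auc"][0])


class TestShuffleTest:
    def test_formula_floor(self):
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]

        def evaluator(lab):
            return 1.0 if np.array_equal(lab, labels) else 0.0

        res = sel.shuffle_test(evaluator, labels, n_perm=100, seed=0)
        assert res["p"] == pytest.approx(1 / 101)

    def test_hand_counted_p(self):
        labels = np.r_[np.ones(6, int), np.zeros(6, int)]
        state = {"calls": -1}

        def evaluator(lab):
            state["calls"] += 1
            if state["calls"] == 0:
                return 0.5          # observed statistic
            return 1.0 if state["calls"] <= 30 else 0.0

        res = sel.shuffle_test(evaluator, labels, n_perm=199, seed=1)
        assert res["p"] == pytest.approx(31 / 200)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            sel.shuffle_test(lambda l: 0.0, np.array([0, 1]), n_perm=10)


class TestCompareClassifiers:
    def test_identical_scores_p_one(self, rng):
        y = (rng.random(50) < 0.5).astype(int)
        s = rng.normal(size=50)
        res = sel.compare_classifiers(s, s.copy(), y, n_perm=200, seed=0)
        assert res["p"] == 1.0 and res["observed"] == 0.0

    def test_perfect_vs_random_significant(self, rng):
        n = 200
        y = (rng.random(n) < 0.5).astype(int)
        perfect = y + 0.01 * rng.normal(size=n)
        random_scores = rng.normal(size=n)
        res = sel.compare_classifiers(perfect, random_scores, y, n_perm=500,
                                      seed=1)
        assert res["p"] <= 0.01

    def test_mismatched_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            sel.compare_classifiers(np.ones(5), np.ones(6),
                                    np.array([0, 1, 0, 1, 0]))
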