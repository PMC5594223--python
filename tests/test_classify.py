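"""Nested classifier: SVM contract, ranking, greedy selection, votes,
accuracy metrics, leakage guarantees and determinism."""

from fractions import Fraction

import numpy as np
import pytest

import eegspect.classify as clf_mod
from eegspect.classify import (
    PairwiseComparison,
    SelectionConfig,
    accuracy_per_group,
    consolidate_votes,
    greedy_forward_select,
    max_chance,
    rank_by_ttest,
    train_svm,
)


def two_clouds(n=40, sep=4.0, d=3, seed=0):
    rng = np.random.default_rng(seed)
    Xa = rng.standard_normal((n, d))
    Xb = rng.standard_normal((n, d)) + sep
    X = np.vstack([Xa, Xb])
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


class TestSVM:
    def test_separable_clouds_perfect_training_accuracy(self):
        X, y = two_clouds(sep=6.0)
        clf = train_svm(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ValueError, match="two classes"):
            train_svm(X, np.array(["A"] * 10))

    def test_duplicating_training_points_keeps_decision(self):
        # in the separable regime the margin solution ignores multiplicity
        X, y = two_clouds(sep=8.0, seed=3)
        probe, _ = two_clouds(n=25, sep=8.0, seed=4)
        p1 = train_svm(X, y).predict(probe)
        p2 = train_svm(np.vstack([X, X]), np.concatenate([y, y])).predict(probe)
        assert np.array_equal(p1, p2)

    def test_label_independent_features_near_chance(self):
        """Permutation null: held-out accuracy ~ 0.5 over random relabelings."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 5))
        accs = []
        for _ in range(10):
            y = np.array(["A", "B"])[rng.permutation(200) % 2]
            clf = train_svm(X[:150], y[:150])
            accs.append((clf.predict(X[150:]) == y[150:]).mean())
        assert abs(np.mean(accs) - 0.5) < 0.1


class TestRanking:
    def test_informative_feature_ranked_first(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((200, 50))
        y = np.array(["A"] * 100 + ["B"] * 100)
        X[y == "B", 17] += 5.0  # 5-sd separation
        order, p = rank_by_ttest(X, y, ("A", "B"))
        assert order[0] == 17

    def test_output_is_permutation(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 12))
        y = np.array(["A"] * 15 + ["B"] * 15)
        order, p = rank_by_ttest(X, y, ("A", "B"))
        assert sorted(order) == list(range(12))
        assert len(p) == 12

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(8)
        tops = set()
        for seed in range(8):
            X = rng.standard_normal((60, 40))
            y = np.array(["A"] * 30 + ["B"] * 30)
            order, p = rank_by_ttest(X, y, ("A", "B"))
            tops.add(int(order[0]))
            assert 0.2 < np.mean(p) < 0.8
        assert len(tops) > 1  # not systematically the same winner

    def test_zero_variance_feature_gets_p_one(self):
        X = np.random.default_rng(9).standard_normal((20, 3))
        X[:, 1] = 2.5
        y = np.array(["A"] * 10 + ["B"] * 10)
        order, p = rank_by_ttest(X, y, ("A", "B"))
        assert p[1] == 1.0
        assert order[-1] == 1 or p[order[-1]] == 1.0

    def test_small_groups_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match=">= 2"):
            rank_by_ttest(X, np.array(["A", "A", "B"]), ("A", "B"))


class TestGreedySelection:
    def _config(self, **kw):
        return SelectionConfig(**kw)

    def test_single_feature_forced_choice(self):
        X, y = two_clouds(n=60, sep=2.0, d=1, seed=10)
        cfg = self._config()
        sel = greedy_forward_select(
            X, y, ("A", "B"), np.array([0]), cfg, np.random.default_rng(0)
        )
        assert sel == [0]

    def test_stall_rule_halts_after_ten_percent_rejections(self, monkeypatch):
        """1000 features, stall fraction 0.10 -> stop after 100 rejections."""
        evaluated = []

        def fake_scores(X, y, pair, feat_idx, folds, C, standardize):
            evaluated.append(tuple(feat_idx))
            # first vector sets the bar; every candidate afterwards is worse
            if len(feat_idx) == 1:
                return Fraction(9, 10), Fraction(9, 10), Fraction(9, 10)
            return Fraction(1, 10), Fraction(1, 10), Fraction(1, 10)

        monkeypatch.setattr(clf_mod, "_inner_cv_scores", fake_scores)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 1000))
        y = np.array(["A"] * 20 + ["B"] * 20)
        sel = greedy_forward_select(
            X, y, ("A", "B"), np.arange(1000), self._config(), rng
        )
        assert sel == [0]
        # 1 initial evaluation + exactly 100 rejected candidates
        assert len(evaluated) == 101

    def test_growth_cap_enforced(self, monkeypatch):
        accs = iter(range(1, 2000))

        def improving(X, y, pair, feat_idx, folds, C, standardize):
            a = Fraction(next(accs), 2000)
            return a, a, a

        monkeypatch.setattr(clf_mod, "_inner_cv_scores", improving)
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 200))
        y = np.array(["A"] * 20 + ["B"] * 20)
        sel = greedy_forward_select(
            X, y, ("A", "B"), np.arange(200), self._config(), rng
        )
        assert len(sel) == 40  # growth cap

    def test_recovers_informative_features(self):
        """3 informative among 100 noise features are found in >= 8/10 runs."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((120, 103))
            y = np.array(["A"] * 60 + ["B"] * 60)
            informative = [10, 50, 90]
            for k, f in enumerate(informative):
                X[y == "B", f] += 3.0 + 0.5 * k
            order, _ = rank_by_ttest(X, y, ("A", "B"))
            sel = greedy_forward_select(
                X, y, ("A", "B"), order, self._config(), rng
            )
            if set(informative) <= set(sel):
                hits += 1
        assert hits >= 8


class TestVotes:
    def _cfg(self):
        return SelectionConfig()

    def test_unanimity(self):
        final = consolidate_votes([[7]] * 10, self._cfg())
        assert final == [7]

    def test_fallback_to_two_votes(self):
        sels = [[3], [3]] + [[i + 10] for i in range(8)]
        final = consolidate_votes(sels, self._cfg())
        assert final[0] == 3

    def test_fallback_to_one_vote(self):
        sels = [[i] for i in range(10)]
        final = consolidate_votes(sels, self._cfg())
        assert set(final) == set(range(10))

    def test_cap_at_41_most_voted(self):
        # 50 features each selected in >= 3 folds
        sels = [[f for f in range(50)] for _ in range(3)] + [[]] * 7
        with pytest.raises(ValueError, match="empty"):
            consolidate_votes([[]] * 10, self._cfg())
        final = consolidate_votes(sels, self._cfg())
        assert len(final) == 41

    def test_wrong_fold_count_rejected(self):
        with pytest.raises(ValueError, match="10"):
            consolidate_votes([[1]] * 4, self._cfg())


class TestMetrics:
    def test_all_correct(self):
        pred = np.array(["A", "A", "B"])
        assert accuracy_per_group(pred, pred, ("A", "B")) == (1.0, 1.0)

    def test_counting_example(self):
        labels = np.array(["A"] * 4 + ["B"] * 5)
        pred = np.array(["A", "A", "A", "B"] + ["A"] * 5)
        acc = accuracy_per_group(pred, labels, ("A", "B"))
        assert acc == (0.75, 0.0)

    def test_overall_is_size_weighted_mean(self):
        rng = np.random.default_rng(11)
        labels = np.array(["A"] * 7 + ["B"] * 13)
        pred = np.where(rng.random(20) < 0.6, labels, "A")
        a1, a2 = accuracy_per_group(pred, labels, ("A", "B"))
        overall = (pred == labels).mean()
        assert overall == pytest.approx((7 * a1 + 13 * a2) / 20)

    def test_empty_group_flagged(self):
        acc = accuracy_per_group(np.array(["A"]), np.array(["A"]), ("A", "B"))
        assert acc[0] == 1.0 and np.isnan(acc[1])

    @pytest.mark.parametrize(
        "n1,n2,expected",
        [(41, 71, 0.63), (71, 69, 0.51), (10, 10, 0.5),
         (41, 39, 0.51), (41, 69, 0.63), (71, 39, 0.65), (39, 69, 0.64)],
    )
    def test_max_chance(self, n1, n2, expected):
        assert round(max_chance(n1, n2), 2) == expected


@pytest.fixture(scope="module")
def informative_problem():
    """39 vs 41 subjects, 12 features of which 3 separate the groups."""
    rng = np.random.default_rng(77)
    n1, n2 = 41, 39
    X = rng.standard_normal((n1 + n2, 12))
    y = np.array(["aSCC"] * n1 + ["AD"] * n2)
    for k, f in enumerate((2, 5, 9)):
        X[y == "AD", f] += 2.5
    return X, y


class TestPairwiseComparison:
    def test_outer_training_set_size_72(self, informative_problem):
        """90/10 split of 41+39 subjects trains on 72."""
        X, y = informative_problem
        res = PairwiseComparison(X, y, ("aSCC", "AD")).fit(seed=5)
        assert res.n_train == 72
        assert res.n_test == 8
        assert res.chance_level == pytest.approx(41 / 80)

    def test_no_leakage_of_outer_test_subjects(self, informative_problem):
        """Outer-test subjects never enter ranking/inner CV (fold logs)."""
        X, y = informative_problem
        res = PairwiseComparison(X, y, ("aSCC", "AD")).fit(seed=6)
        test_set = set(res.outer_test_indices.tolist())
        train_set = set(res.outer_train_indices.tolist())
        assert not test_set & train_set
        assert len(res.middle_fold_train_indices) == 10
        for fold_train in res.middle_fold_train_indices:
            assert not test_set & set(fold_train.tolist())
            assert set(fold_train.tolist()) <= train_set

    def test_final_feature_list_capped(self, informative_problem):
        X, y = informative_problem
        res = PairwiseComparison(X, y, ("aSCC", "AD")).fit(seed=7)
        assert 1 <= len(res.final_features) <= 41

    def test_determinism(self, informative_problem):
        X, y = informative_problem
        r1 = PairwiseComparison(X, y, ("aSCC", "AD")).fit(seed=8)
        r2 = PairwiseComparison(X, y, ("aSCC", "AD")).fit(seed=8)
        assert r1.overall_accuracy == r2.overall_accuracy
        assert r1.final_features == r2.final_features
        assert r1.per_fold_selections == r2.per_fold_selections

    def test_informative_problem_beats_chance(self, informative_problem):
        X, y = informative_problem
        res = PairwiseComparison(X, y, ("aSCC", "AD")).fit(seed=9)
        assert res.overall_accuracy > res.chance_level

    def test_too_small_groups_reported(self):
        X = np.random.default_rng(0).standard_normal((12, 4))
        y = np.array(["A"] * 6 + ["B"] * 6)
        with pytest.raises(ValueError, match="too small"):
            PairwiseComparison(X, y, ("A", "B"))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="outer_test_fraction"):
            SelectionConfig(outer_test_fraction=1.5)
        with pytest.raises(ValueError, match="decreasing"):
            SelectionConfig(vote_thresholds=(1, 2, 3))
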