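"""Metrics, chance-level calibration, Wilcoxon test, evaluation protocols."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from playaffect.dataset import FeatureSetSpec
from playaffect.evaluation import (
    chance_threshold,
    classification_metrics,
    cohort_summary,
    cross_game_evaluate,
    losocv_evaluate,
    wilcoxon_signed_rank,
)
from playaffect.exceptions import InvalidInputError, ProtocolError

from conftest import separable_samples

FEATURES = ("F1", "F2", "F3", "F4")
SPEC = FeatureSetSpec("TEST", FEATURES)


class TestMetrics:
    def test_all_correct(self):
        m = classification_metrics(["stress", "boredom"] * 3, ["stress", "boredom"] * 3)
        assert all(v == 1.0 for v in m.values())

    def test_hand_computed_confusion_table(self):
        # stress positive: TP=3, FP=1, FN=2, TN=4
        labels = ["stress"] * 5 + ["boredom"] * 5
        preds = (["stress"] * 3 + ["boredom"] * 2) + (["stress"] * 1 + ["boredom"] * 4)
        m = classification_metrics(preds, labels)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["precision_stress"] == pytest.approx(3 / 4)
        assert m["recall_stress"] == pytest.approx(3 / 5)
        assert m["f1_stress"] == pytest.approx(2 * 0.75 * 0.6 / (0.75 + 0.6))

    def test_degenerate_all_one_class_prediction(self):
        labels = ["stress", "boredom"] * 4
        m = classification_metrics(["stress"] * 8, labels)
        assert m["accuracy"] == 0.5
        assert m["recall_stress"] == 1.0
        assert m["recall_boredom"] == 0.0
        assert m["precision_boredom"] == 0.0  # zero-denominator convention

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            classification_metrics([], [])


def enumerate_chance_threshold(n, c, alpha, convention):
    """Independent oracle: explicit probability sums with exact rationals."""
    from fractions import Fraction

    p = Fraction(1, c)
    pmf = [math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]
    if convention == "inverse_cdf":
        acc = Fraction(0)
        for k in range(n + 1):
            acc += pmf[k]
            if acc >= 1 - Fraction(alpha).limit_denominator(10**6):
                return k
    else:
        for k in range(n + 1):
            tail = sum(pmf[k:], Fraction(0))
            if tail <= Fraction(alpha).limit_denominator(10**6):
                return k
    raise AssertionError("no threshold")


class TestChanceLevel:
    @pytest.mark.parametrize("n", [10, 33, 64, 100])
    @pytest.mark.parametrize("convention", ["inverse_cdf", "strict_tail"])
    def test_matches_exact_enumeration(self, n, convention):
        res = chance_threshold(n, 2, 0.05, convention)
        assert res.k_min == enumerate_chance_threshold(n, 2, 0.05, convention)
        assert res.threshold_exact == pytest.approx(100 * res.k_min / n)
        assert res.threshold_floor_pct == math.floor(res.threshold_exact)

    def test_balanced_two_class_n64_prints_60_percent(self):
        res = chance_threshold(64, 2, 0.05)
        assert res.threshold_floor_pct == 60
        assert res.k_min == 39
        assert res.threshold_exact == pytest.approx(60.9375)

    def test_strict_tail_n10(self):
        res = chance_threshold(10, 2, 0.05, convention="strict_tail")
        # P(X >= 9) = 11/1024 <= 0.05 < P(X >= 8)
        assert res.k_min == 9 and res.threshold_exact == pytest.approx(90.0)

    def test_large_n_approaches_even_odds(self):
        res = chance_threshold(10**6, 2, 0.05)
        assert abs(res.threshold_exact - 50.0) <= 0.2

    @given(n=st.integers(5, 400))
    @settings(deadline=None, max_examples=60)
    def test_threshold_above_even_odds_and_monotone(self, n):
        a = chance_threshold(n, 2, 0.05)
        b = chance_threshold(n + 50, 2, 0.05)
        assert a.threshold_exact >= 50.0
        assert b.threshold_exact <= a.threshold_exact + 1e-9
        stricter = chance_threshold(n, 2, 0.01)
        assert stricter.threshold_exact >= a.threshold_exact - 1e-9

    def test_invalid_parameters(self):
        for bad in [(0, 2, 0.05), (10, 1, 0.05), (10, 2, 0.0), (10, 2, 1.0)]:
            with pytest.raises(InvalidInputError):
                chance_threshold(*bad)


def exhaustive_signflip_p(d):
    """Oracle: two-sided p over all 2^n sign assignments of |d| ranks."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    n = len(d)
    mu = ranks.sum() / 2.0
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product((0.0, 1.0), repeat=n):
        w = float(np.dot(signs, ranks))
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.z == 0.0 and res.p == 1.0 and res.n_used == 0

    def test_antisymmetric_differences_z_zero(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [0.0, 3.0, 2.0, 5.0, 4.0, 7.0]  # differences +1, -1, +1, -1, +1, -1
        res = wilcoxon_signed_rank(x, y)
        assert res.z == 0.0 and res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.4, 1.0, 12)
        y = rng.normal(0.0, 1.0, 12)
        res = wilcoxon_signed_rank(x, y)
        assert res.exact
        assert res.p == pytest.approx(exhaustive_signflip_p(x - y), abs=1e-6)

    def test_exact_p_with_tied_ranks(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = x - np.array([2.0, 2.0, -2.0, 3.0, 3.0, -3.0, 5.0])  # tied |d| groups
        res = wilcoxon_signed_rank(x, y)
        assert res.p == pytest.approx(exhaustive_signflip_p(x - y), abs=1e-6)

    def test_matches_scipy_exact_for_untied_data(self, rng):
        x = rng.normal(0.5, 1.0, 14)
        y = rng.normal(0.0, 1.0, 14)
        ours = wilcoxon_signed_rank(x, y)
        ref = scipy.stats.wilcoxon(x, y, mode="exact")
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_normal_approximation_for_large_n(self, rng):
        x = rng.normal(0.3, 1.0, 60)
        y = rng.normal(0.0, 1.0, 60)
        ours = wilcoxon_signed_rank(x, y)
        ref = scipy.stats.wilcoxon(x, y, mode="approx", correction=True)
        assert not ours.exact
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)
        assert 0.0 <= ours.r <= 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InvalidInputError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])


class TestProtocols:
    def test_losocv_three_folds_and_mean(self, fast_model_cfg):
        samples = separable_samples(n_per_class=30, separation=10.0)
        res = losocv_evaluate(samples, SPEC, fast_model_cfg, subject_id=1)
        assert len(res.fold_accuracies) == 3
        assert res.accuracy == pytest.approx(np.mean(res.fold_accuracies))
        assert res.accuracy >= 0.9  # strongly separated states

    def test_losocv_needs_three_games(self, fast_model_cfg):
        samples = separable_samples(games=("game1", "game2"))
        with pytest.raises(ProtocolError):
            losocv_evaluate(samples, SPEC, fast_model_cfg)

    def test_cross_game_perfect_on_matching_clusters(self, fast_model_cfg):
        train = separable_samples(n_per_class=30, separation=10.0)
        rng = np.random.default_rng(5)
        test = train.sample(20, random_state=1).copy()
        test["source"] = "level3"
        test.loc[:, FEATURES] += rng.normal(0, 0.1, (20, len(FEATURES)))
        res = cross_game_evaluate(train, test, SPEC, fast_model_cfg, subject_id=2)
        assert res.accuracy == 1.0

    def test_cross_game_single_class_test_set(self, fast_model_cfg):
        train = separable_samples(n_per_class=30, separation=10.0)
        test = train[train["label"] == "stress"].head(10).copy()
        test["source"] = "level3"
        res = cross_game_evaluate(train, test, SPEC, fast_model_cfg)
        assert res.accuracy == 1.0
        assert res.class_counts == {"stress": 10}

    def test_cross_game_empty_test_rejected(self, fast_model_cfg):
        train = separable_samples()
        with pytest.raises(ProtocolError):
            cross_game_evaluate(train, train.head(0), SPEC, fast_model_cfg)

    def test_cohort_summary_aggregates(self, fast_model_cfg):
        samples = separable_samples(n_per_class=30, separation=10.0)
        res = losocv_evaluate(samples, SPEC, fast_model_cfg, subject_id=1)
        summary = cohort_summary([res])
        assert summary["mean_accuracy"] == res.accuracy
        assert sum(summary["accuracy_histogram"]["counts"]) == 1
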