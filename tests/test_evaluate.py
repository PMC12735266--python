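"""Greedy point matching, detection scores, mean localization error."""

import numpy as np
import pytest
from itertools import combinations, permutations

from lfe.evaluate import (
    detection_scores,
    evaluation_report,
    match_points,
    mean_localization_error,
)


def nearest_first_oracle(gt, pred, thr):
    """Exhaustive reference: repeatedly consume the globally nearest free pair.

    Ties break on (distance, gt index, pred index).  Returns the matched pairs.
    """
    gt = np.asarray(gt, float).reshape(-1, 2)
    pred = np.asarray(pred, float).reshape(-1, 2)
    cand = [
        (float(np.linalg.norm(g - p)), gi, pi)
        for gi, g in enumerate(gt)
        for pi, p in enumerate(pred)
        if np.linalg.norm(g - p) < thr
    ]
    pairs = []
    used_g, used_p = set(), set()
    while True:
        free = [c for c in cand if c[1] not in used_g and c[2] not in used_p]
        if not free:
            return pairs
        d, gi, pi = min(free)
        pairs.append((gi, pi, d))
        used_g.add(gi)
        used_p.add(pi)


def max_cardinality_tp(gt, pred, thr):
    """Brute-force maximum one-to-one matching size with all distances < thr."""
    gt = np.asarray(gt, float).reshape(-1, 2)
    pred = np.asarray(pred, float).reshape(-1, 2)
    if len(gt) == 0 or len(pred) == 0:
        return 0
    d = np.sqrt(((gt[:, None] - pred[None]) ** 2).sum(-1))
    for k in range(min(len(gt), len(pred)), 0, -1):
        for gs in combinations(range(len(gt)), k):
            for ps in permutations(range(len(pred)), k):
                if all(d[g, p] < thr for g, p in zip(gs, ps)):
                    return k
    return 0


class TestMatchPoints:
    def test_identical_points_all_matched_at_zero(self):
        pts = np.array([[1.0, 2.0], [5.0, 5.0], [9.0, 1.0]])
        m = match_points(pts, pts, threshold=6)
        assert m.tp == 3 and m.fp == 0 and m.fn == 0
        assert all(d == 0 for _, _, d in m.pairs)

    def test_nearest_wins_spare_becomes_fp(self):
        m = match_points([(0.0, 0.0)], [(0.0, 5.0), (0.0, 7.0)], threshold=6)
        assert m.tp == 1 and m.fp == 1 and m.fn == 0
        assert m.pairs[0] == (0, 0, pytest.approx(5.0))

    def test_crossing_two_by_two_matches_min_total_distance(self):
        gt = [(0.0, 0.0), (0.0, 3.0)]
        pred = [(0.0, 1.0), (0.0, 2.0)]
        m = match_points(gt, pred, threshold=6)
        # straight pairing (total 2) beats crossing (total 4)
        assert sorted((g, p) for g, p, _ in m.pairs) == [(0, 0), (1, 1)]

    def test_strictly_inside_threshold(self):
        m = match_points([(0.0, 0.0)], [(0.0, 6.0)], threshold=6)
        assert m.tp == 0 and m.fp == 1 and m.fn == 1

    def test_counts_partition_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            gt = rng.uniform(0, 20, (rng.integers(0, 6), 2))
            pred = rng.uniform(0, 20, (rng.integers(0, 6), 2))
            m = match_points(gt, pred, threshold=5)
            assert m.tp + m.fn == len(gt)
            assert m.tp + m.fp == len(pred)
            assert all(d < 5 for _, _, d in m.pairs)

    def test_equals_exhaustive_nearest_first_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            gt = rng.uniform(0, 12, (rng.integers(0, 4), 2))
            pred = rng.uniform(0, 12, (rng.integers(0, 4), 2))
            m = match_points(gt, pred, threshold=6)
            oracle = nearest_first_oracle(gt, pred, 6)
            assert sorted((g, p) for g, p, _ in m.pairs) == sorted(
                (g, p) for g, p, _ in oracle
            )

    def test_greedy_within_one_of_maximum_matching(self):
        """Greedy is maximal, hence at most one short of optimal on ≤3×3."""
        rng = np.random.default_rng(2)
        short = 0
        for _ in range(500):
            gt = rng.uniform(0, 12, (rng.integers(0, 4), 2))
            pred = rng.uniform(0, 12, (rng.integers(0, 4), 2))
            tp = match_points(gt, pred, threshold=6).tp
            opt = max_cardinality_tp(gt, pred, 6)
            assert opt - 1 <= tp <= opt
            short += opt - tp
        assert short < 25  # rare in practice

    def test_hungarian_variant_maximizes_cardinality(self):
        gt = [(0.0, 0.0), (3.0, 0.0)]
        pred = [(1.0, 0.0), (-3.0, 0.0)]
        greedy = match_points(gt, pred, threshold=6, method="greedy")
        hung = match_points(gt, pred, threshold=6, method="hungarian")
        assert greedy.tp == 1  # nearest-first blocks the second pair
        assert hung.tp == 2


class TestDetectionScores:
    def test_perfect(self):
        m = match_points([(1.0, 1.0)], [(1.0, 1.0)], 6)
        assert detection_scores(m) == (1.0, 1.0, 1.0)

    def test_half_precision(self):
        m = match_points([(0.0, 0.0)], [(0.0, 1.0), (19.0, 19.0)], 6)
        p, r, f1 = detection_scores(m)
        assert (p, r) == (0.5, 1.0)
        assert f1 == pytest.approx(2 / 3)

    def test_no_predictions(self):
        m = match_points([(0.0, 0.0)], np.empty((0, 2)), 6)
        p, r, f1 = detection_scores(m)
        assert (r, f1) == (0.0, 0.0)

    def test_both_empty(self):
        m = match_points(np.empty((0, 2)), np.empty((0, 2)), 6)
        assert detection_scores(m) == (1.0, 1.0, 1.0)

    def test_invariant_to_joint_permutation(self):
        rng = np.random.default_rng(3)
        gt = rng.uniform(0, 10, (5, 2))
        pred = rng.uniform(0, 10, (4, 2))
        base = detection_scores(match_points(gt, pred, 6))
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            shuffled = detection_scores(
                match_points(gt[r2.permutation(5)], pred[r2.permutation(4)], 6)
            )
            assert shuffled == pytest.approx(base)


class TestMeanLocalizationError:
    def test_perfect_is_zero(self):
        m = match_points([(2.0, 2.0)], [(2.0, 2.0)], 6)
        assert mean_localization_error(m) == 0.0

    def test_single_pair_distance(self):
        m = match_points([(0.0, 0.0)], [(0.0, 5.0)], 6)
        assert mean_localization_error(m) == pytest.approx(5.0)

    def test_unmatched_penalty(self):
        m = match_points([(0.0, 0.0), (0.0, 2.0), (50.0, 50.0)],
                         [(0.0, 0.0), (0.0, 6.0)], threshold=8)
        # distances {0, 4}, one unmatched gt with explicit penalty 16
        assert mean_localization_error(m, penalty=16) == pytest.approx((0 + 4 + 16) / 3)

    def test_default_penalty_is_threshold(self):
        m = match_points([(0.0, 0.0)], np.empty((0, 2)), threshold=6)
        assert mean_localization_error(m) == pytest.approx(6.0)

    def test_empty_undefined(self):
        m = match_points(np.empty((0, 2)), np.empty((0, 2)), 6)
        with pytest.raises(ValueError):
            mean_localization_error(m)


def test_evaluation_report_bundle():
    rep = evaluation_report([(0.0, 0.0)], [(0.0, 1.0)], threshold=6)
    assert rep["tp"] == 1 and rep["f1"] == 1.0
    assert rep["mle"] == pytest.approx(1.0)
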