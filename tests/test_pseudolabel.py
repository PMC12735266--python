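"""Pseudo-label partitioning and the positive–negative refinement loss."""

import numpy as np
import pytest

from lfe.bmm import BetaMixture, unlabeled_losses
from lfe.localize import PeakSet
from lfe.pseudolabel import (
    EmptyPositiveSetError,
    partition_unlabeled,
    pn_loss,
    pn_loss_grad,
)


def make_peaks(coords, posteriors):
    coords = np.asarray(coords, dtype=int).reshape(-1, 2)
    return PeakSet(
        coordinates=coords,
        values=np.ones(len(coords)),
        posteriors=np.asarray(posteriors, dtype=float),
    )


@pytest.fixture()
def grid():
    """7×7 count maps: one provided-positive block, one confident hidden object."""
    cgt = np.zeros((7, 7))
    cgt[1, 1] = 1.0  # provided positive entry
    mask = (cgt != 0).astype(float)
    cpre = np.zeros((7, 7))
    cpre[1, 1] = 1.0
    cpre[5, 5] = 0.9  # hidden object response
    cpre[5, 1] = 0.2  # weak response
    return cpre, cgt, mask


class TestPartition:
    def test_disjoint_cover(self, grid):
        cpre, cgt, mask = grid
        losses = unlabeled_losses(cpre, cgt)
        peaks = make_peaks([(5, 5), (5, 1)], [0.99, 0.5])
        part = partition_unlabeled(peaks, losses, mask)
        seen = {}
        for name, coords in part.sets().items():
            for rc in map(tuple, coords):
                assert rc not in seen, f"{rc} in both {seen.get(rc)} and {name}"
                seen[rc] = name
        assert len(seen) == 49

    def test_confident_peak_becomes_predicted_positive(self, grid):
        cpre, cgt, mask = grid
        part = partition_unlabeled(
            make_peaks([(5, 5)], [0.99]), unlabeled_losses(cpre, cgt), mask,
            tau_pos=0.95,
        )
        assert (5, 5) in set(map(tuple, part.predicted_pos))

    def test_intermediate_posterior_ignored(self, grid):
        cpre, cgt, mask = grid
        part = partition_unlabeled(
            make_peaks([(5, 5)], [0.5]), unlabeled_losses(cpre, cgt), mask
        )
        assert (5, 5) in set(map(tuple, part.ignored))

    def test_low_posterior_predicted_negative(self, grid):
        cpre, cgt, mask = grid
        part = partition_unlabeled(
            make_peaks([(5, 5)], [0.01]), unlabeled_losses(cpre, cgt), mask
        )
        assert (5, 5) in set(map(tuple, part.predicted_neg))

    def test_provided_labels_win_over_peaks(self, grid):
        cpre, cgt, mask = grid
        part = partition_unlabeled(
            make_peaks([(1, 1)], [0.99]), unlabeled_losses(cpre, cgt), mask
        )
        assert (1, 1) in set(map(tuple, part.provided_pos))
        assert len(part.predicted_pos) == 0

    def test_peak_near_provided_positive_absorbed(self, grid):
        cpre, cgt, mask = grid
        cpre = cpre.copy()
        cpre[2, 2] = 0.8
        part = partition_unlabeled(
            make_peaks([(2, 2)], [0.99]), unlabeled_losses(cpre, cgt), mask,
            absorb_radius=4,
        )
        assert (2, 2) not in set(map(tuple, part.predicted_pos))

    def test_clear_negatives_from_zero_prediction(self, grid):
        _, cgt, mask = grid
        cpre = np.zeros((7, 7))
        cpre[5, 5] = 0.9  # keep one survivor so the loss set is not degenerate
        part = partition_unlabeled(
            make_peaks([], []), unlabeled_losses(cpre, cgt), mask
        )
        assert len(part.predicted_pos) == 0
        # everything unlabeled except the single survivor is a clear negative
        assert len(part.clear_neg) == 49 - 1 - 1

    def test_threshold_ordering_validated(self, grid):
        cpre, cgt, mask = grid
        with pytest.raises(ValueError):
            partition_unlabeled(
                make_peaks([], []), unlabeled_losses(cpre, cgt), mask,
                tau_pos=0.3, tau_neg=0.6,
            )

    def test_posteriors_from_mixture_when_not_given(self, grid):
        cpre, cgt, mask = grid
        losses = unlabeled_losses(cpre, cgt)
        mix = BetaMixture(weights=(0.5, 0.5), alphas=(2.0, 18.0), betas=(18.0, 2.0))
        peaks = PeakSet(
            coordinates=np.array([[5, 5]]), values=np.array([0.9]), posteriors=None
        )
        part = partition_unlabeled(peaks, losses, mask, mix=mix, tau_pos=0.9)
        # (5,5) has the largest loss -> normalized near 1 -> confidently noisy
        assert (5, 5) in set(map(tuple, part.predicted_pos))

    def test_oracle_posterior_recovers_full_positive_set(self):
        """With a perfect posterior, Φ+ equals the full true positive set."""
        cgt_full = np.zeros((9, 9))
        true_centers = [(2, 2), (6, 6), (2, 6)]
        for rc in true_centers:
            cgt_full[rc] = 1.0
        labeled = [(2, 2)]
        cgt = np.zeros((9, 9))
        for rc in labeled:
            cgt[rc] = 1.0
        mask = (cgt != 0).astype(float)
        cpre = cgt_full.copy()
        losses = unlabeled_losses(cpre, cgt)
        hidden = [rc for rc in true_centers if rc not in labeled]
        peaks = make_peaks(hidden, [1.0] * len(hidden))
        part = partition_unlabeled(peaks, losses, mask, tau_pos=0.95)
        phi_plus = set(map(tuple, part.provided_pos)) | set(
            map(tuple, part.predicted_pos)
        )
        assert phi_plus == set(true_centers)


class TestPNLoss:
    def build(self, cpre, peaks, posts, cgt, mask, **kw):
        return partition_unlabeled(
            make_peaks(peaks, posts), unlabeled_losses(cpre, cgt), mask, **kw
        )

    def test_zero_at_ideal_prediction(self, grid):
        cpre, cgt, mask = grid
        part = self.build(cpre, [(5, 5)], [0.99], cgt, mask)
        ideal = np.zeros((7, 7))
        for r, c in np.vstack([part.provided_pos, part.predicted_pos]):
            ideal[r, c] = 1.0
        assert pn_loss(ideal, part) == pytest.approx(0.0)

    def test_hand_value_single_positive_miss(self):
        cgt = np.zeros((5, 5))
        cgt[2, 2] = 1.0
        mask = (cgt != 0).astype(float)
        cpre_probe = np.zeros((5, 5))
        cpre_probe[0, 0] = 0.5  # a survivor so losses are not degenerate
        part = self.build(cpre_probe, [], [], cgt, mask, tau_pos=0.95)
        # evaluate the loss at an all-zero prediction: one Φ+ entry missed
        loss = pn_loss(np.zeros((5, 5)), part)
        assert loss == pytest.approx(1 / 25)

    def test_ignored_coordinates_do_not_contribute(self, grid):
        cpre, cgt, mask = grid
        with_ign = self.build(cpre, [(5, 5), (5, 1)], [0.99, 0.5], cgt, mask)
        without = self.build(cpre, [(5, 5)], [0.99], cgt, mask)
        probe = np.random.default_rng(0).random((7, 7))
        # (5,1) is ignored in the first partition, predicted-negative-free in both
        probe[5, 1] = 0.0
        assert pn_loss(probe, with_ign) == pytest.approx(pn_loss(probe, without))

    def test_monotone_toward_targets(self, grid):
        cpre, cgt, mask = grid
        part = self.build(cpre, [(5, 5)], [0.99], cgt, mask)
        probe = np.full((7, 7), 0.3)
        base = pn_loss(probe, part)
        up = probe.copy()
        up[5, 5] = 0.8  # Φ+ entry toward 1
        assert pn_loss(up, part) < base
        down = up.copy()
        down[3, 3] = 0.05  # Φ− entry toward 0
        assert pn_loss(down, part) < pn_loss(up, part)

    def test_empty_positive_set_raises(self):
        cgt = np.zeros((5, 5))
        cpre = np.zeros((5, 5))
        cpre[0, 0] = 0.5
        part = self.build(cpre, [], [], cgt, np.zeros((5, 5)))
        with pytest.raises(EmptyPositiveSetError):
            pn_loss(cpre, part)

    def test_gradient_matches_finite_differences(self, grid):
        cpre, cgt, mask = grid
        part = self.build(cpre, [(5, 5)], [0.99], cgt, mask)
        probe = np.random.default_rng(1).random((7, 7))
        _, grad = pn_loss_grad(probe, part)
        eps = 1e-6
        for idx in [(1, 1), (5, 5), (3, 3), (0, 6)]:
            hi, lo = probe.copy(), probe.copy()
            hi[idx] += eps
            lo[idx] -= eps
            fd = (pn_loss(hi, part) - pn_loss(lo, part)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-10)
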