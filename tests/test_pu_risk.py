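"""Non-negative PU risk: hand-computed values, clamp semantics, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfe.countmap import CountMapConfig
from lfe.pu_risk import (
    NoPositivesError,
    PURiskConfig,
    negative_risk_tanh,
    nonneg_pu_risk,
    nonneg_pu_risk_grad,
    positive_risk,
)


@pytest.fixture()
def toy():
    """5×5 toy: mask of 9 ones from a centered 3×3 window, unit targets."""
    cgt = np.zeros((5, 5))
    cgt[1:4, 1:4] = 1.0
    mask = (cgt != 0).astype(float)
    cfg = PURiskConfig(class_prior=0.1, kernel=CountMapConfig(3))
    return cgt, mask, cfg


class TestPositiveRisk:
    def test_zero_when_prediction_matches_on_mask(self, toy):
        cgt, mask, _ = toy
        assert positive_risk(cgt.copy(), cgt, mask) == 0.0

    def test_unit_residuals_give_one(self, toy):
        cgt, mask, _ = toy
        assert positive_risk(np.zeros((5, 5)), cgt, mask) == pytest.approx(1.0)

    def test_quadratic_scaling(self, toy):
        cgt, mask, _ = toy
        base = positive_risk(np.zeros((5, 5)), cgt, mask)
        doubled = positive_risk(-cgt, cgt, mask)  # residual doubled on mask
        assert doubled == pytest.approx(4 * base)

    def test_empty_mask_raises(self, toy):
        cgt, _, _ = toy
        with pytest.raises(NoPositivesError):
            positive_risk(cgt, cgt, np.zeros((5, 5)))


class TestNegativeRiskTanh:
    def test_zero_prediction_gives_zero(self, toy):
        _, mask, cfg = toy
        assert negative_risk_tanh(np.zeros((5, 5)), mask, cfg) == 0.0

    def test_single_off_mask_entry(self, toy):
        _, mask, cfg = toy
        cpre = np.zeros((5, 5))
        cpre[0, 0] = 1.0  # off the mask
        expected = np.tanh(1.0) / 25
        assert negative_risk_tanh(cpre, mask, cfg) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.030464, abs=1e-6)

    def test_single_on_mask_entry(self, toy):
        _, mask, cfg = toy
        cpre = np.zeros((5, 5))
        cpre[2, 2] = 1.0  # on the mask
        expected = np.tanh(1.0) / 25 - 0.1 * np.tanh(1.0) / 9
        assert negative_risk_tanh(cpre, mask, cfg) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.0220017, abs=1e-6)

    def test_empty_mask_drops_correction_term(self, toy):
        _, _, cfg = toy
        cpre = np.full((5, 5), 2.0)
        val = negative_risk_tanh(cpre, np.zeros((5, 5)), cfg)
        assert val == pytest.approx(np.tanh(2.0))


class TestNonnegPURisk:
    def test_zero_prediction_total(self, toy):
        cgt, mask, cfg = toy
        risk = nonneg_pu_risk(np.zeros((5, 5)), cgt, mask, cfg)
        assert risk.total == pytest.approx(0.1)
        assert not risk.clamped

    def test_clamp_engages_when_negative_term_negative(self, toy):
        _, _, cfg = toy
        # sparse grid (N_p/N < π_p) with responses concentrated on the mask:
        # the subtracted term dominates and the estimate goes negative
        cgt = np.zeros((25, 25))
        cgt[11:14, 11:14] = 1.0
        mask = (cgt != 0).astype(float)
        cpre = 3.0 * mask
        risk = nonneg_pu_risk(cpre, cgt, mask, cfg)
        assert risk.negative_term < 0
        assert risk.clamped
        assert risk.total == pytest.approx(cfg.class_prior * risk.positive_term)

    def test_total_lower_bounded_by_positive_part(self, toy):
        cgt, mask, cfg = toy
        rng = np.random.default_rng(0)
        for _ in range(20):
            cpre = rng.random((5, 5)) * 3
            risk = nonneg_pu_risk(cpre, cgt, mask, cfg)
            assert risk.total >= cfg.class_prior * risk.positive_term - 1e-12
            if not risk.clamped:
                assert risk.total == pytest.approx(
                    cfg.class_prior * risk.positive_term + risk.negative_term
                )

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 1000))
    def test_invariant_to_permuting_unlabeled_entries(self, seed):
        cgt = np.zeros((5, 5))
        cgt[1:4, 1:4] = 1.0
        mask = (cgt != 0).astype(float)
        cfg = PURiskConfig(class_prior=0.1, kernel=CountMapConfig(3))
        rng = np.random.default_rng(seed)
        cpre = rng.random((5, 5))
        unl = np.argwhere(mask == 0)
        perm = rng.permutation(len(unl))
        cpre2 = cpre.copy()
        cpre2[unl[:, 0], unl[:, 1]] = cpre[unl[perm, 0], unl[perm, 1]]
        a = nonneg_pu_risk(cpre, cgt, mask, cfg)
        b = nonneg_pu_risk(cpre2, cgt, mask, cfg)
        assert a.total == pytest.approx(b.total, abs=1e-12)

    def test_subtracted_term_monotone_in_prior(self, toy):
        cgt, mask, _ = toy
        rng = np.random.default_rng(1)
        cpre = rng.random((5, 5)) * 2
        kernel = CountMapConfig(3)
        priors = [0.05, 0.1, 0.3, 0.6]
        negs = [
            negative_risk_tanh(cpre, mask, PURiskConfig(p, kernel)) for p in priors
        ]
        assert all(a > b for a, b in zip(negs, negs[1:]))

    def test_gradient_matches_finite_differences(self, toy):
        cgt, mask, cfg = toy
        rng = np.random.default_rng(2)
        cpre = rng.random((5, 5)) * 2
        _, grad = nonneg_pu_risk_grad(cpre, cgt, mask, cfg)
        eps = 1e-6
        for idx in [(0, 0), (2, 2), (1, 3), (4, 4)]:
            hi = cpre.copy()
            hi[idx] += eps
            lo = cpre.copy()
            lo[idx] -= eps
            fd = (
                nonneg_pu_risk(hi, cgt, mask, cfg).total
                - nonneg_pu_risk(lo, cgt, mask, cfg).total
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_clamped_gradient_is_positive_part_only(self, toy):
        _, _, cfg = toy
        cgt = np.zeros((25, 25))
        cgt[11:14, 11:14] = 1.0
        mask = (cgt != 0).astype(float)
        cpre = 3.0 * mask
        risk, grad = nonneg_pu_risk_grad(cpre, cgt, mask, cfg)
        assert risk.clamped
        expected = cfg.class_prior * 2 / 9 * (cpre - cgt) * mask
        np.testing.assert_allclose(grad, expected)

    def test_batched_maps_count_every_entry(self, toy):
        """N spans all images in a stacked batch, N_p all masked entries."""
        cgt, mask, cfg = toy
        cgt_b = np.stack([cgt, np.zeros((5, 5))])
        mask_b = np.stack([mask, np.zeros((5, 5))])
        cpre_b = np.zeros((2, 5, 5))
        cpre_b[1, 0, 0] = 1.0
        risk = nonneg_pu_risk(cpre_b, cgt_b, mask_b, cfg)
        assert risk.negative_term == pytest.approx(np.tanh(1.0) / 50)
        assert risk.positive_term == pytest.approx(1.0)
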