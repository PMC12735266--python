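"""Non-negative positive-unlabeled risk over redundant count maps.

Only the windows around the few provided point annotations are known positives;
every other count-map entry is unlabeled (background *or* an unannotated
object).  The PU risk combines an L2 fit on the known-positive windows with a
de-biased negative risk on everything, clamped at zero so that a flexible
predictor cannot drive the estimated negative risk below its true minimum and
overfit.  tanh replaces the plain L2 in the negative term because it saturates:
large responses at hidden objects are penalized no harder than moderate ones,
which suppresses background noise without erasing true targets.

All functions also expose the gradient with respect to the predicted count map
so the trainer can backpropagate through the (linear, self-adjoint) count-map
operator into the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .countmap import CountMapConfig

__all__ = [
    "PURiskConfig",
    "RiskValue",
    "positive_risk",
    "negative_risk_tanh",
    "nonneg_pu_risk",
    "nonneg_pu_risk_grad",
    "NoPositivesError",
]


class NoPositivesError(ValueError):
    """Raised when a batch contains no positive count-map entries (N_p = 0)."""


@dataclass(frozen=True)
class PURiskConfig:
    """Class prior and kernel for the PU risk.

    ``class_prior`` is π_p, the marginal probability that a count-map entry is
    positive.  A fixed 0.1 works across datasets; ``countmap.estimate_class_prior``
    gives the principled per-dataset estimate μr²/(ωh).
    """

    class_prior: float = 0.1
    kernel: CountMapConfig = CountMapConfig(7)

    def __post_init__(self) -> None:
        if not (0.0 < self.class_prior < 1.0):
            raise ValueError(f"class_prior must be in (0, 1), got {self.class_prior}")


@dataclass(frozen=True)
class RiskValue:
    """Decomposed non-negative PU risk.

    ``total = π_p · positive_term + max(0, negative_term)``; ``clamped`` records
    whether the clamp was active (negative_term < 0).
    """

    total: float
    positive_term: float
    negative_term: float
    clamped: bool


def _as_maps(*arrays: np.ndarray) -> list[np.ndarray]:
    out = [np.asarray(a, dtype=float) for a in arrays]
    shapes = {a.shape for a in out}
    if len(shapes) != 1:
        raise ValueError(f"count map / mask shapes differ: {sorted(shapes)}")
    return out


def positive_risk(cpre: np.ndarray, cgt: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared count error over the known-positive entries.

    R̂p+ = (1/N_p) ‖(C_pre − C̃_gt) ⊙ M‖²_F.  Raises :class:`NoPositivesError`
    when the mask is empty; the caller should skip such a batch.
    """
    cpre, cgt, mask = _as_maps(cpre, cgt, mask)
    n_p = float(np.sum(mask != 0))
    if n_p == 0:
        raise NoPositivesError("positive risk undefined: mask has no positive entries")
    resid = (cpre - cgt) * (mask != 0)
    return float(np.sum(resid**2) / n_p)


def negative_risk_tanh(
    cpre: np.ndarray, mask: np.ndarray, cfg: PURiskConfig
) -> float:
    """De-biased negative risk with tanh saturation.

    R̂u− − π_p R̂p− = (1/N) Σ tanh(C_pre) − (π_p/N_p) Σ tanh(C_pre)⊙M, where N is
    the total number of count-map entries.  When N_p = 0 the correction term is
    defined as 0 (an all-unlabeled batch still contributes the first term).
    """
    cpre, mask = _as_maps(cpre, mask)
    n = cpre.size
    n_p = float(np.sum(mask != 0))
    t = np.tanh(cpre)
    first = float(np.sum(t) / n)
    if n_p == 0:
        return first
    return first - cfg.class_prior / n_p * float(np.sum(t * (mask != 0)))


def nonneg_pu_risk(
    cpre: np.ndarray, cgt: np.ndarray, mask: np.ndarray, cfg: PURiskConfig
) -> RiskValue:
    """Non-negative PU risk: π_p R̂p+ + max(0, R̂u− − π_p R̂p−)."""
    pos = positive_risk(cpre, cgt, mask)
    neg = negative_risk_tanh(cpre, mask, cfg)
    clamped = neg < 0.0
    total = cfg.class_prior * pos + max(0.0, neg)
    return RiskValue(total=float(total), positive_term=pos, negative_term=neg, clamped=clamped)


def nonneg_pu_risk_grad(
    cpre: np.ndarray, cgt: np.ndarray, mask: np.ndarray, cfg: PURiskConfig
) -> tuple[RiskValue, np.ndarray]:
    """Risk and its gradient with respect to the predicted count map.

    The clamp passes zero gradient when active (plain subgradient of max).
    """
    risk = nonneg_pu_risk(cpre, cgt, mask, cfg)
    cpre_a, cgt_a, mask_a = _as_maps(cpre, cgt, mask)
    m = (mask_a != 0).astype(float)
    n_p = m.sum()
    n = cpre_a.size
    grad = cfg.class_prior * 2.0 / n_p * (cpre_a - cgt_a) * m
    if not risk.clamped:
        sech2 = 1.0 - np.tanh(cpre_a) ** 2
        grad = grad + sech2 / n
        if n_p > 0:
            grad = grad - cfg.class_prior / n_p * sech2 * m
    return risk, grad
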