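"""Pseudo-labeling: turn unlabeled count-map entries into usable labels.

After PU training, the unlabeled region Φu is split into three groups using the
beta-mixture posterior of each local maximum of the predicted location map:
clear negatives (tiny losses — confidently background), predicted positives
(peaks whose posterior of being a hidden object exceeds a confidence threshold),
and predicted negatives (everything else).  Peaks with intermediate posteriors
are *ignored* rather than guessed, since an injected false positive harms
training more than a skipped true one.  Together with the provided positives Φp
this enables an ordinary positive–negative refinement stage with an L2-tanh loss
that preserves count information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bmm import CLEAR_NEGATIVE_THRESHOLD, BetaMixture, UnlabeledLossSet, posterior_noisy
from .localize import PeakSet

__all__ = ["PseudoLabelPartition", "partition_unlabeled", "pn_loss", "pn_loss_grad",
           "EmptyPositiveSetError"]


class EmptyPositiveSetError(ValueError):
    """Raised when a partition has no positives at all (training would collapse)."""


@dataclass(frozen=True)
class PseudoLabelPartition:
    """Disjoint label sets over count-map coordinates.

    ``provided_pos`` (Φp, from the annotation mask), ``clear_neg`` (Φclr−),
    ``predicted_pos`` (Φpre+), ``predicted_neg`` (Φpre−) and ``ignored`` — each
    an (n, 2) integer coordinate array.  The five sets are pairwise disjoint and
    cover the grid.
    """

    shape: tuple[int, int]
    provided_pos: np.ndarray
    clear_neg: np.ndarray
    predicted_pos: np.ndarray
    predicted_neg: np.ndarray
    ignored: np.ndarray

    def sets(self) -> dict[str, np.ndarray]:
        return {
            "provided_pos": self.provided_pos,
            "clear_neg": self.clear_neg,
            "predicted_pos": self.predicted_pos,
            "predicted_neg": self.predicted_neg,
            "ignored": self.ignored,
        }

    def to_dataframe(self):
        """Audit dump: one row per coordinate with its set name."""
        import pandas as pd

        rows = [
            (int(r), int(c), name)
            for name, coords in self.sets().items()
            for r, c in coords
        ]
        return pd.DataFrame(rows, columns=["row", "col", "set"])


def partition_unlabeled(
    peaks: PeakSet,
    losses: UnlabeledLossSet,
    mask: np.ndarray,
    tau_pos: float = 0.95,
    tau_neg: float = 0.05,
    mix: BetaMixture | None = None,
    absorb_radius: int | None = None,
) -> PseudoLabelPartition:
    """Partition the count-map grid into pseudo-label sets.

    Mask ones become Φp (provided labels always win, even where a peak
    coincides).  Unlabeled coordinates with raw loss below the clear-negative
    threshold become Φclr−.  Peaks are scored either by ``peaks.posteriors`` or
    by evaluating ``mix`` on their normalized losses: posterior ≥ tau_pos →
    Φpre+, ≤ tau_neg → Φpre−, in between → ignored.  Remaining unlabeled
    non-peak coordinates go to Φpre−.  Peaks within ``absorb_radius`` (Chebyshev,
    default ⌈r/2⌉ handled by the caller via this argument) of a provided
    positive are absorbed into Φp rather than double-counted.
    """
    if not (0.0 <= tau_neg <= tau_pos <= 1.0):
        raise ValueError(f"need 0 <= tau_neg <= tau_pos <= 1, got {tau_neg}, {tau_pos}")
    mask_a = np.asarray(mask) != 0
    shape = mask_a.shape
    label = np.full(shape, -1, dtype=np.int8)  # -1 unset
    P_PROV, C_NEG, P_POS, P_NEG, IGN = 0, 1, 2, 3, 4
    label[mask_a] = P_PROV

    raw_grid = np.zeros(shape)
    raw_grid[losses.coords[:, 0], losses.coords[:, 1]] = losses.raw
    unl = ~mask_a
    label[unl & (raw_grid < CLEAR_NEGATIVE_THRESHOLD)] = C_NEG
    label[unl & (raw_grid >= CLEAR_NEGATIVE_THRESHOLD)] = P_NEG  # default; peaks may upgrade

    if len(peaks):
        if peaks.posteriors is not None:
            post = np.asarray(peaks.posteriors, dtype=float)
        elif mix is not None:
            post = np.asarray(
                posterior_noisy(mix, losses.normalize(raw_grid[
                    peaks.coordinates[:, 0], peaks.coordinates[:, 1]
                ]))
            )
        else:
            raise ValueError("peaks carry no posteriors and no mixture was given")
        prov_coords = np.argwhere(mask_a)
        for (r, c), p in zip(peaks.coordinates, post):
            if mask_a[r, c]:
                continue  # provided labels win
            if absorb_radius and len(prov_coords):
                cheb = np.max(np.abs(prov_coords - np.array([r, c])), axis=1)
                if cheb.min() <= absorb_radius:
                    continue  # absorbed into Φp's object, not double-counted
            if label[r, c] == C_NEG:
                # a clear-negative loss outranks the peak posterior
                continue
            if p >= tau_pos:
                label[r, c] = P_POS
            elif p <= tau_neg:
                label[r, c] = P_NEG
            else:
                label[r, c] = IGN

    def coords_of(code: int) -> np.ndarray:
        return np.argwhere(label == code)

    return PseudoLabelPartition(
        shape=shape,
        provided_pos=coords_of(P_PROV),
        clear_neg=coords_of(C_NEG),
        predicted_pos=coords_of(P_POS),
        predicted_neg=coords_of(P_NEG),
        ignored=coords_of(IGN),
    )


def _pos_neg_indices(part: PseudoLabelPartition) -> tuple[np.ndarray, np.ndarray]:
    pos = np.vstack([part.predicted_pos.reshape(-1, 2), part.provided_pos.reshape(-1, 2)])
    neg = np.vstack([part.clear_neg.reshape(-1, 2), part.predicted_neg.reshape(-1, 2)])
    return pos.astype(int), neg.astype(int)


def pn_loss(cpre: np.ndarray, part: PseudoLabelPartition) -> float:
    """Positive–negative refinement loss.

    L = (1/N) [ Σ_{Φ+} (C_pre − 1)² + Σ_{Φ−} tanh(C_pre) ] with Φ+ = Φpre+ ∪ Φp
    and Φ− = Φclr− ∪ Φpre−.  Each predicted positive is assumed to cover exactly
    one object (the kernel is smaller than the objects), hence the unit count
    target.  Ignored coordinates contribute nothing.
    """
    cpre_a = np.asarray(cpre, dtype=float)
    if cpre_a.shape != part.shape:
        raise ValueError(f"count map shape {cpre_a.shape} != partition shape {part.shape}")
    pos, neg = _pos_neg_indices(part)
    if len(pos) == 0:
        raise EmptyPositiveSetError("no provided or predicted positives in the partition")
    n = cpre_a.size
    pos_term = np.sum((cpre_a[pos[:, 0], pos[:, 1]] - 1.0) ** 2)
    neg_term = np.sum(np.tanh(cpre_a[neg[:, 0], neg[:, 1]])) if len(neg) else 0.0
    return float((pos_term + neg_term) / n)


def pn_loss_grad(cpre: np.ndarray, part: PseudoLabelPartition) -> tuple[float, np.ndarray]:
    """PN loss and its gradient with respect to the predicted count map."""
    loss = pn_loss(cpre, part)
    cpre_a = np.asarray(cpre, dtype=float)
    pos, neg = _pos_neg_indices(part)
    grad = np.zeros_like(cpre_a)
    n = cpre_a.size
    grad[pos[:, 0], pos[:, 1]] = 2.0 * (cpre_a[pos[:, 0], pos[:, 1]] - 1.0) / n
    if len(neg):
        grad[neg[:, 0], neg[:, 1]] = (1.0 - np.tanh(cpre_a[neg[:, 0], neg[:, 1]]) ** 2) / n
    return loss, grad
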