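"""Two-stage training: PU learning, then beta-mixture pseudo-labeling.

Stage 1 optimizes the non-negative PU risk over redundant count maps.  Each
batch holds 4n images: n positive images (each carrying its few point
annotations), n randomly rotated/flipped copies of those same images (with the
annotations transformed along), and 2n images drawn from the unlabeled pool —
which is the entire training set, since the PU risk does not require positives
and unlabeled data to be independent.  Every epoch a fresh random 2/3 of each
image's annotations is kept, which stabilizes training against the tiny label
set.  Localization quality on a validation set is only scored after a delay
(early maps are noise and peak search on them is wasted work); the best
validation checkpoint seeds stage 2.

Stage 2 refits, once per epoch, a two-component beta mixture to the pooled
unlabeled losses, partitions the unlabeled region into pseudo-labels, and
optimizes the positive–negative L2-tanh loss at a much smaller learning rate.
The best validation checkpoint again wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .bmm import (
    CLEAR_NEGATIVE_THRESHOLD,
    DegenerateLossesError,
    UnlabeledLossSet,
    fit_bmm_em,
)
from .countmap import CountMapConfig, make_count_map, positive_mask
from .evaluate import match_points
from .localize import find_peaks
from .network import Adam, PredictorConfig, UNetPredictor
from .pseudolabel import EmptyPositiveSetError, partition_unlabeled, pn_loss_grad
from .pu_risk import PURiskConfig, nonneg_pu_risk_grad
from .synthetic import AnnotatedImage, subsample_annotations

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "Checkpoint", "make_batch", "augment_image",
           "train_stage1_pu", "train_stage2_pseudo", "evaluate_localization"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the two-stage schedule.

    The learning rates (1e-4 for PU learning, 1e-6 for pseudo-label refinement)
    are the reference values for batches of at least 8 images; for smaller
    batches the stage-1 rate is scaled down linearly with batch size.  The
    positive class prior defaults to the fixed 0.1 used across datasets.
    """

    kernel: CountMapConfig = CountMapConfig(7)
    class_prior: float = 0.1
    stage1_lr: float = 1e-4
    stage2_lr: float = 1e-6
    stage1_epochs: int = 100
    stage2_epochs: int = 100
    batch_factor: int = 2  # n; batches hold 4n images
    keep_fraction: float = 2.0 / 3.0
    eval_delay: int = 20
    eval_threshold: float = 6.0  # px radius for a validation true positive
    tau_pos: float = 0.95
    tau_neg: float = 0.05
    augment: bool = True
    plateau_patience: int = 10
    min_bmm_losses: int = 10
    seed: int = 0
    predictor: PredictorConfig = field(default_factory=PredictorConfig)

    def __post_init__(self) -> None:
        if self.stage1_lr <= 0 or self.stage2_lr <= 0:
            raise ValueError("learning rates must be positive")
        if not (0 < self.keep_fraction <= 1):
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.eval_delay >= self.stage1_epochs:
            raise ValueError("eval_delay must be smaller than stage1_epochs")

    @property
    def batch_size(self) -> int:
        return 4 * self.batch_factor

    def scaled_stage1_lr(self) -> float:
        return self.stage1_lr * min(1.0, self.batch_size / 8.0)

    def risk_config(self) -> PURiskConfig:
        return PURiskConfig(class_prior=self.class_prior, kernel=self.kernel)


@dataclass
class Checkpoint:
    """A trained predictor state with its provenance."""

    stage: str
    state: dict[str, np.ndarray]
    epoch: int
    val_f1: float
    config: TrainConfig
    history: pd.DataFrame


def _box_filter_batch(maps: np.ndarray, r: int) -> np.ndarray:
    """Clipped r×r box sum applied to a (B, H, W) stack (and its own adjoint)."""
    return ndimage.uniform_filter(
        np.asarray(maps, dtype=float), size=(1, r, r), mode="constant", cval=0.0
    ) * float(r * r)


def augment_image(
    image: np.ndarray, points: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random 90°-multiple rotation plus optional flip, applied to image and points."""
    img = np.asarray(image)
    pts = np.asarray(points, dtype=float).reshape(-1, 2).copy()
    k = int(rng.integers(0, 4))
    for _ in range(k):
        h, w = img.shape
        img = np.rot90(img)
        pts = np.stack([w - 1 - pts[:, 1], pts[:, 0]], axis=1) if len(pts) else pts
    if rng.integers(0, 2):
        img = img[::-1]
        if len(pts):
            pts[:, 0] = img.shape[0] - 1 - pts[:, 0]
    if rng.integers(0, 2):
        img = img[:, ::-1]
        if len(pts):
            pts[:, 1] = img.shape[1] - 1 - pts[:, 1]
    return np.ascontiguousarray(img), pts


def _rasterize(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    loc = np.zeros(shape, dtype=float)
    for r, c in np.asarray(points, dtype=float).reshape(-1, 2):
        loc[int(math.ceil(r - 0.5)), int(math.ceil(c - 0.5))] = 1.0
    return loc


def make_batch(
    positives: list[AnnotatedImage],
    unlabeled_pool: list[AnnotatedImage],
    n: int,
    rng: np.random.Generator | int,
    annotations: list[np.ndarray] | None = None,
    augment: bool = True,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Assemble a 4n-image batch: n positives, n augmented copies, 2n unlabeled.

    ``annotations`` optionally overrides each positive image's label set (e.g.
    the per-epoch 2/3 subsample).  Returns the image stack (4n, H, W) and the
    per-image annotation lists — empty arrays for the unlabeled half, whose
    labels (if any) are deliberately not used.
    """
    if not positives or not unlabeled_pool:
        raise ValueError("positive and unlabeled pools must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if annotations is None:
        annotations = [im.labeled for im in positives]
    reps = int(np.ceil(n / len(positives)))
    pos_idx = (list(range(len(positives))) * reps)[:n]
    images: list[np.ndarray] = []
    anns: list[np.ndarray] = []
    for i in pos_idx:
        images.append(np.asarray(positives[i].image))
        anns.append(np.asarray(annotations[i], dtype=float).reshape(-1, 2))
    for i in pos_idx:
        if augment:
            img, pts = augment_image(positives[i].image, annotations[i], rng)
        else:
            img, pts = np.asarray(positives[i].image), np.asarray(
                annotations[i], dtype=float
            ).reshape(-1, 2)
        images.append(img)
        anns.append(pts)
    unl_idx = rng.integers(0, len(unlabeled_pool), size=2 * n)
    for i in unl_idx:
        images.append(np.asarray(unlabeled_pool[int(i)].image))
        anns.append(np.empty((0, 2)))
    return np.stack(images), anns


def evaluate_localization(
    net: UNetPredictor,
    images: list[AnnotatedImage],
    cfg: TrainConfig,
    min_value: float | None = None,
) -> dict:
    """Micro-averaged precision/recall/F1 of peak detections against full centers."""
    tp = fp = fn = 0
    for im in images:
        pred_map = net.forward(np.asarray(im.image)[None], train=False)[0]
        peaks = find_peaks(pred_map, cfg.kernel, min_value)
        m = match_points(im.centers, peaks.coordinates, cfg.eval_threshold)
        tp += m.tp
        fp += m.fp
        fn += m.fn
    precision = tp / (tp + fp) if (tp + fp) else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "tp": tp, "fp": fp, "fn": fn}


def _epoch_annotations(
    train_images: list[AnnotatedImage], cfg: TrainConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    return [
        subsample_annotations(im.labeled, cfg.keep_fraction, rng) for im in train_images
    ]


def _targets_from_annotations(
    anns: list[np.ndarray], shape: tuple[int, int], kernel: CountMapConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (B,H,W) ground-truth count maps and positive masks."""
    cgts, masks = [], []
    for pts in anns:
        if len(pts):
            cgt = make_count_map(_rasterize(pts, shape), kernel)
        else:
            cgt = np.zeros(shape)
        cgts.append(cgt)
        masks.append(positive_mask(cgt) if len(pts) else np.zeros(shape))
    return np.stack(cgts), np.stack(masks)


def train_stage1_pu(
    train_images: list[AnnotatedImage],
    val_images: list[AnnotatedImage],
    cfg: TrainConfig,
    net: UNetPredictor | None = None,
) -> Checkpoint:
    """PU-learning stage; returns the checkpoint with the best validation F1."""
    root = np.random.SeedSequence(cfg.seed)
    ss_init, ss_sub, ss_batch = root.spawn(3)
    if net is None:
        net = UNetPredictor(cfg.predictor, seed=int(ss_init.generate_state(1)[0] % 2**31))
    rng_sub = np.random.default_rng(ss_sub)
    rng_batch = np.random.default_rng(ss_batch)
    opt = Adam(net.params, lr=cfg.scaled_stage1_lr())
    risk_cfg = cfg.risk_config()
    r = cfg.kernel.kernel_size
    shape = np.asarray(train_images[0].image).shape
    n = cfg.batch_factor
    steps = max(1, len(train_images) // n)

    best_f1 = -1.0
    best_state = net.state_copy()
    best_epoch = 0
    since_improve = 0
    rows = []
    for epoch in range(1, cfg.stage1_epochs + 1):
        anns = _epoch_annotations(train_images, cfg, rng_sub)
        order = rng_batch.permutation(len(train_images))
        risks = []
        for s in range(steps):
            idx = order[s * n : s * n + n]
            if len(idx) == 0:
                continue
            pos = [train_images[i] for i in idx]
            pos_anns = [anns[i] for i in idx]
            batch, batch_anns = make_batch(
                pos, train_images, len(pos), rng_batch,
                annotations=pos_anns, augment=cfg.augment,
            )
            cgt_b, mask_b = _targets_from_annotations(batch_anns, shape, cfg.kernel)
            ppre = net.forward(batch, train=True)
            cpre = _box_filter_batch(ppre, r)
            risk, d_cpre = nonneg_pu_risk_grad(cpre, cgt_b, mask_b, risk_cfg)
            if not np.isfinite(risk.total):
                raise FloatingPointError(
                    f"PU risk diverged at epoch {epoch}: {risk}"
                )
            d_ppre = _box_filter_batch(d_cpre, r)
            grads = net.backward(d_ppre.astype(np.float32))
            opt.step(grads)
            risks.append(risk.total)
        row = {"epoch": epoch, "risk": float(np.mean(risks)), "lr": opt.lr,
               "val_f1": np.nan}
        if epoch > cfg.eval_delay:
            metrics = evaluate_localization(net, val_images, cfg)
            row["val_f1"] = metrics["f1"]
            if metrics["f1"] > best_f1:
                best_f1 = metrics["f1"]
                best_state = net.state_copy()
                best_epoch = epoch
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= cfg.plateau_patience:
                    opt.lr *= 0.5
                    since_improve = 0
                    logger.info("halving stage-1 learning rate to %g", opt.lr)
        rows.append(row)
    history = pd.DataFrame(rows)
    return Checkpoint(
        stage="stage1_best", state=best_state, epoch=best_epoch,
        val_f1=max(best_f1, 0.0), config=cfg, history=history,
    )


def _pooled_unlabeled_losses(
    cpres: list[np.ndarray], cgts: list[np.ndarray]
) -> tuple[list[UnlabeledLossSet], np.ndarray]:
    """Per-image unlabeled loss sets sharing one global normalization.

    Losses are pooled over images before the mixture fit so that one image's
    scale does not distort another's posteriors.
    """
    per_image = []
    pooled_raw = []
    for cpre, cgt in zip(cpres, cgts):
        coords = np.argwhere(cgt == 0)
        raw = cpre[cgt == 0] ** 2
        per_image.append((coords, raw))
        pooled_raw.append(raw[raw >= CLEAR_NEGATIVE_THRESHOLD])
    pooled = np.concatenate(pooled_raw) if pooled_raw else np.empty(0)
    if len(pooled) == 0:
        raise DegenerateLossesError("no unlabeled losses above the clear-negative threshold")
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        hi = lo + 1e-12
    eps = 1e-4
    sets = []
    for coords, raw in per_image:
        survivors = np.flatnonzero(raw >= CLEAR_NEGATIVE_THRESHOLD)
        normalized = eps + (1 - 2 * eps) * (raw[survivors] - lo) / (hi - lo)
        sets.append(
            UnlabeledLossSet(coords=coords, raw=raw, survivors=survivors,
                             normalized=normalized, bounds=(lo, hi))
        )
    pooled_norm = eps + (1 - 2 * eps) * (pooled - lo) / (hi - lo)
    return sets, pooled_norm


def train_stage2_pseudo(
    train_images: list[AnnotatedImage],
    val_images: list[AnnotatedImage],
    stage1_ckpt: Checkpoint,
    cfg: TrainConfig,
) -> Checkpoint:
    """Pseudo-labeling refinement stage, initialized from the stage-1 best model.

    Per epoch: one inference pass over the training set pools the unlabeled
    losses and fits the beta mixture, peaks of each predicted map are scored by
    the noisy-component posterior and partitioned into pseudo-label sets, and
    the PN loss is optimized over image minibatches.  The best validation
    checkpoint (including the stage-1 initialization itself, scored before any
    update) is returned.
    """
    root = np.random.SeedSequence([cfg.seed, 2])
    ss_bmm, ss_batch = root.spawn(2)
    rng_batch = np.random.default_rng(ss_batch)
    net = UNetPredictor(cfg.predictor, seed=0)
    net.load_state(stage1_ckpt.state)
    opt = Adam(net.params, lr=cfg.stage2_lr)
    r = cfg.kernel.kernel_size
    shape = np.asarray(train_images[0].image).shape
    absorb = (r + 1) // 2
    anns = [im.labeled for im in train_images]
    cgts_masks = _targets_from_annotations(anns, shape, cfg.kernel)
    cgts = list(cgts_masks[0])
    masks = list(cgts_masks[1])

    metrics0 = evaluate_localization(net, val_images, cfg)
    best_f1 = metrics0["f1"]
    best_state = net.state_copy()
    best_epoch = 0
    rows = [{"epoch": 0, "pn_loss": np.nan, "val_f1": best_f1, "n_pseudo_pos": np.nan}]

    batch = max(1, 4 * cfg.batch_factor)
    for epoch in range(1, cfg.stage2_epochs + 1):
        preds = [net.forward(np.asarray(im.image)[None], train=False)[0]
                 for im in train_images]
        cpres = [make_count_map(p, cfg.kernel) for p in preds]
        try:
            loss_sets, pooled_norm = _pooled_unlabeled_losses(cpres, cgts)
            mix = fit_bmm_em(pooled_norm, seed=int(ss_bmm.generate_state(1)[0] % 2**31))
        except DegenerateLossesError as exc:
            logger.warning("epoch %d: skipping pseudo-labeling (%s)", epoch, exc)
            rows.append({"epoch": epoch, "pn_loss": np.nan, "val_f1": np.nan,
                         "n_pseudo_pos": 0})
            continue
        partitions = []
        n_pos = 0
        for pred, lset, mask in zip(preds, loss_sets, masks):
            peaks = find_peaks(pred, cfg.kernel)
            part = partition_unlabeled(
                peaks, lset, mask, tau_pos=cfg.tau_pos, tau_neg=cfg.tau_neg,
                mix=mix, absorb_radius=absorb,
            )
            partitions.append(part)
            n_pos += len(part.predicted_pos)
        order = rng_batch.permutation(len(train_images))
        losses = []
        for s in range(0, len(order), batch):
            idx = order[s : s + batch]
            imgs = np.stack([np.asarray(train_images[i].image) for i in idx])
            ppre = net.forward(imgs, train=True)
            cpre_b = _box_filter_batch(ppre, r)
            d_cpre = np.zeros_like(cpre_b)
            batch_loss = 0.0
            n_used = 0
            for j, i in enumerate(idx):
                try:
                    loss_j, grad_j = pn_loss_grad(cpre_b[j], partitions[i])
                except EmptyPositiveSetError:
                    logger.warning("image %d: empty positive set, skipped", i)
                    continue
                d_cpre[j] = grad_j
                batch_loss += loss_j
                n_used += 1
            if n_used == 0:
                net._cache = None
                continue
            d_ppre = _box_filter_batch(d_cpre, r) / n_used
            grads = net.backward(d_ppre.astype(np.float32))
            opt.step(grads)
            losses.append(batch_loss / n_used)
        metrics = evaluate_localization(net, val_images, cfg)
        rows.append({"epoch": epoch, "pn_loss": float(np.mean(losses)) if losses else np.nan,
                     "val_f1": metrics["f1"], "n_pseudo_pos": n_pos})
        if metrics["f1"] > best_f1:
            best_f1 = metrics["f1"]
            best_state = net.state_copy()
            best_epoch = epoch
    history = pd.DataFrame(rows)
    return Checkpoint(
        stage="stage2_best", state=best_state, epoch=best_epoch,
        val_f1=best_f1, config=cfg, history=history,
    )
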