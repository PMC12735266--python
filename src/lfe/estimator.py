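"""Model/Results interface over the two-stage localization pipeline.

:class:`LFELocalizer` is constructed from annotated images (the few labeled
points per image are the supervision; full center lists, where known, are used
only for validation scoring), ``fit()`` runs PU learning and optionally the
pseudo-label refinement, and returns an :class:`LFEResults` carrying the best
checkpoints, the epoch-by-epoch training history, and prediction/evaluation
methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countmap import CountMapConfig
from .localize import PeakSet, detections_from_peaks, find_peaks, peak_prominence_stats
from .network import UNetPredictor, predict_location_map
from .synthetic import AnnotatedImage
from .train import (
    Checkpoint,
    TrainConfig,
    evaluate_localization,
    train_stage1_pu,
    train_stage2_pseudo,
)

__all__ = ["LFELocalizer", "LFEResults"]


class LFELocalizer:
    """Small-object localizer trained from sparse point annotations.

    Parameters
    ----------
    train_images : list of AnnotatedImage
        Training scenes; only their ``labeled`` points supervise training.
    val_images : list of AnnotatedImage, optional
        Fully annotated validation scenes used for checkpoint selection.  When
        omitted, the last 15% (at least one) of ``train_images`` is held out —
        sensible only if those images carry full annotations.
    config : TrainConfig, optional
        Schedule and loss hyper-parameters (kernel size, class prior, rates).
    """

    def __init__(
        self,
        train_images: list[AnnotatedImage],
        val_images: list[AnnotatedImage] | None = None,
        config: TrainConfig | None = None,
    ):
        if val_images is None:
            n_hold = max(1, len(train_images) * 15 // 100)
            if len(train_images) <= n_hold:
                raise ValueError("too few images to hold out a validation split")
            val_images = train_images[-n_hold:]
            train_images = train_images[:-n_hold]
        if not train_images:
            raise ValueError("no training images")
        self.train_images = train_images
        self.val_images = val_images
        self.config = config if config is not None else TrainConfig()

    def fit(self, stages: int = 2, net: UNetPredictor | None = None) -> "LFEResults":
        """Run the training schedule and return the fitted results.

        ``stages=1`` stops after PU learning; ``stages=2`` (default) adds the
        beta-mixture pseudo-labeling refinement.
        """
        if stages not in (1, 2):
            raise ValueError("stages must be 1 or 2")
        stage1 = train_stage1_pu(self.train_images, self.val_images, self.config, net=net)
        stage2 = None
        if stages == 2:
            stage2 = train_stage2_pseudo(
                self.train_images, self.val_images, stage1, self.config
            )
        return LFEResults(model=self, config=self.config, stage1=stage1, stage2=stage2)


@dataclass
class LFEResults:
    """Fitted localizer: best checkpoints, training history, and predictions."""

    model: LFELocalizer
    config: TrainConfig
    stage1: Checkpoint
    stage2: Checkpoint | None = None
    _net: UNetPredictor = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._net = UNetPredictor(self.config.predictor, seed=0)
        self._net.load_state(self.best_checkpoint.state)

    @property
    def best_checkpoint(self) -> Checkpoint:
        return self.stage2 if self.stage2 is not None else self.stage1

    @property
    def kernel(self) -> CountMapConfig:
        return self.config.kernel

    @property
    def history(self) -> pd.DataFrame:
        """Stacked per-epoch history of both stages."""
        frames = [self.stage1.history.assign(stage="pu")]
        if self.stage2 is not None:
            frames.append(self.stage2.history.assign(stage="pseudo"))
        return pd.concat(frames, ignore_index=True)

    # -- prediction -----------------------------------------------------------

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Non-negative predicted location map for one image."""
        return predict_location_map(self._net, np.asarray(image))

    def find_peaks(self, image: np.ndarray, min_value: float | None = None) -> PeakSet:
        return find_peaks(self.predict(image), self.kernel, min_value)

    def detect(self, image: np.ndarray, min_value: float | None = None) -> pd.DataFrame:
        """Detected object centers as a DataFrame (row, col, score, proportion)."""
        loc = self.predict(image)
        peaks = find_peaks(loc, self.kernel, min_value)
        dets = detections_from_peaks(loc, peaks, self.kernel)
        return pd.DataFrame(
            [(d.row, d.col, d.value, d.proportion) for d in dets],
            columns=["row", "col", "score", "proportion"],
        )

    # -- evaluation -----------------------------------------------------------

    def evaluate(
        self, images: list[AnnotatedImage], threshold: float | None = None
    ) -> dict:
        """Micro-averaged precision/recall/F1 against the images' full centers."""
        cfg = self.config
        if threshold is not None:
            from dataclasses import replace

            cfg = replace(cfg, eval_threshold=threshold)
        return evaluate_localization(self._net, images, cfg)

    def peak_statistics(self, images: list[AnnotatedImage]) -> dict:
        """Prominence statistics of detected peaks pooled over images."""
        dets = []
        for im in images:
            loc = self.predict(im.image)
            peaks = find_peaks(loc, self.kernel)
            dets.extend(detections_from_peaks(loc, peaks, self.kernel))
        return peak_prominence_stats(dets, self.kernel)

    def summary(self) -> str:
        """Plain-text fit summary."""
        cfg = self.config
        lines = [
            "Learn-from-educator small-object localizer",
            "=" * 44,
            f"kernel size r:            {cfg.kernel.kernel_size}",
            f"class prior pi_p:         {cfg.class_prior}",
            f"training images:          {len(self.model.train_images)}",
            f"validation images:        {len(self.model.val_images)}",
            f"annotations per image:    "
            f"{np.mean([len(im.labeled) for im in self.model.train_images]):.1f}",
            f"network parameters:       {self._net.n_parameters}",
            "-" * 44,
            f"stage 1 (PU risk):        best val F1 {self.stage1.val_f1:.3f}"
            f" @ epoch {self.stage1.epoch}",
        ]
        if self.stage2 is not None:
            lines.append(
                f"stage 2 (pseudo-label):   best val F1 {self.stage2.val_f1:.3f}"
                f" @ epoch {self.stage2.epoch}"
            )
        return "\n".join(lines)
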