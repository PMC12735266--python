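"""Synthetic scenes of dense small quasi-circular objects with known centers.

Emulates the regime the localizer is built for — tens to hundreds of small,
similar-looking targets per image (nuclei in tissue, cells in droplets, insects,
crowd heads) of which only a handful carry point annotations.  Objects are
rendered as soft-edged bright disks on a darker background with additive Gaussian
noise; centers are recorded exactly, so every training stage can be tested
end-to-end without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SceneConfig",
    "AnnotatedImage",
    "generate_scene",
    "generate_dataset",
    "subsample_annotations",
    "sample_beta_mixture",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults describe the packaged small-object benchmark: 96×96 px images with
    about 15 non-overlapping soft disks of radius 4 (diameter 9, slightly larger
    than the default 7-px count-map kernel), moderate contrast and mild sensor
    noise, and a single labeled point per image (~7% of the annotations).
    """

    height: int = 96
    width: int = 96
    n_objects: int = 15
    n_objects_sd: float = 0.0
    object_radius: float = 4.0
    contrast: float = 0.6
    background: float = 0.15
    noise_sd: float = 0.03
    labeled_count: int = 1
    min_separation: float = 11.0
    max_place_tries: int = 2000

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.labeled_count > self.n_objects:
            raise ValueError(
                f"labeled_count ({self.labeled_count}) exceeds n_objects ({self.n_objects})"
            )
        if self.object_radius <= 0:
            raise ValueError("object_radius must be positive")


@dataclass(frozen=True)
class AnnotatedImage:
    """A rendered scene, its full center list, and the labeled subset shown to the learner."""

    image: np.ndarray
    centers: np.ndarray  # (n, 2) float, (row, col)
    labeled: np.ndarray  # (k, 2) float, subset of centers
    seed: int

    @property
    def n_objects(self) -> int:
        return len(self.centers)

    def location_map(self, labeled_only: bool = True) -> np.ndarray:
        """Binary location map with a unit impulse at each (labeled) center.

        Fractional centers are rasterized to the nearest pixel, ties toward the
        smaller index.
        """
        pts = self.labeled if labeled_only else self.centers
        loc = np.zeros(self.image.shape[:2], dtype=float)
        for r, c in pts:
            loc[_round_half_down(r), _round_half_down(c)] = 1.0
        return loc


def _round_half_down(x: float) -> int:
    # nearest pixel, ties toward the smaller index
    return int(math.ceil(x - 0.5))


def _place_centers(cfg: SceneConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Reject-and-retry packing of n centers at min_separation, away from borders."""
    margin = cfg.object_radius + 1.0
    lo_r, hi_r = margin, cfg.height - 1 - margin
    lo_c, hi_c = margin, cfg.width - 1 - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("scene too small for the configured object radius")
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries >= cfg.max_place_tries:
            raise RuntimeError(
                f"could not place {n} objects at min_separation={cfg.min_separation} "
                f"within {cfg.max_place_tries} tries"
            )
        tries += 1
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= cfg.min_separation**2 for rr, cc in centers):
            centers.append((r, c))
    return np.array(centers, dtype=float).reshape(n, 2)


def _render(cfg: SceneConfig, centers: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    rows = np.arange(cfg.height, dtype=float)[:, None]
    cols = np.arange(cfg.width, dtype=float)[None, :]
    img = np.full((cfg.height, cfg.width), cfg.background, dtype=float)
    for r, c in centers:
        d = np.sqrt((rows - r) ** 2 + (cols - c) ** 2)
        # disk with a 1-px anti-aliased soft edge and a gentle dome (10% brighter
        # at the center than at the rim) so the intensity maximum sits at the
        # recorded center rather than anywhere on a flat top
        profile = np.clip(cfg.object_radius + 0.5 - d, 0.0, 1.0)
        dome = 1.0 - 0.1 * np.clip(d / cfg.object_radius, 0.0, 1.0) ** 2
        img += cfg.contrast * profile * dome
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_scene(cfg: SceneConfig, seed: int) -> AnnotatedImage:
    """Render one scene deterministically from ``seed``.

    The object count is drawn from N(n_objects, n_objects_sd) (rounded, at least
    ``labeled_count``); centers are packed by rejection sampling at
    ``min_separation`` and at least one object radius from the border, disks are
    rendered with a soft edge, and Gaussian noise is added before clipping to
    [0, 1].  The labeled subset is drawn uniformly without replacement.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_objects
    if cfg.n_objects_sd > 0:
        n = max(cfg.labeled_count, int(round(rng.normal(cfg.n_objects, cfg.n_objects_sd))))
    centers = _place_centers(cfg, rng, n)
    img = _render(cfg, centers, rng)
    idx = rng.choice(n, size=cfg.labeled_count, replace=False) if n else np.array([], int)
    labeled = centers[np.sort(idx)]
    return AnnotatedImage(image=img, centers=centers, labeled=labeled, seed=seed)


def generate_dataset(cfg: SceneConfig, n_images: int, seed: int) -> list[AnnotatedImage]:
    """Generate ``n_images`` independent scenes; per-scene seeds spawn from ``seed``."""
    root = np.random.default_rng(seed)
    scene_seeds = root.integers(0, 2**31 - 1, size=n_images)
    return [generate_scene(cfg, int(s)) for s in scene_seeds]


def subsample_annotations(
    points: np.ndarray, fraction: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ⌈fraction·n⌉ annotation points without replacement.

    Re-drawing a fresh random 2/3 of each image's annotations every epoch
    stabilizes PU training and prevents overfitting to the few labeled examples;
    this helper is called per epoch per image.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValueError("cannot subsample an empty annotation list")
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    k = int(math.ceil(fraction * len(pts)))
    idx = rng.choice(len(pts), size=k, replace=False)
    return pts[np.sort(idx)]


def sample_beta_mixture(mix, n: int, seed: int) -> np.ndarray:
    """Draw n i.i.d. variates from a two-component beta mixture.

    Component k is chosen with probability λ_k, then a Beta(α_k, β_k) variate is
    drawn.  Mainly a fixture source for testing the mixture-fitting EM.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    weights = np.asarray(mix.weights, dtype=float)
    alphas = np.asarray(mix.alphas, dtype=float)
    betas = np.asarray(mix.betas, dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must be non-negative and sum to 1")
    if np.any(alphas <= 0) or np.any(betas <= 0):
        raise ValueError("beta shape parameters must be strictly positive")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    return rng.beta(alphas[comp], betas[comp])
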