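"""Two-component beta-mixture modeling of unlabeled-region losses.

After PU training, the squared predicted counts at unlabeled count-map
coordinates separate into two populations: small losses where the background was
correctly suppressed (clean negatives) and large losses where a hidden,
unannotated object produced a confident response (noisy "negatives" that are
really positives).  Fitting a two-component beta mixture to these losses by EM
and reading off the posterior of the high-mean component gives each local
maximum a calibrated probability of being a true object — the confidence that
drives pseudo-labeling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BetaMixture",
    "UnlabeledLossSet",
    "unlabeled_losses",
    "fit_bmm_em",
    "posterior_noisy",
    "CLEAR_NEGATIVE_THRESHOLD",
]

#: Raw squared-count losses below this are "clear negatives": so abundant and so
#: close to zero that they would dominate the mixture fit, so they are removed
#: before EM and labeled negative directly.
CLEAR_NEGATIVE_THRESHOLD = 0.01

_EPS = 1e-4  # support margin for normalized losses
_MIN_SHAPE = 1e-2
_MAX_SHAPE = 1e4


class DegenerateLossesError(ValueError):
    """Raised when too few unlabeled losses survive clear-negative removal."""


@dataclass(frozen=True)
class BetaMixture:
    """Two-component beta mixture over normalized losses in (0, 1).

    Component 1 is the *clean* (lower-mean) component, component 2 the *noisy*
    (higher-mean) one; :func:`fit_bmm_em` sorts them this way.  ``loss_bounds``
    records the affine map applied to raw losses so posteriors can be queried on
    the raw scale.
    """

    weights: tuple[float, float]
    alphas: tuple[float, float]
    betas: tuple[float, float]
    loss_bounds: tuple[float, float] | None = None
    log_likelihood: float = float("nan")
    n_iter: int = 0

    @property
    def means(self) -> tuple[float, float]:
        return tuple(
            a / (a + b) for a, b in zip(self.alphas, self.betas)
        )  # type: ignore[return-value]

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": list(self.weights),
                "alphas": list(self.alphas),
                "betas": list(self.betas),
                "loss_bounds": list(self.loss_bounds) if self.loss_bounds else None,
                "log_likelihood": self.log_likelihood,
                "n_iter": self.n_iter,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BetaMixture":
        d = json.loads(text)
        return cls(
            weights=tuple(d["weights"]),
            alphas=tuple(d["alphas"]),
            betas=tuple(d["betas"]),
            loss_bounds=tuple(d["loss_bounds"]) if d["loss_bounds"] else None,
            log_likelihood=d["log_likelihood"],
            n_iter=d["n_iter"],
        )


@dataclass(frozen=True)
class UnlabeledLossSet:
    """Losses l(i,j) = C_pre(i,j)² at unlabeled (C̃_gt = 0) coordinates.

    ``coords``/``raw`` hold every unlabeled coordinate and its raw loss;
    ``survivors`` indexes those with raw loss ≥ the clear-negative threshold, and
    ``normalized`` maps the survivors affinely into (ε, 1−ε) for beta support.
    """

    coords: np.ndarray  # (n, 2) int
    raw: np.ndarray  # (n,) float
    survivors: np.ndarray  # (m,) int indices into coords/raw
    normalized: np.ndarray  # (m,) float in (0, 1)
    bounds: tuple[float, float]  # (min, max) of surviving raw losses

    @property
    def clear_negative(self) -> np.ndarray:
        mask = np.ones(len(self.raw), dtype=bool)
        mask[self.survivors] = False
        return mask

    def normalize(self, raw: np.ndarray | float) -> np.ndarray:
        """Map raw losses onto the fitted (ε, 1−ε) scale, clipping outside the bounds."""
        lo, hi = self.bounds
        x = (np.asarray(raw, dtype=float) - lo) / (hi - lo)
        return _EPS + (1.0 - 2.0 * _EPS) * np.clip(x, 0.0, 1.0)


def unlabeled_losses(cpre: np.ndarray, cgt: np.ndarray, min_survivors: int = 1) -> UnlabeledLossSet:
    """Collect squared predicted counts over the unlabeled region Φu.

    Raises :class:`DegenerateLossesError` when fewer than ``min_survivors``
    losses exceed the clear-negative threshold (the caller then skips
    pseudo-labeling for this round).
    """
    cpre = np.asarray(cpre, dtype=float)
    cgt = np.asarray(cgt, dtype=float)
    if cpre.shape != cgt.shape:
        raise ValueError(f"shape mismatch: {cpre.shape} vs {cgt.shape}")
    coords = np.argwhere(cgt == 0)
    raw = cpre[cgt == 0] ** 2
    survivors = np.flatnonzero(raw >= CLEAR_NEGATIVE_THRESHOLD)
    if len(survivors) < min_survivors:
        raise DegenerateLossesError(
            f"only {len(survivors)} unlabeled losses exceed the clear-negative "
            f"threshold (need {min_survivors})"
        )
    surv = raw[survivors]
    lo, hi = float(surv.min()), float(surv.max())
    if hi <= lo:
        hi = lo + 1e-12
    normalized = _EPS + (1.0 - 2.0 * _EPS) * (surv - lo) / (hi - lo)
    return UnlabeledLossSet(
        coords=coords, raw=raw, survivors=survivors, normalized=normalized, bounds=(lo, hi)
    )


def _moments_to_shapes(mean: float, var: float) -> tuple[float, float]:
    """Method-of-moments beta shapes from a (weighted) mean and variance."""
    mean = float(np.clip(mean, _EPS, 1.0 - _EPS))
    var = float(max(var, 1e-8))
    # variance of a beta cannot reach mean(1-mean); back off if the data's does
    var = min(var, mean * (1.0 - mean) * 0.999)
    kappa = mean * (1.0 - mean) / var - 1.0
    alpha = np.clip(mean * kappa, _MIN_SHAPE, _MAX_SHAPE)
    beta = np.clip((1.0 - mean) * kappa, _MIN_SHAPE, _MAX_SHAPE)
    return float(alpha), float(beta)


def _weighted_beta_mle(
    x: np.ndarray, w: np.ndarray, init: tuple[float, float]
) -> tuple[float, float]:
    """Weighted maximum-likelihood beta shapes.

    Maximizes Σ w_i log Beta(x_i | α, β) over log-shapes with L-BFGS starting
    from ``init`` (typically method-of-moments).  An exact M-step keeps the EM
    log-likelihood monotone, which a moments update does not guarantee.
    """
    from scipy.optimize import minimize
    from scipy.special import betaln, digamma

    wsum = float(w.sum())
    if wsum <= 0:
        return init
    mlogx = float(np.average(np.log(x), weights=w))
    mlog1x = float(np.average(np.log1p(-x), weights=w))

    def neg_ll(theta):
        a, b = np.exp(theta)
        val = -wsum * ((a - 1) * mlogx + (b - 1) * mlog1x - betaln(a, b))
        dab = digamma(a + b)
        ga = -wsum * (mlogx - digamma(a) + dab) * a
        gb = -wsum * (mlog1x - digamma(b) + dab) * b
        return val, np.array([ga, gb])

    res = minimize(
        neg_ll,
        np.log(np.clip(init, _MIN_SHAPE, _MAX_SHAPE)),
        jac=True,
        method="L-BFGS-B",
        bounds=[(np.log(_MIN_SHAPE), np.log(_MAX_SHAPE))] * 2,
    )
    a, b = np.exp(res.x)
    return float(a), float(b)


def _component_logpdf(x: np.ndarray, alphas, betas) -> np.ndarray:
    """(n, 2) matrix of per-component beta log-densities."""
    return np.stack(
        [stats.beta.logpdf(x, a, b) for a, b in zip(alphas, betas)], axis=1
    )


def fit_bmm_em(
    losses: UnlabeledLossSet | np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
    trace: list | None = None,
) -> BetaMixture:
    """Fit a two-component beta mixture to normalized losses by EM.

    The E-step computes responsibilities from the current beta densities; the
    M-step re-estimates mixing weights as mean responsibilities and beta shapes
    by weighted maximum likelihood (method-of-moments initialized, refined on
    the digamma equations), so the observed-data log-likelihood is monotone
    non-decreasing.  Initialization splits the sample at its
    median (deterministic given the data); the seed only feeds the one random
    re-initialization attempted if a component collapses.  Components are
    returned sorted by mean, clean first.  Pass a list as ``trace`` to record
    the log-likelihood per iteration.
    """
    if isinstance(losses, UnlabeledLossSet):
        x = losses.normalized
        bounds = losses.bounds
    else:
        x = np.asarray(losses, dtype=float)
        bounds = None
    if len(x) < 10:
        raise DegenerateLossesError(f"need at least 10 losses to fit a mixture, got {len(x)}")
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("losses must lie strictly inside (0, 1); normalize first")

    def init_median() -> tuple[np.ndarray, list, list]:
        med = np.median(x)
        lo_half = x[x <= med]
        hi_half = x[x > med]
        if len(hi_half) < 2:  # heavily tied sample; fall back to an even split
            order = np.argsort(x)
            lo_half, hi_half = x[order[: len(x) // 2]], x[order[len(x) // 2 :]]
        weights = np.array([len(lo_half), len(hi_half)], dtype=float)
        weights /= weights.sum()
        shapes = [_moments_to_shapes(h.mean(), h.var()) for h in (lo_half, hi_half)]
        return weights, [s[0] for s in shapes], [s[1] for s in shapes]

    def init_random(rng: np.random.Generator) -> tuple[np.ndarray, list, list]:
        resp = rng.uniform(size=len(x))
        w = np.array([np.mean(1 - resp), np.mean(resp)])
        shapes = []
        for rk in (1 - resp, resp):
            m = np.average(x, weights=rk)
            v = np.average((x - m) ** 2, weights=rk)
            shapes.append(_moments_to_shapes(m, v))
        return w, [s[0] for s in shapes], [s[1] for s in shapes]

    rng = np.random.default_rng(seed)
    for attempt in range(2):
        if trace is not None:
            trace.clear()
        weights, alphas, betas = init_median() if attempt == 0 else init_random(rng)
        prev_ll = -np.inf
        ll = prev_ll
        degenerate = False
        for it in range(1, max_iter + 1):
            log_comp = _component_logpdf(x, alphas, betas) + np.log(np.maximum(weights, 1e-300))
            log_norm = np.logaddexp(log_comp[:, 0], log_comp[:, 1])
            ll = float(np.sum(log_norm))
            if trace is not None:
                trace.append(ll)
            resp = np.exp(log_comp - log_norm[:, None])
            eff = resp.sum(axis=0)
            if np.any(eff < 2.0):
                degenerate = True
                break
            weights = eff / len(x)
            new_shapes = []
            for k in range(2):
                m = float(np.average(x, weights=resp[:, k]))
                v = float(np.average((x - m) ** 2, weights=resp[:, k]))
                new_shapes.append(
                    _weighted_beta_mle(x, resp[:, k], _moments_to_shapes(m, v))
                )
            alphas = [s[0] for s in new_shapes]
            betas = [s[1] for s in new_shapes]
            if abs(ll - prev_ll) < tol:
                break
            prev_ll = ll
        if not degenerate:
            break
    else:  # pragma: no cover - both initializations collapsed
        raise DegenerateLossesError("beta-mixture EM collapsed under both initializations")

    order = np.argsort([a / (a + b) for a, b in zip(alphas, betas)])
    return BetaMixture(
        weights=tuple(float(weights[k]) for k in order),
        alphas=tuple(float(alphas[k]) for k in order),
        betas=tuple(float(betas[k]) for k in order),
        loss_bounds=bounds,
        log_likelihood=ll,
        n_iter=it,
    )


def posterior_noisy(mix: BetaMixture, l: np.ndarray | float) -> np.ndarray | float:
    """Posterior probability that a normalized loss belongs to the noisy component.

    Computed in log space to survive density underflow near the support edges.
    Scalar in, scalar out.
    """
    x = np.clip(np.asarray(l, dtype=float), _EPS / 2, 1.0 - _EPS / 2)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    log_comp = _component_logpdf(x, mix.alphas, mix.betas) + np.log(
        np.maximum(np.asarray(mix.weights), 1e-300)
    )
    post = np.exp(log_comp[:, 1] - np.logaddexp(log_comp[:, 0], log_comp[:, 1]))
    return float(post[0]) if scalar else post
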