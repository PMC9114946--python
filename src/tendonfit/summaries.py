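"""Posterior post-processing: intervals, correlations, skewness, predictive bands.

All summaries operate on the natural parameter scale and on post-burn-in
samples only.  Credible intervals are equal-tailed sample percentiles.
Intervals and correlations are computed on the unthinned chain; thinning is
provided for visualization and export.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .inference import Chain
from .models import get_model

__all__ = [
    "PosteriorSummary",
    "PredictiveBand",
    "credible_interval",
    "skewness_statistic",
    "summarize_chain",
    "predictive_band",
    "thin",
]


def credible_interval(samples, level: float = 0.95):
    """Equal-tailed credible interval: percentiles at (1 -/+ level)/2."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    tail = 100.0 * 0.5 * (1.0 - level)
    lo, hi = np.percentile(samples, [tail, 100.0 - tail])
    return float(lo), float(hi)


def skewness_statistic(a, b, c):
    """Triangle skewness (2c - b - a)/(b - a): -1 at c = a, 0 when symmetric, 1 at c = b.

    Evaluated as ((c - a) - (b - c)) / (b - a), which is algebraically
    identical and exact at the one-sided limits c = a and c = b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    return ((c - a) - (b - c)) / (b - a)


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter posterior location and spread plus the correlation matrix."""

    param_names: tuple
    means: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    correlations: np.ndarray
    skewness: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.param_names),
                "mean": self.means,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    def correlation(self, name_i: str, name_j: str) -> float:
        i = self.param_names.index(name_i)
        j = self.param_names.index(name_j)
        return float(self.correlations[i, j])


def summarize_chain(chain: Chain, level: float = 0.95) -> PosteriorSummary:
    """Posterior means, equal-tailed intervals and correlations (natural scale).

    For the general-triangle model the per-draw skewness statistic of the
    recruitment distribution is attached as well.
    """
    natural = chain.natural_posterior
    if len(natural) < 2:
        raise ValueError("chain has fewer than 2 post-burn-in samples")
    means = natural.mean(axis=0)
    bounds = np.array([credible_interval(natural[:, j], level) for j in range(natural.shape[1])])
    corr = np.corrcoef(natural, rowvar=False)
    skew = None
    names = chain.param_names
    if chain.model == "gt":
        a = natural[:, names.index("a")]
        c = natural[:, names.index("c")]
        b = natural[:, names.index("b")]
        skew = skewness_statistic(a, b, c)
    return PosteriorSummary(
        param_names=tuple(names),
        means=means,
        lower=bounds[:, 0],
        upper=bounds[:, 1],
        level=level,
        correlations=corr,
        skewness=skew,
    )


class PredictiveBand(NamedTuple):
    """Pointwise posterior-predictive mean and mean +/- k*sd stress band."""

    stretch: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stretch": self.stretch,
                "mean": self.mean,
                "sd": self.sd,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def predictive_band(
    chain: Chain,
    grid,
    n_draws: int = 50_000,
    k: float = 5.0,
    seed=None,
) -> PredictiveBand:
    """Band of predicted stresses across posterior draws on a stretch grid.

    Up to ``n_draws`` post-burn-in parameter vectors are subsampled without
    replacement (all of them if the chain is shorter); the band is the
    pointwise mean +/- k standard deviations of the predicted stress.
    Parameter uncertainty only; no observation noise is added.
    """
    grid = np.asarray(grid, dtype=float)
    natural = chain.natural_posterior
    if len(natural) == 0:
        raise ValueError("chain has no post-burn-in samples")
    spec = get_model(chain.model)
    rng = np.random.default_rng(seed)
    if len(natural) > n_draws:
        idx = rng.choice(len(natural), size=n_draws, replace=False)
        natural = natural[idx]
    curves = np.empty((len(natural), len(grid)))
    for i, params in enumerate(natural):
        curves[i] = spec.stress(params, grid)
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0)
    return PredictiveBand(grid, mean, sd, mean - k * sd, mean + k * sd)


def thin(chain: Chain, factor: int = 10) -> Chain:
    """Keep every ``factor``-th post-burn-in sample (burn-in dropped entirely)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    sl = slice(chain.burn_in, None, factor)
    return replace(
        chain,
        samples=chain.samples[sl],
        accepted=chain.accepted[sl],
        log_post=chain.log_post[sl],
        burn_in=0,
    )
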