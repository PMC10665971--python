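"""Between-cohort posterior contrasts: the pipeline's headline quantities.

A contrast is the distribution of d_i = 100 * (p_post,i - p_pre,i) over
paired posterior draws of the two cohorts' group probabilities.  Summaries
are the posterior mean difference, central 70% and 90% credible intervals,
and the probability mass on either side of zero — on the percentage-point
scale for proportions, or the per-100-games scale for incidences.

Draws are stored signed as post-minus-pre; reporting layers may flip the
sign for display (a published "reduction of 18.8 pp" is mean_diff = -18.8
here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .posterior_engine import PosteriorDraws

__all__ = [
    "ContrastResult",
    "make_contrast",
    "percentile_interval",
    "hpd_interval",
    "probability_mass_positive",
    "sign_masses",
]

Scale = Literal["pp", "per_100_games"]


@dataclass(frozen=True)
class ContrastResult:
    """Summary of the posterior between-cohort difference for one variable."""

    variable: str
    scale: Scale
    mean_diff: float
    cri90: tuple[float, float]
    cri70: tuple[float, float]
    pm_positive: float
    pm_negative: float
    ties: float
    n_draws: int

    def __post_init__(self) -> None:
        lo90, hi90 = self.cri90
        lo70, hi70 = self.cri70
        if not (lo90 <= lo70 <= hi70 <= hi90):
            raise ValueError("credible intervals must nest: 90% contains 70%")
        if abs(self.pm_positive + self.pm_negative + self.ties - 1.0) > 1e-12:
            raise ValueError("sign masses must sum to 1")


def percentile_interval(diff_draws: Sequence[float], mass: float) -> tuple[float, float]:
    """Equal-tailed central interval: quantiles at (1-mass)/2 and 1-(1-mass)/2.

    Linear interpolation between order statistics (the numpy default).
    """
    draws = np.asarray(diff_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot compute an interval from no draws")
    if not 0 < mass <= 1:
        raise ValueError("interval mass must lie in (0, 1]")
    tail = (1.0 - mass) / 2.0
    lo, hi = np.quantile(draws, [tail, 1.0 - tail])
    return float(lo), float(hi)


def hpd_interval(diff_draws: Sequence[float], mass: float) -> tuple[float, float]:
    """Highest-posterior-density interval (optional alternative reporting)."""
    import arviz as az

    draws = np.asarray(diff_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot compute an interval from no draws")
    lo, hi = az.hdi(draws, hdi_prob=mass)
    return float(lo), float(hi)


def sign_masses(diff_draws: Sequence[float]) -> tuple[float, float, float]:
    """(positive, negative, exactly-zero) fractions of the difference draws."""
    draws = np.asarray(diff_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot compute sign masses from no draws")
    pos = float(np.mean(draws > 0))
    neg = float(np.mean(draws < 0))
    return pos, neg, 1.0 - pos - neg


def probability_mass_positive(diff_draws: Sequence[float]) -> float:
    """Fraction of difference draws strictly above zero."""
    return sign_masses(diff_draws)[0]


def make_contrast(
    draws_pre: PosteriorDraws,
    draws_post: PosteriorDraws,
    scale: Scale,
    seed: int = 0,
    interval_kind: Literal["percentile", "hpd"] = "percentile",
) -> tuple[ContrastResult, np.ndarray]:
    """Pair two cohorts' posterior draws and summarize their difference.

    The cohorts are independent, so draws are paired draw-by-draw after an
    independent seeded shuffle of each collection — in particular the
    deterministic quantile-spaced quadrature pseudo-draws become a valid
    Monte-Carlo sample of the joint (pre, post) distribution.  Returns the
    summary together with the shuffled difference draws (for plotting).
    """
    if draws_pre.n_draws != draws_post.n_draws:
        raise ValueError(
            f"mismatched draw counts: {draws_pre.n_draws} vs {draws_post.n_draws}"
        )
    if draws_pre.variable != draws_post.variable:
        raise ValueError(
            f"mismatched variables: {draws_pre.variable!r} vs {draws_post.variable!r}"
        )
    rng = np.random.default_rng(seed)
    pre = rng.permutation(draws_pre.draws_prob)
    post = rng.permutation(draws_post.draws_prob)
    diff = 100.0 * (post - pre)

    interval = percentile_interval if interval_kind == "percentile" else hpd_interval
    pos, neg, ties = sign_masses(diff)
    result = ContrastResult(
        variable=draws_pre.variable,
        scale=scale,
        mean_diff=float(diff.mean()),
        cri90=interval(diff, 0.90),
        cri70=interval(diff, 0.70),
        pm_positive=pos,
        pm_negative=neg,
        ties=ties,
        n_draws=int(diff.size),
    )
    return result, diff
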