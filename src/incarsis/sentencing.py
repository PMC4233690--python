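"""Race-specific sentence-length distributions (months served).

Sentence lengths play the role of the SIS infectious period: an agent is
"infectious" to its family and close friends for exactly as many months as
it is incarcerated.  Published summaries for drug possession give only a
mean and a median per race (Whites: mean 14, median 10; Blacks: mean 17,
median 12), so we fit a negative binomial by moment/quantile matching.

The fitted law is a negative binomial on {0, 1, 2, ...} shifted by +1
month, so the support is {1, 2, ...}: a zero-month sentence would make the
infectious period empty and the monthly-rate derivation ill-defined.  The
mean constraint applies to the shifted variable.  Fitting is a
deterministic grid search over the dispersion parameter ``r`` (scipy's
``n``), with the success probability solved from the mean constraint; among
parameterisations whose CDF-based integer median hits the target exactly,
the smallest ``r`` is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

GRID_LO = 0.05
GRID_HI = 50.0
GRID_STEP = 0.005


class SentenceFitError(ValueError):
    """Raised when no negative-binomial parameterisation attains the targets."""


@dataclass(frozen=True)
class SentenceDistribution:
    """A fitted sentence-length law on integer months >= 1.

    ``r`` and ``q`` are the scipy ``nbinom(n=r, p=q)`` parameters of the
    unshifted variable; ``shift`` months (always 1) are added to every
    draw.  ``degenerate`` marks the point-mass corner used when the target
    mean equals the target median.
    """

    label: str
    r: float
    q: float
    shift: int = 1
    degenerate: bool = False
    point_mass: int = 0
    achieved_mean: float = field(default=0.0)
    achieved_median: int = field(default=0)

    # ---------------------------------------------------------------- law
    def mean(self) -> float:
        if self.degenerate:
            return float(self.point_mass)
        return self.shift + self.r * (1 - self.q) / self.q

    def median(self) -> int:
        """Smallest integer m with CDF(m) >= 0.5."""
        if self.degenerate:
            return self.point_mass
        return self.shift + int(stats.nbinom.ppf(0.5, self.r, self.q))

    def pmf(self, months) -> np.ndarray:
        months = np.asarray(months)
        if self.degenerate:
            return np.where(months == self.point_mass, 1.0, 0.0)
        return stats.nbinom.pmf(months - self.shift, self.r, self.q)

    def cdf(self, months) -> np.ndarray:
        months = np.asarray(months)
        if self.degenerate:
            return np.where(months >= self.point_mass, 1.0, 0.0)
        return stats.nbinom.cdf(months - self.shift, self.r, self.q)

    def sample(self, rng: np.random.Generator, size=None):
        """Draw integer sentence lengths (months, >= 1)."""
        if self.degenerate:
            if size is None:
                return self.point_mass
            return np.full(size, self.point_mass, dtype=np.int64)
        draws = rng.negative_binomial(self.r, self.q, size=size)
        return draws + self.shift

    def support_upper(self, tail_mass: float = 1e-10) -> int:
        """Smallest s_max whose survivor mass beyond it is < tail_mass."""
        if self.degenerate:
            return self.point_mass
        return self.shift + int(stats.nbinom.isf(tail_mass, self.r, self.q))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "r": self.r,
            "q": self.q,
            "shift": self.shift,
            "degenerate": self.degenerate,
            "point_mass": self.point_mass,
            "achieved_mean": self.achieved_mean,
            "achieved_median": self.achieved_median,
        }


def fit_negative_binomial(
    target_mean: float, target_median: int, label: str = ""
) -> SentenceDistribution:
    """Fit a shifted negative binomial to a (mean, median) pair.

    The dispersion parameter is scanned over ``(0.05, 50]`` in steps of
    0.005; for each candidate the success probability is solved exactly
    from the mean constraint, so every candidate matches the mean and the
    search reduces to hitting the integer median.  Among feasible
    candidates the smallest dispersion parameter wins (determinism).
    """
    if target_median < 1:
        raise SentenceFitError("target median must be >= 1 month")
    if target_mean < target_median:
        raise SentenceFitError(
            "right-skew required: target mean must be >= target median"
        )
    if target_mean == target_median:
        m = int(target_median)
        return SentenceDistribution(
            label=label, r=np.nan, q=np.nan, degenerate=True, point_mass=m,
            achieved_mean=float(m), achieved_median=m,
        )

    shifted_mean = target_mean - 1
    shifted_median = target_median - 1
    rs = np.arange(GRID_LO + GRID_STEP, GRID_HI + GRID_STEP / 2, GRID_STEP)
    qs = rs / (rs + shifted_mean)
    medians = stats.nbinom.ppf(0.5, rs, qs)
    hits = np.flatnonzero(medians == shifted_median)
    if hits.size == 0:
        attained = np.unique(medians[np.isfinite(medians)]).astype(int) + 1
        nearest = attained[np.argmin(np.abs(attained - target_median))]
        raise SentenceFitError(
            f"no parameterisation with mean {target_mean} attains median "
            f"{target_median}; nearest attainable median is {nearest}"
        )
    r = float(rs[hits[0]])
    q = float(qs[hits[0]])
    dist = SentenceDistribution(label=label, r=r, q=q)
    return SentenceDistribution(
        label=label, r=r, q=q,
        achieved_mean=dist.mean(), achieved_median=dist.median(),
    )


def sample_sentence(dist: SentenceDistribution, rng: np.random.Generator, size=None):
    """Draw sentence length(s) in months from a fitted distribution."""
    return dist.sample(rng, size=size)


# Published summary statistics for months served for drug possession.
WHITE_TARGETS = (14.0, 10)
BLACK_TARGETS = (17.0, 12)


def default_distributions() -> dict:
    """Fitted White and Black sentence distributions at the packaged targets."""
    return {
        "white": fit_negative_binomial(*WHITE_TARGETS, label="white"),
        "black": fit_negative_binomial(*BLACK_TARGETS, label="black"),
    }
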