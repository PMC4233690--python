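"""Non-contagious control: spontaneous incarceration at a flat monthly rate.

The control keeps every piece of bookkeeping of the contact model (clock,
sentences, deaths, eligibility, event-log schema) but switches the
mechanism of interest off: each susceptible, alive, incarcerable-age agent
becomes incarcerated independently with probability ``spontaneous_rate``
per month, regardless of its neighbours' states.

For a small rate pi0 and mean sentence E[s], flow balance (new spells per
month = releases per month) gives the closed-form equilibrium prevalence
``pi0 * E[s] / (1 + pi0 * E[s])``, which both anchors the rate tuner and
serves as an independent oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .engine import EngineError, EnsembleResult, EpidemicConfig, \
    SimulationResult, run_ensemble, run_epidemic
from .population import SyntheticPopulation
from .sentencing import SentenceDistribution


@dataclass
class NullConfig:
    sentence_dist: SentenceDistribution
    spontaneous_rate: float = 0.0
    init_prevalence: float = 0.01
    horizon: int = 600
    n_replicates: int = 250
    min_incarcerable_age: int = 15
    epidemic_start_year: int = 150
    rng_seed: int = 0

    def to_epidemic_config(self) -> EpidemicConfig:
        return EpidemicConfig(
            sentence_dist=self.sentence_dist, rate_table=None,
            init_prevalence=self.init_prevalence, horizon=self.horizon,
            n_replicates=self.n_replicates,
            min_incarcerable_age=self.min_incarcerable_age,
            epidemic_start_year=self.epidemic_start_year,
            rng_seed=self.rng_seed,
            spontaneous_rate=self.spontaneous_rate)


def run_null_epidemic(population: SyntheticPopulation, config: NullConfig,
                      seed: int | None = None) -> SimulationResult:
    """One replicate of the non-contagious model (same log schema as SIS)."""
    return run_epidemic(population, config.to_epidemic_config(), seed)


def run_null_ensemble(population: SyntheticPopulation, config: NullConfig,
                      base_seed: int | None = None) -> EnsembleResult:
    return run_ensemble(population, config.to_epidemic_config(), base_seed)


def equilibrium_prevalence(rate: float, mean_sentence: float) -> float:
    """Flow-balance equilibrium pi0*E[s] / (1 + pi0*E[s])."""
    x = rate * mean_sentence
    return x / (1.0 + x)


def analytic_rate_guess(target_prevalence: float, mean_sentence: float) -> float:
    """Invert the flow-balance equilibrium for the spontaneous rate."""
    if not 0 <= target_prevalence < 1:
        raise EngineError("target prevalence must lie in [0, 1)")
    return target_prevalence / ((1.0 - target_prevalence) * mean_sentence)


def tune_spontaneous_rate(population: SyntheticPopulation, config: NullConfig,
                          target_prevalence: float, tolerance: float = 0.003,
                          n_replicates: int = 25, base_seed: int = 0,
                          max_iter: int = 30) -> float:
    """Bisection on the rate against ensemble-mean final prevalence.

    Starts from the flow-balance analytic guess and brackets by doubling /
    halving; a reduced replicate count keeps each evaluation cheap.
    """
    if target_prevalence == 0:
        return 0.0
    if not 0 < target_prevalence < 1:
        raise EngineError("target prevalence must lie in (0, 1)")

    def final_prev(rate: float) -> float:
        cfg = replace(config, spontaneous_rate=rate, n_replicates=n_replicates)
        ens = run_null_ensemble(population, cfg, base_seed=base_seed)
        return ens.final_mean_prevalence

    guess = analytic_rate_guess(target_prevalence, config.sentence_dist.mean())
    lo, hi = guess / 4, guess * 4
    f_lo, f_hi = final_prev(lo), final_prev(hi)
    if not (f_lo < target_prevalence < f_hi):
        raise EngineError(
            f"bisection bounds do not bracket the target "
            f"(final prevalence {f_lo:.4f} at rate {lo:.3g}, "
            f"{f_hi:.4f} at rate {hi:.3g})")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = final_prev(mid)
        if abs(f_mid - target_prevalence) <= tolerance:
            return mid
        if f_mid < target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
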