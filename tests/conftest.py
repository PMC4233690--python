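"""Shared fixtures: default population/network and the session ensembles.

The expensive objects (full-scale population, 50-replicate ensembles) are
session-scoped and lazily built, so unit-test-only runs never pay for
them while the ensemble-level tests share one set of simulations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from incarsis.engine import CompiledNetwork, EpidemicConfig, run_ensemble
from incarsis.lifetable import LifeTable
from incarsis.nullmodel import NullConfig, run_null_ensemble, \
    tune_spontaneous_rate
from incarsis.population import PopulationConfig, SyntheticPopulation, \
    generate_population
from incarsis.sentencing import default_distributions
from incarsis.transmission import MonthlyRateTable, SurveyTable

POP_SEED = 1
ENSEMBLE_REPLICATES = 50
ENSEMBLE_BASE_SEED = 20_000


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return LifeTable.default()


@pytest.fixture(scope="session")
def dists() -> dict:
    return default_distributions()


@pytest.fixture(scope="session")
def rate_table() -> MonthlyRateTable:
    return SurveyTable.default().derive_monthly()


@pytest.fixture(scope="session")
def population() -> SyntheticPopulation:
    return generate_population(PopulationConfig(), seed=POP_SEED)


@pytest.fixture(scope="session")
def network(population, rate_table) -> CompiledNetwork:
    return CompiledNetwork(population, rate_table)


@pytest.fixture(scope="session")
def clock_maps(population):
    ag = population.agents
    birth = dict(zip(ag["id"], (ag["birth_year"] - 150) * 12))
    death = dict(zip(ag["id"], (ag["death_year"] - 150) * 12))
    return birth, death


def _contact_ensemble(network, dists, rate_table, race, init, horizon,
                      seed_offset):
    cfg = EpidemicConfig(sentence_dist=dists[race], rate_table=rate_table,
                         init_prevalence=init, horizon=horizon,
                         n_replicates=ENSEMBLE_REPLICATES)
    return run_ensemble(network, cfg,
                        base_seed=ENSEMBLE_BASE_SEED + seed_offset)


@pytest.fixture(scope="session")
def ens_black_600(network, dists, rate_table):
    return _contact_ensemble(network, dists, rate_table, "black", 0.01, 600, 0)


@pytest.fixture(scope="session")
def ens_white_600(network, dists, rate_table):
    return _contact_ensemble(network, dists, rate_table, "white", 0.01, 600, 1000)


@pytest.fixture(scope="session")
def ens_black_300(network, dists, rate_table):
    return _contact_ensemble(network, dists, rate_table, "black", 0.01, 300, 2000)


@pytest.fixture(scope="session")
def ens_white_300_low(network, dists, rate_table):
    return _contact_ensemble(network, dists, rate_table, "white", 0.0015, 300,
                             3000)


@pytest.fixture(scope="session")
def tuned_null_rate(population, dists):
    ncfg = NullConfig(sentence_dist=dists["black"], init_prevalence=0.01,
                      horizon=600)
    return tune_spontaneous_rate(population, ncfg, target_prevalence=0.03,
                                 tolerance=0.003, n_replicates=10,
                                 base_seed=ENSEMBLE_BASE_SEED + 4000)


@pytest.fixture(scope="session")
def null_black_600(population, dists, tuned_null_rate):
    cfg = NullConfig(sentence_dist=dists["black"],
                     spontaneous_rate=tuned_null_rate, init_prevalence=0.01,
                     horizon=600, n_replicates=ENSEMBLE_REPLICATES)
    return run_null_ensemble(population, cfg,
                             base_seed=ENSEMBLE_BASE_SEED + 5000)


@pytest.fixture(scope="session")
def null_white_600(population, dists, tuned_null_rate):
    cfg = NullConfig(sentence_dist=dists["white"],
                     spontaneous_rate=tuned_null_rate, init_prevalence=0.01,
                     horizon=600, n_replicates=ENSEMBLE_REPLICATES)
    return run_null_ensemble(population, cfg,
                             base_seed=ENSEMBLE_BASE_SEED + 6000)


# --------------------------------------------------------------- helpers


def make_static_population(agents_rows, ties_rows) -> SyntheticPopulation:
    """Hand-built population for engine-level tests.

    ``agents_rows``: (id, sex, birth_year, death_year, x, y, mother, father);
    ``ties_rows``: (agent_a, agent_b, relation, parent_endpoint).
    """
    agents = pd.DataFrame(agents_rows, columns=[
        "id", "sex", "birth_year", "death_year", "x", "y",
        "mother_id", "father_id"])
    agents["age_first_birth"] = np.nan
    agents["n_children"] = np.nan
    ties = pd.DataFrame(ties_rows, columns=[
        "agent_a", "agent_b", "relation", "parent_endpoint"])
    return SyntheticPopulation(agents=agents, ties=ties, retained_from=150,
                               total_iterations=200,
                               config=PopulationConfig())


def adult_row(i, sex="male", birth=100, death=400, x=0.5, y=0.5):
    """An agent who is a 50-year-old adult at epidemic month 0 and never dies
    within any test horizon."""
    return (i, sex, birth, death, x, y, -1, -1)
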