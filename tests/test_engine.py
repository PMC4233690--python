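"""Epidemic engine: bookkeeping contracts, stochastic rates, determinism."""

import numpy as np
import pandas as pd
import pytest

from conftest import adult_row, make_static_population
from incarsis.engine import EngineError, EpidemicConfig, compare_ensembles, \
    initialize_states, run_ensemble, run_epidemic
from incarsis.sentencing import fit_negative_binomial
from incarsis.transmission import INMATE_SEXES, RELATIONS, MonthlyRateTable


def const_table(value: float) -> MonthlyRateTable:
    return MonthlyRateTable(
        cells={(r, s): value for r in RELATIONS for s in INMATE_SEXES})


def reconstruct_incarcerated(events: pd.DataFrame, horizon: int) -> np.ndarray:
    """Independent per-month incarcerated counts from the spell log alone.

    A spell is active over [start, end); spells truncated by the horizon are
    still being served at the horizon month itself.
    """
    counts = np.zeros(horizon + 1, dtype=int)
    for start, end, reason in zip(events["start_month"], events["end_month"],
                                  events["end_reason"]):
        counts[start:end] += 1
        if reason == "horizon":
            counts[horizon] += 1
    return counts


def assert_log_consistent(events: pd.DataFrame, horizon: int) -> None:
    assert (events["end_month"] >= events["start_month"]).all()
    released = events["end_reason"] == "released"
    assert (events.loc[released, "end_month"] ==
            events.loc[released, "start_month"]
            + events.loc[released, "sentence_months"]).all()
    other = events[~released]
    assert (other["end_month"] <=
            other["start_month"] + other["sentence_months"]).all()
    for (_, _), grp in events.groupby(["replicate", "agent"]):
        g = grp.sort_values("start_month")
        assert (g["spell_index"].to_numpy() ==
                np.arange(1, len(g) + 1)).all()
        assert (g["start_month"].to_numpy()[1:] >=
                g["end_month"].to_numpy()[:-1]).all()


@pytest.fixture()
def pair_pop():
    """Two adult brothers, alive throughout."""
    return make_static_population(
        [adult_row(0, "male"), adult_row(1, "male")],
        [(0, 1, "sibling", -1)])


def test_infection_timing_contract(pair_pop):
    """An agent infected at month t with sentence 5 is infectious during
    t+1..t+5 and susceptible again at t+6."""
    cfg = EpidemicConfig(sentence_dist=fit_negative_binomial(5, 5),
                         rate_table=const_table(1.0), init_prevalence=0.5,
                         horizon=8, n_replicates=1)
    res = run_epidemic(pair_pop, cfg, replicate_seed=0)
    ev = res.events
    seed_spell = ev[ev["source"] == "initial"].iloc[0]
    assert seed_spell["start_month"] == 0
    assert seed_spell["end_month"] == 5  # released at start + sentence
    first_contact = ev[ev["source"] == "contact"].sort_values(
        "start_month").iloc[0]
    assert first_contact["start_month"] == 1  # infected at month 0
    assert first_contact["transmitting_agent"] == seed_spell["agent"]
    assert first_contact["end_month"] == 6
    assert_log_consistent(ev, 8)


def test_no_within_month_infection_chains():
    """On a line A-B-C with certain transmission, C is reached one month
    after B, never in the same month."""
    pop = make_static_population(
        [adult_row(0, "male", x=0.1), adult_row(1, "male", x=0.2),
         adult_row(2, "male", x=0.3)],
        [(0, 1, "sibling", -1), (1, 2, "sibling", -1)])
    cfg = EpidemicConfig(sentence_dist=fit_negative_binomial(6, 6),
                         rate_table=const_table(1.0), init_prevalence=0.34,
                         horizon=4, n_replicates=1)
    res = run_epidemic(pop, cfg, replicate_seed=3)
    ev = res.events.sort_values("start_month")
    starts = ev["start_month"].tolist()
    seed_agent = ev.loc[ev["source"] == "initial", "agent"].iloc[0]
    if seed_agent == 1:  # seeded in the middle: both neighbours at month 1
        assert starts == [0, 1, 1]
    else:
        assert starts == [0, 1, 2]


def test_single_step_infection_frequency_matches_edge_rates():
    """One month of exposure reproduces the per-edge Bernoulli rates
    (brother 0.0333.., sister 0.004 for the default table) across thousands
    of independent sibling pairs."""
    n_pairs = 20_000
    rows, ties = [], []
    for k in range(n_pairs):
        rows.append(adult_row(2 * k, "female"))
        rows.append(adult_row(2 * k + 1, "male"))
        ties.append((2 * k, 2 * k + 1, "sibling", -1))
    pop = make_static_population(rows, ties)
    from incarsis.transmission import SurveyTable
    table = SurveyTable.default().derive_monthly()
    cfg = EpidemicConfig(sentence_dist=fit_negative_binomial(5, 5),
                         rate_table=table, init_prevalence=0.5, horizon=1,
                         n_replicates=1)
    res = run_epidemic(pop, cfg, replicate_seed=13)
    ev = res.events
    initial = set(ev.loc[ev["source"] == "initial", "agent"])
    infected = set(ev.loc[ev["source"] == "contact", "agent"])
    f2m = m2f = n_f2m = n_m2f = 0
    for k in range(n_pairs):
        f, m = 2 * k, 2 * k + 1
        if f in initial and m not in initial:
            n_f2m += 1
            f2m += m in infected
        if m in initial and f not in initial:
            n_m2f += 1
            m2f += f in infected
    p_b = table[("brother", "female")]
    p_s = table[("sister", "male")]
    se_b = np.sqrt(p_b * (1 - p_b) / n_f2m)
    se_s = np.sqrt(p_s * (1 - p_s) / n_m2f)
    assert f2m / n_f2m == pytest.approx(p_b, abs=3.5 * se_b)
    assert m2f / n_m2f == pytest.approx(p_s, abs=3.5 * se_s)


def test_death_truncates_spell():
    pop = make_static_population(
        [adult_row(0, "male", death=151), adult_row(1, "male", birth=145)],
        [(0, 1, "sibling", -1)])  # agent 1 is a child: ineligible
    cfg = EpidemicConfig(sentence_dist=fit_negative_binomial(30, 30),
                         rate_table=const_table(0.0), init_prevalence=0.5,
                         horizon=24, n_replicates=1)
    res = run_epidemic(pop, cfg, replicate_seed=0)
    ev = res.events
    assert len(ev) == 1
    spell = ev.iloc[0]
    assert spell["agent"] == 0
    assert spell["end_reason"] == "died"
    assert spell["end_month"] == 12  # dies at year 151 = month 12
    assert res.incarcerated[12:].sum() == 0


def test_zero_rates_decay_to_extinction(population, dists):
    cfg = EpidemicConfig(sentence_dist=dists["white"],
                         rate_table=const_table(0.0), init_prevalence=0.01,
                         horizon=120, n_replicates=1)
    res = run_epidemic(population, cfg, replicate_seed=5)
    max_sentence = res.events["sentence_months"].max()
    assert res.incarcerated[min(int(max_sentence) + 1, 120):].sum() == 0
    assert np.all(res.prevalence >= 0) and np.all(res.prevalence <= 1)


def test_same_seed_reproduces_identical_event_log(population, dists,
                                                  rate_table):
    cfg = EpidemicConfig(sentence_dist=dists["black"], rate_table=rate_table,
                         init_prevalence=0.01, horizon=60, n_replicates=1)
    a = run_epidemic(population, cfg, replicate_seed=21)
    b = run_epidemic(population, cfg, replicate_seed=21)
    pd.testing.assert_frame_equal(a.events, b.events)
    np.testing.assert_array_equal(a.incarcerated, b.incarcerated)


def test_event_log_consistency_and_series_reconstruction(population, dists,
                                                         rate_table):
    """Prevalence series and spell log describe the same epidemic."""
    cfg = EpidemicConfig(sentence_dist=dists["black"], rate_table=rate_table,
                         init_prevalence=0.01, horizon=120, n_replicates=1)
    res = run_epidemic(population, cfg, replicate_seed=2)
    assert_log_consistent(res.events, 120)
    np.testing.assert_array_equal(
        reconstruct_incarcerated(res.events, 120), res.incarcerated)
    assert np.all(res.incarcerated <= res.alive)


def test_initialize_states_counts():
    rows = [adult_row(i, "male" if i % 2 else "female") for i in range(200)]
    pop = make_static_population(rows, [])
    cfg = EpidemicConfig(sentence_dist=fit_negative_binomial(14, 10),
                         rate_table=None, init_prevalence=0.01, horizon=1)
    rng = np.random.default_rng(0)
    state, seeded = initialize_states(pop, cfg, rng)
    assert len(seeded) == 2  # round(0.01 * 200)
    assert (state == 1).sum() == 2
    cfg0 = EpidemicConfig(sentence_dist=fit_negative_binomial(14, 10),
                          rate_table=None, init_prevalence=0.0, horizon=1)
    state, seeded = initialize_states(pop, cfg0, np.random.default_rng(0))
    assert not seeded and (state == 1).sum() == 0


def test_initialize_with_no_eligible_agents_raises():
    pop = make_static_population([adult_row(0, "male", birth=145)], [])
    cfg = EpidemicConfig(sentence_dist=fit_negative_binomial(14, 10),
                         rate_table=None, init_prevalence=0.01, horizon=1)
    with pytest.raises(EngineError):
        initialize_states(pop, cfg, np.random.default_rng(0))


def test_compare_ensembles_degenerate_and_separated():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 1.0, size=(50, 10))
    shifted = a + 5.0  # 5 standard deviations apart
    res = compare_ensembles(a, shifted)
    assert (res["p_value"] < 1e-6).all()
    const = np.full((10, 4), 0.3)
    res_same = compare_ensembles(const, const.copy())
    assert res_same["degenerate"].all()
    assert (res_same["p_value"] == 1.0).all()


def test_compare_ensembles_input_validation():
    with pytest.raises(EngineError):
        compare_ensembles(np.zeros((3, 5)), np.zeros((3, 6)))
    with pytest.raises(EngineError):
        compare_ensembles(np.zeros((1, 5)), np.zeros((3, 5)))


def test_ensemble_band_and_seeding(population, dists, rate_table):
    cfg = EpidemicConfig(sentence_dist=dists["white"], rate_table=rate_table,
                         init_prevalence=0.01, horizon=24, n_replicates=4)
    ens = run_ensemble(population, cfg, base_seed=300)
    assert ens.prevalence.shape == (4, 25)
    s = ens.summary()
    assert (s["p2.5"] <= s["mean"]).all() and (s["mean"] <= s["p97.5"]).all()
    # replicate r is the single run with seed base + r
    single = run_epidemic(population, cfg, replicate_seed=302, replicate=2)
    np.testing.assert_array_equal(single.incarcerated, ens.incarcerated[2])
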