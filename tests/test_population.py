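"""Synthetic population generation: rules, invariants, demographics."""

import numpy as np
import pandas as pd
import pytest

from incarsis.lifetable import FEMALE, MALE, LifeTable
from incarsis.population import ExtinctionError, PopulationConfig, \
    PopulationError, _Builder, generate_population, sample_agent_attributes


def _immortal_table() -> LifeTable:
    q = np.zeros(120)
    q[119] = 1.0
    return LifeTable(q, q)


def _builder(**cfg_kwargs) -> _Builder:
    cfg = PopulationConfig(**cfg_kwargs)
    return _Builder(cfg, _immortal_table(), np.random.default_rng(0))


def _add(b, sex, birth, x, y, mother=-1, father=-1):
    return b._add_agent(sex, birth, x, y, mother, father)


# ------------------------------------------------------------ attributes


def test_agent_attribute_distributions():
    cfg = PopulationConfig()
    lt = LifeTable.default()
    rng = np.random.default_rng(5)
    recs = [sample_agent_attributes(cfg, lt, rng) for _ in range(20_000)]
    df = pd.DataFrame(recs)
    assert df["sex"].eq(FEMALE).mean() == pytest.approx(0.5, abs=0.01)
    fem = df[df["sex"] == FEMALE]
    assert fem["age_first_birth"].mean() == pytest.approx(25.6, abs=0.15)
    assert fem["n_children"].mean() == pytest.approx(2.07, abs=0.05)
    assert (df["death_year"] > df["birth_year"]).all()
    assert df["birth_year"].between(cfg.birth_range_lo,
                                    cfg.birth_range_hi - 1).all()
    assert df["x"].between(0, 1).all() and df["y"].between(0, 1).all()
    assert (fem["age_first_birth"] >= 15).all()


def test_config_validation_errors():
    with pytest.raises(PopulationError):
        PopulationConfig(seed_size=1).validate()
    with pytest.raises(PopulationError):
        PopulationConfig(burn_in=200, total_iterations=200).validate()
    with pytest.raises(PopulationError):
        PopulationConfig(friend_count_pmf={0: 0.5, 1: 0.4}).validate()
    with pytest.raises(PopulationError):
        PopulationConfig(partner_age_gap_lo=5, partner_age_gap_hi=1).validate()


# ------------------------------------------------------------ friendship


def test_friends_nearest_two_of_three_candidates():
    b = _builder(friend_count_pmf={2: 1.0})
    i = _add(b, MALE, 0, 0.5, 0.5)
    near = _add(b, MALE, 0, 0.5, 0.6)     # distance 0.1
    mid = _add(b, FEMALE, 1, 0.5, 0.7)    # distance 0.2, age 9 at year 10
    far = _add(b, MALE, -1, 0.5, 0.8)     # distance 0.3, age 11
    b.fire_friendships(10)
    partners = {tuple(sorted(t)) for t in b.friend_ties}
    assert (i, near) in partners and (i, mid) in partners
    assert (min(i, far), max(i, far)) not in partners


def test_friends_zero_candidates_yield_zero_ties():
    b = _builder(friend_count_pmf={3: 1.0})
    _add(b, MALE, 0, 0.5, 0.5)
    _add(b, MALE, 20, 0.5, 0.51)  # age -10 at year 10: unborn
    b.fire_friendships(10)
    assert not b.friend_ties


def test_sibling_never_selected_as_friend_even_at_distance_zero():
    b = _builder(friend_count_pmf={1: 1.0})
    mom = _add(b, FEMALE, -30, 0.5, 0.5)
    i = _add(b, MALE, 0, 0.5, 0.5, mother=mom)
    sib = _add(b, FEMALE, 1, 0.5, 0.5, mother=mom)   # same location
    other = _add(b, MALE, 1, 0.9, 0.9)               # far but eligible
    b.fire_friendships(10)
    pairs = {tuple(sorted(t)) for t in b.friend_ties}
    assert (i, sib) not in pairs
    assert (i, other) in pairs


def test_friend_age_window_is_9_to_11():
    b = _builder(friend_count_pmf={5: 1.0})
    i = _add(b, MALE, 0, 0.5, 0.5)
    too_young = _add(b, MALE, 2, 0.5, 0.52)   # age 8
    too_old = _add(b, MALE, -2, 0.5, 0.53)    # age 12
    ok = _add(b, MALE, -1, 0.5, 0.54)         # age 11
    b.fire_friendships(10)
    pairs = {tuple(sorted(t)) for t in b.friend_ties}
    assert (i, ok) in pairs
    assert not any(too_young in p or too_old in p for p in pairs)


# ------------------------------------------------------------ partnership


def test_partner_age_window_excludes_ten_years_older():
    b = _builder()
    f = _add(b, FEMALE, 0, 0.5, 0.5)
    _add(b, MALE, -10, 0.5, 0.51)  # 10 years older: outside [0, 9]
    assert b._choose_partner(f, 25) == -1


def test_partner_nearest_eligible_male_chosen():
    b = _builder()
    f = _add(b, FEMALE, 0, 0.5, 0.5)
    near = _add(b, MALE, -3, 0.5, 0.55)
    _add(b, MALE, -3, 0.5, 0.7)
    assert b._choose_partner(f, 25) == near


def test_brother_skipped_for_next_nearest_eligible_male():
    b = _builder()
    mom = _add(b, FEMALE, -30, 0.5, 0.5)
    f = _add(b, FEMALE, 0, 0.5, 0.5, mother=mom)
    _add(b, MALE, -2, 0.5, 0.5, mother=mom)       # brother at distance 0
    unrelated = _add(b, MALE, -2, 0.5, 0.6)
    assert b._choose_partner(f, 25) == unrelated


def test_married_male_not_chosen_again():
    b = _builder()
    f1 = _add(b, FEMALE, 0, 0.5, 0.5)
    f2 = _add(b, FEMALE, 0, 0.5, 0.5)
    m = _add(b, MALE, -2, 0.5, 0.55)
    assert b._choose_partner(f1, 25) == m
    b.spouse_of[f1] = m
    b.spouse_of[m] = f1
    assert b._choose_partner(f2, 25) == -1


# ------------------------------------------------------------ children


def test_children_born_and_located_near_parents_midpoint():
    b = _builder(children_count_pmf={3: 1.0})
    mom = _add(b, FEMALE, 0, 0.2, 0.2)
    dad = _add(b, MALE, 0, 0.4, 0.2)
    b.n_children[mom] = 3
    b._schedule_children(mom, dad, 25)
    # first child exists now, born in the current year
    kids = b.children_of_mother[mom]
    assert len(kids) >= 1 and b.birth[kids[0]] == 25
    # realize the remaining scheduled births
    for year in range(26, 80):
        b.fire_births(year)
    kids = b.children_of_mother[mom]
    assert len(kids) == 3
    for k in kids:
        assert abs(b.x[k] - 0.3) <= 0.05 + 1e-12
        assert abs(b.y[k] - 0.2) <= 0.05 + 1e-12


def test_single_child_mother_has_exactly_one_child_in_current_year():
    b = _builder()
    mom = _add(b, FEMALE, 0, 0.5, 0.5)
    b.n_children[mom] = 1
    b._schedule_children(mom, -1, 30)
    for year in range(31, 90):
        b.fire_births(year)
    assert len(b.children_of_mother[mom]) == 1
    assert b.birth[b.children_of_mother[mom][0]] == 30


def test_interbirth_offsets_have_mean_4_5():
    b = _builder()
    offsets = []
    mom = _add(b, FEMALE, 0, 0.5, 0.5)
    for _ in range(30_000):
        b.birth_queue.clear()
        b.n_children[mom] = 2
        b._schedule_children(mom, -1, 100)
        for year, entries in b.birth_queue.items():
            offsets.extend([year - 100] * len(entries))
    # offsets exclude same-year (0) births realized immediately; add them back
    n_same_year = 30_000 - len(offsets)
    offsets = np.concatenate([np.asarray(offsets), np.zeros(n_same_year)])
    assert offsets.mean() == pytest.approx(4.5, abs=0.05)


# ---------------------------------------------------------- whole-run


@pytest.fixture(scope="module")
def small_pop():
    cfg = PopulationConfig(seed_size=400, total_iterations=120, burn_in=80)
    return generate_population(cfg, seed=9)


def test_generation_is_deterministic(small_pop):
    cfg = PopulationConfig(seed_size=400, total_iterations=120, burn_in=80)
    again = generate_population(cfg, seed=9)
    pd.testing.assert_frame_equal(small_pop.agents, again.agents)
    pd.testing.assert_frame_equal(small_pop.ties, again.ties)


def test_referential_integrity_and_no_duplicate_pairs(small_pop):
    ids = set(small_pop.agents["id"])
    ties = small_pop.ties
    assert ties["agent_a"].isin(ids).all()
    assert ties["agent_b"].isin(ids).all()
    assert (ties["agent_a"] != ties["agent_b"]).all()
    pairs = ties.apply(lambda r: (min(r.agent_a, r.agent_b),
                                  max(r.agent_a, r.agent_b)), axis=1)
    assert pairs.is_unique


def test_retention_rule(small_pop):
    assert (small_pop.agents["death_year"] > small_pop.retained_from).all()


def test_sibling_closure(small_pop):
    ag = small_pop.agents
    with_mother = ag[ag["mother_id"] >= 0]
    sib_ties = small_pop.ties.query("relation == 'sibling'")
    have = {(min(a, b), max(a, b))
            for a, b in zip(sib_ties["agent_a"], sib_ties["agent_b"])}
    for _, grp in with_mother.groupby("mother_id"):
        kids = sorted(grp["id"])
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                assert (kids[i], kids[j]) in have


def test_parent_child_age_logic(small_pop):
    ag = small_pop.agents.set_index("id")
    pc = small_pop.ties.query("relation == 'parent_child'")
    for _, row in pc.iterrows():
        parent = row["parent_endpoint"]
        child = row["agent_b"] if row["agent_a"] == parent else row["agent_a"]
        assert ag.loc[parent, "birth_year"] + 15 <= ag.loc[child, "birth_year"]


def test_default_scale_matches_reference_order_of_magnitude(population):
    """Full-size run stays in the thousands of agents / tens of thousands of
    ties, the scale of the reference realisation."""
    assert 3_000 <= population.n_agents <= 20_000
    assert 10_000 <= population.n_ties <= 120_000


def test_extinction_raises_named_year():
    q = np.ones(120)  # everyone dies at age 0
    lt = LifeTable(q, q)
    cfg = PopulationConfig(seed_size=5, total_iterations=100, burn_in=50,
                           birth_range_lo=-10, birth_range_hi=0)
    with pytest.raises(ExtinctionError, match="year"):
        generate_population(cfg, lt, seed=0)


def test_csv_round_trip(small_pop, tmp_path):
    small_pop.to_csv(tmp_path / "agents.csv", tmp_path / "ties.csv")
    from incarsis.population import SyntheticPopulation
    back = SyntheticPopulation.from_csv(tmp_path / "agents.csv",
                                        tmp_path / "ties.csv",
                                        retained_from=80,
                                        total_iterations=120)
    pd.testing.assert_frame_equal(
        back.agents, small_pop.agents, check_dtype=False)
    pd.testing.assert_frame_equal(back.ties, small_pop.ties, check_dtype=False)
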