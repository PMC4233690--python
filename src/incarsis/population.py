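"""Synthetic multi-generational population with kinship and friendship ties.

The generator builds the influence network over which incarceration
"transmits".  Starting from a founder cohort (default 1500 agents born
uniformly over the 60 years before iteration 0), a yearly clock fires, in
fixed order within each year: scheduled births, friendship formation for
agents turning 10, partner assignment plus child scheduling for females
reaching their age at first birth, and deaths (implicit through each
agent's death year).  The first 150 iterations are a burn-in; agents alive
at any time at or after the burn-in year are retained, together with all
parent-child, sibling, spouse and close-friend ties among them.

Attribute distributions: sex ~ Bernoulli(0.5); lifespan from an annual
life table; age at first birth 15 + Poisson(10.6) (mean 25.6 years);
number of children from a configurable pmf with mean 2.07; inter-birth
offsets iid Poisson(4.5) added to the first-birth year; locations in the
unit square, children placed at the parents' midpoint plus Uniform(+-0.05)
noise per axis.  Friends are the nearest (Euclidean) non-sibling agents
aged 9-11 at the chooser's 10th birthday; partners are the nearest
unrelated, non-friend, unmarried male 0-9 years older than the mother in
her first-birth year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetable import FEMALE, MALE, LifeTable

DEFAULT_FRIEND_PMF = {0: 0.25, 1: 0.30, 2: 0.25, 3: 0.15, 4: 0.04, 5: 0.01}
DEFAULT_CHILDREN_PMF = {0: 0.15, 1: 0.17, 2: 0.33, 3: 0.21, 4: 0.09, 5: 0.05}

RELATION_LABELS = ("parent_child", "sibling", "spouse", "friend")


class PopulationError(ValueError):
    pass


class ExtinctionError(RuntimeError):
    """Population died out before the end of burn-in."""


@dataclass
class PopulationConfig:
    seed_size: int = 1500
    birth_range_lo: int = -60
    birth_range_hi: int = 0
    total_iterations: int = 200
    burn_in: int = 150
    friend_count_pmf: dict = field(default_factory=lambda: dict(DEFAULT_FRIEND_PMF))
    children_count_pmf: dict = field(default_factory=lambda: dict(DEFAULT_CHILDREN_PMF))
    age_first_birth_min: int = 15
    age_first_birth_offset_mean: float = 10.6
    interbirth_mean: float = 4.5
    partner_age_gap_lo: int = 0
    partner_age_gap_hi: int = 9
    friend_age_lo: int = 9
    friend_age_hi: int = 11
    friendship_age: int = 10
    child_location_noise: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        if self.seed_size < 2:
            raise PopulationError("seed_size must be >= 2")
        if not self.burn_in < self.total_iterations:
            raise PopulationError("burn_in must be < total_iterations")
        if self.birth_range_lo >= self.birth_range_hi:
            raise PopulationError("birth range must be non-empty (lo < hi)")
        if self.partner_age_gap_lo > self.partner_age_gap_hi:
            raise PopulationError("partner age gap bounds out of order")
        for name, pmf in (("friend_count_pmf", self.friend_count_pmf),
                          ("children_count_pmf", self.children_count_pmf)):
            total = sum(pmf.values())
            if abs(total - 1.0) > 1e-9:
                raise PopulationError(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in pmf.values()):
                raise PopulationError(f"{name} has negative probabilities")


def _pmf_arrays(pmf: dict):
    ks = np.array(sorted(pmf), dtype=np.int64)
    ps = np.array([pmf[int(k)] for k in ks], dtype=float)
    return ks, ps / ps.sum()


@dataclass(frozen=True)
class SyntheticPopulation:
    """Retained agents and ties, on the population (years) clock.

    ``agents`` columns: id, sex, birth_year, death_year, x, y, mother_id,
    father_id, age_first_birth, n_children (NaN where not applicable; ids
    of discarded parents are kept so pedigree remains interpretable).
    ``ties`` columns: agent_a, agent_b, relation, parent_endpoint (the id
    of the parent for parent_child ties, else -1); both endpoints always
    retained; unordered pairs unique.
    """

    agents: pd.DataFrame
    ties: pd.DataFrame
    retained_from: int
    total_iterations: int
    config: PopulationConfig

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    @property
    def n_ties(self) -> int:
        return len(self.ties)

    def to_csv(self, agents_path, ties_path) -> None:
        self.agents.to_csv(agents_path, index=False)
        self.ties.to_csv(ties_path, index=False)

    @classmethod
    def from_csv(cls, agents_path, ties_path, retained_from: int = 150,
                 total_iterations: int = 200,
                 config: PopulationConfig | None = None) -> "SyntheticPopulation":
        return cls(
            agents=pd.read_csv(agents_path),
            ties=pd.read_csv(ties_path),
            retained_from=retained_from,
            total_iterations=total_iterations,
            config=config or PopulationConfig(),
        )


# ---------------------------------------------------------------- sampling


def sample_agent_attributes(config: PopulationConfig, life_table: LifeTable,
                            rng: np.random.Generator) -> dict:
    """One founder's attributes: sex, birth/death years, location, fertility."""
    sex = FEMALE if rng.random() < 0.5 else MALE
    birth = int(rng.integers(config.birth_range_lo, config.birth_range_hi))
    x, y = rng.random(), rng.random()
    lifespan = int(life_table.sample_lifespan(sex, rng))
    rec = {
        "sex": sex, "birth_year": birth, "death_year": birth + lifespan + 1,
        "x": x, "y": y, "mother_id": -1, "father_id": -1,
        "age_first_birth": np.nan, "n_children": np.nan,
    }
    if sex == FEMALE:
        ks, ps = _pmf_arrays(config.children_count_pmf)
        rec["age_first_birth"] = config.age_first_birth_min + int(
            rng.poisson(config.age_first_birth_offset_mean))
        rec["n_children"] = int(rng.choice(ks, p=ps))
    return rec


# ---------------------------------------------------------------- builder


class _Builder:
    """Mutable state for one generation run; rng consumption order is the
    within-year event order (births, friendships, partnerships) with agents
    visited in ascending id order."""

    def __init__(self, config: PopulationConfig, life_table: LifeTable,
                 rng: np.random.Generator):
        self.cfg = config
        self.lt = life_table
        self.rng = rng
        # parallel per-agent lists
        self.sex: list[str] = []
        self.birth: list[int] = []
        self.death: list[int] = []
        self.x: list[float] = []
        self.y: list[float] = []
        self.mother: list[int] = []
        self.father: list[int] = []
        self.h: list[float] = []          # age at first birth (females)
        self.n_children: list[float] = []
        self.born_in: dict[int, list[int]] = {}   # birth year -> agent ids
        self.birth_queue: dict[int, list] = {}    # year -> [(mother, father)]
        self.friend_ties: set[tuple[int, int]] = set()
        self.friends_of: dict[int, set[int]] = {}
        self.spouse_ties: list[tuple[int, int]] = []
        self.spouse_of: dict[int, int] = {}
        self.children_of_mother: dict[int, list[int]] = {}
        self.friend_ks, self.friend_ps = _pmf_arrays(config.friend_count_pmf)
        self.child_ks, self.child_ps = _pmf_arrays(config.children_count_pmf)

    # -- agent creation -------------------------------------------------
    def _add_agent(self, sex, birth, x, y, mother, father) -> int:
        i = len(self.sex)
        lifespan = int(self.lt.sample_lifespan(sex, self.rng))
        self.sex.append(sex)
        self.birth.append(birth)
        self.death.append(birth + lifespan + 1)
        self.x.append(x)
        self.y.append(y)
        self.mother.append(mother)
        self.father.append(father)
        if sex == FEMALE:
            self.h.append(self.cfg.age_first_birth_min
                          + int(self.rng.poisson(self.cfg.age_first_birth_offset_mean)))
            self.n_children.append(int(self.rng.choice(self.child_ks, p=self.child_ps)))
        else:
            self.h.append(np.nan)
            self.n_children.append(np.nan)
        self.born_in.setdefault(birth, []).append(i)
        if mother >= 0:
            self.children_of_mother.setdefault(mother, []).append(i)
        return i

    def add_founder(self) -> int:
        sex = FEMALE if self.rng.random() < 0.5 else MALE
        birth = int(self.rng.integers(self.cfg.birth_range_lo, self.cfg.birth_range_hi))
        x, y = self.rng.random(), self.rng.random()
        return self._add_agent(sex, birth, x, y, -1, -1)

    def alive(self, i: int, year: int) -> bool:
        return self.birth[i] <= year < self.death[i]

    # -- yearly events ---------------------------------------------------
    def fire_births(self, year: int) -> None:
        noise = self.cfg.child_location_noise
        for mother, father in self.birth_queue.pop(year, []):
            if not self.alive(mother, year):
                continue
            if father >= 0:
                mx = 0.5 * (self.x[mother] + self.x[father])
                my = 0.5 * (self.y[mother] + self.y[father])
            else:
                mx, my = self.x[mother], self.y[mother]
            cx = float(np.clip(mx + self.rng.uniform(-noise, noise), 0.0, 1.0))
            cy = float(np.clip(my + self.rng.uniform(-noise, noise), 0.0, 1.0))
            sex = FEMALE if self.rng.random() < 0.5 else MALE
            self._add_agent(sex, year, cx, cy, mother, father)

    def _siblings(self, i: int) -> set[int]:
        # monogamy => sharing a father implies sharing the mother
        m = self.mother[i]
        sibs = set(self.children_of_mother.get(m, [])) if m >= 0 else set()
        sibs.discard(i)
        return sibs

    def fire_friendships(self, year: int) -> None:
        cfg = self.cfg
        choosers = [i for i in self.born_in.get(year - cfg.friendship_age, [])
                    if self.alive(i, year)]
        if not choosers:
            return
        cand_ids = []
        for age in range(cfg.friend_age_lo, cfg.friend_age_hi + 1):
            cand_ids.extend(j for j in self.born_in.get(year - age, [])
                            if self.alive(j, year))
        cand_ids = np.array(sorted(cand_ids), dtype=np.int64)
        if cand_ids.size:
            cx = np.array([self.x[j] for j in cand_ids])
            cy = np.array([self.y[j] for j in cand_ids])
        for i in choosers:
            f_i = int(self.rng.choice(self.friend_ks, p=self.friend_ps))
            if f_i == 0 or cand_ids.size == 0:
                continue
            sibs = self._siblings(i)
            mask = cand_ids != i
            if sibs:
                mask &= ~np.isin(cand_ids, list(sibs))
            pool = cand_ids[mask]
            if pool.size == 0:
                continue
            d2 = (cx[mask] - self.x[i]) ** 2 + (cy[mask] - self.y[i]) ** 2
            order = np.argsort(d2, kind="stable")
            for j in pool[order[:f_i]]:
                self._add_friend(i, int(j))

    def _add_friend(self, i: int, j: int) -> None:
        key = (i, j) if i < j else (j, i)
        if key in self.friend_ties:
            return
        self.friend_ties.add(key)
        self.friends_of.setdefault(i, set()).add(j)
        self.friends_of.setdefault(j, set()).add(i)

    def _close_kin(self, i: int) -> set[int]:
        """Ancestors within two generations: parents and grandparents."""
        out = set()
        for p in (self.mother[i], self.father[i]):
            if p >= 0:
                out.add(p)
                for g in (self.mother[p], self.father[p]):
                    if g >= 0:
                        out.add(g)
        return out

    def _related(self, a: int, b: int) -> bool:
        """Share an ancestor within two generations, or one is such an
        ancestor of the other."""
        ka = self._close_kin(a)
        kb = self._close_kin(b)
        return a in kb or b in ka or bool(ka & kb)

    def fire_partnerships(self, year: int) -> None:
        cfg = self.cfg
        mothers = []
        for birth_year, ids in list(self.born_in.items()):
            age = year - birth_year
            if age < cfg.age_first_birth_min:
                continue
            for i in ids:
                if (self.sex[i] == FEMALE and self.alive(i, year)
                        and self.h[i] == age and self.n_children[i] >= 1):
                    mothers.append(i)
        for i in sorted(mothers):
            partner = self._choose_partner(i, year)
            if partner >= 0:
                self.spouse_ties.append((i, partner) if i < partner else (partner, i))
                self.spouse_of[i] = partner
                self.spouse_of[partner] = i
            self._schedule_children(i, partner, year)

    def _choose_partner(self, i: int, year: int) -> int:
        cfg = self.cfg
        age = year - self.birth[i]
        cands = []
        for gap in range(cfg.partner_age_gap_lo, cfg.partner_age_gap_hi + 1):
            for j in self.born_in.get(year - age - gap, []):
                if (self.sex[j] == MALE and self.alive(j, year)
                        and j not in self.spouse_of
                        and j not in self.friends_of.get(i, ())
                        and not self._related(i, j)):
                    cands.append(j)
        if not cands:
            return -1
        cands = np.array(sorted(cands), dtype=np.int64)
        d2 = ((np.array([self.x[j] for j in cands]) - self.x[i]) ** 2
              + (np.array([self.y[j] for j in cands]) - self.y[i]) ** 2)
        return int(cands[np.argmin(d2)])

    def _schedule_children(self, mother: int, father: int, year: int) -> None:
        n = int(self.n_children[mother])
        self.fire_single_birth(mother, father, year)
        for _ in range(n - 1):
            offset = int(self.rng.poisson(self.cfg.interbirth_mean))
            target = year + offset
            if target == year:
                self.fire_single_birth(mother, father, year)
            else:
                self.birth_queue.setdefault(target, []).append((mother, father))

    def fire_single_birth(self, mother: int, father: int, year: int) -> None:
        self.birth_queue.setdefault(year, []).append((mother, father))
        # immediate creation keeps same-year births inside this year's pass
        self.fire_births(year)

    # -- assembly --------------------------------------------------------
    def build(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        cfg = self.cfg
        n = len(self.sex)
        birth = np.array(self.birth)
        death = np.array(self.death)
        retained = death > cfg.burn_in
        agents = pd.DataFrame({
            "id": np.arange(n), "sex": self.sex, "birth_year": birth,
            "death_year": death, "x": self.x, "y": self.y,
            "mother_id": self.mother, "father_id": self.father,
            "age_first_birth": self.h, "n_children": self.n_children,
        })[retained].reset_index(drop=True)
        keep = set(agents["id"].tolist())

        rows = []
        for i in agents["id"]:
            for p in (self.mother[i], self.father[i]):
                if p in keep:
                    a, b = (p, i) if p < i else (i, p)
                    rows.append((a, b, "parent_child", p))
        sib_seen = set()
        for kids in self.children_of_mother.values():
            kept = sorted(k for k in kids if k in keep)
            for u in range(len(kept)):
                for v in range(u + 1, len(kept)):
                    key = (kept[u], kept[v])
                    if key not in sib_seen:
                        sib_seen.add(key)
                        rows.append((*key, "sibling", -1))
        for a, b in sorted(self.spouse_ties):
            if a in keep and b in keep:
                rows.append((a, b, "spouse", -1))
        for a, b in sorted(self.friend_ties):
            if a in keep and b in keep:
                rows.append((a, b, "friend", -1))
        ties = pd.DataFrame(rows, columns=["agent_a", "agent_b", "relation",
                                           "parent_endpoint"])
        return agents, ties


def generate_population(config: PopulationConfig | None = None,
                        life_table: LifeTable | None = None,
                        seed: int | None = None) -> SyntheticPopulation:
    """Run the generation algorithm and return the retained population.

    Fully reproducible from (config, seed); ``seed`` overrides
    ``config.rng_seed`` when given.  Raises :class:`ExtinctionError` if no
    agent is alive in some year up to the end of burn-in.
    """
    cfg = config or PopulationConfig()
    cfg.validate()
    lt = life_table or LifeTable.default()
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    b = _Builder(cfg, lt, rng)
    for _ in range(cfg.seed_size):
        b.add_founder()

    for year in range(cfg.birth_range_lo, cfg.total_iterations):
        b.fire_births(year)
        b.fire_friendships(year)
        b.fire_partnerships(year)
        if year <= cfg.burn_in and not any(
                bi <= year < di for bi, di in zip(b.birth, b.death)):
            raise ExtinctionError(
                f"population extinct in year {year}, before end of burn-in")

    agents, ties = b.build()
    return SyntheticPopulation(agents=agents, ties=ties,
                               retained_from=cfg.burn_in,
                               total_iterations=cfg.total_iterations, config=cfg)
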