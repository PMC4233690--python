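"""Monthly-step SIS epidemic engine on the synthetic influence network.

The epidemic clock ticks in months; month 0 corresponds to the population
clock's burn-in year (year 150 by default), so the retained 50-year window
of the population lines up with a 600-month epidemic horizon.  Each month,
in order: scheduled deaths are applied (an inmate's death truncates its
spell); every incarcerated agent attempts an independent Bernoulli
transmission to each alive, susceptible, incarcerable-age neighbour at the
relationship-resolved monthly rate (infections are computed from the
start-of-month infectious set only, so there are no within-month chains);
inmates whose sentence has run out return to the susceptible state; newly
infected agents begin a freshly drawn sentence the following month.

The same bookkeeping drives the non-contagious control
(:mod:`incarsis.nullmodel`), which replaces contact transmission with a
flat spontaneous rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .lifetable import FEMALE
from .population import SyntheticPopulation
from .sentencing import SentenceDistribution
from .transmission import DEFAULT_ADULT_CHILD_AGE, MonthlyRateTable

SUS, INC, DEAD = 0, 1, 2

EVENT_COLUMNS = ["replicate", "agent", "spell_index", "start_month",
                 "sentence_months", "end_month", "end_reason", "source",
                 "transmitting_agent"]


class EngineError(RuntimeError):
    pass


@dataclass
class EpidemicConfig:
    sentence_dist: SentenceDistribution
    rate_table: MonthlyRateTable | None
    init_prevalence: float = 0.01
    horizon: int = 600
    n_replicates: int = 250
    min_incarcerable_age: int = 15
    adult_child_age: int = DEFAULT_ADULT_CHILD_AGE
    epidemic_start_year: int = 150
    rng_seed: int = 0
    spontaneous_rate: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.init_prevalence <= 1:
            raise EngineError("init_prevalence must lie in [0, 1]")
        if self.horizon < 1 or self.n_replicates < 1:
            raise EngineError("horizon and n_replicates must be >= 1")
        if not 0 <= self.spontaneous_rate <= 1:
            raise EngineError("spontaneous_rate must lie in [0, 1]")


# ------------------------------------------------------------ compiled net


class CompiledNetwork:
    """Population compiled to month-clock arrays plus a directed-edge CSR.

    Each undirected tie yields two directed edges (infectious source ->
    susceptible target) carrying the resolved monthly rate and the first
    month at which the target is a legal transmission target (its
    incarcerable-age birthday, and for the inmate->child direction its
    adult-child birthday).
    """

    def __init__(self, population: SyntheticPopulation,
                 rate_table: MonthlyRateTable | None,
                 min_incarcerable_age: int = 15,
                 adult_child_age: int = DEFAULT_ADULT_CHILD_AGE,
                 epidemic_start_year: int = 150):
        ag = population.agents
        self.ids = ag["id"].to_numpy()
        self.n = len(ag)
        self.index = {int(i): k for k, i in enumerate(self.ids)}
        epoch = epidemic_start_year
        birth = ag["birth_year"].to_numpy()
        death = ag["death_year"].to_numpy()
        self.birth_month = (birth - epoch) * 12
        self.death_month = (death - epoch) * 12
        self.elig_from = (birth + min_incarcerable_age - epoch) * 12
        self.sex_female = (ag["sex"] == FEMALE).to_numpy()

        src, dst, rate, eff = [], [], [], []
        if rate_table is not None:
            for a, bb, rel, parent in population.ties[
                    ["agent_a", "agent_b", "relation", "parent_endpoint"]
            ].itertuples(index=False):
                ia, ib = self.index[int(a)], self.index[int(bb)]
                for i, j in ((ia, ib), (ib, ia)):  # i infectious -> j susceptible
                    r, act = self._edge_rate(i, j, rel, parent, rate_table,
                                             adult_child_age, epoch)
                    if r > 0:
                        src.append(i)
                        dst.append(j)
                        rate.append(r)
                        eff.append(max(act, self.elig_from[j]))
        order = np.lexsort((np.asarray(dst, dtype=np.int64),
                            np.asarray(src, dtype=np.int64)))
        src = np.asarray(src, dtype=np.int64)[order]
        self.edge_dst = np.asarray(dst, dtype=np.int64)[order]
        self.edge_rate = np.asarray(rate, dtype=float)[order]
        self.edge_eff = np.asarray(eff, dtype=np.int64)[order]
        self.indptr = np.zeros(self.n + 1, dtype=np.int64)
        np.add.at(self.indptr, src + 1, 1)
        np.cumsum(self.indptr, out=self.indptr)

        # deaths grouped by month (only those occurring inside any horizon)
        self.death_order = np.argsort(self.death_month, kind="stable")

    def _edge_rate(self, i, j, rel, parent, table, adult_age, epoch):
        inmate_sex = "female" if self.sex_female[i] else "male"
        sus_sex = "female" if self.sex_female[j] else "male"
        activation = np.iinfo(np.int64).min
        if rel == "parent_child":
            parent_idx = self.index[int(parent)]
            if parent_idx == j:  # susceptible is the inmate's parent
                row = "mother" if sus_sex == "female" else "father"
            else:                # susceptible is the inmate's child
                row = "adult_child"
                activation = int(self.birth_month[j] + adult_age * 12)
        elif rel in ("sibling", "friend"):
            row = "sister" if sus_sex == "female" else "brother"
        elif rel == "spouse":
            row = "spouse"
        else:
            raise EngineError(f"unknown relation label {rel!r}")
        return table[(row, inmate_sex)], activation

    def alive_counts(self, horizon: int) -> np.ndarray:
        """Alive agents at the start of each month 0..horizon."""
        months = np.arange(horizon + 1)
        starts = np.clip(self.birth_month, 0, horizon + 1)
        ends = np.clip(self.death_month, 0, horizon + 1)
        delta = np.zeros(horizon + 2, dtype=np.int64)
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
        return np.cumsum(delta)[: horizon + 1]


# ------------------------------------------------------------------ results


@dataclass
class SimulationResult:
    """One replicate: full spell log plus the monthly prevalence series."""

    events: pd.DataFrame
    months: np.ndarray
    incarcerated: np.ndarray
    alive: np.ndarray

    @property
    def prevalence(self) -> np.ndarray:
        return self.incarcerated / np.maximum(self.alive, 1)


@dataclass
class EnsembleResult:
    events: pd.DataFrame                  # pooled log with replicate column
    prevalence: np.ndarray                # (n_replicates, horizon + 1)
    incarcerated: np.ndarray
    alive: np.ndarray                     # (horizon + 1,)
    replicate_seeds: np.ndarray
    horizon: int

    def summary(self) -> pd.DataFrame:
        mean = self.prevalence.mean(axis=0)
        lo = np.percentile(self.prevalence, 2.5, axis=0)
        hi = np.percentile(self.prevalence, 97.5, axis=0)
        return pd.DataFrame({"month": np.arange(self.horizon + 1),
                             "mean": mean, "p2.5": lo, "p97.5": hi,
                             "alive": self.alive})

    @property
    def final_mean_prevalence(self) -> float:
        return float(self.prevalence[:, -1].mean())

    def prevalence_frame(self) -> pd.DataFrame:
        reps, months = np.meshgrid(np.arange(self.prevalence.shape[0]),
                                   np.arange(self.horizon + 1), indexing="ij")
        return pd.DataFrame({
            "replicate": reps.ravel(), "month": months.ravel(),
            "incarcerated": self.incarcerated.ravel(),
            "alive": np.broadcast_to(self.alive, self.prevalence.shape).ravel(),
            "prevalence": self.prevalence.ravel(),
        })


# ------------------------------------------------------------------- core


def _multi_slice(indptr, starts_at):
    """Concatenated CSR slice indices for the given source rows."""
    starts = indptr[starts_at]
    stops = indptr[starts_at + 1]
    counts = stops - starts
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    pos = np.zeros(len(counts), dtype=np.int64)
    np.cumsum(counts[:-1], out=pos[1:])
    out[pos] = starts
    out[pos[1:]] -= starts[:-1] + counts[:-1] - 1
    return np.cumsum(out)


def run_epidemic(population_or_net, config: EpidemicConfig,
                 replicate_seed: int | None = None,
                 replicate: int = 0) -> SimulationResult:
    """Run one replicate; deterministic given (population, config, seed)."""
    config.validate()
    net = _as_network(population_or_net, config)
    rng = np.random.default_rng(
        config.rng_seed if replicate_seed is None else replicate_seed)
    return _simulate(net, config, rng, replicate)


def _as_network(population_or_net, config: EpidemicConfig) -> CompiledNetwork:
    if isinstance(population_or_net, CompiledNetwork):
        return population_or_net
    return CompiledNetwork(
        population_or_net, config.rate_table,
        min_incarcerable_age=config.min_incarcerable_age,
        adult_child_age=config.adult_child_age,
        epidemic_start_year=config.epidemic_start_year)


def _simulate(net: CompiledNetwork, config: EpidemicConfig,
              rng: np.random.Generator, replicate: int) -> SimulationResult:
    n = net.n
    horizon = config.horizon
    state = np.full(n, SUS, dtype=np.int8)
    state[net.death_month <= 0] = DEAD
    remaining = np.zeros(n, dtype=np.int64)
    cur_start = np.full(n, -1, dtype=np.int64)
    cur_sentence = np.zeros(n, dtype=np.int64)
    cur_source = np.empty(n, dtype=object)
    cur_transmitter = np.full(n, -1, dtype=np.int64)

    log_rows: list[tuple] = []

    def close_spell(idx, end_month, reason):
        for k in np.atleast_1d(idx):
            log_rows.append((int(net.ids[k]), int(cur_start[k]),
                             int(cur_sentence[k]), int(end_month), reason,
                             cur_source[k],
                             int(cur_transmitter[k])))

    def open_spell(idx, start_month, sentences, source, transmitters=None):
        state[idx] = INC
        remaining[idx] = sentences
        cur_start[idx] = start_month
        cur_sentence[idx] = sentences
        for k in np.atleast_1d(idx):
            cur_source[k] = source
        cur_transmitter[idx] = -1 if transmitters is None else transmitters

    # --- initialization: ~init_prevalence of eligible alive agents at month 0
    eligible = (state == SUS) & (net.elig_from <= 0) & (net.death_month > 0) \
        & (net.birth_month <= 0)
    n_elig = int(eligible.sum())
    n_alive = int(((net.birth_month <= 0) & (net.death_month > 0)).sum())
    k = min(int(round(config.init_prevalence * n_alive)), n_elig)
    if config.init_prevalence > 0 and n_elig == 0:
        raise EngineError("no eligible agents to initialize")
    if k > 0:
        chosen = rng.choice(np.flatnonzero(eligible), size=k, replace=False)
        open_spell(chosen, 0, config.sentence_dist.sample(rng, size=k),
                   "initial")

    # deaths grouped by month
    dm = net.death_month[net.death_order]
    in_window = (dm > 0) & (dm <= horizon)
    death_agents = net.death_order[in_window]
    death_months = dm[in_window]
    death_ptr = 0

    inc_series = np.zeros(horizon + 1, dtype=np.int64)
    contact = net.edge_rate.size > 0
    spont = config.spontaneous_rate > 0

    for m in range(horizon):
        # (1) deaths scheduled this month
        while death_ptr < len(death_agents) and death_months[death_ptr] == m:
            a = death_agents[death_ptr]
            if state[a] == INC:
                close_spell(a, m, "died")
            state[a] = DEAD
            death_ptr += 1
        inc_series[m] = np.count_nonzero(state == INC)

        # (2) transmissions from the start-of-month infectious set
        new_idx = None
        new_srcs = None
        if contact:
            infectious = np.flatnonzero(state == INC)
            if infectious.size:
                e = _multi_slice(net.indptr, infectious)
                dsts = net.edge_dst[e]
                ok = (state[dsts] == SUS) & (net.edge_eff[e] <= m) \
                    & (net.death_month[dsts] > m)
                e = e[ok]
                if e.size:
                    hits = rng.random(e.size) < net.edge_rate[e]
                    if hits.any():
                        e = e[hits]
                        dsts = net.edge_dst[e]
                        # first successful source in ascending agent-id order
                        order = np.lexsort((e, dsts))
                        dsts = dsts[order]
                        first = np.ones(dsts.size, dtype=bool)
                        first[1:] = dsts[1:] != dsts[:-1]
                        new_idx = dsts[first]
                        srcs_sorted = _edge_src_of(net, e[order][first])
                        new_srcs = srcs_sorted
        if spont:
            pool = np.flatnonzero((state == SUS) & (net.elig_from <= m)
                                  & (net.death_month > m)
                                  & (net.birth_month <= m))
            if pool.size:
                hits = rng.random(pool.size) < config.spontaneous_rate
                sp_idx = pool[hits]
                if sp_idx.size:
                    if new_idx is None:
                        new_idx, new_srcs = sp_idx, None
                    else:  # contact infection takes precedence on overlap
                        extra = sp_idx[~np.isin(sp_idx, new_idx)]
                        new_idx = np.concatenate([new_idx, extra])
                        new_srcs = np.concatenate(
                            [new_srcs, np.full(extra.size, -1)])

        # (3) releases: sentences that have run out
        serving = state == INC
        remaining[serving] -= 1
        released = serving & (remaining == 0)
        if released.any():
            rel = np.flatnonzero(released)
            close_spell(rel, m + 1, "released")
            state[rel] = SUS

        # (4) new spells begin next month
        if new_idx is not None and new_idx.size:
            sentences = config.sentence_dist.sample(rng, size=new_idx.size)
            if new_srcs is None:
                open_spell(new_idx, m + 1, sentences, "spontaneous")
            else:
                sources = np.where(new_srcs >= 0, "contact", "spontaneous")
                state[new_idx] = INC
                remaining[new_idx] = sentences
                cur_start[new_idx] = m + 1
                cur_sentence[new_idx] = sentences
                for k2, s2 in zip(new_idx, sources):
                    cur_source[k2] = s2
                cur_transmitter[new_idx] = np.where(
                    new_srcs >= 0, net.ids[np.maximum(new_srcs, 0)], -1)

    inc_series[horizon] = np.count_nonzero(state == INC)
    open_idx = np.flatnonzero(state == INC)
    close_spell(open_idx, horizon, "horizon")

    events = pd.DataFrame(log_rows, columns=["agent", "start_month",
                                             "sentence_months", "end_month",
                                             "end_reason", "source",
                                             "transmitting_agent"])
    events = events.sort_values(["agent", "start_month"], kind="stable")
    events["spell_index"] = events.groupby("agent").cumcount() + 1
    events.insert(0, "replicate", replicate)
    events = events[EVENT_COLUMNS].reset_index(drop=True)
    return SimulationResult(events=events, months=np.arange(horizon + 1),
                            incarcerated=inc_series,
                            alive=_as_alive(net, horizon))


def _edge_src_of(net: CompiledNetwork, edge_idx: np.ndarray) -> np.ndarray:
    return np.searchsorted(net.indptr, edge_idx, side="right") - 1


def _as_alive(net: CompiledNetwork, horizon: int) -> np.ndarray:
    return net.alive_counts(horizon)


def initialize_states(population: SyntheticPopulation, config: EpidemicConfig,
                      rng: np.random.Generator):
    """Month-0 states and initial spells (exposed for inspection/testing).

    Returns ``(state, initial_events)`` where ``state`` codes are
    0=susceptible, 1=incarcerated, 2=dead and ``initial_events`` lists
    (agent_id, sentence_months) for the seeded inmates.
    """
    config.validate()
    net = _as_network(population, config)
    state = np.full(net.n, SUS, dtype=np.int8)
    state[net.death_month <= 0] = DEAD
    eligible = (state == SUS) & (net.elig_from <= 0) & (net.birth_month <= 0)
    n_elig = int(eligible.sum())
    if config.init_prevalence > 0 and n_elig == 0:
        raise EngineError("no eligible agents to initialize")
    n_alive = int(((net.birth_month <= 0) & (net.death_month > 0)).sum())
    k = min(int(round(config.init_prevalence * n_alive)), n_elig)
    rows = []
    if k:
        chosen = rng.choice(np.flatnonzero(eligible), size=k, replace=False)
        state[chosen] = INC
        for a, s in zip(net.ids[chosen],
                        np.atleast_1d(config.sentence_dist.sample(rng, size=k))):
            rows.append((int(a), int(s)))
    return state, rows


def run_ensemble(population: SyntheticPopulation | CompiledNetwork,
                 config: EpidemicConfig,
                 base_seed: int | None = None) -> EnsembleResult:
    """Replicate r runs with seed base_seed + r; summaries are month-wise."""
    config.validate()
    net = _as_network(population, config)
    base = config.rng_seed if base_seed is None else base_seed
    logs, prevs, incs = [], [], []
    alive = net.alive_counts(config.horizon)
    for r in range(config.n_replicates):
        res = _simulate(net, config, np.random.default_rng(base + r), r)
        logs.append(res.events)
        incs.append(res.incarcerated)
        prevs.append(res.prevalence)
    return EnsembleResult(
        events=pd.concat(logs, ignore_index=True),
        prevalence=np.vstack(prevs), incarcerated=np.vstack(incs),
        alive=alive,
        replicate_seeds=np.arange(base, base + config.n_replicates),
        horizon=config.horizon)


def compare_ensembles(series_a: np.ndarray, series_b: np.ndarray) -> pd.DataFrame:
    """Per-month Welch two-sample t-test between two replicate x month arrays.

    Degenerate months (zero variance in both ensembles) are flagged rather
    than raising; identical-constant months report p = 1.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise EngineError("ensembles must share a horizon")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise EngineError("need >= 2 replicates per ensemble")
    months = np.arange(a.shape[1])
    pvals = np.empty(a.shape[1])
    degenerate = np.zeros(a.shape[1], dtype=bool)
    for m in months:
        va, vb = a[:, m], b[:, m]
        scale = max(abs(va.mean()), abs(vb.mean()), 1.0)
        if va.std() <= 1e-12 * scale and vb.std() <= 1e-12 * scale:
            degenerate[m] = True
            pvals[m] = 1.0 if abs(va.mean() - vb.mean()) <= 1e-12 * scale \
                else 0.0
            continue
        pvals[m] = sstats.ttest_ind(va, vb, equal_var=False).pvalue
    return pd.DataFrame({"month": months, "p_value": pvals,
                         "degenerate": degenerate})
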