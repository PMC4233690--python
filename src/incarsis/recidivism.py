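"""Recidivism summaries from epidemic event logs.

A release record is one completed spell ending in release.  An agent
recidivates if a new spell starts within the follow-up window (36 months,
matching 3-year recidivism reporting).  Releases whose follow-up window is
cut short by the simulation horizon or the agent's death are censored and
excluded from rate denominators.

Four summaries mirror standard corrections reporting: the return rate by
number of prior incarcerations, by age at release, by length of the
completed sentence, and the cumulative fraction returned by months since
release (among returners).  Each is computed per replicate and then
summarised across replicates with the mean and the empirical 2.5/97.5
percentiles ("95% simulation intervals").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_FOLLOWUP = 36
DEFAULT_PRIOR_BINS = (1, 2, 3, 4, 5)        # last bin is "5+"
DEFAULT_AGE_EDGES = tuple(range(15, 61, 5))  # 15-19 ... 55-59, then 60+
DEFAULT_SENTENCE_EDGES = tuple(range(0, 97, 12))  # 0-12, 13-24, ..., 97+


class RecidivismError(ValueError):
    pass


@dataclass
class BinConfig:
    followup: int = DEFAULT_FOLLOWUP
    prior_bins: tuple = DEFAULT_PRIOR_BINS
    age_edges: tuple = DEFAULT_AGE_EDGES
    sentence_edges: tuple = DEFAULT_SENTENCE_EDGES


def extract_release_records(event_log: pd.DataFrame, horizon: int,
                            followup: int = DEFAULT_FOLLOWUP,
                            birth_months: dict | None = None,
                            death_months: dict | None = None) -> pd.DataFrame:
    """One record per spell ending in release.

    ``months_to_return`` is the gap to the agent's next spell start (NaN if
    none); ``followup_complete`` is False when the horizon or the agent's
    death interrupts the follow-up window.  ``birth_months``/
    ``death_months`` map agent id to months on the epidemic clock; age at
    release is reported in years when births are supplied.
    """
    log = event_log.sort_values(["replicate", "agent", "start_month"],
                                kind="stable").reset_index(drop=True)
    starts = log["start_month"].to_numpy()
    ends = log["end_month"].to_numpy()
    if np.any(ends < starts):
        raise RecidivismError("malformed log: spell ends before it starts")
    same_agent = (log["agent"].shift(-1) == log["agent"]) & \
        (log["replicate"].shift(-1) == log["replicate"])
    next_start = np.where(same_agent, log["start_month"].shift(-1), np.nan)
    prev_end = np.where(same_agent.shift(1, fill_value=False),
                        log["end_month"].shift(1), np.nan)
    overlap = np.nan_to_num(starts - prev_end, nan=0.0) < 0
    if overlap.any():
        raise RecidivismError("malformed log: overlapping spells for an agent")

    released = log["end_reason"] == "released"
    rec = log.loc[released, ["replicate", "agent", "spell_index",
                             "start_month", "sentence_months"]].copy()
    rec = rec.rename(columns={"spell_index": "prior_spell_count"})
    rec["release_month"] = ends[released.to_numpy()]
    mtr = next_start[released.to_numpy()] - rec["release_month"].to_numpy()
    mtr = np.where(mtr > followup, np.nan, mtr)
    rec["months_to_return"] = mtr

    death = np.full(len(rec), np.inf)
    age = np.full(len(rec), np.nan)
    if death_months is not None:
        death = rec["agent"].map(death_months).fillna(np.inf).to_numpy()
    if birth_months is not None:
        age = (rec["release_month"].to_numpy()
               - rec["agent"].map(birth_months).to_numpy()) / 12.0
    rec["age_at_release"] = age
    rec["followup_complete"] = (
        (rec["release_month"] + followup <= horizon)
        & (rec["release_month"] + followup <= death)
    )
    return rec.reset_index(drop=True)


def _bin_priors(count: np.ndarray, bins: tuple) -> np.ndarray:
    top = bins[-1]
    clipped = np.minimum(count, top)
    labels = np.array([f"{b}" for b in bins[:-1]] + [f"{top}+"])
    idx = np.searchsorted(np.asarray(bins), clipped, side="right") - 1
    return labels[idx]


def _bin_edges(values: np.ndarray, edges: tuple, width: int) -> np.ndarray:
    e = np.asarray(edges, dtype=float)
    idx = np.clip(np.searchsorted(e, values, side="right") - 1, 0, len(e) - 1)
    labels = [f"{int(lo)}-{int(lo + width - 1)}" for lo in e[:-1]] + [f"{int(e[-1])}+"]
    return np.asarray(labels)[idx]


@dataclass
class RecidivismTables:
    """Per-metric cross-replicate summaries plus the per-replicate values."""

    by_prior_count: pd.DataFrame
    by_age: pd.DataFrame
    by_sentence: pd.DataFrame
    cumulative: pd.DataFrame
    per_replicate: dict = field(default_factory=dict)

    def to_csv(self, out_dir) -> None:
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.by_prior_count.to_csv(out / "recidivism_by_prior_count.csv", index=False)
        self.by_age.to_csv(out / "recidivism_by_age.csv", index=False)
        self.by_sentence.to_csv(out / "recidivism_by_sentence.csv", index=False)
        self.cumulative.to_csv(out / "recidivism_cumulative.csv", index=False)


def simulation_intervals(per_replicate: pd.DataFrame, value_col: str = "rate",
                         bin_col: str = "bin") -> pd.DataFrame:
    """Mean and 2.5/97.5 empirical percentiles of a statistic across replicates.

    Percentiles use linear interpolation between order statistics.
    """
    if per_replicate["replicate"].nunique() < 2:
        raise RecidivismError("simulation intervals need >= 2 replicates")
    g = per_replicate.groupby(bin_col, sort=False, observed=True)[value_col]
    out = g.agg(
        mean="mean",
        **{"p2.5": lambda v: np.percentile(v, 2.5),
           "p97.5": lambda v: np.percentile(v, 97.5)},
        n_replicates="count",
    ).reset_index()
    return out


def _rates_by(rec: pd.DataFrame, bin_values: np.ndarray,
              order: list) -> pd.DataFrame:
    df = rec.assign(bin=bin_values)
    df = df[df["followup_complete"]]
    per = (df.assign(returned=df["months_to_return"].notna())
             .groupby(["replicate", "bin"], sort=False, observed=True)
             .agg(rate=("returned", "mean"), n=("returned", "size"))
             .reset_index())
    per["bin"] = pd.Categorical(per["bin"], categories=order, ordered=True)
    per = per.sort_values(["replicate", "bin"], kind="stable")
    return per.dropna(subset=["bin"]).reset_index(drop=True)


def compute_recidivism_tables(records: pd.DataFrame,
                              bins: BinConfig | None = None) -> RecidivismTables:
    """All four recidivism summaries with cross-replicate simulation intervals.

    Rates are returners-within-followup over complete-followup releases per
    bin; the cumulative curve is normalised over returners.  Bins that a
    replicate never populates are simply absent for that replicate (never
    reported as zero).
    """
    bins = bins or BinConfig()
    rec = records[records["followup_complete"]]
    if rec.empty:
        raise RecidivismError("no complete-followup release records")

    prior_order = [f"{b}" for b in bins.prior_bins[:-1]] + [f"{bins.prior_bins[-1]}+"]
    per_prior = _rates_by(rec, _bin_priors(
        rec["prior_spell_count"].to_numpy(), bins.prior_bins), prior_order)

    age_w = int(bins.age_edges[1] - bins.age_edges[0])
    age_order = [f"{int(lo)}-{int(lo + age_w - 1)}"
                 for lo in bins.age_edges[:-1]] + [f"{int(bins.age_edges[-1])}+"]
    have_age = rec[rec["age_at_release"].notna()]
    per_age = _rates_by(have_age, _bin_edges(
        have_age["age_at_release"].to_numpy(), bins.age_edges, age_w), age_order)

    sen_w = int(bins.sentence_edges[1] - bins.sentence_edges[0])
    sen_order = [f"{int(lo)}-{int(lo + sen_w - 1)}"
                 for lo in bins.sentence_edges[:-1]] + [f"{int(bins.sentence_edges[-1])}+"]
    per_sen = _rates_by(rec, _bin_edges(
        rec["sentence_months"].to_numpy(), bins.sentence_edges, sen_w), sen_order)

    # cumulative return curve among returners, per replicate
    ret = rec[rec["months_to_return"].notna()]
    curves = []
    for rep, grp in ret.groupby("replicate", sort=True):
        m = grp["months_to_return"].to_numpy()
        months = np.arange(1, bins.followup + 1)
        cum = np.array([(m <= j).mean() for j in months])
        curves.append(pd.DataFrame({"replicate": rep, "bin": months,
                                    "rate": cum}))
    per_cum = pd.concat(curves, ignore_index=True) if curves else \
        pd.DataFrame(columns=["replicate", "bin", "rate"])

    return RecidivismTables(
        by_prior_count=simulation_intervals(per_prior),
        by_age=simulation_intervals(per_age),
        by_sentence=simulation_intervals(per_sen),
        cumulative=simulation_intervals(per_cum),
        per_replicate={"prior": per_prior, "age": per_age,
                       "sentence": per_sen, "cumulative": per_cum},
    )


def cumulative_shape_index(cumulative_mean: pd.DataFrame) -> float:
    """Mean signed departure of the cumulative return curve from linearity.

    Positive for concave curves (mass returns early), negative for convex
    ones; a constant return hazard is close to 0 (slightly positive).
    """
    months = cumulative_mean["bin"].to_numpy(dtype=float)
    curve = cumulative_mean["mean"].to_numpy(dtype=float)
    diagonal = months / months.max()
    return float(np.mean(curve - diagonal))
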