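"""Relationship-typed transmission probabilities.

An incarcerated agent "transmits" incarceration risk to each susceptible
network neighbour with a monthly probability that depends on the
susceptible's role relative to the inmate (mother, father, sister,
brother, spouse, adult child; close friends are treated as siblings) and
on the inmate's sex.  The calibration source is an inmate survey giving,
by inmate sex, the probability that each such relation is *also*
incarcerated; those whole-sentence probabilities are converted to monthly
rates by inverting the cumulative-risk identity

    p_sentence = 1 - (1 - p_monthly) ** s

at a calibration sentence of s = 14 months (between the White and Black
mean sentences).  Marginalising the cumulative risk over a fitted
sentence-length distribution gives the per-race marginal transmission
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sentencing import SentenceDistribution

RELATIONS = ("mother", "father", "sister", "brother", "spouse", "adult_child")
INMATE_SEXES = ("female", "male")

# Inmate-survey co-incarceration probabilities by (relation, inmate sex).
DEFAULT_SURVEY = {
    ("mother", "female"): 0.012, ("mother", "male"): 0.048,
    ("father", "female"): 0.147, ("father", "male"): 0.148,
    ("sister", "female"): 0.107, ("sister", "male"): 0.059,
    ("brother", "female"): 0.377, ("brother", "male"): 0.349,
    ("spouse", "female"): 0.059, ("spouse", "male"): 0.011,
    ("adult_child", "female"): 0.213, ("adult_child", "male"): 0.085,
}

DEFAULT_CALIBRATION_SENTENCE = 14
DEFAULT_ADULT_CHILD_AGE = 18


class TransmissionError(ValueError):
    pass


def cumulative_probability(p_monthly: float, s: int) -> float:
    """Probability of at least one transmission over an s-month sentence.

    The complement of never transmitting in any of the s months:
    ``1 - (1 - p)**s``.
    """
    p = np.asarray(p_monthly, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise TransmissionError("monthly probability must lie in [0, 1]")
    if np.any(np.asarray(s) < 0):
        raise TransmissionError("sentence length must be >= 0")
    out = 1.0 - (1.0 - p) ** np.asarray(s)
    return float(out) if out.ndim == 0 else out


def derive_monthly_rate(p_total: float, s: int) -> float:
    """Invert cumulative risk: monthly rate ``1 - (1 - p_total)**(1/s)``."""
    if not 0 <= p_total < 1:
        raise TransmissionError(
            "whole-sentence probability must lie in [0, 1); a certain "
            "transmission has no finite monthly rate"
        )
    if s < 1:
        raise TransmissionError("calibration sentence must be >= 1 month")
    return 1.0 - (1.0 - p_total) ** (1.0 / s)


def _validate_cells(cells: dict, name: str) -> dict:
    out = {}
    for rel in RELATIONS:
        for sex in INMATE_SEXES:
            key = (rel, sex)
            if key not in cells:
                raise TransmissionError(f"{name} is missing cell {key}")
            v = float(cells[key])
            if not 0 <= v <= 1:
                raise TransmissionError(f"{name} cell {key} outside [0, 1]")
            out[key] = v
    return out


@dataclass(frozen=True)
class SurveyTable:
    """Whole-sentence co-incarceration probabilities by (relation, inmate sex)."""

    cells: dict

    def __post_init__(self):
        object.__setattr__(self, "cells", _validate_cells(self.cells, "survey table"))

    @classmethod
    def default(cls) -> "SurveyTable":
        return cls(dict(DEFAULT_SURVEY))

    def __getitem__(self, key):
        return self.cells[key]

    def derive_monthly(self, s: int = DEFAULT_CALIBRATION_SENTENCE) -> "MonthlyRateTable":
        rates = {k: derive_monthly_rate(v, s) for k, v in self.cells.items()}
        return MonthlyRateTable(cells=rates, calibration_sentence=s)

    def to_frame(self) -> pd.DataFrame:
        return _cells_to_frame(self.cells)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurveyTable":
        return cls(_frame_to_cells(pd.read_csv(path)))


@dataclass(frozen=True)
class MonthlyRateTable:
    """Monthly transmission probabilities p(i -> j) by (susceptible's role, inmate sex)."""

    cells: dict
    calibration_sentence: int = DEFAULT_CALIBRATION_SENTENCE

    def __post_init__(self):
        object.__setattr__(self, "cells", _validate_cells(self.cells, "rate table"))

    @classmethod
    def default(cls) -> "MonthlyRateTable":
        return SurveyTable.default().derive_monthly()

    @classmethod
    def zeros(cls) -> "MonthlyRateTable":
        cells = {(r, s): 0.0 for r in RELATIONS for s in INMATE_SEXES}
        return cls(cells=cells)

    def __getitem__(self, key):
        return self.cells[key]

    def rounded(self, decimals: int = 3) -> dict:
        """Half-up rounding for display against published 3-decimal tables."""
        scale = 10 ** decimals
        return {k: np.floor(v * scale + 0.5) / scale for k, v in self.cells.items()}

    def to_frame(self) -> pd.DataFrame:
        return _cells_to_frame(self.cells)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, calibration_sentence: int = DEFAULT_CALIBRATION_SENTENCE):
        return cls(_frame_to_cells(pd.read_csv(path)),
                   calibration_sentence=calibration_sentence)


def _cells_to_frame(cells: dict) -> pd.DataFrame:
    rows = [
        {"relation": rel,
         "female": cells[(rel, "female")],
         "male": cells[(rel, "male")]}
        for rel in RELATIONS
    ]
    return pd.DataFrame(rows)


def _frame_to_cells(df: pd.DataFrame) -> dict:
    required = {"relation", "female", "male"}
    if not required.issubset(df.columns):
        raise TransmissionError(f"table CSV needs columns {sorted(required)}")
    cells = {}
    for _, row in df.iterrows():
        cells[(row["relation"], "female")] = float(row["female"])
        cells[(row["relation"], "male")] = float(row["male"])
    return cells


# ------------------------------------------------------------ marginals

def exact_marginal_probability(
    p_monthly: float, sentence_dist: SentenceDistribution, tail_mass: float = 1e-10
) -> float:
    """Sentence-marginalised transmission probability by direct summation.

    Sums pmf(s) * (1 - (1-p)**s) over s = 1..s_max with s_max chosen so the
    neglected tail mass is below ``tail_mass``.  Serves as the independent
    oracle for the Monte-Carlo estimator.
    """
    s_max = sentence_dist.support_upper(tail_mass)
    s = np.arange(1, s_max + 1)
    pmf = sentence_dist.pmf(s)
    return float(np.sum(pmf * (1.0 - (1.0 - p_monthly) ** s)))


def marginal_probability(
    p_monthly: float,
    sentence_dist: SentenceDistribution,
    n_mc: int,
    rng: np.random.Generator,
):
    """Monte-Carlo sentence-marginalised transmission probability.

    Averages ``1 - (1-p)**S`` over ``n_mc`` sentence draws S.  Returns
    ``(estimate, standard_error)``.
    """
    if n_mc < 10_000:
        raise TransmissionError("marginal estimate requires n_mc >= 10_000")
    s = sentence_dist.sample(rng, size=n_mc)
    vals = 1.0 - (1.0 - p_monthly) ** s
    est = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(n_mc))
    return est, se


def marginal_table(
    rate_table: MonthlyRateTable,
    sentence_dist: SentenceDistribution,
    n_mc: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """All 12 marginal cells for one sentence distribution (MC + exact oracle)."""
    rows = []
    for rel in RELATIONS:
        for sex in INMATE_SEXES:
            p = rate_table[(rel, sex)]
            est, se = marginal_probability(p, sentence_dist, n_mc, rng)
            rows.append({
                "relation": rel, "inmate_sex": sex, "p_monthly": p,
                "marginal_mc": est, "marginal_se": se,
                "marginal_exact": exact_marginal_probability(p, sentence_dist),
            })
    return pd.DataFrame(rows)


# ------------------------------------------------------- per-edge lookup

def resolve_rate(
    inmate_sex: str,
    susceptible_sex: str,
    relation: str,
    table: MonthlyRateTable,
    susceptible_is_parent_of_inmate: bool = False,
    inmate_is_parent_of_susceptible: bool = False,
    susceptible_age: float | None = None,
    adult_child_age: int = DEFAULT_ADULT_CHILD_AGE,
) -> float:
    """Monthly rate from an incarcerated agent to one susceptible neighbour.

    The table row is the susceptible's role relative to the inmate; the
    column is always the inmate's sex.  Friends take the sibling row of the
    susceptible's sex.  A susceptible child of the inmate maps to the
    adult-child row only once its age reaches ``adult_child_age``; younger
    children receive rate 0 (no published rate exists for minors).
    """
    if relation == "parent_child":
        if susceptible_is_parent_of_inmate:
            row = "mother" if susceptible_sex == "female" else "father"
        elif inmate_is_parent_of_susceptible:
            if susceptible_age is not None and susceptible_age < adult_child_age:
                return 0.0
            row = "adult_child"
        else:
            raise TransmissionError(
                "parent_child tie must identify which endpoint is the parent"
            )
    elif relation in ("sibling", "friend"):
        row = "sister" if susceptible_sex == "female" else "brother"
    elif relation == "spouse":
        row = "spouse"
    else:
        raise TransmissionError(f"unknown relation label {relation!r}")
    return table[(row, inmate_sex)]
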