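"""Annual life tables: per-sex probabilities of death at each integer age.

A :class:`LifeTable` holds, for each sex and each integer age 0–119, the
probability of dying during the next year of life conditional on having
reached that age.  Age 119 is absorbing (probability 1), so every sampled
lifespan is finite.  Lifespans are *completed ages at death*: an agent with
lifespan ``l`` born in year ``b`` is alive during calendar years
``[b, b + l + 1)``.

The packaged default is a Gompertz–Makeham schedule,
``q(x) = A + B * exp(x / g)`` capped at 1, with constants chosen so the
expected completed age at death is 80 years for females and 75 for males
(roughly 2009-era US period life expectancies of ~81 and ~76 once the
partial final year is counted).  A real period life table (e.g. SSA 2009)
may be loaded from CSV with columns ``sex, age, q_death``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MAX_AGE = 119
N_AGES = MAX_AGE + 1

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

# Gompertz-Makeham constants for the packaged default schedule.
_GM_SHAPE_YEARS = 11.5
_GM_PARAMS = {
    FEMALE: (0.0008, 3.577494818448254e-05),
    MALE: (0.0015, 4.646498758019623e-05),
}


class LifeTableError(ValueError):
    """Raised for malformed life tables (bad shape or probabilities)."""


class LifeTable:
    """Per-sex annual death probabilities over ages 0..119."""

    def __init__(self, q_female: np.ndarray, q_male: np.ndarray):
        self._q = {}
        for sex, q in ((FEMALE, q_female), (MALE, q_male)):
            q = np.asarray(q, dtype=float)
            if q.shape != (N_AGES,):
                raise LifeTableError(
                    f"{sex} table must cover ages 0..{MAX_AGE} "
                    f"(got shape {q.shape})"
                )
            if np.any(~np.isfinite(q)) or np.any(q < 0) or np.any(q > 1):
                raise LifeTableError(
                    f"{sex} table has death probabilities outside [0, 1]"
                )
            if q[MAX_AGE] != 1.0:
                raise LifeTableError(
                    f"{sex} table must be absorbing at age {MAX_AGE} (q=1)"
                )
            self._q[sex] = q
        # Death-age pmf: P(die at completed age k) = S(k) * q(k).
        self._pmf = {}
        for sex, q in self._q.items():
            surv = np.concatenate([[1.0], np.cumprod(1.0 - q)[:-1]])
            pmf = surv * q
            pmf /= pmf.sum()
            self._pmf[sex] = pmf

    def q(self, sex: str) -> np.ndarray:
        """Annual death probabilities for one sex (read-only view)."""
        out = self._q[sex].view()
        out.flags.writeable = False
        return out

    def death_age_pmf(self, sex: str) -> np.ndarray:
        out = self._pmf[sex].view()
        out.flags.writeable = False
        return out

    def expected_lifespan(self, sex: str) -> float:
        """Exact expected completed age at death, by direct summation."""
        pmf = self._pmf[sex]
        return float((pmf * np.arange(N_AGES)).sum())

    def sample_lifespan(self, sex: str, rng: np.random.Generator, size=None):
        """Sample completed age(s) at death.

        Equivalent to surviving year by year through the annual death
        probabilities; implemented as a categorical draw from the exact
        death-age pmf.
        """
        if sex not in self._pmf:
            raise LifeTableError(f"unknown sex {sex!r}")
        return rng.choice(N_AGES, size=size, p=self._pmf[sex])

    # ------------------------------------------------------------------ io
    @classmethod
    def default(cls) -> "LifeTable":
        """Packaged Gompertz-Makeham default (synthetic, not an SSA table)."""
        cols = {}
        ages = np.arange(N_AGES)
        for sex, (a, b) in _GM_PARAMS.items():
            q = np.minimum(1.0, a + b * np.exp(ages / _GM_SHAPE_YEARS))
            q[MAX_AGE] = 1.0
            cols[sex] = q
        return cls(cols[FEMALE], cols[MALE])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        required = {"sex", "age", "q_death"}
        if not required.issubset(df.columns):
            raise LifeTableError(
                f"life table CSV must have columns {sorted(required)}"
            )
        cols = {}
        for sex in SEXES:
            sub = df[df["sex"] == sex].set_index("age")["q_death"]
            if not np.array_equal(np.sort(sub.index.to_numpy()), np.arange(N_AGES)):
                raise LifeTableError(
                    f"life table CSV must cover ages 0..{MAX_AGE} for {sex}"
                )
            cols[sex] = sub.sort_index().to_numpy(dtype=float)
        return cls(cols[FEMALE], cols[MALE])

    def to_csv(self, path) -> None:
        frames = []
        for sex in SEXES:
            frames.append(
                pd.DataFrame(
                    {"sex": sex, "age": np.arange(N_AGES), "q_death": self._q[sex]}
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def sample_lifespan(life_table: LifeTable, sex: str, rng: np.random.Generator, size=None):
    """Module-level convenience wrapper around LifeTable.sample_lifespan."""
    return life_table.sample_lifespan(sex, rng, size=size)
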