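"""Target-population incidence tables and baseline-rate uncertainty.

A population table stores registered cancer cases and person-years by sex,
5-year age group and calendar year (registry convention).  Lookups past
the last covered year fall back to that year's rates, mirroring how
registries lag the present.  The statistical uncertainty of the baseline
rate is propagated by resampling the registered case count from a Poisson
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["PopulationTable"]

COLUMNS = ["sex", "age_low", "age_high", "year", "cases", "person_years"]


@dataclass
class PopulationTable:
    """Cases, person-years and rates by sex, age group and calendar year."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"population table misses columns {missing}")
        if not set(df["sex"]).issubset({"m", "f"}):
            raise InputError("sex must be coded 'm' or 'f'")
        if (df["person_years"] <= 0).any():
            raise InputError("person-years must be positive")
        if (df["cases"] < 0).any() or not np.allclose(df["cases"], df["cases"].round()):
            raise InputError("cases must be non-negative integers")
        df["cases"] = df["cases"].round().astype(int)
        df["rate"] = df["cases"] / df["person_years"]
        self.data = df.reset_index(drop=True)
        self._last_year = int(df["year"].max())
        self._first_year = int(df["year"].min())

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "PopulationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    # -- lookup ------------------------------------------------------------
    def _row(self, sex: str, age: float, year: int) -> pd.Series:
        if year > self._last_year:
            year = self._last_year  # registry lag: reuse the last year
        elif year < self._first_year:
            raise InputError(
                f"year {year} precedes table coverage ({self._first_year}-{self._last_year})"
            )
        df = self.data
        hit = df[
            (df["sex"] == sex)
            & (df["age_low"] <= age)
            & (age <= df["age_high"])
            & (df["year"] == year)
        ]
        if hit.empty:
            raise InputError(f"no population record for sex={sex}, age={age}, year={year}")
        return hit.iloc[0]

    def baseline_rate(self, sex: str, age: float, year: int) -> float:
        """Point baseline incidence rate (cases per person-year)."""
        return float(self._row(sex, age, year)["rate"])

    def sample_baseline(
        self, sex: str, age: float, year: int, rng: np.random.Generator
    ) -> float:
        """Poisson-resampled baseline rate k/PY with k ~ Poisson(cases).

        Zero registered cases would pin the baseline (and hence the
        assigned share) degenerately, so the Poisson mean is floored at
        0.5 cases.
        """
        row = self._row(sex, age, year)
        mean = max(float(row["cases"]), 0.5)
        k = rng.poisson(mean)
        return float(k / row["person_years"])
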