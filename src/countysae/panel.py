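"""The county x age x year birth-count panel and its delimited-text format.

The analysis operates on tabulated live births: for county i, maternal age
group k (six 5-year groups, 15-19 through 40-44), and calendar year t, the
panel stores total live births n_ikt, preterm births (<37 weeks) and early
preterm births (<34 weeks).  Cells absent from the input are stored as zero
births (the likelihood skips them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_GROUPS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44")

PANEL_COLUMNS = ["county_id", "age_group", "year", "births", "preterm", "early_preterm"]

__all__ = ["AGE_GROUPS", "CountPanel", "read_panel", "validate_panel"]


@dataclass
class CountPanel:
    """Rectangular count arrays indexed county x age group x year.

    Attributes
    ----------
    county_ids, age_groups, years : ordered index labels.
    births : (N, K, T) int array of total live births n_ikt.
    preterm, early_preterm : (N, K, T) int arrays of outcome counts Y_ikt.
    """

    county_ids: list
    age_groups: list
    years: list
    births: np.ndarray
    preterm: np.ndarray
    early_preterm: np.ndarray
    county_index: dict = field(init=False)

    def __post_init__(self):
        shape = (len(self.county_ids), len(self.age_groups), len(self.years))
        for name in ("births", "preterm", "early_preterm"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if np.any(arr < 0):
                raise ValueError(f"negative counts in {name}")
            setattr(self, name, arr.astype(np.int64))
        if np.any(self.preterm > self.births):
            raise ValueError("preterm counts exceed births")
        if np.any(self.early_preterm > self.preterm):
            raise ValueError("early preterm counts exceed preterm counts")
        self.county_index = {c: i for i, c in enumerate(self.county_ids)}

    # -- basic shape -----------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.births.shape

    def outcome_counts(self, outcome: str) -> np.ndarray:
        """Outcome count array: 'preterm' or 'early_preterm'."""
        if outcome not in ("preterm", "early_preterm"):
            raise ValueError(f"unknown outcome {outcome!r}")
        return getattr(self, outcome)

    def crude_rates(self, outcome: str = "preterm") -> np.ndarray:
        """Crude cell rates per 100 live births; NaN where births are zero."""
        y = self.outcome_counts(outcome).astype(float)
        n = self.births.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = 100.0 * y / n
        r[n == 0] = np.nan
        return r

    def total_births_by_county_year(self) -> np.ndarray:
        """(N, T) totals across age groups (reliability denominator)."""
        return self.births.sum(axis=1)

    # -- pandas / file I/O ----------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountPanel":
        """Build from a long table with the standard panel columns.

        Missing cells are filled with zero births; duplicate
        (county, age, year) keys are an error.
        """
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        if df.duplicated(["county_id", "age_group", "year"]).any():
            raise ValueError("duplicate (county_id, age_group, year) rows")
        county_ids = sorted(df["county_id"].astype(str).unique())
        age_groups = [a for a in AGE_GROUPS if a in set(df["age_group"])]
        extra = set(df["age_group"]) - set(AGE_GROUPS)
        if extra:
            raise ValueError(f"age groups outside 15-44: {sorted(extra)}")
        years = sorted(int(y) for y in df["year"].unique())
        shape = (len(county_ids), len(age_groups), len(years))
        arrays = {k: np.zeros(shape, dtype=np.int64) for k in ("births", "preterm", "early_preterm")}
        ci = {c: i for i, c in enumerate(county_ids)}
        ai = {a: i for i, a in enumerate(age_groups)}
        yi = {y: i for i, y in enumerate(years)}
        rows_i = df["county_id"].astype(str).map(ci).to_numpy()
        rows_k = df["age_group"].map(ai).to_numpy()
        rows_t = df["year"].astype(int).map(yi).to_numpy()
        for name in ("births", "preterm", "early_preterm"):
            arrays[name][rows_i, rows_k, rows_t] = df[name].to_numpy()
        return cls(county_ids, age_groups, years, **arrays)

    def to_dataframe(self) -> pd.DataFrame:
        n, k, t = self.shape
        idx = pd.MultiIndex.from_product(
            [self.county_ids, self.age_groups, self.years],
            names=["county_id", "age_group", "year"],
        )
        out = pd.DataFrame(
            {
                "births": self.births.reshape(-1),
                "preterm": self.preterm.reshape(-1),
                "early_preterm": self.early_preterm.reshape(-1),
            },
            index=idx,
        ).reset_index()
        return out

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    # -- aggregation -----------------------------------------------------
    def subset_counties(self, county_ids) -> "CountPanel":
        idx = [self.county_index[c] for c in county_ids]
        return CountPanel(
            list(county_ids),
            list(self.age_groups),
            list(self.years),
            self.births[idx],
            self.preterm[idx],
            self.early_preterm[idx],
        )


def read_panel(path) -> CountPanel:
    """Read the standard delimited panel file into a CountPanel."""
    df = pd.read_csv(path, dtype={"county_id": str})
    return CountPanel.from_dataframe(df)


def validate_panel(path) -> list:
    """Schema and consistency checks on a panel file; returns a list of
    violation strings (empty when the file is clean).

    Checks: required columns; age-group labels restricted to the six
    standard 5-year groups between 15 and 44; non-negative counts;
    preterm <= births and early_preterm <= preterm; duplicate keys.
    """
    violations = []
    df = pd.read_csv(path, dtype={"county_id": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    bad_age = df.loc[~df["age_group"].isin(AGE_GROUPS), "age_group"].unique()
    for a in bad_age:
        violations.append(f"age group outside 15-44: {a!r}")
    dup = df.duplicated(["county_id", "age_group", "year"])
    if dup.any():
        violations.append(f"{int(dup.sum())} duplicate (county_id, age_group, year) rows")
    for name in ("births", "preterm", "early_preterm"):
        neg = df[name] < 0
        if neg.any():
            violations.append(f"{int(neg.sum())} negative values in {name}")
    over = df["preterm"] > df["births"]
    if over.any():
        for _, row in df[over].iterrows():
            violations.append(
                f"preterm > births for county {row['county_id']} "
                f"age {row['age_group']} year {row['year']}"
            )
    over2 = df["early_preterm"] > df["preterm"]
    if over2.any():
        violations.append(f"{int(over2.sum())} rows with early_preterm > preterm")
    return violations
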