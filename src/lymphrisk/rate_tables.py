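"""Background cause-specific mortality rate tables.

Rates are stored the way national statistics offices tabulate them: one row
per (country, sex, cause, age band), in deaths per 100,000 person-years.
Age bands are half-open ``[lo, hi)`` and must partition ``[0, inf)`` for each
(sex, cause) series; the last band is open-ended.  Lookup is
piecewise-constant within bands — no smoothing is applied, because the
source tabulations carry no sub-band information.

Regional tables (e.g. "Western Europe") are built by averaging member
country tables cell-by-cell, optionally with population weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, RateLookupError, SchemaError

#: Endpoints whose mortality the model projects.
ENDPOINTS = (
    "coronary_heart_disease",
    "heart_failure",
    "valvular_heart_disease",
    "other_cardiac",
    "stroke",
    "lung_cancer",
    "breast_cancer",
    "esophageal_cancer",
)

#: The cardiovascular subset, reported jointly as "CVD".
CVD_ENDPOINTS = ENDPOINTS[:5]

#: Residual competing-mortality cause.
ALL_OTHER = "all_other_causes"

SEXES = ("male", "female")

_CSV_COLUMNS = ("country", "sex", "cause", "age_lo", "age_hi", "rate_per_100k")


@dataclass(frozen=True)
class RegionSpec:
    """A named region assembled from member-country rate tables.

    ``weights``, when given, align 1:1 with ``member_countries`` and must be
    non-negative and sum to 1 (population weights).  Without weights the
    member countries are averaged equally.
    """

    region_name: str
    member_countries: tuple[str, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.member_countries:
            raise DataValidationError(f"region {self.region_name!r} has no member countries")
        if self.weights is not None:
            if len(self.weights) != len(self.member_countries):
                raise DataValidationError(
                    f"region {self.region_name!r}: {len(self.weights)} weights for "
                    f"{len(self.member_countries)} countries"
                )
            if any(w < 0 for w in self.weights):
                raise DataValidationError(f"region {self.region_name!r}: negative weight")
            if not math.isclose(sum(self.weights), 1.0, rel_tol=0, abs_tol=1e-9):
                raise DataValidationError(
                    f"region {self.region_name!r}: weights sum to {sum(self.weights)}, not 1"
                )


class RateTable:
    """Validated cause-, sex-, and age-specific mortality rates for one population.

    Parameters
    ----------
    name
        Country or region identifier.
    data
        Frame with columns ``sex, cause, age_lo, age_hi, rate_per_100k``;
        ``age_hi`` is ``inf`` for the open-ended band.
    """

    def __init__(self, name: str, data: pd.DataFrame) -> None:
        required = {"sex", "cause", "age_lo", "age_hi", "rate_per_100k"}
        missing = required - set(data.columns)
        if missing:
            raise SchemaError(f"rate table {name!r} missing columns: {sorted(missing)}")
        df = data.loc[:, ["sex", "cause", "age_lo", "age_hi", "rate_per_100k"]].copy()
        df["age_lo"] = df["age_lo"].astype(float)
        df["age_hi"] = df["age_hi"].astype(float)
        df["rate_per_100k"] = df["rate_per_100k"].astype(float)
        df = df.sort_values(["sex", "cause", "age_lo"], kind="stable").reset_index(drop=True)
        self.name = name
        self.data = df
        self._bands: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self._validate()

    def _validate(self) -> None:
        neg = self.data[self.data["rate_per_100k"] < 0]
        if not neg.empty:
            row = neg.iloc[0]
            raise DataValidationError(
                f"rate table {self.name!r}: negative rate {row['rate_per_100k']} for "
                f"({row['sex']}, {row['cause']})"
            )
        for (sex, cause), grp in self.data.groupby(["sex", "cause"], sort=False):
            lo = grp["age_lo"].to_numpy()
            hi = grp["age_hi"].to_numpy()
            key = f"({sex}, {cause})"
            if lo[0] != 0:
                raise DataValidationError(
                    f"rate table {self.name!r}: {key} bands start at {lo[0]}, "
                    f"leaving gap [0, {lo[0]})"
                )
            if not np.isinf(hi[-1]):
                raise DataValidationError(
                    f"rate table {self.name!r}: {key} last band [{lo[-1]}, {hi[-1]}) "
                    "is not open-ended"
                )
            for i in range(len(lo)):
                if not hi[i] > lo[i]:
                    raise DataValidationError(
                        f"rate table {self.name!r}: {key} empty band [{lo[i]}, {hi[i]})"
                    )
                if i + 1 < len(lo) and hi[i] != lo[i + 1]:
                    kind = "gap" if hi[i] < lo[i + 1] else "overlap"
                    a, b = sorted((hi[i], lo[i + 1]))
                    raise DataValidationError(
                        f"rate table {self.name!r}: {key} {kind} between bands at "
                        f"[{a}, {b})"
                    )
            self._bands[(sex, cause)] = (lo, grp["rate_per_100k"].to_numpy() / 1e5)

    # -- lookup ----------------------------------------------------------

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self._bands}))

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(sorted({c for _, c in self._bands}))

    def has(self, sex: str, cause: str) -> bool:
        return (sex, cause) in self._bands

    def hazard(self, sex: str, cause: str, attained_age: float) -> float:
        """Annual hazard (per person-year) at an attained age.

        Piecewise-constant on the age bands; ages beyond the last closed
        band use the open-ended band.
        """
        return float(self.hazard_vector(sex, cause, np.asarray([attained_age]))[0])

    def hazard_vector(self, sex: str, cause: str, ages: np.ndarray) -> np.ndarray:
        if (sex, cause) not in self._bands:
            raise RateLookupError(
                f"rate table {self.name!r} has no rates for ({sex}, {cause})"
            )
        ages = np.asarray(ages, dtype=float)
        if np.any(ages < 0):
            raise DataValidationError("attained age must be >= 0")
        lo, haz = self._bands[(sex, cause)]
        idx = np.searchsorted(lo, ages, side="right") - 1
        return haz[idx]

    def check_complete(self, causes: Sequence[str] = ENDPOINTS + (ALL_OTHER,)) -> None:
        """Raise unless every modeled cause is present for both sexes."""
        for sex in SEXES:
            for cause in causes:
                if not self.has(sex, cause):
                    raise RateLookupError(
                        f"rate table {self.name!r} has no rates for ({sex}, {cause})"
                    )

    def max_closed_age(self) -> float:
        """Largest finite band boundary in the table."""
        return float(max(lo[-1] for lo, _ in self._bands.values()))

    def to_frame(self, country: str | None = None) -> pd.DataFrame:
        df = self.data.copy()
        df.insert(0, "country", country or self.name)
        return df

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RateTable)
            and self.name == other.name
            and self.data.equals(other.data)
        )


# -- IO -------------------------------------------------------------------


def read_rate_tables(path, schema: Mapping[str, str] | None = None) -> dict[str, RateTable]:
    """Read a rates CSV and return one validated :class:`RateTable` per country.

    ``schema`` optionally maps canonical column names to the file's column
    names.  An empty ``age_hi`` marks the open-ended band.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    df["age_hi"] = pd.to_numeric(df["age_hi"], errors="coerce").fillna(np.inf)
    return {
        str(country): RateTable(str(country), grp.drop(columns="country"))
        for country, grp in df.groupby("country", sort=False)
    }


def read_rate_table(path, schema: Mapping[str, str] | None = None,
                    country: str | None = None) -> RateTable:
    """Read a single country's rate table from a rates CSV."""
    tables = read_rate_tables(path, schema=schema)
    if country is not None:
        if country not in tables:
            raise RateLookupError(f"{path}: country {country!r} not found")
        return tables[country]
    if len(tables) != 1:
        raise SchemaError(
            f"{path}: contains {len(tables)} countries ({sorted(tables)}); "
            "pass country= to select one"
        )
    return next(iter(tables.values()))


def write_rate_tables(tables: Mapping[str, RateTable], path) -> None:
    frames = [t.to_frame(country) for country, t in tables.items()]
    out = pd.concat(frames, ignore_index=True)
    out["age_hi"] = out["age_hi"].replace(np.inf, np.nan)
    out.to_csv(path, index=False)


# -- regional aggregation -------------------------------------------------


def _reband_annual(table: RateTable, max_age: float) -> pd.DataFrame:
    """Expand a table to 1-year bands up to ``max_age`` (lossless under the
    piecewise-constant model)."""
    rows = []
    edges = np.arange(0.0, max_age)
    for (sex, cause), (lo, haz) in table._bands.items():
        idx = np.searchsorted(lo, edges, side="right") - 1
        rates = haz[idx] * 1e5
        for e, r in zip(edges, rates):
            rows.append((sex, cause, e, e + 1.0, r))
        rows.append((sex, cause, max_age, np.inf, haz[-1] * 1e5))
    return pd.DataFrame(rows, columns=["sex", "cause", "age_lo", "age_hi", "rate_per_100k"])


def build_region_table(countries: Sequence[RateTable] | Mapping[str, RateTable],
                       spec: RegionSpec) -> RateTable:
    """Aggregate member-country tables into one regional table.

    Per-cell rate is the (weighted) mean of the member countries' rates.
    Countries whose band structures disagree are first expanded to 1-year
    bands by piecewise-constant fill.
    """
    if isinstance(countries, Mapping):
        pool = dict(countries)
    else:
        pool = {t.name: t for t in countries}
    members = []
    for c in spec.member_countries:
        if c not in pool:
            raise RateLookupError(f"region {spec.region_name!r}: country {c!r} not supplied")
        members.append(pool[c])
    weights = spec.weights or tuple(1.0 / len(members) for _ in members)

    structures = {
        tuple(sorted((k, tuple(lo)) for k, (lo, _) in t._bands.items())) for t in members
    }
    if len(structures) > 1:
        max_age = max(t.max_closed_age() for t in members)
        frames = [_reband_annual(t, max_age) for t in members]
    else:
        frames = [t.data for t in members]

    merged = frames[0][["sex", "cause", "age_lo", "age_hi"]].copy()
    acc = np.zeros(len(merged))
    for frame, w in zip(frames, weights):
        aligned = merged.merge(frame, on=["sex", "cause", "age_lo", "age_hi"], how="left")
        if aligned["rate_per_100k"].isna().any():
            raise DataValidationError(
                f"region {spec.region_name!r}: member tables have mismatched (sex, cause) series"
            )
        acc = acc + w * aligned["rate_per_100k"].to_numpy()
    merged["rate_per_100k"] = acc
    return RateTable(spec.region_name, merged)
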