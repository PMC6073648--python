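"""Canonical record schema, readers/writers and the reference summary table.

The interchange format is a UTF-8 CSV with one row per man:

    population_id, subsistence, male_id, age, wealth, wives, rs

``age`` in integer years at censor, ``wealth`` a non-negative rival-wealth
proxy in arbitrary units, ``wives`` the number of times married, ``rs``
count-valued reproductive success.  Extra columns are preserved as
passthrough (the synthetic generator adds latent ground-truth columns).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBSISTENCE_TYPES = ("foraging", "horticulture", "agropastoral", "agriculture")
MARRIAGE_SYSTEMS = ("monogamy", "mixed", "polygyny")
REQUIRED_COLUMNS = ("population_id", "subsistence", "male_id", "age", "wealth", "wives", "rs")

#: Age at which wives and wealth are considered "completed", by analogy to
#: completed fertility.  Configurable in the age-adjustment API for
#: sensitivity analyses.
COMPLETION_AGE = 60

__all__ = [
    "SUBSISTENCE_TYPES",
    "MARRIAGE_SYSTEMS",
    "REQUIRED_COLUMNS",
    "COMPLETION_AGE",
    "PopulationDataset",
    "ValidationError",
    "read_records",
    "write_records",
    "validate_records",
    "load_published_summaries",
]


class ValidationError(ValueError):
    """Record-level validation failures, reported together."""


@dataclass
class PopulationDataset:
    """A multi-site collection of individual records plus site metadata.

    ``records`` follows the canonical schema; ``sites`` has one row per
    population with columns population_id, subsistence and (optionally)
    marriage_system and n_males.
    """

    records: pd.DataFrame
    sites: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sites is None:
            self.sites = (
                self.records.groupby("population_id", sort=False)
                .agg(subsistence=("subsistence", "first"), n_males=("male_id", "size"))
                .reset_index()
            )

    @property
    def population_ids(self) -> list:
        return list(self.sites["population_id"])

    def population(self, population_id) -> pd.DataFrame:
        return self.records[self.records["population_id"] == population_id]


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the canonical schema; collect all row-level failures before raising."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")
    problems: list[str] = []
    for col, ok in (
        ("age", lambda v: np.isfinite(v) & (v >= 0)),
        ("wealth", lambda v: np.isfinite(v) & (v >= 0)),
        ("wives", lambda v: np.isfinite(v) & (v >= 0) & (v == np.floor(v))),
        ("rs", lambda v: np.isfinite(v) & (v >= 0) & (v == np.floor(v))),
    ):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        vals[np.isnan(vals)] = -1.0
        bad = np.flatnonzero(~ok(vals))
        for i in bad[:20]:
            problems.append(f"row {i}: invalid {col} = {df[col].iloc[i]!r}")
        if bad.size > 20:
            problems.append(f"... and {bad.size - 20} more invalid {col} rows")
    dup = df.duplicated(subset=["population_id", "male_id"])
    if dup.any():
        problems.append(
            f"{int(dup.sum())} duplicated (population_id, male_id) pairs, "
            f"first at row {int(np.flatnonzero(dup)[0])}"
        )
    unknown = set(df["subsistence"].unique()) - set(SUBSISTENCE_TYPES)
    if unknown:
        problems.append(
            f"unknown subsistence label(s) {sorted(unknown)}; "
            f"expected one of {SUBSISTENCE_TYPES}"
        )
    if problems:
        raise ValidationError("record validation failed:\n" + "\n".join(problems))
    out = df.copy()
    out["age"] = out["age"].astype(int)
    out["wives"] = out["wives"].astype(int)
    out["rs"] = out["rs"].astype(int)
    out["wealth"] = out["wealth"].astype(float)
    return out


def read_records(path) -> PopulationDataset:
    """Read and validate a canonical CSV of individual records."""
    df = pd.read_csv(path)
    return PopulationDataset(records=validate_records(df))


def write_records(dataset: PopulationDataset, path) -> None:
    """Write a dataset's records to a canonical CSV (RFC-4180, header row)."""
    dataset.records.to_csv(path, index=False)


def load_published_summaries() -> pd.DataFrame:
    """Published population-level summary medians from a 29-population comparative study.

    One row per population: subsistence category, wealth Gini, rich:poor
    wealth ratio, proportion rich (minimal fraction of men holding 50% of
    total wealth), percent completed female polygyny, and the observed
    percent polygyny among men aged 60+ (missing for two populations in
    which all men married once).  Used for the in-table arithmetic checks
    (subsistence-block means, completed-vs-over-60 correlation).
    """
    ref = importlib.resources.files("polythresh.data").joinpath(
        "published_population_summaries.csv"
    )
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)
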