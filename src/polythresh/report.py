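"""Cross-population reporting: summary tables, subsistence-block means,
Gini-polygyny regressions, proportion-rich contrasts and the
completed-vs-over-60 consistency check.

All operations accept a per-population summary table (one row per
population) of the shape produced by
:func:`polythresh.age_adjust.age_adjust_dataset` — or a hand-entered table
of published estimates (see :func:`polythresh.io.load_published_summaries`)
— and are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .age_adjust import CompletedMeasures
from .io import PopulationDataset

__all__ = [
    "SummaryTable",
    "RegressionResult",
    "Contrast",
    "table_report",
    "subsistence_means",
    "polygyny_gini_regression",
    "prop_rich_contrast",
    "completed_vs_over60_correlation",
]

_POINT_COLUMNS = (
    "gini_median",
    "wealth_ratio_median",
    "proportion_rich_median",
    "polygyny_median",
    "polygyny_over60",
)


@dataclass
class SummaryTable:
    """Per-population posterior summaries plus per-subsistence mean rows."""

    populations: pd.DataFrame
    subsistence_means: pd.DataFrame
    phi: float


def table_report(
    dataset: PopulationDataset, completed: CompletedMeasures, phi: float | None = None
) -> SummaryTable:
    """Assemble the per-population summary table from completed-measure draws.

    Columns: wealth Gini, wealth ratio and proportion rich at the share
    criterion phi, percent completed polygyny (all medians with 90%
    intervals) and the observed percent polygyny among men past the
    completion age (missing where no such men exist).  Subsistence-block
    mean rows average the member point estimates.
    """
    pops = completed.population_summary.copy()
    site_cols = [c for c in ("marriage_system",) if c in dataset.sites.columns]
    if site_cols:
        pops = pops.merge(
            dataset.sites[["population_id", *site_cols]], on="population_id", how="left"
        )
    return SummaryTable(
        populations=pops,
        subsistence_means=subsistence_means(pops),
        phi=phi if phi is not None else completed.phi,
    )


def subsistence_means(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of per-population point estimates within each subsistence type.

    Empty categories are omitted; missing cells (e.g. polygyny-over-60 in
    populations with no men past the horizon) are skipped pairwise.
    """
    cols = [c for c in _POINT_COLUMNS if c in table.columns]
    return (
        table.groupby("subsistence", sort=False)[cols]
        .mean()
        .reset_index()
    )


@dataclass
class RegressionResult:
    slope: float
    lo: float
    hi: float
    intercept: float
    n: int


def polygyny_gini_regression(
    table: pd.DataFrame,
    category: str,
    gini_col: str = "gini_median",
    polygyny_col: str = "polygyny_median",
    weights: np.ndarray | None = None,
) -> RegressionResult:
    """OLS slope (with 90% CI) of percent completed polygyny on wealth Gini.

    Run across the populations of one subsistence category.  ``weights``
    enables a measurement-error-aware variant (e.g. inverse squared
    interval widths); the default is unweighted, treating the
    population-level point estimates as data.
    """
    sub = table[table["subsistence"] == category].dropna(subset=[gini_col, polygyny_col])
    if len(sub) < 3:
        raise ValueError(
            f"need at least 3 populations in category {category!r}, got {len(sub)}"
        )
    X = sm.add_constant(sub[gini_col].to_numpy())
    y = sub[polygyny_col].to_numpy()
    model = sm.WLS(y, X, weights=weights) if weights is not None else sm.OLS(y, X)
    res = model.fit()
    ci = res.conf_int(alpha=0.10)
    return RegressionResult(
        slope=float(res.params[1]),
        lo=float(ci[1][0]),
        hi=float(ci[1][1]),
        intercept=float(res.params[0]),
        n=len(sub),
    )


@dataclass
class Contrast:
    difference: float
    lo: float
    hi: float
    n_focal: int
    n_reference: int


def prop_rich_contrast(
    table: pd.DataFrame,
    category: str,
    reference: str = "agriculture",
    col: str = "proportion_rich_median",
) -> Contrast:
    """Welch two-sample mean difference of proportion rich vs the reference category.

    Positive values mean the focal category has a larger fraction of rich
    men; the 90% CI comes from the unequal-variance t distribution.
    """
    focal = table.loc[table["subsistence"] == category, col].dropna().to_numpy()
    ref = table.loc[table["subsistence"] == reference, col].dropna().to_numpy()
    if focal.size < 2 or ref.size < 2:
        raise ValueError(
            f"need >= 2 populations per group for a t contrast "
            f"(got {focal.size} {category!r}, {ref.size} {reference!r})"
        )
    res = stats.ttest_ind(focal, ref, equal_var=False)
    ci = res.confidence_interval(confidence_level=0.90)
    return Contrast(
        difference=float(focal.mean() - ref.mean()),
        lo=float(ci.low),
        hi=float(ci.high),
        n_focal=int(focal.size),
        n_reference=int(ref.size),
    )


def completed_vs_over60_correlation(
    table: pd.DataFrame,
    completed_col: str = "polygyny_median",
    observed_col: str = "polygyny_over60",
) -> float:
    """Pearson correlation between completed-polygyny estimates and the
    observed polygyny of men past the completion age, pairwise-complete.

    A strong correlation indicates the age adjustment preserves the
    population-level signal carried by the uncensored subsample.
    """
    sub = table[[completed_col, observed_col]].dropna()
    if len(sub) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(sub)}")
    return float(stats.pearsonr(sub[completed_col], sub[observed_col]).statistic)
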