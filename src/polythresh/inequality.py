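"""Empirical wealth-distribution and polygyny statistics.

Operates on vectors of individual wealth and wife counts (and on the
canonical records table, see :mod:`polythresh.io`).  The Gini here is half
the relative mean absolute difference; the "proportion rich" reductions
turn a continuous wealth distribution into the two-class summaries
(theta-hat, wealth ratio) that the theoretical model speaks in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LorenzCurve",
    "TwoClassSummary",
    "PolygynyThreshold",
    "gini",
    "lorenz",
    "proportion_rich_share",
    "two_class_summary",
    "polygyny_wealth_threshold",
    "percent_female_polygyny",
    "polygyny_over_60",
]


def _as_wealth(wealth) -> np.ndarray:
    x = np.asarray(wealth, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector of at least 2 wealth values")
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise ValueError("wealth values must be finite and non-negative")
    if x.sum() <= 0:
        raise ValueError("Gini/Lorenz are undefined when total wealth is zero")
    return x


def gini(wealth) -> float:
    """Gini coefficient: half the relative mean absolute difference.

    G = sum_ij |x_i - x_j| / (2 n^2 mean(x)), computed via the sorted
    O(n log n) identity.  No small-sample correction is applied.
    """
    x = np.sort(_as_wealth(wealth))
    n = x.size
    # sum_ij |xi - xj| = 2 * sum_i (2i - n + 1) x_(i)   (i zero-based)
    i = np.arange(n)
    mad_sum = 2.0 * np.sum((2 * i - n + 1) * x)
    return float(mad_sum / (2.0 * n * n * x.mean()))


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative-share curve: points (population fraction, wealth fraction)."""

    points: np.ndarray  # shape (n+1, 2), starts (0,0), ends (1,1)

    def gini_area(self) -> float:
        """Twice the area between the diagonal and the curve (trapezoid rule)."""
        p, w = self.points[:, 0], self.points[:, 1]
        return float(2.0 * np.trapezoid(p - w, p))

    def wealth_share_below(self, pop_fraction: float) -> float:
        """Wealth share of the poorest ``pop_fraction`` of the population."""
        p, w = self.points[:, 0], self.points[:, 1]
        return float(np.interp(pop_fraction, p, w))


def lorenz(wealth) -> LorenzCurve:
    """Lorenz curve of a wealth vector (sorted ascending, cumulative shares)."""
    x = np.sort(_as_wealth(wealth))
    n = x.size
    pop = np.arange(n + 1) / n
    wsh = np.concatenate([[0.0], np.cumsum(x)]) / x.sum()
    return LorenzCurve(points=np.column_stack([pop, wsh]))


def proportion_rich_share(wealth, phi: float) -> float:
    """Minimal fraction of men jointly holding at least a share ``phi`` of total wealth.

    Men are sorted by wealth descending (stable, so ties resolve by input
    order); the smallest k with cumulative share >= phi is returned as k/n.
    """
    if not (0.0 < phi <= 1.0):
        raise ValueError(f"phi must lie in (0, 1], got {phi}")
    x = _as_wealth(wealth)
    order = np.argsort(-x, kind="stable")
    shares = np.cumsum(x[order]) / x.sum()
    k = int(np.searchsorted(shares, phi - 1e-12) + 1)
    k = min(k, x.size)
    return k / x.size


@dataclass(frozen=True)
class TwoClassSummary:
    """Two-class reduction of a wealth distribution at share criterion ``phi``.

    ``theta_hat`` is the minimal fraction of men holding >= phi of wealth,
    ``f`` their actual wealth share, and ``wealth_ratio`` the ratio of the
    rich-class mean to the mean of the rest.  The Gini of the implied
    two-class distribution is approximately f - theta_hat.
    """

    theta_hat: float
    wealth_ratio: float
    f: float
    phi: float


def two_class_summary(wealth, phi: float) -> TwoClassSummary:
    """Reduce a wealth vector to (theta_hat, wealth ratio, rich share) at ``phi``."""
    x = _as_wealth(wealth)
    theta_hat = proportion_rich_share(x, phi)
    k = int(round(theta_hat * x.size))
    order = np.argsort(-x, kind="stable")
    top, rest = x[order[:k]], x[order[k:]]
    if rest.size == 0:
        raise ValueError(
            f"the non-rich class is empty at phi={phi}; wealth ratio undefined"
        )
    if rest.mean() == 0:
        raise ValueError("the non-rich class holds zero wealth; ratio undefined")
    return TwoClassSummary(
        theta_hat=theta_hat,
        wealth_ratio=float(top.mean() / rest.mean()),
        f=float(top.sum() / x.sum()),
        phi=phi,
    )


@dataclass(frozen=True)
class PolygynyThreshold:
    """Empirical 2-polygyny wealth threshold and the fraction of men above it."""

    psi: float
    proportion_above: float
    mean_wealth_one_wife: float
    mean_wealth_two_wives: float


def polygyny_wealth_threshold(wealth, wives) -> PolygynyThreshold:
    """Wealth level separating 1-wife from 2-wife men, and the fraction above it.

    psi is the midpoint between the average wealth of men with exactly one
    wife and of men with exactly two wives.  Populations in which one of
    the classes is absent (e.g. strictly monogamous sites) have no defined
    threshold and raise.
    """
    x = _as_wealth(wealth)
    n = np.asarray(wives)
    if n.shape != x.shape:
        raise ValueError("wealth and wives must have equal length")
    one, two = x[n == 1], x[n == 2]
    if one.size == 0 or two.size == 0:
        raise ValueError(
            "the 2-polygyny threshold needs men with exactly one wife and "
            "men with exactly two wives; at least one class is absent "
            f"(n1={one.size}, n2={two.size}) — the metric does not apply "
            "to this population"
        )
    psi = 0.5 * (one.mean() + two.mean())
    return PolygynyThreshold(
        psi=float(psi),
        proportion_above=float(np.mean(x > psi)),
        mean_wealth_one_wife=float(one.mean()),
        mean_wealth_two_wives=float(two.mean()),
    )


def percent_female_polygyny(wives) -> float:
    """Fraction of wives whose husband marries more than once.

    Counts sequential as well as concurrent marriage: sum of n_i over men
    with n_i >= 2, divided by the total number of wives.
    """
    n = np.asarray(wives, dtype=float)
    if n.size == 0 or np.any(n < 0) or np.any(n != np.floor(n)):
        raise ValueError("wives must be non-negative integer counts")
    total = n.sum()
    if total == 0:
        raise ValueError("percent female polygyny is undefined with no married men")
    return float(n[n >= 2].sum() / total)


def polygyny_over_60(records: pd.DataFrame, horizon: int = 60) -> float:
    """Observed percent female polygyny among men at or above the completion age.

    Uses raw (not age-adjusted) wife counts of men aged >= ``horizon``; a
    check on the age-adjustment machinery.  Returns NaN (and logs) when no
    man has reached the horizon or none of those men ever married.
    """
    old = records.loc[records["age"] >= horizon, "wives"]
    if old.empty or old.sum() == 0:
        logger.info(
            "polygyny_over_60: no married men aged >= %d; returning missing", horizon
        )
        return float("nan")
    return percent_female_polygyny(old.to_numpy())
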