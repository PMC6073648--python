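"""Seeded generator of multi-population individual-level datasets.

Emulates the structure of cross-cultural wealth/marriage/fertility tables:
per-site subsistence archetypes (forager, horticultural, agropastoral,
agricultural), completed rival wealth drawn from a two-class or log-normal
distribution, completed wife counts tied to wealth through the mate-choice
demand rule n* = m*(delta - mu)/(c*delta), count-valued reproductive
success with Cobb-Douglas mean n**(delta-mu) * m**mu, and cross-sectional
censoring along a saturating age-acquisition trajectory.

Latent ground-truth columns (``true_completed_*``) are retained in the
output so that every downstream estimator can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .io import COMPLETION_AGE, MARRIAGE_SYSTEMS, SUBSISTENCE_TYPES, PopulationDataset

__all__ = [
    "TwoClassWealth",
    "LogNormalWealth",
    "PopulationConfig",
    "SimConfig",
    "archetype_config",
    "default_sim_config",
    "generate_population",
    "generate_multisite",
    "acquisition_fraction",
]


@dataclass(frozen=True)
class TwoClassWealth:
    """Two-point wealth distribution: fraction ``theta`` rich at ``m_r``, rest at 1."""

    theta: float
    m_r: float

    def __post_init__(self):
        if not (0.0 < self.theta < 1.0):
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")
        if self.m_r < 1.0:
            raise ValueError(f"m_r must be >= 1, got {self.m_r}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.where(rng.random(n) < self.theta, self.m_r, 1.0)

    def reference(self, wealth: np.ndarray) -> float:
        return 1.0  # poor-class wealth is the unit


@dataclass(frozen=True)
class LogNormalWealth:
    """Continuous log-normal wealth (suits continuous proxies such as body weight)."""

    meanlog: float = 0.0
    sdlog: float = 0.5

    def __post_init__(self):
        if self.sdlog <= 0:
            raise ValueError(f"sdlog must be positive, got {self.sdlog}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(rng.normal(self.meanlog, self.sdlog, n))

    def reference(self, wealth: np.ndarray) -> float:
        # "poor-male" wealth unit for the demand rule: lower-quartile wealth
        return float(np.quantile(wealth, 0.25))


WealthModel = Union[TwoClassWealth, LogNormalWealth]


@dataclass(frozen=True)
class PopulationConfig:
    """Generative settings for one site.

    The elasticities (mu, delta), mating cost c and the wealth model are the
    same quantities as in :class:`polythresh.theory.ModelParams`; gamma acts
    only through the baseline fertility scale because non-rival wealth is
    constant within a generated site.
    """

    population_id: str
    subsistence: str
    n_males: int
    wealth: WealthModel
    marriage_system: str = "mixed"
    marriage_process: str = "concurrent"  # concurrent | serial
    mu: float = 0.08
    delta: float = 0.5
    c: float = 1.0
    base_fertility: float = 3.0
    rs_dispersion: float = 10.0  # negative-binomial shape; inf -> Poisson
    max_wives: int = 10
    age_min: int = 18
    age_max: int = 80
    traj_shape: float = 3.0
    traj_scale: float = 8.0

    def __post_init__(self):
        if self.n_males <= 0:
            raise ValueError("n_males must be positive")
        if self.subsistence not in SUBSISTENCE_TYPES:
            raise ValueError(
                f"subsistence must be one of {SUBSISTENCE_TYPES}, got {self.subsistence!r}"
            )
        if self.marriage_system not in MARRIAGE_SYSTEMS:
            raise ValueError(f"unknown marriage system {self.marriage_system!r}")
        if self.marriage_process not in ("concurrent", "serial"):
            raise ValueError(f"unknown marriage process {self.marriage_process!r}")
        if self.delta <= self.mu:
            raise ValueError(
                f"delta must exceed mu (got delta={self.delta}, mu={self.mu}); "
                "otherwise the elasticity of fitness on wives is non-positive"
            )
        if self.c <= 0 or self.base_fertility <= 0 or self.rs_dispersion <= 0:
            raise ValueError("c, base_fertility and rs_dispersion must be positive")
        if not (0 <= self.age_min < self.age_max):
            raise ValueError("need 0 <= age_min < age_max")

    def with_(self, **kwargs) -> "PopulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimConfig:
    """A bundle of per-site configurations forming a multi-site study."""

    populations: Sequence[PopulationConfig]

    def __post_init__(self):
        ids = [p.population_id for p in self.populations]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate population ids: {sorted(dupes)}")


#: Archetype wealth structures: the stylized contrasts of a stratified
#: agricultural economy (few very rich), a moderately unequal horticultural
#: economy (many moderately rich), agropastoralists in between, and foragers
#: with a continuous low-variance distribution.
_ARCHETYPES = {
    "foraging": dict(
        wealth=LogNormalWealth(meanlog=0.0, sdlog=0.5), marriage_system="mixed"
    ),
    "horticulture": dict(
        wealth=TwoClassWealth(theta=0.45, m_r=5.0), marriage_system="mixed"
    ),
    "agropastoral": dict(
        wealth=TwoClassWealth(theta=0.20, m_r=8.0), marriage_system="polygyny"
    ),
    "agriculture": dict(
        wealth=TwoClassWealth(theta=0.05, m_r=35.0), marriage_system="monogamy"
    ),
}

#: Default archetype mix: 8 forager, 9 horticultural, 8 agropastoral and
#: 4 agricultural sites, mirroring the composition of the 29-population
#: comparative sample.
DEFAULT_SITE_MIX = (
    ("foraging", 8),
    ("horticulture", 9),
    ("agropastoral", 8),
    ("agriculture", 4),
)


def archetype_config(
    subsistence: str, population_id: str, n_males: int = 150, **overrides
) -> PopulationConfig:
    """A :class:`PopulationConfig` for one of the four subsistence archetypes."""
    if subsistence not in _ARCHETYPES:
        raise ValueError(
            f"unknown archetype {subsistence!r}; expected one of {sorted(_ARCHETYPES)}"
        )
    kwargs = dict(_ARCHETYPES[subsistence])
    kwargs.update(overrides)
    return PopulationConfig(
        population_id=population_id,
        subsistence=subsistence,
        n_males=n_males,
        **kwargs,
    )


def default_sim_config(n_per_site: int = 150) -> SimConfig:
    """The default 29-site archetype bundle."""
    pops = []
    for subsistence, count in DEFAULT_SITE_MIX:
        for k in range(count):
            pops.append(
                archetype_config(
                    subsistence, f"{subsistence[:4]}_{k + 1:02d}", n_males=n_per_site
                )
            )
    return SimConfig(populations=tuple(pops))


def acquisition_fraction(
    age, shape: float, scale: float, age_min: int = 18, horizon: int = COMPLETION_AGE
):
    """Fraction of the completed (age-60) stock held at a given censor age.

    A scaled gamma-CDF in years since ``age_min``: smooth, monotone and
    saturating near the completion horizon; flat above it.
    """
    a = np.minimum(np.asarray(age, dtype=float), horizon)
    num = gamma_dist.cdf(np.maximum(a - age_min, 0.0), shape, scale=scale)
    den = gamma_dist.cdf(horizon - age_min, shape, scale=scale)
    return num / den


def _draw_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator):
    if np.isinf(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def generate_population(config: PopulationConfig, seed) -> pd.DataFrame:
    """Generate one site's individual records (canonical schema + ground truth).

    Completed wealth is drawn from the configured distribution; completed
    wife counts are Poisson around the demand rule n* = (w/ref) *
    (delta - mu)/(c * delta), truncated at ``max_wives``; completed
    reproductive success is negative-binomial with Cobb-Douglas mean;
    observed wealth/wives/rs at the censor age are thinned back along the
    acquisition trajectory.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = config.n_males

    completed_wealth = config.wealth.draw(n, rng)
    ref = config.wealth.reference(completed_wealth)
    scaled = completed_wealth / ref

    demand = scaled * (config.delta - config.mu) / (config.c * config.delta)
    completed_wives = np.minimum(rng.poisson(demand), config.max_wives)

    married = completed_wives >= 1
    rs_mean = np.where(
        married,
        config.base_fertility
        * np.maximum(completed_wives, 1) ** (config.delta - config.mu)
        * scaled**config.mu,
        0.0,
    )
    completed_rs = np.zeros(n, dtype=int)
    completed_rs[married] = _draw_counts(rs_mean[married], config.rs_dispersion, rng)

    # "wives" is times married; under a serial process no two marriages
    # co-occur, so the concurrent count never exceeds one.
    if config.marriage_process == "serial":
        concurrent = np.minimum(completed_wives, 1)
    else:
        concurrent = completed_wives

    ages = rng.integers(config.age_min, config.age_max + 1, n)
    # The acquisition clock starts at the beginning of adulthood (age 18)
    # regardless of the sampled age window, and saturates at the horizon.
    q = acquisition_fraction(ages, config.traj_shape, config.traj_scale, age_min=18)
    observed_wealth = completed_wealth * q
    observed_wives = rng.binomial(completed_wives, q)
    observed_rs = rng.binomial(completed_rs, q)

    return pd.DataFrame(
        {
            "population_id": config.population_id,
            "subsistence": config.subsistence,
            "male_id": [f"{config.population_id}_m{i:04d}" for i in range(n)],
            "age": ages,
            "wealth": observed_wealth,
            "wives": observed_wives,
            "rs": observed_rs,
            "true_completed_wealth": completed_wealth,
            "true_completed_wives": completed_wives,
            "true_completed_rs": completed_rs,
            "max_concurrent_wives": concurrent,
        }
    )


def generate_multisite(config: SimConfig, seed) -> PopulationDataset:
    """Generate a multi-site dataset with per-site seeds spawned from ``seed``.

    The same master seed always yields byte-identical output.
    """
    seqs = np.random.SeedSequence(seed).spawn(len(config.populations))
    frames = [
        generate_population(pop, child)
        for pop, child in zip(config.populations, seqs)
    ]
    records = pd.concat(frames, ignore_index=True)
    sites = pd.DataFrame(
        {
            "population_id": [p.population_id for p in config.populations],
            "subsistence": [p.subsistence for p in config.populations],
            "marriage_system": [p.marriage_system for p in config.populations],
            "n_males": [p.n_males for p in config.populations],
        }
    )
    return PopulationDataset(records=records, sites=sites)
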