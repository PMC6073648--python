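"""Mutual mate-choice (generalized polygyny-threshold) model.

A population contains two classes of men, rich (frequency ``theta``) and
poor, differing in rival wealth (``m_r`` vs ``m_p``, wealth that must be
divided among wives, e.g. land or livestock) and non-rival wealth (``g_r``
vs ``g_p``, wealth passed to all offspring in equal measure, e.g. knowledge
or network ties).  A man with ``n`` wives pays a mating investment ``c`` per
wife and his fitness is the effective number of wives times their average
fitness,

    w(n) = n**delta * g**gamma * ((m - c*n)/n)**mu,

a Cobb-Douglas form in the two wealth types.  ``mu`` and ``gamma`` are the
fitness elasticities of rival and non-rival wealth per wife; ``delta`` is
the wife-number exponent (``delta < 1`` means diminishing returns to
additional wives beyond those imposed by sharing rival wealth).

Both sexes choose: women compare the fitness of being the nth wife of a
rich man against being the sole wife of a poor man (the generalized
polygyny threshold), while each rich man demands the number of wives that
maximizes w(n), which has the closed form n* = m_r*(delta - mu)/(c*delta).
Whichever side binds determines the equilibrium, and the percent of wives
with co-wives in the demand-limited interior is P = s*theta*n* (``s`` is
the male:female sex ratio), truncated at fixation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "DomainError",
    "ModelParams",
    "EquilibriumOutcome",
    "male_fitness",
    "wife_fitness",
    "polygyny_threshold_holds",
    "optimal_wives",
    "optimal_wives_numeric",
    "supply_max_rank",
    "equilibrium",
    "gini_two_class",
    "dgini_dtheta_is_negative",
    "sti_fertility_retention",
    "sti_infertility_risk",
]


class DomainError(ValueError):
    """A quantity left the model's feasible domain (e.g. negative residual wealth)."""


@dataclass(frozen=True)
class ModelParams:
    """Parameter bundle for the two-class mutual mate-choice model.

    Wealth is normalized to poor-male units: ``m_p = g_p = 1`` by default,
    and ``m_r``, ``g_r`` are rich:poor ratios.  ``c`` is the total mating
    investment per wife in units of poor-male rival wealth.
    """

    gamma: float = 0.2
    mu: float = 0.4
    delta: float = 0.5
    c: float = 1.0
    s: float = 1.0
    theta: float = 0.05
    m_r: float = 6.0
    m_p: float = 1.0
    g_r: float = 1.0
    g_p: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ValueError(f"gamma must lie in (0, 1), got {self.gamma}")
        if not (0.0 < self.mu < 1.0):
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        if self.mu + self.gamma >= 1.0:
            raise ValueError(
                f"mu + gamma must be < 1, got {self.mu} + {self.gamma}"
            )
        if not (self.mu < self.delta <= 1.0):
            raise ValueError(
                f"delta must lie in (mu, 1], got delta={self.delta}, mu={self.mu}"
            )
        if self.m_p <= 0 or self.g_p <= 0:
            raise ValueError("m_p and g_p must be positive")
        if self.m_r < self.m_p:
            raise ValueError(f"m_r must be >= m_p, got {self.m_r} < {self.m_p}")
        if self.g_r < self.g_p:
            raise ValueError(f"g_r must be >= g_p, got {self.g_r} < {self.g_p}")
        # The model's worked scenarios sit at the boundary c = m_p, so the
        # affordability constraint is enforced as c <= m_p.
        if not (0.0 < self.c <= self.m_p):
            raise ValueError(
                f"c must lie in (0, m_p]; a poor man must afford one wife "
                f"(got c={self.c}, m_p={self.m_p})"
            )
        if self.s <= 0:
            raise ValueError(f"s (males per female) must be positive, got {self.s}")
        if not (0.0 <= self.theta < 1.0):
            raise ValueError(f"theta must lie in [0, 1), got {self.theta}")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EquilibriumOutcome:
    """Equilibrium marriage-market outcome.

    ``n_star`` is the number of wives per rich male after the binding
    constraint is applied; ``demand`` and ``supply_limit`` are the two
    sides before binding; ``P`` is the percent of wives with co-wives,
    truncated at 1 (``capped``) when the parameters drive polygyny to
    fixation.
    """

    n_star: float
    P: float
    regime: str  # demand_limiting | supply_limiting | market_clearing
    capped: bool
    demand: float
    supply_limit: float


def male_fitness(n: float, g: float, m: float, params: ModelParams) -> float:
    """Fitness of a male with ``n`` wives, non-rival wealth ``g`` and rival wealth ``m``.

    w = n**delta * g**gamma * ((m - c*n)/n)**mu.  Requires positive ``n``
    and ``g`` and non-negative residual rival wealth ``m - c*n``.
    """
    if n <= 0:
        raise DomainError(f"number of wives must be positive, got n={n}")
    if g <= 0:
        raise DomainError(f"non-rival wealth must be positive, got g={g}")
    residual = m - params.c * n
    if residual < 0:
        raise DomainError(
            f"residual rival wealth is negative at n={n}: m - c*n = "
            f"{m} - {params.c}*{n} = {residual}"
        )
    share = residual / n
    return n ** params.delta * g ** params.gamma * share ** params.mu


def wife_fitness(n: float, g: float, m: float, params: ModelParams) -> float:
    """Fitness of one of ``n`` wives of a male with wealth (``g``, ``m``).

    The male's fitness divided by his number of wives; strictly decreasing
    in ``n`` when delta < 1.
    """
    return male_fitness(n, g, m, params) / n


def polygyny_threshold_holds(n: float, params: ModelParams) -> bool:
    """Whether a woman prefers being the nth wife of a rich man to the sole wife of a poor man.

    The generalized polygyny threshold: wife_fitness(n; g_r, m_r) >=
    wife_fitness(1; g_p, m_p).  Ranks a rich man cannot provision
    (``n >= m_r / c``) are infeasible and return False.
    """
    if n < 1:
        raise ValueError(f"wife rank n must be >= 1, got {n}")
    if params.m_r - params.c * n < 0:
        return False
    lhs = wife_fitness(n, params.g_r, params.m_r, params)
    rhs = wife_fitness(1.0, params.g_p, params.m_p, params)
    return lhs >= rhs


def optimal_wives(params: ModelParams) -> float:
    """Closed-form demand: the number of wives maximizing a rich male's fitness.

    n* = m_r * (delta - mu) / (c * delta).  Increasing in m_r and delta,
    decreasing in c and mu.
    """
    return params.m_r * (params.delta - params.mu) / (params.c * params.delta)


def optimal_wives_numeric(params: ModelParams, tolerance: float = 1e-8) -> float:
    """Demand by bounded numerical maximization of male fitness over n in (0, m_r/c).

    Independent of :func:`optimal_wives`; the two agree to within the
    tolerance and serve as oracles for each other.
    """
    upper = params.m_r / params.c
    res = minimize_scalar(
        lambda n: -male_fitness(n, params.g_r, params.m_r, params),
        bounds=(tolerance, upper * (1.0 - 1e-12)),
        method="bounded",
        options={"xatol": tolerance},
    )
    if not res.success:
        raise RuntimeError(
            f"demand maximization failed to converge on bracket "
            f"(0, {upper}): {res.message}"
        )
    return float(res.x)


def supply_max_rank(params: ModelParams, tol: float = 1e-8) -> float:
    """Largest wife rank n at which the polygyny threshold still holds.

    Found by bisection on (1, m_r/c); the rich-side wife fitness is strictly
    decreasing in n, so the boundary is unique.  If the threshold holds all
    the way to the provisioning limit (e.g. when the poor man's residual
    wealth is zero), the feasibility bound m_r/c is returned.
    """
    rhs = wife_fitness(1.0, params.g_p, params.m_p, params)
    upper = params.m_r / params.c * (1.0 - 1e-12)
    if not polygyny_threshold_holds(1.0, params):
        return 1.0  # first wives are always obtainable; no polygynous rank
    if wife_fitness(upper, params.g_r, params.m_r, params) >= rhs:
        return params.m_r / params.c

    def gap(n: float) -> float:
        return wife_fitness(n, params.g_r, params.m_r, params) - rhs

    return float(brentq(gap, 1.0, upper, xtol=tol))


def equilibrium(params: ModelParams, integer_wives: bool = False) -> EquilibriumOutcome:
    """Nash-equilibrium wives per rich male and percent female polygyny.

    Demand is the closed-form n*; supply is the largest rank women will
    accept under the threshold.  The binding side sets the realized wife
    number, and P = s * theta * n at equilibrium, truncated at 1 (all wives
    have co-wives) with ``capped=True``.

    ``integer_wives=True`` applies a ceiling to the continuous demand, the
    convention under which rich men take whole wives; the default keeps the
    model's continuous closed forms.
    """
    demand = optimal_wives(params)
    if integer_wives:
        demand = float(math.ceil(demand - 1e-12))
        demand = min(demand, params.m_r / params.c * (1.0 - 1e-12))
    supply = supply_max_rank(params)
    if abs(demand - supply) <= 1e-9:
        regime = "market_clearing"
    elif demand < supply:
        regime = "demand_limiting"
    else:
        regime = "supply_limiting"
    n_eff = min(demand, supply)
    p_raw = params.s * params.theta * n_eff
    capped = p_raw > 1.0
    return EquilibriumOutcome(
        n_star=n_eff,
        P=min(1.0, p_raw),
        regime=regime,
        capped=capped,
        demand=demand,
        supply_limit=supply,
    )


def gini_two_class(theta: float, m_r: float) -> float:
    """Gini coefficient of a two-class wealth distribution.

    A fraction ``theta`` of men hold ``m_r`` units each and the rest hold 1:
    G = theta*m_r / (theta*m_r + (1 - theta)) - theta, i.e. the wealth share
    of the rich minus their population share.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    if m_r < 1.0:
        raise ValueError(f"m_r must be >= 1, got {m_r}")
    return theta * m_r / (theta * m_r + (1.0 - theta)) - theta


def dgini_dtheta_is_negative(theta: float, m_r: float) -> bool:
    """Whether the two-class Gini falls as the rich-male frequency rises.

    dG/dtheta = m_r / (1 + theta*(m_r - 1))**2 - 1, which is negative
    exactly when theta > 1/(1 + sqrt(m_r)).  Over that range a *decrease*
    in theta (a growing poor class) *increases* wealth inequality; the
    bound goes to zero as m_r grows, so the effect applies ever more
    widely in highly stratified populations.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    if m_r <= 1.0:
        return False  # G is identically 0 at m_r = 1
    return theta > 1.0 / (1.0 + math.sqrt(m_r))


def sti_fertility_retention(kappa: float, n: float) -> float:
    """Probability that none of a man's ``n`` wives carries a sterilizing infection.

    With prevalence ``kappa`` in the female population, (1 - kappa)**n.
    """
    if not (0.0 <= kappa <= 1.0):
        raise ValueError(f"kappa must lie in [0, 1], got {kappa}")
    if n < 0:
        raise ValueError(f"number of wives must be >= 0, got {n}")
    return (1.0 - kappa) ** n


def sti_infertility_risk(kappa: float, n: float) -> float:
    """Probability that at least one of ``n`` wives carries a sterilizing infection."""
    return 1.0 - sti_fertility_retention(kappa, n)
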