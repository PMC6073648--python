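"""Closed-form model: fitness, thresholds, equilibria, two-class Gini, STI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polythresh.theory import (
    DomainError,
    ModelParams,
    dgini_dtheta_is_negative,
    equilibrium,
    gini_two_class,
    male_fitness,
    optimal_wives,
    optimal_wives_numeric,
    polygyny_threshold_holds,
    sti_fertility_retention,
    sti_infertility_risk,
    supply_max_rank,
    wife_fitness,
)

BASE = ModelParams(gamma=0.2, mu=0.4, delta=0.5, c=1.0, s=1.0, theta=0.05, m_r=6.0)


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu": 0.6, "gamma": 0.5},  # mu + gamma >= 1
            {"delta": 0.3, "mu": 0.4},  # delta <= mu
            {"delta": 1.2},  # delta > 1
            {"c": 1.5, "m_p": 1.0},  # poor man cannot afford a wife
            {"c": 0.0},
            {"theta": 1.0},
            {"m_r": 0.5},  # rich below poor
            {"s": 0.0},
        ],
    )
    def test_rejects_infeasible_parameters(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**{**{"gamma": 0.2, "mu": 0.4, "delta": 0.5}, **kwargs})

    def test_with_replaces_fields(self):
        assert BASE.with_(m_r=35.0).m_r == 35.0


class TestFitness:
    def test_unit_case_is_one(self):
        # n = 1, g = 1, m = 2, c = 1: every factor equals 1
        assert male_fitness(1, 1.0, 2.0, BASE) == pytest.approx(1.0)

    def test_cobb_douglas_value(self):
        # 2^0.5 * (4/2)^0.4, cross-checked in log space
        w = male_fitness(2, 1.0, 6.0, BASE)
        assert w == pytest.approx(1.8661, abs=1e-4)
        log_w = 0.5 * math.log(2) + 0.4 * math.log((6 - 2) / 2)
        assert w == pytest.approx(math.exp(log_w))

    def test_zero_residual_wealth_gives_zero_fitness(self):
        assert male_fitness(6, 1.0, 6.0, BASE) == 0.0

    def test_negative_residual_raises_domain_error(self):
        with pytest.raises(DomainError, match="n=7"):
            male_fitness(7, 1.0, 6.0, BASE)

    def test_wife_fitness_is_per_capita_share(self):
        assert wife_fitness(1, 1.0, 2.0, BASE) == male_fitness(1, 1.0, 2.0, BASE)
        assert wife_fitness(2, 1.0, 6.0, BASE) == pytest.approx(0.9330, abs=1e-4)

    def test_wife_fitness_decreasing_in_rank_when_delta_below_one(self):
        vals = [wife_fitness(n, 1.0, 35.0, BASE.with_(m_r=35.0)) for n in (1, 2, 4, 8, 16)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestPolygynyThreshold:
    def test_symmetric_case_holds_with_equality(self):
        p = BASE.with_(m_r=1.0, g_r=1.0)
        assert polygyny_threshold_holds(1, p)

    def test_zero_poor_residual_makes_all_feasible_ranks_acceptable(self):
        # m_p = c: a poor man's wife gets no rival wealth, so any rank beats her
        p = BASE.with_(m_r=35.0, c=1.0, m_p=1.0)
        for n in (1, 5, 20, 34):
            assert polygyny_threshold_holds(n, p)

    def test_boundary_rank_against_direct_arithmetic(self):
        # mu=0.4, delta=0.5, m_r=35, c=1, m_p=2, equal g: the nth-wife-of-rich
        # fitness n^(d-1)((m_r-cn)/n)^mu crosses (m_p-c)^mu = 1 between n=4
        # (0.5*7.75^0.4 = 1.134) and n=5 (0.447*6^0.4 = 0.916).
        p = BASE.with_(m_r=35.0, m_p=2.0)
        assert polygyny_threshold_holds(4, p)
        assert not polygyny_threshold_holds(5, p)
        rank = supply_max_rank(p)
        assert 4.0 < rank < 5.0
        assert polygyny_threshold_holds(rank - 1e-6, p)
        assert not polygyny_threshold_holds(rank + 1e-6, p)

    def test_infeasible_rank_rejected(self):
        assert not polygyny_threshold_holds(40, BASE.with_(m_r=35.0))


class TestDemand:
    @pytest.mark.parametrize(
        "m_r,expected", [(35.0, 7.0), (5.0, 1.0), (6.0, 1.2)]
    )
    def test_closed_form_matches_grid_verified_values(self, m_r, expected):
        assert optimal_wives(BASE.with_(m_r=m_r)) == pytest.approx(expected)

    @pytest.mark.parametrize("m_r", [35.0, 5.0, 6.0])
    def test_numeric_maximizer_agrees_with_closed_form(self, m_r):
        p = BASE.with_(m_r=m_r)
        assert optimal_wives_numeric(p) == pytest.approx(optimal_wives(p), abs=1e-5)

    @settings(max_examples=60, deadline=None)
    @given(
        mu=st.floats(0.05, 0.6),
        ddelta=st.floats(0.02, 0.39),
        c=st.floats(0.1, 1.0),
        m_r=st.floats(1.5, 60.0),
    )
    def test_oracle_equivalence_over_random_parameters(self, mu, ddelta, c, m_r):
        delta = min(mu + ddelta, 1.0)
        p = ModelParams(gamma=0.2, mu=mu, delta=delta, c=c, m_r=m_r)
        n_star = optimal_wives(p)
        if n_star < 1e-3 or n_star > m_r / c * 0.999:
            return  # boundary optima are not interior maxima
        assert optimal_wives_numeric(p) == pytest.approx(n_star, abs=1e-5)

    def test_comparative_statics(self):
        # demand rises with m_r and delta, falls with c and mu
        grid = np.linspace(2.0, 40.0, 8)
        n_mr = [optimal_wives(BASE.with_(m_r=m)) for m in grid]
        assert all(a < b for a, b in zip(n_mr, n_mr[1:]))
        n_d = [optimal_wives(BASE.with_(delta=d)) for d in np.linspace(0.41, 0.99, 8)]
        assert all(a < b for a, b in zip(n_d, n_d[1:]))
        n_c = [optimal_wives(BASE.with_(c=c)) for c in np.linspace(0.1, 1.0, 8)]
        assert all(a > b for a, b in zip(n_c, n_c[1:]))
        n_mu = [optimal_wives(BASE.with_(mu=m)) for m in np.linspace(0.05, 0.45, 8)]
        assert all(a > b for a, b in zip(n_mu, n_mu[1:]))

    def test_lower_delta_weakly_lowers_demand_and_supply(self):
        p_hi = BASE.with_(m_r=35.0, m_p=2.0, delta=0.6)
        p_lo = p_hi.with_(delta=0.45)
        assert optimal_wives(p_lo) < optimal_wives(p_hi)
        assert supply_max_rank(p_lo) < supply_max_rank(p_hi)


class TestEquilibrium:
    def test_moderate_inequality_supports_more_polygyny(self):
        # theta=0.45, m_r=5 vs theta=0.05, m_r=35 at s=c=m_p=1, mu=0.4, delta=0.5
        eq_y = equilibrium(BASE.with_(theta=0.45, m_r=5.0))
        eq_x = equilibrium(BASE.with_(theta=0.05, m_r=35.0))
        assert eq_y.P == pytest.approx(0.45, abs=1e-9)
        assert eq_x.P == pytest.approx(0.35, abs=1e-9)
        assert eq_y.regime == "demand_limiting"
        assert eq_x.regime == "demand_limiting"

    def test_no_rich_men_no_polygyny(self):
        assert equilibrium(BASE.with_(theta=0.0)).P == 0.0

    def test_cap_at_fixation(self):
        eq = equilibrium(BASE.with_(theta=0.76, m_r=6.0), integer_wives=True)
        assert eq.P == 1.0 and eq.capped

    def test_integer_mode_takes_ceiling_of_demand(self):
        eq = equilibrium(BASE.with_(theta=0.05, m_r=6.0), integer_wives=True)
        assert eq.demand == 2.0
        assert eq.P == pytest.approx(0.10)

    def test_supply_limiting_regime(self):
        # rich barely better provisioned than poor: women cap the rank below demand
        p = BASE.with_(m_r=35.0, m_p=2.0, c=1.0)
        eq = equilibrium(p)
        assert eq.regime == "supply_limiting"
        assert eq.n_star == pytest.approx(eq.supply_limit)
        assert eq.n_star < eq.demand

    def test_polygyny_nondecreasing_in_theta_until_cap(self):
        ps = [equilibrium(BASE.with_(theta=t, m_r=35.0)).P for t in np.linspace(0.0, 0.9, 15)]
        assert all(b >= a - 1e-12 for a, b in zip(ps, ps[1:]))
        assert ps[-1] == 1.0


class TestTwoClassGini:
    def test_published_worked_values(self):
        assert round(gini_two_class(0.05, 6.0), 2) == 0.19
        assert round(gini_two_class(0.76, 6.0), 2) == 0.19
        assert round(gini_two_class(0.05, 35.0), 2) == 0.60
        assert round(gini_two_class(0.45, 5.0), 2) == 0.35

    def test_no_wealth_difference_no_inequality(self):
        assert gini_two_class(0.3, 1.0) == pytest.approx(0.0)

    @settings(max_examples=50, deadline=None)
    @given(theta=st.floats(0.02, 0.98), m_r=st.floats(1.5, 100.0))
    def test_derivative_condition_matches_central_difference(self, theta, m_r):
        h = 1e-6
        num = (gini_two_class(theta + h, m_r) - gini_two_class(theta - h, m_r)) / (2 * h)
        if abs(num) < 1e-7:
            return  # too close to the stationary point to sign reliably
        assert dgini_dtheta_is_negative(theta, m_r) == (num < 0)

    def test_growing_poor_class_raises_gini_when_theta_above_bound(self):
        # theta > 1/(1+sqrt(m_r)): shrinking the rich class increases G
        assert dgini_dtheta_is_negative(0.2, 100.0)
        assert dgini_dtheta_is_negative(0.5, 3.0)
        assert not dgini_dtheta_is_negative(0.5, 1.0)  # G is identically zero


class TestSti:
    def test_published_arithmetic(self):
        assert sti_fertility_retention(0.07, 1) == pytest.approx(0.93)
        assert sti_fertility_retention(0.07, 2) == pytest.approx(0.8649)
        assert round(sti_infertility_risk(0.07, 10), 2) == 0.52

    def test_no_wives_no_risk(self):
        assert sti_fertility_retention(0.3, 0) == 1.0

    def test_monotone_in_wives_and_prevalence(self):
        r = [sti_fertility_retention(0.07, n) for n in range(8)]
        assert all(a >= b for a, b in zip(r, r[1:]))
        k = [sti_fertility_retention(kap, 3) for kap in np.linspace(0.0, 1.0, 9)]
        assert all(a >= b for a, b in zip(k, k[1:]))
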