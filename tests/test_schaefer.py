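"""Analytics and propagators of the harvested logistic model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cprsim import (
    ResourceState,
    SchaeferParams,
    equilibrium_resource,
    growth_rate,
    harvest_rate,
    msy_effort,
    msy_yield,
    productivity_max,
    propagate_closed_form,
    propagate_numeric,
    resource_integral,
    return_rate,
    sustainable_yield,
)

PARAM_DRAWS = st.builds(
    SchaeferParams,
    mu_R=st.floats(0.02, 0.5),
    K=st.floats(10.0, 1000.0),
    q=st.floats(0.001, 0.05),
)


class TestRates:
    @pytest.mark.parametrize(
        "R, mu, K, q, F, expected",
        [
            (100.0, 0.1, 100.0, 0.01, 0.0, 0.0),  # logistic vanishes at K
            (50.0, 0.1, 100.0, 0.01, 0.0, 2.5),
            (50.0, 0.1, 100.0, 0.01, 5.0, 0.0),  # production balances harvest
        ],
    )
    def test_growth_rate_examples(self, R, mu, K, q, F, expected):
        p = SchaeferParams(mu_R=mu, K=K, q=q)
        assert growth_rate(ResourceState(0.0, R), p, F) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "R, E, expected",
        [(100.0, 5.0, 5.0), (42.0, 0.0, 0.0), (0.0, 7.0, 0.0)],
    )
    def test_harvest_rate_examples(self, params, R, E, expected):
        assert harvest_rate(R, E, params) == pytest.approx(expected)

    def test_return_rate_examples(self, params):
        assert return_rate(100.0, 5.0, params) == pytest.approx(4.5)
        free = SchaeferParams(p=0.0, c=0.1)
        assert return_rate(33.0, 5.0, free) == pytest.approx(-0.5)
        assert return_rate(50.0, 0.0, params) == 0.0

    @pytest.mark.parametrize("bad_R, bad_E", [(-1.0, 5.0), (10.0, -0.5)])
    def test_negative_inputs_rejected(self, params, bad_R, bad_E):
        with pytest.raises(ValueError):
            harvest_rate(bad_R, bad_E, params)
        with pytest.raises(ValueError):
            growth_rate(ResourceState(0.0, 10.0), params, -1.0)


class TestEquilibriumAnalytics:
    @pytest.mark.parametrize(
        "F, expected", [(0.0, 100.0), (5.0, 50.0), (10.0, 0.0), (25.0, 0.0)]
    )
    def test_equilibrium_resource(self, params, F, expected):
        assert equilibrium_resource(params, F) == pytest.approx(expected)

    def test_msy_effort(self):
        assert msy_effort(SchaeferParams(mu_R=0.1, q=0.01)) == pytest.approx(5.0)
        assert msy_effort(SchaeferParams(mu_R=0.2, q=0.01)) == pytest.approx(10.0)

    @pytest.mark.parametrize("F, expected", [(0.0, 0.0), (5.0, 2.5), (10.0, 0.0)])
    def test_sustainable_yield(self, params, F, expected):
        assert sustainable_yield(params, F) == pytest.approx(expected)

    def test_yield_at_msy_equals_quarter_muK(self, params):
        assert sustainable_yield(params, msy_effort(params)) == pytest.approx(
            params.mu_R * params.K / 4.0
        ) == pytest.approx(msy_yield(params))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(PARAM_DRAWS)
    def test_msy_grid_oracle(self, p):
        """Brute-force effort grid confirms mu_R/(2q) as the maximizer."""
        grid = np.linspace(0.0, p.mu_R / p.q, 2001)
        yields = [sustainable_yield(p, F) for F in grid]
        best = grid[int(np.argmax(yields))]
        step = grid[1] - grid[0]
        assert abs(best - msy_effort(p)) <= step
        assert max(yields) <= p.mu_R * p.K / 4.0 + 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(PARAM_DRAWS)
    def test_productivity_grid_oracle(self, p):
        """Numeric argmax of logistic production lands at K/2."""
        grid = np.linspace(0.0, p.K, 2001)
        production = p.mu_R * grid * (1.0 - grid / p.K)
        best = grid[int(np.argmax(production))]
        step = grid[1] - grid[0]
        assert abs(best - productivity_max(p)) <= step
        assert productivity_max(SchaeferParams(K=1.0)) == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        PARAM_DRAWS,
        st.floats(0.0, 0.99),
        st.floats(0.001, 0.95),
    )
    def test_equilibrium_strictly_decreasing_below_collapse(self, p, f1, df):
        """R_eq is strictly decreasing in effort on [0, mu_R/q)."""
        F1 = f1 * p.mu_R / p.q
        F2 = min(F1 + df * p.mu_R / p.q, 0.999 * p.mu_R / p.q)
        if F2 > F1:
            assert equilibrium_resource(p, F2) < equilibrium_resource(p, F1)


class TestPropagation:
    def test_zero_dt_is_identity(self, params):
        s = ResourceState(3.0, 42.0)
        assert propagate_closed_form(s, 0.0, params, 5.0).R == 42.0
        assert propagate_numeric(s, 0.0, 0.01, params, 5.0).R == 42.0

    def test_closed_form_degenerate_rate_hand_value(self, params):
        """r = mu_R - q*F = 0: harmonic decay R0/(1 + (mu_R/K) R0 dt)."""
        s = ResourceState(0.0, 100.0)
        out = propagate_closed_form(s, 90.0, params, 10.0)
        assert out.R == pytest.approx(100.0 / (1.0 + 0.001 * 100.0 * 90.0))
        assert out.R == pytest.approx(10.0)

    def test_closed_form_approaches_equilibrium(self, params):
        s = ResourceState(0.0, 100.0)
        out = propagate_closed_form(s, 5000.0, params, 5.0)
        assert out.R == pytest.approx(equilibrium_resource(params, 5.0), rel=1e-9)

    def test_fixed_points(self, params):
        at_K = ResourceState(0.0, params.K)
        assert propagate_closed_form(at_K, 57.0, params, 0.0).R == pytest.approx(params.K)
        assert propagate_numeric(at_K, 57.0, 0.01, params, 0.0).R == pytest.approx(params.K)
        extinct = ResourceState(0.0, 0.0)
        assert propagate_closed_form(extinct, 57.0, params, 0.0).R == 0.0
        assert propagate_numeric(extinct, 57.0, 0.01, params, 3.0).R == 0.0

    def test_invalid_inputs(self, params):
        s = ResourceState(0.0, 10.0)
        with pytest.raises(ValueError):
            propagate_closed_form(s, -1.0, params, 0.0)
        with pytest.raises(ValueError):
            propagate_numeric(s, 1.0, 0.0, params, 0.0)
        with pytest.raises(ValueError):
            propagate_numeric(s, 1.0, -0.5, params, 0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        PARAM_DRAWS,
        st.floats(0.0, 1.0),  # R0 as a fraction of K (can exceed eq.)
        st.floats(0.0, 3.0),  # total effort as multiple of MSY effort
        st.floats(0.0, 50.0),
    )
    def test_rk4_matches_closed_form(self, p, rfrac, fmult, dt):
        """The closed form is the oracle for the numeric integrator."""
        s = ResourceState(0.0, rfrac * p.K)
        F = fmult * msy_effort(p)
        exact = propagate_closed_form(s, dt, p, F).R
        numeric = propagate_numeric(s, dt, 0.01, p, F).R
        assert numeric == pytest.approx(exact, rel=1e-8, abs=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        PARAM_DRAWS,
        st.floats(0.001, 1.5),
        st.floats(0.0, 2.5),
        st.floats(0.0, 40.0),
        st.floats(0.0, 40.0),
    )
    def test_semigroup_property(self, p, rfrac, fmult, dt1, dt2):
        """Propagating dt1 then dt2 equals propagating dt1+dt2."""
        s = ResourceState(0.0, rfrac * p.K)
        F = fmult * msy_effort(p)
        two_step = propagate_closed_form(propagate_closed_form(s, dt1, p, F), dt2, p, F)
        one_step = propagate_closed_form(s, dt1 + dt2, p, F)
        assert two_step.R == pytest.approx(one_step.R, rel=1e-10, abs=1e-12)
        assert propagate_closed_form(s, dt1, p, F).R >= 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(PARAM_DRAWS, st.floats(0.0, 2.0), st.floats(0.0, 4.0), st.floats(0.01, 30.0))
    def test_resource_integral_matches_quadrature(self, p, rfrac, fmult, dt):
        """The exact segment integral agrees with fine trapezoid quadrature."""
        R0 = rfrac * p.K
        F = fmult * msy_effort(p)
        exact = resource_integral(R0, dt, p, F)
        ts = np.linspace(0.0, dt, 4001)
        Rs = [propagate_closed_form(ResourceState(0.0, R0), float(u), p, F).R for u in ts]
        quad = float(np.trapezoid(Rs, ts))
        assert exact == pytest.approx(quad, rel=1e-5, abs=1e-8)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu_R": 0.0},
            {"K": -5.0},
            {"q": 0.0},
            {"p": -1.0},
            {"c": -0.1},
            {"E_max": 0.0},
            {"N": 0},
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            SchaeferParams(**kwargs)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            ResourceState(0.0, -1.0)
        with pytest.raises(ValueError):
            ResourceState(math.inf, 1.0)
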