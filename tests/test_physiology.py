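"""Response functions and the daily tissue update."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thialloc as th
from thialloc import physiology as phys

P = th.ModelParameters()


class TestResponseFunctions:
    def test_recruitment_endpoints_and_value(self):
        assert th.recruitment_probability(P.c_x, P) == 1.0
        assert th.recruitment_probability(0.0, P) == 0.0
        p = P.replace(v=0.025)
        assert th.recruitment_probability(15.0, p) == pytest.approx(0.9828205985, abs=1e-9)

    def test_daily_survival_spans_derived_bounds(self):
        assert th.daily_survival(0.0, P) == pytest.approx(P.p0, abs=1e-15)
        assert th.daily_survival(P.c_x, P) == pytest.approx(P.px, abs=1e-15)
        # a very large exponent pushes interior survival to the floor
        steep = P.replace(u=500.0)
        assert th.daily_survival(15.0, steep) == pytest.approx(P.p0, abs=1e-9)

    def test_migration_survival(self):
        assert th.migration_survival(P.c_x, P) == 1.0
        assert th.migration_survival(0.0, P) == 0.0
        assert th.migration_survival(15.0, P) == pytest.approx(0.8705505633, abs=1e-9)

    def test_negative_concentration_rejected(self):
        for fn in (th.recruitment_probability, th.daily_survival, th.migration_survival):
            with pytest.raises(ValueError):
                fn(-0.1, P)


class TestLossRates:
    def test_sigmoid_frozen_values(self):
        k = th.loss_rate_sigmoid(np.array([0.0, 15.0, 30.0]), 0.5, 30.0, 200.0)
        assert k[0] == pytest.approx(0.002512437189, abs=1e-10)
        assert k[1] == pytest.approx(0.251250, abs=1e-9)  # k_x*(b+1)/(2b)
        assert k[2] == pytest.approx(0.497537068, abs=1e-9)

    def test_sigmoid_approaches_step_function(self):
        lo = [float(th.loss_rate_sigmoid(12.0, 1.0, 30.0, b)) for b in (1e2, 1e6, 1e12)]
        hi = [float(th.loss_rate_sigmoid(18.0, 1.0, 30.0, b)) for b in (1e2, 1e6, 1e12)]
        assert lo == sorted(lo, reverse=True) and lo[-1] < 0.01
        assert hi == sorted(hi) and hi[-1] > 0.99

    def test_sigmoid_rejects_degenerate_shape(self):
        with pytest.raises(ValueError):
            th.loss_rate_sigmoid(1.0, 0.5, 30.0, 1.0)

    def test_reabsorption_branches_continuous_and_endpoints(self):
        a = th.derive_reabsorption_coefficient(6.0, 0.5, 30.0, 3.0)
        below = th.loss_rate_reabsorption(6.0 - 1e-12, 0.5, 30.0, 3.0, 6.0, a)
        at = th.loss_rate_reabsorption(6.0, 0.5, 30.0, 3.0, 6.0, a)
        assert at == pytest.approx(0.1, abs=1e-12)
        assert below == pytest.approx(at, abs=1e-11)
        assert th.loss_rate_reabsorption(0.0, 0.5, 30.0, 3.0, 6.0, a) == 0.0
        assert th.loss_rate_reabsorption(30.0, 0.5, 30.0, 3.0, 6.0, a) == pytest.approx(0.5)

    def test_reabsorption_reduces_to_linear_when_bc_is_one(self):
        a = th.derive_reabsorption_coefficient(10.0, 0.35, 30.0, 1.0)
        c = np.linspace(0, 30, 13)
        np.testing.assert_allclose(
            th.loss_rate_reabsorption(c, 0.35, 30.0, 1.0, 10.0, a),
            th.loss_rate_linear(c, 0.35, 30.0),
            atol=1e-15,
        )

    def test_inconsistent_coefficient_rejected(self):
        with pytest.raises(ValueError):
            th.loss_rate_reabsorption(5.0, 0.5, 30.0, 3.0, 6.0, 1e-3)

    def test_default_loss_ratio_muscles_to_gonads(self):
        assert P.k_x_m / P.k_x_g == pytest.approx(0.7)

    @settings(max_examples=50, derandomize=True)
    @given(
        b=st.floats(1.01, 1e6),
        k_x=st.floats(0.01, 2.0),
        c=st.floats(0, 30),
        dc=st.floats(1e-6, 10),
    )
    def test_sigmoid_monotone_increasing(self, b, k_x, c, dc):
        hi = min(c + dc, 30.0)
        assert th.loss_rate_sigmoid(hi, k_x, 30.0, b) >= th.loss_rate_sigmoid(
            c, k_x, 30.0, b
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        b_c=st.floats(1.0, 8.0),
        c_t=st.floats(1.0, 25.0),
        c=st.floats(0, 30),
        dc=st.floats(1e-6, 10),
    )
    def test_reabsorption_monotone_non_decreasing(self, b_c, c_t, c, dc):
        a = th.derive_reabsorption_coefficient(c_t, 0.5, 30.0, b_c)
        hi = min(c + dc, 30.0)
        assert th.loss_rate_reabsorption(hi, 0.5, 30.0, b_c, c_t, a) >= th.loss_rate_reabsorption(
            c, 0.5, 30.0, b_c, c_t, a
        ) - 1e-15

    @settings(max_examples=50, derandomize=True)
    @given(
        u=st.floats(0.01, 10.0),
        v=st.floats(0.01, 10.0),
        c=st.floats(0, 30),
        dc=st.floats(1e-6, 10),
    )
    def test_survival_and_recruitment_monotone(self, u, v, c, dc):
        p = P.replace(u=u, v=v)
        hi = min(c + dc, 30.0)
        assert th.daily_survival(hi, p) >= th.daily_survival(c, p)
        assert th.recruitment_probability(hi, p) >= th.recruitment_probability(c, p)


class TestDailyUpdate:
    def test_hand_computed_single_step(self):
        # start (c_g, c_m) = (5, 10), alpha 0.5, c_b 2, sigmoid b = 200,
        # constant masses w_g = 100, w_m = 1000, w_b = 50
        state = th.daily_update(
            phys.TissueState(5.0, 10.0), 0.5, 2.0, 100.0, 1000.0, 50.0, 100.0, 1000.0, P
        )
        assert float(state.c_g) == pytest.approx(5.48565659457582, abs=1e-12)
        assert float(state.c_m) == pytest.approx(9.993452439649047, abs=1e-12)

    def test_all_to_muscles_with_empty_gonads_stays_empty(self):
        state = th.daily_update(
            phys.TissueState(0.0, 10.0), 1.0, 5.0, 100.0, 1000.0, 50.0, 100.0, 1000.0, P
        )
        assert float(state.c_g) == 0.0

    def test_zero_loss_conservation(self):
        # with excretion disabled the amount gained per day is exactly
        # c_b*w_b*(alpha*q_m + (1 - alpha))
        p = P.replace(k_x_g=0.0, k_x_m=0.0, excretion_model="linear")
        rng = np.random.default_rng(0)
        for _ in range(20):
            cg, cm = rng.uniform(0, 10, 2)
            alpha, cb = rng.uniform(0, 1), rng.uniform(0, 6)
            wg, wm, wb = 100.0, 1000.0, 50.0
            state = th.daily_update(
                phys.TissueState(cg, cm), alpha, cb, wg, wm, wb, wg, wm, p
            )
            gained = (float(state.c_g) * wg + float(state.c_m) * wm) - (cg * wg + cm * wm)
            expected = cb * wb * (alpha * p.q_m + (1 - alpha))
            assert gained == pytest.approx(expected, abs=1e-9)

    def test_loss_cannot_exceed_content(self):
        # tiny gonad content, large loss: amount floors at zero and is logged
        counters = {}
        state = th.daily_update(
            phys.TissueState(0.01, 0.01), 0.5, 0.0, 100.0, 1000.0, 50.0,
            100.0, 1000.0, P.replace(b=2.0), counters,
        )
        assert float(state.c_g) >= 0.0 and float(state.c_m) >= 0.0

    def test_ceiling_clamp_is_counted(self):
        counters = {}
        state = th.daily_update(
            phys.TissueState(29.9, 10.0), 0.0, 6.0, 1.0, 1000.0, 50.0,
            1.0, 1000.0, P, counters,
        )
        assert float(state.c_g) == P.c_x
        assert counters["gonad_clamped"] == 1

    def test_growth_dilutes_concentration(self):
        p = P.replace(k_x_g=0.0, k_x_m=0.0, excretion_model="linear")
        state = th.daily_update(
            phys.TissueState(10.0, 10.0), 0.5, 0.0, 100.0, 1000.0, 50.0,
            200.0, 2000.0, p,
        )
        assert float(state.c_g) == pytest.approx(5.0)
        assert float(state.c_m) == pytest.approx(5.0)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            th.daily_update(
                phys.TissueState(1.0, 1.0), 1.5, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0, P
            )
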