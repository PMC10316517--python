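"""Auxiliary rate laws: temperature scaling, resource limitation, shading,
space caps, losses, biodegradation and phosphorus bookkeeping."""

import math

import numpy as np
import pytest

import aquacosm as aq
from aquacosm.core_model import _rhs
from aquacosm.groups import EPIPHYTON, MACROPHYTES, PERIPHYTON, PHYTO_ALPHA
from aquacosm.simulate import build_context, initial_state

from conftest import make_treatment


class TestTemperatureFactor:
    @pytest.mark.parametrize(
        "T,T_ref,Q10,expected",
        [
            (22, 22, 2.0, 1.0),
            (32, 22, 2.0, 2.0),
            (26, 22, 2.0, 2 ** 0.4),
            (12, 22, 2.0, 0.5),
        ],
    )
    def test_closed_form(self, T, T_ref, Q10, expected):
        assert aq.temperature_factor(T, T_ref, Q10) == pytest.approx(expected)

    def test_monotone_in_temperature(self):
        temps = np.linspace(10, 35, 20)
        factors = [aq.temperature_factor(t, 22, 2.0) for t in temps]
        assert all(a < b for a, b in zip(factors, factors[1:]))

    @pytest.mark.parametrize("bad", [0.5, np.nan, -1.0])
    def test_rejects_invalid_q10(self, bad):
        with pytest.raises(ValueError):
            aq.temperature_factor(22, 22, bad)

    def test_rejects_nonfinite_temperature(self):
        with pytest.raises(ValueError):
            aq.temperature_factor(np.nan, 22, 2.0)


class TestResourceLimitation:
    @pytest.mark.parametrize(
        "P,K,expected", [(0, 5, 0.0), (5, 5, 0.5), (45, 5, 0.9)]
    )
    def test_monod_phosphorus(self, P, K, expected):
        assert aq.nutrient_limitation(P, K) == pytest.approx(expected)

    def test_monod_light_at_mean_irradiance(self):
        # photoperiod-averaged surface light of the default geometry
        I = 77.2 * 16 / 24
        assert aq.light_limitation(I, 40.0) == pytest.approx(
            I / (I + 40.0)
        )
        assert aq.light_limitation(I, 40.0) == pytest.approx(0.5627, abs=1e-4)

    @pytest.mark.parametrize("fn", [aq.nutrient_limitation, aq.light_limitation])
    def test_rejects_negative_inputs(self, fn):
        with pytest.raises(ValueError):
            fn(-1.0, 5.0)
        with pytest.raises(ValueError):
            fn(1.0, 0.0)


class TestSpaceAndArea:
    @pytest.mark.parametrize(
        "C,Cmax,expected",
        [(0, 1000, 1.0), (1000, 1000, 0.0), (250, 1000, 0.75), (2000, 1000, 0.0)],
    )
    def test_linear_space_factor(self, C, Cmax, expected):
        assert aq.space_limitation(C, Cmax) == pytest.approx(expected)

    def test_space_rejects_bad_capacity(self):
        with pytest.raises(ValueError):
            aq.space_limitation(10, 0)

    def test_epiphyte_area_linear_in_plant_carbon(self):
        assert aq.epiphyte_area(0, 1e-4) == 0
        assert aq.epiphyte_area(2000, 1e-4) == pytest.approx(0.2)
        assert aq.epiphyte_area(4000, 1e-4) == pytest.approx(
            2 * aq.epiphyte_area(2000, 1e-4)
        )

    def test_epiphyte_area_rejects_negative(self):
        with pytest.raises(ValueError):
            aq.epiphyte_area(-1, 1e-4)


class TestEffectiveIrradiance:
    def test_transparent_limit_returns_surface_light(self):
        geo = aq.MicrocosmGeometry()
        light = aq.LightParameters(k_bg=1e-9, k_chl=0.0, k_epi=0.0)
        I0 = geo.mean_irradiance
        for group in aq.ALL_GROUPS:
            I = aq.effective_irradiance(group, 0.0, 0.0, geo, light)
            assert I == pytest.approx(I0, rel=1e-6)
            assert I <= I0 + 1e-9

    def test_depth_average_closed_form(self):
        # k = 0.5 m^-1, H from default geometry: average of exp profile
        geo = aq.MicrocosmGeometry()
        light = aq.LightParameters(k_bg=0.5, k_chl=0.0)
        kh = 0.5 * geo.H
        expected = geo.mean_irradiance * (1 - math.exp(-kh)) / kh
        got = aq.effective_irradiance("phyto_alpha", 0.0, 0.0, geo, light)
        assert got == pytest.approx(expected, rel=1e-12)
        # H ~ 0.163 m: the average transmits ~96% of surface light
        assert got / geo.mean_irradiance == pytest.approx(0.9600, abs=2e-3)

    def test_phytoplankton_shading_reduces_macrophyte_light(self):
        geo = aq.MicrocosmGeometry()
        light = aq.LightParameters()
        lo = aq.effective_irradiance(MACROPHYTES, 2000.0, 0.0, geo, light)
        hi = aq.effective_irradiance(MACROPHYTES, 1000.0, 0.0, geo, light)
        assert lo < hi

    def test_epiphyton_layer_shades_only_macrophytes(self):
        geo = aq.MicrocosmGeometry()
        light = aq.LightParameters()
        m0 = aq.effective_irradiance(MACROPHYTES, 0.0, 0.0, geo, light)
        m1 = aq.effective_irradiance(MACROPHYTES, 0.0, 500.0, geo, light)
        assert m1 < m0
        e0 = aq.effective_irradiance(EPIPHYTON, 0.0, 0.0, geo, light)
        e1 = aq.effective_irradiance(EPIPHYTON, 0.0, 500.0, geo, light)
        assert e0 == e1

    def test_rejects_nonpositive_background_extinction(self):
        with pytest.raises(ValueError):
            aq.effective_irradiance(
                "phyto_alpha", 0.0, 0.0, aq.MicrocosmGeometry(),
                aq.LightParameters.model_construct(k_bg=0.0, k_chl=0.0, k_epi=0.0),
            )


class TestGrowthAndLossRates:
    def _context(self, setup, level=0, temp=22.0):
        return build_context(
            setup, aq.build_scenario("A1"), aq.community_set(3),
            make_treatment(level, temp),
        )

    def test_tox_factor_is_multiplicative(self, setup):
        ctx = self._context(setup)
        y = initial_state(setup, ctx.layout)
        full = aq.growth_rate(PHYTO_ALPHA, y, ctx, tox_factor=1.0)
        half = aq.growth_rate(PHYTO_ALPHA, y, ctx, tox_factor=0.5)
        assert half == pytest.approx(0.5 * full)

    def test_periphyton_at_capacity_stops_growing(self, setup):
        ctx = self._context(setup)
        y = initial_state(setup, ctx.layout)
        y[ctx.layout.live[PERIPHYTON]] = setup.params[PERIPHYTON].C_max
        assert aq.growth_rate(PERIPHYTON, y, ctx) == 0.0

    def test_unlimited_growth_reduces_to_pmax_times_ft(self, setup):
        # pin every limitation factor to ~1 via extreme half-saturations
        params = {
            g: p.model_copy(update={"K_P": 1e-12, "K_I": 1e-12})
            for g, p in setup.params.items()
        }
        local = aq.ModelSetup(
            params=params, light=aq.LightParameters(k_bg=1e-12, k_chl=0, k_epi=0)
        )
        ctx = build_context(
            local, aq.build_scenario("A1"), aq.community_set(3),
            make_treatment(0, 26.0),
        )
        y = initial_state(local, ctx.layout)
        p = aq.growth_rate(MACROPHYTES, y, ctx)
        expected = params[MACROPHYTES].p_max * aq.temperature_factor(26, 22, 2.0)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_loss_rates_sum_and_q10_double(self):
        gp = aq.GroupParameters(p_max=1.0, l_d0=0.02, l_exu0=0.01)
        l_d, l_exu, l = aq.loss_rates(gp, 22.0)
        assert (l_d, l_exu, l) == pytest.approx((0.02, 0.01, 0.03))
        l_d2, l_exu2, _ = aq.loss_rates(gp, 32.0)
        assert l_d2 == pytest.approx(2 * l_d)
        assert l_exu2 == pytest.approx(2 * l_exu)

    def test_zero_loss_parameters_give_zero_losses(self):
        gp = aq.GroupParameters(p_max=1.0, l_d0=0.0, l_exu0=0.0)
        assert aq.loss_rates(gp, 30.0) == (0.0, 0.0, 0.0)

    def test_biodegradation_scales_with_q10(self):
        decomp = aq.DecompositionParameters()
        base_dead, base_exu = aq.biodegradation_rates(decomp, 22.0)
        warm_dead, warm_exu = aq.biodegradation_rates(decomp, 26.0)
        for g in aq.ALL_GROUPS:
            assert warm_dead[g] == pytest.approx(base_dead[g] * 2 ** 0.4)
            assert warm_exu[g] == pytest.approx(base_exu[g] * 2 ** 0.4)


class TestPhosphorusBookkeeping:
    def _context(self, setup):
        return build_context(
            setup, aq.build_scenario("A1"), aq.community_set(3), make_treatment(0)
        )

    def test_zero_biomass_has_zero_sources(self, setup):
        ctx = self._context(setup)
        y = np.zeros(ctx.layout.size)
        y[ctx.layout.i_P] = 50.0
        p_rates = {g: 0.1 for g in ctx.layout.groups}
        b_dead, b_exu = aq.biodegradation_rates(setup.decomposition, 22.0)
        S = aq.phosphorus_sources(y, p_rates, ctx, b_dead, b_exu)
        assert all(v == 0 for v in S.values())

    def test_growth_only_draws_phosphorus_down(self, setup):
        ctx = self._context(setup)
        y = initial_state(setup, ctx.layout)  # live pools only, no detritus
        p_rates = {g: aq.growth_rate(g, y, ctx) for g in ctx.layout.groups}
        b_dead, b_exu = aq.biodegradation_rates(setup.decomposition, 22.0)
        S = aq.phosphorus_sources(y, p_rates, ctx, b_dead, b_exu)
        assert all(v < 0 for v in S.values())

    def test_total_phosphorus_derivative_vanishes_at_random_states(self, setup, rng):
        """Brute-force closure: quota-weighted total P has zero time
        derivative at 100 random positive states."""
        ctx = self._context(setup)
        lay = ctx.layout
        for _ in range(100):
            y = rng.uniform(0.0, 100.0, size=lay.size)
            dy = _rhs(0.5, y, ctx)
            # directional derivative of total P along dy
            eps = 1e-6
            tp0 = aq.total_phosphorus(y, ctx)
            tp1 = aq.total_phosphorus(y + eps * dy, ctx)
            scale = max(1.0, abs(tp0))
            assert abs(tp1 - tp0) / eps / scale < 1e-9

    def test_all_zero_biomass_state_is_stationary(self, setup):
        ctx = self._context(setup)
        y = np.zeros(ctx.layout.size)
        y[ctx.layout.i_P] = 123.0
        dy = aq.derivatives(y, 1.0, ctx)
        assert np.all(dy == 0)

    def test_control_rhs_identical_across_scenarios(self, setup):
        """With zero toxicant the dose-response is inert, so every scenario
        produces the same derivatives."""
        y = None
        reference = None
        for sid in aq.SCENARIO_IDS:
            ctx = build_context(
                setup, aq.build_scenario(sid), aq.community_set(3),
                make_treatment(0),
            )
            if y is None:
                y = initial_state(setup, ctx.layout)
                y[ctx.layout.live[PHYTO_ALPHA]] = 42.0
            dy = aq.derivatives(y, 2.5, ctx)
            if reference is None:
                reference = dy
            np.testing.assert_array_equal(dy, reference)

    def test_derivatives_reject_bad_states(self, setup):
        ctx = self._context(setup)
        y = np.zeros(ctx.layout.size)
        y[0] = -1e-6
        with pytest.raises(ValueError, match="negative"):
            aq.derivatives(y, 0.0, ctx)
        y[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            aq.derivatives(y, 0.0, ctx)
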