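"""Closed-form binding kinetics against limits, algebra and the ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preqfit import (
    AssayConditions,
    BindingParameters,
    ModelIntermediates,
    apparent_from_true,
    ei_concentration,
    ei_equilibrium,
    ei_ode_oracle,
    ki_from_rates,
    residual_rate_eq,
    residual_rate_preeq,
    true_from_apparent,
)

from conftest import EI_2D_2NM_900S, TABLE2


class TestEiConcentration:
    def test_matches_frozen_ode_oracle_value(self, peptide_2d):
        ei = ei_concentration(900.0, 2e-9, 2e-9, peptide_2d)
        assert ei == pytest.approx(EI_2D_2NM_900S, rel=1e-8)

    @pytest.mark.parametrize("t", [0.0, 1.0, 900.0, 1e6])
    def test_zero_inhibitor_gives_zero_occupancy(self, peptide_2d, t):
        assert ei_concentration(t, 1e-9, 0.0, peptide_2d) == 0.0

    @pytest.mark.parametrize("I0", [0.0, 1e-10, 1e-9, 1e-8])
    def test_zero_time_gives_zero_occupancy(self, peptide_2d, I0):
        assert ei_concentration(0.0, 1e-9, I0, peptide_2d) == 0.0

    def test_monotone_nondecreasing_in_time(self, peptide_2d):
        t = np.logspace(0, 6, 200)
        ei = ei_concentration(t, 2e-9, 1e-9, peptide_2d)
        assert np.all(np.diff(ei) >= -1e-30)

    def test_long_time_limit_equals_equilibrium_root(self, peptide_2d):
        for I0 in [1e-10, 1e-9, 2e-9, 8e-9]:
            lim = ei_concentration(1e7, 2e-9, I0, peptide_2d)
            eq = ei_equilibrium(2e-9, I0, peptide_2d.K_i)
            assert lim == pytest.approx(eq, rel=1e-9)

    def test_degenerate_branch_matches_ode_and_series_limit(self):
        # k_off = 0 with E_0 = I_0 makes the relaxation rate b vanish
        params = BindingParameters(k_on=1e6, k_off=0.0)
        E0 = I0 = 1e-9
        for t in [10.0, 100.0, 1000.0]:
            closed = ei_concentration(t, E0, I0, params)
            a = params.k_on * (E0 + I0)
            series = a**2 * t / (2 * params.k_on * (2 + a * t))
            assert closed == pytest.approx(series, rel=1e-12)
            assert closed == pytest.approx(ei_ode_oracle(t, E0, I0, params), rel=1e-6)

    def test_no_overflow_at_extreme_times(self, peptide_2d):
        # b*t ~ 1e9: exponential term underflows harmlessly to equilibrium
        ei = ei_concentration(1e12, 2e-9, 2e-9, peptide_2d)
        assert np.isfinite(ei)
        assert ei == pytest.approx(ei_equilibrium(2e-9, 2e-9, peptide_2d.K_i), rel=1e-9)

    @pytest.mark.parametrize(
        "t,E0,I0", [(-1.0, 1e-9, 1e-9), (1.0, -1e-9, 1e-9), (1.0, 1e-9, -1e-9), (1.0, 0.0, 1e-9)]
    )
    def test_domain_errors(self, peptide_2d, t, E0, I0):
        with pytest.raises(ValueError):
            ei_concentration(t, E0, I0, peptide_2d)

    @settings(deadline=None, max_examples=60)
    @given(
        lE0=st.floats(-11, -7),
        lI0=st.floats(-11, -7),
        lkon=st.floats(4, 8),
        lkoff=st.floats(-6, -1),
        lt=st.floats(0, 5),
    )
    def test_conservation_property(self, lE0, lI0, lkon, lkoff, lt):
        E0, I0, t = 10.0**lE0, 10.0**lI0, 10.0**lt
        params = BindingParameters(k_on=10.0**lkon, k_off=10.0**lkoff)
        ei = ei_concentration(t, E0, I0, params)
        assert 0.0 <= ei <= min(E0, I0)


class TestOdeOracle:
    def test_zero_time(self, peptide_2d):
        assert ei_ode_oracle(0.0, 1e-9, 1e-9, peptide_2d) == 0.0

    def test_equilibrium_is_fixed_point_of_the_ode(self, peptide_2d):
        E0, I0 = 2e-9, 3e-9
        ei_eq = ei_equilibrium(E0, I0, peptide_2d.K_i)
        deriv = (
            peptide_2d.k_on * (E0 - ei_eq) * (I0 - ei_eq) - peptide_2d.k_off * ei_eq
        )
        assert abs(deriv) <= 1e-12

    def test_closed_form_agrees_with_integration_sweep(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(25):
            E0 = 10 ** rng.uniform(-11, -7)
            I0 = 10 ** rng.uniform(-11, -7)
            params = BindingParameters(
                k_on=10 ** rng.uniform(4, 8), k_off=10 ** rng.uniform(-6, -1)
            )
            t = 10 ** rng.uniform(0, 5)
            dev = abs(
                ei_concentration(t, E0, I0, params) - ei_ode_oracle(t, E0, I0, params)
            ) / min(E0, I0)
            worst = max(worst, dev)
        assert worst <= 1e-6


class TestEquilibriumModel:
    def test_zero_inhibitor(self):
        assert ei_equilibrium(1e-9, 0.0, 1e-9) == 0.0

    def test_stoichiometric_limit_full_occupancy(self):
        # infinitely tight binding with excess inhibitor saturates the enzyme
        assert ei_equilibrium(1e-9, 2e-9, 0.0) == pytest.approx(1e-9, rel=1e-12)

    def test_morrison_curve_equals_long_time_integrated_law(self, peptide_2d):
        grid = np.array([16e-9 / 2**i for i in range(11)] + [0.0])
        v_eq = residual_rate_eq(1.0, 2e-9, grid, peptide_2d.K_i)
        v_pre = residual_rate_preeq(1.0, 1e8, 2e-9, grid, peptide_2d)
        assert np.max(np.abs(v_eq - v_pre)) <= 1e-9


class TestResidualRates:
    def test_no_inhibitor_and_no_incubation_return_v0(self, peptide_2d):
        assert residual_rate_preeq(3.0, 900.0, 1e-9, 0.0, peptide_2d) == 3.0
        assert residual_rate_preeq(3.0, 0.0, 1e-9, 5e-9, peptide_2d) == 3.0

    def test_frozen_oracle_residual_rate(self, peptide_2d):
        v = residual_rate_preeq(1.0, 900.0, 2e-9, 2e-9, peptide_2d)
        assert v == pytest.approx(1.0 - EI_2D_2NM_900S / 2e-9, rel=1e-8)

    def test_strictly_decreasing_in_inhibitor(self, peptide_2d):
        grid = np.array([16e-9 / 2**i for i in range(11)])[::-1]  # increasing I_0
        v = residual_rate_preeq(1.0, 900.0, 2e-9, grid, peptide_2d)
        assert np.all(np.diff(v) < 0)

    def test_rejects_nonpositive_v0(self, peptide_2d):
        with pytest.raises(ValueError):
            residual_rate_preeq(0.0, 900.0, 1e-9, 1e-9, peptide_2d)


class TestApparentTrueConversion:
    def test_identity_at_zero_substrate(self, peptide_2d):
        app = apparent_from_true(peptide_2d, S=0.0, K_m=2e-4)
        assert app.k_on == peptide_2d.k_on
        assert app.k_off == peptide_2d.k_off

    def test_substrate_at_km_doubles_ki(self):
        true = BindingParameters(k_on=1e6, k_off=1e-3)  # K_i = 1 nM
        app = apparent_from_true(true, S=2e-5, K_m=2e-5)
        assert app.K_i == pytest.approx(2e-9, rel=1e-12)
        assert app.k_on == pytest.approx(true.k_on / 2, rel=1e-12)
        assert app.k_off == true.k_off

    @settings(deadline=None, max_examples=40)
    @given(
        lkon=st.floats(4, 8),
        lkoff=st.floats(-6, -1),
        s_over_km=st.floats(0, 50),
    )
    def test_ratio_closure_and_roundtrip(self, lkon, lkoff, s_over_km):
        true = BindingParameters(k_on=10.0**lkon, k_off=10.0**lkoff)
        K_m = 2e-5
        app = apparent_from_true(true, S=s_over_km * K_m, K_m=K_m)
        assert app.K_i == pytest.approx(app.k_off / app.k_on, rel=1e-12)
        back = true_from_apparent(app, S=s_over_km * K_m, K_m=K_m)
        assert back.k_on == pytest.approx(true.k_on, rel=1e-12)
        assert back.k_off == true.k_off

    def test_invalid_km_raises(self, peptide_2d):
        with pytest.raises(ValueError):
            apparent_from_true(peptide_2d, S=1e-5, K_m=0.0)


class TestKiFromRates:
    @pytest.mark.parametrize("peptide", ["1b", "2b", "2d", "4b"])
    def test_published_pairs_close_at_printed_precision(self, peptide):
        k_on, k_off, ki_nM = TABLE2[peptide]
        computed_nM = ki_from_rates(k_on, k_off) / 1e-9
        decimals = len(str(ki_nM).split(".")[1])
        assert round(computed_nM, decimals) == ki_nM

    def test_zero_dissociation_gives_zero_ki(self):
        assert ki_from_rates(1e6, 0.0) == 0.0

    def test_nonpositive_kon_raises(self):
        with pytest.raises(ValueError):
            ki_from_rates(0.0, 1e-4)


class TestDomainTypes:
    def test_binding_parameters_ki_identity(self):
        p = BindingParameters(k_on=3.86e5, k_off=7.0e-4)
        assert p.K_i == pytest.approx(p.k_off / p.k_on, rel=1e-12)

    def test_binding_parameters_invariants(self):
        with pytest.raises(ValueError):
            BindingParameters(k_on=-1.0, k_off=1e-4)
        with pytest.raises(ValueError):
            BindingParameters(k_on=1e6, k_off=-1e-4)

    def test_conditions_require_increasing_positive_timepoints(self):
        with pytest.raises(ValueError):
            AssayConditions(E_0=1e-9, timepoints=(900.0, 300.0))
        with pytest.raises(ValueError):
            AssayConditions(E_0=1e-9, timepoints=(0.0, 300.0))
        with pytest.raises(ValueError):
            AssayConditions(E_0=0.0, timepoints=(300.0,))

    def test_intermediates_invariants(self, peptide_2d):
        im = ModelIntermediates.compute(900.0, 2e-9, 1e-9, peptide_2d)
        assert 0.0 <= im.b <= im.a
        assert 0.0 <= im.c < 1.0
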