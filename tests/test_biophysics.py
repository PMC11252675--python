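"""Single-cell biophysics: transport, viscosity, nucleation and the tau clock."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from iceprop.biophysics import (
    BiophysicsError,
    CellParams,
    CoolingProtocol,
    cytoplasm_viscosity,
    freezing_point,
    hydraulic_conductivity,
    integrate_dehydration,
    mole_fraction_water,
    nucleation_rate,
    tau_of_time,
    water_transport_rhs,
    water_viscosity,
)


class TestHydraulicConductivity:
    def test_identity_at_reference_temperature(self, hepatocyte):
        assert hydraulic_conductivity(hepatocyte, 273.15) == pytest.approx(1.5e-12, rel=1e-12)

    def test_below_reference_is_below_lpg(self, hepatocyte):
        assert hydraulic_conductivity(hepatocyte, 270.0) < hepatocyte.Lpg

    def test_arrhenius_value_at_263K(self, hepatocyte):
        # frozen value from independent arithmetic evaluation of the formula
        assert hydraulic_conductivity(hepatocyte, 263.15) == pytest.approx(
            4.905620897448596e-15, rel=1e-10
        )

    @given(st.floats(min_value=230.0, max_value=272.0))
    def test_strictly_increasing_in_T(self, hepatocyte, T):
        assert hydraulic_conductivity(hepatocyte, T) < hydraulic_conductivity(hepatocyte, T + 1.0)

    def test_nonpositive_temperature_rejected(self, hepatocyte):
        with pytest.raises(BiophysicsError):
            hydraulic_conductivity(hepatocyte, -1.0)


class TestViscosity:
    def test_unit_base_at_450K(self):
        assert water_viscosity(450.0) == pytest.approx(0.139, rel=1e-12)

    def test_value_at_freezing_point(self):
        assert water_viscosity(273.15) == pytest.approx(1.7423532587377233, rel=1e-10)

    def test_decreasing_in_T(self):
        assert water_viscosity(260.0) > water_viscosity(280.0)

    def test_domain_error_at_divergence(self):
        with pytest.raises(BiophysicsError):
            water_viscosity(225.0)

    def test_cytoplasm_equals_water_at_zero_solids(self):
        assert cytoplasm_viscosity(0.0, 260.0) == pytest.approx(water_viscosity(260.0))

    def test_crowding_ratio_at_isotonic_solids(self):
        # exp(1.275 / 0.68941), independent arithmetic
        ratio = cytoplasm_viscosity(0.51, 270.0) / water_viscosity(270.0)
        assert ratio == pytest.approx(6.356052219070917, rel=1e-10)

    @given(st.floats(min_value=0.0, max_value=0.9))
    def test_increasing_in_solid_fraction(self, phi):
        assert cytoplasm_viscosity(phi + 0.05, 260.0) > cytoplasm_viscosity(phi, 260.0)

    def test_domain_error_at_packing_singularity(self):
        with pytest.raises(BiophysicsError):
            cytoplasm_viscosity(1.0 / 0.609, 260.0)


class TestFreezingPointAndMoleFraction:
    def test_pure_water_gives_isotonic_freezing_point(self, hepatocyte):
        assert freezing_point(hepatocyte, 1.0) == pytest.approx(272.63)

    def test_depression_with_solute(self, hepatocyte):
        assert freezing_point(hepatocyte, 0.98) < 272.63

    def test_value_at_095(self, hepatocyte):
        assert freezing_point(hepatocyte, 0.95) == pytest.approx(267.4644494806147, rel=1e-10)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.01])
    def test_rejects_out_of_range(self, hepatocyte, bad):
        with pytest.raises(BiophysicsError):
            freezing_point(hepatocyte, bad)

    @pytest.mark.parametrize(
        "n_w, n_s, expected",
        [(5.0, 0.0, 1.0), (98.0, 1.0, 0.98), (0.0, 2.0, 0.0)],
    )
    def test_mole_fraction(self, n_w, n_s, expected):
        assert mole_fraction_water(n_w, n_s) == pytest.approx(expected)

    def test_mole_fraction_rejects_negative(self):
        with pytest.raises(BiophysicsError):
            mole_fraction_water(-1.0, 1.0)


class TestWaterTransport:
    def test_zero_at_chemical_equilibrium(self, hepatocyte):
        # equilibrium volume at 265 K from independent closed-form inversion
        V_eq = 2629.1025119103765
        assert water_transport_rhs(hepatocyte, V_eq, 265.0, 100.0) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_supercooled_cell_loses_water(self, hepatocyte):
        # dV/dT > 0 means V decreases as T falls during cooling
        assert water_transport_rhs(hepatocyte, hepatocyte.V_iso, 270.0, 100.0) > 0

    def test_fixed_triple_value(self, hepatocyte):
        assert water_transport_rhs(hepatocyte, 4000.0, 265.0, 100.0) == pytest.approx(
            110.41141744584655, rel=1e-9
        )

    def test_degenerate_volume_rejected(self, hepatocyte):
        with pytest.raises(BiophysicsError):
            water_transport_rhs(hepatocyte, hepatocyte.V_b, 265.0, 100.0)


class TestDehydrationTrajectory:
    def test_moderate_cooling_nearly_full_dehydration(self, hepatocyte, protocol_moderate):
        tr = integrate_dehydration(hepatocyte, protocol_moderate)
        assert tr.retained_water_fraction < 0.10  # "loses almost all of its water"

    def test_monotone_state_variables(self, hepatocyte, protocol_fast):
        tr = integrate_dehydration(hepatocyte, protocol_fast)
        assert np.all(np.diff(tr.V) <= 1e-9)
        assert np.all(np.diff(tr.x_w) <= 1e-12)
        assert np.all(np.diff(tr.Tf) <= 1e-9)
        assert np.all(np.diff(tr.tau) >= 0.0)
        assert np.all(tr.V >= hepatocyte.v_b * hepatocyte.V_iso - 1e-9)

    def test_quasi_static_limit_tracks_equilibrium(self, hepatocyte):
        tr = integrate_dehydration(
            hepatocyte, CoolingProtocol(T0=272.15, B=1.0, T_end=268.15)
        )
        # at a very slow rate the chemical-potential bracket stays near zero
        bracket = np.log(tr.V_w / (tr.V_w + hepatocyte.v_w * hepatocyte.v_s * hepatocyte.n_s)) + (
            hepatocyte.dHf_J / hepatocyte.Rgas
        ) * (1.0 / tr.T - 1.0 / hepatocyte.T_R)
        assert np.max(np.abs(bracket[tr.T < 272.0])) < 5e-3

    def test_step_halving_convergence_of_retained_water(self, hepatocyte, protocol_fast):
        a = integrate_dehydration(hepatocyte, protocol_fast, grid_step=0.05)
        b = integrate_dehydration(hepatocyte, protocol_fast, grid_step=0.025, rtol=1e-10)
        diff = abs(a.retained_water_fraction - b.retained_water_fraction)
        assert diff < 1e-3  # < 0.1 percentage points

    def test_iif_probability_nondecreasing_in_cooling_rate(self, hepatocyte):
        taus = []
        for B in (50.0, 100.0, 200.0, 400.0):
            tr = integrate_dehydration(
                hepatocyte, CoolingProtocol(T0=272.15, B=B, T_end=258.15)
            )
            taus.append(tr.tau[-1])
        p = 1.0 - np.exp(-np.asarray(taus))
        assert np.all(np.diff(p) >= 0.0)


class TestNucleationRate:
    def test_zero_without_supercooling(self, hepatocyte):
        assert nucleation_rate(hepatocyte, T=271.0, eta=15.0, Tf=270.0) == 0.0

    def test_value_at_five_kelvin_supercooling(self, hepatocyte):
        assert nucleation_rate(hepatocyte, T=265.0, eta=20.0, Tf=270.0) == pytest.approx(
            0.47743855762739773, rel=1e-10
        )

    def test_vanishes_under_deep_dehydration(self, hepatocyte):
        thin = nucleation_rate(hepatocyte, T=265.0, eta=20.0, Tf=270.0)
        thick = nucleation_rate(hepatocyte, T=265.0, eta=2e6, Tf=270.0)
        assert thick < 1e-4 * thin


class TestTauClock:
    def test_starts_at_zero_and_constant_rate_closed_form(self):
        t = np.linspace(0.0, 3.0, 7)
        tau = tau_of_time(t, np.full_like(t, 2.5))
        assert tau[0] == 0.0
        assert tau[-1] == pytest.approx(7.5, rel=1e-12)

    def test_rejects_unsorted_times(self):
        with pytest.raises(BiophysicsError):
            tau_of_time([0.0, 2.0, 1.0], [1.0, 1.0, 1.0])

    def test_matches_fine_grid_quadrature(self, hepatocyte, protocol_moderate):
        coarse = integrate_dehydration(hepatocyte, protocol_moderate, grid_step=0.05)
        fine = integrate_dehydration(hepatocyte, protocol_moderate, grid_step=0.005)
        assert fine.tau[-1] == pytest.approx(coarse.tau[-1], rel=2e-3)
        # tau-T curve is strictly monotone wherever the nucleation rate is live
        live = (coarse.Ji[:-1] > 0) & (coarse.Ji[1:] > 0)
        assert live.any()
        assert np.all(np.diff(coarse.tau)[live] > 0)

    def test_inverse_map_roundtrip(self, hepatocyte, protocol_fast):
        tm = integrate_dehydration(hepatocyte, protocol_fast).tau_map()
        probe = np.array([0.1, 0.5, 1.0]) * tm.tau_final
        assert np.allclose(tm.tau_at_t(tm.t_at_tau(probe)), probe, rtol=1e-6)
        assert math.isinf(tm.t_at_tau(tm.tau_final * 1.5))
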