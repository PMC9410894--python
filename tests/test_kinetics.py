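"""Closed forms, decoupling conditions, Bell rates and the master equation."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from orf1kin import (KineticParams, OccupancyFractions, PRESETS, bell_rate,
                     check_decoupling_conditions, closed_form_extension,
                     equilibrium_oligomer_fraction, master_equation_solve,
                     secondary_amplitude)


class TestClosedForm:
    def test_zero_at_time_zero(self):
        assert closed_form_extension(0.0, -0.04, 1.0, -0.25, 0.01) == 0.0

    def test_asymptote_is_sum_of_amplitudes(self):
        # amplitudes -0.04 and -0.25 sum to the full-compaction -0.29 nm/nt
        assert closed_form_extension(1e9, -0.04, 1.0, -0.25, 0.01) == (
            pytest.approx(-0.29, abs=1e-12))

    def test_arithmetic_value_at_100s(self):
        # -0.04*(1-e^-100) - 0.25*(1-e^-1), evaluated independently
        expected = -0.04 * (1 - np.exp(-100.0)) - 0.25 * (1 - np.exp(-1.0))
        assert closed_form_extension(100.0, -0.04, 1.0, -0.25, 0.01) == (
            pytest.approx(expected, rel=1e-12))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            closed_form_extension(-1.0, -0.04, 1.0, -0.25, 0.01)
        with pytest.raises(ValueError):
            closed_form_extension(1.0, -0.04, 0.0, -0.25, 0.01)


class TestEquilibriumAndAmplitude:
    @pytest.mark.parametrize("ko,kmo,expected", [
        (0.5, 0.5, 0.5), (1.0, 0.0, 1.0), (0.009, 0.001, 0.9),
    ])
    def test_equilibrium_fraction(self, ko, kmo, expected):
        assert equilibrium_oligomer_fraction(ko, kmo) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            equilibrium_oligomer_fraction(0.0, 0.0)

    def test_single_protein_has_zero_secondary_amplitude(self):
        assert secondary_amplitude(-1.5, 1, 0.009, 0.001) == 0.0

    def test_amplitude_arithmetic(self):
        assert secondary_amplitude(-1.5, 101, 0.009, 0.001) == (
            pytest.approx(-135.0))

    def test_no_oligomerization_no_amplitude(self):
        assert secondary_amplitude(-1.5, 101, 0.0, 0.001) == 0.0

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            secondary_amplitude(-1.5, 0, 0.009, 0.001)


class TestDecoupling:
    def test_default_preset_satisfies_both(self, kin111):
        rep = check_decoupling_conditions(kin111, ratio_min=10.0)
        assert rep["condition2"] and rep["condition3"]
        assert rep["ratios"]["binding_vs_unbinding"] == pytest.approx(200.0)
        assert rep["ratios"]["binding_vs_oligomerization"] == pytest.approx(100.0)

    def test_slow_binding_fails_condition3(self, kin111):
        kin = replace(kin111, k_b=0.02 / 30.0)  # c*k_b = 0.02 vs k_s = 0.01
        rep = check_decoupling_conditions(kin, ratio_min=10.0)
        assert not rep["condition3"]

    def test_zero_concentration_fails_both(self, kin111):
        rep = check_decoupling_conditions(replace(kin111, c=0.0), 10.0)
        assert not rep["condition2"] and not rep["condition3"]


class TestBellRate:
    def test_reference_force_returns_k0(self):
        assert bell_rate(0.009, 5.0, 0.5, 5.0) == pytest.approx(0.009)

    def test_zero_distance_is_force_independent(self):
        assert bell_rate(0.009, 75.0, 0.0, 5.0) == pytest.approx(0.009)

    def test_exponential_suppression_value(self):
        # 0.009 * exp(-25 * 0.5 / 4.11), computed independently
        expected = 0.009 * np.exp(-25.0 * 0.5 / 4.11)
        assert bell_rate(0.009, 30.0, 0.5, 5.0, 4.11) == (
            pytest.approx(expected, rel=1e-12))


class TestOccupancyFractions:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            OccupancyFractions(0.5, 0.5, 0.5)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_valid_simplex_points_accepted(self, a, b):
        t0 = a
        tb = (1.0 - a) * b
        fr = OccupancyFractions(t0, tb, 1.0 - t0 - tb)
        assert 0 <= fr.theta_oligo <= 1


class TestMasterEquation:
    def test_conservation_everywhere(self, kin111):
        sol = master_equation_solve(kin111, 5.0, np.linspace(0, 1000, 200))
        total = sol.theta_0 + sol.theta_b + sol.theta_oligo
        assert np.abs(total - 1.0).max() < 1e-9

    def test_two_state_limit_single_exponential(self, kin111):
        # k_oligo = 0: theta_b approaches kon/(kon+koff) at rate kon+koff
        kin = replace(kin111, k_oligo0=0.0)
        t = np.linspace(0, 10, 50)
        sol = master_equation_solve(kin, 5.0, t)
        kon, koff = kin.k_on(), kin.k_minus_b
        expected = kon / (kon + koff) * (1 - np.exp(-(kon + koff) * t))
        assert np.allclose(sol.theta_b, expected, atol=1e-9)
        assert np.all(sol.theta_oligo == 0)

    def test_pure_decay_from_bound(self, kin111):
        kin = replace(kin111, c=0.0, k_oligo0=0.0)
        sol = master_equation_solve(kin, 5.0, np.linspace(0, 600, 100),
                                    theta0=(0.0, 1.0, 0.0))
        assert np.all(np.diff(sol.theta_0) > 0)
        assert sol.theta_0[-1] == pytest.approx(
            1 - np.exp(-kin.k_minus_b * 600.0), rel=1e-6)

    def test_closed_form_matches_when_conditions_hold(self, kin111):
        """Under the decoupling conditions (>= 50x) the exact solution and
        the biphasic closed form agree to within 2% RMS of the total
        amplitude, and the discrepancy grows as binding slows."""
        t = np.linspace(0, 600, 300)
        gb = kin111.gamma_b_at(5.0)
        eq = equilibrium_oligomer_fraction(kin111.k_oligo(5.0),
                                           kin111.k_minus_oligo)
        dx_i = -gb
        dx_tot = -(eq + (1 - eq) * gb)
        dx_s = dx_tot - dx_i
        k_s = kin111.k_oligo(5.0) + kin111.k_minus_oligo
        rms_prev = None
        for scale in (1.0, 0.1, 0.03):
            kin = replace(kin111, k_b=kin111.k_b * scale)
            sol = master_equation_solve(kin, 5.0, t)
            cf = closed_form_extension(t, dx_i, kin.k_on(), dx_s, k_s)
            rms = np.sqrt(np.mean((cf - (sol.extension_rel - 1.0)) ** 2))
            rms /= abs(dx_tot)
            if scale == 1.0:     # conditions hold at 100x / 200x
                assert rms < 0.02
            if rms_prev is not None:
                assert rms > rms_prev
            rms_prev = rms

    def test_force_suppresses_equilibrium_oligomer(self, kin111):
        t = np.array([0.0, 5e4])
        lo = master_equation_solve(kin111, 5.0, t).theta_oligo[-1]
        hi = master_equation_solve(kin111, 30.0, t).theta_oligo[-1]
        assert hi < 0.1 * lo

    def test_bad_grid_rejected(self, kin111):
        with pytest.raises(ValueError):
            master_equation_solve(kin111, 5.0, [1.0, 0.5])


class TestPresetContracts:
    def test_retro_competent_share_secondary_rate(self):
        ks = {n: PRESETS[n].kinetic.k_oligo0 + PRESETS[n].kinetic.k_minus_oligo
              for n in PRESETS}
        assert ks["111p"] == ks["m14p"]
        assert ks["m15p"] == pytest.approx(ks["111p"], rel=1e-9)
        assert ks["111p"] == pytest.approx(0.01)

    def test_151p_oligomerization_negligible(self):
        assert PRESETS["151p"].kinetic.k_oligo0 <= 1e-4

    def test_equilibrium_fraction_separates_competence(self):
        for name, preset in PRESETS.items():
            k = preset.kinetic
            eq = equilibrium_oligomer_fraction(k.k_oligo0, k.k_minus_oligo)
            if preset.retro_competent:
                assert eq >= 0.85
            else:
                assert eq <= 0.15

    def test_invalid_kinetic_params_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(gamma_b=0.5, gamma_o=0.3)
        with pytest.raises(ValueError):
            KineticParams(k_minus_b=-1.0)
        with pytest.raises(ValueError):
            KineticParams(footprint=0)
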