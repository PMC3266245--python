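"""Cantilever dynamics engine: closed-form, perturbation and time-domain
oracles, energy accounting, determinism."""

import numpy as np
import pytest

from fmafm.dynamics import (ContactOverloadError, DriveSignal,
                            energy_budget, free_drive_force, free_resonance,
                            integrate_to_steady_state, liquid_preset,
                            single_mode_preset, virial_frequency_shift)
from fmafm.forces import ContactMaterial, ForceModel, TipGeometry


def constant_gradient_model(kts_npm: float) -> ForceModel:
    """Linear-spring surface probed while permanently indented: the tip
    sees F = -k_ts * gap, a constant-gradient interaction."""
    mat = ContactMaterial(elastic_modulus=0.0, contact_law="linear_spring",
                          spring_constant=kts_npm)
    return ForceModel(tip=TipGeometry(10.0), material=mat)


class TestFreeOscillation:
    def test_single_mode_closed_form(self, single_mode):
        f_res, f_d = free_drive_force(single_mode, 1.0)
        assert f_res == pytest.approx(single_mode.f0, rel=1e-9)
        r = integrate_to_steady_state(single_mode, DriveSignal(f_res, f_d),
                                      None, 50.0)
        q, k = 2.0, 600.0  # Q1, pN/nm
        assert r.fundamental_amplitude == pytest.approx(q * f_d / k, rel=1e-9)
        assert r.phase_lag == pytest.approx(np.pi / 2, abs=1e-9)
        assert r.energy_tipsample_per_cycle == pytest.approx(0.0, abs=1e-12)
        assert r.closure_error < 1e-10

    def test_two_mode_free_state(self, cantilever):
        f_res, f_d = free_drive_force(cantilever, 1.0)
        r = integrate_to_steady_state(cantilever, DriveSignal(f_res, f_d),
                                      None, 50.0)
        assert r.fundamental_amplitude == pytest.approx(1.0, rel=1e-9)
        assert r.phase_lag == pytest.approx(np.pi / 2, abs=1e-9)
        # pure tone: negligible harmonic content
        assert np.all(r.harmonic_amplitudes[1:] < 1e-9)

    def test_free_budget_has_no_higher_harmonics(self, cantilever):
        f_res, f_d = free_drive_force(cantilever, 1.0)
        r = integrate_to_steady_state(cantilever, DriveSignal(f_res, f_d),
                                      None, 50.0)
        b = energy_budget(r)
        assert b.fraction_higher_medium < 1e-3
        assert b.fraction_fundamental_medium == pytest.approx(1.0, abs=1e-3)


@pytest.fixture(scope="module")
def grazing(cantilever, contact_model):
    f_res, f_d = free_drive_force(cantilever, 1.0)
    return integrate_to_steady_state(
        cantilever, DriveSignal(f_res, 1.3 * f_d), contact_model, 0.95)


class TestInteractingSteadyState:

    def test_conservative_interaction_dissipates_nothing(self, grazing):
        assert abs(grazing.energy_tipsample_per_cycle) < \
            1e-3 * grazing.energy_drive_per_cycle

    def test_energy_closure(self, grazing):
        assert grazing.closure_error < 1e-2

    def test_budget_fractions_sum_to_one(self, grazing):
        b = energy_budget(grazing)
        total = (b.fraction_fundamental_medium + b.fraction_higher_medium
                 + b.fraction_tipsample)
        assert total == pytest.approx(1.0, abs=1e-2)

    def test_grazing_contact_harmonic_loss_exceeds_tipsample(self, grazing):
        # conservative contact in liquid: the drive surplus is dissipated by
        # the medium through harmonics, not by the tip-sample interaction
        b = energy_budget(grazing)
        assert b.fraction_higher_medium > abs(b.fraction_tipsample)
        assert b.fraction_higher_medium > 1e-4

    def test_determinism_bit_identical(self, cantilever, contact_model):
        f_res, f_d = free_drive_force(cantilever, 1.0)
        drv = DriveSignal(f_res, 1.3 * f_d)
        r1 = integrate_to_steady_state(cantilever, drv, contact_model, 0.95)
        r2 = integrate_to_steady_state(cantilever, drv, contact_model, 0.95)
        assert np.array_equal(r1.coefficients, r2.coefficients)
        assert r1.energy_drive_per_cycle == r2.energy_drive_per_cycle

    def test_harmonic_distortion_grows_into_contact(self, cantilever,
                                                    contact_model):
        f_res, f_d = free_drive_force(cantilever, 1.0)
        thd = []
        for z in (1.3, 1.0, 0.95, 0.9):
            r = integrate_to_steady_state(cantilever, DriveSignal(f_res, f_d),
                                          contact_model, z)
            h = r.harmonic_amplitudes
            thd.append(np.sqrt(np.sum(h[1:] ** 2)) / h[0])
        assert all(b > a for a, b in zip(thd, thd[1:]))

    def test_contact_overload_raises(self, cantilever):
        model = constant_gradient_model(0.05)
        f_res, f_d = free_drive_force(cantilever, 1.0)
        with pytest.raises(ContactOverloadError):
            integrate_to_steady_state(cantilever, DriveSignal(f_res, f_d),
                                      model, -30.0)


class TestLinearRegime:
    def test_resonance_shift_matches_perturbation(self, single_mode):
        # linearized interaction F = -k_ts q: df/f0 = k_ts/(2 k) within 1%
        kts = 0.01  # N/m vs k = 0.6 N/m
        model = constant_gradient_model(kts)
        from fmafm.control import OperatingSetpoint, track_resonance
        st = track_resonance(single_mode, model, -30.0,
                             OperatingSetpoint(1.0),
                             overload_indentation=50.0)
        predicted = single_mode.f0 * kts / (2 * 0.6)
        assert st.frequency_shift == pytest.approx(predicted, rel=0.01)

    def test_virial_zero_force(self, cantilever):
        model = ForceModel(tip=TipGeometry(10.0),
                           material=ContactMaterial(elastic_modulus=1e9))
        assert virial_frequency_shift(model, 50.0, 1.0, cantilever) == \
            pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("amplitude", [0.3, 1.0, 2.5])
    def test_virial_constant_gradient_amplitude_independent(self, single_mode,
                                                            amplitude):
        kts = 0.02
        model = constant_gradient_model(kts)
        df = virial_frequency_shift(model, -50.0, amplitude, single_mode)
        assert df == pytest.approx(single_mode.f0 * kts / (2 * 0.6), rel=1e-6)

    def test_virial_matches_tracked_engine_on_default_model(self, cantilever,
                                                            approach_model):
        from fmafm.control import OperatingSetpoint, track_resonance
        z = 2.6  # imaging-scale engagement (~40 Hz shift)
        st = track_resonance(cantilever, approach_model, z,
                             OperatingSetpoint(1.0))
        dv = virial_frequency_shift(approach_model, z, 1.0, cantilever)
        assert dv == pytest.approx(st.frequency_shift, rel=0.05)


class TestTimeDomainCrossCheck:
    def test_time_domain_agrees_with_harmonic_balance(self, single_mode):
        model = constant_gradient_model(0.01)
        f_res, f_d = free_drive_force(single_mode, 1.0)
        drv = DriveSignal(f_res * 1.005, f_d)
        kw = dict(overload_indentation=50.0)
        hb = integrate_to_steady_state(single_mode, drv, model, -30.0, **kw)
        td = integrate_to_steady_state(single_mode, drv, model, -30.0,
                                       method="time_domain", **kw)
        assert td.fundamental_amplitude == pytest.approx(
            hb.fundamental_amplitude, rel=2e-3)
        assert td.phase_lag == pytest.approx(hb.phase_lag, abs=5e-3)
        assert td.mean_deflection == pytest.approx(hb.mean_deflection,
                                                   abs=1e-3)

    def test_time_domain_free_closed_form(self, single_mode):
        f_res, f_d = free_drive_force(single_mode, 1.0)
        r = integrate_to_steady_state(single_mode, DriveSignal(f_res, f_d),
                                      None, 50.0, method="time_domain")
        assert r.fundamental_amplitude == pytest.approx(1.0, rel=1e-3)
        assert r.phase_lag == pytest.approx(np.pi / 2, abs=5e-3)


def test_free_resonance_multimode_reference(cantilever, single_mode):
    # the pi/2 crossing of the summed response defines the frequency-shift
    # origin; the higher mode pulls it slightly above f1
    assert free_resonance(single_mode) == pytest.approx(19000.0, abs=0.01)
    f2 = free_resonance(cantilever)
    assert 19000.0 < f2 < 19200.0
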