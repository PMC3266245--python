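"""Tip-sample force laws: formula oracles, continuity, conservativity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fmafm.forces import (ContactMaterial, ForceModel, GapState,
                          InvalidParameterError, SolvationParams, TipGeometry,
                          VdwTail, contact_force, solvation_force,
                          total_force, viscous_force,
                          default_approach_model)


class TestContactForce:
    def test_out_of_contact_is_zero_without_adhesion(self):
        mat = ContactMaterial(elastic_modulus=5e7, adhesion_force=0.0)
        assert contact_force(5.0, mat, TipGeometry(10.0)) == 0.0

    def test_dmt_boundary_value_is_minus_adhesion(self):
        mat = ContactMaterial(adhesion_force=50.0)
        assert contact_force(0.0, mat, TipGeometry(10.0)) == pytest.approx(-50.0)

    def test_hertz_formula_oracle(self):
        # independent high-precision evaluation of (4/3) E* sqrt(R) d^(3/2)
        e_star_pa, radius, delta = 50e6, 10.0, 1.0
        expected = (4.0 / 3.0) * (e_star_pa * 1e-6) * np.sqrt(radius) * delta**1.5
        mat = ContactMaterial(elastic_modulus=e_star_pa)
        assert contact_force(-delta, mat, TipGeometry(radius)) == pytest.approx(
            expected, rel=1e-12)

    def test_linear_spring_law(self):
        mat = ContactMaterial(elastic_modulus=0.0, contact_law="linear_spring",
                              spring_constant=0.6, adhesion_force=10.0)
        # 0.6 N/m = 600 pN/nm
        assert contact_force(-0.5, mat, TipGeometry(10.0)) == pytest.approx(
            0.6e3 * 0.5 - 10.0)

    def test_adhesion_tail_continuous_at_touch(self):
        mat = ContactMaterial(adhesion_force=80.0, adhesion_range=0.2)
        tip = TipGeometry(10.0)
        f_in = contact_force(-1e-12, mat, tip)
        f_out = contact_force(+1e-12, mat, tip)
        assert abs(f_in - f_out) < 1e-6

    @given(delta=st.floats(0.01, 3.0), scale=st.floats(1.1, 10.0))
    def test_hertz_monotone_in_indentation_and_modulus(self, delta, scale):
        tip = TipGeometry(10.0)
        mat = ContactMaterial(elastic_modulus=1e8)
        stiffer = ContactMaterial(elastic_modulus=1e8 * scale)
        f1 = contact_force(-delta, mat, tip)
        f2 = contact_force(-delta * scale, mat, tip)
        f3 = contact_force(-delta, stiffer, tip)
        assert f2 > f1 > 0
        assert f3 > f1

    @pytest.mark.parametrize("bad", [
        dict(elastic_modulus=-1.0),
        dict(adhesion_force=-5.0),
        dict(viscosity=-0.1),
        dict(contact_law="jkr"),
        dict(contact_law="linear_spring", spring_constant=0.0),
    ])
    def test_invalid_material_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            ContactMaterial(**bad)

    def test_invalid_tip(self):
        with pytest.raises(InvalidParameterError):
            TipGeometry(radius=-1.0)


class TestSolvationForce:
    def test_definition_at_one_decay_length(self):
        # phase chosen so the cosine is exactly 1 at gap = decay_length
        lam, period = 0.5, 0.3
        phase = -2.0 * np.pi * lam / period
        p = SolvationParams(amplitude=40.0, decay_length=lam, period=period,
                            phase=phase)
        assert solvation_force(lam, p) == pytest.approx(40.0 * np.exp(-1.0))

    @given(amp=st.floats(1.0, 1000.0), lam=st.floats(0.1, 2.0),
           period=st.floats(0.1, 2.0))
    def test_decay_limit(self, amp, lam, period):
        p = SolvationParams(amplitude=amp, decay_length=lam, period=period)
        assert abs(solvation_force(10.0 * lam, p)) < 1e-4 * amp + 1e-12


class TestViscousForce:
    def test_zero_rate_and_zero_viscosity(self):
        tip = TipGeometry(10.0)
        wet = ContactMaterial(viscosity=100.0)
        dry = ContactMaterial(viscosity=0.0)
        assert viscous_force(-1.0, 0.0, wet, tip) == 0.0
        assert viscous_force(-1.0, -1e4, dry, tip) == 0.0

    def test_formula_oracle(self):
        # -eta sqrt(R delta) * gap_rate, eta in internal pN*s/nm^2
        eta_pas, radius, delta, rate = 100.0, 10.0, 1.0, -1e4
        expected = -(eta_pas * 1e-6) * np.sqrt(radius * delta) * rate
        mat = ContactMaterial(viscosity=eta_pas)
        assert viscous_force(-delta, rate, mat, TipGeometry(radius)) == \
            pytest.approx(expected, rel=1e-12)

    @given(rate=st.floats(-1e5, 1e5))
    def test_opposes_motion_in_contact(self, rate):
        mat = ContactMaterial(viscosity=50.0)
        f = viscous_force(-1.0, rate, mat, TipGeometry(10.0))
        assert f * rate <= 0.0

    def test_vanishes_out_of_contact(self):
        mat = ContactMaterial(viscosity=50.0)
        assert viscous_force(0.5, -1e4, mat, TipGeometry(10.0)) == 0.0


class TestTotalForce:
    def test_far_field_null(self, approach_model):
        assert abs(total_force(GapState(100.0), approach_model)) < 0.01

    def test_decay_at_ten_decay_lengths(self, approach_model):
        solv = approach_model.solvation
        f = total_force(GapState(10.0 * solv.decay_length), approach_model)
        assert abs(f) < 1e-2 * solv.amplitude

    @pytest.mark.parametrize("fadh", [0.0, 60.0])
    def test_continuity_at_contact(self, fadh):
        model = ForceModel(tip=TipGeometry(10.0),
                           material=ContactMaterial(elastic_modulus=1e9,
                                                    adhesion_force=fadh),
                           solvation=SolvationParams(100.0, 0.5, 0.4),
                           long_range=VdwTail())
        below = total_force(GapState(-1e-9), model)
        above = total_force(GapState(+1e-9), model)
        assert abs(below - above) < 1e-6

    def test_conservative_closed_cycle_work_is_zero(self, approach_model):
        # eta = 0: the state-function force does no net work on any closed
        # gap cycle; quadrature over a dense out-and-back path
        gaps = np.concatenate([np.linspace(3.0, -0.5, 20001),
                               np.linspace(-0.5, 3.0, 20001)])
        f = np.asarray(approach_model.conservative(gaps))
        work = np.trapezoid(f, gaps)
        peak = np.max(np.abs(f)) * 3.5
        assert abs(work) < 1e-6 * peak

    def test_viscous_cycle_dissipates(self):
        # with viscosity, a closed sinusoidal cycle loses energy
        mat = ContactMaterial(elastic_modulus=1e8, viscosity=100.0)
        model = ForceModel(tip=TipGeometry(10.0), material=mat)
        t = np.linspace(0.0, 1.0, 4001)
        gap = 0.5 - 1.0 * np.sin(2 * np.pi * t)
        rate = -1.0 * 2 * np.pi * np.cos(2 * np.pi * t)
        f = np.asarray(model.total(gap, rate))
        work_on_tip = np.trapezoid(f * rate, t)
        assert work_on_tip < 0.0
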