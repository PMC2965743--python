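"""Membrane flux models: LCC waveform, NCX, leak, calibration, distribution."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttcasim.membrane import (
    CellParams,
    FluxScenario,
    IonConditions,
    LCCParams,
    LeakParams,
    NCXParams,
    PhysicalConstants,
    SpatialWeightParams,
    VoltageProtocol,
    build_boundary_flux,
    calibrate_lcc_amplitude,
    calibrate_rest_leak,
    current_density_to_flux,
    lcc_current_density,
    lcc_spatial_weight,
    lcc_template_peak_time,
    leak_flux,
    membrane_facets,
    ncx_flux,
    nernst_ECa,
    scenario_weights,
)

PROTO = VoltageProtocol()
LCC = LCCParams(amplitude=1.0)


class TestLCCWaveform:
    def test_zero_at_stimulus_onset(self):
        assert lcc_current_density(0.0, PROTO, LCC) == 0.0
        assert lcc_current_density(-5.0, PROTO, LCC) == 0.0

    def test_template_peak_time_closed_form(self):
        """The template extremum sits at τ_act·ln(1 + τ_inact/τ_act) ≈ 11.67 ms."""
        tstar = lcc_template_peak_time(LCC)
        assert tstar == pytest.approx(4.0 * math.log(18.5), rel=1e-12)
        t = np.linspace(0.0, PROTO.pulse_duration, 14001)
        i = lcc_current_density(t, PROTO, LCC)
        assert t[np.argmin(i)] == pytest.approx(tstar, abs=0.01)

    def test_inward_during_pulse_and_deactivated_after(self):
        t = np.linspace(0.5, 69.5, 100)
        assert np.all(lcc_current_density(t, PROTO, LCC) < 0)
        late = PROTO.pulse_duration + 10.0 * LCC.tau_deact
        assert abs(lcc_current_density(late, PROTO, LCC)) < 1e-4 * LCC.amplitude

    def test_tail_is_continuous_at_repolarization(self):
        eps = 1e-9
        a = lcc_current_density(PROTO.pulse_duration - eps, PROTO, LCC)
        b = lcc_current_density(PROTO.pulse_duration + eps, PROTO, LCC)
        assert a == pytest.approx(b, rel=1e-6)


class TestSpatialWeight:
    def test_table_values(self):
        assert lcc_spatial_weight(0.0) == pytest.approx(0.4515 * 1.0033, rel=1e-12)
        ratio = lcc_spatial_weight(5.645) / lcc_spatial_weight(0.0)
        assert ratio == pytest.approx(1.67, abs=0.01)

    def test_unit_polynomial(self):
        p = SpatialWeightParams(C=1.0, p1=0.0, p2=0.0, p3=0.0, p4=1.0)
        x = np.linspace(0, p.x_max, 7)
        assert np.allclose(lcc_spatial_weight(x, p), 1.0)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            lcc_spatial_weight(-0.5)
        with pytest.raises(ValueError):
            lcc_spatial_weight(6.0)


class TestNCX:
    def test_resting_efflux_value(self):
        """Direct evaluation with the published constants at rest."""
        assert ncx_flux(-50.0, 0.1) == pytest.approx(-1.685e-3, rel=0.01)

    def test_entry_mode_during_pulse(self):
        assert ncx_flux(10.0, 0.1) > 0

    def test_reversal_potential(self):
        """The flux vanishes exactly where the electrochemical driving term
        changes sign, and switches direction across it."""
        k = PhysicalConstants()
        ions = IonConditions()
        ca = 0.15
        v_rev = k.RT_over_F * math.log(ions.Na_e**3 * ca / (ions.Na_i**3 * ions.Ca_e))
        assert abs(ncx_flux(v_rev, ca)) < 1e-12
        assert ncx_flux(v_rev + 1.0, ca) > 0 > ncx_flux(v_rev - 1.0, ca)

    def test_rate_increases_on_repolarization(self):
        """Returning to −50 mV with elevated Ca²⁺ gives faster extrusion than
        the exchanger's entry rate just before repolarization."""
        assert abs(ncx_flux(-50.0, 0.163)) > 0  # efflux
        assert ncx_flux(-50.0, 0.163) < 0 < ncx_flux(10.0, 0.163)


class TestLeakAndCalibration:
    def test_zero_at_equilibrium_potential(self):
        ions = IonConditions(Ca_e=1000.0)
        assert leak_flux(0.0, 1000.0, ions) == pytest.approx(0.0, abs=1e-15)

    def test_nernst_rest(self):
        assert nernst_ECa(0.1, 1000.0) == pytest.approx(117.05, abs=0.05)

    def test_rejects_zero_ca(self):
        with pytest.raises(ValueError):
            leak_flux(-50.0, 0.0)

    def test_calibrated_leak_cancels_ncx_exactly(self):
        ions = IonConditions()
        lk = calibrate_rest_leak(ions)
        total = leak_flux(-50.0, 0.1, ions, lk) + ncx_flux(-50.0, 0.1, ions)
        assert abs(total) < 1e-18
        assert lk.g_leak > 0

    def test_sign_flips_without_external_sodium(self):
        lk = calibrate_rest_leak(IonConditions(Na_e=0.0))
        assert lk.g_leak < 0


class TestFluxConversion:
    def test_values(self):
        assert current_density_to_flux(0.0) == 0.0
        # unit-conversion oracle: 8.8 pF/pL / (2 * 96.5 C/mmol)
        assert current_density_to_flux(-1.0) == pytest.approx(8.8 / 193.0, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.floats(0.1, 10))
    def test_linearity(self, i, a):
        assert current_density_to_flux(a * i) == pytest.approx(
            a * current_density_to_flux(i), rel=1e-12, abs=1e-15)


class TestBoundaryDistribution:
    def test_homogeneous_density_uniform(self, cyl_mesh):
        out = build_boundary_flux(cyl_mesh, FluxScenario(lcc_mode="homogeneous",
                                                         ncx_ttubule_ratio=1.0),
                                  t=11.67, V=10.0, local_Ca=0.1,
                                  lcc=LCCParams(amplitude=1.0))
        for comp in ("lcc", "ncx", "leak"):
            assert np.allclose(out[comp], out[comp][0])

    def test_uniform6x_ratio_and_conservation(self, cyl_mesh):
        mf = membrane_facets(cyl_mesh)
        lcc = LCCParams(amplitude=1.0)
        t, v = 11.67, 10.0
        totals = {}
        for mode, ratio in [("homogeneous", 1.0), ("uniform_6x_ttubule", 3.0),
                            ("heterogeneous_polynomial", 3.0)]:
            out = build_boundary_flux(cyl_mesh, FluxScenario(lcc_mode=mode,
                                                             ncx_ttubule_ratio=ratio),
                                      t=t, V=v, local_Ca=0.1, lcc=lcc)
            totals[mode] = {c: float((out[c] * mf.areas).sum())
                            for c in ("lcc", "ncx", "leak")}
        # redistribution conserves every component's whole-compartment total
        for comp in ("lcc", "ncx", "leak"):
            vals = [totals[m][comp] for m in totals]
            assert np.allclose(vals, vals[0], rtol=1e-12)
        # t-tubule : external density ratio is exactly 6 in the uniform-6x mode
        out = build_boundary_flux(cyl_mesh,
                                  FluxScenario(lcc_mode="uniform_6x_ttubule"),
                                  t=t, V=v, local_Ca=0.1, lcc=lcc)
        tt = out["lcc"][mf.is_ttubule][0]
        ext = out["lcc"][~mf.is_ttubule][0]
        assert tt / ext == pytest.approx(6.0, rel=1e-12)

    def test_heterogeneous_grades_along_tubule(self, cyl_mesh):
        """Within the tubule the LCC density follows the depth polynomial:
        deepest/shallowest ≈ the published ~1.7-fold increase."""
        mf = membrane_facets(cyl_mesh)
        out = build_boundary_flux(cyl_mesh,
                                  FluxScenario(lcc_mode="heterogeneous_polynomial"),
                                  t=11.67, V=10.0, local_Ca=0.1,
                                  lcc=LCCParams(amplitude=1.0))
        dens = out["lcc"]
        tt = mf.is_ttubule
        d_deep = dens[tt][np.argmax(mf.depth[tt])]
        d_shallow = dens[tt][np.argmin(mf.depth[tt])]
        expected = (lcc_spatial_weight(min(mf.depth[tt].max(), 5.645))
                    / lcc_spatial_weight(mf.depth[tt].min()))
        assert d_deep / d_shallow == pytest.approx(expected, rel=1e-9)
        assert d_deep / d_shallow == pytest.approx(1.67, abs=0.12)


def test_calibrate_amplitude_rest_target_is_zero():
    from ttcasim.solver import SimulationConfig

    assert calibrate_lcc_amplitude(0.1, SimulationConfig()) == 0.0


def test_scenario_validation():
    with pytest.raises(ValueError):
        FluxScenario(lcc_mode="bogus")
    with pytest.raises(ValueError):
        FluxScenario(ncx_ttubule_ratio=2.0)
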