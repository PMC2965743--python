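"""Time integration: 0-D reduction, 3-D FEM runs, conservation, convergence."""

from dataclasses import replace

import numpy as np
import pytest

from ttcasim.analysis import transient_metrics
from ttcasim.membrane import LCCParams, VoltageProtocol
from ttcasim.presets import PRESETS
from ttcasim.solver import (
    SimulationConfig,
    check_conservation,
    run_0d,
    run_3d,
)

NO_PULSE = VoltageProtocol(V_pulse=-50.0)


class TestWellMixed:
    def test_resting_steady_state(self):
        """With the calibrated leak and no stimulus the 0-D model holds the
        100 nM resting level indefinitely."""
        cfg = SimulationConfig(protocol=NO_PULSE, dt=0.1, duration=400.0)
        tr = run_0d(cfg)
        assert np.max(np.abs(tr.Ca - 0.1)) < 1e-6
        assert abs(tr.J_NCX[-1] + tr.J_leak[-1]) < 1e-15

    def test_pulse_without_lcc_raises_then_relaxes(self):
        """Even with zero LCC amplitude the depolarization reverses NCX into
        entry mode, so Ca rises during the pulse and falls afterwards."""
        cfg = SimulationConfig(dt=0.1, duration=400.0)
        tr = run_0d(cfg)
        m = transient_metrics(tr)
        assert 0.1 < m.peak < 0.12
        assert abs(m.t_peak - 70.0) < 1.0
        assert tr.Ca[-1] < m.peak

    def test_ncx_direction_over_protocol(self, lcc_amplitude):
        cfg = SimulationConfig(dt=0.1, duration=400.0,
                               lcc=LCCParams(amplitude=lcc_amplitude))
        tr = run_0d(cfg)
        pulse = (tr.time > 1.0) & (tr.time < 69.9)
        after = tr.time > 70.5
        assert np.all(tr.J_NCX[pulse] > 0)   # entry mode at +10 mV
        assert np.all(tr.J_NCX[after] < 0)   # exit mode back at −50 mV

    def test_temporal_convergence(self, lcc_amplitude):
        """Halving dt changes the global peak by far less than 1 %."""
        base = SimulationConfig(dt=0.1, duration=120.0,
                                lcc=LCCParams(amplitude=lcc_amplitude))
        p1 = transient_metrics(run_0d(base)).peak
        p2 = transient_metrics(run_0d(replace(base, dt=0.05))).peak
        assert abs(p1 - p2) / p2 < 0.01

    def test_dye_removal_raises_peak_same_timing(self, lcc_amplitude):
        """Removing Fluo-3 at fixed LCC amplitude raises the global peak but
        leaves the time to peak unchanged."""
        with_dye = PRESETS["fig4_heterogeneous"].simulation_config(dt=0.1)
        no_dye = PRESETS["fig6_nodye"].simulation_config(dt=0.1)
        m1 = transient_metrics(run_0d(replace(
            with_dye, lcc=LCCParams(amplitude=lcc_amplitude))))
        m2 = transient_metrics(run_0d(replace(
            no_dye, lcc=LCCParams(amplitude=lcc_amplitude))))
        assert m2.peak > 1.3 * m1.peak
        assert abs(m2.t_peak - m1.t_peak) < 2.0


class TestThreeD:
    def test_sealed_membrane_steady_state(self, cyl_mesh):
        """Zero membrane flux from the equilibrium start: all fields constant
        and total Ca exactly conserved."""
        cfg = SimulationConfig(dt=1.0, duration=400.0, output_stride=50,
                               no_membrane_flux=True)
        sol = run_3d(cyl_mesh, cfg)
        for name, arr in sol.fields.items():
            ref = arr[0]
            drift = np.max(np.abs(arr - ref)) / max(float(ref.max()), 1e-12)
            assert drift < 1e-8, name
        rep = check_conservation(sol, rtol=1e-10)
        assert rep.ok

    def test_pulse_conservation_and_positivity(self, cyl_mesh, lcc_amplitude):
        """Influx bookkeeping: total Ca gained equals the integrated membrane
        flux; no field ever goes negative."""
        cfg = PRESETS["fig4_homogeneous"].simulation_config(dt=0.5, output_stride=40)
        cfg = replace(cfg, lcc=LCCParams(amplitude=lcc_amplitude))
        sol = run_3d(cyl_mesh, cfg)
        rep = check_conservation(sol)
        assert rep.ok and rep.max_relative_error < 1e-6
        for arr in sol.fields.values():
            assert np.all(arr >= 0) and np.all(np.isfinite(arr))

    def test_efflux_phase_monotone_decrease(self, cyl_mesh):
        """With no LCC, the post-pulse phase is pure net efflux: the total Ca
        content decreases monotonically after repolarization."""
        cfg = SimulationConfig(dt=1.0, duration=200.0, output_stride=10)
        sol = run_3d(cyl_mesh, cfg)
        after = sol.time >= 72.0
        totals = sol.total_content[after]
        assert np.all(np.diff(totals) < 0)

    def test_0d_equivalence_on_homogeneous_cylinder(self, cyl_mesh, lcc_amplitude):
        """Volume-averaged 3-D Ca with homogeneous fluxes tracks the 0-D
        reduction within 5 % at every output time."""
        cfg = PRESETS["fig4_homogeneous"].simulation_config(dt=0.25, output_stride=16)
        cfg = replace(cfg, lcc=LCCParams(amplitude=lcc_amplitude))
        sol = run_3d(cyl_mesh, cfg)
        tr = run_0d(replace(cfg, dt=0.1))
        avg = sol.volume_average("Ca")
        ref = np.interp(sol.time, tr.time, tr.Ca)
        assert np.max(np.abs(avg - ref) / ref) < 0.05

    def test_3d_temporal_convergence(self, cyl_mesh, lcc_amplitude):
        cfg = PRESETS["fig4_homogeneous"].simulation_config(dt=1.0, output_stride=10)
        cfg = replace(cfg, lcc=LCCParams(amplitude=lcc_amplitude), duration=100.0)
        p1 = float(np.max(run_3d(cyl_mesh, cfg).volume_average("Ca")))
        p2 = float(np.max(run_3d(cyl_mesh, replace(cfg, dt=0.5,
                                                   output_stride=20)).volume_average("Ca")))
        assert abs(p1 - p2) / p2 < 0.01

    def test_troponin_excluded_near_membrane(self, scenario_solutions):
        """Stationary troponin C carries no capacity inside the
        sub-sarcolemmal shell: its complex stays at zero on membrane nodes."""
        sol = scenario_solutions["fig4_heterogeneous"]
        from ttcasim.geometry import REFLECTIVE, distance_to_membrane_field

        dist = distance_to_membrane_field(sol.mesh)
        shell = dist < sol.config.buffers.tn_exclusion_depth
        assert shell.any()
        catn = sol.fields["Catroponin C"][-1]
        assert np.max(catn[shell]) == 0.0
        assert np.min(catn[~shell]) > 0.0
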