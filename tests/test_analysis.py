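"""Line-scan extraction, SCH statistic, transient metrics, front detection."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttcasim.analysis import (
    LineScanImage,
    LineScanSpec,
    compute_sch,
    detect_front,
    extract_linescan,
    sch_report,
    transient_metrics,
)
from ttcasim.solver import Solution


def _synthetic_solution(mesh, field_fn, times=(0.0, 10.0)):
    """Wrap an analytic nodal field into a Solution for interpolation tests."""
    n = mesh.n_vertices
    vals = field_fn(mesh.vertices)
    fields = {"Ca": np.tile(vals, (len(times), 1))}
    z = np.zeros(len(times))
    return Solution(time=np.asarray(times, dtype=float), fields=fields, mesh=mesh,
                    node_volumes=np.ones(n), total_content=z.copy(),
                    cumulative_influx=z.copy(), global_fluxes={})


class TestLineScan:
    def test_uniform_field_constant_columns(self, cyl_mesh):
        sol = _synthetic_solution(cyl_mesh, lambda v: np.full(len(v), 0.25))
        img = extract_linescan(sol)
        assert np.allclose(img.values, 0.25)

    def test_linear_field_reproduced_exactly(self, cyl_mesh):
        """P1 interpolation is exact for a field linear in depth."""
        a, b = 0.1, 0.03
        sol = _synthetic_solution(cyl_mesh, lambda v: a + b * v[:, 2])
        img = extract_linescan(sol)
        assert np.allclose(img.values[0], a + b * img.positions, atol=1e-12)

    def test_line_entering_lumen_rejected(self, cyl_mesh):
        sol = _synthetic_solution(cyl_mesh, lambda v: np.full(len(v), 0.1))
        # negative-offset trick is blocked by the spec validator, so aim the
        # line straight at the axis via a spec with tiny radius bounds
        bad = LineScanSpec(offset=1.2)  # exits the box laterally
        with pytest.raises(ValueError):
            extract_linescan(sol, bad)

    def test_dye_complex_exportable(self, scenario_solutions, linescan_spec):
        sol = scenario_solutions["fig4_heterogeneous"]
        img = extract_linescan(sol, linescan_spec, field_name="CaFluo-3")
        assert float(img.values.max()) > 11.9  # above the resting CaFluo level

    def test_higher_near_mouth_at_peak(self, scenario_linescans,
                                       scenario_solutions):
        """Heterogeneous scenario with dye: at the Ca peak the near-mouth end
        of the line is hotter than the deep end."""
        img = scenario_linescans["fig4_heterogeneous"]
        sol = scenario_solutions["fig4_heterogeneous"]
        avg = sol.volume_average("Ca")
        tpk = float(sol.time[int(np.argmax(avg))])
        row = img.values[int(np.argmin(np.abs(img.times - tpk)))]
        near = row[img.positions < 1.0].mean()
        deep = row[img.positions > 4.5].mean()
        assert near > deep


class TestSCH:
    def test_arithmetic_example(self):
        img = LineScanImage(positions=np.array([0.0, 1.0, 2.0]),
                            times=np.array([0.0]),
                            values=np.array([[0.2, 0.16, 0.1]]))
        assert compute_sch(img, [0.0, 1.0, 2.0], 0.0) == pytest.approx(0.5)

    def test_uniform_is_zero(self):
        img = LineScanImage(positions=np.linspace(0, 5, 6),
                            times=np.array([0.0]),
                            values=np.full((1, 6), 0.3))
        assert compute_sch(img, [0.5, 2.5, 4.5], 0.0) == 0.0

    def test_zero_max_rejected(self):
        img = LineScanImage(positions=np.array([0.0, 1.0]),
                            times=np.array([0.0]), values=np.zeros((1, 2)))
        with pytest.raises(ValueError):
            compute_sch(img, [0.0, 1.0], 0.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, scale):
        """SCH is unchanged under uniform scaling of the field."""
        rng = np.random.default_rng(0)
        base = 0.1 + rng.random((3, 8))
        img1 = LineScanImage(positions=np.linspace(0, 7, 8),
                             times=np.array([0.0, 1.0, 2.0]), values=base)
        img2 = LineScanImage(positions=np.linspace(0, 7, 8),
                             times=np.array([0.0, 1.0, 2.0]), values=scale * base)
        spots = [0.5, 3.0, 6.5]
        assert compute_sch(img1, spots, 1.0) == pytest.approx(
            compute_sch(img2, spots, 1.0), rel=1e-9)

    def test_report_epochs(self):
        img = LineScanImage(positions=np.linspace(0, 5, 11),
                            times=np.linspace(0, 100, 21),
                            values=0.1 + np.outer(np.linspace(0, 1, 21),
                                                  np.linspace(0, 0.1, 11)))
        rep = sch_report(img, [0.5, 2.5, 4.5], {"a": 50.0, "b": 100.0})
        assert set(rep.sch) == {"a", "b"}
        assert 0.0 <= rep.sch["a"] <= rep.sch["b"] <= 1.0


class TestTransientMetrics:
    def test_constant_trace(self):
        m = transient_metrics((np.array([0.0, 1.0, 2.0]), np.array([0.1, 0.1, 0.1])))
        assert m.peak == 0.1 and m.t_peak == 0.0
        assert m.value_at(1.5) == pytest.approx(0.1)

    def test_sine_bump_exact_recovery(self):
        t = np.linspace(0.0, 100.0, 401)  # grid contains the maximum at t=50
        v = 0.1 + 0.05 * np.sin(np.pi * t / 100.0)
        m = transient_metrics((t, v))
        assert m.t_peak == pytest.approx(50.0)
        assert m.peak == pytest.approx(0.15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            transient_metrics((np.array([]), np.array([])))


class TestFrontDetection:
    def _image(self, onset_fn, amplitude=1.0, t_end=100.0, nt=201, npos=60):
        times = np.linspace(0.0, t_end, nt)
        pos = np.linspace(0.0, 5.9, npos)
        vals = np.full((nt, npos), 0.1)
        for j, x in enumerate(pos):
            t_on = onset_fn(x)
            if t_on is not None:
                vals[times >= t_on, j] = amplitude
        return LineScanImage(positions=pos, times=times, values=vals)

    def test_simultaneous_rise_is_not_a_front(self):
        img = self._image(lambda x: 20.0)
        assert not detect_front(img, threshold=0.5).initiated

    def test_traveling_ramp_speed_recovered(self):
        """A front moving at 0.05 µm/ms is detected within 5 %."""
        v = 0.05
        img = self._image(lambda x: x / v, t_end=150.0, nt=301)
        fr = detect_front(img, threshold=0.5)
        assert fr.initiated and not fr.faltered
        assert fr.speed == pytest.approx(v, rel=0.05)

    def test_stalled_front_falters(self):
        v = 0.05
        img = self._image(lambda x: x / v if x < 2.0 else None)
        fr = detect_front(img, threshold=0.5)
        assert fr.initiated and fr.faltered
        assert fr.span[1] < 2.5

    def test_threshold_never_crossed(self):
        img = self._image(lambda x: None)
        fr = detect_front(img, threshold=0.5)
        assert not fr.initiated and np.all(np.isnan(fr.onset_times))

    def test_threshold_must_exceed_baseline(self):
        img = self._image(lambda x: 20.0)
        with pytest.raises(ValueError):
            detect_front(img, threshold=0.05)
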