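"""Scenario presets and end-to-end pipeline orchestration.

Each preset bundles the deltas that define one of the study conditions:
flux-distribution scenario, dye load, buffer mobility and extracellular
Na⁺.  ``run_scenario`` executes the full pipeline — mesh generation,
resting-leak and LCC-amplitude calibration, 0-D and 3-D runs, line-scan and
SCH exports — and writes a manifest with every resolved parameter so a run
is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time as _time
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .analysis import (
    LineScanSpec,
    extract_linescan,
    sch_report,
    standard_epochs,
    transient_metrics,
)
from .chemistry import default_buffer_set
from .geometry import TTubuleSpec, compute_geometry_stats, generate_ttubule_mesh
from .io import write_msh, write_vtk
from .membrane import (
    CellParams,
    FluxScenario,
    IonConditions,
    LCCParams,
    calibrate_lcc_amplitude,
    calibrate_rest_leak,
    lcc_template_peak_time,
)
from .solver import SimulationConfig, check_conservation, run_0d, run_3d

MEASURED_PEAK_UM = 0.163  # µM, published whole-cell peak with 100 µM Fluo-3


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    description: str
    fluo3: float = 100.0                    # µM dye load
    lcc_mode: str = "heterogeneous_polynomial"
    ncx_ttubule_ratio: float = 3.0
    Na_e: float = 140.0                     # mM
    immobilize: tuple[str, ...] = ()

    def simulation_config(self, dt: float = 0.1, duration: float = 400.0,
                          output_stride: int = 20) -> SimulationConfig:
        return SimulationConfig(
            buffers=default_buffer_set(fluo3=self.fluo3),
            scenario=FluxScenario(lcc_mode=self.lcc_mode,
                                  ncx_ttubule_ratio=self.ncx_ttubule_ratio),
            ions=IonConditions(Na_e=self.Na_e),
            dt=dt, duration=duration, output_stride=output_stride,
            immobilize=self.immobilize,
        )


PRESETS: dict[str, ScenarioPreset] = {
    "fig4_heterogeneous": ScenarioPreset(
        "fig4_heterogeneous",
        "100 µM Fluo-3; LCC density follows the depth polynomial; NCX 3:1 t-tubule"),
    "fig4_uniform6x": ScenarioPreset(
        "fig4_uniform6x",
        "100 µM Fluo-3; LCC uniform and 6x higher in the t-tubule; NCX 3:1",
        lcc_mode="uniform_6x_ttubule"),
    "fig4_homogeneous": ScenarioPreset(
        "fig4_homogeneous",
        "100 µM Fluo-3; LCC, NCX and leak homogeneous over the sarcolemma",
        lcc_mode="homogeneous", ncx_ttubule_ratio=1.0),
    "fig6_nodye": ScenarioPreset(
        "fig6_nodye",
        "no dye; heterogeneous fluxes (same global LCC waveform as with dye)",
        fluo3=0.0),
    "fig7_immobile": ScenarioPreset(
        "fig7_immobile",
        "no dye; CaATP and Ca-calmodulin complexes immobilized",
        fluo3=0.0, immobilize=("ATP", "calmodulin")),
    "fig8_zeroNa": ScenarioPreset(
        "fig8_zeroNa",
        "no dye; extracellular Na⁺ removed (NCX forward mode inhibited)",
        fluo3=0.0, Na_e=0.0),
}


def available_presets() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {available_presets()}") from None


def calibrated_lcc_amplitude(dt: float = 0.1, duration: float = 400.0,
                             cell: CellParams = CellParams()) -> float:
    """Amplitude calibrated once, under the dye-present condition, to the
    published measured peak; reused unchanged by the dye-free scenarios."""
    cfg = PRESETS["fig4_heterogeneous"].simulation_config(dt=dt, duration=duration)
    return calibrate_lcc_amplitude(MEASURED_PEAK_UM, cfg, cell=cell)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def run_scenario(preset: ScenarioPreset | str, out_dir: str, *,
                 mesh_spec: Optional[TTubuleSpec] = None,
                 edge_length: float = 0.095,
                 dt: float = 0.5, duration: float = 400.0,
                 output_stride: int = 4,
                 linescan: LineScanSpec = LineScanSpec(),
                 lcc_amplitude: Optional[float] = None,
                 cell: CellParams = CellParams(),
                 write_mesh_files: bool = True) -> dict:
    """Execute one preset end to end and write its artifact bundle.

    Returns a result dict with the mesh stats, global transients, SCH report
    and conservation audit; files (manifest, transients, line-scan matrix,
    mesh, final field snapshot) land in ``out_dir``.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    os.makedirs(out_dir, exist_ok=True)
    t0 = _time.time()

    spec = mesh_spec or TTubuleSpec()
    mesh = generate_ttubule_mesh(spec, edge_length)
    stats = compute_geometry_stats(mesh)

    if lcc_amplitude is None:
        lcc_amplitude = calibrated_lcc_amplitude(cell=cell)
    config = preset.simulation_config(dt=dt, duration=duration,
                                      output_stride=output_stride)
    config = replace(config, lcc=replace(config.lcc, amplitude=lcc_amplitude))
    leak = config.resolved_leak()
    config = replace(config, leak=leak)

    trace0d = run_0d(config, cell)
    solution = run_3d(mesh, config, cell)
    conservation = check_conservation(solution)

    image = extract_linescan(solution, linescan)
    avg = solution.volume_average("Ca")
    epochs = standard_epochs((solution.time, avg),
                             lcc_template_peak_time(config.lcc))
    epochs = {k: v for k, v in epochs.items() if v <= duration}
    report = sch_report(image, linescan.spots, epochs)
    metrics = transient_metrics((solution.time, avg))

    # ---- exports -----------------------------------------------------------
    np.savetxt(os.path.join(out_dir, "global_transient_0d.csv"),
               np.column_stack([trace0d.time, trace0d.Ca, trace0d.J_LCC,
                                trace0d.J_NCX, trace0d.J_leak]),
               delimiter=",", header="time_ms,Ca_uM,J_LCC,J_NCX,J_leak", comments="")
    np.savetxt(os.path.join(out_dir, "global_transient_3d.csv"),
               np.column_stack([solution.time, avg]),
               delimiter=",", header="time_ms,Ca_uM", comments="")
    ls_table = np.column_stack([image.times, image.values])
    np.savetxt(os.path.join(out_dir, "linescan.csv"), ls_table, delimiter=",",
               header="time_ms," + ",".join(f"{p:.4f}" for p in image.positions),
               comments="")
    solution.to_hdf5(os.path.join(out_dir, "solution.h5"))
    try:  # heatmap rendering is optional; the CSV matrix is authoritative
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3.2))
        im = ax.imshow(image.values.T, aspect="auto", origin="lower",
                       extent=[image.times[0], image.times[-1],
                               image.positions[0], image.positions[-1]],
                       cmap="inferno")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("depth along scan line (µm)")
        fig.colorbar(im, label="[Ca²⁺]ᵢ (µM)")
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, "linescan.png"), dpi=120)
        plt.close(fig)
    except ImportError:
        pass
    if write_mesh_files:
        write_msh(mesh, os.path.join(out_dir, "mesh.msh"))
        write_vtk(mesh, os.path.join(out_dir, "final_state.vtk"),
                  point_data={"Ca": solution.fields["Ca"][-1]})

    from . import __version__ as _version

    manifest = {
        "software": {"package": "ttcasim", "version": _version},
        "preset": _to_jsonable(preset),
        "mesh_spec": _to_jsonable(spec),
        "edge_length_um": edge_length,
        "geometry_stats": _to_jsonable(stats),
        "config": _to_jsonable(config),
        "lcc_amplitude_pA_per_pF": lcc_amplitude,
        "g_leak_uM_per_mV_ms": leak.g_leak,
        "linescan": _to_jsonable(linescan),
        "results": {
            "global_peak_uM": metrics.peak,
            "time_to_peak_ms": metrics.t_peak,
            "plateau_uM": float(avg[-1]),
            "sch": report.sch,
            "epochs": report.epochs,
            "conservation_max_rel_error": conservation.max_relative_error,
        },
        "wall_time_s": _time.time() - t0,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {"mesh": mesh, "stats": stats, "config": config, "trace0d": trace0d,
            "solution": solution, "linescan": image, "sch": report,
            "metrics": metrics, "conservation": conservation,
            "manifest": manifest}
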