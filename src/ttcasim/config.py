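"""Structured YAML configuration with preset inheritance.

A config file selects a preset by name and overrides any subset of the
blocks ``mesh``, ``scenario``, ``ions``, ``protocol``, ``buffers`` (dye
load, mobility overrides) and ``numerics``.  Example::

    preset: fig4_heterogeneous
    mesh:
      seed: 7
      n_branches: 4
    buffers:
      fluo3: 50.0
    numerics:
      dt: 0.5
      edge_length: 0.12
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any

import yaml

from .chemistry import default_buffer_set
from .geometry import TTubuleSpec
from .membrane import FluxScenario, IonConditions, VoltageProtocol
from .presets import ScenarioPreset, get_preset
from .solver import SimulationConfig


def load_config(path: str) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return data


def mesh_spec_from_config(data: dict[str, Any]) -> TTubuleSpec:
    block = data.get("mesh", {}) or {}
    block = {k: tuple(v) if k == "mouth_center" else v for k, v in block.items()}
    return replace(TTubuleSpec(), **block)


def preset_from_config(data: dict[str, Any]) -> ScenarioPreset:
    preset = get_preset(data.get("preset", "fig4_heterogeneous"))
    overrides = {}
    buffers = data.get("buffers", {}) or {}
    if "fluo3" in buffers:
        overrides["fluo3"] = float(buffers["fluo3"])
    if "immobilize" in buffers:
        overrides["immobilize"] = tuple(buffers["immobilize"])
    scen = data.get("scenario", {}) or {}
    if "lcc_mode" in scen:
        overrides["lcc_mode"] = scen["lcc_mode"]
    if "ncx_ttubule_ratio" in scen:
        overrides["ncx_ttubule_ratio"] = float(scen["ncx_ttubule_ratio"])
    ions = data.get("ions", {}) or {}
    if "Na_e" in ions:
        overrides["Na_e"] = float(ions["Na_e"])
    return replace(preset, **overrides)


def simulation_config_from_config(data: dict[str, Any]) -> SimulationConfig:
    preset = preset_from_config(data)
    num = data.get("numerics", {}) or {}
    cfg = preset.simulation_config(
        dt=float(num.get("dt", 0.1)),
        duration=float(num.get("duration", 400.0)),
        output_stride=int(num.get("output_stride", 20)),
    )
    prot = data.get("protocol", {}) or {}
    if prot:
        cfg = replace(cfg, protocol=replace(VoltageProtocol(), **prot))
    return cfg


def numerics_from_config(data: dict[str, Any]) -> dict[str, float]:
    num = data.get("numerics", {}) or {}
    return {
        "edge_length": float(num.get("edge_length", 0.095)),
        "dt": float(num.get("dt", 0.5)),
        "duration": float(num.get("duration", 400.0)),
        "output_stride": int(num.get("output_stride", 4)),
    }
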