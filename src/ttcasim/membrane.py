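"""Sarcolemmal Ca²⁺ flux models and their spatial distribution.

Three pathways cross the membrane: the L-type Ca²⁺ current (LCC, a
voltage-clamp-driven whole-cell waveform), the Na⁺/Ca²⁺ exchanger (NCX,
electrogenic 3Na:1Ca antiport in the Hinch formulation), and a
phenomenological background leak whose conductance is calibrated so the
resting state carries no net membrane flux.  Whole-cell current densities
(pA/pF) are converted to volume-averaged fluxes (µM/ms) through the
experimentally suggested surface-to-volume ratio, then distributed over
the external and t-tubular membrane facets according to a flux scenario.

Sign conventions: membrane currents are negative inward (electrophysiology
convention); converted fluxes are positive into the cytosol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import EXTERNAL_MEMBRANE, TTUBULE_MEMBRANE, LabeledMesh


@dataclass(frozen=True)
class PhysicalConstants:
    F: float = 96.5      # C mmol^-1
    R: float = 8.314     # J mol^-1 K^-1
    T: float = 295.0     # K

    @property
    def RT_over_F(self) -> float:
        """Thermal voltage RT/F in mV."""
        return self.R * self.T / self.F  # (J/mol)/(C/mmol) = mV


@dataclass(frozen=True)
class CellParams:
    V_cell: float = 36.8              # pL
    C_m: float = 324.0                # pF
    surface_to_volume: float = 8.8    # pF pL^-1
    accessible_fraction: float = 0.37  # aqueous fraction reachable by Ca²⁺

    def __post_init__(self):
        if min(self.V_cell, self.C_m, self.surface_to_volume) <= 0:
            raise ValueError("cell parameters must be positive")
        if not (0.3 <= self.accessible_fraction <= 0.45):
            raise ValueError("accessible fraction outside the plausible range")

    @property
    def accessible_volume_pL(self) -> float:
        return self.V_cell * self.accessible_fraction


@dataclass(frozen=True)
class IonConditions:
    Ca_e: float = 1000.0   # µM
    Ca_rest: float = 0.1   # µM
    Na_i: float = 10.0     # mM, held constant
    Na_e: float = 140.0    # mM; 0 inhibits NCX forward mode

    def __post_init__(self):
        if self.Ca_e <= 0 or self.Na_i <= 0 or self.Na_e < 0 or self.Ca_rest <= 0:
            raise ValueError("invalid ionic conditions")


@dataclass(frozen=True)
class NCXParams:
    V_max: float = 38.5    # µM ms^-1
    eta: float = 0.35      # voltage partition
    K_Na: float = 87.5     # mM
    K_Ca: float = 1380.0   # µM
    k_sat: float = 0.1

    def __post_init__(self):
        if not 0 < self.eta < 1:
            raise ValueError("eta must lie in (0, 1)")
        if min(self.V_max, self.K_Na, self.K_Ca, self.k_sat) <= 0:
            raise ValueError("NCX constants must be positive")


@dataclass(frozen=True)
class LCCParams:
    """Whole-cell LCC waveform template.

    ``amplitude`` (pA/pF) scales the double-exponential template and is a
    calibrated free parameter (see :func:`calibrate_lcc_amplitude`); the
    activation/inactivation time constants are published values and
    ``tau_deact`` models fast channel closing at repolarization.
    """

    A_scale: float = 1.0
    tau_act: float = 4.0     # ms
    tau_inact: float = 70.0  # ms
    tau_deact: float = 1.0   # ms
    amplitude: float = 0.0   # pA/pF, >= 0; set by calibration

    def __post_init__(self):
        if min(self.tau_act, self.tau_inact, self.tau_deact) <= 0:
            raise ValueError("LCC time constants must be positive")


@dataclass(frozen=True)
class LeakParams:
    """Leak conductance g_leak (µM mV⁻¹ ms⁻¹).

    The published reference values are 3.4e-6 at Na_e = 140 mM and -6.8e-6 at
    Na_e = 0; at run time the conductance always comes from
    :func:`calibrate_rest_leak` so the resting balance is exact under this
    module's NCX algebra.
    """

    g_leak: float = 3.4e-6


@dataclass(frozen=True)
class SpatialWeightParams:
    """Cubic polynomial LCC density profile along the tubule depth,
    w(x) = C·(p1·x³ + p2·x² + p3·x + p4), x = depth from the external surface."""

    C: float = 0.4515
    p1: float = -4.1379e-4
    p2: float = -1.1722e-2
    p3: float = 1.978e-1
    p4: float = 1.0033
    x_max: float = 5.645  # µm, domain of validity (tubule depth)


@dataclass(frozen=True)
class VoltageProtocol:
    V_hold: float = -50.0        # mV
    V_pulse: float = 10.0        # mV
    pulse_duration: float = 70.0  # ms
    total_duration: float = 400.0  # ms

    def __post_init__(self):
        if not 0 < self.pulse_duration < self.total_duration:
            raise ValueError("need 0 < pulse_duration < total_duration")

    def voltage(self, t):
        """Membrane potential at time t (ms); the pulse starts at t = 0."""
        t = np.asarray(t, dtype=float)
        v = np.where((t >= 0) & (t < self.pulse_duration), self.V_pulse, self.V_hold)
        return float(v) if v.ndim == 0 else v


LCC_MODES = ("heterogeneous_polynomial", "uniform_6x_ttubule", "homogeneous")


@dataclass(frozen=True)
class FluxScenario:
    """Distribution of LCC/NCX/leak density over the two membrane labels."""

    lcc_mode: str = "heterogeneous_polynomial"
    ncx_ttubule_ratio: float = 3.0
    leak_mode: str = "homogeneous"

    def __post_init__(self):
        if self.lcc_mode not in LCC_MODES:
            raise ValueError(f"unknown lcc_mode {self.lcc_mode!r}")
        if self.ncx_ttubule_ratio not in (1.0, 3.0):
            raise ValueError("ncx_ttubule_ratio must be 3 (t-tubule enriched) or 1")
        if self.leak_mode != "homogeneous":
            raise ValueError("leak is homogeneous in this model")


# ---------------------------------------------------------------------------
# pathway models
# ---------------------------------------------------------------------------


def lcc_current_density(t, protocol: VoltageProtocol, params: LCCParams):
    """Whole-cell LCC current density (pA/pF) at time ``t`` (ms).

    During the pulse the template -A·(1-e^(-t/τ_act))·e^(-t/τ_inact) rises
    with activation and decays with inactivation; at repolarization the
    current deactivates with ``tau_deact``.  Negative values are inward.
    """
    t = np.asarray(t, dtype=float)
    A = params.A_scale * params.amplitude
    tp = protocol.pulse_duration
    template = -(A) * (1.0 - np.exp(-t / params.tau_act)) * np.exp(-t / params.tau_inact)
    i_end = -(A) * (1.0 - np.exp(-tp / params.tau_act)) * np.exp(-tp / params.tau_inact)
    tail = i_end * np.exp(-(t - tp) / params.tau_deact)
    out = np.where(t < 0, 0.0, np.where(t < tp, template, tail))
    return float(out) if out.ndim == 0 else out


def lcc_template_peak_time(params: LCCParams) -> float:
    """Time of the template extremum, τ_act·ln(1 + τ_inact/τ_act) (ms)."""
    return params.tau_act * np.log(1.0 + params.tau_inact / params.tau_act)


def lcc_spatial_weight(x, params: SpatialWeightParams = SpatialWeightParams()):
    """Relative LCC density at depth ``x`` µm below the external surface."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > params.x_max * (1 + 1e-9)):
        raise ValueError(f"depth outside [0, {params.x_max}] µm")
    w = params.C * (params.p1 * x**3 + params.p2 * x**2 + params.p3 * x + params.p4)
    return float(w) if w.ndim == 0 else w


def ncx_flux(V, Ca_i, ions: IonConditions = IonConditions(),
             params: NCXParams = NCXParams(),
             k: PhysicalConstants = PhysicalConstants()):
    """Na⁺/Ca²⁺ exchanger Ca²⁺ flux (µM/ms); positive = Ca²⁺ entry.

    Hinch electrochemical formulation; Na in mM, Ca in µM, V in mV.
    """
    Ca_i = np.asarray(Ca_i, dtype=float)
    if np.any(Ca_i <= 0):
        raise ValueError("Ca_i must be positive")
    vf = np.asarray(V, dtype=float) / k.RT_over_F
    e1 = np.exp(params.eta * vf)
    e2 = np.exp((params.eta - 1.0) * vf)
    num = e1 * ions.Na_i**3 * ions.Ca_e - e2 * ions.Na_e**3 * Ca_i
    den = ((params.K_Na**3 + ions.Na_e**3) * (params.K_Ca + ions.Ca_e)
           * (1.0 + params.k_sat * e2))
    out = params.V_max * num / den
    return float(out) if out.ndim == 0 else out


def ncx_flux_dCa(V, ions: IonConditions = IonConditions(),
                 params: NCXParams = NCXParams(),
                 k: PhysicalConstants = PhysicalConstants()):
    """d(J_NCX)/d(Ca_i); the flux is linear in Ca_i at fixed V."""
    vf = np.asarray(V, dtype=float) / k.RT_over_F
    e2 = np.exp((params.eta - 1.0) * vf)
    den = ((params.K_Na**3 + ions.Na_e**3) * (params.K_Ca + ions.Ca_e)
           * (1.0 + params.k_sat * e2))
    return -params.V_max * e2 * ions.Na_e**3 / den


def nernst_ECa(Ca_i, Ca_e, k: PhysicalConstants = PhysicalConstants()):
    """Ca²⁺ Nernst potential (RT/2F)·ln(Ca_e/Ca_i) in mV."""
    return 0.5 * k.RT_over_F * np.log(Ca_e / np.asarray(Ca_i, dtype=float))


def leak_flux(V, Ca_i, ions: IonConditions = IonConditions(),
              params: LeakParams = LeakParams(),
              k: PhysicalConstants = PhysicalConstants()):
    """Background leak J = g_leak·(E_Ca − V) (µM/ms); positive = entry for g>0."""
    Ca_i = np.asarray(Ca_i, dtype=float)
    if np.any(Ca_i <= 0):
        raise ValueError("E_Ca undefined for Ca_i <= 0")
    out = params.g_leak * (nernst_ECa(Ca_i, ions.Ca_e, k) - np.asarray(V, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def calibrate_rest_leak(ions: IonConditions = IonConditions(),
                        ncx: NCXParams = NCXParams(),
                        protocol: VoltageProtocol = VoltageProtocol(),
                        k: PhysicalConstants = PhysicalConstants()) -> LeakParams:
    """Leak conductance that exactly cancels NCX at rest.

    g_leak = −J_NCX(rest) / (E_Ca − V_hold).  With physiological Na_e the
    exchanger extrudes Ca²⁺ at rest, so g_leak > 0 (inward leak); with
    Na_e = 0 the exchanger can only import Ca²⁺ and the calibrated leak
    conductance flips sign, matching the two published reference values.
    """
    driving = float(nernst_ECa(ions.Ca_rest, ions.Ca_e, k)) - protocol.V_hold
    if abs(driving) < 1e-12:
        raise ValueError("zero leak driving force at rest")
    j_ncx = ncx_flux(protocol.V_hold, ions.Ca_rest, ions, ncx, k)
    return LeakParams(g_leak=-j_ncx / driving)


def current_density_to_flux(I, cell: CellParams = CellParams(),
                            k: PhysicalConstants = PhysicalConstants()):
    """Convert current density (pA/pF) to cytosolic flux (µM/ms).

    J = −I·(surface-to-volume)/(2F); the charge 2 is the Ca²⁺ valence.
    Inward (negative) current gives positive flux.  With 8.8 pF/pL and
    F = 96.5 C/mmol, −1 pA/pF maps to +0.0456 µM/ms.
    """
    out = -np.asarray(I, dtype=float) * cell.surface_to_volume / (2.0 * k.F)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# spatial distribution over the labeled membrane
# ---------------------------------------------------------------------------


@dataclass
class MembraneFacets:
    """Precomputed geometry of membrane-labeled boundary facets."""

    facets: np.ndarray      # (nf, 3) vertex ids
    areas: np.ndarray       # (nf,)
    depth: np.ndarray       # (nf,) centroid depth below the external surface
    is_ttubule: np.ndarray  # (nf,) bool
    total_area: float
    mesh_volume: float


def membrane_facets(mesh: LabeledMesh) -> MembraneFacets:
    sel = (mesh.facet_labels == EXTERNAL_MEMBRANE) | (mesh.facet_labels == TTUBULE_MEMBRANE)
    facets = mesh.boundary_facets[sel]
    labels = mesh.facet_labels[sel]
    tri = mesh.vertices[facets]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    depth = tri[:, :, 2].mean(axis=1)
    volume = float(np.sum(mesh.tet_volumes()))
    return MembraneFacets(facets=facets, areas=areas, depth=depth,
                          is_ttubule=labels == TTUBULE_MEMBRANE,
                          total_area=float(areas.sum()), mesh_volume=volume)


def _normalized_weights(raw: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """Scale facet weights so the area-weighted mean is 1: redistribution
    never changes the whole-compartment total of a flux."""
    total = float(np.sum(raw * areas))
    if total <= 0:
        raise ValueError("flux weights must have positive area integral")
    return raw * (areas.sum() / total)


def scenario_weights(mf: MembraneFacets, scenario: FluxScenario,
                     poly: SpatialWeightParams = SpatialWeightParams()):
    """Per-facet (lcc, ncx, leak) weights, each area-normalized to mean 1."""
    if scenario.lcc_mode == "heterogeneous_polynomial":
        # The depth polynomial grades the LCC density *within* the t-tubule;
        # the tubule keeps the same total flux as the uniform-6x case (the
        # published scaling constant C served exactly that purpose), so the
        # external membrane carries weight 1 and the tubule profile is
        # rescaled to an area-weighted tubule mean of 6.
        x = np.clip(mf.depth, 0.0, poly.x_max)
        p = lcc_spatial_weight(x, poly)
        tt = mf.is_ttubule
        p_mean = float(np.sum(p[tt] * mf.areas[tt]) / np.sum(mf.areas[tt]))
        w_lcc = np.where(tt, 6.0 * p / p_mean, 1.0)
    elif scenario.lcc_mode == "uniform_6x_ttubule":
        w_lcc = np.where(mf.is_ttubule, 6.0, 1.0)
    else:
        w_lcc = np.ones(len(mf.areas))
    w_ncx = np.where(mf.is_ttubule, scenario.ncx_ttubule_ratio, 1.0)
    w_leak = np.ones(len(mf.areas))
    return (_normalized_weights(np.asarray(w_lcc, dtype=float), mf.areas),
            _normalized_weights(w_ncx, mf.areas),
            _normalized_weights(w_leak, mf.areas))


def build_boundary_flux(mesh: LabeledMesh, scenario: FluxScenario, t: float,
                        V: float, local_Ca: np.ndarray, *,
                        protocol: VoltageProtocol = VoltageProtocol(),
                        lcc: LCCParams = LCCParams(),
                        ncx: NCXParams = NCXParams(),
                        leak: Optional[LeakParams] = None,
                        ions: IonConditions = IonConditions(),
                        cell: CellParams = CellParams(),
                        constants: PhysicalConstants = PhysicalConstants(),
                        poly: SpatialWeightParams = SpatialWeightParams(),
                        mf: Optional[MembraneFacets] = None) -> dict[str, np.ndarray]:
    """Per-facet membrane Ca²⁺ flux densities (µM·µm³ per µm² per ms).

    ``local_Ca`` gives the facet-level cytosolic Ca²⁺ (µM) used by the NCX
    and leak models.  The area integral of each component equals the global
    model's whole-compartment flux when ``local_Ca`` is uniform.
    """
    if mf is None:
        mf = membrane_facets(mesh)
    if leak is None:
        leak = calibrate_rest_leak(ions, ncx, protocol, constants)
    local_Ca = np.broadcast_to(np.asarray(local_Ca, dtype=float), mf.areas.shape)
    if local_Ca.shape != mf.areas.shape:
        raise ValueError("local_Ca must match the number of membrane facets")
    w_lcc, w_ncx, w_leak = scenario_weights(mf, scenario, poly)
    vol_per_area = mf.mesh_volume / mf.total_area
    j_lcc = current_density_to_flux(lcc_current_density(t, protocol, lcc), cell, constants)
    dens_lcc = vol_per_area * w_lcc * j_lcc
    dens_ncx = vol_per_area * w_ncx * ncx_flux(V, local_Ca, ions, ncx, constants)
    dens_leak = vol_per_area * w_leak * leak_flux(V, local_Ca, ions, leak, constants)
    return {"lcc": dens_lcc, "ncx": dens_ncx, "leak": dens_leak,
            "total": dens_lcc + dens_ncx + dens_leak}


def calibrate_lcc_amplitude(target_peak: float, config, *,
                            cell: CellParams = CellParams(),
                            tol: float = 1e-3, bracket=(0.0, 40.0),
                            max_iter: int = 60) -> float:
    """LCC template amplitude (pA/pF) whose 0-D global Ca²⁺ peak equals
    ``target_peak`` µM, by monotone bisection.

    ``config`` is a :class:`~ttcasim.solver.SimulationConfig`; the dye load
    it carries is part of the calibration condition (the published measured
    peak, ~0.163 µM, was recorded with 100 µM Fluo-3).
    """
    from .solver import run_0d  # local import to avoid a cycle
    from dataclasses import replace as _replace

    rest = config.ions.Ca_rest
    if target_peak <= rest + tol:
        return 0.0

    def peak(amp: float) -> float:
        cfg = _replace(config, lcc=_replace(config.lcc, amplitude=amp))
        tr = run_0d(cfg, cell)
        return float(np.max(tr.Ca))

    lo, hi = bracket
    p_hi = peak(hi)
    grow = 0
    while p_hi < target_peak and grow < 6:
        hi *= 2.0
        p_hi = peak(hi)
        grow += 1
    if p_hi < target_peak:
        raise RuntimeError(f"target peak {target_peak} µM unreachable below {hi} pA/pF")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if peak(mid) < target_peak:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    amp = 0.5 * (lo + hi)
    if abs(peak(amp) - target_peak) > tol:
        raise RuntimeError("bisection failed to reach the target peak")
    return amp
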