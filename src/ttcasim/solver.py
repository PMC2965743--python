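"""Time integration of the coupled reaction-diffusion system.

Space is discretized with linear (P1) finite elements on the labeled
tetrahedral mesh; time with backward Euler and Strang splitting: an
implicit nodal reaction half-step, an implicit diffusion step per mobile
species (prefactorized sparse solves), and a second reaction half-step.
Membrane Ca²⁺ influx enters the free-Ca equation as a Neumann flux on the
membrane-labeled facets.  The nodal reaction solve reduces to a safeguarded
scalar Newton iteration in free Ca²⁺, because each backward-Euler buffer
update is an explicit rational function of the new free Ca²⁺.

A well-mixed 0-D reduction of the same chemistry and membrane models
(``run_0d``) serves for calibration and cross-validation: with spatially
homogeneous flux distribution the volume-averaged 3-D solution must agree
with it.

Units follow the rest of the package: µM, ms, µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .chemistry import BufferSet, default_buffer_set, equilibrium_state
from .geometry import LabeledMesh, distance_to_membrane_field
from .membrane import (
    CellParams,
    FluxScenario,
    IonConditions,
    LCCParams,
    LeakParams,
    NCXParams,
    PhysicalConstants,
    SpatialWeightParams,
    VoltageProtocol,
    calibrate_rest_leak,
    current_density_to_flux,
    lcc_current_density,
    leak_flux,
    membrane_facets,
    ncx_flux,
    ncx_flux_dCa,
    nernst_ECa,
    scenario_weights,
)


@dataclass(frozen=True)
class SimulationConfig:
    buffers: BufferSet = field(default_factory=default_buffer_set)
    scenario: FluxScenario = field(default_factory=FluxScenario)
    protocol: VoltageProtocol = field(default_factory=VoltageProtocol)
    ions: IonConditions = field(default_factory=IonConditions)
    lcc: LCCParams = field(default_factory=LCCParams)
    ncx: NCXParams = field(default_factory=NCXParams)
    leak: Optional[LeakParams] = None  # None -> calibrated at initialization
    poly: SpatialWeightParams = field(default_factory=SpatialWeightParams)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    dt: float = 0.1                 # ms
    duration: float = 400.0         # ms
    output_stride: int = 20         # store every N-th step
    immobilize: tuple[str, ...] = ()  # buffer names forced stationary
    no_membrane_flux: bool = False  # sealed membrane (steady-state checks)

    def __post_init__(self):
        if self.dt <= 0 or self.duration <= 0 or self.output_stride < 1:
            raise ValueError("invalid time stepping settings")

    def resolved_buffers(self) -> BufferSet:
        if self.immobilize:
            return self.buffers.with_mobility_override(self.immobilize)
        return self.buffers

    def resolved_leak(self) -> LeakParams:
        if self.leak is not None:
            return self.leak
        return calibrate_rest_leak(self.ions, self.ncx, self.protocol, self.constants)


@dataclass
class GlobalTransient:
    """Volume-averaged trajectory of the well-mixed model."""

    time: np.ndarray      # ms
    Ca: np.ndarray        # µM
    CaB: dict[str, np.ndarray]
    J_LCC: np.ndarray     # µM/ms
    J_NCX: np.ndarray
    J_leak: np.ndarray


@dataclass
class Solution:
    """3-D trajectory: nodal fields at the output times plus bookkeeping."""

    time: np.ndarray                    # ms, output times
    fields: dict[str, np.ndarray]       # name -> (nt, n_nodes) µM
    mesh: LabeledMesh
    node_volumes: np.ndarray            # lumped P1 volumes (µm³)
    total_content: np.ndarray           # (nt,) volume-integrated total Ca (µM·µm³)
    cumulative_influx: np.ndarray       # (nt,) time-integrated membrane flux
    global_fluxes: dict[str, np.ndarray]  # per output time, µM/ms volume-avg
    config: SimulationConfig = None

    def volume_average(self, name: str = "Ca") -> np.ndarray:
        w = self.node_volumes / self.node_volumes.sum()
        return self.fields[name] @ w

    def to_hdf5(self, path: str) -> None:
        """Store the full trajectory (fields, times, bookkeeping) in HDF5."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.time)
            f.create_dataset("node_volumes", data=self.node_volumes)
            f.create_dataset("total_content", data=self.total_content)
            f.create_dataset("cumulative_influx", data=self.cumulative_influx)
            g = f.create_group("fields")
            for name, arr in self.fields.items():
                g.create_dataset(name, data=arr)
            g = f.create_group("global_fluxes")
            for name, arr in self.global_fluxes.items():
                g.create_dataset(name, data=arr)
            f.create_dataset("vertices", data=self.mesh.vertices)
            f.create_dataset("tetrahedra", data=self.mesh.tetrahedra)

    def save_vtk_series(self, directory: str, stride: int = 1) -> list[str]:
        """One legacy-VTK snapshot per stored time (all species as point data)."""
        import os

        from .io import write_vtk

        os.makedirs(directory, exist_ok=True)
        paths = []
        for i in range(0, len(self.time), stride):
            p = os.path.join(directory, f"state_{i:04d}.vtk")
            write_vtk(self.mesh, p,
                      point_data={k: v[i] for k, v in self.fields.items()})
            paths.append(p)
        return paths


# ---------------------------------------------------------------------------
# implicit nodal reaction step
# ---------------------------------------------------------------------------


def _reaction_step(Ca, CaB, Bt, kon, koff, dt, newton_tol=1e-12, max_iter=50):
    """Backward-Euler step of the pure buffering chemistry at every node.

    Given the old state, each new complex is a rational function of new free
    Ca: CaB' = (CaB + dt·k_on·B_T·Ca')/(1 + dt·(k_on·Ca' + k_off)), and mass
    balance gives one scalar, monotone equation per node, solved by Newton.
    Conserves total Ca at each node to the Newton tolerance.
    """
    Ca = np.asarray(Ca, dtype=float)
    nbuf = len(kon)
    x = Ca.copy()
    total_old = Ca + CaB.sum(axis=0)

    for _ in range(max_iter):
        num = CaB + dt * kon[:, None] * Bt * x[None, :]
        den = 1.0 + dt * (kon[:, None] * x[None, :] + koff[:, None])
        cab_new = num / den
        g = x - total_old + cab_new.sum(axis=0)
        dcab = (dt * kon[:, None] * Bt * den - num * dt * kon[:, None]) / den**2
        gp = 1.0 + dcab.sum(axis=0)
        dx = g / gp
        x = x - dx
        np.clip(x, 0.0, None, out=x)
        if np.max(np.abs(dx)) < newton_tol * max(1.0, float(np.max(np.abs(x)))):
            break
    num = CaB + dt * kon[:, None] * Bt * x[None, :]
    den = 1.0 + dt * (kon[:, None] * x[None, :] + koff[:, None])
    return x, num / den


# ---------------------------------------------------------------------------
# 0-D reduction
# ---------------------------------------------------------------------------


def run_0d(config: SimulationConfig, cell: CellParams = CellParams()) -> GlobalTransient:
    """Integrate the well-mixed model.

    dCa/dt = J_LCC + J_NCX + J_leak − ΣR_i,  dCaB_i/dt = R_i, starting from
    buffers equilibrated at the resting Ca²⁺.  Backward Euler; the membrane
    fluxes are treated implicitly in Ca (both NCX and leak have analytic
    Ca-derivatives), so the calibrated resting state is an exact fixed point.
    """
    buffers = config.resolved_buffers()
    leak = config.resolved_leak()
    ions, k = config.ions, config.constants
    names = buffers.names()
    kon = np.array([b.k_on for b in buffers])
    koff = np.array([b.k_off for b in buffers])
    Bt = np.array([b.B_total for b in buffers])

    nsteps = int(round(config.duration / config.dt))
    dt = config.dt
    time = np.linspace(0.0, nsteps * dt, nsteps + 1)

    eq = equilibrium_state(ions.Ca_rest, buffers)
    Ca = np.empty(nsteps + 1)
    CaB = np.empty((len(buffers), nsteps + 1))
    Ca[0] = ions.Ca_rest
    CaB[:, 0] = [eq.CaB[n] for n in names]
    jl = np.empty(nsteps + 1)
    jn = np.empty(nsteps + 1)
    jk = np.empty(nsteps + 1)

    def fluxes(t, ca):
        V = config.protocol.voltage(t)
        j_lcc = current_density_to_flux(
            lcc_current_density(t, config.protocol, config.lcc), cell, k)
        j_ncx = ncx_flux(V, ca, ions, config.ncx, k)
        j_leak = leak_flux(V, ca, ions, leak, k)
        return j_lcc, j_ncx, j_leak

    jl[0], jn[0], jk[0] = fluxes(0.0, Ca[0])

    for n in range(nsteps):
        t1 = time[n + 1]
        V = config.protocol.voltage(t1)
        j_lcc = current_density_to_flux(
            lcc_current_density(t1, config.protocol, config.lcc), cell, k)
        djn = ncx_flux_dCa(V, ions, config.ncx, k)
        x = Ca[n]
        cab0 = CaB[:, n]
        # scalar Newton: residual of the fully implicit step in free Ca
        for _ in range(60):
            num = cab0 + dt * kon * Bt * x
            den = 1.0 + dt * (kon * x + koff)
            cab_new = num / den
            j_ncx = ncx_flux(V, x, ions, config.ncx, k)
            j_leak = leak_flux(V, x, ions, leak, k)
            g = x - Ca[n] - dt * (j_lcc + j_ncx + j_leak) + (cab_new - cab0).sum()
            dcab = (dt * kon * Bt * den - num * dt * kon) / den**2
            djk = -leak.g_leak * 0.5 * k.RT_over_F / x
            gp = 1.0 - dt * (djn + djk) + dcab.sum()
            dx = g / gp
            x -= dx
            x = max(x, 1e-9)
            if abs(dx) < 1e-13 * max(1.0, x):
                break
        Ca[n + 1] = x
        num = cab0 + dt * kon * Bt * x
        den = 1.0 + dt * (kon * x + koff)
        CaB[:, n + 1] = num / den
        jl[n + 1], jn[n + 1], jk[n + 1] = fluxes(t1, x)

    return GlobalTransient(time=time, Ca=Ca,
                           CaB={nm: CaB[i] for i, nm in enumerate(names)},
                           J_LCC=jl, J_NCX=jn, J_leak=jk)


# ---------------------------------------------------------------------------
# P1 finite elements
# ---------------------------------------------------------------------------


def assemble_p1(mesh: LabeledMesh):
    """Unit-diffusivity stiffness matrix and lumped mass vector."""
    v = mesh.vertices
    t = mesh.tetrahedra
    n = mesh.n_vertices
    x = v[t]  # (m, 4, 3)
    # gradients of the barycentric shape functions
    e = x[:, 1:, :] - x[:, :1, :]          # (m, 3, 3) edge matrix
    vol6 = np.linalg.det(e)                # 6 * volume
    vol = vol6 / 6.0
    if np.any(vol <= 0):
        raise ValueError("mesh must be positively oriented")
    inv = np.linalg.inv(e)                 # (m, 3, 3)
    grads = np.empty((len(t), 4, 3))
    grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    # local stiffness: vol * grad_i . grad_j
    local = np.einsum("mid,mjd,m->mij", grads, grads, vol)
    rows = np.repeat(t, 4, axis=1).ravel()
    cols = np.tile(t, (1, 4)).ravel()
    K = sp.csr_matrix((local.ravel(), (rows, cols)), shape=(n, n))
    lumped = np.zeros(n)
    np.add.at(lumped, t.ravel(), np.repeat(vol / 4.0, 4))
    return K, lumped


# ---------------------------------------------------------------------------
# 3-D run
# ---------------------------------------------------------------------------


def run_3d(mesh: LabeledMesh, config: SimulationConfig,
           cell: CellParams = CellParams()) -> Solution:
    """Advance the coupled system on ``mesh`` for ``config.duration`` ms.

    Initial state: buffers equilibrated at the resting Ca²⁺, with the
    stationary troponin C total zeroed at nodes inside the sub-sarcolemmal
    exclusion shell.  Reflective faces are zero-flux; membrane facets carry
    the scenario's flux densities as a Neumann condition on free Ca²⁺.
    Deterministic for fixed inputs.
    """
    buffers = config.resolved_buffers()
    leak = config.resolved_leak()
    ions, k = config.ions, config.constants
    names = buffers.names()
    nbuf = len(buffers)
    kon = np.array([b.k_on for b in buffers])
    koff = np.array([b.k_off for b in buffers])
    n = mesh.n_vertices

    # nodal total-buffer fields; stationary buffers are excluded from the
    # sub-sarcolemmal shell next to the membrane
    dist = distance_to_membrane_field(mesh)
    Bt = np.empty((nbuf, n))
    for i, b in enumerate(buffers):
        Bt[i] = b.B_total
        if not b.mobile and b.name == "troponin C":
            Bt[i, dist < buffers.tn_exclusion_depth] = 0.0

    K, lumped = assemble_p1(mesh)
    dt = config.dt
    solvers = {}
    for b in buffers:
        if b.mobile and b.D_complex > 0:
            solvers[b.name] = spla.splu((sp.diags(lumped) + dt * b.D_complex * K).tocsc())
    solvers["Ca"] = spla.splu((sp.diags(lumped) + dt * buffers.D_Ca * K).tocsc())

    mf = membrane_facets(mesh)
    w_lcc, w_ncx, w_leak = scenario_weights(mf, config.scenario, config.poly)
    vol_per_area = mf.mesh_volume / mf.total_area
    facet_nodes = mf.facets  # (nf, 3)

    Ca = np.full(n, ions.Ca_rest)
    CaB = Bt * ions.Ca_rest / (koff[:, None] / kon[:, None] + ions.Ca_rest)

    nsteps = int(round(config.duration / dt))
    out_idx = list(range(0, nsteps + 1, config.output_stride))
    if out_idx[-1] != nsteps:
        out_idx.append(nsteps)
    out_set = {s: i for i, s in enumerate(out_idx)}
    nt = len(out_idx)

    fields = {"Ca": np.empty((nt, n))}
    for nm in names:
        fields["Ca" + nm] = np.empty((nt, n))
    times = np.empty(nt)
    totals = np.empty(nt)
    influx = np.empty(nt)
    gfl = {nm: np.empty(nt) for nm in ("lcc", "ncx", "leak")}

    cum_influx = 0.0

    def total_content():
        return float(lumped @ (Ca + CaB.sum(axis=0)))

    def boundary_densities(t, ca_nodes):
        if config.no_membrane_flux:
            z = np.zeros(len(mf.areas))
            return z, z, z
        V = config.protocol.voltage(t)
        ca_f = ca_nodes[facet_nodes].mean(axis=1)
        j_lcc = current_density_to_flux(
            lcc_current_density(t, config.protocol, config.lcc), cell, k)
        d_lcc = vol_per_area * w_lcc * j_lcc
        d_ncx = vol_per_area * w_ncx * ncx_flux(V, np.maximum(ca_f, 1e-9), ions, config.ncx, k)
        d_leak = vol_per_area * w_leak * leak_flux(V, np.maximum(ca_f, 1e-9), ions, leak, k)
        return d_lcc, d_ncx, d_leak

    def store(step_i, out_i, t):
        times[out_i] = t
        fields["Ca"][out_i] = Ca
        for ib, nm in enumerate(names):
            fields["Ca" + nm][out_i] = CaB[ib]
        totals[out_i] = total_content()
        influx[out_i] = cum_influx
        d_lcc, d_ncx, d_leak = boundary_densities(t, Ca)
        for nm, d in (("lcc", d_lcc), ("ncx", d_ncx), ("leak", d_leak)):
            gfl[nm][out_i] = float((d * mf.areas).sum()) / mf.mesh_volume

    store(0, 0, 0.0)

    for step in range(nsteps):
        t1 = (step + 1) * dt
        # Strang splitting: reaction half, diffusion full, reaction half
        Ca, CaB = _reaction_step(Ca, CaB, Bt, kon, koff, 0.5 * dt)

        d_lcc, d_ncx, d_leak = boundary_densities(t1, Ca)
        dens = d_lcc + d_ncx + d_leak
        b = np.zeros(n)
        contrib = (dens * mf.areas / 3.0)
        np.add.at(b, facet_nodes.ravel(), np.repeat(contrib, 3))
        step_in = float((dens * mf.areas).sum()) * dt
        cum_influx += step_in

        rhs = lumped * Ca + dt * b
        Ca = solvers["Ca"].solve(rhs)
        for ib, buf in enumerate(buffers):
            s = solvers.get(buf.name)
            if s is not None:
                CaB[ib] = s.solve(lumped * CaB[ib])

        Ca, CaB = _reaction_step(Ca, CaB, Bt, kon, koff, 0.5 * dt)

        low = min(float(Ca.min()), float(CaB.min()))
        if low < -1e-6:
            raise RuntimeError(f"negative concentration {low} at t={t1} ms")
        np.clip(Ca, 0.0, None, out=Ca)
        np.clip(CaB, 0.0, None, out=CaB)

        oi = out_set.get(step + 1)
        if oi is not None:
            store(step + 1, oi, t1)

    if not np.all(np.isfinite(fields["Ca"])):
        raise RuntimeError("non-finite concentration field")
    return Solution(time=times, fields=fields, mesh=mesh, node_volumes=lumped,
                    total_content=totals, cumulative_influx=influx,
                    global_fluxes=gfl, config=config)


# ---------------------------------------------------------------------------
# conservation audit
# ---------------------------------------------------------------------------


@dataclass
class ConservationReport:
    ok: bool
    max_relative_error: float
    worst_time: float

    def __str__(self):
        s = "OK" if self.ok else "VIOLATED"
        return (f"mass conservation {s}: max relative error "
                f"{self.max_relative_error:.3e} at t={self.worst_time:.1f} ms")


def check_conservation(solution: Solution, rtol: float = 1e-6) -> ConservationReport:
    """Check that the change of volume-integrated total Ca between output
    times equals the time-integrated membrane influx."""
    gained = solution.total_content - solution.total_content[0]
    applied = solution.cumulative_influx - solution.cumulative_influx[0]
    scale = max(float(np.max(np.abs(applied))), float(solution.total_content[0]))
    err = np.abs(gained - applied) / scale
    worst = int(np.argmax(err))
    return ConservationReport(ok=bool(err[worst] <= rtol),
                              max_relative_error=float(err[worst]),
                              worst_time=float(solution.time[worst]))
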