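# Methods

## Model

The cytosolic domain is a 2 × 2 × 5.96 µm box (half-sarcomeres around one
t-tubule) minus the tubule lumen. Free Ca²⁺ and four buffers react and
diffuse; all binding is 1:1 and non-cooperative; Ca-bound mobile complexes
diffuse at the same coefficient as the free buffer. Troponin C is
stationary and its total is set to zero at nodes closer than 45 nm to the
membrane (midpoint of the reported 40–50 nm sub-sarcolemmal exclusion);
everywhere else buffer totals are spatially uniform. Diffusion is
isotropic. The SR contributes no terms (pharmacologically inhibited), and
[Na⁺]ᵢ is held constant at 10 mM.

Kinetics and transport (µM, ms, µm): D_Ca = 0.39 µm²/ms; Fluo-3 100 µM
(k_on 0.23, k_off 0.17, D 0.10), ATP 260 µM (0.225, 45, 0.168), calmodulin
24 µM (0.125, 0.2975, 0.025), troponin C 70 µM (0.04, 0.04, stationary).
Resting Ca²⁺ 0.1 µM, extracellular Ca²⁺ 1 mM.

### Membrane fluxes

Voltage clamp: hold −50 mV, step to +10 mV for 70 ms, 400 ms total. The
"10 mV pulse" is read as a step to +10 mV (near the LCC current maximum);
the protocol object makes the level switchable.

* **LCC**: whole-cell current density template
  −A·(1 − e^(−t/4 ms))·e^(−t/70 ms) during the pulse, exponential
  deactivation with τ_deact = 1 ms afterwards. The template shape follows
  the published time constants; the amplitude A is a free parameter
  calibrated by bisection so the 0-D global peak with 100 µM Fluo-3 equals
  the measured 163 nM (calibrated value ≈ 4.88 pA/pF). The same amplitude
  is reused for dye-free scenarios (the dye does not alter Ca²⁺ entry).
* **NCX**: Hinch electrochemical form with V_max 38.5 µM/ms, η 0.35,
  K_Na 87.5 mM, K_Ca 1380 µM, k_sat 0.1. The flux is linear in cytosolic
  Ca²⁺ at fixed voltage, which the implicit integrator exploits.
* **Leak**: g_leak·(E_Ca − V). The conductance is always recalibrated at
  initialization so NCX and leak cancel exactly at rest; with Na_e = 140 mM
  this gives g ≈ +1.01e-5 µM/(mV·ms), with Na_e = 0 g ≈ −5.34e-5. These
  reproduce the signs (not the magnitudes) of the two published reference
  conductances — the published +3.4e-6 implies a resting NCX ~3× weaker
  than the canonical Hinch algebra evaluated here; the calibration absorbs
  the difference and keeps the resting state an exact fixed point.
* **Unit conversion**: J = −I·(8.8 pF/pL)/(2F), so −1 pA/pF ↦
  +0.0456 µM/ms. The accessible-volume bookkeeping (36.8 pL × 0.37 =
  13.6 pL) is carried on the cell-parameter object but does not enter the
  flux conversion.

### Spatial flux scenarios

Per-facet weights are area-normalized so every scenario delivers the same
whole-compartment total of each component at matched uniform Ca²⁺:

1. *heterogeneous_polynomial*: within the t-tubule the LCC density follows
   the cubic depth polynomial w(x) = C(p₁x³ + p₂x² + p₃x + p₄)
   (C = 0.4515, p = −4.1379e-4, −1.1722e-2, 1.978e-1, 1.0033; ≈1.67-fold
   increase from mouth to terminus). The profile is rescaled so the
   tubule's area-weighted mean weight is 6× the external membrane's — the
   published scaling constant served exactly this purpose ("the total Ca²⁺
   flux along the t-tubule membrane remained unchanged by redistributing"),
   so cases 1 and 2 share the same tubule/external split and differ only in
   the within-tubule grading.
2. *uniform_6x_ttubule*: 6:1 tubule:external, uniform within each.
3. *homogeneous*: uniform everywhere.

NCX is 3:1 tubule-enriched (scenarios 1–2) or uniform (scenario 3) and is
evaluated with the facet-local Ca²⁺; the leak is always homogeneous.

## Synthetic geometry

The published mesh came from two-photon microscopy; it is not available.
The generator emulates its aggregate statistics with a parametric tubule: a
trunk along the depth axis (depth 5.645 µm) whose radius profile is drawn
from a seeded RNG over control knots and mapped to span the published
caliber range exactly, a short conical mouth flare (opening ≈ 0.75 µm², so
the external membrane is ≈ 3.25 µm² of the 4 µm² top face), and closed
side branches forming a tree. The published 0.19–0.469 µm range is treated
as diameters (the source text says diameter; the radius reading is
inconsistent with the published areas), so radii default to
0.095–0.2345 µm.

The domain is meshed by marching tetrahedra: a structured Kuhn (6-tet)
subdivision of the box, the tubule's level function evaluated at grid
vertices (values within 0.05 h of zero are clamped away from zero to
prevent sliver elements), and every crossed tetrahedron cut along the
linear interpolant's zero plane. Cut cells are re-tetrahedralized by coning
from their centroid, with shared quads split by a
lowest-global-index-vertex diagonal rule so the mesh stays conforming and
watertight. Boundary facets on the top plane are external membrane, other
box planes reflective, all carved facets (tubule wall, flare, branch caps)
t-tubule membrane — branch caps deliberately carry ordinary t-tubule
boundary conditions; their area is small.

Calibration: the profile-shaping exponent (2.3), branch length (0.42 µm),
mouth radius (0.4886 µm) and the shipped seed were fit once, at the default
grid spacing of 0.09 µm, to the published compartment statistics, then
frozen. Measured at those defaults: volume 23.50 µm³ (+0.8 % of 23.31),
membrane 9.02 µm² (+0.2 % of 9.00), t-tubule fraction 63.9 % (64 %
published). Statistics change by <2 % under grid halving. What the
generator does **not** emulate: the true transverse-axial branch topology,
local wall corrugation, and any correlation between branch positions and
dyad locations — so tests passing on this geometry validate the solver and
the directional physics, not the published mesh-specific magnitudes (the
published SCH fold changes, e.g. 2.34× and 2.72×, are therefore treated as
directional properties only).

Desk-scale variants used by the test suite: a cylindrical tubule (r =
0.25 µm, grid 0.25 µm) for 0-D/3-D equivalence, and a branched variant with
radii scaled to 0.15–0.35 µm so a 0.15 µm grid resolves them.

## Numerics

* P1 finite elements, lumped mass; one sparse LU factorization per mobile
  species, reused across steps.
* Backward Euler with Strang splitting: implicit nodal reaction half-step,
  implicit diffusion step (membrane flux enters the free-Ca right-hand side
  at the new time level; NCX/leak use facet Ca²⁺ from the current state),
  implicit reaction half-step. The nodal reaction solve reduces to a
  monotone scalar Newton iteration in free Ca²⁺ (each buffer update is a
  rational function of the new Ca²⁺), so it is unconditionally convergent.
* Default Δt = 0.1 ms (0-D) and 0.25–0.5 ms (3-D desk scale). The
  published 4 ms step is treated as an output stride, not assumed adequate:
  reaction stiffness (k_off·B_T for ATP is ~10⁴/ms·µM) demands implicit
  treatment, and halving Δt changes the global peak by <1 %.
* Conservation is tracked exactly: lumped-mass total Ca (free + bound)
  changes only by the applied boundary-flux integral (zero row sums of the
  stiffness matrix; pointwise-conservative reaction solve), verified to
  ~1e-13 relative.
* Degenerate inputs: non-positive tetrahedra, non-watertight boundaries,
  unresolved lumens, lines leaving the domain and infeasible tubule specs
  are rejected with diagnostics. Concentrations are clipped at zero only
  below 1e-6 µM of undershoot; larger negativity aborts the run.

## Analysis definitions

* Line scan: straight line parallel to the depth axis at radial distance
  (max tubule radius + 200 nm) from the tubule axis, azimuth 120° (60°
  alternative), sampled every 0.06 µm between depths 0.08 and 5.90 µm; the
  published description is schematic, so the construction is parameterized
  and recorded in run manifests. Free Ca²⁺ is the default exported field
  (the dye complex is available as the fluorescence proxy).
* SCH(t) = (max − min)/max over the reference spots (0.17, 3.09, 5.45 µm),
  evaluated at the epochs {LCC-current peak, 70 ms, Ca peak, 100 ms,
  200 ms}.
* Front detection: per-position first crossing of a threshold (default 2×
  the resting level — an elevation dye-buffered transients never reach); a
  front is initiated when onsets are non-decreasing and overall increasing
  over ≥1 µm of contiguous depth, faltered when that run stops before the
  line end; speed = span/Δt.

## Design choices on open points

* The rapid-buffer effective diffusion uses binding ratios at the Ca → 0
  limit (β = B_T/K_d); this reproduces all four published values
  (8, ~6, 10.4, 66 µm²/s) where the alternative (β at 0.1 µM) does not.
* The LCC depth polynomial's coordinate x is depth below the external
  surface, not arc length along branches.
* The phospholipid stationary buffer is supported as an optional extra
  slot; no parameters were published, so none ship as defaults.
* The mobility-override scenario sets D_complex = 0 for CaATP/CaCal
  without touching kinetics.
* A thin CLI exists because the artifact is also a runnable tool, but the
  importable API plus `examples/` is the primary interface.

## Known limitations

* **Time to global Ca²⁺ peak.** In this reconstruction the free-Ca peak
  sits at the end of the 70-ms pulse (~70 ms): once the LCC deactivates
  (τ_deact = 1 ms), slow troponin-C binding (τ ≈ 21 ms) keeps absorbing
  free Ca²⁺, so no flux combination continues the rise. The published
  value (~76 ms) is 6 ms later; neither running at the published 4-ms step
  nor tracking the dye complex reproduces it, and it most likely reflects
  the original study's coarse output grid or a pre-pulse hold segment in
  its protocol timeline. The discrepancy (~8 %) is reported as-is and the
  corresponding acceptance check on the ±4 ms band fails honestly.
* Upon immobilizing CaATP/CaCal the deep reference-spot peaks *rise*
  slightly here rather than falling: on this geometry the deep spots sit
  200 nm from tubule membrane that delivers flux locally, whereas in the
  published geometry they are fed diffusively. The robust, asserted form
  of the finding is that the sub-sarcolemmal peak rises and the
  sub-sarcolemmal/deep ratio grows.
* Continuously distributed fluxes (no discrete channel clusters or dyadic
  clefts), no electrodiffusion, fixed [Na⁺]ᵢ, no fluorescence photophysics
  (CaFluo concentration is the fluorescence proxy).

## Problem sizes

Default geometry: ~42 k nodes / ~217 k tetrahedra at the 0.09 µm
calibration spacing (statistics only). Solver runs in the examples and the
test suite use the desk-scale meshes (2.7–11 k nodes) with Δt = 0.25–1 ms
over 400 ms; the 0-D reduction uses Δt = 0.1 ms. These sizes were chosen so
a full scenario battery runs on one CPU core in minutes; all convergence
checks (grid halving <2 % on geometry statistics, Δt halving <1 % on the
global peak, 0-D vs 3-D <5 %) are part of the test suite.
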