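"""Ca²⁺ buffer kinetics, equilibrium initialization, and effective diffusion.

Units: concentrations in µM, time in ms, length in µm (diffusion
coefficients in µm² ms⁻¹).  The effective diffusion coefficient of free
Ca²⁺ under the rapid-buffer approximation is reported in µm² s⁻¹, the
scale on which measured values are usually quoted.

Each buffer binds Ca²⁺ without cooperativity,

    Ca + B  <-> CaB,    R = k_on [Ca][B] - k_off [CaB],

and the Ca-bound complex of a mobile buffer diffuses with the same
coefficient as the free buffer.  Troponin C is stationary and is excluded
from a thin sub-sarcolemmal shell (~45 nm) because the myofilaments do not
reach the membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class BufferParams:
    name: str
    B_total: float          # µM
    k_on: float             # µM^-1 ms^-1
    k_off: float            # ms^-1
    D_complex: float = 0.0  # µm^2 ms^-1, 0 for stationary buffers
    mobile: bool = False

    def __post_init__(self):
        if self.B_total < 0:
            raise ValueError(f"{self.name}: negative total concentration")
        if self.k_on <= 0 or self.k_off < 0:
            raise ValueError(f"{self.name}: invalid rate constants")
        if not self.mobile and self.D_complex != 0.0:
            raise ValueError(f"{self.name}: stationary buffer with D_complex != 0")

    @property
    def K_d(self) -> float:
        """Dissociation constant k_off/k_on (µM)."""
        return self.k_off / self.k_on


# Published kinetic and transport parameters of the four buffers (22 °C).
FLUO3 = BufferParams("Fluo-3", B_total=100.0, k_on=0.23, k_off=0.17,
                     D_complex=0.10, mobile=True)
ATP = BufferParams("ATP", B_total=260.0, k_on=0.225, k_off=45.0,
                   D_complex=0.168, mobile=True)
CALMODULIN = BufferParams("calmodulin", B_total=24.0, k_on=0.125, k_off=0.2975,
                          D_complex=0.025, mobile=True)
TROPONIN = BufferParams("troponin C", B_total=70.0, k_on=0.04, k_off=0.04,
                        mobile=False)

D_CA_DEFAULT = 0.39          # µm^2 ms^-1, free Ca²⁺
TN_EXCLUSION_DEPTH = 0.045   # µm, sub-sarcolemmal shell without troponin C


@dataclass(frozen=True)
class BufferSet:
    """Ordered buffer collection plus the free-Ca²⁺ transport parameters."""

    buffers: tuple[BufferParams, ...] = (FLUO3, ATP, CALMODULIN, TROPONIN)
    D_Ca: float = D_CA_DEFAULT
    tn_exclusion_depth: float = TN_EXCLUSION_DEPTH

    def __post_init__(self):
        names = [b.name for b in self.buffers]
        if len(set(names)) != len(names):
            raise ValueError("buffer names must be unique")
        if self.D_Ca <= 0:
            raise ValueError("D_Ca must be positive")

    def __iter__(self):
        return iter(self.buffers)

    def __len__(self):
        return len(self.buffers)

    def without(self, name: str) -> "BufferSet":
        return replace(self, buffers=tuple(b for b in self.buffers if b.name != name))

    def with_mobility_override(self, immobile_names: tuple[str, ...]) -> "BufferSet":
        """Freeze the Ca-bound complexes of the named buffers in place
        (D_complex -> 0) without touching their kinetics."""
        new = []
        for b in self.buffers:
            if b.name in immobile_names:
                b = replace(b, D_complex=0.0, mobile=False)
            new.append(b)
        return replace(self, buffers=tuple(new))

    def names(self) -> list[str]:
        return [b.name for b in self.buffers]


def default_buffer_set(fluo3: float = 100.0) -> BufferSet:
    """The study's buffer mix; ``fluo3`` sets the dye load in µM (0 removes it)."""
    buffers = []
    for b in (FLUO3, ATP, CALMODULIN, TROPONIN):
        if b.name == "Fluo-3":
            if fluo3 == 0:
                continue
            b = replace(b, B_total=float(fluo3))
        buffers.append(b)
    return BufferSet(buffers=tuple(buffers))


@dataclass
class SpeciesState:
    """Free Ca²⁺ and per-buffer bound complex concentrations (µM).

    Values may be scalars (well-mixed state) or per-node arrays.
    """

    Ca: np.ndarray | float
    CaB: dict[str, np.ndarray | float]


def equilibrium_state(Ca0: float, buffers: BufferSet) -> SpeciesState:
    """Buffers equilibrated with free Ca²⁺ at ``Ca0``: CaB = B_T·Ca/(K_d+Ca)."""
    if np.any(np.asarray(Ca0) < 0):
        raise ValueError("negative Ca concentration")
    CaB = {b.name: b.B_total * Ca0 / (b.K_d + Ca0) for b in buffers}
    return SpeciesState(Ca=Ca0, CaB=CaB)


def reaction_rate(state: SpeciesState, buffer: BufferParams):
    """Rate of complex formation R = k_on·Ca·(B_T − CaB) − k_off·CaB (µM/ms).

    Positive R consumes free Ca²⁺.
    """
    CaB = state.CaB[buffer.name]
    return buffer.k_on * state.Ca * (buffer.B_total - CaB) - buffer.k_off * CaB


def effective_diffusion(D_Ca: float, buffers: BufferSet | tuple[BufferParams, ...],
                        extra_stationary: BufferParams | None = None) -> float:
    """Rapid-buffer effective diffusion coefficient of free Ca²⁺.

    In the low-Ca linearization every buffer contributes its resting binding
    ratio β = B_T/K_d, and mobile complexes carry Ca²⁺ at their own
    diffusivity:

        D_eff = (D_Ca + Σ_mobile D_i β_i) / (1 + Σ_all β_i)

    ``D_Ca`` is given and the result returned in µm² s⁻¹ (stored complex
    diffusivities, kept in µm² ms⁻¹, are converted internally).
    ``extra_stationary`` admits an additional stationary binding site
    (e.g. membrane phospholipids) without making it a default.
    """
    items = list(buffers)
    if extra_stationary is not None:
        items.append(extra_stationary)
    num = float(D_Ca)
    den = 1.0
    for b in items:
        if b.k_on == 0 or b.K_d == 0:
            raise ValueError(f"{b.name}: K_d must be positive")
        beta = b.B_total / b.K_d
        den += beta
        if b.mobile:
            num += 1000.0 * b.D_complex * beta  # µm²/ms -> µm²/s
        if not np.isfinite(beta):
            raise ValueError(f"{b.name}: invalid binding ratio")
    return num / den
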