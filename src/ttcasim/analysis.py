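"""Post-processing: line-scan extraction, spatial Ca²⁺ heterogeneity (SCH),
transient metrics, and wavefront detection.

A simulated confocal line scan samples the concentration field along a
straight line running parallel to the depth axis, offset a fixed distance
from the t-tubule wall at a chosen azimuthal angle about the tubule axis.
The SCH statistic at a time t is (max − min)/max of the concentration over
a fixed set of reference spots along that line: 0 means spatially uniform,
values toward 1 mean strong heterogeneity.  SCH is scale-free, so it can be
computed equally on free Ca²⁺ or on the dye-complex (fluorescence proxy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import LabeledMesh
from .solver import GlobalTransient, Solution


@dataclass(frozen=True)
class LineScanSpec:
    """Scan-line placement relative to the tubule.

    The line is parallel to the depth axis at radial distance
    (max tubule radius + ``offset``) from the tubule axis, at azimuth
    ``angle_deg`` about that axis.  ``spots`` are reference depths (µm)
    used by the SCH statistic.
    """

    offset: float = 0.2            # µm from the t-tubule wall
    angle_deg: float = 120.0       # about the tubule axis (60 is the alternative)
    spacing: float = 0.06          # µm sample spacing along the line
    spots: tuple[float, ...] = (0.17, 3.09, 5.45)
    z_start: float = 0.08          # below the mouth flare
    z_end: float = 5.90

    def __post_init__(self):
        if self.offset <= 0:
            raise ValueError("offset must be positive")
        if not self.z_start < min(self.spots) or not max(self.spots) < self.z_end:
            raise ValueError("reference spots must lie inside the scanned range")


@dataclass
class LineScanImage:
    positions: np.ndarray   # (np,) µm depth along the line
    times: np.ndarray       # (nt,) ms
    values: np.ndarray      # (nt, np) µM

    def __post_init__(self):
        if self.values.shape != (len(self.times), len(self.positions)):
            raise ValueError("inconsistent line-scan dimensions")


@dataclass
class SCHReport:
    epochs: dict[str, float]             # epoch name -> time (ms)
    sch: dict[str, float]                # epoch name -> SCH value
    spots: tuple[float, ...]


@dataclass
class FrontReport:
    initiated: bool
    onset_times: np.ndarray    # per position, ms (nan where never crossed)
    speed: float               # µm/ms over the monotone window (nan if none)
    faltered: bool
    span: tuple[float, float]  # depth window of the monotone run (µm)


# ---------------------------------------------------------------------------
# point location and interpolation
# ---------------------------------------------------------------------------


class _PointLocator:
    """Locate points in tetrahedra via a centroid KD-tree plus barycentric test."""

    def __init__(self, mesh: LabeledMesh):
        self.mesh = mesh
        v = mesh.vertices
        t = mesh.tetrahedra
        self.centroids = v[t].mean(axis=1)
        self.tree = cKDTree(self.centroids)

    def barycentric(self, tet_ids: np.ndarray, points: np.ndarray) -> np.ndarray:
        v = self.mesh.vertices
        t = self.mesh.tetrahedra[tet_ids]
        a = v[t[:, 0]]
        T = np.stack([v[t[:, 1]] - a, v[t[:, 2]] - a, v[t[:, 3]] - a], axis=2)
        lam = np.linalg.solve(T, (points - a)[..., None])[..., 0]
        return np.column_stack([1.0 - lam.sum(axis=1), lam])

    def locate(self, points: np.ndarray, k: int = 48, tol: float = 1e-9):
        """Return (tet_id, barycentric weights (4,)) per point; tet_id −1 if
        the point lies outside the meshed domain (e.g. inside the lumen)."""
        points = np.atleast_2d(points)
        npts = len(points)
        k = min(k, len(self.centroids))
        _, cand = self.tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        tet_id = np.full(npts, -1, dtype=np.int64)
        weights = np.zeros((npts, 4))
        remaining = np.arange(npts)
        for j in range(k):
            if len(remaining) == 0:
                break
            ids = cand[remaining, j]
            lam = self.barycentric(ids, points[remaining])
            ok = np.all(lam >= -tol - 1e-12, axis=1) & np.all(lam <= 1 + tol + 1e-12, axis=1)
            hit = remaining[ok]
            tet_id[hit] = ids[ok]
            weights[hit] = np.clip(lam[ok], 0.0, 1.0)
            remaining = remaining[~ok]
        return tet_id, weights


def extract_linescan(solution: Solution, spec: LineScanSpec = LineScanSpec(),
                     field_name: str = "Ca") -> LineScanImage:
    """Sample a nodal field along the scan line at every stored time.

    Values are interpolated piecewise-linearly inside the containing
    tetrahedra.  Raises if any sample point falls outside the cytosolic
    domain (line exits the box or enters the tubule lumen).
    """
    mesh = solution.mesh
    tspec = mesh.spec
    if tspec is None:
        raise ValueError("mesh carries no tubule spec; cannot place the scan line")
    cx, cy = tspec.mouth_center
    rho = tspec.radius_max + spec.offset
    ang = np.deg2rad(spec.angle_deg)
    x0, y0 = cx + rho * np.cos(ang), cy + rho * np.sin(ang)
    zs = np.arange(spec.z_start, spec.z_end + 0.5 * spec.spacing, spec.spacing)
    pts = np.column_stack([np.full_like(zs, x0), np.full_like(zs, y0), zs])

    loc = _PointLocator(mesh)
    tet_id, w = loc.locate(pts)
    if np.any(tet_id < 0):
        bad = zs[tet_id < 0]
        raise ValueError(
            f"scan line leaves the cytosolic domain at depths {bad[:4]} µm "
            "(line enters the tubule lumen or exits the box)")
    conn = mesh.tetrahedra[tet_id]          # (np, 4)
    data = solution.fields[field_name]       # (nt, n)
    values = np.einsum("tpj,pj->tp", data[:, conn], w)
    return LineScanImage(positions=zs, times=solution.time.copy(), values=values)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def _values_at(image: LineScanImage, spots: Sequence[float], t: float) -> np.ndarray:
    if t < image.times[0] - 1e-9 or t > image.times[-1] + 1e-9:
        raise ValueError(f"time {t} ms outside the image range")
    spots = np.asarray(spots, dtype=float)
    if np.any(spots < image.positions[0] - 1e-9) or np.any(spots > image.positions[-1] + 1e-9):
        raise ValueError("reference spots outside the scanned positions")
    # bilinear: in time then along the line
    row = np.array([np.interp(t, image.times, image.values[:, j])
                    for j in range(image.values.shape[1])])
    return np.interp(spots, image.positions, row)


def compute_sch(image: LineScanImage, spots: Sequence[float], t: float) -> float:
    """Spatial Ca²⁺ heterogeneity (max − min)/max at the reference spots."""
    vals = _values_at(image, spots, t)
    vmax = float(vals.max())
    if vmax <= 0:
        raise ValueError("SCH undefined: maximal value is zero")
    return float((vmax - vals.min()) / vmax)


def sch_report(image: LineScanImage, spots: Sequence[float],
               epochs: dict[str, float]) -> SCHReport:
    return SCHReport(epochs=dict(epochs),
                     sch={name: compute_sch(image, spots, t) for name, t in epochs.items()},
                     spots=tuple(spots))


def standard_epochs(global_trace, lcc_peak_time: float) -> dict[str, float]:
    """The five reporting epochs: LCC current peak, end of pulse, Ca peak,
    100 ms, 200 ms."""
    m = transient_metrics(global_trace)
    return {"t_Ica_peak": float(lcc_peak_time), "t_70ms": 70.0,
            "t_Ca_peak": m.t_peak, "t_100ms": 100.0, "t_200ms": 200.0}


@dataclass
class TransientMetrics:
    peak: float
    t_peak: float
    time: np.ndarray
    values: np.ndarray

    def value_at(self, t: float) -> float:
        return float(np.interp(t, self.time, self.values))


def transient_metrics(trace) -> TransientMetrics:
    """Peak, time of peak (first occurrence on ties) and interpolated values.

    ``trace`` is a GlobalTransient, a (time, values) pair, or any object with
    ``time`` and ``Ca`` attributes.
    """
    if isinstance(trace, GlobalTransient):
        time, values = trace.time, trace.Ca
    elif hasattr(trace, "time") and hasattr(trace, "Ca"):
        time, values = trace.time, trace.Ca
    else:
        time, values = trace
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(time) == 0:
        raise ValueError("empty trace")
    i = int(np.argmax(values))
    return TransientMetrics(peak=float(values[i]), t_peak=float(time[i]),
                            time=time, values=values)


def detect_front(image: LineScanImage, threshold: Optional[float] = None,
                 min_span: float = 1.0) -> FrontReport:
    """Detect an inward-propagating concentration front on a line-scan image.

    Per position, the onset is the first time the value crosses
    ``threshold`` (default: twice the baseline, a wave-scale elevation that
    dye-buffered transients never reach).  A front counts as initiated when
    onset times are non-decreasing, and strictly increasing overall, over a
    contiguous depth span of at least ``min_span`` µm; it "faltered" if that
    monotone run ends before the deepest scanned position.  A spatially
    simultaneous rise (all onsets equal) is not a front.
    """
    vals = image.values
    baseline = float(vals[0].min())
    if threshold is None:
        threshold = 2.0 * baseline if baseline > 0 else float(vals.max()) / 2.0
    if threshold <= baseline:
        raise ValueError("threshold must exceed the baseline")

    crossed = vals >= threshold
    any_cross = crossed.any(axis=0)
    first = np.argmax(crossed, axis=0)
    onset = np.where(any_cross, image.times[first], np.nan)

    # longest contiguous run of finite, non-decreasing onsets
    best = (0.0, 0, 0)  # (span, i0, i1)
    i = 0
    npos = len(image.positions)
    while i < npos:
        if not np.isfinite(onset[i]):
            i += 1
            continue
        j = i
        while (j + 1 < npos and np.isfinite(onset[j + 1])
               and onset[j + 1] >= onset[j]):
            j += 1
        span = image.positions[j] - image.positions[i]
        if span > best[0] and onset[j] > onset[i]:
            best = (span, i, j)
        i = j + 1
    span, i0, i1 = best
    initiated = span >= min_span
    if initiated:
        dt = onset[i1] - onset[i0]
        speed = float(span / dt)
        faltered = i1 < npos - 1
        window = (float(image.positions[i0]), float(image.positions[i1]))
    else:
        speed = float("nan")
        faltered = False
        window = (float("nan"), float("nan"))
    return FrontReport(initiated=bool(initiated), onset_times=onset,
                       speed=speed, faltered=bool(faltered), span=window)
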