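"""Synthetic labeled tetrahedral meshes of a half-sarcomere box with one t-tubule.

The compartment is a rectangular box (external sarcolemma on the top face)
from which the lumen of a single t-tubule is carved.  The tubule is modeled
as a tree of tapered capsules: a trunk running down the depth axis with a
piecewise-linear radius profile, an optional conical mouth flare where the
tubule opens through the external membrane, and closed side branches.  The
cytosolic domain (box minus lumen) is meshed by marching tetrahedra on a
structured Kuhn subdivision of the box: tetrahedra crossed by the tubule
wall are cut along the linear interpolant of the level function, so the
mesh boundary follows the wall to second order in the grid spacing.

Boundary facets carry one of three labels: the top box face is external
membrane, the carved tubule wall (including branch end caps and the mouth
flare) is t-tubule membrane, and the remaining box faces are reflective
symmetry planes toward the neighbouring sarcomeres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

# boundary facet labels
EXTERNAL_MEMBRANE = 1
TTUBULE_MEMBRANE = 2
REFLECTIVE = 3

LABEL_NAMES = {
    EXTERNAL_MEMBRANE: "external_membrane",
    TTUBULE_MEMBRANE: "ttubule_membrane",
    REFLECTIVE: "reflective",
}

# grid spacing (µm) at which the shipped default spec was calibrated
DEFAULT_EDGE_LENGTH = 0.09


class GeometryError(ValueError):
    """Infeasible tubule specification (exits the box, overlapping branches)."""


class MeshingError(RuntimeError):
    """Mesh construction produced degenerate or inverted elements."""


@dataclass(frozen=True)
class TTubuleSpec:
    """Parameters of the box-plus-tubule compartment.

    Lengths in µm.  ``radius_min``/``radius_max`` bound the radius profile of
    the tubule proper (the published 0.19-0.469 µm caliber range describes
    diameters, hence the defaults).  The mouth flare is controlled separately
    because the opening through the external membrane (~0.75 µm²) is wider
    than the tubule itself.  ``seed`` fixes the branch layout and the radius
    profile; identical spec+seed gives a bit-identical mesh.
    """

    box_x: float = 2.0
    box_y: float = 2.0
    box_depth: float = 5.96
    tubule_depth: float = 5.645
    radius_min: float = 0.095
    radius_max: float = 0.2345
    n_branches: int = 3
    mouth_center: tuple[float, float] = (1.0, 1.0)
    variant: str = "branched"  # or "cylindrical"
    seed: int = 20101028
    # calibrated shape parameters (see docs/methods.md)
    mouth_radius: float = 0.4886
    flare_depth: float = 0.12
    radius_profile_gamma: float = 2.3
    branch_length: float = 0.42
    n_profile_knots: int = 9

    def validate(self) -> None:
        if not (self.box_x > 0 and self.box_y > 0 and self.box_depth > 0):
            raise GeometryError("box dimensions must be positive")
        if not (0 < self.tubule_depth < self.box_depth):
            raise GeometryError("tubule depth must lie inside the box depth")
        if not (0 < self.radius_min <= self.radius_max):
            raise GeometryError("need 0 < radius_min <= radius_max")
        if self.variant not in ("branched", "cylindrical"):
            raise GeometryError(f"unknown variant {self.variant!r}")
        if self.variant == "branched" and self.n_branches < 1:
            raise GeometryError("branched variant needs n_branches >= 1")
        cx, cy = self.mouth_center
        rim = self.mouth_radius if self.variant == "branched" else self.radius_max
        margin = 3.0 * self.radius_max
        if not (rim + 0.05 < cx < self.box_x - rim - 0.05
                and rim + 0.05 < cy < self.box_y - rim - 0.05):
            raise GeometryError("tubule mouth exits the box top face")
        if self.tubule_depth + margin > self.box_depth and \
                self.tubule_depth + 0.05 > self.box_depth:
            raise GeometryError("tubule end too close to the box bottom")


@dataclass
class LabeledMesh:
    """Tetrahedral mesh with labeled boundary facets.

    ``vertices`` (n,3) µm, ``tetrahedra`` (m,4) vertex indices,
    ``boundary_facets`` (k,3) vertex indices, ``facet_labels`` (k,) one of
    EXTERNAL_MEMBRANE / TTUBULE_MEMBRANE / REFLECTIVE.
    """

    vertices: np.ndarray
    tetrahedra: np.ndarray
    boundary_facets: np.ndarray
    facet_labels: np.ndarray
    spec: Optional[TTubuleSpec] = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def tet_volumes(self) -> np.ndarray:
        v = self.vertices
        t = self.tetrahedra
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        c = v[t[:, 3]] - v[t[:, 0]]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def facet_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.boundary_facets
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def validate(self) -> None:
        vol = self.tet_volumes()
        if not np.all(vol > 0):
            raise MeshingError(f"{np.sum(vol <= 0)} non-positive tetrahedra")
        # watertight: every boundary edge shared by exactly two boundary facets
        f = np.sort(self.boundary_facets, axis=1)
        edges = np.vstack([f[:, [0, 1]], f[:, [0, 2]], f[:, [1, 2]]])
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise MeshingError("boundary surface is not watertight")


@dataclass(frozen=True)
class GeometryStats:
    compartment_volume: float
    total_membrane_area: float
    ttubule_area: float
    external_area: float
    ttubule_fraction: float
    radius_range: tuple[float, float]
    tubule_depth: float


# ---------------------------------------------------------------------------
# tubule shape: level function < 0 inside the lumen
# ---------------------------------------------------------------------------


@dataclass
class _TubuleShape:
    cx: float
    cy: float
    depth: float
    z_knots: np.ndarray
    r_knots: np.ndarray
    flare: Optional[tuple[float, float, float]]  # (depth, r_mouth, r_throat)
    branches: list[tuple[np.ndarray, np.ndarray, float, float]]  # a, b, r0, r1

    def level(self, points: np.ndarray) -> np.ndarray:
        x, y, z = points[:, 0], points[:, 1], points[:, 2]
        radial = np.hypot(x - self.cx, y - self.cy)
        r = np.interp(z, self.z_knots, self.r_knots)
        # trunk: tube with flat closed end at z = depth
        f = np.maximum(radial - r, z - self.depth)
        if self.flare is not None:
            fd, rm, rt = self.flare
            r_fl = rm + (rt - rm) * np.clip(z, 0.0, fd) / fd
            f_fl = np.where(z <= fd, radial - r_fl, np.inf)
            f = np.minimum(f, f_fl)
        for a, b, r0, r1 in self.branches:
            ab = b - a
            L2 = float(ab @ ab)
            t = np.clip(((points - a) @ ab) / L2, 0.0, 1.0)
            closest = a[None, :] + t[:, None] * ab[None, :]
            d = np.linalg.norm(points - closest, axis=1)
            f = np.minimum(f, d - (r0 + (r1 - r0) * t))
        return f


def _build_shape(spec: TTubuleSpec) -> _TubuleShape:
    spec.validate()
    cx, cy = spec.mouth_center
    rng = np.random.default_rng(spec.seed)
    if spec.variant == "cylindrical":
        r = 0.5 * (spec.radius_min + spec.radius_max)
        return _TubuleShape(cx, cy, spec.tubule_depth,
                            np.array([0.0, spec.tubule_depth]),
                            np.array([r, r]), None, [])

    # trunk radius profile: knots drawn, biased toward the thin end by the
    # calibrated exponent, then affinely mapped to span [r_min, r_max]
    k = spec.n_profile_knots
    u = rng.random(k) ** spec.radius_profile_gamma
    u = (u - u.min()) / (u.max() - u.min())
    r_knots = spec.radius_min + (spec.radius_max - spec.radius_min) * u
    z_knots = np.linspace(0.0, spec.tubule_depth, k)

    flare = (spec.flare_depth, spec.mouth_radius,
             float(np.interp(spec.flare_depth, z_knots, r_knots)))

    branches = []
    golden = 2.399963229728653
    zlo, zhi = 0.25 * spec.tubule_depth, 0.85 * spec.tubule_depth
    for i in range(spec.n_branches):
        zb = zlo + (zhi - zlo) * (i + 0.5 + 0.3 * (rng.random() - 0.5)) / spec.n_branches
        theta = golden * i + 0.4 * rng.random()
        polar = np.deg2rad(60.0 + 20.0 * rng.random())  # from the depth axis
        direction = np.array([np.sin(polar) * np.cos(theta),
                              np.sin(polar) * np.sin(theta),
                              np.cos(polar)])
        length = spec.branch_length * (0.85 + 0.3 * rng.random())
        a = np.array([cx, cy, zb])
        b = a + length * direction
        r0 = min(spec.radius_max, spec.radius_min + 0.45 * (spec.radius_max - spec.radius_min))
        r1 = spec.radius_min
        branches.append((a, b, r0, r1))

    # feasibility: branches stay inside the box with clearance
    for a, b, r0, r1 in branches:
        clear = r1 + 0.08
        if not (clear < b[0] < spec.box_x - clear and clear < b[1] < spec.box_y - clear
                and 0.1 < b[2] < spec.box_depth - clear):
            raise GeometryError("branch exits the compartment box")
    # pairwise branch overlap (sampled distal halves)
    for i in range(len(branches)):
        for j in range(i + 1, len(branches)):
            ai, bi, r0i, r1i = branches[i]
            aj, bj, r0j, r1j = branches[j]
            ti = np.linspace(0.35, 1.0, 12)[:, None]
            pi = ai + ti * (bi - ai)
            pj = aj + ti * (bj - aj)
            dmin = np.min(np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2))
            if dmin < 0.5 * (r0i + r0j):
                raise GeometryError("overlapping branches")

    return _TubuleShape(cx, cy, spec.tubule_depth, z_knots, r_knots, flare, branches)


# ---------------------------------------------------------------------------
# marching tetrahedra on a Kuhn-subdivided structured grid
# ---------------------------------------------------------------------------

# the six tetrahedra of the Kuhn subdivision of the unit cube, as vertex
# offsets (i,j,k); every tet contains the main diagonal (0,0,0)-(1,1,1)
_KUHN_PATHS = [
    ((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)),
    ((0, 0, 0), (1, 0, 0), (1, 0, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 1, 1)),
    ((0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1)),
]


def _structured_box(spec: TTubuleSpec, h: float):
    nx = max(2, round(spec.box_x / h))
    ny = max(2, round(spec.box_y / h))
    nz = max(2, round(spec.box_depth / h))
    xs = np.linspace(0.0, spec.box_x, nx + 1)
    ys = np.linspace(0.0, spec.box_y, ny + 1)
    zs = np.linspace(0.0, spec.box_depth, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    tets = np.empty((6 * len(I), 4), dtype=np.int64)
    for p, path in enumerate(_KUHN_PATHS):
        for c, (di, dj, dk) in enumerate(path):
            tets[p::6, c] = vid(I + di, J + dj, K + dk)
    hmin = min(spec.box_x / nx, spec.box_y / ny, spec.box_depth / nz)
    return verts, tets, hmin


def _quad_split(q: tuple[int, int, int, int]):
    """Split a cyclic quad by the diagonal through its lowest-index vertex.

    The rule depends only on the vertex ids, so the two tetrahedra sharing a
    cut face triangulate it identically and the mesh stays conforming.
    """
    m = int(np.argmin(q))
    return [(q[m], q[(m + 1) % 4], q[(m + 2) % 4]),
            (q[m], q[(m + 2) % 4], q[(m + 3) % 4])]


def _carve(verts: np.ndarray, tets: np.ndarray, F: np.ndarray, hmin: float):
    """Remove the F<0 region, cutting crossed tets along the interpolated F=0."""
    # clamp near-zero level values away from zero so cut points stay a
    # bounded fraction along their edges (no sliver elements)
    delta = 0.05 * hmin
    F = np.where(np.abs(F) < delta, np.where(F < 0, -delta, delta), F)

    FT = F[tets]
    inside = FT < 0
    k = inside.sum(axis=1)
    kept = tets[k == 0]
    cut_tets = tets[(k > 0) & (k < 4)]

    new_coords: list[np.ndarray] = []
    new_tets: list[tuple[int, int, int, int]] = []
    n_base = len(verts)
    edge_cache: dict[tuple[int, int], int] = {}

    def coord(v: int) -> np.ndarray:
        return verts[v] if v < n_base else new_coords[v - n_base]

    def cutv(i: int, j: int) -> int:
        lo, hi = (i, j) if i < j else (j, i)
        key = (lo, hi)
        v = edge_cache.get(key)
        if v is not None:
            return v
        t = F[lo] / (F[lo] - F[hi])
        new_coords.append(verts[lo] + t * (verts[hi] - verts[lo]))
        v = n_base + len(new_coords) - 1
        edge_cache[key] = v
        return v

    def cone(faces: list[tuple[int, int, int]]):
        vids = sorted({v for f in faces for v in f})
        c = np.mean([coord(v) for v in vids], axis=0)
        new_coords.append(c)
        apex = n_base + len(new_coords) - 1
        for f in faces:
            new_tets.append((apex, f[0], f[1], f[2]))

    for row in cut_tets:
        ins = F[row] < 0
        out_ids = row[~ins]
        in_ids = row[ins]
        m = len(in_ids)
        if m == 3:
            a = int(out_ids[0])
            p = [cutv(a, int(b)) for b in in_ids]
            new_tets.append((a, p[0], p[1], p[2]))
        elif m == 1:
            d = int(in_ids[0])
            a, b, c = (int(v) for v in out_ids)
            pa, pb, pc = cutv(d, a), cutv(d, b), cutv(d, c)
            faces = [(a, b, c), (pa, pb, pc)]
            faces += _quad_split((a, b, pb, pa))
            faces += _quad_split((b, c, pc, pb))
            faces += _quad_split((c, a, pa, pc))
            cone(faces)
        else:  # m == 2
            a, b = (int(v) for v in out_ids)
            c, d = (int(v) for v in in_ids)
            pac, pad = cutv(a, c), cutv(a, d)
            pbc, pbd = cutv(b, c), cutv(b, d)
            faces = [(a, pac, pad), (b, pbc, pbd)]
            faces += _quad_split((a, b, pbc, pac))
            faces += _quad_split((a, b, pbd, pad))
            faces += _quad_split((pac, pbc, pbd, pad))
            cone(faces)

    all_tets = np.vstack([kept, np.asarray(new_tets, dtype=np.int64).reshape(-1, 4)])
    all_verts = np.vstack([verts, np.asarray(new_coords).reshape(-1, 3)])

    # compact vertex numbering
    used = np.unique(all_tets)
    remap = np.full(len(all_verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    all_tets = remap[all_tets]
    all_verts = all_verts[used]

    # orient all tets positively
    a = all_verts[all_tets[:, 1]] - all_verts[all_tets[:, 0]]
    b = all_verts[all_tets[:, 2]] - all_verts[all_tets[:, 0]]
    c = all_verts[all_tets[:, 3]] - all_verts[all_tets[:, 0]]
    vol = np.einsum("ij,ij->i", a, np.cross(b, c))
    flip = vol < 0
    all_tets[flip, 2], all_tets[flip, 3] = all_tets[flip, 3].copy(), all_tets[flip, 2].copy()
    if np.any(np.abs(vol) < 1e-12 * hmin ** 3):
        raise MeshingError("degenerate tetrahedra after carving")
    return all_verts, all_tets


def _boundary_facets(tets: np.ndarray):
    faces = np.vstack([tets[:, [0, 1, 2]], tets[:, [0, 1, 3]],
                       tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]])
    faces_sorted = np.sort(faces, axis=1)
    _, idx, counts = np.unique(faces_sorted, axis=0, return_index=True, return_counts=True)
    return faces_sorted[idx[counts == 1]]


def _label_facets(verts: np.ndarray, facets: np.ndarray, spec: TTubuleSpec,
                  tol: float) -> np.ndarray:
    labels = np.full(len(facets), TTUBULE_MEMBRANE, dtype=np.int32)
    fv = verts[facets]  # (k, 3, 3)
    on = lambda axis, value: np.all(np.abs(fv[:, :, axis] - value) < tol, axis=1)
    top = on(2, 0.0)
    refl = (on(2, spec.box_depth) | on(0, 0.0) | on(0, spec.box_x)
            | on(1, 0.0) | on(1, spec.box_y))
    labels[refl] = REFLECTIVE
    labels[top] = EXTERNAL_MEMBRANE
    return labels


def generate_ttubule_mesh(spec: TTubuleSpec, target_edge_length: float) -> LabeledMesh:
    """Generate the labeled compartment mesh for ``spec``.

    ``target_edge_length`` (µm) sets the structured-grid spacing; it must not
    exceed the minimum tubule radius so the thinnest part of the lumen is
    resolved by at least two elements across its diameter.
    """
    shape = _build_shape(spec)
    if target_edge_length > spec.radius_min * (1 + 1e-9):
        raise MeshingError(
            f"edge length {target_edge_length} µm does not resolve the minimum "
            f"tubule radius {spec.radius_min} µm")
    verts, tets, hmin = _structured_box(spec, target_edge_length)
    F = shape.level(verts)
    if not np.any(F < 0):
        raise MeshingError("tubule lumen not resolved by the grid")
    all_verts, all_tets = _carve(verts, tets, F, hmin)
    facets = _boundary_facets(all_tets)
    labels = _label_facets(all_verts, facets, spec, tol=1e-6 * hmin)
    mesh = LabeledMesh(all_verts, all_tets, facets, labels, spec=spec)
    mesh.validate()
    return mesh


def compute_geometry_stats(mesh: LabeledMesh) -> GeometryStats:
    """Volumes from signed tetrahedron volumes; areas summed per facet label."""
    areas = mesh.facet_areas()
    if np.any(areas <= 0):
        raise MeshingError("degenerate boundary facet")
    volume = float(np.sum(mesh.tet_volumes()))
    a_tt = float(areas[mesh.facet_labels == TTUBULE_MEMBRANE].sum())
    a_ext = float(areas[mesh.facet_labels == EXTERNAL_MEMBRANE].sum())
    total = a_tt + a_ext
    spec = mesh.spec
    rr = (spec.radius_min, spec.radius_max) if spec else (np.nan, np.nan)
    depth = spec.tubule_depth if spec else np.nan
    return GeometryStats(
        compartment_volume=volume,
        total_membrane_area=total,
        ttubule_area=a_tt,
        external_area=a_ext,
        ttubule_fraction=a_tt / total if total > 0 else np.nan,
        radius_range=rr,
        tubule_depth=depth,
    )


def _point_triangle_distance(P: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from points P (n,3) to triangles tri (n,k,3,3), per candidate."""
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    p = P[:, None, :]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    closest = a + v[..., None] * ab + w[..., None] * ac

    # edge/vertex regions
    region_a = (d1 <= 0) & (d2 <= 0)
    region_b = (d3 >= 0) & (d4 <= d3)
    region_c = (d6 >= 0) & (d5 <= d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.clip(np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0), 0, 1)
        t_ac = np.clip(np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0), 0, 1)
        t_bc = np.clip(np.where((d4 - d3) + (d5 - d6) != 0,
                                (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0), 0, 1)
    edge_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    edge_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    edge_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    closest = np.where(edge_bc[..., None], b + t_bc[..., None] * (c - b), closest)
    closest = np.where(edge_ac[..., None], a + t_ac[..., None] * ac, closest)
    closest = np.where(edge_ab[..., None], a + t_ab[..., None] * ab, closest)
    closest = np.where(region_c[..., None], c, closest)
    closest = np.where(region_b[..., None], b, closest)
    closest = np.where(region_a[..., None], a, closest)
    return np.linalg.norm(p - closest, axis=-1)


def distance_to_membrane_field(mesh: LabeledMesh, points: Optional[np.ndarray] = None,
                               k_candidates: int = 24) -> np.ndarray:
    """Distance (µm) from each vertex (or given points) to the nearest
    membrane-labeled boundary facet; reflective box faces are excluded.

    Candidate facets come from a KD-tree over facet centroids and the exact
    point-triangle distance is taken over the nearest candidates.
    """
    membrane = mesh.facet_labels != REFLECTIVE
    facets = mesh.boundary_facets[membrane]
    if len(facets) == 0:
        raise MeshingError("mesh has no membrane facets")
    tri = mesh.vertices[facets]  # (nf, 3, 3)
    centroids = tri.mean(axis=1)
    tree = cKDTree(centroids)
    P = mesh.vertices if points is None else np.atleast_2d(points)
    k = min(k_candidates, len(facets))
    out = np.empty(len(P))
    chunk = 20000
    for s in range(0, len(P), chunk):
        pts = P[s:s + chunk]
        _, idx = tree.query(pts, k=k)
        idx = np.atleast_2d(idx)
        d = _point_triangle_distance(pts, tri[idx])
        out[s:s + chunk] = d.min(axis=1)
    return out
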