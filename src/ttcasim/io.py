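"""Mesh exchange in Gmsh MSH v2.2 ASCII and legacy VTK unstructured grid.

Boundary facet labels travel as Gmsh physical groups (triangles) and as VTK
cell data.  Both formats are plain text; the volume cells are tetrahedra.
"""

from __future__ import annotations

import numpy as np

from .geometry import LabeledMesh, LABEL_NAMES

_MSH_TRIANGLE = 2
_MSH_TET = 4
_VOLUME_TAG = 10


def write_msh(mesh: LabeledMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write("$PhysicalNames\n%d\n" % (len(LABEL_NAMES) + 1))
        for label, name in sorted(LABEL_NAMES.items()):
            fh.write('2 %d "%s"\n' % (label, name))
        fh.write('3 %d "cytosol"\n' % _VOLUME_TAG)
        fh.write("$EndPhysicalNames\n")
        fh.write("$Nodes\n%d\n" % mesh.n_vertices)
        for i, (x, y, z) in enumerate(mesh.vertices, start=1):
            fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
        fh.write("$EndNodes\n")
        n_elem = len(mesh.boundary_facets) + len(mesh.tetrahedra)
        fh.write("$Elements\n%d\n" % n_elem)
        eid = 1
        for facet, label in zip(mesh.boundary_facets, mesh.facet_labels):
            a, b, c = facet + 1
            fh.write(f"{eid} {_MSH_TRIANGLE} 2 {label} {label} {a} {b} {c}\n")
            eid += 1
        for tet in mesh.tetrahedra:
            a, b, c, d = tet + 1
            fh.write(f"{eid} {_MSH_TET} 2 {_VOLUME_TAG} {_VOLUME_TAG} {a} {b} {c} {d}\n")
            eid += 1
        fh.write("$EndElements\n")


def read_msh(path: str) -> LabeledMesh:
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    nodes = None
    tris, tri_labels, tets = [], [], []
    while i < len(lines):
        line = lines[i].strip()
        if line == "$Nodes":
            n = int(lines[i + 1])
            nodes = np.empty((n, 3))
            for j in range(n):
                parts = lines[i + 2 + j].split()
                nodes[int(parts[0]) - 1] = [float(p) for p in parts[1:4]]
            i += n + 2
        elif line == "$Elements":
            n = int(lines[i + 1])
            for j in range(n):
                parts = lines[i + 2 + j].split()
                etype = int(parts[1])
                ntags = int(parts[2])
                conn = [int(p) - 1 for p in parts[3 + ntags:]]
                if etype == _MSH_TRIANGLE:
                    tris.append(conn)
                    tri_labels.append(int(parts[3]) if ntags else 0)
                elif etype == _MSH_TET:
                    tets.append(conn)
            i += n + 2
        else:
            i += 1
    if nodes is None:
        raise ValueError(f"{path}: no $Nodes section")
    return LabeledMesh(
        vertices=nodes,
        tetrahedra=np.asarray(tets, dtype=np.int64),
        boundary_facets=np.asarray(tris, dtype=np.int64),
        facet_labels=np.asarray(tri_labels, dtype=np.int32),
    )


def write_vtk(mesh: LabeledMesh, path: str,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy VTK ASCII unstructured grid; facet labels as cell data
    (tetrahedra carry label 0), optional nodal scalar fields."""
    ntet = len(mesh.tetrahedra)
    ntri = len(mesh.boundary_facets)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nttcasim mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        fh.write(f"CELLS {ntet + ntri} {5 * ntet + 4 * ntri}\n")
        for tet in mesh.tetrahedra:
            fh.write("4 %d %d %d %d\n" % tuple(tet))
        for tri in mesh.boundary_facets:
            fh.write("3 %d %d %d\n" % tuple(tri))
        fh.write(f"CELL_TYPES {ntet + ntri}\n")
        fh.write("10\n" * ntet)  # VTK_TETRA
        fh.write("5\n" * ntri)   # VTK_TRIANGLE
        fh.write(f"CELL_DATA {ntet + ntri}\n")
        fh.write("SCALARS boundary_label int 1\nLOOKUP_TABLE default\n")
        fh.write("0\n" * ntet)
        fh.write("".join(f"{l}\n" for l in mesh.facet_labels))
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, values in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("".join(f"{v:.17g}\n" for v in values))


def read_vtk(path: str) -> LabeledMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    def find(word):
        return tokens.index(word)
    i = find("POINTS")
    n = int(tokens[i + 1])
    pts = np.array(tokens[i + 3:i + 3 + 3 * n], dtype=float).reshape(n, 3)
    i = find("CELLS")
    ncell = int(tokens[i + 1])
    j = i + 3
    cells = []
    for _ in range(ncell):
        m = int(tokens[j])
        cells.append([int(t) for t in tokens[j + 1:j + 1 + m]])
        j += m + 1
    i = find("CELL_TYPES")
    types = np.array(tokens[i + 2:i + 2 + ncell], dtype=int)
    labels = np.zeros(ncell, dtype=np.int32)
    if "boundary_label" in tokens:
        i = tokens.index("boundary_label")
        j = tokens.index("default", i) + 1
        labels = np.array(tokens[j:j + ncell], dtype=np.int32)
    tets = np.array([c for c, t in zip(cells, types) if t == 10], dtype=np.int64)
    tris = [(c, l) for c, t, l in zip(cells, types, labels) if t == 5]
    return LabeledMesh(
        vertices=pts,
        tetrahedra=tets.reshape(-1, 4),
        boundary_facets=np.array([c for c, _ in tris], dtype=np.int64).reshape(-1, 3),
        facet_labels=np.array([l for _, l in tris], dtype=np.int32),
    )
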