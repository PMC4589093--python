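"""Mesh import/export: Gmsh `.msh` (v2.2 ASCII) and legacy ASCII VTK.

Both dialects are plain text; node indices are 1-based in Gmsh and 0-based
in VTK and are converted at this boundary.  Round-trips preserve node
coordinates to full precision and connectivity exactly.
"""

from __future__ import annotations

import numpy as np

from .errors import ContractError
from .mesh import Mesh, _extract_boundary

__all__ = ["write_msh", "read_msh", "write_vtk", "read_vtk"]

_GMSH_TYPE = {"line": 1, "triangle": 2, "tetra": 4}
_VTK_TYPE = {"line": 3, "triangle": 5, "tetra": 10}


def write_msh(mesh: Mesh, path) -> None:
    """Write Gmsh v2.2 ASCII; boundary facets first, then volume elements."""
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
        f.write(f"{mesh.N}\n")
        for i, p in enumerate(mesh.nodes, start=1):
            x, y = float(p[0]), float(p[1])
            z = float(p[2]) if mesh.dimension == 3 else 0.0
            f.write(f"{i} {x!r} {y!r} {z!r}\n")
        f.write("$EndNodes\n$Elements\n")
        n_el = mesh.P + len(mesh.boundary_facets)
        f.write(f"{n_el}\n")
        eid = 1
        ftype = _GMSH_TYPE["line" if mesh.dimension == 2 else "triangle"]
        for fac in mesh.boundary_facets:
            idx = " ".join(str(v + 1) for v in fac)
            f.write(f"{eid} {ftype} 2 0 1 {idx}\n")
            eid += 1
        etype = _GMSH_TYPE["triangle" if mesh.dimension == 2 else "tetra"]
        for el in mesh.elements:
            idx = " ".join(str(v + 1) for v in el)
            f.write(f"{eid} {etype} 2 0 2 {idx}\n")
            eid += 1
        f.write("$EndElements\n")


def read_msh(path) -> Mesh:
    with open(path) as f:
        lines = [ln.strip() for ln in f]
    try:
        n_start = lines.index("$Nodes") + 1
        n_nodes = int(lines[n_start])
        nodes = []
        for ln in lines[n_start + 1 : n_start + 1 + n_nodes]:
            parts = ln.split()
            nodes.append([float(v) for v in parts[1:4]])
        e_start = lines.index("$Elements") + 1
        n_el = int(lines[e_start])
        tris, tets, lines_1d, facets_2d = [], [], [], []
        for ln in lines[e_start + 1 : e_start + 1 + n_el]:
            parts = ln.split()
            etype = int(parts[1])
            ntags = int(parts[2])
            conn = [int(v) - 1 for v in parts[3 + ntags :]]
            if etype == 1:
                lines_1d.append(conn)
            elif etype == 2:
                tris.append(conn)
            elif etype == 4:
                tets.append(conn)
    except (ValueError, IndexError) as exc:
        raise ContractError(f"malformed Gmsh file {path}") from exc
    nodes = np.asarray(nodes)
    if tets:
        elements = np.asarray(tets)
        facets = np.asarray(tris) if tris else _extract_boundary(elements, 3)
        return Mesh(3, nodes, elements, facets)
    if not tris:
        raise ContractError(f"no volume elements in {path}")
    elements = np.asarray(tris)
    facets = np.asarray(lines_1d) if lines_1d else _extract_boundary(elements, 2)
    return Mesh(2, nodes[:, :2], elements, facets)


def write_vtk(mesh: Mesh, path, point_data: dict | None = None) -> None:
    """Legacy ASCII VTK unstructured grid, optionally with nodal scalar maps."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nfmtwave mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.N} double\n")
        for p in mesh.nodes:
            x, y = float(p[0]), float(p[1])
            z = float(p[2]) if mesh.dimension == 3 else 0.0
            f.write(f"{x!r} {y!r} {z!r}\n")
        nv = mesh.dimension + 1
        f.write(f"CELLS {mesh.P} {mesh.P * (nv + 1)}\n")
        for el in mesh.elements:
            f.write(f"{nv} " + " ".join(str(v) for v in el) + "\n")
        f.write(f"CELL_TYPES {mesh.P}\n")
        ct = _VTK_TYPE["triangle" if mesh.dimension == 2 else "tetra"]
        f.write("\n".join([str(ct)] * mesh.P) + "\n")
        if point_data:
            f.write(f"POINT_DATA {mesh.N}\n")
            for name, arr in point_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(repr(float(v)) for v in np.asarray(arr)) + "\n")


def read_vtk(path) -> Mesh:
    with open(path) as f:
        tokens = f.read().split()
    try:
        i = tokens.index("POINTS")
        n = int(tokens[i + 1])
        coords = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float).reshape(n, 3)
        j = tokens.index("CELLS")
        n_cells = int(tokens[j + 1])
        total = int(tokens[j + 2])
        flat = np.array(tokens[j + 3 : j + 3 + total], dtype=int)
        k = tokens.index("CELL_TYPES")
        types = np.array(tokens[k + 2 : k + 2 + n_cells], dtype=int)
    except (ValueError, IndexError) as exc:
        raise ContractError(f"malformed VTK file {path}") from exc
    cells, pos = [], 0
    for _ in range(n_cells):
        cnt = flat[pos]
        cells.append(flat[pos + 1 : pos + 1 + cnt])
        pos += 1 + cnt
    tets = [c for c, t in zip(cells, types) if t == _VTK_TYPE["tetra"]]
    tris = [c for c, t in zip(cells, types) if t == _VTK_TYPE["triangle"]]
    if tets:
        elements = np.asarray(tets)
        return Mesh(3, coords, elements, _extract_boundary(elements, 3))
    if not tris:
        raise ContractError(f"no triangles or tetrahedra in {path}")
    elements = np.asarray(tris)
    return Mesh(2, coords[:, :2], elements, _extract_boundary(elements, 2))
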