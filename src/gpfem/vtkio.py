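"""Legacy ASCII VTK unstructured-grid I/O for hexahedral meshes.

Writes/reads DATASET UNSTRUCTURED_GRID files with VTK_HEXAHEDRON (type 12)
cells, integer/float CELL_DATA fields (compartment, gp_layer, stresses,
OI) and optional POINT_DATA vectors (displacements).  The format is plain
text and self-contained, so externally produced hexahedral meshes can be
injected into the pipeline through the same path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from gpfem.femur import COMPARTMENTS
from gpfem.hexmesh import HexMesh

VTK_HEXAHEDRON = 12


def write_vtk(path, nodes, elements, cell_data=None, point_data=None, title="gpfem mesh"):
    """Write a hexahedral unstructured grid as legacy ASCII VTK."""
    nodes = np.asarray(nodes, float)
    elements = np.asarray(elements, int)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in nodes]
    lines.append(f"CELLS {len(elements)} {len(elements) * 9}")
    lines += ["8 " + " ".join(map(str, e)) for e in elements]
    lines.append(f"CELL_TYPES {len(elements)}")
    lines += [str(VTK_HEXAHEDRON)] * len(elements)
    if cell_data:
        lines.append(f"CELL_DATA {len(elements)}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                lines.append(f"SCALARS {name} {kind} 1")
                lines.append("LOOKUP_TABLE default")
                fmt = "{:d}" if kind == "int" else "{:.9g}"
                lines += [fmt.format(v) for v in arr.tolist()]
            else:
                lines.append(f"FIELD {name}_field 1")
                lines.append(f"{name} {arr.shape[1]} {len(arr)} double")
                lines += [" ".join(f"{v:.9g}" for v in row) for row in arr]
    if point_data:
        lines.append(f"POINT_DATA {len(nodes)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, float)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{v:.9g}" for v in row) for row in arr]
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.9g}" for v in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path):
    """Read a legacy ASCII VTK hexahedral grid written by :func:`write_vtk`.

    Returns ``(nodes, elements, cell_data, point_data)``.
    """
    tokens = Path(path).read_text().split("\n")
    i = 0
    nodes = elements = None
    cell_data, point_data = {}, {}
    n_cells = n_pts = 0
    section = None
    while i < len(tokens):
        line = tokens[i].strip()
        parts = line.split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n_pts = int(parts[1])
            vals = []
            i += 1
            while len(vals) < 3 * n_pts:
                vals += [float(v) for v in tokens[i].split()]
                i += 1
            nodes = np.asarray(vals).reshape(n_pts, 3)
            continue
        if key == "CELLS":
            n_cells = int(parts[1])
            rows = []
            i += 1
            for _ in range(n_cells):
                row = [int(v) for v in tokens[i].split()]
                if row[0] != 8:
                    raise ValueError("only hexahedron cells are supported")
                rows.append(row[1:])
                i += 1
            elements = np.asarray(rows, int)
            continue
        if key == "CELL_TYPES":
            i += 1 + int(parts[1])
            continue
        if key == "CELL_DATA":
            section = cell_data
            i += 1
            continue
        if key == "POINT_DATA":
            section = point_data
            i += 1
            continue
        if key == "SCALARS" and section is not None:
            name, kind = parts[1], parts[2]
            n = n_cells if section is cell_data else n_pts
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < n:
                vals += tokens[i].split()
                i += 1
            arr = np.asarray(vals, dtype=int if kind == "int" else float)
            section[name] = arr
            continue
        if key == "VECTORS" and section is not None:
            name = parts[1]
            n = n_cells if section is cell_data else n_pts
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals += [float(v) for v in tokens[i].split()]
                i += 1
            section[name] = np.asarray(vals).reshape(n, 3)
            continue
        if key == "FIELD" and section is not None:
            n_arrays = int(parts[2])
            i += 1
            for _ in range(n_arrays):
                name, ncomp, ntup = tokens[i].split()[0], int(tokens[i].split()[1]), int(tokens[i].split()[2])
                i += 1
                vals = []
                while len(vals) < ncomp * ntup:
                    vals += [float(v) for v in tokens[i].split()]
                    i += 1
                section[name] = np.asarray(vals).reshape(ntup, ncomp)
            continue
        i += 1
    if nodes is None or elements is None:
        raise ValueError(f"{path} is not a supported VTK unstructured grid")
    return nodes, elements, cell_data, point_data


def write_hexmesh(path, mesh: HexMesh, extra_cell_data=None, point_data=None):
    cd = dict(
        compartment=np.asarray(mesh.compartment, int),
        gp_layer=np.asarray(mesh.gp_layer, int),
    )
    if extra_cell_data:
        cd.update(extra_cell_data)
    write_vtk(path, mesh.nodes, mesh.elements, cell_data=cd, point_data=point_data)


def read_hexmesh(path, element_size=None) -> HexMesh:
    nodes, elements, cell_data, _ = read_vtk(path)
    if "compartment" not in cell_data or "gp_layer" not in cell_data:
        raise ValueError("mesh file lacks compartment/gp_layer cell data")
    comp = np.asarray(cell_data["compartment"], int)
    if comp.max() >= len(COMPARTMENTS) or comp.min() < 0:
        raise ValueError("compartment codes out of range")
    if element_size is None:
        edge = np.linalg.norm(nodes[elements[0, 1]] - nodes[elements[0, 0]])
        element_size = float(edge)
    return HexMesh(
        nodes=nodes,
        elements=elements,
        compartment=comp.astype(np.int8),
        gp_layer=np.asarray(cell_data["gp_layer"], int),
        element_size=element_size,
    )
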