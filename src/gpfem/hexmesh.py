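"""Growth-plate-aligned all-hexahedral meshing of femur geometry.

The femur is rotated so the growth plate's principal orientation lies in
the XY plane (plate normal along +Z, pointing proximally).  A structured
grid is then built whose vertical node levels follow the plate's spherical
shells inside the plate region -- producing exactly ten conforming element
layers of equal height (thickness/10) along the local plate normal -- and
relax to uniform voxel levels elsewhere.  Elements are kept when their
centroid falls inside a compartment; labels come from the compartment
point-containment tests.

Element connectivity uses the standard 8-node hexahedron ordering (bottom
quad counter-clockwise, then top quad), giving positive Jacobians for the
monotone level stacks by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from gpfem.femur import COMPARTMENTS

N_GP_LAYERS = 10

# corner -> (neighbor_a, neighbor_b, neighbor_c) whose edge triple spans a
# right-handed frame on the reference cube
_CORNER_TABLE = (
    (1, 3, 4),
    (2, 0, 5),
    (3, 1, 6),
    (0, 2, 7),
    (7, 5, 0),
    (4, 6, 1),
    (5, 7, 2),
    (6, 4, 3),
)


class MeshingError(RuntimeError):
    pass


@dataclass
class HexMesh:
    nodes: np.ndarray  # (N, 3) mm
    elements: np.ndarray  # (E, 8) int
    compartment: np.ndarray  # (E,) int index into COMPARTMENTS
    gp_layer: np.ndarray  # (E,) 0 = not plate, 1 (proximal) .. 10 (distal)
    element_size: float
    surface_nodes: np.ndarray = field(default=None)  # node indices
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.surface_nodes is None:
            self.surface_nodes = boundary_nodes(self.elements)

    @property
    def compartment_labels(self) -> np.ndarray:
        return np.array([COMPARTMENTS[i] for i in self.compartment])

    def compartment_mask(self, name: str) -> np.ndarray:
        return self.compartment == COMPARTMENTS.index(name)

    def element_coords(self, idx=None) -> np.ndarray:
        els = self.elements if idx is None else self.elements[idx]
        return self.nodes[els]

    def centroids(self, idx=None) -> np.ndarray:
        return self.element_coords(idx).mean(axis=1)

    def surface_nodes_of(self, name: str) -> np.ndarray:
        """Boundary nodes belonging to elements of one compartment."""
        mask = self.compartment_mask(name)
        nodes = np.unique(self.elements[mask])
        return np.intersect1d(nodes, self.surface_nodes, assume_unique=False)


_FACES = np.array(
    [[0, 1, 2, 3], [4, 5, 6, 7], [0, 1, 5, 4], [1, 2, 6, 5], [2, 3, 7, 6], [3, 0, 4, 7]]
)


def boundary_faces(elements: np.ndarray):
    """Faces that belong to exactly one element: (quad node ids, element id)."""
    faces = elements[:, _FACES]  # (E, 6, 4)
    flat = faces.reshape(-1, 4)
    key = np.sort(flat, axis=1)
    order = np.lexsort(key.T)
    sk = key[order]
    dup = np.concatenate([[False], (sk[1:] == sk[:-1]).all(axis=1)])
    single = ~dup & ~np.concatenate([dup[1:], [False]])
    idx = order[single]
    return flat[idx], idx // 6


def boundary_nodes(elements: np.ndarray) -> np.ndarray:
    quads, _ = boundary_faces(elements)
    return np.unique(quads)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def align_to_growth_plate(fss):
    """Rotate the surface set so the plate's main orientation is the XY plane.

    PCA of the growth-plate vertex cloud; the least-variance direction
    becomes +Z (oriented proximally, toward the femoral head).  Returns the
    rotated surface set and the absolute 4x4 rotation applied.
    """
    plate = fss.compartments["growth_plate"]
    verts = np.asarray(plate.vertices, float)
    centered = verts - verts.mean(axis=0)
    cov = centered.T @ centered / len(verts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-6 * max(evals[2], 1.0):
        raise MeshingError("growth-plate vertex cloud is degenerate (line-like)")
    normal = evecs[:, 0]
    toward_head = fss.landmarks["head_center"] - verts.mean(axis=0)
    if np.dot(normal, toward_head) < 0:
        normal = -normal
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    c = float(np.dot(normal, z))
    R = np.eye(3)
    if np.linalg.norm(v) > 1e-12:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K / (1.0 + c)
    elif c < 0:
        R = np.diag([1.0, -1.0, -1.0])
    T = np.eye(4)
    T[:3, :3] = R
    return fss.transformed(T), T


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


def _plate_sphere(fss):
    """Plate mid-sphere (center, mid radius, thickness) in the current frame."""
    meta = fss.meta or {}
    if "gp_center" in meta and "gp_sphere_radius" in meta:
        return (
            np.asarray(meta["gp_center"], float),
            float(meta["gp_sphere_radius"]),
            float(meta["gp_thickness"]),
        )
    from gpfem.geometry import plate_sphere_decomposition

    toward = fss.landmarks["head_center"] - fss.compartments["growth_plate"].vertices.mean(axis=0)
    center, radius, thickness, _ = plate_sphere_decomposition(
        fss.compartments["growth_plate"], toward_head=toward
    )
    return center, radius, thickness


def build_hex_mesh(fss, element_size: float = 1.5, drop_minor_components: float = 0.02) -> HexMesh:
    """Build the growth-plate-aligned hexahedral mesh of an aligned femur.

    ``fss`` must already be aligned (plate normal along +Z, e.g. via
    :func:`align_to_growth_plate`).  The ten plate layers are bounded by
    spherical shells with exactly ``thickness/10`` radial spacing; all other
    levels are near-uniform with spacing ~``element_size``.
    """
    if element_size <= 0:
        raise MeshingError("element_size must be positive")
    if fss.params is not None and element_size > fss.params.cortical_thickness:
        raise MeshingError(
            f"element_size {element_size} mm exceeds the cortical thickness "
            f"{fss.params.cortical_thickness} mm (thinnest compartment)"
        )
    center, R_mid, thickness = _plate_sphere(fss)
    r_b = R_mid - 0.5 * thickness
    normal = fss.meta.get("gp_normal")
    if normal is not None and abs(float(np.asarray(normal)[2])) < 0.99:
        raise MeshingError("surface set is not aligned: plate normal must be +Z")

    lo, hi = np.asarray(fss.full_surface.bounds, float)
    h = float(element_size)
    margin = 0.51 * h
    xs = np.arange(lo[0] - margin, hi[0] + margin + h, h)
    ys = np.arange(lo[1] - margin, hi[1] + margin + h, h)
    z_min, z_max = lo[2] - margin, hi[2] + margin

    X, Y = np.meshgrid(xs, ys, indexing="ij")
    rho = np.hypot(X - center[0], Y - center[1])
    rho_cl = np.minimum(rho, 0.95 * r_b)
    shell_r = r_b + np.arange(N_GP_LAYERS + 1) * (thickness / N_GP_LAYERS)
    shells = center[2] + np.sqrt(
        shell_r[None, None, :] ** 2 - rho_cl[:, :, None] ** 2
    )  # (nx, ny, 11)
    z_b, z_t = shells[:, :, 0], shells[:, :, -1]
    if np.any(z_b <= z_min) or np.any(z_t >= z_max):
        z_min = min(z_min, float(z_b.min()) - 2 * h)
        z_max = max(z_max, float(z_t.max()) + 2 * h)
    n_below = max(1, int(round((np.median(z_b) - z_min) / h)))
    n_above = max(1, int(round((z_max - np.median(z_t)) / h)))

    nx, ny = xs.size, ys.size
    frac_b = np.linspace(0.0, 1.0, n_below + 1)
    below = z_min + (z_b[:, :, None] - z_min) * frac_b[None, None, :]
    frac_a = np.linspace(0.0, 1.0, n_above + 1)
    above = z_t[:, :, None] + (z_max - z_t[:, :, None]) * frac_a[None, None, :]
    levels = np.concatenate([below, shells[:, :, 1:-1], above], axis=2)  # (nx,ny,K+1)
    n_levels = levels.shape[2]
    n_cells_z = n_levels - 1
    band_lo, band_hi = n_below, n_below + N_GP_LAYERS  # plate cells: band_lo <= k < band_hi

    # cell centroids (vectorized over the structured grid)
    cx = 0.5 * (xs[:-1] + xs[1:])
    cy = 0.5 * (ys[:-1] + ys[1:])
    zc = 0.25 * (
        levels[:-1, :-1, :] + levels[1:, :-1, :] + levels[:-1, 1:, :] + levels[1:, 1:, :]
    )
    zc = 0.5 * (zc[:, :, :-1] + zc[:, :, 1:])  # (nx-1, ny-1, ncz)
    CX, CY = np.meshgrid(cx, cy, indexing="ij")
    cents = np.stack(
        [
            np.broadcast_to(CX[:, :, None], zc.shape),
            np.broadcast_to(CY[:, :, None], zc.shape),
            zc,
        ],
        axis=-1,
    ).reshape(-1, 3)

    label = np.full(len(cents), -1, dtype=np.int8)
    for ci, name in enumerate(COMPARTMENTS):
        todo = label < 0
        if not todo.any():
            break
        # cheap bbox prefilter per compartment
        blo, bhi = np.asarray(fss.compartments[name].bounds, float)
        cand = todo & np.all((cents >= blo - h) & (cents <= bhi + h), axis=1)
        if cand.any():
            inside = fss.contains(name, cents[cand])
            idx = np.where(cand)[0][inside]
            label[idx] = ci

    shape = zc.shape
    label3 = label.reshape(shape)
    kk = np.broadcast_to(np.arange(n_cells_z)[None, None, :], shape)
    in_band = (kk >= band_lo) & (kk < band_hi)
    gp_code = COMPARTMENTS.index("growth_plate")
    # plate label outside its band cannot be meshed in layers; reassign
    stray = (label3 == gp_code) & ~in_band
    if stray.any():
        label3[stray] = COMPARTMENTS.index("proximal_trabecular")
    gp_layer3 = np.where(
        (label3 == gp_code) & in_band, band_lo + N_GP_LAYERS - kk, 0
    ).astype(np.int16)

    keep = label3.reshape(-1) >= 0
    if keep.sum() == 0:
        raise MeshingError("no elements inside the femur; check alignment/units")

    # connectivity: global node index (i, j, k) -> i*(ny*n_levels) + j*n_levels + k
    ii, jj, kk2 = np.unravel_index(np.where(keep)[0], shape)

    def nid(i, j, k):
        return (i * ny + j) * n_levels + k

    conn = np.stack(
        [
            nid(ii, jj, kk2),
            nid(ii + 1, jj, kk2),
            nid(ii + 1, jj + 1, kk2),
            nid(ii, jj + 1, kk2),
            nid(ii, jj, kk2 + 1),
            nid(ii + 1, jj, kk2 + 1),
            nid(ii + 1, jj + 1, kk2 + 1),
            nid(ii, jj + 1, kk2 + 1),
        ],
        axis=1,
    )
    used, inverse = np.unique(conn, return_inverse=True)
    elements = inverse.reshape(conn.shape).astype(np.int64)
    ui, uj, uk = np.unravel_index(used, (nx, ny, n_levels))
    nodes = np.column_stack([xs[ui], ys[uj], levels[ui, uj, uk]])

    compartment = label3.reshape(-1)[keep].astype(np.int8)
    gp_layer = gp_layer3.reshape(-1)[keep]

    mesh = HexMesh(
        nodes=nodes,
        elements=elements,
        compartment=compartment,
        gp_layer=gp_layer,
        element_size=h,
        meta=dict(
            plate_center=center,
            plate_mid_radius=R_mid,
            plate_thickness=thickness,
            n_below=n_below,
            n_above=n_above,
        ),
    )
    mesh = _largest_component(mesh, drop_minor_components)
    if not np.any(mesh.gp_layer > 0):
        raise MeshingError("mesh contains no growth-plate layers")
    return mesh


def _largest_component(mesh: HexMesh, tol_fraction: float) -> HexMesh:
    """Keep the dominant connected component; tiny voxel droplets are noise."""
    e = mesh.elements
    n = len(mesh.nodes)
    rows = e.ravel()
    cols = np.repeat(e[:, 0], 8)
    graph = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    ncomp, labels = connected_components(graph + graph.T, directed=False)
    if ncomp == 1:
        return mesh
    el_comp = labels[e[:, 0]]
    counts = np.bincount(el_comp)
    main = int(np.argmax(counts))
    dropped = (el_comp != main).sum()
    if dropped > tol_fraction * len(e):
        raise MeshingError(
            f"mesh splits into {ncomp} components; {dropped} of {len(e)} "
            "elements disconnected -- geometry likely infeasible"
        )
    if dropped:
        warnings.warn(f"dropping {dropped} disconnected voxel elements", stacklevel=2)
    keep = el_comp == main
    return _subset(mesh, keep)


def _subset(mesh: HexMesh, keep: np.ndarray) -> HexMesh:
    e = mesh.elements[keep]
    used, inv = np.unique(e, return_inverse=True)
    return HexMesh(
        nodes=mesh.nodes[used],
        elements=inv.reshape(e.shape),
        compartment=mesh.compartment[keep],
        gp_layer=mesh.gp_layer[keep],
        element_size=mesh.element_size,
        meta=dict(mesh.meta),
    )


# ---------------------------------------------------------------------------
# quality
# ---------------------------------------------------------------------------


def scaled_jacobians(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Corner-based scaled Jacobian per element (min over the 8 corners)."""
    X = nodes[elements]  # (E, 8, 3)
    mins = np.full(len(elements), np.inf)
    for c, (na, nb, nc) in enumerate(_CORNER_TABLE):
        ea = X[:, na] - X[:, c]
        eb = X[:, nb] - X[:, c]
        ec = X[:, nc] - X[:, c]
        det = np.einsum("ij,ij->i", np.cross(ea, eb), ec)
        norm = (
            np.linalg.norm(ea, axis=1)
            * np.linalg.norm(eb, axis=1)
            * np.linalg.norm(ec, axis=1)
        )
        mins = np.minimum(mins, det / np.maximum(norm, 1e-300))
    return mins


def jacobian_audit(mesh: HexMesh, repair: bool = True, relax_iters: int = 10):
    """Scaled-Jacobian audit with the relax-or-remove repair policy.

    Elements with non-positive scaled Jacobian are repaired by local node
    relaxation (Laplacian averaging of the offending elements' interior
    nodes); plate-boundary offenders that resist relaxation are removed
    (they sit at the outer rim of the growth plate); an unrepairable
    interior element is a hard error.  Returns ``(jacobians, mesh)``.
    """
    jac = scaled_jacobians(mesh.nodes, mesh.elements)
    if not repair or np.all(jac > 0):
        return jac, mesh
    work = HexMesh(
        nodes=mesh.nodes.copy(),
        elements=mesh.elements,
        compartment=mesh.compartment,
        gp_layer=mesh.gp_layer,
        element_size=mesh.element_size,
        surface_nodes=mesh.surface_nodes,
        meta=dict(mesh.meta),
    )
    surface = set(work.surface_nodes.tolist())
    # node adjacency for relaxation
    for _ in range(relax_iters):
        jac = scaled_jacobians(work.nodes, work.elements)
        bad = np.where(jac <= 0)[0]
        if bad.size == 0:
            return jac, work
        bad_nodes = np.unique(work.elements[bad])
        bad_nodes = np.array([nd for nd in bad_nodes if nd not in surface], dtype=int)
        if bad_nodes.size == 0:
            break
        for nd in bad_nodes:
            els = np.any(work.elements == nd, axis=1)
            neigh = np.unique(work.elements[els])
            neigh = neigh[neigh != nd]
            work.nodes[nd] = 0.7 * work.nodes[nd] + 0.3 * work.nodes[neigh].mean(axis=0)
    jac = scaled_jacobians(work.nodes, work.elements)
    bad = np.where(jac <= 0)[0]
    if bad.size == 0:
        return jac, work
    # removal allowed only for plate elements on the outer boundary
    _, bel = boundary_faces(work.elements)
    boundary_els = np.unique(bel)
    removable = np.isin(bad, boundary_els) & (work.gp_layer[bad] > 0)
    if not np.all(removable):
        raise MeshingError(
            f"{(~removable).sum()} interior elements have non-positive Jacobian "
            "and could not be repaired"
        )
    keep = np.ones(len(work.elements), dtype=bool)
    keep[bad] = False
    warnings.warn(f"removed {bad.size} low-quality plate rim elements", stacklevel=2)
    out = _subset(work, keep)
    return scaled_jacobians(out.nodes, out.elements), out


# ---------------------------------------------------------------------------
# convergence study
# ---------------------------------------------------------------------------


def convergence_study(fss_aligned, sizes, instances, material_set=None, oi_config=None):
    """Mean osteogenic index on the evaluation layer vs element size.

    Runs the mesh -> materials -> loads -> solve -> OI pipeline for each
    element size and reports the relative change between successive
    refinements.  Returns a list of dict rows.
    """
    from gpfem import fe, osteogenic

    if len(sizes) < 2:
        raise ValueError("need at least two element sizes")
    material_set = material_set or fe.MATERIAL_SETS["hard"]
    oi_config = oi_config or osteogenic.OIConfig()
    rows = []
    prev = None
    for size in sizes:
        mesh = build_hex_mesh(fss_aligned, element_size=size)
        _, mesh = jacobian_audit(mesh)
        model = fe.build_model(mesh, fss_aligned, instances, material_set)
        stresses = fe.solve_all(model)
        oi = osteogenic.compute_oi(stresses, oi_config, mesh)
        mean_oi = float(np.mean(oi.oi))
        rel = np.nan if prev is None else abs(mean_oi - prev) / max(abs(prev), 1e-12)
        rows.append(
            dict(
                element_size=float(size),
                n_elements=len(mesh.elements),
                mean_oi=mean_oi,
                rel_change=rel,
            )
        )
        prev = mean_oi
    return rows
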