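"""Parametric synthetic femur geometry.

Builds a stylized pediatric femur from analytic primitives, split into the
five compartments used for growth-plate finite-element analysis: proximal
trabecular bone (femoral head epiphysis + neck metaphysis), the growth
plate (physis), the cortical shaft, the bone marrow cavity and a distal
trabecular (condylar) block.

Coordinate convention (right femur): right-handed frame with
``X`` anterior, ``Y`` proximal, ``Z`` lateral.  Left femurs are mirror
images across the X-Y (sagittal) plane.  Units are millimetres.

The geometry is deliberately schematic -- capped cylinders, spheres and
spherical-shell caps -- but every morphological parameter that the
downstream estimators measure (neck-shaft angle, anteversion, neck length,
growth-plate sphere radius/convexity) is embedded exactly, so the
generator doubles as a ground-truth oracle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

COMPARTMENTS = (
    "proximal_trabecular",
    "growth_plate",
    "cortical_shaft",
    "bone_marrow",
    "distal_trabecular",
)

# ratio of neck cylinder radius to femoral head radius
NECK_RADIUS_RATIO = 0.72
# condylar block: barrel radius and half-width relative to shaft outer radius
CONDYLE_RADIUS_RATIO = 1.6
CONDYLE_HALFWIDTH_RATIO = 1.8
# condyle barrel axis offset below the shaft (fraction of barrel radius)
CONDYLE_DROP_RATIO = 0.7


class InfeasibleFemurError(ValueError):
    """Requested femur parameters cannot produce a valid geometry."""


@dataclass(frozen=True)
class FemurParams:
    """Ground-truth morphological parameters of a synthetic femur (mm/deg)."""

    head_radius: float = 14.0
    neck_length: float = 46.0
    nsa_deg: float = 133.0
    ava_deg: float = 20.0
    shaft_length: float = 80.0
    shaft_outer_radius: float = 11.0
    cortical_thickness: float = 3.0
    gp_radius: float = 22.0
    gp_thickness: float = 2.5
    side: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = dict(
            head_radius=self.head_radius,
            neck_length=self.neck_length,
            shaft_length=self.shaft_length,
            shaft_outer_radius=self.shaft_outer_radius,
            cortical_thickness=self.cortical_thickness,
            gp_radius=self.gp_radius,
            gp_thickness=self.gp_thickness,
        )
        for name, value in lengths.items():
            if not np.isfinite(value) or value <= 0:
                raise InfeasibleFemurError(f"{name} must be positive, got {value}")
        if self.cortical_thickness >= self.shaft_outer_radius:
            raise InfeasibleFemurError(
                "cortical_thickness must be smaller than shaft_outer_radius"
            )
        if not 90.0 <= self.nsa_deg <= 170.0:
            raise InfeasibleFemurError(f"nsa_deg outside [90, 170]: {self.nsa_deg}")
        if not -20.0 <= self.ava_deg <= 60.0:
            raise InfeasibleFemurError(f"ava_deg outside [-20, 60]: {self.ava_deg}")
        if not 10.0 <= self.gp_radius <= 35.0:
            raise InfeasibleFemurError(
                f"gp_radius outside the supported [10, 35] mm range: {self.gp_radius}"
            )
        if self.side not in ("left", "right"):
            raise InfeasibleFemurError(f"side must be 'left' or 'right': {self.side}")
        _derived_geometry(self)  # raises with a diagnostic when infeasible


def min_neck_length(
    head_radius: float,
    nsa_deg: float,
    gp_radius: float,
    gp_thickness: float = 2.5,
    margin: float = 1.0,
) -> float:
    """Smallest feasible neck length for the given head/angle/plate combination.

    The growth plate (and the metaphysis below it) must clear the plane of
    the shaft top at every azimuth, which couples neck length to the neck
    tilt ``180 - NSA``.
    """
    r_neck = NECK_RADIUS_RATIO * head_radius
    if gp_radius <= r_neck / 0.8:
        raise InfeasibleFemurError(
            f"gp_radius {gp_radius} too small for neck radius {r_neck:.1f} "
            "(growth plate more curved than the neck is wide)"
        )
    beta = np.radians(180.0 - nsa_deg)
    sag = gp_radius - np.sqrt(gp_radius**2 - r_neck**2)
    d_min = head_radius + sag + 0.5 * gp_thickness + r_neck * np.tan(beta) + margin
    return float(head_radius + d_min)


def _derived_geometry(p: FemurParams) -> dict:
    """Internal analytic quantities (right-handed frame, before mirroring)."""
    a = p.head_radius
    r_neck = NECK_RADIUS_RATIO * a
    if p.gp_radius <= r_neck / 0.8:
        raise InfeasibleFemurError(
            f"gp_radius {p.gp_radius} too small for neck radius {r_neck:.2f}"
        )
    d = p.neck_length - a
    if d <= 0:
        raise InfeasibleFemurError("neck_length must exceed head_radius")
    beta = np.radians(180.0 - p.nsa_deg)
    alpha = np.radians(p.ava_deg)
    # neck axis: toward the head, proximal-medial, tipped anteriorly by AVA
    n = np.array(
        [
            np.sin(beta) * np.sin(alpha),
            np.cos(beta),
            -np.sin(beta) * np.cos(alpha),
        ]
    )
    n /= np.linalg.norm(n)
    L = p.shaft_length
    p0 = np.array([0.0, L, 0.0])  # neck origin on the shaft axis (shaft top)
    head_center = p0 + d * n

    s_mid = d - a  # plate mid-surface apex along the neck axis
    s_c = s_mid - p.gp_radius  # plate sphere center (distal of the plate)
    r_bot = p.gp_radius - 0.5 * p.gp_thickness
    r_top = p.gp_radius + 0.5 * p.gp_thickness
    sag = p.gp_radius - np.sqrt(p.gp_radius**2 - r_neck**2)
    s_edge = s_mid - sag - 0.5 * p.gp_thickness  # lowest plate point along axis
    s_join = d - a * np.sqrt(1.0 - NECK_RADIUS_RATIO**2)  # head/neck wall junction
    if s_mid + 0.5 * p.gp_thickness >= s_join:
        raise InfeasibleFemurError(
            "growth plate too thick: its proximal cap reaches the femoral head wall"
        )
    clearance = r_neck * np.tan(beta) + 0.5
    if s_edge < clearance:
        raise InfeasibleFemurError(
            f"neck_length {p.neck_length} too short for NSA {p.nsa_deg}: the "
            f"growth plate would cross the shaft-top plane (need >= "
            f"{min_neck_length(a, p.nsa_deg, p.gp_radius, p.gp_thickness):.1f} mm)"
        )
    r_cond = CONDYLE_RADIUS_RATIO * p.shaft_outer_radius
    return dict(
        r_neck=r_neck,
        d=d,
        beta=beta,
        n=n,
        p0=p0,
        head_center=head_center,
        s_mid=s_mid,
        s_c=s_c,
        r_bot=r_bot,
        r_top=r_top,
        s_edge=s_edge,
        s_join=s_join,
        r_inner=p.shaft_outer_radius - p.cortical_thickness,
        r_cond=r_cond,
        y_cond=-CONDYLE_DROP_RATIO * r_cond,
        w_cond=CONDYLE_HALFWIDTH_RATIO * p.shaft_outer_radius,
        gp_center=p0 + s_c * n,
    )


@dataclass
class FemurSurfaceSet:
    """Five watertight compartment surfaces plus metadata.

    ``meta`` carries the analytic ground truth (axes, plate sphere) in the
    *current* frame; ``transform`` accumulates any rigid/mirror transform
    applied since generation so analytic point-containment tests stay valid.
    """

    compartments: dict
    full_surface: trimesh.Trimesh
    landmarks: dict
    side: str
    params: FemurParams | None = None
    frame: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    transform: np.ndarray = field(default_factory=lambda: np.eye(4))
    _base_contains: dict | None = None

    def contains(self, compartment: str, points: np.ndarray) -> np.ndarray:
        """Vectorized point-in-compartment test (analytic when available)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self._base_contains is not None:
            inv = np.linalg.inv(self.transform)
            local = pts @ inv[:3, :3].T + inv[:3, 3]
            return self._base_contains[compartment](local)
        from gpfem._util import point_in_mesh

        return point_in_mesh(self.compartments[compartment], pts)

    def transformed(self, matrix: np.ndarray) -> "FemurSurfaceSet":
        """Return a copy with a 4x4 homogeneous transform applied."""
        matrix = np.asarray(matrix, dtype=float)
        rot = matrix[:3, :3]

        def _mesh(m: trimesh.Trimesh) -> trimesh.Trimesh:
            out = m.copy()
            out.apply_transform(matrix)
            if out.is_watertight and out.volume < 0:
                out.invert()
            return out

        def _pt(x):
            return rot @ np.asarray(x, float) + matrix[:3, 3]

        def _vec(x):
            v = rot @ np.asarray(x, float)
            return v / np.linalg.norm(v)

        meta = dict(self.meta)
        for key in ("p0", "head_center", "gp_center"):
            if key in meta:
                meta[key] = _pt(meta[key])
        for key in ("neck_dir", "shaft_dir", "gp_normal", "knee_dir"):
            if key in meta:
                meta[key] = _vec(meta[key])
        return FemurSurfaceSet(
            compartments={k: _mesh(v) for k, v in self.compartments.items()},
            full_surface=_mesh(self.full_surface),
            landmarks={k: _pt(v) for k, v in self.landmarks.items()},
            side=self.side,
            params=self.params,
            frame={k: _vec(v) for k, v in self.frame.items()},
            meta=meta,
            transform=matrix @ self.transform,
            _base_contains=self._base_contains,
        )


# ---------------------------------------------------------------------------
# watertight primitive builders
# ---------------------------------------------------------------------------


def _rotation_to(vec: np.ndarray) -> np.ndarray:
    """3x3 rotation taking +Z to ``vec`` by the shortest arc."""
    vec = np.asarray(vec, float)
    vec = vec / np.linalg.norm(vec)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, vec))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, vec)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _finalize(vertices: np.ndarray, faces: list) -> trimesh.Trimesh:
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=True)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _revolve(profile: np.ndarray, sections: int, transform4: np.ndarray) -> trimesh.Trimesh:
    mesh = trimesh.creation.revolve(np.asarray(profile, float), sections=sections)
    mesh.apply_transform(transform4)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _neck_transform(g: dict) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = _rotation_to(g["n"])
    T[:3, 3] = g["p0"]
    return T


def _shaft_transform(L_offset: float = 0.0) -> np.ndarray:
    # revolve axis +Z -> femur frame +Y
    T = np.eye(4)
    T[:3, :3] = _rotation_to(np.array([0.0, 1.0, 0.0])).T @ np.eye(3)
    # simpler: explicit rotation mapping z->y, x->x
    T[:3, :3] = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, -1.0, 0]])
    T[:3, 3] = [0.0, L_offset, 0.0]
    return T


def _metaphysis_mesh(p: FemurParams, g: dict, sections: int) -> trimesh.Trimesh:
    """Neck base: spherical-cap top, cylindrical wall, slanted planar bottom.

    The bottom face lies exactly on the shaft-top plane y = shaft_length, so
    the compartment abuts (never overlaps) the cortical shaft and marrow.
    """
    n = g["n"]
    p0 = g["p0"]
    r_neck = g["r_neck"]
    # orthonormal basis normal to the neck axis
    e1 = np.cross(n, [0.0, 1.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(n, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    S, J, K = sections, 12, 6
    phi = np.linspace(0.0, 2 * np.pi, S, endpoint=False)
    u = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2  # (S,3)

    verts = []
    # top spherical cap (bottom surface of the growth plate), polar grid
    verts.append(p0 + (g["s_c"] + g["r_bot"]) * n)  # apex, index 0
    ring_index = []
    for j in range(1, J + 1):
        rho = r_neck * j / J
        s = g["s_c"] + np.sqrt(g["r_bot"] ** 2 - rho**2)
        ring_index.append(len(verts))
        verts.extend(p0 + s * n + rho * u)
    # wall rows from cap edge down to the slanted plane
    s_top = g["s_c"] + np.sqrt(g["r_bot"] ** 2 - r_neck**2)
    s_plane = -r_neck * u[:, 1] / n[1]  # wall meets plane y = shaft_length
    wall_rows = []
    for k in range(1, K + 1):
        t = k / K
        s_row = (1 - t) * s_top + t * s_plane
        wall_rows.append(len(verts))
        verts.extend(p0 + s_row[:, None] * n + r_neck * u)
    # bottom fan center (centroid of the planar ellipse)
    bottom = np.asarray(verts[wall_rows[-1] : wall_rows[-1] + S])
    center_idx = len(verts)
    verts.append(bottom.mean(axis=0))

    faces = []
    # apex fan
    first = ring_index[0]
    for i in range(S):
        faces.append([0, first + i, first + (i + 1) % S])
    # cap quads
    for j in range(len(ring_index) - 1):
        a0, b0 = ring_index[j], ring_index[j + 1]
        for i in range(S):
            i2 = (i + 1) % S
            faces.append([a0 + i, b0 + i, b0 + i2])
            faces.append([a0 + i, b0 + i2, a0 + i2])
    # wall quads (cap edge ring is ring_index[-1])
    rows = [ring_index[-1]] + wall_rows
    for j in range(len(rows) - 1):
        a0, b0 = rows[j], rows[j + 1]
        for i in range(S):
            i2 = (i + 1) % S
            faces.append([a0 + i, b0 + i, b0 + i2])
            faces.append([a0 + i, b0 + i2, a0 + i2])
    # bottom fan
    b0 = wall_rows[-1]
    for i in range(S):
        faces.append([center_idx, b0 + (i + 1) % S, b0 + i])
    return _finalize(np.asarray(verts), faces)


def _condyle_mesh(p: FemurParams, g: dict, sections: int) -> trimesh.Trimesh:
    """Distal trabecular block: circular-segment prism along the knee (Z) axis."""
    r_c, y_c, w = g["r_cond"], g["y_cond"], g["w_cond"]
    th0 = np.arcsin(min(1.0, -y_c / r_c))
    # arc below y=0, traversed from the +x chord end around the bottom
    theta = np.linspace(np.pi - th0, 2 * np.pi + th0, sections)
    poly = np.column_stack([r_c * np.cos(theta), y_c + r_c * np.sin(theta)])
    m = poly.shape[0]
    bottom = np.column_stack([poly, np.full(m, -w)])
    top = np.column_stack([poly, np.full(m, w)])
    verts = [*bottom, *top]
    cb = len(verts)
    verts.append([poly[:, 0].mean(), poly[:, 1].mean(), -w])
    ct = len(verts)
    verts.append([poly[:, 0].mean(), poly[:, 1].mean(), w])
    faces = []
    for i in range(m):
        i2 = (i + 1) % m
        faces.append([i, i2, m + i2])
        faces.append([i, m + i2, m + i])
        faces.append([cb, i2, i])
        faces.append([ct, m + i, m + i2])
    return _finalize(np.asarray(verts, float), faces)


def _densify(profile: np.ndarray, step: float = 5.0) -> np.ndarray:
    """Insert intermediate points along straight profile segments."""
    out = [profile[:1]]
    for a, b in zip(profile[:-1], profile[1:]):
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / step)))
        seg = np.linspace(a, b, n + 1)[1:]
        out.append(seg)
    return np.vstack(out)


def _cap_profile(g: dict, radius_key: str, r_edge: float, n_pts: int = 24):
    rho = np.linspace(0.0, r_edge, n_pts)
    s = g["s_c"] + np.sqrt(g[radius_key] ** 2 - rho**2)
    return np.column_stack([rho, s])


# ---------------------------------------------------------------------------
# containment (analytic, vectorized; femur frame of a right-handed build)
# ---------------------------------------------------------------------------


def _contains_factory(p: FemurParams, g: dict) -> dict:
    n, p0, L = g["n"], g["p0"], p.shaft_length
    r_i, r_o = g["r_inner"], p.shaft_outer_radius
    r_neck, a = g["r_neck"], p.head_radius
    C, H = g["gp_center"], g["head_center"]

    def _neck_coords(pts):
        rel = pts - p0
        s = rel @ n
        rho = np.linalg.norm(rel - s[:, None] * n, axis=1)
        return s, rho

    def marrow(pts):
        rho = np.hypot(pts[:, 0], pts[:, 2])
        return (rho <= r_i) & (pts[:, 1] >= 0) & (pts[:, 1] <= L)

    def cortical(pts):
        rho = np.hypot(pts[:, 0], pts[:, 2])
        return (rho >= r_i) & (rho <= r_o) & (pts[:, 1] >= 0) & (pts[:, 1] <= L)

    def distal(pts):
        in_barrel = pts[:, 0] ** 2 + (pts[:, 1] - g["y_cond"]) ** 2 <= g["r_cond"] ** 2
        return in_barrel & (np.abs(pts[:, 2]) <= g["w_cond"]) & (pts[:, 1] <= 0)

    def plate(pts):
        s, rho = _neck_coords(pts)
        rad = np.linalg.norm(pts - C, axis=1)
        above = (pts - C) @ n > 0
        return (rho <= r_neck) & (rad >= g["r_bot"]) & (rad <= g["r_top"]) & above

    def proximal(pts):
        s, rho = _neck_coords(pts)
        rad = np.linalg.norm(pts - C, axis=1)
        in_head = np.linalg.norm(pts - H, axis=1) <= a
        in_neck = (rho <= r_neck) & (s <= g["s_join"])
        epi = (in_head | in_neck) & (rad >= g["r_top"]) & (pts[:, 1] >= L)
        meta = (rho <= r_neck) & (rad <= g["r_bot"]) & (pts[:, 1] >= L)
        return epi | meta

    return dict(
        proximal_trabecular=proximal,
        growth_plate=plate,
        cortical_shaft=cortical,
        bone_marrow=marrow,
        distal_trabecular=distal,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_femur(params: FemurParams, sections: int = 64) -> FemurSurfaceSet:
    """Generate the five-compartment surface set for one femur.

    A right femur is constructed analytically; a left femur is its exact
    mirror image across the sagittal (X-Y) plane.  The measured NSA/AVA of
    the output (via :mod:`gpfem.geometry`) equal the requested parameters,
    and the growth plate is a spherical cap of radius ``gp_radius`` whose
    normal follows the neck axis (convex toward the head).
    """
    g = _derived_geometry(params)
    L = params.shaft_length
    r_i, r_o = g["r_inner"], params.shaft_outer_radius

    shaftT = _shaft_transform()
    cortical = _revolve(
        _densify(
            np.array([[r_i, 0.0], [r_o, 0.0], [r_o, L], [r_i, L], [r_i, 0.0]])
        ),
        sections,
        shaftT,
    )
    marrow = _revolve(
        _densify(np.array([[0.0, 0.0], [r_i, 0.0], [r_i, L], [0.0, L]])),
        sections,
        shaftT,
    )

    neckT = _neck_transform(g)
    r_neck = g["r_neck"]
    bot = _cap_profile(g, "r_bot", r_neck)
    top = _cap_profile(g, "r_top", r_neck)
    plate_profile = np.vstack([bot, top[::-1]])
    plate = _revolve(plate_profile, sections, neckT)

    # epiphysis: plate top cap -> neck wall -> head sphere arc
    wall_s = np.linspace(top[-1, 1], g["s_join"], 6)[1:]
    wall = np.column_stack([np.full(wall_s.size, r_neck), wall_s])
    psi_join = np.arcsin(min(1.0, r_neck / params.head_radius))
    psi = np.linspace(psi_join, np.pi, 48)[1:]
    arc = np.column_stack(
        [
            params.head_radius * np.sin(psi),
            g["d"] - params.head_radius * np.cos(psi),
        ]
    )
    epiphysis = _revolve(np.vstack([top, wall, arc]), sections, neckT)

    metaphysis = _metaphysis_mesh(params, g, sections)
    proximal = trimesh.util.concatenate([epiphysis, metaphysis])
    distal = _condyle_mesh(params, g, sections)

    compartments = dict(
        proximal_trabecular=proximal,
        growth_plate=plate,
        cortical_shaft=cortical,
        bone_marrow=marrow,
        distal_trabecular=distal,
    )
    full = trimesh.util.concatenate(list(compartments.values()))
    landmarks = dict(
        head_center=g["head_center"].copy(),
        epicondyle_medial=np.array([0.0, g["y_cond"], -g["w_cond"]]),
        epicondyle_lateral=np.array([0.0, g["y_cond"], g["w_cond"]]),
    )
    meta = dict(
        p0=g["p0"].copy(),
        neck_dir=g["n"].copy(),
        shaft_dir=np.array([0.0, 1.0, 0.0]),
        knee_dir=np.array([0.0, 0.0, 1.0]),
        gp_center=g["gp_center"].copy(),
        gp_sphere_radius=float(params.gp_radius),
        gp_thickness=float(params.gp_thickness),
        gp_footprint_radius=float(r_neck),
        gp_normal=g["n"].copy(),
        head_center=g["head_center"].copy(),
        head_radius=float(params.head_radius),
    )
    frame = dict(
        anterior=np.array([1.0, 0.0, 0.0]),
        proximal=np.array([0.0, 1.0, 0.0]),
        lateral=np.array([0.0, 0.0, 1.0]),
    )
    fss = FemurSurfaceSet(
        compartments=compartments,
        full_surface=full,
        landmarks=landmarks,
        side="right",
        params=params,
        frame=frame,
        meta=meta,
        _base_contains=_contains_factory(params, g),
    )
    if params.side == "left":
        mirror = np.diag([1.0, 1.0, -1.0, 1.0])
        fss = fss.transformed(mirror)
        fss.side = "left"
        # mirroring moves each landmark to the correct anatomical side; only
        # the 'lateral' frame direction needs re-stating (+Z is medial on a
        # left femur)
        fss.frame["lateral"] = np.array([0.0, 0.0, -1.0])
    return fss


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: sampling distributions per profile (mean, sd) and clip ranges
COHORT_DISTRIBUTIONS = {
    "TD": dict(
        head_radius=(14.0, 1.0, 11.5, 17.0),
        gp_radius=(24.0, 3.0, 14.0, 32.0),
        nsa_deg=(133.0, 4.0, 122.0, 145.0),
        ava_deg=(18.0, 6.0, 2.0, 40.0),
        shaft_outer_radius=(11.0, 0.8, 9.0, 13.5),
        cortical_thickness=(3.0, 0.3, 2.2, 4.0),
        shaft_length=(85.0, 6.0, 70.0, 100.0),
        gp_thickness=(2.5, 0.2, 2.0, 3.0),
        size_scale=(1.0, 0.0),
        neck_slack=(3.0, 1.5),
        asym_len=0.01,
        asym_ang=1.5,
    ),
    "CP": dict(
        head_radius=(14.0, 1.2, 11.0, 17.0),
        gp_radius=(24.0, 3.5, 13.0, 33.0),
        nsa_deg=(139.0, 7.0, 118.0, 150.0),
        ava_deg=(30.0, 10.0, 0.0, 50.0),
        shaft_outer_radius=(11.0, 1.0, 8.5, 13.5),
        cortical_thickness=(2.8, 0.4, 2.0, 4.0),
        shaft_length=(85.0, 7.0, 65.0, 100.0),
        gp_thickness=(2.5, 0.25, 2.0, 3.2),
        size_scale=(0.85, 0.05),
        neck_slack=(3.0, 2.0),
        asym_len=0.02,
        asym_ang=3.0,
    ),
}


def _draw(rng: np.random.Generator, spec) -> float:
    mean, sd, lo, hi = spec
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_cohort(n: int, profile: str, seed: int) -> list:
    """Draw ``n`` FemurParams for a synthetic cohort.

    Femurs come in right/left pairs sharing one subject's parameters with a
    small side-to-side asymmetry jitter; consecutive entries ``(2i, 2i+1)``
    belong to subject ``i``.  The CP profile draws smaller overall bone
    sizes and wider NSA/AVA spreads than the TD profile, and a larger
    asymmetry.  Distribution parameters are in :data:`COHORT_DISTRIBUTIONS`.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if profile not in COHORT_DISTRIBUTIONS:
        raise ValueError(f"unknown profile {profile!r}; use 'TD' or 'CP'")
    dist = COHORT_DISTRIBUTIONS[profile]
    rng = np.random.default_rng(seed)
    out: list[FemurParams] = []
    while len(out) < n:
        scale = max(0.6, float(rng.normal(*dist["size_scale"])))
        base = dict(
            head_radius=_draw(rng, dist["head_radius"]) * scale,
            gp_radius=_draw(rng, dist["gp_radius"]) * scale,
            nsa_deg=_draw(rng, dist["nsa_deg"]),
            ava_deg=_draw(rng, dist["ava_deg"]),
            shaft_outer_radius=_draw(rng, dist["shaft_outer_radius"]) * scale,
            cortical_thickness=_draw(rng, dist["cortical_thickness"]) * np.sqrt(scale),
            shaft_length=_draw(rng, dist["shaft_length"]) * scale,
            gp_thickness=_draw(rng, dist["gp_thickness"]),
        )
        base["gp_radius"] = float(np.clip(base["gp_radius"], 10.0, 35.0))
        for side in ("right", "left"):
            if len(out) >= n:
                break
            jl = 1.0 + dist["asym_len"] * rng.standard_normal()
            sub = dict(base)
            for key in ("head_radius", "gp_radius", "shaft_length", "shaft_outer_radius"):
                sub[key] = float(np.clip(sub[key] * jl, *_clip_range(key)))
            sub["nsa_deg"] = float(
                np.clip(sub["nsa_deg"] + dist["asym_ang"] * rng.standard_normal(), 110, 150)
            )
            sub["ava_deg"] = float(
                np.clip(sub["ava_deg"] + dist["asym_ang"] * rng.standard_normal(), 0, 50)
            )
            slack = abs(rng.normal(*dist["neck_slack"]))
            sub["neck_length"] = min_neck_length(
                sub["head_radius"], sub["nsa_deg"], sub["gp_radius"], sub["gp_thickness"]
            ) + slack
            out.append(
                FemurParams(side=side, seed=int(rng.integers(2**31)), **sub)
            )
    return out


def _clip_range(key: str):
    return {
        "head_radius": (8.0, 20.0),
        "gp_radius": (10.0, 35.0),
        "shaft_length": (40.0, 120.0),
        "shaft_outer_radius": (6.0, 16.0),
    }[key]


# ---------------------------------------------------------------------------
# STL + sidecar I/O
# ---------------------------------------------------------------------------


def write_surface_set(
    fss: FemurSurfaceSet, outdir, subject: str, ascii_stl: bool = False
) -> dict:
    """Write one STL per compartment plus a JSON sidecar; returns file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, mesh in fss.compartments.items():
        path = outdir / f"{subject}_{fss.side}_{name}.stl"
        mesh.export(path, file_type="stl_ascii" if ascii_stl else "stl")
        files[name] = str(path)
    sidecar = {
        "subject": subject,
        "side": fss.side,
        "landmarks": {k: list(map(float, v)) for k, v in fss.landmarks.items()},
        "params": dataclasses.asdict(fss.params) if fss.params else None,
    }
    sidecar_path = outdir / f"{subject}_{fss.side}_landmarks.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    files["sidecar"] = str(sidecar_path)
    return files


def read_surface_set(outdir, subject: str, side: str) -> FemurSurfaceSet:
    """Load a surface set written by :func:`write_surface_set`.

    Containment tests fall back to trimesh's watertight-mesh queries, so a
    reloaded set remains usable by the mesher (more slowly).
    """
    outdir = Path(outdir)
    sidecar = json.loads((outdir / f"{subject}_{side}_landmarks.json").read_text())
    compartments = {}
    for name in COMPARTMENTS:
        compartments[name] = trimesh.load(
            outdir / f"{subject}_{side}_{name}.stl", force="mesh"
        )
    params = FemurParams(**sidecar["params"]) if sidecar.get("params") else None
    fss = FemurSurfaceSet(
        compartments=compartments,
        full_surface=trimesh.util.concatenate(list(compartments.values())),
        landmarks={k: np.asarray(v, float) for k, v in sidecar["landmarks"].items()},
        side=sidecar["side"],
        params=params,
    )
    if params is not None:
        # rebuild the analytic oracle for generated geometry
        gen = generate_femur(params)
        fss.meta = gen.meta
        fss.frame = gen.frame
        fss._base_contains = gen._base_contains
        fss.transform = gen.transform
    return fss
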