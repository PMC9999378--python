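"""Shared fixtures: all geometry/mesh/FE inputs are generated at test time.

Session-scoped fixtures cache the expensive stages (meshing, FE solves) so
many tests can probe one solved model.
"""

from __future__ import annotations

import numpy as np
import pytest

from gpfem.femur import FemurParams, generate_femur
from gpfem.hexmesh import HexMesh, align_to_growth_plate, build_hex_mesh


def make_bar_mesh(nx: int, ny: int, nz: int, h: float = 1.0) -> HexMesh:
    """Structured nx x ny x nz unit-cube bar mesh (z is the long axis)."""
    xs, ys, zs = (np.arange(n + 1) * h for n in (nx, ny, nz))
    nodes = np.array([[x, y, z] for x in xs for y in ys for z in zs], float)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    els = [
        [
            nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
            nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
        ]
        for i in range(nx)
        for j in range(ny)
        for k in range(nz)
    ]
    els = np.asarray(els)
    return HexMesh(
        nodes=nodes,
        elements=els,
        compartment=np.zeros(len(els), np.int8),
        gp_layer=np.zeros(len(els), np.int16),
        element_size=h,
    )


@pytest.fixture(scope="session")
def default_params():
    return FemurParams()


@pytest.fixture(scope="session")
def default_fss(default_params):
    return generate_femur(default_params)


@pytest.fixture(scope="session")
def aligned_fss(default_fss):
    aligned, rotation = align_to_growth_plate(default_fss)
    return aligned


@pytest.fixture(scope="session")
def coarse_mesh(aligned_fss):
    return build_hex_mesh(aligned_fss, element_size=2.5)


@pytest.fixture(scope="session")
def solved_femur(default_params):
    """Full single-femur analysis at coarse resolution, with all objects."""
    from gpfem.pipeline import run_single_femur

    return run_single_femur(
        default_params, "TD", element_size=2.5, seed=42, keep_objects=True
    )
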