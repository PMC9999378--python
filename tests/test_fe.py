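"""Finite elements: materials, loads, assembly, solutions, stress recovery."""

import numpy as np
import pytest

from conftest import make_bar_mesh
from gpfem import fe
from gpfem.hexmesh import N_GP_LAYERS


def tributary_end_load(mesh, total, axis=2, end=None, direction=None):
    """Uniform traction on the bar end as tributary nodal forces."""
    nodes = mesh.nodes
    end = nodes[:, axis].max() if end is None else end
    on_end = np.where(np.abs(nodes[:, axis] - end) < 1e-9)[0]
    other = [a for a in range(3) if a != axis]
    f = np.zeros_like(nodes)
    w = np.ones(len(on_end))
    for a in other:
        lo, hi = nodes[:, a].min(), nodes[:, a].max()
        edge = (np.abs(nodes[on_end, a] - lo) < 1e-9) | (
            np.abs(nodes[on_end, a] - hi) < 1e-9
        )
        w *= np.where(edge, 0.5, 1.0)
    d = np.zeros(3)
    d[axis] = 1.0
    if direction is not None:
        d = np.asarray(direction, float)
    f[on_end] = np.outer(w / w.sum() * total, d)
    return f


@pytest.fixture(scope="module")
def bar_model():
    mesh = make_bar_mesh(4, 4, 20)
    E = np.full(len(mesh.elements), 1000.0)
    nu = np.zeros(len(mesh.elements))
    fixed = np.where(mesh.nodes[:, 2] < 1e-9)[0]
    f = tributary_end_load(mesh, total=2.0 * 16.0)  # p = 2 MPa on 16 mm^2
    return fe.FEModel(
        mesh=mesh, element_E=E, element_nu=nu, dirichlet_nodes=fixed, load_cases=[f]
    )


class TestMaterials:
    def test_default_material_table(self):
        hard = fe.MATERIAL_SETS["hard"]
        soft = fe.MATERIAL_SETS["soft"]
        assert hard.young["growth_plate"] == 1000.0
        assert soft.young["growth_plate"] == 100.0
        assert hard.poisson["growth_plate"] == 0.49
        assert hard.young["proximal_trabecular"] == 10000.0
        assert soft.young["proximal_trabecular"] == 2000.0
        assert hard.young["distal_trabecular"] == 10000.0
        assert soft.young["distal_trabecular"] == 5000.0
        assert hard.young["cortical_shaft"] == soft.young["cortical_shaft"] == 20000.0
        assert hard.young["bone_marrow"] == soft.young["bone_marrow"] == 1.0
        for n, v in hard.poisson.items():
            assert v == (0.49 if n == "growth_plate" else 0.3)

    def test_transition_zone_strictly_decreasing_toward_plate(self, coarse_mesh):
        E, nu = fe.assign_materials(coarse_mesh, fe.MATERIAL_SETS["hard"])
        layer_E = {}
        for layer in range(1, N_GP_LAYERS + 1):
            vals = np.unique(E[coarse_mesh.gp_layer == layer])
            assert len(vals) == 1
            layer_E[layer] = vals[0]
        # distal transition layers 8, 9, 10: strictly decreasing toward the plate
        assert layer_E[10] > layer_E[9] > layer_E[8] > 1000.0
        assert layer_E[10] < 10000.0
        for layer in range(1, 8):
            assert layer_E[layer] == 1000.0
        # transition layers keep the plate Poisson ratio
        for layer in (8, 9, 10):
            assert np.all(nu[coarse_mesh.gp_layer == layer] == 0.49)

    def test_transition_values_equally_spaced(self, coarse_mesh):
        E, _ = fe.assign_materials(coarse_mesh, fe.MATERIAL_SETS["hard"])
        vals = [np.unique(E[coarse_mesh.gp_layer == layer])[0] for layer in (10, 9, 8)]
        assert np.allclose(vals, np.linspace(10000.0, 1000.0, 5)[1:-1])

    def test_disabled_transition_gives_sharp_interface(self, coarse_mesh):
        ms = fe.MaterialSet(
            name="hard0",
            young=fe.MATERIAL_SETS["hard"].young,
            poisson=fe.MATERIAL_SETS["hard"].poisson,
            transition_layers=0,
        )
        E, _ = fe.assign_materials(coarse_mesh, ms)
        assert np.all(E[coarse_mesh.gp_layer > 0] == 1000.0)

    def test_evaluation_layer_default(self):
        assert fe.evaluation_layer_default(fe.MATERIAL_SETS["hard"]) == 7


class TestHCFLoad:
    def test_exactly_100_nodes_exact_sum(self, coarse_mesh, aligned_fss):
        hcf = np.array([120.0, -900.0, 260.0])
        loads, info = fe.apply_hcf(
            coarse_mesh, hcf, aligned_fss.landmarks["head_center"]
        )
        loaded = np.where(np.any(loads != 0, axis=1))[0]
        assert len(loaded) == 100
        assert np.allclose(loads.sum(axis=0), hcf, atol=1e-12)
        assert info["patch_area_cm2"] > 0

    def test_zero_vector_zero_load(self, coarse_mesh, aligned_fss):
        loads, _ = fe.apply_hcf(
            coarse_mesh, np.zeros(3), aligned_fss.landmarks["head_center"]
        )
        assert np.all(loads == 0)

    def test_patch_on_the_loaded_side_of_the_head(self, coarse_mesh, aligned_fss):
        head = np.asarray(aligned_fss.landmarks["head_center"])
        hcf = np.array([0.0, 0.0, -1000.0])  # pushing distally (-Z, aligned frame)
        loads, info = fe.apply_hcf(coarse_mesh, hcf, head)
        patch = coarse_mesh.nodes[info["nodes"]]
        # force comes from above: patch sits on the +Z side of the head
        assert (patch - head)[:, 2].mean() > 0


class TestMuscleLoad:
    def test_attachment_on_surface_node_is_chosen(self, coarse_mesh):
        node = coarse_mesh.surface_nodes[10]
        point = coarse_mesh.nodes[node]
        force = np.array([1.0, 2.0, 3.0])
        loads, chosen = fe.apply_muscle_forces(coarse_mesh, [("m", point, force)])
        assert chosen == [node]
        assert np.allclose(loads[node], force)

    def test_total_force_conserved(self, coarse_mesh, aligned_fss):
        rng = np.random.default_rng(0)
        mpls = [
            (f"m{i}", coarse_mesh.nodes[coarse_mesh.surface_nodes[i * 7]], rng.normal(size=3))
            for i in range(6)
        ]
        loads, _ = fe.apply_muscle_forces(coarse_mesh, mpls, frame=aligned_fss.frame)
        total = np.sum([f for _, _, f in mpls], axis=0)
        assert np.allclose(loads.sum(axis=0), total, atol=1e-12)

    def test_quadrant_restriction_matches_bruteforce(self, coarse_mesh, aligned_fss):
        frame = aligned_fss.frame
        prox = frame["proximal"]
        ant = frame["anterior"]
        lat = frame["lateral"]
        surf_idx = coarse_mesh.surface_nodes
        surf = coarse_mesh.nodes[surf_idx]
        # construct an attachment just outside the anterior face of the shaft:
        # displace it so the unrestricted nearest node is posterior
        mid = surf.mean(axis=0)
        height = surf @ prox
        band = np.abs(height - np.median(height)) < 3.0 * coarse_mesh.element_size
        centroid = surf[band].mean(axis=0)
        anterior_nodes = band & ((surf - centroid) @ ant > 2.0) & ((surf - centroid) @ lat > 2.0)
        target = surf[anterior_nodes][0]
        attachment = target + 0.2 * coarse_mesh.element_size * ant

        loads, chosen = fe.apply_muscle_forces(
            coarse_mesh, [("m", attachment, np.array([0.0, 0, 1.0]))], frame=frame
        )
        # brute-force oracle: nearest surface node in the same quadrant
        want = (
            np.sign(np.dot(attachment - centroid, ant)),
            np.sign(np.dot(attachment - centroid, lat)),
        )
        ok = (np.sign((surf - centroid) @ ant) == want[0]) & (
            np.sign((surf - centroid) @ lat) == want[1]
        )
        d = np.linalg.norm(surf - attachment, axis=1)
        oracle = surf_idx[np.where(ok)[0][np.argmin(d[ok])]]
        assert chosen[0] == oracle


class TestAssemblyAndSolve:
    def test_stiffness_symmetric(self, bar_model):
        K = fe.assemble_stiffness(bar_model)
        assert abs(K - K.T).max() < 1e-9 * abs(K).max()

    def test_single_cube_matches_independent_assembly(self):
        # independent oracle: scalar loops over Gauss points and nodes
        mesh = make_bar_mesh(1, 1, 1)
        model = fe.FEModel(
            mesh=mesh,
            element_E=np.array([1.0]),
            element_nu=np.array([0.0]),
            dirichlet_nodes=np.array([0]),
            load_cases=[np.zeros((8, 3))],
        )
        K = fe.assemble_stiffness(model).toarray()

        ref = np.array(
            [
                [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
            ],
            float,
        )
        X = mesh.nodes[mesh.elements[0]]
        gauss = [(a / np.sqrt(3), b / np.sqrt(3), c / np.sqrt(3))
                 for a in (-1, 1) for b in (-1, 1) for c in (-1, 1)]
        D = np.zeros((6, 6))
        D[:3, :3] = 0.0
        for i in range(3):
            D[i, i] = 1.0  # lam=0, mu=0.5 for E=1, nu=0
            D[3 + i, 3 + i] = 0.5
        Ko = np.zeros((24, 24))
        for a, b, c in gauss:
            dN = np.zeros((8, 3))
            for i, (xi, eta, ze) in enumerate(ref):
                dN[i] = [
                    0.125 * xi * (1 + eta * b) * (1 + ze * c),
                    0.125 * (1 + xi * a) * eta * (1 + ze * c),
                    0.125 * (1 + xi * a) * (1 + eta * b) * ze,
                ]
            J = dN.T @ X
            grad = dN @ np.linalg.inv(J).T
            B = np.zeros((6, 24))
            for n in range(8):
                gx, gy, gz = grad[n]
                B[0, 3 * n] = gx
                B[1, 3 * n + 1] = gy
                B[2, 3 * n + 2] = gz
                B[3, 3 * n], B[3, 3 * n + 1] = gy, gx
                B[4, 3 * n + 1], B[4, 3 * n + 2] = gz, gy
                B[5, 3 * n], B[5, 3 * n + 2] = gz, gx
            Ko += B.T @ D @ B * np.linalg.det(J)
        # map element-local dofs onto the global numbering
        gdof = np.array([3 * n + i for n in mesh.elements[0] for i in range(3)])
        Kg = np.zeros((24, 24))
        for p in range(24):
            for q in range(24):
                Kg[p, q] = K[gdof[p], gdof[q]]
        assert np.allclose(Kg, Ko, atol=1e-12)

    def test_rigid_body_modes_in_nullspace(self, bar_model):
        K = fe.assemble_stiffness(bar_model)
        u = np.tile([1.0, -2.0, 0.5], len(bar_model.mesh.nodes))
        assert np.abs(K @ u).max() < 1e-9 * abs(K).max()

    def test_zero_load_zero_displacement(self, bar_model):
        am = fe.AssembledModel(bar_model)
        f = np.zeros(3 * len(bar_model.mesh.nodes))
        u = am.fact.solve(f)
        assert np.all(u == 0)

    def test_reactions_balance_applied_load(self, bar_model):
        sol = fe.solve_instance(bar_model, 0)
        applied = bar_model.load_cases[0].sum(axis=0)
        assert (
            np.linalg.norm(sol.reactions.sum(axis=0) + applied)
            / np.linalg.norm(applied)
            < 1e-8
        )
        assert sol.residual < 1e-8

    def test_superposition(self, bar_model):
        am = fe.AssembledModel(bar_model)
        f = bar_model.load_cases[0].ravel()
        u1 = am.fact.solve(f)
        u2 = am.fact.solve(2.0 * f)
        assert np.allclose(u2, 2.0 * u1, atol=1e-12 * np.abs(u1).max())

    def test_empty_dirichlet_rejected(self, bar_model):
        model = fe.FEModel(
            mesh=bar_model.mesh,
            element_E=bar_model.element_E,
            element_nu=bar_model.element_nu,
            dirichlet_nodes=np.array([], int),
            load_cases=bar_model.load_cases,
        )
        with pytest.raises(fe.SolveError):
            fe.assemble_stiffness(model)


class TestStressRecovery:
    def test_uniaxial_patch_solution(self, bar_model):
        sol = fe.solve_instance(bar_model, 0)
        sf = fe.recover_stresses(bar_model, sol.displacements)
        assert np.abs(sf.tensor[:, 2] - 2.0).max() < 1e-6
        assert np.abs(sf.tensor[:, [0, 1, 3, 4, 5]]).max() < 1e-6
        assert np.allclose(sf.principal[:, 0], 2.0, atol=1e-6)

    def test_hydrostatic_displacement_equal_principals(self):
        mesh = make_bar_mesh(2, 2, 2)
        model = fe.FEModel(
            mesh=mesh,
            element_E=np.full(len(mesh.elements), 500.0),
            element_nu=np.full(len(mesh.elements), 0.3),
            dirichlet_nodes=np.array([0]),
            load_cases=[np.zeros_like(mesh.nodes)],
        )
        u = -0.01 * mesh.nodes  # pure volumetric contraction
        sf = fe.recover_stresses(model, u)
        assert np.allclose(sf.principal[:, 0], sf.principal[:, 1], atol=1e-9)
        assert np.allclose(sf.principal[:, 1], sf.principal[:, 2], atol=1e-9)
        assert np.all(sf.principal[:, 0] < 0)

    def test_principal_invariants_match_tensor(self, solved_femur):
        sf = solved_femur["stresses"][0]
        trace_t = sf.tensor[:, :3].sum(axis=1)
        trace_p = sf.principal.sum(axis=1)
        assert np.allclose(trace_t, trace_p, atol=1e-9 * max(1, np.abs(trace_t).max()))
        assert np.all(np.diff(sf.principal, axis=1) <= 1e-12)

    def test_rotation_leaves_principal_stresses_unchanged(self):
        # same bar solved in a rotated frame: principal values match
        mesh = make_bar_mesh(2, 2, 8)
        E = np.full(len(mesh.elements), 1200.0)
        nu = np.full(len(mesh.elements), 0.25)
        fixed = np.where(mesh.nodes[:, 2] < 1e-9)[0]
        f = tributary_end_load(mesh, total=50.0, direction=[0.6, 0.0, 0.8])
        model = fe.FEModel(mesh=mesh, element_E=E, element_nu=nu,
                           dirichlet_nodes=fixed, load_cases=[f])
        sf0 = fe.recover_stresses(model, fe.solve_instance(model, 0).displacements)

        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1.0],
            ]
        )
        mesh_r = make_bar_mesh(2, 2, 8)
        mesh_r.nodes = mesh_r.nodes @ R.T
        model_r = fe.FEModel(mesh=mesh_r, element_E=E, element_nu=nu,
                             dirichlet_nodes=fixed, load_cases=[f @ R.T])
        sf1 = fe.recover_stresses(model_r, fe.solve_instance(model_r, 0).displacements)
        assert np.abs(sf0.principal - sf1.principal).max() < 1e-6


class TestFemurSolve:
    def test_all_instances_in_equilibrium(self, solved_femur):
        assert max(solved_femur["mesh_info"]["residuals"]) < 1e-8

    def test_nine_load_cases(self, solved_femur):
        assert len(solved_femur["model"].load_cases) == 9
        assert len(solved_femur["stresses"]) == 9

    def test_load_case_totals_match_instances(self, solved_femur):
        for case, li in zip(solved_femur["model"].load_cases, solved_femur["instances"]):
            assert np.allclose(case.sum(axis=0), li.total_force, atol=1e-9)
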