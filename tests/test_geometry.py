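"""Morphology estimators: primitive fits, axes, NSA/AVA, plate metrics."""

import numpy as np
import pytest
import trimesh
from scipy.optimize import least_squares

from gpfem._util import angle_deg
from gpfem.femur import FemurParams, generate_femur, min_neck_length
from gpfem.geometry import (
    DegenerateGeometryError,
    compute_AVA,
    compute_NSA,
    condylar_axis,
    fit_cylinder_axis,
    fit_sphere,
    growth_plate_metrics,
    measure_axes,
    plate_sphere_decomposition,
    shaft_axis,
)


def sphere_cloud(center, radius, n, rng, sigma=0.0):
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = np.asarray(center) + radius * u
    if sigma:
        pts = pts + rng.normal(scale=sigma, size=pts.shape)
    return pts


class TestFitSphere:
    def test_exact_recovery(self):
        pts = sphere_cloud([1, 2, 3], 5.0, 100, np.random.default_rng(0))
        c, r, res = fit_sphere(pts)
        assert np.allclose(c, [1, 2, 3], atol=1e-9)
        assert abs(r - 5.0) < 1e-9

    def test_noisy_recovery_within_relative_tolerance(self):
        rng = np.random.default_rng(1)
        pts = sphere_cloud([1, 2, 3], 5.0, 500, rng, sigma=0.01)
        _, r, _ = fit_sphere(pts)
        assert abs(r - 5.0) < 0.01 * 5.0

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(pts)

    def test_matches_brute_force_nonlinear_least_squares(self):
        rng = np.random.default_rng(2)
        pts = sphere_cloud([0.3, -1.0, 2.0], 4.0, 40, rng, sigma=0.05)
        c, r, _ = fit_sphere(pts)

        def resid(x):
            return np.linalg.norm(pts - x[:3], axis=1) - x[3]

        best = None
        for guess in ([0, 0, 0, 1], [1, -1, 1, 5], [0.3, -1, 2, 4]):
            sol = least_squares(resid, np.array(guess, float), method="lm")
            if best is None or sol.cost < best.cost:
                best = sol
        assert np.allclose(c, best.x[:3], atol=1e-6)
        assert abs(r - best.x[3]) < 1e-6


def cylinder_cloud(q, d, radius, n, rng, length=20.0):
    d = np.asarray(d, float) / np.linalg.norm(d)
    tmp = np.eye(3)[np.argmin(np.abs(d))]
    e1 = np.cross(d, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    t = rng.uniform(-length / 2, length / 2, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    return (
        np.asarray(q, float)
        + t[:, None] * d
        + radius * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )


class TestFitCylinder:
    def test_exact_axis_recovery(self):
        d_true = np.array([0, 1, 1.0]) / np.sqrt(2)
        pts = cylinder_cloud([0.5, -0.3, 0.2], d_true, 3.0, 400, np.random.default_rng(0))
        _, d, radius, rms = fit_cylinder_axis(pts)
        assert angle_deg(d, d_true) < 0.1 or angle_deg(-d, d_true) < 0.1
        assert abs(radius - 3.0) < 1e-6
        assert rms < 1e-8

    def test_constraint_point_on_axis_is_inactive(self):
        d_true = np.array([0.2, 0.9, 0.1])
        q_true = np.array([1.0, 2.0, 3.0])
        pts = cylinder_cloud(q_true, d_true, 2.0, 300, np.random.default_rng(1))
        _, d_free, _, _ = fit_cylinder_axis(pts)
        _, d_con, _, _ = fit_cylinder_axis(pts, through=q_true)
        assert min(angle_deg(d_free, d_con), angle_deg(-d_free, d_con)) < 0.05

    def test_degenerate_cloud_rejected(self):
        pts = np.tile([1.0, 2.0, 3.0], (20, 1))
        with pytest.raises(DegenerateGeometryError):
            fit_cylinder_axis(pts)

    def test_matches_direction_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        d_true = np.array([0.3, 1.0, -0.2])
        pts = cylinder_cloud([0, 0, 0], d_true, 2.5, 50, rng, length=12.0)
        _, d_fit, _, rms_fit = fit_cylinder_axis(pts)

        # oracle: coarse direction grid + local nonlinear polish of the best
        def rms_for(d):
            d = d / np.linalg.norm(d)
            rel = pts - pts.mean(axis=0)
            rho = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
            return np.sqrt(np.mean((rho - rho.mean()) ** 2))

        best_d, best = None, np.inf
        for theta in np.linspace(0, np.pi, 24):
            for phi in np.linspace(0, 2 * np.pi, 48, endpoint=False):
                d = np.array(
                    [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
                )
                v = rms_for(d)
                if v < best:
                    best, best_d = v, d
        _, d_oracle, _, rms_oracle = fit_cylinder_axis(pts, initial_axis=best_d)
        assert abs(rms_fit - rms_oracle) < 1e-6
        assert min(angle_deg(d_fit, d_oracle), angle_deg(-d_fit, d_oracle)) < 1e-3


class TestShaftAxis:
    def test_axis_of_straight_cylinder(self):
        cyl = trimesh.creation.cylinder(radius=10, height=100, sections=48)
        _, d = shaft_axis(cyl, proximal_hint=[0, 0, 1])
        assert angle_deg(d, [0, 0, 1]) < 0.1

    def test_rotated_cylinder_recovers_rotation(self):
        cyl = trimesh.creation.cylinder(radius=10, height=100, sections=48)
        R = trimesh.transformations.rotation_matrix(0.7, [1, 0.2, -0.4])
        cyl.apply_transform(R)
        true = R[:3, :3] @ np.array([0, 0, 1.0])
        _, d = shaft_axis(cyl, proximal_hint=true)
        assert angle_deg(d, true) < 0.1

    def test_direction_points_along_hint(self):
        cyl = trimesh.creation.cylinder(radius=5, height=50, sections=32)
        _, d = shaft_axis(cyl, proximal_hint=[0, 0, -1])
        assert d[2] < 0


class TestCondylarAxis:
    def test_synthetic_condyle_cylinder_axis(self, default_fss):
        q, d, fallback = condylar_axis(
            default_fss.compartments["distal_trabecular"], default_fss.landmarks
        )
        assert not fallback
        assert angle_deg(d, [0, 0, -1]) < 0.5  # lateral -> medial on a right femur

    def test_fallback_to_landmarks_on_degraded_surface(self, default_fss):
        rng = np.random.default_rng(0)
        bad = default_fss.compartments["distal_trabecular"].copy()
        bad.vertices = bad.vertices + rng.normal(scale=4.0, size=bad.vertices.shape)
        q, d, fallback = condylar_axis(bad, default_fss.landmarks, residual_threshold=0.01)
        assert fallback
        med = default_fss.landmarks["epicondyle_medial"]
        lat = default_fss.landmarks["epicondyle_lateral"]
        assert angle_deg(d, med - lat) < 1e-9

    def test_no_fit_no_landmarks_rejected(self):
        rng = np.random.default_rng(1)
        cloud = trimesh.Trimesh(
            vertices=rng.normal(size=(30, 3)), faces=[[0, 1, 2]], process=False
        )
        with pytest.raises(DegenerateGeometryError):
            condylar_axis(cloud, landmarks=None, residual_threshold=1e-9)


class TestAngles:
    def test_nsa_trivial_cases(self):
        assert compute_NSA([0, 1, 0], [0, 1, 0]) == pytest.approx(180.0)
        assert compute_NSA([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_ava_zero_for_aligned_axes(self):
        # neck projecting onto the medial knee direction exactly
        assert compute_AVA([0, 0.5, -0.8], [0, 0, -1]) == pytest.approx(0.0)

    def test_ava_degenerate_projection_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            compute_AVA([0, 1, 0], [0, 0, -1])

    @pytest.mark.parametrize("nsa,ava", [(120.0, 10.0), (135.0, 30.0), (150.0, 50.0)])
    def test_construction_recovery(self, nsa, ava):
        neck_length = max(46.0, min_neck_length(14.0, nsa, 22.0) + 3.0)
        fss = generate_femur(FemurParams(nsa_deg=nsa, ava_deg=ava, neck_length=neck_length))
        ax = measure_axes(fss)
        assert abs(compute_NSA(ax.neck_dir, ax.shaft_dir) - nsa) < 2.0
        assert (
            abs(
                compute_AVA(
                    ax.neck_dir, ax.knee_dir, fss.frame["anterior"], fss.frame["proximal"]
                )
                - ava
            )
            < 2.0
        )

    def test_mirror_invariance_of_scalar_metrics(self):
        kwargs = dict(nsa_deg=135.0, ava_deg=30.0)
        vals = {}
        for side in ("right", "left"):
            fss = generate_femur(FemurParams(side=side, **kwargs))
            ax = measure_axes(fss)
            vals[side] = (
                compute_NSA(ax.neck_dir, ax.shaft_dir),
                compute_AVA(
                    ax.neck_dir, ax.knee_dir, fss.frame["anterior"], fss.frame["proximal"]
                ),
                ax.head_radius,
            )
        assert np.allclose(vals["right"], vals["left"], atol=0.2)

    def test_rigid_motion_invariance(self, default_fss):
        T = trimesh.transformations.rotation_matrix(0.5, [0.3, 1, 0.1])
        T[:3, 3] = [10.0, -4.0, 7.0]
        moved = default_fss.transformed(T)
        ax0 = measure_axes(default_fss)
        ax1 = measure_axes(moved)
        nsa0 = compute_NSA(ax0.neck_dir, ax0.shaft_dir)
        nsa1 = compute_NSA(ax1.neck_dir, ax1.shaft_dir)
        assert abs(nsa0 - nsa1) < 0.3
        ava0 = compute_AVA(
            ax0.neck_dir, ax0.knee_dir, default_fss.frame["anterior"], default_fss.frame["proximal"]
        )
        ava1 = compute_AVA(ax1.neck_dir, ax1.knee_dir, moved.frame["anterior"], moved.frame["proximal"])
        assert abs(ava0 - ava1) < 0.3


class TestGrowthPlateMetrics:
    @pytest.mark.parametrize("gp_radius", [15.0, 20.0, 28.0])
    def test_sphere_radius_and_convexity(self, gp_radius):
        fss = generate_femur(FemurParams(gp_radius=gp_radius))
        _, r, thick, _ = plate_sphere_decomposition(
            fss.compartments["growth_plate"],
            toward_head=fss.meta["neck_dir"],
        )
        assert abs(r - gp_radius) < 0.5
        assert abs(thick - 2.5) < 0.2

    def test_full_metrics_on_default_femur(self, default_fss, default_params):
        ax = measure_axes(default_fss)
        m = growth_plate_metrics(
            default_fss.compartments["growth_plate"],
            ax,
            default_fss.frame,
            proximal_mesh=default_fss.compartments["proximal_trabecular"],
        )
        assert m.convexity == "convex"
        assert abs(m.neck_length - default_params.neck_length) < 1.0
        assert 0.0 <= m.location_normalized <= 1.5
        # normal parallel to a reference vector -> zero angle in all planes
        angles = m.orientation_angles
        assert ("neck_axis", "3D") in angles
        assert angles[("neck_axis", "3D")] < 2.0  # plate normal follows the neck

    def test_parallel_reference_gives_zero_angles(self, default_fss):
        from gpfem.geometry import orientation_angle_table

        v = np.array([0.3, 0.8, -0.5])
        table = orientation_angle_table(v, dict(same=v.copy()), default_fss.frame)
        for plane in ("transverse", "frontal", "sagittal", "3D"):
            assert table[("same", plane)] == pytest.approx(0.0, abs=1e-5)
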