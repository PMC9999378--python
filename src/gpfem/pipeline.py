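"""End-to-end orchestration: cohort -> geometry -> mesh -> FE -> OI -> stats.

One run executes a fixed analysis arm (one loading variant x one material
set) over a synthetic cohort, mirrors the study design's exclusion rules
(femurs whose FE analysis fails are excluded; intra-subject comparisons
drop subjects missing a side), and writes deterministic CSV outputs plus a
JSON run manifest.  Two runs with different arms can be contrasted with
:func:`compare_arms`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gpfem import fe, geometry, growthmap, hexmesh, loading, osteogenic, variability
from gpfem.femur import FemurParams, generate_cohort, generate_femur

#: default body mass (kg) per cohort profile
BODY_MASS = {"TD": 36.8, "CP": 30.1}
#: reference femoral geometry used by the generic-scaled loading variant
GENERIC_REFERENCE = dict(nsa_deg=135.0, ava_deg=20.0)


@dataclass
class PipelineConfig:
    groups: dict = field(default_factory=lambda: {"TD": 2, "CP": 2})  # subjects per profile
    element_size: float = 1.5
    material: str = "hard"
    model_variant: str = "personalized"  # or "generic"
    grid_size: int = 100
    oi_a: float = 0.02
    oi_b: float = 0.01
    outlier_mad_threshold: float = 3.0
    n_trials: int = 5
    seed: int = 0
    outdir: str = "gpfem_run"
    fix_radius: float = 5.0
    render_maps: bool = False
    save_vtk: bool = False
    femur_params: list | None = None  # explicit cohort; overrides `groups`

    def validate(self):
        if self.material not in fe.MATERIAL_SETS:
            raise ValueError(f"material must be one of {list(fe.MATERIAL_SETS)}")
        if self.model_variant not in ("personalized", "generic"):
            raise ValueError("model_variant must be 'personalized' or 'generic'")
        for prof in self.groups:
            if prof not in BODY_MASS:
                raise ValueError(f"unknown profile {prof!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.femur_params:
            d["femur_params"] = [dataclasses.asdict(p) for p in self.femur_params]
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class FemurResult:
    femur_id: str
    subject: str
    side: str
    profile: str
    status: str  # completed | excluded_nonconvergence | failed
    error: str = ""
    stats: growthmap.RegionStats | None = None
    heatmap: growthmap.OIHeatmap | None = None
    oi_field: osteogenic.OIField | None = None
    morphology: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    mesh_info: dict = field(default_factory=dict)


def run_single_femur(
    params: FemurParams,
    profile: str,
    element_size: float = 1.5,
    material: str = "hard",
    model_variant: str = "personalized",
    grid_size: int = 100,
    oi_config: osteogenic.OIConfig | None = None,
    n_trials: int = 5,
    seed: int = 0,
    fix_radius: float = 5.0,
    keep_objects: bool = False,
):
    """The full per-femur analysis; returns a dict of results.

    With ``keep_objects=True`` the intermediate mesh/model/stress objects
    are included (used by examples and the convergence utility).
    """
    timings = {}
    t0 = time.perf_counter()
    fss = generate_femur(params)
    aligned, rotation = hexmesh.align_to_growth_plate(fss)
    timings["geometry"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mesh = hexmesh.build_hex_mesh(aligned, element_size=element_size)
    jac, mesh = hexmesh.jacobian_audit(mesh)
    timings["mesh"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if model_variant == "generic":
        nsa, ava = GENERIC_REFERENCE["nsa_deg"], GENERIC_REFERENCE["ava_deg"]
    else:
        nsa, ava = params.nsa_deg, params.ava_deg
    trials = loading.synthesize_trials(
        profile, n_trials, BODY_MASS[profile], seed,
        femur=aligned, nsa_deg=nsa, ava_deg=ava,
    )
    rep = loading.select_representative_trial(trials)
    instances = loading.select_load_instances(trials[rep])
    timings["loading"] = time.perf_counter() - t0

    material_set = fe.MATERIAL_SETS[material]
    t0 = time.perf_counter()
    model = fe.build_model(mesh, aligned, instances, material_set, fix_radius=fix_radius)
    stresses = fe.solve_all(model)
    timings["fe"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    oi_config = oi_config or osteogenic.OIConfig()
    oi = osteogenic.compute_oi(stresses, oi_config, mesh, material_set=material_set)
    heatmap = growthmap.project_to_grid(
        oi, aligned.frame, grid_size=grid_size, side=params.side
    )
    stats = growthmap.region_stats(heatmap)
    timings["oi"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    axes = geometry.measure_axes(aligned)
    # the bottom faces of layer-5 elements lie on the plate mid-sphere
    mid_nodes = np.unique(mesh.elements[mesh.gp_layer == 5][:, :4])
    gpm = geometry.growth_plate_metrics(
        aligned.compartments["growth_plate"],
        axes,
        aligned.frame,
        hcf_waveform=trials[rep].hcf,
        proximal_mesh=aligned.compartments["proximal_trabecular"],
        mid_points=mesh.nodes[mid_nodes],
    )
    morphology = dict(
        nsa_deg=geometry.compute_NSA(axes.neck_dir, axes.shaft_dir),
        ava_deg=geometry.compute_AVA(
            axes.neck_dir, axes.knee_dir, aligned.frame["anterior"], aligned.frame["proximal"]
        ),
        neck_length=gpm.neck_length,
        head_radius=axes.head_radius,
        gp_sphere_radius=gpm.sphere_radius,
        gp_convexity=gpm.convexity,
        gp_location=gpm.location_distance,
        gp_location_normalized=gpm.location_normalized,
    )
    for (ref, plane), val in gpm.orientation_angles.items():
        morphology[f"angle_{ref}_{plane}"] = val
    timings["morphology"] = time.perf_counter() - t0

    out = dict(
        params=params,
        stats=stats,
        heatmap=heatmap,
        oi_field=oi,
        morphology=morphology,
        timings=timings,
        mesh_info=dict(
            n_nodes=len(mesh.nodes),
            n_elements=len(mesh.elements),
            min_scaled_jacobian=float(jac.min()),
            n_gp_layers=int(len(np.unique(mesh.gp_layer[mesh.gp_layer > 0]))),
            residuals=model.meta.get("residuals", []),
        ),
    )
    if keep_objects:
        out.update(
            fss=fss, aligned=aligned, rotation=rotation, mesh=mesh,
            trials=trials, instances=instances, model=model, stresses=stresses,
        )
    return out


def run_pipeline(config: PipelineConfig):
    """Run the complete multi-femur workflow; returns (manifest, results).

    Per-femur failures are recorded (status ``excluded_nonconvergence`` for
    FE failures, ``failed`` otherwise) and the pipeline continues; paired
    analyses include only subjects with both sides completed.
    """
    config.validate()
    outdir = Path(config.outdir)
    (outdir / "heatmaps").mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(config.seed)

    if config.femur_params is not None:
        cohort = [(p, getattr(p, "_profile", "TD")) for p in config.femur_params]
    else:
        cohort = []
        for gi, (prof, n_subjects) in enumerate(sorted(config.groups.items())):
            params_list = generate_cohort(
                2 * n_subjects, prof, seed=int(root_ss.spawn(1)[0].generate_state(1)[0] % 2**31) + gi
            )
            cohort.extend((p, prof) for p in params_list)

    oi_config = osteogenic.OIConfig(
        a=config.oi_a, b=config.oi_b,
        outlier_mad_threshold=config.outlier_mad_threshold,
    )
    results: list[FemurResult] = []
    counters: dict[str, int] = {}
    for i, (params, prof) in enumerate(cohort):
        subj_idx = i // 2
        femur_seed = int(
            np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % 2**31
        )
        subject = f"{prof}{subj_idx:02d}"
        femur_id = f"{subject}_{params.side}"
        res = FemurResult(
            femur_id=femur_id, subject=subject, side=params.side, profile=prof,
            status="completed",
        )
        try:
            single = run_single_femur(
                params, prof,
                element_size=config.element_size,
                material=config.material,
                model_variant=config.model_variant,
                grid_size=config.grid_size,
                oi_config=oi_config,
                n_trials=config.n_trials,
                seed=femur_seed,
                fix_radius=config.fix_radius,
            )
            res.stats = single["stats"]
            res.heatmap = single["heatmap"]
            res.oi_field = single["oi_field"]
            res.morphology = single["morphology"]
            res.timings = single["timings"]
            res.mesh_info = single["mesh_info"]
        except fe.SolveError as exc:
            res.status = "excluded_nonconvergence"
            res.error = str(exc)
        except Exception as exc:  # noqa: BLE001 - stage errors recorded, run continues
            res.status = "failed"
            res.error = str(exc)
        results.append(res)

    _write_outputs(config, results, outdir)
    manifest = dict(
        config=config.to_dict(),
        config_hash=config.hash(),
        seed=config.seed,
        femurs=[
            dict(
                femur_id=r.femur_id, subject=r.subject, side=r.side, profile=r.profile,
                status=r.status, error=r.error,
                timings={k: round(v, 3) for k, v in r.timings.items()},
                mesh=dict(
                    n_nodes=r.mesh_info.get("n_nodes"),
                    n_elements=r.mesh_info.get("n_elements"),
                ),
            )
            for r in results
        ],
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest, results


def _write_outputs(config: PipelineConfig, results, outdir: Path):
    rows = []
    for r in results:
        row = dict(
            femur_id=r.femur_id, subject=r.subject, side=r.side, profile=r.profile,
            status=r.status,
        )
        if r.stats is not None:
            row.update(
                oi_mean=r.stats.oi_mean, oi_median=r.stats.oi_median,
                oi_range=r.stats.oi_range,
                argmax_region=r.stats.argmax_region, argmin_region=r.stats.argmin_region,
            )
            for reg, val in r.stats.region_means.items():
                row[f"mean_{reg}"] = val
            for reg, val in r.stats.normalized_means.items():
                row[f"norm_{reg}"] = val
        row.update(r.morphology)
        rows.append(row)
    femurs = pd.DataFrame(rows)
    femurs.to_csv(outdir / "femurs.csv", index=False, float_format="%.10g")

    # per-femur OI element tables and heatmap grids
    for r in results:
        if r.oi_field is None:
            continue
        oi = r.oi_field
        pd.DataFrame(
            dict(
                element_id=oi.element_ids,
                centroid_x=oi.centroids[:, 0],
                centroid_y=oi.centroids[:, 1],
                centroid_z=oi.centroids[:, 2],
                oi=oi.oi,
                flag=oi.flags,
            )
        ).to_csv(outdir / f"oi_{r.femur_id}.csv", index=False, float_format="%.10g")
        np.savetxt(
            outdir / "heatmaps" / f"{r.femur_id}_grid.csv",
            r.heatmap.grid, delimiter=",", fmt="%.10g",
        )
        if config.render_maps:
            growthmap.render(r.heatmap, outdir / "heatmaps" / f"{r.femur_id}.png")

    # intra-subject (both sides completed)
    intra_rows = []
    by_subject: dict[str, dict] = {}
    for r in results:
        if r.status == "completed":
            by_subject.setdefault(r.subject, {})[r.side] = r
    for subject, sides in sorted(by_subject.items()):
        if "left" not in sides or "right" not in sides:
            continue
        L, R = sides["left"], sides["right"]
        v = variability.intra_subject(L.stats, R.stats, L.heatmap, R.heatmap)
        intra_rows.append(
            dict(
                subject=subject, profile=L.profile,
                shape_variability=v.shape_variability, raw_ncc=v.raw_ncc,
                mean_diff=v.mean_diff, range_diff=v.range_diff,
                argmax_region_match=v.argmax_region_match,
                argmin_region_match=v.argmin_region_match,
            )
        )
    intra = pd.DataFrame(intra_rows)
    intra.to_csv(outdir / "intra_subject.csv", index=False, float_format="%.10g")

    # inter-subject per group + reference heatmaps
    inter_rows = []
    comp_rows = []
    group_values: dict[str, dict] = {}
    for prof in sorted({r.profile for r in results}):
        done = [r for r in results if r.profile == prof and r.status == "completed"]
        if len(done) >= 2:
            maps = [r.heatmap for r in done]
            scores = variability.inter_subject(maps)
            for r, s in zip(done, scores):
                inter_rows.append(
                    dict(femur_id=r.femur_id, profile=prof, mean_variability=float(s))
                )
            ref = growthmap.reference_heatmap(maps, group_n=len(maps))
            np.savetxt(
                outdir / "heatmaps" / f"reference_{prof}_grid.csv",
                ref.grid, delimiter=",", fmt="%.10g",
            )
            if config.render_maps:
                growthmap.render(ref, outdir / "heatmaps" / f"reference_{prof}.png")
            group_values[prof] = dict(
                oi_mean=[r.stats.oi_mean for r in done],
                oi_range=[r.stats.oi_range for r in done],
                inter_variability=list(map(float, scores)),
                **{
                    f"norm_{reg}": [
                        r.stats.normalized_means[reg]
                        for r in done
                        if reg in r.stats.normalized_means
                    ]
                    for reg in growthmap.REGIONS
                },
            )
    pd.DataFrame(inter_rows).to_csv(
        outdir / "inter_subject.csv", index=False, float_format="%.10g"
    )

    # group comparisons when two groups are available
    profs = sorted(group_values)
    if len(profs) == 2:
        a, b = profs
        for metric in group_values[a]:
            va, vb = group_values[a][metric], group_values[b][metric]
            if len(va) < 2 or len(vb) < 2:
                continue
            for test in ("independent_t", "levene"):
                try:
                    gc = variability.group_compare(va, vb, test=test, metric=metric)
                except ValueError:
                    continue
                comp_rows.append(
                    dict(
                        metric=metric, group_a=a, group_b=b, test=test,
                        statistic=gc.statistic, p_value=gc.p_value,
                        tier=gc.significance_tier,
                        mean_a=gc.mean_a, mean_b=gc.mean_b,
                        sd_a=gc.sd_a, sd_b=gc.sd_b, n_a=gc.n_a, n_b=gc.n_b,
                    )
                )
    pd.DataFrame(comp_rows).to_csv(
        outdir / "group_comparisons.csv", index=False, float_format="%.10g"
    )


def compare_arms(dir_a, dir_b) -> dict:
    """Fraction of femurs whose highest-mean region changed between two runs.

    Both directories must contain ``femurs.csv`` from :func:`run_pipeline`
    over the same femur set.
    """
    fa = pd.read_csv(Path(dir_a) / "femurs.csv")
    fb = pd.read_csv(Path(dir_b) / "femurs.csv")
    if set(fa.femur_id) != set(fb.femur_id):
        raise ValueError("the two runs cover different femur sets")
    merged = fa.merge(fb, on="femur_id", suffixes=("_a", "_b"))
    done = merged[(merged.status_a == "completed") & (merged.status_b == "completed")]
    changed = done[done.argmax_region_a != done.argmax_region_b]
    rows = [
        dict(femur_id=row.femur_id, region_a=row.argmax_region_a,
             region_b=row.argmax_region_b,
             changed=row.argmax_region_a != row.argmax_region_b)
        for row in done.itertuples()
    ]
    return dict(
        n_compared=len(done),
        n_changed=len(changed),
        fraction_changed=float(len(changed) / len(done)) if len(done) else float("nan"),
        rows=rows,
    )
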