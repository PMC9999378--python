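# Methods

This note documents the models, parameters and numerical choices behind
`gpfem`, and what the synthetic data generators do and do not emulate.

## Synthetic femur geometry

The femur is built from analytic primitives in a fixed right-handed frame
(X anterior, Y proximal, Z lateral for a right femur; left femurs are
exact mirror images across the X–Y plane; units mm/N/MPa throughout, which
is self-consistent since N/mm² = MPa):

- **cortical shaft**: hollow circular cylinder (outer radius `shaft_outer_radius`,
  wall `cortical_thickness`, length `shaft_length`);
- **bone marrow**: the enclosed inner cylinder;
- **distal trabecular block**: a circular-segment prism around the knee
  (condylar) axis, carrying the epicondyle landmarks; it abuts the shaft
  at its bottom plane;
- **proximal trabecular bone**: femoral head sphere (radius `head_radius`)
  plus a neck cylinder (radius 0.72·`head_radius`) along the neck axis,
  split by the growth plate into an epiphysis and a metaphysis; the
  metaphysis is cut by the shaft-top plane so compartments never overlap;
- **growth plate**: a constant-thickness spherical shell band
  (mid-surface radius `gp_radius`, thickness `gp_thickness`) spanning the
  full neck cross-section, convex toward the head (sphere center distal).

The neck axis direction encodes the neck-shaft angle (NSA, the 3D angle to
the distal shaft direction) and the anteversion angle (AVA, transverse-plane
angle to the condylar axis, positive anterior). Because the construction is
exact, every downstream estimator can be validated against the requested
parameters; the package's own estimators recover NSA/AVA to well under 1°
and the plate sphere radius to machine precision.

**Feasibility.** The growth plate and the neck base must clear the
shaft-top plane at every azimuth, which couples the minimum neck length to
the neck tilt (180° − NSA): `min_neck_length()` gives the bound, and
infeasible parameter sets are rejected with a diagnostic. The cohort
generator always draws `neck_length` above this bound.

**Scale.** The geometry is a stylized *proximal femur plus short shaft*
(default shaft 80 mm), not a full anatomical femur; no trochanters or
condylar detail are modeled. Head radius, NSA (110–150°), AVA (0–50°) and
plate sphere radius (10–35 mm) defaults sit in the ranges reported for
children. Because the diaphysis is its own compartment, the pipeline fits
the shaft axis to it directly; the generic `shaft_axis` operation (trim
20% off both ends of a surface, dominant inertia axis of area-uniform
samples, polished by a cylinder fit) is exposed for whole-femur input.

**Cohorts.** `generate_cohort(n, profile, seed)` draws n femurs as
right/left pairs sharing one subject's parameters with a small side
asymmetry. The CP profile scales bone sizes by ~0.85 (clinically, CP
femurs are smaller), widens the NSA/AVA spreads, and doubles the
asymmetry jitter relative to TD; all distribution parameters are in
`COHORT_DISTRIBUTIONS`.

## Synthetic gait loading

Hip contact force (HCF) resultants are monotone-segment (PCHIP) waveforms
through five control points — heel strike, first peak (~25% stance),
valley (50%), second peak (~75%), toe-off — which guarantees exactly two
strict local maxima per trial. Peak levels are drawn per trial
(TD: ≈4.0/4.2 body weights, sd 0.2; CP: ≈3.7/3.9, sd 0.45; valley ≈2.6),
so inter-trial variability lives in the control points rather than in
pointwise noise; CP trials are roughly twice as variable as TD. The HCF
direction is mostly distal, tilted toward the neck axis (weight 0.35) with
a small anterior-to-posterior sweep across stance. Five muscles (gluteus
medius/maximus, psoas, adductor magnus, vastus lateralis) act at
parameterized attachment sites with Gaussian activation bumps; nominal
peak forces are scaled by the body-mass ratio to the 2/3 power
(`scale_muscle_strength`), referenced to a 36.8 kg child.

What this emulates: the double-peaked stance HCF, realistic peak
magnitudes (2–6 BW), trial-to-trial variability, larger variability in CP,
and muscle point loads with stable attachment sites. What it does not:
subject-specific gait kinematics, muscle redundancy resolution,
EMG-informed activations, or any coupling between geometry and gait beyond
the HCF orientation. Passing tests therefore demonstrate the correctness
of the mechanics and statistics pipeline, not clinical fidelity of the
load magnitudes.

**Analysis arms.** The "personalized vs generic" loading contrast is
implemented as two variants of the generator: personalized orients the HCF
using the femur's own NSA/AVA; generic uses reference angles (135°/20°).
The "hard vs soft" material contrast uses the two material sets below.

**Load instances.** The representative trial minimizes the RMS difference
of its HCF resultant to the pointwise mean waveform (ties to the lowest
index). Nine instances are the two dominant peaks (after a 3-sample moving
average; if more than two maxima exist, the two largest), the interior
valley, and three equally spaced stance percentages inside each half —
the equal-spacing rule for the six non-anchor instants is this package's
choice and is configurable (`n_between`). Muscle forces are linearly
interpolated at the same stance percentages.

## Hexahedral meshing

The femur is rotated so the plate's least-variance PCA direction (its
normal, oriented toward the head) is +Z. The mesh is a single structured
grid: each vertical node column follows the plate's spherical shells
inside the plate footprint — ten layers bounded by eleven concentric
shells with *exactly* thickness/10 radial spacing (equal height along the
local growth direction; a curved plate cannot have globally equal heights
along the global normal and constant thickness at once) — and relaxes to
near-uniform levels of spacing ≈ `element_size` (default 1.5 mm) above and
below. Elements are kept when their centroid lies inside a compartment
(analytic containment for generated femurs; ray-parity tests for loaded
STL sets); layer 1 is most proximal, layer 10 most distal. Minor
disconnected voxel droplets (< 2% of elements) are discarded; a larger
split is an error. Meshed compartment volumes agree with the analytic
volumes to < 1% at 1.5 mm.

**Quality.** Scaled Jacobians are evaluated at all eight corners (edge
triples per the standard hexahedron corner tables). The structured
construction yields strictly positive Jacobians; the audit's repair policy
(Laplacian relaxation of interior nodes of offending elements, removal of
plate-rim boundary offenders, hard error otherwise) exists for imported
meshes and deliberate distortions. Element sizes larger than the cortical
wall are rejected because the thin shaft shell could not be resolved.

## Finite elements

Standard isoparametric 8-node trilinear hexahedra, 2×2×2 Gauss quadrature,
isotropic linear elasticity in Voigt form (engineering shear). Material
sets ("hard"/"soft"):

| compartment        | E hard (MPa) | E soft (MPa) | ν    |
|--------------------|-------------:|-------------:|------|
| growth plate       | 1000         | 100          | 0.49 |
| proximal trabecular| 10000        | 2000         | 0.3  |
| distal trabecular  | 10000        | 5000         | 0.3  |
| cortical bone      | 20000        | 20000        | 0.3  |
| bone marrow        | 1            | 1            | 0.3  |

The three plate layers adjacent to the distal trabecular bone (layers
8–10) form a transition zone with Young's moduli linearly interpolated
between trabecular and plate values (the three interior points of the
5-point linspace) and the plate's Poisson ratio — the distal side is where
bone mineralizes; the side and layer count are configurable. The
evaluation layer defaults to layer 7, the most distal non-transition
layer.

Boundary conditions: all DOFs fixed at surface nodes within 5 mm (at
least 1.8 element sizes) of each epicondyle landmark. The HCF is split
equally over the 100 head-surface nodes closest to the contact point
(where the force's line of action through the head center pierces the
head), conserving the vector sum exactly; each muscle force is applied at
the surface node nearest its attachment, restricted to the attachment's
anterior/posterior × medial/lateral quadrant of the cross-section at that
height. The solver reduces the fixed DOFs, reorders with reverse
Cuthill–McKee, and factors once per model with sparse LU (natural order);
all nine instances reuse the factorization. A diagonally preconditioned CG
(rtol 1e-10) is the fallback; factorization failure or a relative residual
above 1e-6 marks the femur as excluded, mirroring how non-converging
models drop out of paired analyses. Achieved equilibrium residuals are
~1e-11. Stresses are recovered at element centroids (mean of the eight
Gauss-point strains); principal stresses are eigenvalues sorted
descending. Full integration of a ν = 0.49 layer is mildly stiff
(volumetric locking); with the thin-layer geometry this biases magnitudes,
not the spatial pattern the analyses compare.

## Osteogenic index

OI = a·maxᵢ σ_S,i + b·minᵢ σ_H,i per evaluation-layer element, with
a = 0.02, b = 0.01 MPa⁻¹month⁻¹ (ratio 0.5). The octahedral shear is the
standard (1/3)√Σ(Δσ)² convention; the alternative √(Σ/3) reading is
available via `OIConfig(shear_sqrt_inside=True)`. Outliers — values more
than 3 scaled MADs (1.4826·MAD) from the median, which occur at the plate
rim where element quality is lowest — are replaced by the extreme
non-outlier value on the corresponding side; the rule is idempotent, and a
zero MAD with non-constant data skips replacement with a warning.

## Heatmaps, regions, variability

Evaluation-layer OI values are projected along the plate normal onto a
square grid (default 100×100) spanning the footprint's bounding square,
with linear barycentric interpolation inside the convex hull and no
extrapolation. Grid axes are anatomical: +x lateral, +y anterior — using
the side-aware lateral direction mirrors left femurs into the right-femur
convention automatically. Five regions: a center disc of diameter 50% of
the grid width, and four sectors split by the square's diagonals (cells on
a diagonal belong to the medial/lateral sectors; the rule is deterministic).
Region means are normalized to each femur's OI range; argmax/argmin ties
break alphabetically. Group reference maps average cellwise where strictly
more than half of the group's femurs have valid data.

Shape/distribution variability between two maps is 1 − r, where r is the
zero-mean normalized cross-correlation coefficient over the full grids
(invalid cells filled with each map's mean; the single-offset equivalent of
normalized-correlation template matching). Negative r is clamped to 0 so
the score stays in [0, 1]; the raw r is reported alongside. Group
contrasts use pooled-variance independent t-tests (Welch via flag), paired
t-tests for within-subject contrasts, and mean-centered Levene tests
(median-centering via flag), all two-sided, reported with p < 0.05/0.01/0.001
tiers and no multiplicity correction.

## Reproducibility and problem sizes

Every pipeline run is a pure function of its config and seed; per-femur
seeds derive from the run seed via `numpy.random.SeedSequence`, and all
CSV outputs are written with fixed float formatting so identical runs are
byte-identical. The reference element size is 1.5 mm (~27k elements,
~97k DOF for the default femur; the full nine-instance analysis takes a
few minutes on one CPU). The test suite and examples use 2.0–2.5 mm
(~6–11k elements, seconds per femur) — the structural contracts (layer
counts, equilibrium, conservation) are resolution-independent, and the
mesh convergence utility (`convergence_study`) quantifies the OI's
resolution sensitivity directly.

## Known limitations

- Linear elastic, isotropic, small-strain mechanics only; no anisotropy,
  poroelasticity, contact, or geometric nonlinearity.
- Mechanical OI only — no biological growth-rate term and no growth
  (geometry update) simulation.
- The synthetic femur omits trochanters and condylar detail; muscle
  attachments are schematic sites, not measured footprints.
- Full-integration hex8 with a nearly incompressible plate layer locks
  volumetrically; magnitudes on the plate are conservative.
- The loading generator's CP/TD contrast is a variability/scale contrast,
  not a model of pathological gait.
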