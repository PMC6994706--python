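# Methods

This note documents the models, parameters and numerical choices behind
`callosoplan`, and what the phantom-based tests do and do not demonstrate.

## Coordinate conventions

All geometry is computed in world millimetres in a right-handed RAS-like
frame (x left→right, y posterior→anterior, z inferior→superior) carried by
the NIfTI affine. Voxel indices are 0-based and address voxel centres;
masks live on the half-open voxel lattice. Rasterisation and mask lookup
are the only places where world geometry meets the lattice: lookups round
to the nearest voxel centre, dilations threshold an exact Euclidean
distance transform (so radii keep true millimetre semantics on anisotropic
grids), and distance values along trajectories are trilinearly
interpolated. All inputs — parcellation, vessel mask, streamlines — are
assumed pre-registered to a single grid; the package performs no
registration.

## The digital head phantom

The phantom is a geometric stand-in for a parcellated T1 volume plus an
angiographic vessel segmentation, built so that every topographic claim
the planner relies on is true by construction. It is not an MR simulation:
there is no cortical folding, no diffusion physics, no intensity model.

- **Head**: ellipsoid (semi-axes 41 × 44 × 41 mm) flattened at the vertex
  (z ≤ 34 mm). The flat vertex gives the frontal entry row a region where
  near-orthogonal drilling (≤ 15°) toward the rostrum is geometrically
  possible, playing the role of the relatively flat superior frontal
  convexity. Scalp and skull are 3 mm erosion shells; everything deeper is
  brain.
- **Corpus callosum**: a circular-arch slab — circle of radius 18 mm in
  the sagittal plane swept from −35° (rostrum, anterior-inferior) to 160°
  (splenium, posterior), thickened to 7 mm radially and extruded to
  ±5 mm laterally. The 10 mm width matters: it leaves room for a
  paramedian catheter corridor *inside* the callosum, lateral to the
  midline arteries, while staying within reach of a single 15 mm-diameter
  cavity. The arch's arc fraction t ∈ [0, 1] (rostrum→splenium) is the
  phantom's longitudinal coordinate; sectors are rostrum < 0.20 ≤ genu
  < 0.55 ≤ posterior body < 0.85 ≤ splenium.
- **Cingulate band**: wraps the arch 2 mm outside its surface, 6 mm thick,
  partitioned at arc fractions 0.12 / 0.45 / 0.75 into subcallosal,
  anterior, middle and posterior segments. These fractions place the
  7 mm-dilation overlaps — and hence the generated targets — at the
  rostrum, genu and posterior body, with the posterior target just
  anterior of the 2/3 coronal cut.
- **Ventricles**: paired ellipsoids under the arch, so that midline
  transgression is a live constraint.
- **Entry gyri**: five cortical-shell patches (12° angular windows) whose
  centre directions were solved so that each admits trajectories
  satisfying its row's length/angle bound.
- **Vessels** (separate volume, as when vasculature comes from
  angiography): paired pericallosal arteries (radius 1 mm) running 1 mm
  above the dorsal callosal surface at x = ±2 mm — everywhere within 3 mm
  of the callosum, which is what forces the planner's lateral shift; a
  midline dorsal sinus (radius 2 mm) just inside the brain surface; and
  four cortex-to-sinus bridging vessels. The adversarial variant adds a
  vascular plate sealing the right frontal corridor, reproducing the
  failure mode in which cortical vasculature blocks the rostrum
  trajectory.
- **Streamlines**: noisy near-coronal circular arcs through a crossing
  point sampled uniformly over arc fractions 0.02–0.98 of the arch, always
  left→right. They emulate the *selection geometry* of interhemispheric
  tractography (every streamline crosses the callosum once, at a known
  position), not fibre propagation. Generation is the pipeline's only
  stochastic component and is fully determined by one seed.

Because the phantom's label geometry is analytic, several oracles are
closed-form: the arch-slab volume (annular sector × width, matched by the
voxel count within 10 %), capsule/cylinder volumes for vessels and
cavities (within 15 % at 1 mm voxels), and the arc-fraction sector of any
world point.

## Risk model

The per-node vascular risk is piecewise linear in the node's interpolated
distance d to the nearest vessel voxel, with safe margin d_safe = 3 mm and
horizon d_risk = 10 mm: r = 0 above the horizon, r = (d_risk − d)/(d_risk
− d_safe) ∈ (0, 1] in between, r = 1 + (d_safe − d)/d_safe ∈ (1, 2] inside
the margin. The trajectory score aggregates 128 nodes spanning
entry→target inclusive; the default aggregation is the maximum, under
which the calibration "score < 1 ⟺ every node more than 3 mm from
vasculature" holds exactly in both directions (mean aggregation is
available as a secondary summary). This piecewise-linear family is this
package's own formulation — chosen as the simplest one making the
calibration statement literally true — not a reproduction of any
proprietary planner's internals. Node placement spanning entry→target
(rather than skull→target) matches the convention that trajectory length
is measured from the skull surface over the entry gyrus.

## Planner

The search is exhaustive over stride-subsampled entry-surface ×
target-voxel pairs (defaults: every 3rd deduplicated surface point, every
4th target voxel, centroid always included). Entry points are
entry-gyrus voxels projected radially to the outer scalp surface; surface
normals come from the gradient of a 2 mm-Gaussian-smoothed signed distance
field, which stabilises normals on voxelised surfaces (planar-fixture
accuracy ~2–3°). Exhaustive-with-stride was chosen over stochastic
optimisation because it is deterministic, oracle-checkable, and fast
enough (~20 s per plan at 96³ on one CPU).

Hard constraints: maximum length, maximum drilling angle, no ventricular
transgression (stereotactic practice), and no passage *through* a vessel
voxel. Vessel *proximity* is deliberately soft — it enters the objective
through the risk score and minimum distance — so sub-3 mm corridors remain
admissible when the anatomy offers nothing better, as clinical planning
accepts. The collision constraint is what makes a vascular wall render a
row infeasible rather than merely expensive.

Ranking uses a weighted sum of pool-normalised (min–max) metrics, with
minimum vessel distance and callosal fraction negated. Default weights:
risk 0.3, min distance 0.1, intracerebral length 0.1, drilling angle 0.05,
callosal fraction 0.45. The dominant weight on the callosal fraction is a
deliberate design choice: the clinical objective of callosotomy planning
is a catheter lying *along* the commissure (so that staged pull-backs
ablate a long callosal segment), and with weaker callosal weighting the
optimiser drifts to safe but shallow crossings whose three cavities cannot
cover the anterior two-thirds. With these defaults the selected plan on
the phantom shows the expected clinical signature: arch-aligned catheters
shifted a few millimetres off midline by the pericallosal arteries, one of
them accepting a 2.7 mm corridor (risk slightly above 1).

Selection: the anterior row's best candidate, plus the better of the two
middle rows and of the two posterior rows, compared under a joint
normalisation of both pools. Ties break by risk, then intracerebral
length, then entry coordinates, making the whole plan deterministic. An
infeasible row marks the plan partially infeasible but does not abort the
remaining targets.

## Ablation cavities

Pull-backs per catheter: ⌈callosal segment length / 7 mm⌉, minimum one;
the ceiling guarantees the whole segment is covered. The callosal segment
is the longest contiguous in-callosum interval of the entry→target path at
0.5 mm sampling; centres are anchored at the distal (target) end —
pull-*back* semantics — and stepped proximally. Each ablation is a 15 mm
sphere (configurable 5–15 mm); at confluent spacing (spacing ≤ diameter,
enforced) the union converges to a capped cylinder and is
rotation-invariant on the lattice. By default the cavity is clipped to the
callosum dilated by 2 mm, modelling the surgeon limiting ablation to the
commissure to protect the cingulate and fornix; clipping can be disabled
for worst-case cavity extents. No thermal physics (MR thermometry,
Arrhenius damage, heat sinks) is modelled.

## Disconnection assessment

A streamline is excluded when any point of its polyline, resampled at
≤ 0.5 mm arc length, falls in the cavity mask by nearest-voxel lookup;
decisions at 0.5 mm agree with 0.1 mm on ≥ 99 % of phantom streamlines.
Residual connectivity is the set of callosal voxels visited by survivors
(threshold: ≥ 1 visiting streamline), reported as voxel count × voxel
volume in cm³ — volumes are measured directly on the lattice, since mesh
conversion adds only mesher-dependent variance. The callosum is
partitioned by a coronal plane at 2/3 of its anterior–posterior voxel
extent (fraction configurable; anatomical splenium shares vary), the
anterior part containing the anterior-most voxel, the partition exact by
construction. Reports localise any anterior residual by its mean relative
AP position (0 = anterior-most callosal plane).

## Problem sizes and determinism

Default runs use a 96³ grid at 1 mm, 5000 streamlines, and the stride
defaults above; the full pipeline (phantom → plan → ablate → disconnect)
completes in about half a minute on one CPU, and the whole test suite in a
few minutes. One global seed drives streamline sampling; all other stages
are deterministic functions of their inputs, so repeated runs produce
identical reports.

## Limitations

- The phantom's analytic geometry makes constraint satisfaction easier
  than on real anatomy: no sulcal vessels along entry corridors, no
  partial-volume ambiguity in the parcellation, vessels from a clean
  parametric tree. Passing phantom tests demonstrates the pipeline's
  mechanics and calibration, not clinical performance.
- Cohort-level comparisons against expert manual plans require patient
  imaging and are out of scope; the `score` subcommand scores externally
  supplied trajectory lists so such comparisons can be run where data
  exist.
- Streamlines encode only crossing topology; residual-connectivity volumes
  on the phantom are therefore indicative, not biophysical.
- Laterality roles are named in the left-dominant convention of the
  default row table; flipping the dominance flag mirrors the geometry
  while keeping the role names, which should then be read as
  dominance-relative.
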