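# Methods

This note documents the models, conventions and numerical choices in
`lvfusion`, and what the synthetic phantoms do and do not establish
about behaviour on clinical data. Units everywhere: lengths mm, volumes
ml, mass g, angles degrees at interfaces (radians internally).

## Cardiac coordinate frame

A subject-specific right-handed frame is built from fiducial landmarks:

- origin — the **basal centroid** (both modalities identify the base
  reliably, and the longitudinal coordinate then runs 0 at the base to
  1 at the apex);
- `e_long` — unit vector from the basal to the apical centroid;
- `e_rv` — unit component, orthogonal to `e_long`, of the direction
  from the origin to the RV centroid;
- `e_norm = e_long × e_rv`.

The RV centroid is the mean of all labelled and unlabelled RV insertion
points when both are available (CMR convention). In the echo
convention only the inferior insertion is given, and the RV centroid
direction is estimated 70° **clockwise** from it as seen by a viewer at
the apex looking toward the base. With `e_long` pointing base→apex,
that viewpoint makes "clockwise" a rotation by **−70° about `e_long`**
under the right-hand rule; this sign is declared once here and used
everywhere. Degenerate configurations (coincident apex/base, RV
direction within 1° of the long axis) raise errors.

Cardiac coordinates of a point are `(u, φ, r)`: u the longitudinal
position normalized by the apex extent, φ the angle from `e_rv` toward
`e_norm` in [0°, 360°), r the distance from the long axis.

## Rigid registration

Coarse alignment is the unique proper rigid map carrying the echo
frame's origin and axes onto the CMR frame's — i.e. aligning long axis
and RV direction. Refinement is point-to-point ICP over the union of
endo- and epicardial vertices: one-way nearest-neighbour correspondence
(src→ref, ties to the lowest index), closed-form SVD (Kabsch) update,
convergence when the RMS residual changes by < `tol` (default 1e-4 mm)
within `max_iter` (default 100). ED and ES are always solved
independently, with no shared parameters. A caller-supplied manual
override transform replaces ICP for a phase. Non-convergence and an
RMS residual above the acceptance threshold (default 5 mm) produce
warnings, not exceptions — they flag fusions that would have failed
visual inspection.

ICP replaces an interactive manual refinement step that cannot be
reproduced by a machine; initialising it at the coarse landmark
alignment keeps it in the correct basin. Two known limitations, both
verified empirically: (i) registering a structured mesh to an identical
copy of itself has spurious local minima at lattice shifts (one
circumferential or longitudinal mesh step), so pure ICP started far
from the optimum without the coarse stage is only reliable within about
half a mesh step; (ii) under a global rotation of both inputs,
nearest-neighbour ties at Voronoi boundaries can flip, moving the
converged transform by ~1e-4 mm — the coarse path is exactly
equivariant, the ICP path equivariant to ~1e-3 mm in downstream MSD.

## Common-template surface re-fit

Each surface is re-fitted to a canonical radial field r(u_i, v_j) on a
regular grid, u ∈ [0, 1] (n_u rows) by φ ∈ [0°, 360°) (n_v columns,
periodic), by solving the linear least-squares problem

    min_r  Σ_j (B(u_j, φ_j)·r − r_j)²  +  λ ‖D r‖²

with B bilinear interpolation on the periodic grid and D the stacked
second-difference operator (open in u, periodic in φ). Defaults:
n_u = n_v = 24, λ = 1.0. The system is sparse and solved directly;
the fit is deterministic and linear in the data. This radial-field
template is the package's own substitute for proprietary finite-element
bases: linear, inspectable, and sufficient for star-shaped LV surfaces.

Conventions and safeguards:

- **Node order** is canonical (u-major), so two surfaces fitted on
  equal grids correspond node-by-node — the correspondence the regional
  MSD requires. The triangulated mesh has n_u·n_v + 1 vertices; the
  extra apical pole vertex sits on the long axis at u = 1 (the apical
  row of the grid carries the fitted near-apex radii; an additional
  radial pole offset has no consistent meaning once the grid itself
  reaches the apex).
- **Apex extent per surface**: the endocardial extent comes from the
  landmarks; the epicardial apex lies a wall thickness beyond it, so
  the epicardium uses the maximal longitudinal extent of the reference
  (CMR) epi data. Both modalities share each surface's extent,
  preserving correspondence; mass and shell computations rescale u
  between the two extents when they mix surfaces.
- **Star-shapedness**: the template assumes single-valued r(u, φ). If
  two data points in one interior grid cell differ radially by more
  than 15 mm the input is rejected as multi-valued. The apical cell
  row is exempt — the radius legitimately collapses toward zero there
  (up to ~16 mm within a cell for wide hypertrophic epicardia), and a
  genuinely multi-valued surface trips cells at every level.
- Points on the long axis (undefined φ) are dropped from the fit;
  points up to 0.05 outside u ∈ [0, 1] are clamped, more than 5%
  outside raises a coverage error; grid cells without data fall back on
  the smoothness prior (with a warning), or raise if λ = 0.

## AHA partition and regional MSD

Longitudinal thirds by u — basal [0, 1/3), mid [1/3, 2/3), apical
[2/3, cap_u) — and the apical cap [cap_u, 1] (epicardium only; on the
endocardium cap nodes are masked, leaving 16 segments vs 17). The cap
boundary default cap_u = 0.90 is a declared convention (configurable);
no standard pins it exactly, and all partition tests are
boundary-agnostic. φ = 0 (the RV direction) is taken as the
mid-septum. Basal and mid rings use 60° sectors walking from the
septum toward the anterior wall: anteroseptal [0°, 60°), anterior,
anterolateral, inferolateral, inferior, inferoseptal; the apical ring
uses 90° sectors (septal centred on 0°, anterior on 90°, lateral 180°,
inferior 270°). AHA numbering: basal 1–6, mid 7–12, apical 13–16,
cap 17; e.g. segment 1 = basal anterior, 6 = basal anterolateral,
10 = mid inferior. Sector boundaries are half-open (ties to the lower
sector).

Per segment, with labels computed on the reference (CMR) surface and
applied to both via node correspondence,

    MSD_seg = (1/N_p) Σ_p ‖M_p − E_p‖   [mm].

Node-index correspondence (not nearest-point matching) makes the
statistic symmetric in its arguments and exactly 5.000 mm in every
segment under a 5 mm uniform shift. Segments with no unmasked nodes
are reported as absent, never as zero.

## Global indices

Cavity volume closes the fitted mesh with a triangle fan from the basal
ring to its centroid (cap included in the cavity) and evaluates the
divergence-theorem sum of signed tetrahedra, taking the absolute value
so triangle winding cannot flip the sign. At a 48×48 grid the
piecewise-linear surface inscribed in a smooth phantom underestimates
volume by ≈0.3% (polygonal chord deficit); at the default 24×24 it is
≈1%. LV mass = (V_epi − V_endo) × density, density 1.05 g/ml (the
standard echocardiographic convention; configurable), from the ED
models; the epi⊇endo pre-check compares the epicardial radius at each
endocardial node's physical position with 0.1 mm tolerance.
EF = 100·(EDV − ESV)/EDV; indexed values divide by BSA. Volumes are
always computed on fitted template surfaces so that every method shares
one volume operator and inter-method differences are geometric, not
mesh-processing artefacts.

## Signal intensity

Images are normalized per image: clip to [0, p95] and divide by p95,
the 95th percentile over all voxels (linear interpolation between order
statistics). A voxel belongs to the myocardium when, at its (u, φ),
its radius lies between the fitted endo and epi radii — exact for
star-shaped surfaces and fast on regular grids; this "shell sampling"
choice (rather than whole-image sectors) is deliberate, since dropout
matters where it affects wall delineation. Per AHA segment (epicardial
17-segment rules) the mean normalized intensity × 100 is reported as a
percentage of the peak signal.

## Agreement statistics

- **Paired t**: classical paired t on d = x − y with n−1 df; default
  significance threshold two-tailed P < 0.05/3 ≈ 0.0167 (Bonferroni for
  three echo methods; m configurable). Zero-variance differences are a
  defined error, not a silent NaN.
- **ICC(A,k)** (McGraw–Wong): two-way model, absolute agreement,
  average of k measures, from the ANOVA mean squares:
  `(MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n)`. Chosen because the
  "average measure, absolute agreement, two-way mixed" family is what
  the study design calls for; identical columns give exactly 1, and a
  constant offset between methods is penalized.
- **Bland-Altman, two methods**: bias = mean(d),
  LoA = bias ± 1.96·SD(d) (sample SD).
- **Bland-Altman, multi-method** (k ≥ 3): differences of each method
  from the per-subject mean; per-method biases (which sum to zero by
  construction) and symmetric LoA = ±1.96 × the pooled SD of all n·k
  differences. The pooled SD is used *without* a k/(k−1) inflation for
  the correlation induced by subtracting the row mean; consequently the
  half-width converges to 1.96·σ·√((k−1)/k), not 1.96·σ, for i.i.d.
  noise. This matches the method-vs-mean construction as commonly
  described; callers wanting the inflated variant can scale by
  √(k/(k−1)).

## Synthetic phantoms

`PhantomSpec` defaults define the study conditions: endocardial
semi-axes (26, 23, 76) mm truncated 0.4·c below the equator (ED cavity
≈ 149 ml, base–apex length ≈ 106 mm), wall thickness 9 mm (epicardium =
ellipsoid with all semi-axes enlarged by the thickness — exactly the
thickness at the apex, approximately elsewhere, avoiding the undefined
axis-radial offset at the pole), EF target 0.63 reached exactly by
uniform inward radial scaling for ES (epicardium scaled to conserve
wall volume; no longitudinal shortening — sufficient to produce
distinct per-phase registrations, not a mechanics model), BSA 1.88 m²,
misalignments up to 10° / 10 mm per phase, ~2500 mesh vertices per
surface, no added noise by default. Cohort draws: a ~ N(26, 2) mm,
b = a·U(0.85, 0.95), c ~ N(76, 6) mm, thickness N(9, 1) mm with a 1.6×
hypertrophic multiplier in 1 of 7 subjects, EF ~ N(0.63, 0.06), BSA ~
N(1.88, 0.22) clipped to [1.41, 2.37] m²; subject i uses generator seed
(cohort seed, i), so everything regenerates bit-identically.

RV insertions sit on the epicardial basal ring at ±70° about the RV
direction (inferior at +70°): with the declared clockwise convention,
the echo-style estimate from the inferior insertion then reproduces the
CMR RV direction exactly, so the two landmark conventions agree on an
unperturbed phantom.

Echo-style regional underestimation is modelled explicitly: an inward
radial displacement equal to the requested amplitude across a target
segment's own (u, φ) extent, decaying by a raised-cosine taper (default
20° / 0.10 u) beyond its edges. The taper intentionally reaches
adjacent segments — a deformation confined exactly to one segment would
be physiologically implausible and would also make the segment mean
under-read the amplitude.

`make_echo_volume` builds a 1 mm isotropic intensity volume with the
myocardial shell piecewise-constant at per-segment targets (unspecified
segments at the peak value 1.0 so the 95th percentile anchors there),
low constant blood pool (0.05) and near-zero background, plus optional
multiplicative Gaussian speckle. Speckle defaults to 0 so the
documented exact round-trip (realized shell means = targets up to
boundary-voxel discretization) holds at defaults; noise is opt-in.

**What the phantoms do not emulate**: trabeculae and papillary muscles
(the contouring convention excludes them; underestimation enters only
through the explicit bias), true systolic wall mechanics, realistic
speckle statistics and attenuation physics, probe-angle-dependent
dropout, or landmark identification error (phantom landmarks are
analytic and exact — which is why coarse registration alone is exact on
phantoms, while clinical coarse alignment inherits landmark noise).
Passing tests therefore establish the correctness of the *operators*,
not clinical accuracy bounds.

## Problem sizes and determinism

Default analyses run comfortably on one CPU: a 20-subject cohort with
three echo methods registers, refits and reports in ~10 s; the
acceptance script (100 registrations, 40k-point analytic fits, a
voxel-counting volume oracle at 0.5 mm, 10k-row statistics simulations
and the 20-subject cohort twice) completes in about half a minute.
Report CSVs/JSONs are byte-identical across reruns with the same seed;
wall-clock timestamps appear only in the log.
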