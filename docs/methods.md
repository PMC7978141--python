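# Methods

## Problem setting

Topographic fNIRS measures cortical hemodynamics through source–detector
channels held on the scalp by a rigid grid. A study images `N_p`
participants with one montage of `N_c` channels; per channel the scalp
location `s_ij` of participant `j` is projected to their cortex at `b_ij`
(common space) with label `L_ij`. Montage quality is summarized by two
indices:

* `GIV_i = sqrt( (1/(N_p−1)) Σ_j ‖b_ij − b̄_i‖² )` — the root of the pooled
  per-axis sample variances of the brain locations (mm). The printed form
  of this dispersion is ambiguous about where the square root sits; we fix
  the convention as above, which yields values on the ~mm scale consistent
  with reported montage GIVs, and use the *same* formula everywhere a
  dispersion appears (atlas `σ_B`, scalp-space variability), so the error
  decomposition below is internally consistent.
* `GIA_i = (1/N_p) Σ_j 1[L_ij ∈ ROI]` — the fraction of participants whose
  channel samples the target.

Montage-level GIV and GIA are channel means.

## Continuous proportional coordinates

CPC is a fiducial-anchored 2D parameterization of the superior scalp that
transfers locations between heads of different size and shape. The
construction here is hierarchical, mirroring tape measurement of 10/20
landmarks:

1. the *midsagittal curve* is the mesh section by the plane containing Nz,
   Iz and the superior direction (`up = cross(AR−AL, Nz−Iz)`, normalized),
   parameterized by proportional arc length from Nz;
2. for a scalp point `p`, the *coronal curve* through `p` is the section by
   the plane through (AL, AR, p); `p2` is the proportional arc length of
   `p` along it from AL;
3. `p1` is the proportional midsagittal position of that coronal curve's
   crossing with the midsagittal plane.

An alternative reading defines `p1` symmetrically via the plane through
(Nz, Iz, p). We rejected it after finding that its image does not cover the
unit square (on a sphere it satisfies `cos²(πp1) + cos²(πp2) ≤ 1`), so
regular CPC grids would contain unreachable points. The hierarchical
construction covers the open unit square, is bijective on convex-ish
scalps, and admits a *direct* inverse: walk the midsagittal curve to `p1`,
section the coronal plane through that point, walk to `p2`. Forward and
inverse maps round-trip to ~1e-12 CPC units on the test meshes; the
tolerance promised by the API is 1e-3.

Numerics: plane–mesh sections are computed from per-vertex signed
distances, with intersection points chained through shared mesh edges into
ordered polylines (open chains end at boundary edges; the four fiducials,
lying exactly on their own section planes, are handled by an eps
perturbation of zero distances). Arc length is the polyline length; since
section vertices lie on mesh edges, interpolated arc points lie exactly on
mesh faces. Sections cost O(F); a CPC100 grid (99×99 interior points)
shares one coronal section per row and builds in well under a second on the
meshes used here.

Degenerate inputs: the four fiducials are poles (one coordinate 0/1, the
other undefined, returned as NaN); points below the Nz–AL–Iz–AR band are a
domain error; points farther than 1 mm from the surface are rejected,
nearer ones snapped.

## Transcranial atlas

For each CPC grid point `s` and each head in a population: `s` is carried
to that head's scalp via the CPC correspondence, projected to its cortex,
and the projected vertex's label and common-space coordinate are pooled.
`P(l|s)` is the label frequency (with an explicit background label so
normalization is exact); `σ_B(s)` is the GIV-formula dispersion of the
common-space points (0 for a single head). ROI queries use
`GIA^(s) = max_{l∈ROI} P(l|s)` — max, not the union probability, the convention used for adjacent-ROI
estimation in the TBA literature — and `GIV^(s) = σ_B(s)`. Lookup at arbitrary CPC
uses the nearest grid point with no interpolation, so the estimator is
exactly the stored table. Grid points where any head fails (CPC inversion
or projection) are masked rather than imputed.

## Scalp-to-cortex projection

The balloon-inflation idea — a point pushed inward from the scalp lands on
the nearest cortical patch — is realized as a deterministic rule: collect
the brain vertices within `d_min + δ` of the scalp point (`d_min` the
distance to the nearest brain vertex, `δ = 3 mm`), and return the brain
vertex nearest that patch's centroid. A query already on a brain vertex
returns it, making the projection idempotent. The output is a mesh vertex,
so its accuracy is bounded by cortical vertex spacing; the concentric-
sphere limit case in the tests uses a finely sampled sphere for that
reason. On uneven meshes the patch centroid is density-weighted; the
synthetic cortices are near-uniform so the bias is negligible at the tested
tolerances.

## Montage placement

Holders are rows×cols grids with nominal inter-optode distance `d`
(default 30 mm) enforced as 3D chord distance, since physical holders are
rigid straight links. Placement at (center CPC, orientation θ): seed the
grid in the tangent plane (θ measured from the tangent projection of the
increasing-p1 direction; range [0, π) by the half-turn symmetry of the
undirected grid), then alternate spring relaxation of edge lengths with
closest-point projection onto the mesh, pinning the on-surface projection
of the central node (odd grids) or central node pair midpoint (even grids)
to the requested center. Convergence: max edge error < 0.1 mm, hard
feasibility bound 1% of `d`, cap 500 iterations. Pinning compares the
*snapped* reference midpoint with the center — the raw chord midpoint of an
even grid's central pair lies strictly inside a curved surface and would
make the constraint unsatisfiable. A placement whose nodes leave the
fiducial band, or whose relaxation cannot meet the 1% bound (excessive
curvature), is infeasible. On a flat surface the relaxation is a no-op and
the grid is exact.

Channels form at grid-adjacent source–detector pairs; the channel location
is the chord midpoint snapped to the surface, expressed in CPC; a channel
is *effective* when its GIA^ is strictly above the threshold `t`
(default 0.5 — below that, fewer than half the population would sample the
ROI, unreliable for channel-wise analysis).

## Arrangement optimization

Level 1 (fixed placement): a seed source–detector pair occupies the central
grid edge (nearest the holder centroid; lexicographic tie-break; source on
the lower node index). Sources and detectors are then added alternately
(source first) at the free node creating the channel with maximal GIA^,
until no candidate would create an effective channel or optodes run out;
when one type is exhausted the other continues. Excess optodes are placed
on free nodes adjacent to occupied ones by a seeded RNG (a deterministic
lowest-index mode exists for reproducible comparisons); they form control
channels. All tie-breaks are lexicographic on node index.

Level 2: an exhaustive sweep over sampled centers (by default the effective
locations, optionally restricted to a radius in CPC units — 1 unit = 0.01 —
around the GIA^-weighted center of mass `s_ec`) and orientations
`θ_j = jπ/n_θ`. The objective `f(x_i, θ_j)` is the average GIA^ over
effective channels of the greedy solution (0 when none; an all-channels
objective is available). Because the number of effective channels `N_ce`
trades off against average accuracy, the result retains the best
arrangement per `N_ce` value. Candidates for this per-`N_ce` selection are
not only the final greedy solutions: every intermediate state of each
greedy run (after the seed and after each scored addition) and a pruning
chain (optodes discarded one at a time, each time removing the one whose
removal maximizes the remaining average) compete at their own `N_ce`.
Final-state-only selection systematically misses low-`N_ce` arrangements at
the best centers — the greedy always spends all optodes there — and the
characteristic accuracy-vs-coverage trade-off then fails to materialize; with
trajectory and pruning candidates it emerges robustly. Note the trade-off
remains an empirical property of smooth unimodal accuracy maps and
full-size holders, not a theorem: on small holders, closed
source–detector–source–detector cycles over a narrow hotspot have no
`N_ce − 1` derivative, and genuinely non-monotone envelopes exist.

Determinism: per-placement RNG streams derive from (seed, center index,
theta index); identical inputs and seed give identical results.

## Evaluation and error decomposition

Given individual head models, an intended montage, and realized channel
CPCs per participant (digitized or simulated), per channel we compute the
actual GIA/GIV from the realized positions, the *ideal* GIA/GIV from the
intended positions (placement error removed), and the atlas estimates at
the intended CPC. Defining `ε1 = ideal − estimate` (anatomy: population
correspondence standing in for individual anatomy) and
`ε2 = actual − ideal` (placement), the identities
`GIA = GIA^ + ε1A + ε2A` and `GIV = GIV^ + ε1V + ε2V` hold to machine
precision by construction. Participants with missing realized positions
are masked per channel with `N_p` recomputed; GIV needs ≥ 2 participants.
Scalp-space variability maps realized CPCs onto the typical scalp and
applies the GIV formula there (mm).

When the atlas is built from the very heads being evaluated, channels sit
exactly on grid points, and the ROI is a single label, `ε1A` is exactly
zero; off-grid channels see quantization of the nearest-grid-point lookup
(up to half a grid cell, ~1–3 mm on the grids used here), which the tests
account for.

## Synthetic head populations

Each individual is an upper-half ellipsoid scalp (semi-axes ~ Normal(mean,
sd); defaults 75×92×80 mm, sd 3 mm — adult-head scale), meshed on a
lat-long grid so the four fiducials and the vertex are exact mesh vertices;
the cortex is the scalp shrunk by `brain_scale` (default 0.85) with a
smooth low-order radial relief (population-level phase, ±2%); the
parcellation is K azimuthal sectors (default 6; the montage-comparison
experiments use 12 for 30° parcels) whose boundaries rotate per individual
by Normal(0, `jitter_sigma`), default 5° — this boundary jitter is what
makes scalp–brain correspondence probabilistic. `to_common` is the diagonal
affine onto the population-mean ellipsoid. With zero axis sd and zero
jitter, all individuals are bit-identical and the atlas is binary.

Realized-placement noise is an isotropic 2D Gaussian (per-axis SD in mm,
default 5 mm) in each participant's tangent plane, re-projected to their
scalp and re-expressed in CPC; draws landing below the fiducial band are
rejected and redrawn (the noise is truncated to the CPC domain), and the
mean displacement matches the Rayleigh expectation `σ√(π/2)` within
sampling error.

What this emulates — and what it does not: the generator reproduces the
*structure* of the problem (between-subject shape variation, probabilistic
scalp–brain correspondence, rigid-holder constraints, placement error) on
smooth convex geometry. It has no cortical folding, no gyral/sulcal label
geometry, no tissue layers, no photon transport, and its common-space
normalization is exact by construction (so anatomical dispersion in common
space is dominated by parcel jitter and mesh quantization rather than true
shape residuals). Passing tests therefore validate the method's logic and
internal consistency, not its quantitative behavior on real MRI-derived
anatomy; cohort-specific values reported for real data (atlases built from
MRI cohorts of ~100 subjects) are not reproducible here and are not targets
of the test suite.

## Problem sizes

Defaults keep everything desk-scale: meshes with ~40×16 lat-long
resolution (~650 vertices), CPC grids of resolution 16–20 for pipeline
runs (CPC100 is built where only the grid itself is exercised), cohorts of
5–20 heads, and search spaces of ≤ ~50 center×orientation samples. The
acceptance script's cohort is 20 heads with a 12-parcel cortex; the
directional montage comparison runs 20 independent 5-head cohorts.
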