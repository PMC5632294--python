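# Methods

## Overview

`treeclone` fits a stochastic, self-organizing tree growth model to a
target tree given as a cylinder table, by minimizing a structural distance
between empirical morphology distributions, and then uses the fitted model
as a generator of morphological clones. This note records the model, the
numerical choices, and what the synthetic test targets do and do not
establish about real scan data.

## Cylinder tables and Gravelius orders

A tree is an ordered table of circular cylinders (start point, unit axis,
length, radius, parent row). Topology annotations are derived, not
trusted: `assign_orders` walks the tree from the root, and at every
junction the child with the largest first-segment radius continues its
parent's branch and Gravelius order w, while thinner children start
lateral branches of order w+1. The trunk is order 0. Ties in radius go to
the lowest row index — deterministic, and the limiting case of "thickest
continues". Orders are capped at a configurable `w_max` (default 10) to
guard against pathological inputs. The rule is an approximation to the
richer topology extraction a scan-reconstruction pipeline performs; for
strongly apically dominant forms it coincides with the true growth
lineage, for shrubby forms it is the convention applied consistently to
both target and model, which is what the distance requires.

Attachment (a child's start lying on its parent's tip) is enforced for
simulated trees (tolerance 1e-6 m) and *not* checked for imported QSMs,
which carry reconstruction noise.

## Feature tables

Branch tables carry (β, α, L_t, R_f, L_a); segment tables carry
(R, L, γ, ζ). Conventions the data model leaves open:

* **Trunk frame.** The trunk has no parent, so its β is measured from
  global +z and its α around +z from global +x. Fits are in any case
  meaningful only up to a rotation about the vertical axis, so the
  absolute azimuth reference is immaterial to the distance; it only has
  to be fixed.
* **α reference.** Projection of global +x onto the plane normal to the
  parent axis; +y if the parent axis is within 1e-6 of +x. Range [0, 360).
* **ζ.** Absolute difference of the two segments' elevation angles
  (angle from the XY plane), in [0, 180] — rotation-invariant about z,
  unlike a literal "angle between vertical projections".
* **Degenerate γ.** If a projected axis has horizontal norm < 1e-9
  (vertical segment), γ := 0, the limit of a vanishing horizontal
  component.
* **L** is measured to the segment *base*, so the first segment of every
  branch has L = 0.

Branch and segment tables differ in dimension and are never merged with
each other; same-kind tables of different orders concatenate into joint
data sets (S^{0,1}, B^{2,3,4}, ...).

## Structural distance

D_S is the mean over n quasi-random unit directions of the two-sample
Kolmogorov–Smirnov statistic between the 1-D projections of the two
tables (distribution tomography). Numerical choices:

* **Directions.** Unscrambled Sobol points in (0,1)^d, mapped through the
  standard-normal inverse CDF and normalized — asymptotically uniform on
  the sphere because the isotropic Gaussian is spherically symmetric.
  The all-zeros first point and the midpoint (which maps to the zero
  vector) are skipped; regeneration with the same (dim, n, sequence id)
  is bit-identical, and directions are fixed per run so the optimization
  objective is deterministic. Antipodal duplicates are not removed: the
  KS statistic of a negated projection equals that of the original, so
  they are harmless. Default n = 1000 lines.
* **Standardization.** Columns mix meters and degrees, so each table pair
  is centered and scaled column-wise by the *pooled* median and IQR
  before projection; zero-IQR columns pass through unscaled. Pooling
  keeps the transform symmetric in the two tables, preserving
  D_S(A, B) = D_S(B, A).
* **KS with ties.** The per-line statistic is computed by a stable sort
  of the pooled projections with a cumulative ±1/n weight sweep; the ECDF
  gap is evaluated only after the last occurrence of each distinct value,
  which handles ties exactly (verified against a brute-force oracle to
  1e-12).
* **Empty tables.** If exactly one table of a pair is empty (the model
  grew no branches of a requested order), the pair scores the maximal
  distance 1, steering the optimizer toward producing the missing orders.
  If both are empty they are indistinguishable and score 0 — required
  for the exact self-match property when a small target itself lacks an
  order.
* **Aggregation.** With several table pairs the objective is their
  unweighted mean.

The computation is linear in the number of lines and of table pairs and
n log n in the sample count; an `OpCounter` records the dominant
operation counts so the complexity shape can be asserted without
wall-clock measurements.

## Classical metrics

Height h is the highest cylinder endpoint; girth g is the ground
segment's diameter (breast-height diameter is ill-defined for multi-stem
shrubby forms); crown spread c uses 36 azimuthal spokes at 10°
separation from the ground segment's XY position — each spoke reaches the
most distant cylinder endpoint in its half-open sector, empty sectors
count 0, and c is twice the mean spoke length. Relative errors d_i =
|i_d − i_m| / i_d use the target (data) value as reference and can exceed
1, which is expected for girth: its absolute scale (centimeters against
meters of tree) makes d_g a noisy descriptor.

## Growth model

Each iteration: (1) every metamer tip deposits shadow into an inverted
voxel pyramid below it, layer q gaining a·b^(−q) down to a fixed depth;
(2) each bud reads exposure Q = max(C − sensitivity·(s − a_own), 0)·g(z),
where s is accumulated shadow, a_own removes the bud's own contribution
and g(z) = 1 + gradient·z/extent is a vertical light gain; (3) exposures
sum tip-to-root, then resource flows root-to-tip, split at every node by
the extended Borchert–Honda rule — the terminal path receives
v·λQ_m/(λQ_m + (1−λ)ΣQ_l) and laterals share the remainder in proportion
to their exposure, so λ=1 is full apical dominance and λ=0 full lateral
dominance; (4) each bud converts resource v into floor(resource_coeff·v)
metamers of fixed 0.2 m length (capped at 10 per bud per iteration as a
guard against runaway allocation). Terminal shoots continue their parent
direction with small angular wobble; lateral shoots leave at the
branching angle (mean ± spread·noise) at a phyllotactic azimuth advanced
by the divergence angle per node. Tropism blends a fixed direction into
every new metamer's axis. Angular noise is normal or uniform
(unit-variance scaling) per the `angle_noise_kind` switch. Dormant
lateral buds activate with probability `bud_break_prob` per iteration and
abort when their exposure falls below `shed_threshold`; laterals beyond
`max_order` are never created.

The 27 parameters split into five groups — I growth/pipe (6: iterations,
initial metamers, resource coefficient, pipe exponent, tip radius, max
order), II environment (5: shading sensitivity, light gradient, tropism
strength/elevation/azimuth), III apical dominance (3: λ, bud-break
probability, shed threshold), IV shadow propagation (4: a, b, base
exposure C, pyramid depth), V angular (5: branching angle mean and
spread, divergence angle and spread, noise kind) — plus 4 fixed (segment
length 0.2 m, voxel size 0.2 m, 12 m cubic arena, base at the center of
the arena floor). Defaults (a=0.1, b=2, depth=4, C=1) follow the
self-organizing-tree literature's treatment of these as tunable
constants. Growth clips at the arena walls rather than erroring.

**Determinism.** All randomness comes from a counter-based Philox stream
keyed by (seed, iteration), with per-bud draws indexed by metamer id —
growth is reproducible bit-for-bit and independent of bud evaluation
order. After growth, radii are assigned by the pipe model
(r_pᵉ = Σ r_cᵉ exactly, tips at `tip_radius`) and orders by the same
thickest-branch rule used for imports.

## Inverse fitting

The objective simulates the model at v with a *fixed* seed, extracts
tables matching each target table's kind and orders, and returns the mean
D_S; it is a pure function of v, which stochastic-model optimization
requires. Simulation failures score 1.0 rather than aborting. The GA uses
tournament-of-3 selection, intermediate crossover (rate 0.8), per-gene
mutation (rate 0.15; Gaussian at 10% of the range for reals, uniform
reset for integers), elitism, rounding/clipping to global bounds, and
stops after a stall window (default 10 generations without improvement)
or a generation cap. Initial populations are drawn from the initial
ranges, a subset of the global bounds; `refine_specs` re-centers initial
ranges on a previous best fit for sequential group-by-group refinement.
Selection, crossover and mutation internals are this package's own
defaults — the contract is only that the optimizer be integer-aware,
bounded, elitist and stall-stopped.

## Synthetic targets

The deterministic fractal target (perfect bifurcation, per-level 90°
twist, geometric length decay, pipe radii) provides closed-form oracles
for height, girth, crown spread and branch counts. The simulated
self-target provides the exact-recovery regime: at the generating
parameters with the matched seed the objective is exactly 0.
`corrupt_tree` jitters radii and axes (re-chaining positions so
attachment holds) to emulate measurement noise. These fixtures exercise
every code path at realistic feature scales, but they do not contain
scan-specific artifacts — occlusion gaps, cylinder-fitting bias,
non-uniform segment lengths (a real QSM's median segment length can be
~0.06 m against the model's fixed 0.2 m), or environmental asymmetries
(wind, neighbors, sun). Passing the suite therefore validates the
machinery and its contracts, not the fidelity of any particular fit to a
real tree.

## Problem sizes

Tests and the acceptance script run the model at a reduced size chosen to
keep full-suite runtime around a minute: 6 m arena, ~10 growth
iterations, a few hundred segments per tree, 128–256 projection lines in
optimization loops and the full 1000 lines where the distance itself is
under test; GA recovery uses population 20 over ≤ 7 generations and ten
independent trials. These sizes are the package's own defaults for
self-contained experiments; full-scale fits (12 m arena, 20+ iterations,
1000 lines, larger populations) use the same code paths.

## Known limitations

* The thickest-branch rule is only an approximation of scan-pipeline
  topology extraction; no attempt is made to read point clouds or
  proprietary QSM formats (a one-off CSV conversion is the supported
  route).
* The shadow model is an inverted pyramid on a cubic lattice — cheap and
  adequate for self-shading competition, but not a radiative-transfer
  model; no leaves or seasons.
* Clone "realism screening" is structural only (validation invariants,
  pipe conservation, arena bounds); no aesthetic filtering.
* The fitted model is identifiable only up to rotation about z, and
  distance landscapes are rugged and replicate-dependent, so any best fit
  is best for its particular random realization; clone-level variability
  is the object of interest, not a unique parameter point.
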