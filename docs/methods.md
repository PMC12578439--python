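# Methods

`mtoligo` analyzes the *coordinate-space* geometry of protein oligomers
decorating microtubules, as recorded in cryo-ET subtomogram metadata
(positions, orientations, cross-correlation scores, filament assignments).
No densities or images are touched: the unit of data is a particle — here a
WD40:WD40 LRRK2 dimer — described by a point in the tomogram frame and a
proper rotation mapping its own frame into that tomogram frame.

## Coordinate model

All internal positions are nanometres; all internal orientations are 3×3
rotation matrices. Euler triplets exist only at the file boundary:
Dynamo-style tables carry intrinsic ZXZ angles (tdrot, tilt, narot), STAR
files intrinsic ZYZ (rot, tilt, psi). Matrix→angle extraction is done with
atan2 directly on matrix elements, which keeps the round trip at the 1e-12
level even adjacent to gimbal lock (where the third angle is set to zero by
convention). Dynamo pixel coordinates define the internal frame
(`nm = px · Å/px / 10`); STAR coordinates are treated as 0-based and are
shifted by one voxel on ingest/export.

A particle's axes have a fixed meaning on the filament surface: **z** points
radially outwards, **y** along the filament axis (up to sign), **x**
completes the right-handed frame. Polarity harmonization ("flipping")
post-rotates a particle 180° about its own x-axis, which inverts the y and z
senses simultaneously — the same operation a subtomogram pipeline applies
when a filament was traced against its growth direction.

## Filament paths

Hand-clicked traces are piecewise-linearly interpolated and resampled at a
constant arc-length step (default 7 nm, matching the ring separation used in
picking). Local frames are rotation-minimizing (parallel transport):
Frenet frames are undefined on the straight stretches that dominate
microtubules. Cylindrical coordinates (s, r, φ) of a particle are computed
against the nearest path node with sub-spacing refinement by projection onto
the local tangent; the foot point is clamped to the path extent so r equals
the minimal distance to the finite centerline. φ = 0 lies along the
transported normal.

Two caveats of polyline resampling are documented rather than hidden: steps
are uniform in *arc length*, so the Euclidean gap across a sharp corner is
shorter than the spacing, and re-resampling a *curved* polyline shifts
points slightly (corner-cutting shortens it). Both effects vanish on the
gently curved centerlines the package targets; tests pin the exact behavior
on straight paths and bound it on arcs.

## Seeding and cleaning

Ring seeding reproduces tubular-surface over-picking: one ring per path
point, 18 seeds per ring at 23 nm radius, rings 7 nm apart, every seed's
z-axis pointing outwards and azimuths starting at the transported normal.
Azimuth randomization spins each seed about its own z-axis by an independent
U[0°, 360°) angle (metadata counterpart of missing-wedge mitigation).
Duplicate removal is greedy in descending score order (ties broken by row
order; unscored particles count as score 0): a particle is kept iff no
previously kept particle lies within `min_dist` (default 7 nm, one particle
footprint). Score filtering removes particles with cross-correlation
strictly below the threshold (default 0.32); a scoreless particle is an
error, never silently kept or dropped.

## Pair geometry and the θ angle

For every same-filament pair within `max_dist` (default 16 nm) the θ angle
is measured between the *oriented* displacement and the filament growth
tangent at the pair midpoint. The displacement is oriented by the particle
frame: it points from the member whose own y-axis has a non-negative
component along it. Because a bound dimer's y-axis can point with or
against the growth direction, θ spans [0°, 180°]; a circumferential (ring)
pair sits at 90°, an axially pitched helix at its helical angle.

One consequence of this convention is worth stating: when particle
orientations and positions are both noisy, the sign choice correlates with
the same axial jitter that perturbs θ, so the measured θ of true ring pairs
is biased slightly *below* 90° (by ≈6° at the default noise levels). The
distribution still peaks in the 90° histogram bin in the large majority of
random fixtures; the bias is a property of the convention, not of the
estimator, and disappears as orientation noise dominates positional noise
or vice versa.

Pairs are classified perpendicular (|θ − 90°| ≤ `tol_perp`), parallel
(θ ≤ `tol_par` or θ ≥ 180° − `tol_par`) or other; the windows must not
overlap.

## Chain grouping

Chains are connected components of the particle graph whose edges are
retained pairs: class within `chain_classes` (default: perpendicular) and
separation inside `dist_window`. Members are ordered by azimuth along the
minimal covering arc; a chain's angular extent is that arc's length, and
its copy number the member count. Isolated particles are copy-number-1
chains (individual dimers).

The default edge windows are derived from the decoration geometry, not
fitted: adjacent dimers in a ring at 23 nm radius with 18 azimuthal sites
are separated by a chord of 2·23·sin(10°) ≈ 8.0 nm at θ = 90°, while the
nearest confounders are the inter-ring diagonal (7 nm axial + one site:
10.6 nm at θ ≈ 49°) and the two-site chord (15.7 nm). With ≈1 nm positional
jitter, θ of a ring edge scatters with σ ≈ 10°, so the perpendicular window
±20° (midpoint between 90° and 49° is ≈70°) and the distance window
(5, 10) nm separate edges from confounders by ≥2σ on each axis. Wider
windows — e.g. ±30° and (5, 16) nm — demonstrably merge distinct chains
under the same noise. For helical decorations the consecutive-member step
is ≈14.7 nm at 33°, so a helical analysis configures
`chain_classes: [other]` and a wider distance window; these are run-config
parameters, not code changes.

Decoration density is particles per nm of filament, reported per filament
and pooled (total particles / total length; the pooled value is re-checked
against the length-weighted per-filament mean at report time).

## Synthetic data

The generator emulates the statistical structure of the experimental
coordinate data; all parameters are config-exposed.

* **Lattice**: subunit *n* of the 1-start helix at azimuth n·twist and
  axial n·rise on a cylinder (13-pf defaults: twist −27.7°, rise 9.4 Å,
  subunit radius 11.5 nm — the subunit radius is deliberately smaller than
  the 23 nm decoration radius; presets for 11–16 protofilaments use the
  ideal −360/N twist, no supertwist). `estimate_helical_params` inverts the
  construction (circular-mean azimuth increment, mean axial increment) and
  is exact on noise-free lattices.
* **Ring mode** (sparse, autoinhibited-like): each ring hosts a chain with
  probability `occupancy` (default 0.3); chain length is drawn from a
  truncated geometric law on 1..6 (p = 0.5) — a one-parameter monotone law
  matching the qualitative observation of short oligomers with at most six
  dimers; members occupy consecutive azimuthal sites at the same axial
  position.
* **Helical mode** (active-like): one continuous helix whose
  consecutive-member displacement makes the target angle (default 33°) with
  the axis, thinned by `occupancy` (default 0.95).
* **Nuisance processes**: orientation noise (rotation-vector components
  N(0, 8°) by default), positional jitter (N(0, 1 nm) per coordinate),
  spurious particles uniform on the decoration cylinder (1 per 100 nm —
  false picks surviving the score filter), and a per-filament polarity flip
  (probability 0.5, since traces are digitized in random directions).
  "Noise-free" means all four processes off; for helical decorations it
  additionally means full occupancy, since a vacancy changes the angle
  subtended by its neighbors.

Ground truth (chain memberships, polarity map) is returned with every
decoration, so analyses can be validated exactly: in the zero-noise limit
the recovered chains equal the generated ones member-for-member.

What the generator does **not** model: missing-wedge anisotropy (the tilt
scheme is metadata only), density-level effects (defocus, CTF), correlated
alignment errors along a filament, protofilament-number transitions within
one filament, and real score distributions (scores are uniform on
[0.32, 1)). Passing tests therefore demonstrate the correctness of the
geometry and bookkeeping, not robustness to every failure mode of real
tomograms.

## Problem sizes and determinism

The standard fixture is 20 filaments × 500 nm (~900 particles, ~700 pairs),
which the full pipeline analyzes in well under a second; the lattice checks
use 200 subunits and the θ-range sweep 10,000 pairs. Every stochastic
component takes an explicit seed, and identical config + seed reproduces
byte-identical output files. Histogram bins are centered on multiples of
the bin width (θ default 10°, edges at ±5°); the histogram mode breaks ties
toward the lower bin center.

## Known limitations

* θ is computed against the tangent at the path node nearest the pair
  midpoint; on strongly curved filaments (radius comparable to the pair
  separation) this is a first-order approximation.
* Chain edge windows assume the 23 nm / 18-site decoration geometry; other
  radii or site counts require re-deriving `dist_window` and `tol_perp`
  from the corresponding chord lengths.
* Polarity is an input label (from the generator or the user), never
  inferred from the coordinates; axial-sense statistics on unknown-polarity
  filaments treat them as plus.
* The Dynamo dialect reader assumes the common 35-column layout (column
  indices configurable); exotic table variants need an explicit
  `DynamoColumns`.
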