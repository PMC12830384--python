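# Methods

## Problem and model

An *aggregate* is a collection of small, similar, touching components —
berries in a grape bunch, tomatoes on a truss. Multi-view reconstruction
(SfM/MVS) of such an object yields one fused point cloud in which the
individual components are not separated. `aggrefit` segments that cloud
into components under a single modeling assumption: **each component is
well approximated by an affinely placed template mesh**, a sphere by
default. The output is one placed template per component (translation,
per-axis scale, rotation) plus the per-point clustering that produced it.

The pipeline has five stages:

1. **Preprocessing.** Optional HSV color filtering and box cropping isolate
   the aggregate; the cloud is then centered on its bounding-box midpoint
   and scaled uniformly so its largest extent spans `[-1, 1]` (uniform so
   sphericity is preserved), and downsampled on a `200^3` voxel grid,
   replacing the points of each occupied voxel by their centroid.
2. **Clustering.** k-means (Lloyd's algorithm, k-means++ seeding, explicit
   seed) with user-chosen `k` *larger* than the expected component count
   `N_e`; 1.5-2 x N_e is the recommended over-provisioning. Density-based
   clustering is deliberately not offered: SfM clouds have inhomogeneous
   density that destabilizes neighborhood-radius parameters.
3. **Component fitting (RANSAC + chamfer refinement).** Per cluster,
   `n_hypo = 50` hypotheses: draw 10% of the cluster (min 3 points), place
   the template at the subsample centroid with the user's initial radius,
   and greedily refine. Each refinement iteration scores 35 candidates —
   7 translations (none, +/-0.01 on each axis) x 5 radius scalings (0.8,
   0.9, 1.0, 1.1, 1.2, multiplicative on the current radius) — by the
   symmetric chamfer distance

       d_CD(P, V) = mean_p min_v ||x_p - x_v|| + mean_v min_p ||x_v - x_p||

   between the subsample and the placed template vertices, and adopts the
   best strictly improving candidate. Refinement stops when the chamfer
   drops below `d_th1 = 0.015`, improves by less than `d_th2 = 0.001`, or
   reaches `n_refi = 50` iterations. Every cluster point is then classified
   by its distance to the refined sphere surface, `d_p = |r - ||x_p - c|||`;
   the hypothesis is *valid* if the fraction with `d_p < eps = 0.015`
   strictly exceeds 50%. Among valid hypotheses the one with the smallest
   chamfer (recomputed against its inlier points) wins.
4. **Merging to a fixpoint.** Two fitted spheres overlap when their center
   distance is strictly below `alpha (r_i + r_j)` with `alpha = 0.9`.
   Connected groups of overlapping fits are pooled and re-clustered with
   k = (group size - 1), refit, and the round repeats until no overlap
   remains (guaranteed within the initial k rounds since k strictly
   decreases whenever anything merges).
5. **Detailed fitting.** Each surviving cluster's best sphere seeds a
   coordinate-descent search over translation, *per-axis* scale, and
   rotation (+/-10 degrees per move about each axis, accumulating across
   iterations), scored against all cluster points with the same three
   stopping rules.

For ellipsoidal or slightly deformed templates three generalizations
activate: the inlier criterion becomes the fraction of placed template
vertices within `eps` of the cluster; hypothesis refinement gains the six
rotation moves; and the merge test becomes "more than n% of either
component's vertices lie strictly inside the other" (n = 2 for ellipsoids,
10 for deformed spheres). The vertex-fraction validity cutoff defaults to
0.35 rather than mirroring the spherical 50% rule: vertex coverage — unlike
the point-inlier ratio — is bounded by the cluster's share of the visible
surface, and with ~80% visibility a component split across two clusters
tops out near 40%; a 0.5 cutoff would reject every split component and
disable merging exactly where it is needed. Junk placements measure far
below 0.35. Inside/outside is decided by the
generalized winding number of the watertight template mesh; surface points
(winding 1/2) do not count as inside.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `k` | user | - | initial cluster count; use 1.5-2 x expected components |
| `initial_radius` | user | normalized | start radius; set to the smallest expected component |
| `n_hypo`, `n_refi` | 50, 50 | - | hypothesis and refinement budgets |
| `sample_fraction` | 0.10 | - | RANSAC subsample per hypothesis |
| `epsilon` | 0.015 | normalized | inlier distance threshold (strict `<`) |
| `min_inlier_ratio` | 0.5 | - | validity cutoff (strict `>`) |
| `d_th1`, `d_th2` | 0.015, 0.001 | normalized | chamfer stop / improvement stop |
| `translation_step` | 0.01 | normalized | candidate translation width |
| `scale_factors` | 0.8...1.2 | - | multiplicative radius/axis-scale moves |
| `alpha` | 0.9 | - | sphere-overlap merge factor |
| voxel resolution | 200 | per axis | downsampling grid over `[-1,1]^3` |
| template subdivisions | 2 | - | icosphere tessellation (162 vertices) |

All distance-like thresholds are expressed in the normalized frame, which
ties them to the component scale: they suit components whose normalized
radius is roughly 0.05-0.15 (berry-sized relative to the whole bunch).
Components much larger than ~0.17 make the fixed steps proportionally too
small — refinement stalls short of the center and hypotheses fail the 50%
rule; components much smaller than ~0.07 let the chamfer dip under `d_th1`
so refinement stops on partial caps and over-segmentation appears. This
scale window is a property of the printed absolute thresholds, not of the
implementation. Within the window the pipeline is forgiving of the
initial-radius guess: the chamfer floor of a berry-sized cluster stays
above `d_th1`, refinement keeps iterating, and the multiplicative scale
steps recover the true radius from starts as far off as ~0.7-1.3 x;
systematic over-segmentation from undersized starts appears only for
components small enough that `d_th1` halts refinement early.

The template tessellation sets the chamfer floor: with 162 vertices the
nearest-vertex distance for an exactly fitting sphere of radius r averages
about 0.11 r, so chamfer values below that floor are unreachable and the
improvement criterion (`d_th2`), not `d_th1`, usually terminates the
refinement.

## Synthetic aggregates

The generator emulates what SfM typically delivers for a bunch:

* **Packing.** Components are placed by seeded sequential rejection
  sampling: each new component touches a randomly chosen anchor (center
  distance 0.95-1.0 x the radius sum), directions biased along a vertical
  axis, lateral excursions capped, so the bunch elongates realistically.
  Deep interpenetration (pairwise distance below 0.95 x radius sum) is
  rejected. The finished bunch is rescaled to span `[-1, 1]`; since that
  rescale is what fixes the *normalized* radii, the elongation scales with
  component count and twelve candidate arrangements are drawn per seed,
  keeping the realized normalized radii inside the requested range
  (default 0.08-0.15) for counts around 10-15.
* **Sampling.** Uniform surface samples at `density_per_component = 12000`
  points per unit area (roughly 1.5-3.5 x 10^3 raw points per berry-sized
  component, matching typical photogrammetric clouds of 1-10 x 10^3 points
  per component); area-weighted rejection keeps ellipsoid sampling uniform.
* **Occlusion.** Points strictly inside a neighboring component are deleted
  (contact occlusion), then one random spherical cap covering
  `occlusion_fraction = 0.2` of each component's directions is removed
  (camera shadowing). Contact occlusion is applied first; the order only
  affects retention bookkeeping.
* **Noise.** Isotropic Gaussian noise, `noise_sd = 0.005` normalized units
  (a third of `eps`), added to every surviving point.
* **Shapes.** `ellipsoid` elongates one axis by 1.25-1.45 under a random
  rotation; `deformed` perturbs the radius with a smooth low-order field
  (weighted second-Legendre lobes, amplitude 8% of the radius).

What the generator does **not** emulate: structured SfM error (depth-
dependent noise, streaks), varying density with viewing angle, stem/rachis
geometry, and components invisible to *every* camera. Passing recovery
tests on these clouds therefore demonstrates the geometry pipeline —
clustering, fitting, merging — under noise and partial coverage, not
robustness to every artifact of real photogrammetry.

## Evaluation

Recovered components are matched to ground truth by minimum-total-distance
one-to-one assignment (Hungarian algorithm) on center distances; `M_d`/`M_s`
are the mean and sample (n-1) standard deviation of matched center
distances, normalized by the diagonal of the input cloud's bounding box.
Because a global assignment will happily pair a spurious component with a
missed berry on the far side of the bunch, a pair only counts as a
correspondence when the found center lies within the true component's
bounding radius — i.e. a recovered component corresponds to the berry its
center sits in, which is how a human would pair them during visual
inspection. Remoter pairs and surplus components on either side are
reported as unmatched, not folded into `M_d` as penalties.

## Numerical and design choices

* **Tie-breaking.** Candidate enumeration places the identity move first
  and `argmin` takes the first minimum, so exact ties prefer not moving
  and refinement then stops on the improvement criterion.
* **Strict inequalities** for the inlier test, the validity rule, and the
  sphere-overlap rule; boundary points are excluded everywhere.
* **Voxel membership** is half-open `[lo, hi)` per axis with the last
  voxel closed, so boundary points are assigned deterministically.
* **Connected components, not cliques,** define a merge group: chained
  over-splits (A overlaps B overlaps C) merge in one round.
* **Re-clustering a pair** (m = 2, k = 1) is implemented as a label union;
  running k-means with k = 1 would produce the same partition.
* **Detailed-fit candidates** form the union of single moves (6
  translations + single-axis scale moves + 6 rotations) rather than a full
  Cartesian product, i.e. coordinate descent; per-axis scales are clamped
  to [0.4, 2.5] x the initial radius to prevent degenerate flattening on
  one-sided clusters; the composed rotation is re-orthonormalized (SVD)
  after every update.
* **Seeding.** One master seed; every stage, cluster, and hypothesis
  derives a 31-bit sub-seed from `SeedSequence([master, stage_tag, ...])`,
  so adding hypotheses or rounds never shifts unrelated draws and reports
  are byte-reproducible.
* **Hypothesis ranking** uses the chamfer against inlier points only (for
  the sphere template); detailed fitting scores against all cluster
  points. For non-spherical templates the ranking chamfer uses all cluster
  points, since the generalized criterion classifies vertices rather than
  points.

## Known limitations

* The absolute thresholds tie the method to berry-scale components
  (normalized radii ~0.05-0.15); outside that window counts degrade as
  described above. Automatic scaling of `eps`/steps with the initial
  radius would widen the window but is deliberately not done, to keep the
  standard parameterization.
* Components whose every cluster fails the 50% validity rule produce no
  output component and cannot trigger merging; densely packed or deeply
  occluded components are undercounted rather than mislocated (`M_d` stays
  small while `N_m` drops).
* The merge step only reduces the cluster count; a single cluster spanning
  two components is split only indirectly, by over-provisioning `k`.
* Problem sizes in the test suite and the acceptance script (bunches of
  8-15 components, one pipeline run per seed) were chosen to exercise the
  full pipeline at desk scale; the method itself has no such limit.
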