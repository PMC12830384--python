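# aggrefit

Segment a point cloud of an *aggregate* — a grape bunch, a tomato truss,
any collection of small near-spherical touching components — into
individual components, each exported as its own mesh.

Generic multi-view reconstruction (COLMAP-style SfM/MVS) of such objects
produces one fused cloud: the bunch has a shape, the berries do not.
`aggrefit` recovers the berries with geometry-aware clustering, for
computer-graphics modeling and 3D fruit phenotyping (component counts,
sizes, positions) alike.

## Method

Given a cloud `P` and a component template mesh (unit icosphere by
default), the pipeline runs:

1. **Normalize + downsample** — uniform scale into `[-1, 1]^3`, then a
   `200^3` voxel grid keeps one centroid per occupied voxel.
2. **k-means** with user-chosen `k` (use 1.5-2 x the expected component
   count `N_e`; over-provisioning is corrected later).
3. **RANSAC sphere fitting per cluster** — 50 hypotheses, each refining a
   sphere `(c, r)` on a random 10% subsample by greedy descent over 35
   candidates per iteration (7 translations x 5 radius scalings), scored
   by the symmetric chamfer distance

   `d_CD(P, V) = (1/|P|) Σ_p min_v ‖x_p − x_v‖ + (1/|V|) Σ_v min_p ‖x_v − x_p‖`.

   A hypothesis is valid when more than 50% of the cluster lies within
   `ε = 0.015` of the sphere surface (`d_p = |r − ‖x_p − c‖|`).
4. **Merge overlapping fits** — spheres with `‖c_i − c_j‖ < 0.9 (r_i + r_j)`
   mark clusters for pooling and re-clustering at (group size − 1),
   iterated until no overlaps remain.
5. **Detailed fitting** — per-axis scaling and ±10° rotation moves refine
   each component against its full cluster.

With ground truth available, recovery is scored by the component counts
`N_e` vs `N_m` and by `M_d` / `M_s`, the mean / standard deviation of
matched center-to-center distances normalized by the input bounding-box
diagonal. See `docs/methods.md` for the full model, parameters, and
limitations.

## Worked example

Generate a synthetic 12-berry bunch with SfM-like noise and occlusion,
segment it, and compare against the generator's ground truth:

```python
import aggrefit as ag
from aggrefit.pipeline import PipelineConfig, run_pipeline, normalized_min_radius

aggregate = ag.generate_packing(12, seed=0)          # ground-truthed bunch
cloud, _ = ag.sample_surface(aggregate, seed=0)      # SfM-like point cloud

cfg = PipelineConfig(
    k=24,                                            # 2 x expected count
    initial_radius=normalized_min_radius(cloud, aggregate),
    seed=0,
)
result = run_pipeline(cloud, cfg, truth=aggregate)
print(ag.format_table(result.evaluation, n_vertices=len(cloud), n_initial=24))
result.write_meshes("out_meshes")                    # one OBJ per component
```

Output:

```
N_v (input points)                   16738
N_i (initial clusters)               24
N_e (true components)                12
N_m (found components)               11
M_d (mean center dist., normalized)  0.012295
M_s (sd center dist., normalized)    0.012722
```

Reading: from ~17k input points and 24 deliberately over-provisioned
clusters, merging collapsed the segmentation to 11 fitted components for
12 true berries (one deeply occluded berry produced no valid fit), and
the matched centers sit within ~1.2% of the bounding-box diagonal of
their true positions — comparable to the ~2% the method achieves on real
photogrammetric clouds.

The same workflow is available from the shell:

```sh
aggrefit simulate --n-components 12 --seed 0 --out-cloud bunch.ply --out-truth truth.json
aggrefit fit bunch.ply --k 24 --initial-radius 0.08 --truth truth.json --out-dir out/
aggrefit sweep --truth truth.json --out sweep.csv     # k / initial-radius sensitivity
```

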