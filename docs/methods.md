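# Methods

## Model and assumptions

The package estimates the length of the loop connecting two α-helices in a
medium-resolution CryoEM density map, measured along the map's skeleton — the
one-voxel-thick medial axis of the density iso-surface. It assumes that

* skeletonization and helix detection have already happened upstream: the
  inputs are a skeleton point cloud (MRC volume or XYZ text, coordinates in Å)
  and the two helix central axes, each given by its two endpoints in Å;
* the voxel lattice is cubic (isotropic voxel size); anisotropic maps are
  rejected;
* a continuous skeleton links the two helices where a loop exists — when it
  does not, the affected endpoint pairs come back infeasible rather than
  producing a number.

The measured quantity is the length of the simplified polyline from one helix
endpoint to the other, *including* the two straight attachment segments that
join the endpoints to the loop skeleton. The reference value for a loop of
`n` residues is 3.8 Å × (n + 1).

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| helix mask radius | 2.3 | Å | α-helix radius is 2.3–2.5 Å; skeleton voxels within this distance of a helix axis belong to the helix, not the loop |
| max LCG edge length `l` | 2.0 (strict `<`) | voxel units | `l < 2` joins all 26-neighbours on a unit lattice (step lengths 1, √2, √3) while separating clusters ≥ 2 voxels apart |
| attachment cutoff | 5.0 | Å | an endpoint farther than 5 Å from every node of its best LCG marks the pair infeasible; exactly 5.0 Å is still accepted (only *longer* edges are discarded) |
| ε sweep | 0 : 6 : 0.05 | Å | 121 samples of the vertex-removal band half-width; measured length is a non-increasing step function of ε |

All four pairs are always evaluated and reported; the package does not guess
which pair carries the real loop. The best-ε report requires an expected
length (a residue count) — it is an evaluation device, not a blind predictor.
Without one, the unsimplified (ε = 0) measurement is reported.

## Numerical and design choices

* **Mask boundary** — "within 2.3 Å" is read inclusively: a point at exactly
  2.3 Å is removed. Distances go to the *finite* axis segment, not the
  infinite line, so loop voxels beyond the helix ends survive.
* **LCG determinism** — nodes are sorted lexicographically and components
  labelled `lcg0, lcg1, …` by (size descending, then smallest node), so ids,
  tie-breaks and BFS neighbor order are reproducible bit-for-bit.
* **LCG selection** — the directed Hausdorff criterion is an argmin over
  clusters; ties break by larger node count, then smaller id. The first
  argument is always the endpoint pair and the second the cluster (the
  distance is not symmetric). The selection is greedy and can pick a wrong
  cluster when a decoy hugs both endpoints more tightly than the loop; no
  repair heuristic is applied — the error surfaces as a wrong measurement.
* **BFS** — unweighted minimum-hop search, expanding neighbours in ascending
  lexicographic coordinate order. A `--weighted-path` variant was considered
  and rejected for the default: hop-minimal paths on the 26-connected lattice
  already favour long diagonal steps, and the simplification stage dominates
  the final length.
* **Douglas-Peucker** — the distance test uses the perpendicular distance to
  the infinite line through the current segment's endpoints; coincident
  endpoints fall back to point distance. The split condition is strict
  (d_max > ε), so ε = 0 removes only exactly collinear vertices, which is
  length-neutral. Equal maximal deviations split at the earliest index.
  Because the split vertex depends only on geometry, retained vertex sets are
  nested across ε, which yields the non-increasing step function.
* **Best ε** — the smallest sampled ε attaining the minimum
  |measured − expected|.

## Synthetic fixture generator

`generate_hlh` emulates the *post-masking* skeleton of a helix-loop-helix
motif rather than simulating a density map and re-skeletonizing it:

* the loop is a cubic Bézier with a gentle bulge (10–20% of the chord, with a
  small out-of-plane twist), uniformly scaled so that its analytic arc length
  (adaptive quadrature, relative error ≤ 1e-9) equals 3.8 × (n + 1) exactly;
  the whole scene gets a random rigid rotation;
* the two helix axes (8–12 Å long) continue the loop's end tangents, the way
  a real loop leaves a helix;
* the curve is sampled at ≤ 0.3 × voxel-size arc spacing, which guarantees the
  snapped loop stays 26-connected;
* jitter is a *spatially correlated* Gaussian displacement field (drawn at 8
  knots along the curve and interpolated, pointwise sd = `jitter_sd`).
  Independent per-voxel jitter would shatter the snapped skeleton into
  fragments, which is not how skeletonization errs — its bias is smooth along
  the curve;
* decoy clusters are compact Gaussian blobs placed ≥ 8 Å from the true pair's
  endpoints; noise points are uniform singletons ≥ 5 Å from everything;
* points within 2.3 Å of either axis are removed, mirroring the mask the
  pipeline would apply.

What the fixtures do **not** model: real loop-geometry statistics (protein
loops are not Bézier curves), density artefacts (missing or spurious density,
resolution anisotropy), helix-detection error in the axis endpoints, and
skeletonization topology errors other than smooth displacement. Passing the
synthetic recovery tests therefore demonstrates the correctness of the
measurement pipeline given a reasonable skeleton, not performance on
experimental maps, where upstream detection quality dominates.

## Test problem sizes

The suite's behavioural checks use: 500 random point/cluster draws for the
directed-Hausdorff oracle, 200 random ≤ 10-vertex polylines × 5 ε values for
the simplifier oracle, one 500-point cloud for the clustering oracle, four
fixtures × 121 ε samples for the step-function property, and 50 seeded
fixtures each (n cycling through 1..10) for the clean (≤ 0.5 Å at the best
sweep ε, ≥ 95%) and noisy (jitter sd 0.5 Å, two decoys, ≤ 2 Å, ≥ 80%)
recovery rates. The whole suite runs in well under a minute on one CPU.

## Known limitations

* The greedy Hausdorff selection has no fallback; pathological segmentations
  can select the wrong cluster for a pair and yield a confidently wrong
  length.
* Lengths are measured along a hop-minimal path; in a cluster with cycles a
  different homotopy class of path (e.g. around a bulge) is never explored.
* ε must be chosen (or swept against an expected length); no blind ε
  selection rule ships with the package.
* MRC maps with permuted axis order are only handled with `--permissive`;
  anisotropic voxels are rejected outright.
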