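# Methods

`cbparc` implements connectivity-based parcellation (CBP): subdividing a
seed region of cortex by clustering its voxels on the similarity of their
tractography-derived whole-brain connectivity profiles, then validating the
cluster number, building group maps, and characterizing the subregions by
their connectivity fingerprints and hierarchical module structure. This note
records the model, the operationalizations chosen where the procedure was
genuinely open, the defaults and their units, and what the synthetic data do
and do not establish.

## Connectivity profiles and preprocessing

The input per subject is an M × N matrix of streamline-arrival counts: M
seed voxels, N whole-brain columns (native voxels, or target regions after
aggregation), with `samples_per_voxel` streamlines seeded per voxel
(default 15,000). Preprocessing:

* **Count threshold** (`min_count`, default 20): entries below 20 counts —
  connection probability below 20/15,000 — are set to zero, the
  conventional false-positive filter for probabilistic tractography.
  Applied per subject, before down-sampling; the filter is idempotent and
  monotone in the threshold.
* **Down-sampling** (`downsample_mm`, default 2.0 mm): whole-brain columns
  are summed within axis-aligned blocks tiled from the volume origin, with
  block edge `ceil(target/native)` native voxels (half-open intervals,
  0-based indices). Summation conserves per-row totals exactly, so
  count-based thresholds keep their semantics downstream.
* **Cross-correlation**: Pearson correlation between every pair of seed
  voxel profiles. Rows with zero variance (all connections removed by the
  threshold) are kept, flagged, and given off-diagonal correlation 0:
  dropping them would desynchronize the voxel bookkeeping against the seed
  mask.

## Spectral parcellation

The correlation matrix is mapped to a non-negative affinity
`a = (r + 1) / 2` — an order-preserving rescaling of [−1, 1] onto [0, 1];
the literature this pipeline follows does not fix a transform, so the
simplest monotone one is used and is configurable in principle. Clustering
is normalized-cut spectral clustering (scikit-learn, precomputed affinity):
k-means on the leading Laplacian eigenvectors, 10 restarts, best inertia,
fixed seed. Runs are deterministic given the seed; per-(subject, k) seeds
are spawned from one root seed. Outcomes with empty clusters are flagged
degenerate, never silently relabeled.

## Cluster-number selection

Two arms of evidence:

**Cross-validation indices.** Cramer's V between two subjects'
parcellations is `sqrt(chi2 / (n (min(r,c) − 1)))` on the label contingency
table — 1 for identical partitions up to relabeling, undefined when both
sides have a single cluster. The cohort score at each k is the mean over
all subject pairs (V is permutation-invariant, so no label matching is
needed first). The topological distance TpD compares the parcel-adjacency
graphs of the two hemispheres: parcels are adjacent when any voxels are
6-connected across the boundary, and TpD is the minimum over parcel
correspondences of the fraction of mismatched off-diagonal adjacency
entries — 0 iff the graphs are isomorphic. The source literature gives TpD
no closed formula; this mismatch fraction is our operationalization and
satisfies every stated property (range [0, 1], 0 for similar topology).
Parcellations with unequal k get TpD 1 by convention, matching the index's
role of finding a k shared by both hemispheres. The matching is exhaustive
up to k = 8; beyond that a seeded FAQ quadratic-assignment heuristic gives
an upper bound, flagged by a warning.

Candidate k are interior local maxima of mean V intersected with interior
local minima of mean TpD. Plateau edges count as extrema, and so do
interior attainers of the series' global optimum: TpD in particular sits on
a flat plateau of exactly 0 whenever several k give isomorphic hemispheric
topologies (common for small parcel graphs), and a strict-valley rule would
never fire there even though the index is at its best.

**PCA criteria.** Per subject, the spectrum of the seed-voxel correlation
matrix (seed voxels as variables, z-scored; whole-brain columns as
observations) yields three component counts: (1) the smallest count whose
cumulative proportion of variance reaches 80%, with a 1% lower-limit
allowance (so ≥ 79% accepted); (2) the Kaiser count of eigenvalues > 1,
extended by the next eigenvalue when it lies within `eigen_closeness`
(default 0.2 — the source states "next closest to 1" without a bound) of 1;
(3) the elbow of a power curve `a·x^(−b)` fitted by log-log least squares
to the sorted eigenvalues, taken as the rank where the fitted curve, with
both axes normalized to [0, 1], lies farthest below the chord joining its
endpoints. The elbow is deterministic and oracle-checkable; a flat spectrum
has no elbow and is flagged. Column standardization is required for the
"eigenvalue > 1" criterion to be meaningful (correlation-scale spectrum).

The per-subject elbow values are averaged after greedy stability trimming:
while the most deviant subject differs from the current mean by more than
`stability_delta` (default 0.5), it is excluded and the mean recomputed.
The rounded stable mean breaks ties among candidates; when no candidate
exists it is itself used, with a prominent warning.

## Group maps

Cluster labels are arbitrary per subject, so each subject is matched to a
reference subject (first by id) by the Hungarian assignment maximizing
total voxel overlap. The maximum probability map then assigns each voxel
its most frequent matched label; per-label frequency maps are kept, exact
ties go deterministically to the lowest label id and are flagged. Subarea
masks are frequency maps thresholded inclusively at `prob_threshold`
(default 0.25, i.e. 2 of 8 subjects). Registration to a common space is
assumed done upstream; the synthetic cohort shares one space by
construction.

## Fingerprints and comparisons

Per-voxel connection probabilities (counts / samples) below
`seed_threshold` (default 3.08 × 10⁻⁵) are zeroed at the individual level;
the strength of a (subarea, target) pair is the mean over the subarea's
seed voxels of the summed surviving probability into the target's columns.
The mean (not the sum) is used so subarea size does not dominate; this is
logged and configurable in principle. Population tract maps binarize each
subject's surviving connections and keep columns present in at least
`population_fraction` (default 0.5, i.e. 4 of 8) of subjects — monotone in
the fraction. Inter-subject similarity is the Pearson correlation of
subarea fingerprint vectors with two-sided p-values, flagged at p < 0.001.
Tracer coherence is `|tracer ∩ found| / |tracer| × 100` — the tracer list
is the denominator, so additional tractography findings do not penalize;
name harmonization between nomenclatures is the caller's responsibility.
Network shares sum fingerprint strength over each named network's regions
(overlapping networks each count) and normalize per subarea to 1.

## Hierarchical modularity

Group-averaged subregion fingerprints are hierarchically clustered under a
grid of distance metrics {euclidean, seuclidean, cityblock, cosine,
correlation} × linkages {average, weighted, complete, single, ward}; Ward
is valid only with Euclidean distances and is skipped elsewhere with a
note. Each dendrogram is scored by its cophenetic correlation coefficient
(correlation between original and merge-height distances); the maximum
wins. Linkages are ordered by typical cophenetic fidelity with average
first — the canonical choice for dendrogram faithfulness — so exact ties
(e.g. several linkages reproducing an exact ultrametric) resolve to
average, and are flagged. Negative cophenetic values are reported raw with
a warning, not clamped. Families are extracted by cutting the winning
dendrogram either at a requested count or automatically in the largest gap
between consecutive merge heights (which always yields between 2 and n − 1
families); the automatic rule is our choice — the source reports three
families without stating how three was chosen, so both modes exist.
Hemispheres are clustered separately by default; a bilateral mode
concatenates left and right subregions as separate items.

## Synthetic data

The generator emulates the *output* of probabilistic tractography, not the
tractography itself: per seed voxel, a multinomial draw of
`samples_per_voxel` streamlines over target-region voxels plus a sink
category absorbing streamlines lost to implausible or truncated paths
(`sink_fraction`, default 0.3), so per-voxel totals are at most the nominal
sample count, as the 20/15,000 threshold assumes. Structure is planted as
`k_planted` spatially contiguous parcels grown by seeded region-growing on
the voxel grid (farthest-point seeds, round-robin 6-neighbor claims), which
guarantees a meaningful parcel-adjacency graph for TpD. Each cluster's
target-preference profile combines round-robin preferred targets (0.6
weight) with a seeded Dirichlet tilt over all targets (0.4): exactly
complementary profiles would make the seed-voxel correlation spectrum rank
k − 1 and bias every PCA criterion low, a symmetry real tract systems do
not have. `profile_separation` mixes cluster-specific profiles with a
shared baseline; critically, per-subject Dirichlet perturbations (scale set
by `subject_noise`; concentration 1/noise² at the subject level, 4/noise²
at the voxel level) are applied to the shared and specific components
*separately* and then mixed, so subject variability cannot re-create
separation the configuration removed — at separation 0 the planted
structure is genuinely unrecoverable. Bilateral datasets mirror the
hemisphere across the first axis with identical planted topology; counts
are sampled independently per hemisphere, while the explicit
`mirror_hemisphere` operation copies counts row-for-row (a topological
mirror).

Defaults mirror the emulated study loosely: 8 subjects, 15,000 samples per
voxel, bilateral; the desk-scale grid is 6 × 6 × 2 voxels per hemisphere
with 4 planted clusters and 12 target regions (2 × 2 × 2 voxel blocks at
1 mm, so 2 mm down-sampling aggregates a region into exactly one column),
separation 0.9 and noise 0.1.

What the synthetic data do **not** emulate: diffusion signal, fiber
orientation, streamline propagation, distance correction, registration
error, susceptibility artifacts, and spatially correlated noise. Passing
tests therefore establish the correctness and internal consistency of the
*analysis* — indices matching their definitions, planted structure
recovered under stated conditions — not performance on real diffusion MRI.

## Numerical choices and degenerate inputs

Thresholds are inclusive (`>=`) throughout. Coordinates are 0-based voxel
indices with half-open down-sampling blocks, recorded in the I/O sidecars.
All randomness flows from one seeded generator per run; identical config
and seed reproduce bit-identical outputs, including manifest hashes.
Degenerate cases are explicit errors or flagged results, never silent:
single-cluster Cramer's V errors (not 0), degenerate parcellations error in
TpD, flat spectra have no elbow, empty subareas give flagged zero rows,
constant fingerprints error naming the item, MPM ties are flagged.

The test and acceptance workloads use the desk-scale problem sizes above
(about 144 seed voxels per subject, k searched over 2–7, 20 replicate
seeds for the stochastic checks), chosen so the full suite exercises every
stage end-to-end while remaining quick to run.
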