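# Methods

## The model

`fcparc` treats cortical parcellation as a clustering-then-adaptation
problem on a shared triangulated surface. The observable for each ROI
vertex is its functional connectivity profile: the vector of Pearson
correlations between its conditioned BOLD time course and that of every
cortical vertex. Vertices belonging to the same functional network are
assumed to share a latent time course (plus vertex-specific noise), so
their profiles are nearly collinear, and cosine similarity — not Euclidean
distance — is the right metric: it ignores overall correlation magnitude
(which varies with per-vertex SNR) and compares profile *shape*.

Profiles are stored full-length with the self-correlation entry masked to
exactly 0. Dropping the self entry (so each vertex's profile has a
different coordinate system) would make profiles of different vertices
incomparable; masking keeps them in one vector space with identical
information.

### Group atlas

Subject-averaged profiles are clustered by spherical k-means: rows are
L2-normalized, assignment is by maximal cosine, centroids are normalized
means, and convergence is declared when assignments stop changing (at most
300 Lloyd iterations; empty clusters seize the worst-fitting vertex). The
objective — the "aggregate distance" Σ over vertices of (1 − cosine to the
assigned centroid) — is the natural spherical k-means loss; the best of
`n_restarts` random initializations wins (500 by default; the validation
pipeline uses 50, which at desk-scale problem sizes reaches the same
optimum in every paired check we ran while keeping the suite fast).

Model order is selected where the product of split-half reproducibility
(Dice) and silhouette has a strict interior local maximum over the scanned
K range; endpoints are never selected and plateaus resolve to the smaller
K. The silhouette uses the standard per-sample Rousseeuw form with cosine
distance (a = mean distance to own cluster, b = nearest other cluster's
mean distance); singleton clusters and exact a=b=0 ties score 0.

Dice between independently clustered parcellations is only defined after
solving the label-permutation problem; we use Hungarian assignment on the
vertex-overlap matrix. Network-level Dice is 2·V_overlap/(V₁+V₂); the
parcellation-level value is the *unweighted* mean over networks, whereas
both homogeneity metrics weight networks by vertex count — the two
conventions coexist deliberately and are implemented exactly as printed in
the field's formulas.

Spatial clusters (connected components of same-labeled vertices on the
mesh graph) whose summed vertex area is 10 mm² or smaller are dissolved:
each member takes its neighbors' majority label, with frequency ties
broken by the Pearson correlation between the vertex's profile and the
mean profile of each tied network. Passes repeat (≤ 100) until no small
component remains.

### Individualization

Iteration 0 computes per-network reference signals: member time courses
are standardized (mean 0, sd 1), averaged, and the average re-standardized,
so high-variance vertices cannot dominate. Each iteration then

1. reassigns every ROI vertex to the reference it correlates with most
   (ties to the lowest label);
2. computes each vertex's confidence r₁/max(r₂, 1e-6) — the ε floor makes
   an uncontested winner (non-positive second correlation) maximally
   confident; a vertex whose *winning* correlation is non-positive gets
   confidence 1;
3. averages the vertices with confidence strictly above 1.3 into a
   high-confidence signal per network (a network with none keeps its
   reference unchanged);
4. forms the next reference as the standardized equal-weight mean of the
   high-confidence signal and the current reference.

Ten iterations are run; the consecutive-iteration Dice trace is returned
so stability is observable (it reaches 1.0 well before iteration 10 at the
reference study conditions). Setting the threshold to ∞ provably freezes
the references, reducing the procedure to a single correlation
reassignment — a limit the tests exercise.

Two textual ambiguities in the antecedent method were resolved as explicit
options: the loop blends with the *current* reference by default
(`averaging="current"`, matching the loop semantics), with an
`averaging="original"` variant that always blends with the group-derived
reference; and the blended objects are time courses (not connectivity
profiles), since time-course correlations are what drive reassignment.
Both variants recover ground truth on synthetic subjects.

## Inference machinery

* **Mantel test**: Spearman correlation of the strictly-upper-triangular
  entries of two subject-similarity matrices; the null jointly permutes
  rows and columns of the first matrix; the two-sided p uses the add-one
  convention (1 + #{|null| ≥ |obs|})/(1 + B), so p ≥ 1/(1+B) and never 0.
* **Benjamini-Hochberg**: standard step-up (statsmodels backend), rejection
  at adjusted p ≤ α.
* **Paired comparisons**: Friedman omnibus plus all pairwise Wilcoxon
  signed-rank tests (zero differences excluded, counts logged), BH-adjusted,
  with the direction of each difference reported. Completely tied data
  yield statistic 0, p 1.
* **Cluster-extent correction**: one-sample t maps are thresholded at
  |t| > 8 by default (the forming threshold is configurable); clusters are
  connected components on the mesh graph and their extent is *surface
  area in mm²* — the natural size measure on a mesh, consistent with the
  10 mm² rule, and, unlike vertex counts, nearly tie-free, which keeps the
  max-extent permutation null calibrated (measured family-wise error
  ≈ 0.049 at nominal 0.05 versus ≈ 0.028 with integer counts). The null
  flips subject map signs (valid for the symmetric one-sample design);
  cluster p-values use the add-one convention against the max-extent null.

## The synthetic cohort generator

The generator emulates exactly the statistical structure the method
assumes, with defaults that define the package's reference study
conditions:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 8 | cohort size |
| `sessions_per_subject` | 2 | for intra-subject reproducibility |
| `runs_per_session` × `timepoints_per_run` | 1 × 200 | ~9 min at TR 2.8 s |
| `tr_seconds` | 2.8 | repetition time |
| `mesh_subdivisions` | 3 | icosphere, 642 vertices, ~25% ROI cap |
| `k_true` | 4 | true network count |
| `boundary_jitter` | 0.2 | fraction of ROI vertices whose true label deviates from the template |
| `snr` | 1.0 | latent sd / vertex noise sd |
| `latent_correlation` | 0.3 | pairwise correlation among network latents |

Subject-specific truths are boundary-only perturbations of a contiguous
group template (labels flip only at network borders, to a neighboring
network's label, never emptying a network) — spatially coherent individual
differences rather than salt-and-pepper relabeling. Latents are band-limited
to the 0.01–0.08 Hz analysis band, so filtering is near-transparent to
clean signal and filter behavior can be tested separately from signal
content; they carry a modest 0.3 pairwise correlation because resting-state
networks are never orthogonal. Non-ROI cortex carries a second,
*independent* network layout, so ROI profiles differ across networks for a
genuine reason, as in real cortex. With shared latent variance 1 and noise
sd 1/snr, two same-network vertices correlate at snr²/(1+snr²) — 0.5 at the
default SNR — which the tests verify against Monte-Carlo estimates. Anatomy
(thickness mean 2.5 ± 0.3 mm, curvature 0 ± 0.15 mm⁻¹) is generated by
neighbor-averaged Gaussian fields independent of network labels, making it
a true null for the Mantel analysis.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: hemodynamic convolution, motion and physiological
artifacts, spatial autocorrelation of noise, inter-subject surface
registration error, multi-hemisphere structure, and vertex-dependent SNR.
Recovery at Dice 1.0 under the reference conditions says the algorithm is
correct and self-consistent, not that real auditory-cortex parcellations
will reach that accuracy; on real 7T data, intra-subject reproducibility in
the 70% range is the realistic regime.

## Numerical choices

* Fisher transform clips |r| at 1 − 1e-7 (z ≈ 8.38) so exact ±1 stays finite.
* Zero-variance vertices are never silently dropped: profiles flag them in
  an exclusion list, reassignment gives them label 1 / confidence 1 with a
  flag.
* Sample (N−1) standard deviation in functional inhomogeneity;
  single-vertex networks contribute sd 0 with a warning.
* The band-pass is a 4th-order zero-phase Butterworth (`sosfiltfilt`);
  conditioning is applied per run before concatenation, and profiles are
  computed on the concatenated conditioned series. A second filter pass
  changes profiles of in-band signal by ~1e-3 (finite-length edge
  transients), so conditioning is near- but not exactly idempotent.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng` child seeds; every CLI stage is bit-reproducible
  (HDF5 is written with `track_times=False`, TSVs use `repr` floats).

## Validation problem sizes

The acceptance battery runs the reference cohort (8 subjects × 2 sessions
× 200 timepoints on 642 vertices), a noise-free variant, 20 replicate
cohorts for the intra-vs-inter ordering, 500 Mantel replicates at 999
permutations (n = 12 subjects), and 200 cluster-FWE replicates at 500
sign-flip permutations (12 subjects, 162-vertex mesh, forming threshold
2.0 — a calibration check needs a non-degenerate supra-threshold process,
which the production threshold of 8 cannot produce at these sample sizes).
These sizes were chosen as the smallest at which each property is
statistically meaningful.

## Known limitations

* The silhouette's "between" term is the nearest-other-cluster mean; with
  a mean-over-all-clusters variant, selected model orders could differ.
* Inter-subject Dice pools all cross-subject session pairs; a
  matched-session variant is computable from the same summary.
* Whole-cortex (non-ROI) individualization and CIFTI/volumetric inputs are
  out of scope; the ROI is a single contiguous patch on one mesh.
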