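# Methods

## The model

`mbnet` analyses brain morphology at the level of *individual* morphological
brain networks (MBNs). For one subject, each of the R atlas regions (90 for
the AAL parcellation; R is a free parameter throughout) contributes a
multiset of vertex feature values — in the MRI use case, smoothed modulated
gray-matter intensities of the voxels carrying that region's label,
optionally multivariate (d features per vertex). The network is built from
pairwise comparisons of these empirical distributions; no spatial
information beyond label membership is used.

### Edge definition: energy distance and exponential similarity

For regions X = {x₁…x_{n₁}} and Y = {y₁…y_{n₂}} (rows of feature vectors),
the dissimilarity is the multivariate energy distance

    e(X, Y) = n₁n₂/(n₁+n₂) · [ 2/(n₁n₂) Σᵢⱼ ‖xᵢ−yⱼ‖₂
                               − 1/n₁² Σᵢⱼ ‖xᵢ−xⱼ‖₂
                               − 1/n₂² Σᵢⱼ ‖yᵢ−yⱼ‖₂ ],

which is non-negative and zero exactly when the two empirical distributions
coincide. The three double sums are evaluated with `scipy.spatial.distance.cdist`
in double precision; the result is clamped at 0 against ~1e−16 round-off.

Per subject, the R(R−1)/2 off-diagonal distances are min–max normalised and
converted to similarities

    c(X, Y) = exp(−(e − e_min)/(e_max − e_min)),

so every subject's closest pair scores exactly 1, its farthest pair exactly
e⁻¹ ≈ 0.368, and all off-diagonal values lie in [e⁻¹, 1]. The
normalisation domain is deliberately *per subject*: a per-pair min–max is
degenerate (0/0), and a pooled-across-subjects variant — exposed nowhere as
a default because it couples subjects — would destroy the individual-level
interpretation. The diagonal is fixed at 0 and excluded from thresholding,
as self-similarity carries no edge information. If every pair is
equidistant (possible only in pathological toy inputs) the matrix
degenerates to all-ones off-diagonal with a logged warning.

One consequence worth knowing: because e_max is a per-subject quantity, a
strong regional perturbation in one group shifts the normalisation of *all*
that group's edges, so secondary group differences of opposite sign can
appear on edges far from the perturbed regions. This is a property of the
construction itself, visible in the planted-effect simulations.

### Graph metrics over the sparsity sweep

Each similarity matrix is binarised at sparsity levels S ∈ {0.05, 0.06, …,
0.40} (36 points): the ⌊S·R(R−1)/2⌋ strongest off-diagonal weights become
edges, with ties broken by ascending (row, col) index, which makes edge sets
nested in S and the sweep fully deterministic. Graphs are binary; weighted
variants are out of scope.

At each S we compute the standard measures: clustering coefficient Cp,
characteristic path length Lp, global and local efficiency (Eglob, Eloc),
nodal degree, betweenness centrality and nodal efficiency, plus the
null-normalised indices γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩ and small-worldness
σ = γ/λ against degree-preserving (Maslov–Sneppen) rewired nulls (default
100 nulls, 10·|E| attempted swaps each; a numba kernel keeps the ~10⁵ null
graphs of a cohort sweep tractable). Conventions for degenerate cases:

* Lp averages only reachable ordered pairs (disconnection is surfaced via
  warnings, not infinities); Eglob counts unreachable pairs as 0.
* Nodes with fewer than two neighbours contribute 0 to Eloc; isolated nodes
  have nodal efficiency 0.
* An empty graph returns all-zero metrics with a warning; γ is an error when
  the null clustering mean is 0 (the sparsity sweep records NaN there and
  warns rather than aborting a whole subject).
* Betweenness is normalised by (R−1)(R−2)/2.

Shortest paths use BFS through `scipy.sparse.csgraph`; triangle counts use
dense matrix products; betweenness uses networkx's Brandes algorithm (it is
never needed on null graphs). The test suite checks all of these against
independent brute-force oracles (naive double sums for the energy distance,
Floyd–Warshall for distances, a path-counting identity for betweenness).

Each metric's curve over the grid is summarised by its trapezoidal AUC
(range 0.35); all group inference operates on AUCs, never on a single
privileged sparsity.

### Inference

*Metric AUCs* are compared by two-tailed label-permutation tests on the
group mean difference, p = (#{|null| ≥ |obs|} + 1)/(n_perm + 1) (default
n_perm = 1000; the +1 convention keeps p ≥ 1/(n_perm+1)). The null's
2.5th/97.5th percentiles are reported alongside as critical values. The
null sample is generated from the pooled values in a canonical sort order,
which makes results exactly invariant to subject ordering and to swapping
the two groups. Nodal metrics form one BH-FDR family per metric (R tests
each); correlation analyses form their own family.

*NBS*: edge-wise equal-variance t-tests on similarity values; per contrast
direction, edges with two-sided p below the primary threshold (default
0.05) and the matching t-sign form connected components; each observed
component's extent (edge count) is referred to the permutation null of the
maximum suprathreshold component extent (default 1000 permutations). The
choice of two-sided-p-plus-sign rather than a one-sided threshold is a
convention; component-level error control is unaffected because the null is
generated under the identical rule. An optional `node_subset` restricts the
analysis to regions previously flagged by nodal tests.

*Partial correlation*: Pearson correlation of OLS residuals after
regressing both variables on covariates plus intercept (age and sex in the
clinical use case), p from the t-distribution with n − 2 − k degrees of
freedom. Missing values drop subjects pairwise with a log entry; a
(near-)constant residual — e.g. correlating a variable with itself or a
covariate — returns r = 0 with a warning instead of numerical noise.

## The synthetic cohort generator

Because per-subject MRI feature sets are rarely shareable, the generator
produces cohorts with the statistical structure the analysis assumes, and
it is the substrate of every end-to-end test.

* **Region model.** Region means sit on a 1-D latent axis organised into 6
  modules (centres ~ N(0, module_sd²), within-module scatter
  within_module_sd, per-subject jitter subject_sd; defaults 0.10 / 0.05 /
  0.05 in units of the vertex sd). Vertex values are Gaussian around the
  subject's region mean (Student-t with unit-variance rescaling as a
  heavy-tailed stress option); region scales get mild log-normal jitter
  (sd 0.05). Vertex counts are uniform on a configurable range (default
  50–200 per region).
* **Why these scales.** They were chosen, by pilot simulation, to place the
  resulting similarity networks in the small-world regime that real
  gray-matter MBNs occupy: modules give clustered proximity structure
  (γ ≈ 2.1 averaged over the grid at the defaults) while subject jitter and
  finite-vertex sampling noise supply shortcut edges (λ ≈ 1.2). Because the
  latent axis is one-dimensional, λ floors around 1.2 rather than 1.0; the
  generator reproduces the qualitative architecture (γ > 1, λ near 1,
  σ > 1), not any particular cohort's numbers.
* **Planted effects.** Group B subjects shift the vertex distribution of
  the chosen effect regions by `effect_size` within-region standard
  deviations (a variance-inflation option exists). Each subject's realised
  shift gets a ±25% severity jitter so that covariate associations are
  recoverable *within* the affected group. A location shift leaves
  within-effect-set distances unchanged, so the ground-truth perturbed
  edges (`planted_edges`) are exactly the pairs with one endpoint in the
  effect set.
* **Covariates.** Age ~ N(10, 2.5²) clipped to 6–16 years, sex ~
  Bernoulli(0.5) coded 0/1, off-therapy duration uniform on 1–6 years
  (absent for group A, mirroring a healthy-control arm). IQ, TMT-A and
  digit span are linear in the realised shift plus Gaussian noise, anchored
  at the population norms (100, 29 s, 7) for shift 0 and near
  survivor-typical levels (≈80, ≈90 s, ≈4) at shift 1.
* **What it does not emulate.** No spatial smoothing-induced dependence
  between neighbouring regions, no hemispheric symmetry, no realistic
  region-volume distribution, no site or age effects on morphology.
  Passing tests therefore demonstrate the *machinery* (calibration,
  recovery, determinism), not claims about any real population.

Everything is deterministic given the spec's seed; the random stream is
consumed in a fixed order so cohorts differing only in `effect_size` share
all other draws.

## Numerical and design choices

* Sparsity grid read as the closed set {0.05…0.40} step 0.01; AUC needs
  fixed endpoints.
* All Monte-Carlo seeds derive from one master seed via named
  `SeedSequence` substreams (`pipeline.sub_seed`), making every output file
  byte-reproducible from the run config alone.
* TSV serialisation uses `%.17g` and round-trip float parsing, so disk
  round trips are bit-exact.
* Problem sizes in the test and acceptance workloads (e.g. 20-region
  6+6-subject replicate cohorts for calibration, 200 replicates; a
  10+10×90-region cohort with 100 nulls per graph for the small-world
  summary) were chosen as the smallest sizes at which the statistical
  properties under test are stable.

## Known limitations

* λ of synthetic cohorts does not reach 1.0 exactly (1-D latent geometry);
  see above.
* NBS implements the extent statistic only (no cluster-mass variant) and
  equal-variance t edge tests.
* Weighted-graph metrics, modularity, rich-club and assortativity are out
  of scope.
* The feature-extraction entry point treats any labelled sampling unit as a
  vertex; it does no resampling, smoothing or registration — it expects
  preprocessed, atlas-aligned images.
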