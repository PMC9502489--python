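# mbnet — individual morphological brain networks

`mbnet` builds and analyses *individual-level morphological brain networks*
(MBNs): graphs whose nodes are atlas regions (e.g. the 90 AAL regions) and
whose edges measure how similar two regions' gray-matter morphology is
*within a single subject*. Group-level structural covariance needs a whole
cohort to form one network; the energy-distance construction used here
yields one network per person, so network topology can be related to that
person's clinical scores. The intended users are neuroimaging researchers
comparing patient and control groups on T1-derived gray-matter features —
the motivating application is long-term cognitive sequelae in young cancer
survivors — but every operation is atlas-agnostic and works on any
"regions × vertex features" data.

## The method

For one subject, each region is the multiset of its vertex feature values
(e.g. smoothed modulated GM intensities of its voxels). For regions
X = {x₁…x_{n₁}}, Y = {y₁…y_{n₂}}:

1. **Energy distance** (combined Euclidean distance):
   e(X,Y) = n₁n₂/(n₁+n₂) · [2/(n₁n₂) Σᵢⱼ‖xᵢ−yⱼ‖₂ − 1/n₁² Σᵢⱼ‖xᵢ−xⱼ‖₂ −
   1/n₂² Σᵢⱼ‖yᵢ−yⱼ‖₂] ≥ 0, zero iff the feature distributions coincide.
2. **Similarity**: per-subject min–max normalisation and exponential
   conversion, c(X,Y) = exp(−(e−e_min)/(e_max−e_min)) ∈ [e⁻¹, 1], giving a
   symmetric R×R zero-diagonal similarity matrix.
3. **Graph metrics**: binarise at sparsities S ∈ {0.05,…,0.40} (step 0.01)
   and compute Cp, Lp, Eglob, Eloc, γ, λ, σ (against degree-preserving
   rewired nulls) and nodal degree/betweenness/efficiency; summarise each
   metric by its trapezoidal AUC over the grid.
4. **Inference**: label-permutation tests on AUCs with Benjamini–Hochberg
   FDR across nodes; network-based statistics (NBS: suprathreshold edge
   components vs the max-component-extent permutation null); partial
   correlations with clinical variables controlling age and sex.

A synthetic cohort generator (`mbnet.cohort`) produces region-wise vertex
features with modular latent structure, planted group effects of known
location and size, and covariates coupled to the effect — so the entire
pipeline is testable end to end without any imaging data. See
`docs/methods.md` for model details and limitations.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from mbnet import (CohortSpec, simulate_cohort, similarity_matrix, sweep_metrics,
                   sparsity_grid, nbs, planted_edges)

# 10 controls + 10 patients, 30 regions; regions 1-6 shifted by 2 SD in patients
spec = CohortSpec(n_group_a=10, n_group_b=10, n_regions=30,
                  vertices_per_region=(40, 80),
                  effect_regions=(1, 2, 3, 4, 5, 6), effect_size=2.0, seed=5)
cohort = simulate_cohort(spec)
mats = [similarity_matrix(s) for s in cohort]

curves = sweep_metrics(mats[0], sparsity_grid(), n_nulls=50, seed=1)
print(f"subject {mats[0].subject_id}: "
      f"Cp AUC = {curves['Cp'].auc:.3f}, Lp AUC = {curves['Lp'].auc:.3f}, "
      f"gamma = {curves['gamma'].values.mean():.2f}, "
      f"lambda = {curves['lambda'].values.mean():.2f}")

res = nbs(mats[:10], mats[10:], n_perm=1000, seed=9)["A>B"]
comp = res.components[0]
cov = len(set(comp.edges) & set(planted_edges(spec))) / len(planted_edges(spec))
print(f"largest A>B component: {comp.extent} edges over {len(comp.nodes)} nodes, "
      f"p = {comp.p:.4f}, covers {100*cov:.0f}% of planted edges")
```

Output:

```
subject A01: Cp AUC = 0.199, Lp AUC = 0.879, gamma = 2.32, lambda = 1.17
largest A>B component: 142 edges over 30 nodes, p = 0.0020, covers 99% of planted edges
```

The first line says this subject's network is small-world: clustering is
2.3× its degree-matched random expectation while path length is only 1.17×
(σ = γ/λ ≈ 2). The second line shows NBS recovering the planted group
difference: the component of edges weaker in patients is highly significant
(p ≈ 0.002 over 1000 permutations) and contains 99% of the truly perturbed
region pairs.

The same analysis is available from the shell:

```bash
mbnet simulate --seed 5 --out cohort/ --n-regions 30 --effect-regions 1,2,3 --effect-size 2
mbnet run-all --config config.json --seed 5 --out results/
```

`run-all` writes per-subject similarity matrices, tidy metric/AUC tables,
permutation and NBS result tables, partial-correlation tables and a JSON
manifest; identical configs give byte-identical outputs. Real data enter
either as the two TSV tables (covariates + long-form vertex features) or as
NIfTI feature/atlas-label images via `mbnet extract`.

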