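# dimes-chromatin

Maximum-entropy reconstruction of 3D chromatin structural ensembles from mean
pairwise distance matrices (the DIMES approach), for researchers working with
multiplexed DNA-FISH chromatin tracing data or Hi-C contact maps.

## The problem and the model

Chromatin tracing experiments report the 3D coordinates of N genomic loci in
thousands of single cells; Hi-C reports population-averaged contact
probabilities. Neither directly yields the *ensemble* of 3D structures. Given
the mean squared pairwise distances ⟨r²_ij⟩ between loci, the distribution
over conformations {**x**_i} with maximal entropy subject to those constraints
is

    P({x_i}) ∝ exp( − Σ_{i<j} k_ij ‖x_i − x_j‖² )

a multivariate Gaussian whose Lagrange multipliers k_ij play the role of
effective pairwise couplings (the generalized-Rouse-model form; negative
values — effective repulsion — are allowed as long as the model stays
normalizable). Collecting the couplings into the Laplacian-structured
*connectivity matrix* **K** (K_ij = k_ij, K_ii = −Σ_{j≠i} k_ij), the model is
fully analytic:

- coordinate covariance **Σ** = −**K**⁺ (Moore–Penrose pseudoinverse;
  one exact zero mode = the center of mass),
- mean squared distances ⟨r²_ij⟩ = 3 ω²_ij with ω²_ij = Σ_ii + Σ_jj − 2Σ_ij,
- structures sampled by normal modes: eigendecompose **K**, draw each non-zero
  mode from Normal(0, −1/ω_i) per spatial dimension.

The couplings are fitted to a target matrix a_ij = ⟨r²_ij,exp⟩ by iterative
scaling,

    k_ij(t+1) = k_ij(t) + γ / Σ_{i<j}⟨r²_ij⟩(t) · ln( ⟨r²_ij⟩(t) / a_ij ),

(γ = 10) or by gradient descent on the maximum-entropy dual, with every
⟨r²_ij⟩(t) evaluated analytically — no simulation anywhere. Hi-C contact maps
enter through the power law ⟨r_ij⟩ = Λ p_ij^(−1/α) (α = 4 by default; Λ, α can
be calibrated against imaging data by least squares).

On top of the core model the package computes the downstream ensemble
statistics used to validate and interpret such models: per-pair distance
distributions and their Jensen–Shannon divergence, triplet co-localization
probabilities π_ijk and gap-product Z-scores, radius of gyration and shape
anisotropy κ², single-cell domain-boundary probabilities, conformation
clustering (t-SNE + Ward), A/B compartment inference from the coupling
matrix, the mixing metric Q_k and long-range contact metric F_k, and
structural-variant predictions (segment inversion, locus deletion) scored by
the Perturbation Index.

## Worked example

```python
import numpy as np
import dimes
from dimes import fixtures

# synthetic ground truth: 64 loci, A/B blocks, ~300 nm bead spacing
K_true, labels = fixtures.make_block_copolymer(64, seed=0)
target = dimes.mean_sq_distances_from_connectivity(K_true)

result = dimes.fit_iterative_scaling(target, dimes.FitConfig(tol=1e-2, max_iter=10_000))
fitted = dimes.mean_sq_distances_from_connectivity(result.connectivity)

iu = np.triu_indices(64, 1)
r = np.corrcoef(np.sqrt(fitted.d2[iu]), np.sqrt(target.d2[iu]))[0, 1]
ensemble = dimes.sample_conformations(result.connectivity, 1000, seed=1)
```

Running `python examples/01_fit_and_sample.py` prints:

```
converged: False after 10000 iterations
relative mean distance error: 0.0128
Pearson r, fitted vs target mean distances: 0.9929
sampled 1000 conformations; mean radius of gyration 263 nm (cell-to-cell sd 37 nm)
```

The fitted model reproduces the input mean distances nearly perfectly
(r = 0.993), and the R_g spread across sampled conformations quantifies the
cell-to-cell structural heterogeneity implied by the Gaussian ensemble. The
other scripts in `examples/` walk through missing-data cross-validation
(predicting 90% of a distance map from the remaining 10%, r ≈ 0.996),
higher-order statistics (JSD ≈ 0.008, triplet correlation ≈ 0.99),
compartment inference from the couplings, and structural-variant predictions.

A thin CLI wraps the same functions for shell pipelines:

```bash
dimes simulate --n-loci 64 --n-cells 3000 --seed 1 --out-dir fix/
dimes fit --target fix/d2.tsv --out fit.h5
dimes sample --connectivity fit.h5 --n 1000 --seed 2 --out ensemble.pdb
```

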