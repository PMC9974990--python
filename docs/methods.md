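# Methods

## Model and conventions

The ensemble is the maximum-entropy distribution over loci coordinates
constrained by mean squared pairwise distances,
P({x_i}) ∝ exp(−Σ_{i<j} k_ij ‖x_i − x_j‖²). We use the operational
convention **Σ** = −**K**⁺ together with ⟨r²_ij⟩ = 3(Σ_ii + Σ_jj − 2Σ_ij) and
mode variances −1/ω_i in the sampler. A literal reading of the density would
give **Σ** = −½**K**⁺; the two conventions differ only by a global factor of 2
on all k_ij, and we adopt the former throughout because it is the one the
fitting, distance and sampling formulas are written in. Units: coordinates
and distances in nm, squared distances in nm², couplings in nm⁻². A unitless
"model" mode is the same algebra with k = O(1); fitted structures can be
rescaled freely when the physical length scale is unknown (Λ = 1).

Validity requires **K** negative semidefinite with exactly one zero eigenvalue
(the center-of-mass translation; the sampler pins that mode to the origin,
which is also how the gauge of the pseudoinverse is fixed). Eigenvalues with
|ω| ≤ 10⁻¹⁰·max|ω| are treated as the zero mode. Degenerate inputs are
rejected with specific errors: a positive eigenvalue beyond tolerance
(non-normalizable model, reported with the offending eigenvalue), more than
one near-zero mode (disconnected coupling graph, reported with its
components), K = 0 (no gauge).

## Fitting

Both optimizers evaluate ⟨r²_ij⟩(t) analytically each step (one
eigendecomposition per iteration) and stop when the relative mean absolute
error mean|⟨r²⟩ − a|/mean(a) over observed pairs falls below `tol`
(default 10⁻²; no stopping rule is standard for this problem, so the
threshold is ours). An error that grows ten-fold above its running minimum
aborts the fit with the trace attached.

- **Iterative scaling** uses the printed update with γ = 10; the
  normalization by Σ⟨r²⟩ makes the step scale-invariant, so the same γ works
  in nm² and model units.
- **Gradient descent** descends the maximum-entropy dual
  ψ(k) = ln Z + Σ k_ij a_ij, whose gradient is a_ij − ⟨r²_ij⟩; the stable
  default learning rate is γ = 0.3/max(a)², because the step-size limit is
  set by the most sensitive (largest-distance) pair, |∂⟨r²⟩/∂k| ≈ ⟨r²⟩²/3.
  An optional ridge penalty λΣk² (default λ = 0) damps the GD update by
  −2γλk.
- **Initialization** defaults to an ideal chain whose nearest-neighbor
  coupling matches the observed mean of the target
  (k₀ = 3·mean|i−j| / mean a), guaranteeing a connected, sane starting model;
  `zeros`, `direct_inversion` (double-centering of −d²/6 followed by −Σ⁺) and
  user-supplied tables are also available. Direct inversion of a
  model-realizable target is an exact fixed point of both optimizers.
- **NSD repair**: if an update pushes **K** out of the negative-semidefinite
  cone, positive eigenvalues are clipped to zero in the eigenbasis and the
  coupling table reassembled. In masked fits the frozen couplings are
  restored after the clip (the freeze contract outranks exact projection);
  on realizable targets the repair is rarely triggered.
- **Missing data**: masked pairs never enter the update; their couplings stay
  bitwise at initialization. Identifiability requires the observed-pair graph
  to be connected (checked, with components reported). Held-out entries are
  read from the converged model's complete distance map.

Cross-validation accuracy depends on how parsimonious the true coupling
structure is. On a TAD-structured chain (couplings supported on short-range
blocks) 10% of the map predicts the held-out 90% with r ≈ 0.996; on a fixture
whose ground truth couples *every* pair, the model class restricted to the
observed-pair support cannot represent the truth and held-out correlation
saturates near 0.91 regardless of convergence depth. Real Mbp-scale imaging
targets behave like the former.

## Contact-map conversion

⟨r²_ij⟩ = (Λ p_ij^(−1/α))², α = 4 and Λ = 1 by default. Raw count matrices
are normalized by their maximum off-diagonal entry before conversion (our
rule; upstream balancing such as ICE/KR is out of scope). Zero or missing
probabilities become masked pairs rather than being converted. Calibration of
(Λ, α) against a reference distance map minimizes
χ = mean (Λp^(−1/α) − r)² on *distances*; χ is linear-separable in Λ, so only
α is searched — a deterministic log grid over [2, 8] plus a bounded local
refinement — making recovery of an exact power law essentially exact.

## Synthetic generators (what they emulate, and what not)

The fixtures emulate multiplexed-FISH chromatin tracing of a ~2 Mbp region:
N = 64 loci, backbone coupling k = 3/(300 nm)² (≈300 nm nearest-neighbor
distance), alternating A/B blocks of 8 loci with same-class attraction
0.05·k_backbone and weaker cross-class repulsion −0.005·k_backbone (the
imbalance mirrors fitted chromosome couplings, where cross-class repulsion is
the smallest term and keeps **K** NSD), ±20% coupling jitter, M = 3000 cells,
10% of loci missing at random per cell, and 20 nm isotropic localization
noise (which inflates every ⟨r²⟩ by 6σ² ≈ 2.4·10³ nm²; at typical distances
this is a ≲1% bias that we do not correct). If a parameter choice ever
renders **K** indefinite, non-backbone couplings are halved until it is not.
A TAD-chain generator (chain + intra-domain attraction, optional boundary
anchors) provides the parsimonious coupling structure used for
cross-validation tests, and a Rouse chain gives closed-form oracles
(⟨r²_ij⟩ = 3|i−j|/k, the graph resistance distance).

The generators draw from the model itself plus additive Gaussian localization
noise, so passing tests demonstrate self-consistency of the pipeline under
realistic degradation — not robustness to the non-Gaussian, locus-dependent
errors, chromatic offsets, or segmentation artifacts of real imaging data.

## Ensemble statistics

- **Histograms/JSD**: per-pair Freedman–Diaconis bins on the pooled samples
  of the two ensembles being compared; JSD in log base 2 (bounded in [0, 1]),
  0·log 0 = 0.
- **Triplets**: π_ijk(a) with a = 300 nm by default (the threshold at which
  model–experiment triplet agreement peaks); Z-scores grouped by the literal
  gap product |j−i|·|k−j|, population standard deviation, zero-variance
  groups → Z = 0. Conditioned sub-ensembles are produced by rejection
  filtering.
- **Boundary probability**: an insulation-style score — mean inter-window
  distance across the locus over mean intra-window distance (window w = 5,
  ≥80% observed entries required) — with local maxima above 1.2 called
  boundaries; edge loci are reported missing. The upstream reference for
  this statistic leaves the algorithm unspecified, so these parameters are
  our concrete, configurable choice. Ideal homopolymers genuinely show weak
  fluctuation-driven boundaries; tests assert that, rather than zero.
- **Conformation metric** D_mn sums over ordered pairs as written (equal to
  the Euclidean metric on flattened distance maps divided by N); clustering
  embeds D with seeded t-SNE and applies Ward-linkage agglomerative
  clustering (both as library black boxes), reporting occupancies, medoid
  representatives (lowest mean D within cluster) and per-cluster mean
  distance maps.
- **Q_k / F_k**: k nearest spatial neighbors per locus, self excluded, ties
  broken by the lower locus index (stable argsort). F₀ₖ = (1+k/2)/2. Note
  that a strictly alternating ABAB chain is *anti*-mixed under Q₂ (both
  nearest neighbors are the opposite type, Q₂ = 2(N−2)/N); the configuration
  realizing the random-mixing expectation Q₂ = 0 on a chain has period-4
  AABB labels.

## Compartments from the couplings

The default correlation matrix is the Gaussian model's own position
correlation, ρ_ij = Σ_ij/√(Σ_ii Σ_jj) with **Σ** = −**K**⁺, and compartments
are the sign classes of PC1 of ρ (A negative, orientation fixed by reference
labels when given, else by forcing the first locus non-positive; PC1 = 0
stays unassigned). Computed through the pseudoinverse, this construction is
robust to coupling-level noise: it recovers planted labels perfectly both
from ground-truth matrices and from models refitted to 3000-cell empirical
maps. The Hi-C-style alternative — Pearson correlation of coupling rows with
the mutual entries excluded (`method="coupling_rows"`) — is retained; it
works on clean coupling matrices but at N ≈ 64 the Monte-Carlo coupling noise
of a refit (≈12% in Frobenius norm, against a class signal of a few percent
of the backbone) leaves it uninformative, which is why it is not the default.
The center-of-mass gauge gives ρ a slightly negative baseline (rows of Σ sum
to zero); PC1 is insensitive to it.

⟨k(s)⟩ profiles normalize per class by the class's own pair count at each
separation (the unrestricted 1/(N−s) normalization would damp class curves by
their abundance); the count-weighted class means recombine exactly to the
unlabeled profile. The additivity diagnostic reports the difference curves
⟨k_AA(s)⟩−⟨k_AB(s)⟩ etc. with a std/|mean| flatness summary — exactly zero
variance for a coupling table built as k₀(i,j) + k_e(class).

## Structural variants

Inversion is an index permutation of the coupling table (a similarity
transform: the spectrum, and hence model validity, is preserved exactly;
double inversion restores the original bitwise). Deletion removes the
locus's row/column and reassembles the Laplacian diagonal; with non-negative
couplings the result is again a graph Laplacian and provably valid, while
negative couplings can genuinely destabilize the reduced model, in which case
the edit is rejected (and per-locus deletion profiles report NaN, as for
disconnecting deletions). Deletion is *not* Gaussian marginalization —
marginalizing a locus leaves all other statistics untouched, deleting it
rewires the chain — and the two coincide only for leaf loci; the marginal
oracle is provided for exactly that check. Duplications and insertions
change the locus set in ways a coupling edit cannot express and are rejected
with instructions to refit. The Perturbation Index compares mean *distances*
(not squared), is scale-invariant, and for the reference figure-style plots a
floor constant PI_base = 0.2 applies only to plotting, never to reported
values.

## Problem sizes and limitations

Analyses and tests run at N ≤ 65 loci and M ≤ 5000 conformations with
10⁴-iteration fitting budgets — desk-scale study conditions chosen so the
complete validation pipeline (fit, sample, histogram, triplet enumeration)
remains interactive; all algorithms are O(N³) per iteration or better and
have been exercised unchanged at a few hundred loci. Known limitations: at
N ≈ 64 the coupling-row correlation route to compartments does not survive
finite-cell refit noise (see above); boundary probabilities depend on the
chosen window/threshold; Λ from contact maps is only defined up to the
physical scale of the reference; and the model is Gaussian by construction —
heavy-tailed single-cell heterogeneity beyond second moments is reproduced
only to the extent a Gaussian mixture of modes can express it.
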