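"""Predict the structural impact of inversions and deletions.

Edits the fitted coupling matrix directly — an inversion permutes it, a
deletion removes a locus — and quantifies the change in the mean distance
map with the Perturbation Index (PI).
"""

import numpy as np

import dimes
from dimes import fixtures
from dimes.perturbation import pi_deletion_profile

K, labels = fixtures.make_block_copolymer(32, block_size=8, k_inter=0.0, seed=0)
d2 = dimes.mean_sq_distances_from_connectivity(K)
d_wt = np.sqrt(d2.d2)

# invert a segment spanning an A/B boundary
K_inv = dimes.invert_segment(K, (4, 11))
d_inv = np.sqrt(dimes.mean_sq_distances_from_connectivity(K_inv).d2)
print(f"PI of inverting loci 4–11: {dimes.perturbation_index(d_wt, d_inv):.4f}")

# a symmetric homopolymer is immune to inversion
chain = fixtures.make_rouse_chain(32)
d_c = np.sqrt(dimes.mean_sq_distances_from_connectivity(chain).d2)
d_ci = np.sqrt(dimes.mean_sq_distances_from_connectivity(
    dimes.invert_segment(chain, (0, 31))).d2)
print(f"PI of fully inverting a homopolymer: {dimes.perturbation_index(d_c, d_ci):.4f}")

# which single-locus deletions matter most?
profile = pi_deletion_profile(K)
order = np.argsort(profile)[::-1][:4]
print("loci whose deletion perturbs the fold most:", order.tolist())
print("their PI values:", np.round(profile[order], 3).tolist())
print("block boundaries are at loci 7/8, 15/16, 23/24")
# High-PI loci coincide with compartment boundaries: boundary elements carry
# the structural integrity of the fold, as seen in perturbation analyses of
# real chromosomes.

# predicted contact map of the variant (for browser-style comparison)
cm = dimes.predict_variant_contact_map(
    K, [{"op": "invert", "start": 4, "end": 11}], dimes.ConversionParams(300.0, 4.0)
)
print(f"predicted variant contact map: {cm.n_loci}×{cm.n_loci}, "
      f"p range [{cm.p.min():.3f}, {cm.p.max():.3f}]")
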