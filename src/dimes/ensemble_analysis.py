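"""Ensemble statistics: distance distributions, JSD, triplet co-localization,
shape descriptors, single-cell boundary probabilities, conformation clustering,
and the A/B mixing (Q_k) and long-range contact (F_k) metrics.

All statistics depend on the conformations only through pairwise distances, so
they are invariant under rigid translations and rotations of each cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import jensenshannon, pdist, squareform

from .exceptions import ValidationError
from .sampling import ConformationEnsemble

_DEFAULT_CONTACT_RADIUS = 300.0  # nm; threshold where triplet agreement peaks


def _coords(ens) -> np.ndarray:
    return ens.coords if isinstance(ens, ConformationEnsemble) else np.asarray(ens, dtype=float)


def pairwise_distance_matrices(ens) -> np.ndarray:
    """(M, N, N) Euclidean distance matrices, NaN where a locus is missing."""
    coords = _coords(ens)
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    return np.sqrt(np.einsum("mijp,mijp->mij", diff, diff))


# ---------------------------------------------------------------------------
# distance distributions and JSD
# ---------------------------------------------------------------------------

@dataclass
class PairDistanceHistograms:
    """Per-pair normalized histograms of r_ij on per-pair bin edges."""

    pairs: np.ndarray          # (P, 2) locus indices, i < j
    edges: list                # per-pair bin edge arrays
    probabilities: list        # per-pair probability-mass vectors (sum 1)


def _fd_edges(samples: np.ndarray, min_bins: int = 4, max_bins: int = 200) -> np.ndarray:
    """Freedman–Diaconis bin edges with sane fallbacks for degenerate data."""
    samples = samples[np.isfinite(samples)]
    lo, hi = samples.min(), samples.max()
    if hi == lo:
        return np.array([lo - 0.5, hi + 0.5])
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    width = 2.0 * iqr / len(samples) ** (1.0 / 3.0)
    if width <= 0:
        width = (hi - lo) / 10.0
    nbins = int(np.clip(np.ceil((hi - lo) / width), min_bins, max_bins))
    return np.linspace(lo, hi, nbins + 1)


def distance_distributions(ens, bins="fd") -> PairDistanceHistograms:
    """Normalized per-pair histograms P(r_ij).

    ``bins`` is 'fd' (Freedman–Diaconis, per pair), an integer count, or an
    explicit edge array shared by all pairs.
    """
    dm = pairwise_distance_matrices(ens)
    n = dm.shape[1]
    pairs, edges, probs = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            r = dm[:, i, j]
            r = r[np.isfinite(r)]
            if r.size == 0:
                continue
            if isinstance(bins, str) and bins == "fd":
                e = _fd_edges(r)
            elif np.isscalar(bins):
                e = np.linspace(r.min(), r.max() + 1e-12, int(bins) + 1)
            else:
                e = np.asarray(bins)
            h, _ = np.histogram(r, bins=e)
            pairs.append((i, j))
            edges.append(e)
            probs.append(h / h.sum())
    return PairDistanceHistograms(pairs=np.asarray(pairs), edges=edges, probabilities=probs)


def shared_distance_distributions(ens_p, ens_q) -> tuple[PairDistanceHistograms, PairDistanceHistograms]:
    """Histogram two ensembles on shared per-pair Freedman–Diaconis bins
    computed from the pooled samples — the binning used for JSD comparisons."""
    dm_p = pairwise_distance_matrices(ens_p)
    dm_q = pairwise_distance_matrices(ens_q)
    if dm_p.shape[1] != dm_q.shape[1]:
        raise ValidationError("ensembles have different numbers of loci")
    n = dm_p.shape[1]
    pairs, edges, prob_p, prob_q = [], [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            rp = dm_p[:, i, j]
            rq = dm_q[:, i, j]
            rp, rq = rp[np.isfinite(rp)], rq[np.isfinite(rq)]
            if rp.size == 0 or rq.size == 0:
                continue
            e = _fd_edges(np.concatenate([rp, rq]))
            hp, _ = np.histogram(rp, bins=e)
            hq, _ = np.histogram(rq, bins=e)
            pairs.append((i, j))
            edges.append(e)
            prob_p.append(hp / hp.sum())
            prob_q.append(hq / hq.sum())
    pairs = np.asarray(pairs)
    return (
        PairDistanceHistograms(pairs=pairs, edges=edges, probabilities=prob_p),
        PairDistanceHistograms(pairs=pairs, edges=[e.copy() for e in edges], probabilities=prob_q),
    )


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon divergence, log base 2, bounded in [0, 1].

    ``(D(p||m) + D(q||m)) / 2`` with ``m = (p + q)/2`` and the 0·log 0 = 0
    convention (handled inside scipy's implementation).
    """
    return float(jensenshannon(p, q, base=2) ** 2)


def jsd_matrix(p_ens: PairDistanceHistograms, q_ens: PairDistanceHistograms, n_loci: int | None = None) -> np.ndarray:
    """Symmetric N×N matrix of per-pair JSD values (NaN where unobserved)."""
    if len(p_ens.pairs) != len(q_ens.pairs) or not np.array_equal(p_ens.pairs, q_ens.pairs):
        raise ValidationError("histogram sets cover different pairs")
    for ep, eq in zip(p_ens.edges, q_ens.edges):
        if ep.shape != eq.shape or not np.allclose(ep, eq):
            raise ValidationError("histograms use mismatched bin edges")
    if n_loci is None:
        n_loci = int(p_ens.pairs.max()) + 1
    out = np.full((n_loci, n_loci), np.nan)
    np.fill_diagonal(out, 0.0)
    for (i, j), p, q in zip(p_ens.pairs, p_ens.probabilities, q_ens.probabilities):
        out[i, j] = out[j, i] = jsd(p, q)
    return out


def ensemble_jsd(ens_p, ens_q) -> np.ndarray:
    """Convenience: shared-bin histograms of two ensembles → JSD matrix."""
    hp, hq = shared_distance_distributions(ens_p, ens_q)
    n = _coords(ens_p).shape[1]
    return jsd_matrix(hp, hq, n_loci=n)


# ---------------------------------------------------------------------------
# triplet co-localization
# ---------------------------------------------------------------------------

@dataclass
class TripletStats:
    """π_ijk (and optional Z_ijk) over all triplets i < j < k."""

    threshold_a: float
    triplets: np.ndarray       # (T, 3) locus indices
    pi: np.ndarray             # (T,)
    grouping_key: np.ndarray   # (T,) |j−i|·|k−j|
    z: np.ndarray | None = None


def triplet_colocalization(ens, a: float = _DEFAULT_CONTACT_RADIUS) -> TripletStats:
    """π_ijk(a) = fraction of conformations with all three pairwise distances < a."""
    dm = pairwise_distance_matrices(ens)
    n = dm.shape[1]
    if n < 3:
        raise ValidationError("triplet statistics need at least 3 loci")
    contact = (dm < a).astype(np.float32)  # NaN distances compare False
    m = contact.shape[0]
    idx_i, idx_j, idx_k, pis = [], [], [], []
    for i in range(n - 2):
        ci = contact[:, i, :]  # (M, N)
        # counts[j, k] = #conformations with contacts (i,j), (i,k) and (j,k)
        both = contact * ci[:, :, None] * ci[:, None, :]
        counts = both.sum(axis=0)
        for j in range(i + 1, n - 1):
            ks = np.arange(j + 1, n)
            idx_i.extend([i] * len(ks))
            idx_j.extend([j] * len(ks))
            idx_k.extend(ks)
            pis.extend(counts[j, ks] / m)
    triplets = np.column_stack([idx_i, idx_j, idx_k])
    pi = np.asarray(pis, dtype=float)
    key = (triplets[:, 1] - triplets[:, 0]) * (triplets[:, 2] - triplets[:, 1])
    return TripletStats(threshold_a=float(a), triplets=triplets, pi=pi, grouping_key=key)


def triplet_zscore(stats: TripletStats) -> TripletStats:
    """Z_ijk = (π_ijk − μ_g) / σ_g within groups of equal gap product |j−i|·|k−j|.

    μ_g and σ_g are the population mean and standard deviation over the group;
    zero-variance (including singleton) groups yield Z = 0.
    """
    z = np.zeros_like(stats.pi)
    for key in np.unique(stats.grouping_key):
        sel = stats.grouping_key == key
        vals = stats.pi[sel]
        sd = vals.std()  # population std
        if sd > 0:
            z[sel] = (vals - vals.mean()) / sd
    stats.z = z
    return stats


def colocalized_subset(ens, triplet, a: float = _DEFAULT_CONTACT_RADIUS) -> ConformationEnsemble:
    """Conformations in which the three loci are mutually within ``a`` (rejection filter)."""
    i, j, k = triplet
    dm = pairwise_distance_matrices(ens)
    keep = (dm[:, i, j] < a) & (dm[:, i, k] < a) & (dm[:, j, k] < a)
    if not keep.any():
        warnings.warn("no conformation satisfies the co-localization constraint", stacklevel=2)
    coords = _coords(ens)[keep]
    source = ens.source if isinstance(ens, ConformationEnsemble) else "sampled"
    seed = ens.seed if isinstance(ens, ConformationEnsemble) else None
    out = ConformationEnsemble.__new__(ConformationEnsemble)
    out.coords, out.seed, out.source = coords, seed, source
    return out


# ---------------------------------------------------------------------------
# size and shape
# ---------------------------------------------------------------------------

@dataclass
class ShapeStats:
    """Per-conformation radius of gyration and relative shape anisotropy."""

    rg: np.ndarray
    kappa2: np.ndarray
    segment: tuple


def shape_stats(ens, segment: tuple | None = None) -> ShapeStats:
    """R_g and κ² of the gyration tensor for loci in ``segment`` (inclusive).

    κ² = 1 − 3(λ₁λ₂ + λ₂λ₃ + λ₃λ₁)/(λ₁ + λ₂ + λ₃)² ∈ [0, 1]; 0 for a
    spherically symmetric mass distribution, 1 for collinear loci.
    """
    coords = _coords(ens)
    n = coords.shape[1]
    if segment is None:
        segment = (0, n - 1)
    a, b = segment
    if not (0 <= a < b <= n - 1):
        raise ValidationError("segment must satisfy 0 <= start < stop <= N-1")
    seg = coords[:, a : b + 1, :]
    centered = seg - np.nanmean(seg, axis=1, keepdims=True)
    gyr = np.einsum("mlp,mlq->mpq", np.nan_to_num(centered), np.nan_to_num(centered))
    counts = np.sum(np.all(np.isfinite(seg), axis=2), axis=1)
    gyr = gyr / counts[:, None, None]
    lam = np.linalg.eigvalsh(gyr)
    trace = lam.sum(axis=1)
    pair_sum = lam[:, 0] * lam[:, 1] + lam[:, 1] * lam[:, 2] + lam[:, 0] * lam[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa2 = 1.0 - 3.0 * pair_sum / trace**2
    return ShapeStats(rg=np.sqrt(trace), kappa2=np.clip(kappa2, 0.0, 1.0), segment=(a, b))


# ---------------------------------------------------------------------------
# single-cell domain boundaries
# ---------------------------------------------------------------------------

def boundary_probability(
    cell_dms: np.ndarray,
    window: int = 5,
    threshold: float = 1.2,
    min_observed: float = 0.8,
) -> np.ndarray:
    """Probability that each locus acts as a single-cell domain boundary.

    Per cell, an insulation-style score is assigned to every interior locus:
    the mean distance between the ``window`` loci on its left and the
    ``window`` loci on its right (inter-window), divided by the mean distance
    within each flank (intra-window).  Loci that are local maxima of the score
    and exceed ``threshold`` are called boundaries; the probability is the
    fraction of cells in which a locus is a boundary.  Edge loci (within
    ``window`` of either end) are reported as NaN.
    """
    cell_dms = np.asarray(cell_dms, dtype=float)
    if cell_dms.ndim == 2:
        cell_dms = cell_dms[None]
    m, n, _ = cell_dms.shape
    if window >= n / 2:
        raise ValidationError("window must be smaller than N/2")
    scores = np.full((m, n), np.nan)
    for c in range(m):
        d = cell_dms[c]
        for i in range(window, n - window):
            left = np.arange(i - window, i)
            right = np.arange(i + 1, i + 1 + window)
            inter = d[np.ix_(left, right)].ravel()
            intra = np.concatenate(
                [d[np.ix_(left, left)][np.triu_indices(window, 1)],
                 d[np.ix_(right, right)][np.triu_indices(window, 1)]]
            )
            used = np.concatenate([inter, intra])
            if np.isfinite(used).mean() < min_observed:
                continue
            it = np.nanmean(intra)
            if it > 0:
                scores[c, i] = np.nanmean(inter) / it
    is_boundary = np.zeros((m, n), dtype=float)
    valid = np.isfinite(scores)
    for c in range(m):
        s = scores[c]
        for i in range(window, n - window):
            if not valid[c, i] or s[i] <= threshold:
                continue
            lo = s[i - 1] if valid[c, i - 1] else -np.inf
            hi = s[i + 1] if i + 1 < n and valid[c, i + 1] else -np.inf
            if s[i] >= lo and s[i] >= hi:
                is_boundary[c, i] = 1.0
    prob = np.full(n, np.nan)
    interior = np.arange(window, n - window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        counts = valid[:, interior].sum(axis=0)
        prob[interior] = np.where(
            counts > 0, is_boundary[:, interior].sum(axis=0) / np.maximum(counts, 1), np.nan
        )
    return prob


# ---------------------------------------------------------------------------
# conformation metric and clustering
# ---------------------------------------------------------------------------

def conformation_distance(m_coords: np.ndarray, n_coords: np.ndarray) -> float:
    """D_mn = sqrt((1/N²) Σ_{i,j} (r_ij^(m) − r_ij^(n))²), over ordered pairs."""
    dm = squareform(pdist(m_coords))
    dn = squareform(pdist(n_coords))
    n = dm.shape[0]
    return float(np.sqrt(np.sum((dm - dn) ** 2) / n**2))


def conformation_distance_matrix(ens) -> np.ndarray:
    """All-vs-all D_mn; equals the Euclidean metric on flattened distance maps / N."""
    dm = pairwise_distance_matrices(ens)
    m, n, _ = dm.shape
    flat = dm.reshape(m, n * n)
    return squareform(pdist(flat)) / n


@dataclass
class ClusterResult:
    labels: np.ndarray           # per-conformation cluster id
    fractions: np.ndarray        # per-cluster occupancy, sums to 1
    representatives: np.ndarray  # per-cluster index of the medoid conformation
    mean_distance_maps: list     # per-cluster mean pairwise-distance map
    embedding: np.ndarray        # (M, 2) stochastic-neighbor embedding


def cluster_ensemble(ens, n_clusters: int = 2, seed: int = 0) -> ClusterResult:
    """Partition the ensemble by structural similarity.

    The pairwise conformation metric D_mn is embedded in 2D with t-SNE
    (seeded), the embedding is clustered by Ward-linkage agglomerative
    clustering, and each cluster is summarized by its occupancy fraction, its
    medoid (lowest average D_mn to members of the same cluster), and its mean
    distance map.
    """
    from sklearn.cluster import AgglomerativeClustering
    from sklearn.manifold import TSNE

    coords = _coords(ens)
    m = coords.shape[0]
    if m < n_clusters:
        raise ValidationError("need at least n_clusters conformations")
    D = conformation_distance_matrix(ens)
    perplexity = max(2.0, min(30.0, (m - 1) / 3.0))
    emb = TSNE(
        n_components=2, metric="precomputed", init="random",
        random_state=seed, perplexity=perplexity,
    ).fit_transform(D)
    labels = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(emb)
    fractions = np.bincount(labels, minlength=n_clusters) / m
    reps = np.empty(n_clusters, dtype=int)
    maps = []
    dm = pairwise_distance_matrices(ens)
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        mean_d = D[np.ix_(members, members)].mean(axis=1)
        reps[c] = members[int(np.argmin(mean_d))]
        maps.append(dm[members].mean(axis=0))
    return ClusterResult(
        labels=labels, fractions=fractions, representatives=reps,
        mean_distance_maps=maps, embedding=emb,
    )


# ---------------------------------------------------------------------------
# A/B mixing (Q_k) and long-range contacts (F_k)
# ---------------------------------------------------------------------------

def _labels_array(labels, n: int) -> np.ndarray:
    if hasattr(labels, "label"):
        labels = labels.label
    labels = np.asarray(labels, dtype=object)
    if labels.shape != (n,):
        raise ValidationError("labels length must equal the number of loci")
    return labels


def _nearest_neighbors(dm_row: np.ndarray, i: int, k: int) -> np.ndarray:
    """Indices of the k nearest spatial neighbors of locus i (self excluded,
    ties broken by lower locus index via a stable sort)."""
    d = dm_row.copy()
    d[i] = np.inf
    d[~np.isfinite(d)] = np.inf
    order = np.argsort(d, kind="stable")
    return order[:k]


def mixing_metric(ens, labels, k: int) -> np.ndarray:
    """Per-conformation Q_k, the degree of spatial mixing of A and B loci.

    Q_k = (1/N) Σ_i |n_A(i;k)/ñ_A − n_B(i;k)/ñ_B| with ñ_A = kN_A/N and
    ñ_B = kN_B/N the random-mixing expectations.  Q_k = 0 for perfect mixing;
    2 for fully demixed equal-sized compartments.
    """
    dm = pairwise_distance_matrices(ens)
    m, n, _ = dm.shape
    if k >= n:
        raise ValidationError("k must be smaller than the number of loci")
    lab = _labels_array(labels, n)
    is_a = lab == "A"
    is_b = lab == "B"
    n_a, n_b = int(is_a.sum()), int(is_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValidationError("Q_k needs both A and B loci present")
    na_tilde = k * n_a / n
    nb_tilde = k * n_b / n
    out = np.empty(m)
    for c in range(m):
        tot = 0.0
        for i in range(n):
            nn = _nearest_neighbors(dm[c, i], i, k)
            tot += abs(is_a[nn].sum() / na_tilde - is_b[nn].sum() / nb_tilde)
        out[c] = tot / n
    return out


def longrange_metric(ens, k: int) -> np.ndarray:
    """Per-conformation F_k, the normalized mean sequence separation of the k
    nearest spatial neighbors.

    F_k = (1/(kN F₀ₖ)) Σ_i Σ_{j ∈ m_i(k)} |j − i| with F₀ₖ = (1/2)(1 + k/2),
    the straight-chain value; F_k > 1 signals long-range spatial contacts.
    """
    dm = pairwise_distance_matrices(ens)
    m, n, _ = dm.shape
    if k >= n:
        raise ValidationError("k must be smaller than the number of loci")
    f0 = 0.5 * (1.0 + k / 2.0)
    out = np.empty(m)
    idx = np.arange(n)
    for c in range(m):
        tot = 0
        for i in range(n):
            nn = _nearest_neighbors(dm[c, i], i, k)
            tot += np.abs(nn - i).sum()
        out[c] = tot / (k * n * f0)
    return out
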