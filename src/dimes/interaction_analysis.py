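"""Interpreting the fitted coupling matrix: compartments and interaction profiles.

The couplings k_ij act as effective interaction strengths (positive =
attraction, negative = repulsion).  Loci with similar coupling profiles belong
to the same compartment, so the Pearson correlation matrix ρ of the rows of K
shows the familiar A/B checkerboard and its leading principal component (PC1)
assigns the compartments: A where PC1 < 0, B where PC1 > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .model_core import ConnectivityMatrix

CLASSES = ("A-A", "B-B", "A-B")


@dataclass
class CompartmentLabels:
    """Per-locus A/B assignment with the underlying PC1 scores."""

    pc1: np.ndarray
    label: np.ndarray

    @property
    def n_A(self) -> int:
        return int((self.label == "A").sum())

    @property
    def n_B(self) -> int:
        return int((self.label == "B").sum())

    @property
    def n_unassigned(self) -> int:
        return int((self.label == "unassigned").sum())


def correlation_from_connectivity(K: ConnectivityMatrix, method: str = "position") -> np.ndarray:
    """Correlation matrix ρ derived from the coupling matrix K.

    ``method="position"`` (default) is the Gaussian model's own correlation
    matrix, ``ρ_ij = Σ_ij / √(Σ_ii Σ_jj)`` with ``Σ = -K⁺``: loci that move
    together in the ensemble are positively correlated.  Because it is
    computed through the (smoothing) pseudoinverse it is robust to the
    coupling-level noise of models fitted to finite-cell empirical maps, and
    it carries the A/B checkerboard directly.  Note the center-of-mass gauge
    forces slightly negative baseline correlations (rows of Σ sum to zero).

    ``method="coupling_rows"`` is the Hi-C-style alternative: the Pearson
    correlation of the off-diagonal coupling rows of K, with the entries at
    positions i and j excluded from both rows.  Rows with zero variance get
    NaN correlations.
    """
    n = K.n_loci
    if n < 3:
        raise ValidationError("correlation matrix needs at least 3 loci")
    if method == "position":
        from .model_core import covariance_from_connectivity

        sigma = covariance_from_connectivity(K).sigma
        d = np.sqrt(np.diag(sigma))
        rho = sigma / np.outer(d, d)
        np.fill_diagonal(rho, 1.0)
        return np.clip(0.5 * (rho + rho.T), -1.0, 1.0)
    if method != "coupling_rows":
        raise ValidationError("method must be 'position' or 'coupling_rows'")
    off = K.offdiag
    rho = np.full((n, n), np.nan)
    np.fill_diagonal(rho, 1.0)
    all_idx = np.arange(n)
    for i in range(n):
        for j in range(i + 1, n):
            keep = (all_idx != i) & (all_idx != j)
            xi = off[i, keep]
            xj = off[j, keep]
            sx, sy = xi.std(), xj.std()
            if sx == 0 or sy == 0:
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            rho[i, j] = rho[j, i] = r
    return rho


def compartments_from_correlation(
    rho: np.ndarray, reference_labels: np.ndarray | None = None
) -> CompartmentLabels:
    """A/B compartments from PC1 of the correlation matrix.

    PC1 is the projection of each locus's correlation profile onto the leading
    principal axis of ρ.  Eigenvectors are sign-ambiguous: with reference
    labels, the sign is chosen so A loci have negative mean PC1; otherwise the
    first locus's score is made non-positive (documented convention).  Loci
    with PC1 exactly 0 stay unassigned.
    """
    from sklearn.decomposition import PCA

    rho = np.asarray(rho, dtype=float)
    n = rho.shape[0]
    work = np.nan_to_num(rho, nan=0.0)
    pca = PCA(n_components=min(2, n), svd_solver="full")
    scores = pca.fit_transform(work)
    if len(pca.explained_variance_) > 1:
        gap = pca.explained_variance_[0] - pca.explained_variance_[1]
        if gap < 1e-8:
            warnings.warn("degenerate leading principal component (gap < 1e-8)", stacklevel=2)
    pc1 = scores[:, 0]
    if reference_labels is not None:
        ref = np.asarray(reference_labels, dtype=object)
        a_mean = pc1[ref == "A"].mean() if (ref == "A").any() else 0.0
        if a_mean > 0:
            pc1 = -pc1
    else:
        first = pc1[np.flatnonzero(pc1 != 0)[0]] if np.any(pc1 != 0) else 0.0
        if first > 0:
            pc1 = -pc1
    label = np.where(pc1 < 0, "A", np.where(pc1 > 0, "B", "unassigned")).astype(object)
    return CompartmentLabels(pc1=pc1, label=label)


def compartments_from_connectivity(
    K: ConnectivityMatrix, reference_labels: np.ndarray | None = None
) -> CompartmentLabels:
    """Convenience composition K → ρ → compartments."""
    return compartments_from_correlation(correlation_from_connectivity(K), reference_labels)


def _pair_class(lab_i, lab_j):
    if "unassigned" in (lab_i, lab_j):
        return None
    return "A-A" if lab_i == lab_j == "A" else ("B-B" if lab_i == lab_j == "B" else "A-B")


def k_profile_by_s(K: ConnectivityMatrix, labels=None) -> pd.DataFrame:
    """Mean coupling ⟨k(s)⟩ versus genomic separation s (in loci units).

    Without labels, returns the 'all' profile, the mean over the N−s pairs at
    each separation.  With labels, additionally returns per-class (A-A, B-B,
    A-B) profiles, each normalized by the class's own pair count at that s
    (classes are subsets of the pairs, so the count-weighted class means
    recombine to the 'all' profile).
    """
    off = K.offdiag
    n = K.n_loci
    lab = None
    if labels is not None:
        lab = labels.label if isinstance(labels, CompartmentLabels) else np.asarray(labels, dtype=object)
    rows = []
    for s in range(1, n):
        i = np.arange(n - s)
        j = i + s
        ks = off[i, j]
        rows.append({"s": s, "class": "all", "mean_k": ks.mean(), "n_pairs": len(ks)})
        if lab is not None:
            classes = np.array([_pair_class(lab[a], lab[b]) for a, b in zip(i, j)], dtype=object)
            for c in CLASSES:
                sel = classes == c
                rows.append(
                    {
                        "s": s,
                        "class": c,
                        "mean_k": ks[sel].mean() if sel.any() else np.nan,
                        "n_pairs": int(sel.sum()),
                    }
                )
    return pd.DataFrame(rows)


def k_histograms_by_class(K: ConnectivityMatrix, labels, bins: int = 50):
    """Histograms and means of off-diagonal k_ij split by pair class.

    Returns ``(histograms, means)``: ``histograms[class] = (counts, edges)``
    on shared edges over all off-diagonal couplings, and the per-class means.
    """
    off = K.offdiag
    n = K.n_loci
    lab = labels.label if isinstance(labels, CompartmentLabels) else np.asarray(labels, dtype=object)
    iu, ju = np.triu_indices(n, 1)
    vals = off[iu, ju]
    classes = np.array([_pair_class(lab[a], lab[b]) for a, b in zip(iu, ju)], dtype=object)
    edges = np.histogram_bin_edges(vals, bins=bins)
    hists, means = {}, {}
    for c in CLASSES:
        sel = classes == c
        hists[c] = (np.histogram(vals[sel], bins=edges)[0], edges)
        means[c] = float(vals[sel].mean()) if sel.any() else np.nan
    return hists, means


def additivity_diagnostic(
    K: ConnectivityMatrix, labels, s_range: tuple[int, int] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Test whether couplings decompose as k_ij = k₀(i,j) + k_e(class).

    Under that additive decomposition the difference curves
    ⟨k_AA(s)⟩−⟨k_AB(s)⟩, ⟨k_AA(s)⟩−⟨k_BB(s)⟩ and ⟨k_BB(s)⟩−⟨k_AB(s)⟩ are
    independent of s.  Returns the curves and a flatness summary
    (std/|mean| over ``s_range``) per difference.
    """
    prof = k_profile_by_s(K, labels)
    wide = prof.pivot(index="s", columns="class", values="mean_k")
    diffs = pd.DataFrame(
        {
            "AA_minus_AB": wide["A-A"] - wide["A-B"],
            "AA_minus_BB": wide["A-A"] - wide["B-B"],
            "BB_minus_AB": wide["B-B"] - wide["A-B"],
        }
    )
    if s_range is not None:
        sel = diffs.loc[s_range[0] : s_range[1]]
    else:
        sel = diffs
    summary = {}
    for col in diffs.columns:
        v = sel[col].dropna().to_numpy()
        if v.size == 0:
            summary[col] = np.nan
        else:
            mean = v.mean()
            summary[col] = float(v.std() / abs(mean)) if mean != 0 else (0.0 if v.std() == 0 else np.inf)
    return diffs, summary


def labels_to_bed(
    labels: CompartmentLabels, chrom: str, starts: np.ndarray, resolution: int
) -> pd.DataFrame:
    """BED-like table (chrom, start, end, label, PC1) for genome-browser export."""
    starts = np.asarray(starts)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + resolution,
            "label": labels.label,
            "pc1": labels.pc1,
        }
    )
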