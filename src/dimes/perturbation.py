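"""Structural-variant predictions by editing the fitted coupling matrix.

A segment inversion is an index permutation of K (a similarity transform, so
the eigenvalue spectrum — and hence model validity — is preserved exactly);
a single-locus deletion removes the locus's row and column from the coupling
table and reassembles the Laplacian diagonal.  Changes in the predicted mean
distance map are summarized by the Perturbation Index

    PI = sqrt( Σ_{i<j} (⟨r̃_ij⟩ − ⟨r_ij⟩)²  /  Σ_{i<j} ⟨r̃_ij⟩² )

where ⟨r̃_ij⟩ are the wild-type mean *distances* (not squared) and ⟨r_ij⟩ the
post-edit values.  Duplications and insertions change the locus set in ways a
coupling edit cannot express and are rejected; they require refitting to an
edited contact or distance map.
"""

from __future__ import annotations

import numpy as np

from .data_io import ContactMap, ConversionParams, contacts_from_distances
from .exceptions import DisconnectedError, InvalidConnectivityError, ValidationError
from .model_core import (
    ConnectivityMatrix,
    assemble_connectivity,
    connected_components_of,
    covariance_from_connectivity,
    mean_sq_distances,
)


def invert_segment(K: ConnectivityMatrix, segment: tuple[int, int]) -> ConnectivityMatrix:
    """Reverse the locus order within ``segment = (a, b)`` (inclusive, 0-based).

    k'_ij = k_{σ(i)σ(j)} with σ the permutation reversing [a, b]; the diagonal
    is reassembled, and negative semidefiniteness is preserved exactly because
    the edit is a permutation similarity.
    """
    a, b = segment
    n = K.n_loci
    if not (0 <= a < b < n):
        raise ValidationError(f"segment {segment} out of bounds for N={n}")
    perm = np.arange(n)
    perm[a : b + 1] = perm[a : b + 1][::-1]
    return assemble_connectivity(K.offdiag[np.ix_(perm, perm)])


def delete_locus(K: ConnectivityMatrix, i: int) -> ConnectivityMatrix:
    """Remove locus ``i`` from the coupling table (N−1 loci remain).

    Raises :class:`DisconnectedError` if the remaining coupling graph falls
    apart (the Gaussian model would be degenerate).
    """
    n = K.n_loci
    if n < 3:
        raise ValidationError("deletion needs at least 3 loci")
    if not (0 <= i < n):
        raise ValidationError(f"locus {i} out of bounds for N={n}")
    off = np.delete(np.delete(K.offdiag, i, axis=0), i, axis=1)
    comps = connected_components_of(off)
    if len(comps) > 1:
        raise DisconnectedError(comps, what=f"coupling graph after deleting locus {i}")
    K_del = assemble_connectivity(off)
    # with non-negative couplings the result is a graph Laplacian and stays
    # NSD; negative couplings can destabilize the reduced model, in which
    # case no valid Gaussian remains and the edit is rejected
    if np.any(off < 0):
        w, _ = K_del.eigh()
        tol = 1e-9 * np.abs(w).max()
        if w[-1] > tol:
            raise InvalidConnectivityError(float(w[-1]), float(tol))
    return K_del


def marginalize_locus(K: ConnectivityMatrix, i: int) -> np.ndarray:
    """Gaussian marginal distance map over the surviving loci (internal oracle).

    Integrating locus ``i`` out of the joint Gaussian leaves the remaining
    loci's statistics untouched, so this is simply the wild-type mean distance
    map with row/column ``i`` dropped.  It coincides with
    :func:`delete_locus` + recompute only when ``i`` is a leaf of the coupling
    graph; otherwise deletion rewires the effective couplings and the two
    disagree — deletion models physically removing the locus from the chain,
    marginalization merely not observing it.
    """
    d2 = mean_sq_distances(covariance_from_connectivity(K)).d2
    return np.sqrt(np.delete(np.delete(d2, i, axis=0), i, axis=1))


def _mean_distances(K: ConnectivityMatrix) -> np.ndarray:
    return np.sqrt(mean_sq_distances(covariance_from_connectivity(K)).d2)


def perturbation_index(
    d_wt: np.ndarray, d_mut: np.ndarray, pair_subset: np.ndarray | None = None
) -> float:
    """PI between a wild-type and a mutant mean-distance map (matched shapes).

    ``pair_subset`` is an optional boolean matrix restricting the sum (e.g.
    pairs not involving a deleted locus); by default all i<j pairs are used.
    PI is non-negative, zero iff the maps agree on the subset, and invariant
    under a common rescaling of both maps.
    """
    d_wt = np.asarray(d_wt, dtype=float)
    d_mut = np.asarray(d_mut, dtype=float)
    if d_wt.shape != d_mut.shape:
        raise ValidationError("distance maps must have matching shapes")
    n = d_wt.shape[0]
    sel = np.triu(np.ones((n, n), dtype=bool), 1)
    if pair_subset is not None:
        sel &= np.asarray(pair_subset, dtype=bool)
    if not sel.any():
        raise ValidationError("empty pair subset")
    num = np.sum((d_wt[sel] - d_mut[sel]) ** 2)
    den = np.sum(d_wt[sel] ** 2)
    return float(np.sqrt(num / den))


def pi_deletion_profile(K: ConnectivityMatrix) -> np.ndarray:
    """Perturbation Index of deleting each locus in turn.

    For locus i: delete, recompute the mean distance map of the N−1 survivors,
    and compare with the wild-type map restricted to the surviving pairs.
    Loci whose deletion disconnects the chain — or destabilizes a model with
    negative couplings — are reported as NaN.
    """
    n = K.n_loci
    d_wt = _mean_distances(K)
    out = np.full(n, np.nan)
    for i in range(n):
        try:
            K_del = delete_locus(K, i)
        except (DisconnectedError, InvalidConnectivityError, ValidationError):
            continue
        d_mut = _mean_distances(K_del)
        d_wt_i = np.delete(np.delete(d_wt, i, axis=0), i, axis=1)
        out[i] = perturbation_index(d_wt_i, d_mut)
    return out


def apply_edits(K: ConnectivityMatrix, edits: list[dict]) -> ConnectivityMatrix:
    """Apply an ordered list of edit specs ``{"op": "invert"|"delete", "start": i, "end": j}``.

    ``start``/``end`` are 0-based locus indices (inclusive); a delete spec
    removes the loci start..end one at a time (end defaults to start).
    Duplications and insertions are rejected: they change the number of loci
    and require refitting to an edited contact or distance map.
    """
    for edit in edits:
        op = edit.get("op")
        if op == "invert":
            K = invert_segment(K, (int(edit["start"]), int(edit["end"])))
        elif op == "delete":
            start = int(edit["start"])
            end = int(edit.get("end", start))
            for _ in range(start, end + 1):
                K = delete_locus(K, start)  # indices shift after each removal
        elif op in ("duplicate", "insert"):
            raise ValidationError(
                f"'{op}' edits are not expressible as coupling-matrix perturbations; "
                "refit the model to the mutated contact or distance map instead"
            )
        else:
            raise ValidationError(f"unknown edit op: {op!r}")
    return K


def predict_variant_contact_map(
    K: ConnectivityMatrix, edits: list[dict], params: ConversionParams | None = None
) -> ContactMap:
    """Compose edits → mean distances → contact map (deterministic)."""
    K_mut = apply_edits(K, edits)
    d2 = mean_sq_distances(covariance_from_connectivity(K_mut))
    return contacts_from_distances(d2, params or ConversionParams())
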