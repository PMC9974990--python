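"""Core maximum-entropy Gaussian model of chromatin loci.

The model treats the ``N`` imaged genomic loci as a multivariate Gaussian whose
density is ``P({x_i}) ∝ exp(-Σ_{i<j} k_ij ||x_i - x_j||²)``.  The Lagrange
multipliers ``k_ij`` play the role of effective harmonic couplings between loci
(the generalized Rouse model form); they are collected in a Laplacian-structured
*connectivity matrix* ``K`` with ``K_ij = k_ij`` (i ≠ j) and
``K_ii = -Σ_{j≠i} k_ij``, so every row of ``K`` sums to zero and, for a valid
(normalizable) model, ``K`` is negative semidefinite with a single zero mode —
the rigid translation of the center of mass.

Exact algebraic maps implemented here:

* coordinate covariance       ``Σ = -K⁺``  (Moore–Penrose pseudoinverse),
* mean squared distances      ``⟨r_ij²⟩ = 3 ω_ij²``, ``ω_ij² = Σ_ii + Σ_jj - 2Σ_ij``,
* the inverse map d² → K via double-centering of the squared-distance matrix.

Units: coordinates in nm, squared distances in nm², couplings in nm⁻² under this
convention.  A unitless "model" mode is just the same algebra with k = O(1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DisconnectedError,
    InvalidConnectivityError,
    NotRealizableError,
    ValidationError,
)

#: relative eigenvalue tolerance used to identify the zero (center-of-mass) mode
ZERO_MODE_RTOL = 1e-10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LociSystem:
    """Genomic bookkeeping for a set of N loci.

    Parameters
    ----------
    n_loci
        Number of loci, N >= 2.
    genomic_start
        Optional per-locus genomic coordinate (bp, 1-based), strictly increasing.
    resolution
        bp per locus; 0 marks irregular spacing.
    labels
        Optional per-locus compartment tag, each in {"A", "B", "unassigned"}.
    """

    n_loci: int
    genomic_start: np.ndarray | None = None
    resolution: int = 0
    labels: np.ndarray | None = None

    def __post_init__(self):
        if self.n_loci < 2:
            raise ValidationError("a loci system needs at least 2 loci")
        if self.genomic_start is not None:
            self.genomic_start = np.asarray(self.genomic_start)
            if self.genomic_start.shape != (self.n_loci,):
                raise ValidationError("genomic_start length must equal n_loci")
            if not np.all(np.diff(self.genomic_start) > 0):
                raise ValidationError("genomic coordinates must be strictly increasing")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (self.n_loci,):
                raise ValidationError("labels length must equal n_loci")
            bad = set(self.labels) - {"A", "B", "unassigned"}
            if bad:
                raise ValidationError(f"unknown compartment labels: {bad}")


@dataclass
class ConnectivityMatrix:
    """Symmetric coupling table k_ij plus the assembled Laplacian-style K.

    ``offdiag`` stores the couplings with a zero diagonal; ``matrix`` assembles
    the full K with ``K_ii = -Σ_{j≠i} k_ij`` so rows sum to exactly zero.
    """

    offdiag: np.ndarray

    def __post_init__(self):
        self.offdiag = np.asarray(self.offdiag, dtype=float)

    @property
    def n_loci(self) -> int:
        return self.offdiag.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        K = self.offdiag.copy()
        np.fill_diagonal(K, 0.0)
        np.fill_diagonal(K, -K.sum(axis=1))
        return K

    def eigh(self):
        """Eigendecomposition of the assembled K (ascending eigenvalues)."""
        return np.linalg.eigh(self.matrix)


@dataclass
class CovarianceMatrix:
    """Coordinate covariance Σ (nm²) in the center-of-mass gauge.

    The uniform vector is in the null space: each row of Σ sums to zero.
    """

    sigma: np.ndarray
    gauge: str = "center_of_mass"

    @property
    def n_loci(self) -> int:
        return self.sigma.shape[0]


@dataclass
class SquaredDistanceMatrix:
    """Mean squared pairwise distances ⟨r_ij²⟩ (nm²), optionally masked.

    ``mask`` is True where a pair is *missing* (unobserved); it is symmetric
    with a False diagonal.
    """

    d2: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.d2 = np.asarray(self.d2, dtype=float)
        n = self.d2.shape[0]
        if self.d2.shape != (n, n):
            raise ValidationError("d2 must be square")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.d2.shape:
                raise ValidationError("mask shape must match d2")
            if not np.array_equal(self.mask, self.mask.T):
                raise ValidationError("mask must be symmetric")
            if self.mask.diagonal().any():
                raise ValidationError("mask diagonal must be False")

    @property
    def n_loci(self) -> int:
        return self.d2.shape[0]

    @property
    def observed(self) -> np.ndarray:
        """Boolean matrix, True where the pair is observed (off-diagonal)."""
        obs = ~np.eye(self.n_loci, dtype=bool)
        if self.mask is not None:
            obs &= ~self.mask
        return obs

    def distances(self) -> np.ndarray:
        """Mean distance scale sqrt(⟨r²⟩); masked entries are NaN."""
        r = np.sqrt(np.maximum(self.d2, 0.0))
        if self.mask is not None:
            r = np.where(self.mask, np.nan, r)
        return r


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _check_symmetric_finite(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"{name} must be a square matrix, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"{name} contains non-finite entries")
    if not np.allclose(a, a.T, rtol=0, atol=1e-12 * max(1.0, np.abs(a).max())):
        raise ValidationError(f"{name} must be symmetric")
    return a


def assemble_connectivity(offdiag: np.ndarray) -> ConnectivityMatrix:
    """Build a ConnectivityMatrix from a symmetric pair-coupling table.

    The diagonal of ``offdiag`` is ignored; the assembled K gets
    ``K_ii = -Σ_{j≠i} k_ij`` so each row sums to exactly zero.
    """
    offdiag = _check_symmetric_finite(offdiag, "coupling table").copy()
    offdiag = 0.5 * (offdiag + offdiag.T)  # exact symmetry
    np.fill_diagonal(offdiag, 0.0)
    return ConnectivityMatrix(offdiag=offdiag)


def connected_components_of(offdiag: np.ndarray, tol: float = 0.0):
    """Connected components of the coupling graph (edges where |k_ij| > tol)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = (np.abs(offdiag) > tol).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comps = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
    return comps


def covariance_from_connectivity(
    K: ConnectivityMatrix, rtol: float = ZERO_MODE_RTOL
) -> CovarianceMatrix:
    """Σ = -K⁺ (Moore–Penrose pseudoinverse), center-of-mass gauge.

    Raises
    ------
    InvalidConnectivityError
        If K has a positive eigenvalue beyond tolerance (model not normalizable).
    DisconnectedError
        If K has more than one near-zero mode (disconnected coupling graph),
        or all modes are zero (fully decoupled loci — no valid gauge).
    """
    w, U = K.eigh()
    scale = np.abs(w).max()
    if scale == 0.0:
        raise DisconnectedError(
            connected_components_of(K.offdiag), what="coupling graph (K = 0, degenerate model)"
        )
    tol = rtol * scale
    if w[-1] > tol:
        raise InvalidConnectivityError(float(w[-1]), float(tol))
    zero = np.abs(w) <= tol
    if zero.sum() != 1:
        raise DisconnectedError(connected_components_of(K.offdiag))
    inv = np.where(zero, 0.0, -1.0 / np.where(zero, 1.0, w))
    sigma = (U * inv) @ U.T
    sigma = 0.5 * (sigma + sigma.T)
    return CovarianceMatrix(sigma=sigma)


def mean_sq_distances(sigma: CovarianceMatrix | np.ndarray) -> SquaredDistanceMatrix:
    """⟨r_ij²⟩ = 3 (Σ_ii + Σ_jj - 2Σ_ij); zero diagonal, symmetric."""
    S = sigma.sigma if isinstance(sigma, CovarianceMatrix) else np.asarray(sigma)
    d = np.diag(S)
    d2 = 3.0 * (d[:, None] + d[None, :] - 2.0 * S)
    np.fill_diagonal(d2, 0.0)
    return SquaredDistanceMatrix(d2=0.5 * (d2 + d2.T))


def mean_sq_distances_from_connectivity(K: ConnectivityMatrix) -> SquaredDistanceMatrix:
    """Convenience composition ``mean_sq_distances(covariance_from_connectivity(K))``."""
    return mean_sq_distances(covariance_from_connectivity(K))


def connectivity_from_distances(
    d2: SquaredDistanceMatrix | np.ndarray,
    project_psd: bool = False,
    rtol: float = ZERO_MODE_RTOL,
) -> ConnectivityMatrix:
    """Direct (optimization-free) inversion of a complete squared-distance matrix.

    Reconstructs Σ from ω² = d²/3 under the zero-row-sum gauge by double
    centering ``Σ = -½ J (d²/3) J`` with ``J = I - 11ᵀ/N``, then ``K = -Σ⁺``.
    Round-trips :func:`mean_sq_distances_from_connectivity` when the target is
    model-realizable.

    With ``project_psd`` on, negative eigenvalues of the centered Σ are clipped
    to zero (with a warning) instead of raising :class:`NotRealizableError`.
    """
    if isinstance(d2, SquaredDistanceMatrix):
        if d2.mask is not None and d2.mask.any():
            raise ValidationError("direct inversion requires a complete (unmasked) d2")
        d2 = d2.d2
    d2 = _check_symmetric_finite(d2, "d2")
    n = d2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    sigma = -0.5 * J @ (d2 / 3.0) @ J
    sigma = 0.5 * (sigma + sigma.T)
    w, U = np.linalg.eigh(sigma)
    scale = np.abs(w).max()
    tol = max(rtol * scale, np.finfo(float).tiny)
    if w[0] < -tol:
        if not project_psd:
            raise NotRealizableError(
                f"non-realizable distance matrix: centered Gram matrix has negative "
                f"eigenvalue {w[0]:.6g} (tolerance {tol:.3g}); pass project_psd=True to clip"
            )
        warnings.warn(
            f"clipping {int((w < -tol).sum())} negative eigenvalue(s) of the centered "
            "Gram matrix to 0 (PSD projection)",
            stacklevel=2,
        )
    w = np.clip(w, 0.0, None)
    zero = w <= tol
    inv = np.where(zero, 0.0, -1.0 / np.where(zero, 1.0, w))
    K = (U * inv) @ U.T
    K = 0.5 * (K + K.T)
    offdiag = K.copy()
    np.fill_diagonal(offdiag, 0.0)
    return ConnectivityMatrix(offdiag=offdiag)
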