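"""Drawing 3D conformations from the fitted Gaussian model via normal modes.

The connectivity matrix is eigendecomposed, ``K = U diag(ω) Uᵀ``; for each
spatial dimension an independent amplitude is drawn for every non-zero mode
from ``Normal(0, −1/ω_i)`` and the coordinates are recovered as the linear
combination of modes.  The zero mode (uniform eigenvector, eigenvalue 0) is
the rigid translation of the center of mass and is pinned to zero, so every
sampled conformation is centered at the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DisconnectedError, InvalidConnectivityError, ValidationError
from .model_core import (
    ZERO_MODE_RTOL,
    ConnectivityMatrix,
    SquaredDistanceMatrix,
    connected_components_of,
)


@dataclass
class ConformationEnsemble:
    """M conformations × N loci × 3 coordinates (nm).

    Sampled ensembles are centered per conformation and contain no NaNs;
    ``source="experimental"`` ensembles (imaging-derived) may have missing
    loci marked NaN.
    """

    coords: np.ndarray
    seed: int | None = None
    source: str = "sampled"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (M, N, 3)")
        if self.coords.shape[0] < 1:
            raise ValidationError("an ensemble needs at least one conformation")
        if self.source == "sampled" and not np.all(np.isfinite(self.coords)):
            raise ValidationError("sampled ensembles must not contain non-finite values")

    @property
    def n_conformations(self) -> int:
        return self.coords.shape[0]

    @property
    def n_loci(self) -> int:
        return self.coords.shape[1]

    def subset(self, keep: np.ndarray) -> "ConformationEnsemble":
        return ConformationEnsemble(coords=self.coords[keep], seed=self.seed, source=self.source)


def sample_conformations(
    K: ConnectivityMatrix,
    n_samples: int,
    seed: int,
    rtol: float = ZERO_MODE_RTOL,
) -> ConformationEnsemble:
    """Sample ``n_samples`` conformations from the model defined by ``K``.

    Reproducible: identical seeds give bitwise-identical ensembles.  The three
    spatial dimensions are drawn in fixed order (x, y, z).
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    w, U = K.eigh()
    scale = np.abs(w).max()
    if scale == 0.0:
        raise DisconnectedError(connected_components_of(K.offdiag), what="coupling graph (K = 0)")
    tol = rtol * scale
    if w[-1] > tol:
        raise InvalidConnectivityError(float(w[-1]), float(tol))
    zero = np.abs(w) <= tol
    if zero.sum() != 1:
        raise DisconnectedError(connected_components_of(K.offdiag))
    std = np.where(zero, 0.0, np.sqrt(np.where(zero, 0.0, -1.0 / np.where(zero, 1.0, w))))

    rng = np.random.default_rng(seed)
    n = K.n_loci
    coords = np.empty((n_samples, n, 3))
    for p in range(3):  # fixed dimension order for reproducibility
        amplitudes = rng.standard_normal((n, n_samples)) * std[:, None]
        coords[:, :, p] = (U @ amplitudes).T
    # pin the center of mass exactly at the origin (removes residual float drift
    # from the numerically-estimated zero mode)
    coords -= coords.mean(axis=1, keepdims=True)
    return ConformationEnsemble(coords=coords, seed=seed, source="sampled")


def ensemble_mean_sq_distances(
    ens: ConformationEnsemble | np.ndarray,
    min_cells: int = 1,
    warn_below: int = 5,
) -> SquaredDistanceMatrix:
    """Empirical ⟨r_ij²⟩ over conformations observing both loci.

    Missing coordinates (NaN, experimental ensembles) are skipped per pair.
    Pairs observed in fewer than ``min_cells`` conformations are masked; a
    warning is emitted when any pair count falls below ``warn_below``.
    """
    coords = ens.coords if isinstance(ens, ConformationEnsemble) else np.asarray(ens, dtype=float)
    m, n, _ = coords.shape
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=np.int64)
    chunk = max(1, int(2**22 // max(n * n, 1)))
    for lo in range(0, m, chunk):
        block = coords[lo : lo + chunk]
        diff = block[:, :, None, :] - block[:, None, :, :]
        d2 = np.einsum("mijp,mijp->mij", diff, diff)
        ok = np.isfinite(d2)
        total += np.where(ok, d2, 0.0).sum(axis=0)
        count += ok.sum(axis=0)
    np.fill_diagonal(count, 0)
    offdiag = ~np.eye(n, dtype=bool)
    mask = offdiag & (count < min_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2_mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    np.fill_diagonal(d2_mean, 0.0)
    d2_mean[mask] = 0.0
    low = offdiag & (count < warn_below)
    if low.any():
        warnings.warn(
            f"{int(low.sum() // 2)} pair(s) observed in fewer than {warn_below} conformations",
            stacklevel=2,
        )
    return SquaredDistanceMatrix(d2=d2_mean, mask=mask if mask.any() else None)
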