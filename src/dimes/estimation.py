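"""Fitting the connectivity matrix to a target mean squared-distance matrix.

Two first-order schemes are provided, both of which evaluate the model's
``⟨r_ij²⟩`` analytically at every step (one eigendecomposition per iteration,
no sampling):

* iterative scaling:
  ``k_ij(t+1) = k_ij(t) + γ / Σ_{i<j}⟨r_ij²⟩(t) · ln(⟨r_ij²⟩(t) / a_ij)``
* gradient descent:
  ``k_ij(t+1) = k_ij(t) − γ · [⟨r_ij²⟩(t) − a_ij]`` (optionally ridge-damped)

where ``a_ij`` is the target.  The iterative-scaling step is scale invariant
(the denominator carries the units), so the printed learning rate γ = 10 works
for targets in nm² or in model units alike.  Masked (missing) pairs are frozen
at their initialization value and never updated; after convergence their
distances are read off the fitted model, which is how held-out entries of an
experimental distance map are predicted.

If an update pushes K out of the negative-semidefinite cone the positive
eigenvalues are clipped to zero in the eigenbasis and the coupling table is
reassembled (frozen entries restored), keeping the distribution normalizable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvergenceError, DisconnectedError, ValidationError
from .model_core import (
    ZERO_MODE_RTOL,
    ConnectivityMatrix,
    SquaredDistanceMatrix,
    assemble_connectivity,
    connected_components_of,
    connectivity_from_distances,
)

_METHODS = ("iterative_scaling", "gradient_descent")
_INITS = ("ideal_chain", "zeros", "direct_inversion", "user")


@dataclass
class FitConfig:
    """Optimization settings.

    ``gamma`` defaults to 10 for iterative scaling; for gradient descent the
    default is the scale-aware ``0.3 / max(a_ij)²`` because the plain GD step
    carries units of the target and its stability is limited by the
    largest-distance pair.  ``tol`` is the relative convergence threshold
    on ``mean |⟨r²⟩ − a| / mean a``.  ``ridge`` adds an optional penalty
    ``λ Σ_{i<j} k_ij²`` to the gradient-descent objective (update term
    ``−2γλ k_ij``).  ``seed`` is recorded for provenance; the fits themselves
    are deterministic.
    """

    method: str = "iterative_scaling"
    gamma: float | None = None
    max_iter: int = 10000
    tol: float = 1e-2
    ridge: float = 0.0
    init: str = "ideal_chain"
    init_offdiag: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValidationError(f"method must be one of {_METHODS}")
        if self.init not in _INITS:
            raise ValidationError(f"init must be one of {_INITS}")
        if self.gamma is not None and self.gamma < 0:
            raise ValidationError("gamma must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.ridge < 0:
            raise ValidationError("ridge must be >= 0")
        if self.init == "user" and self.init_offdiag is None:
            raise ValidationError("init='user' requires init_offdiag")


@dataclass
class FitResult:
    connectivity: ConnectivityMatrix
    error_trace: np.ndarray
    converged: bool
    n_iter: int
    config: FitConfig | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _pinv_from_eigh(w, U, rtol=ZERO_MODE_RTOL):
    """Σ = -K⁺ and model d2 from an eigendecomposition of K."""
    tol = rtol * np.abs(w).max()
    zero = np.abs(w) <= tol
    inv = np.where(zero, 0.0, -1.0 / np.where(zero, 1.0, w))
    sigma = (U * inv) @ U.T
    d = np.diag(sigma)
    d2 = 3.0 * (d[:, None] + d[None, :] - 2.0 * sigma)
    np.fill_diagonal(d2, 0.0)
    return d2


def _ideal_chain_init(a, observed):
    """Nearest-neighbor chain whose mean d2 matches the observed target mean.

    A uniform chain with coupling k has ⟨r_ij²⟩ = 3|i−j|/k, so matching means
    gives k = 3·mean(|i−j|) / mean(a) over the observed pairs.
    """
    n = a.shape[0]
    ii, jj = np.nonzero(np.triu(observed, 1))
    seps = np.abs(jj - ii)
    k0 = 3.0 * seps.mean() / a[ii, jj].mean()
    off = np.zeros((n, n))
    idx = np.arange(n - 1)
    off[idx, idx + 1] = off[idx + 1, idx] = k0
    return off


def _initial_offdiag(target: SquaredDistanceMatrix, config: FitConfig):
    n = target.n_loci
    obs = target.observed
    if config.init == "zeros":
        return np.zeros((n, n))
    if config.init == "user":
        off = np.asarray(config.init_offdiag, dtype=float).copy()
        if off.shape != (n, n):
            raise ValidationError("init_offdiag shape must match target")
        np.fill_diagonal(off, 0.0)
        return off
    if config.init == "direct_inversion":
        if target.mask is not None and target.mask.any():
            raise ValidationError("init='direct_inversion' requires a complete target")
        return connectivity_from_distances(target, project_psd=True).offdiag.copy()
    return _ideal_chain_init(target.d2, obs)


def _repair_nsd(offdiag, frozen_mask, frozen_values, rtol=ZERO_MODE_RTOL):
    """Return (offdiag, w, U) with K projected to the NSD cone if needed.

    Frozen entries are restored after the projection (their values are part of
    the masked-fit contract), so the repaired K is re-decomposed.
    """
    K = assemble_connectivity(offdiag)
    w, U = K.eigh()
    tol = rtol * max(np.abs(w).max(), np.finfo(float).tiny)
    if w[-1] <= tol:
        return K.offdiag, w, U
    Kc = (U * np.minimum(w, 0.0)) @ U.T
    off = 0.5 * (Kc + Kc.T)
    np.fill_diagonal(off, 0.0)
    if frozen_mask is not None:
        off[frozen_mask] = frozen_values[frozen_mask]
    K = assemble_connectivity(off)
    w, U = K.eigh()
    return K.offdiag, w, U


def model_error(K: ConnectivityMatrix, target: SquaredDistanceMatrix) -> float:
    """Relative mean absolute error ``mean|⟨r²⟩ − a| / mean(a)`` over observed pairs.

    Zero iff the model matches the target exactly on the observed entries.
    Note the normalization is by the *target* mean, so the measure is not
    symmetric under swapping model and target scales.
    """
    if K.n_loci != target.n_loci:
        raise ValidationError("connectivity and target sizes differ")
    w, U = K.eigh()
    d2 = _pinv_from_eigh(w, U)
    return _error_on(d2, target.d2, np.triu(target.observed, 1))


def _error_on(d2_model, a, upper_obs):
    num = np.abs(d2_model[upper_obs] - a[upper_obs]).mean()
    return float(num / a[upper_obs].mean())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit(target: SquaredDistanceMatrix, config: FitConfig) -> FitResult:
    a = target.d2
    n = target.n_loci
    obs = target.observed
    upper_obs = np.triu(obs, 1)
    if not upper_obs.any():
        raise ValidationError("target has no observed off-diagonal pairs")
    if np.any(a[upper_obs] <= 0):
        raise ValidationError("target a_ij must be > 0 on observed off-diagonal pairs")

    # identifiability of masked fits requires the observed graph to connect all loci
    if target.mask is not None and target.mask.any():
        adj = obs.astype(float)
        comps = connected_components_of(adj)
        if len(comps) > 1:
            raise DisconnectedError(comps, what="observed-pair graph (fit unidentifiable)")

    frozen_mask = None
    off = _initial_offdiag(target, config)
    frozen_values = off.copy()
    if target.mask is not None and target.mask.any():
        frozen_mask = target.mask.copy()

    gamma = config.gamma
    if gamma is None:
        # GD stability is set by the most sensitive (largest-distance) pair:
        # |∂⟨r²⟩/∂k| ~ ⟨r²⟩²/3, so the step must shrink with max(a)²
        gamma = 10.0 if config.method == "iterative_scaling" else 0.3 / a[upper_obs].max() ** 2

    trace = []
    converged = False
    best = np.inf
    for _ in range(config.max_iter):
        off, w, U = _repair_nsd(off, frozen_mask, frozen_values)
        d2 = _pinv_from_eigh(w, U)
        err = _error_on(d2, a, upper_obs)
        trace.append(err)
        best = min(best, err)
        if err <= config.tol:
            converged = True
            break
        if err > 10.0 * best and err > config.tol:
            raise ConvergenceError(
                f"fit diverged: error {err:.4g} grew 10x above the running minimum {best:.4g}",
                np.asarray(trace),
            )
        if config.method == "iterative_scaling":
            denom = d2[np.triu_indices(n, 1)].sum()
            log_ratio = np.zeros_like(d2)
            log_ratio[obs] = np.log(d2[obs] / a[obs])
            step = (gamma / denom) * log_ratio
        else:
            # descent on the max-ent dual ψ(k) = ln Z + Σ k_ij a_ij, whose
            # gradient is a_ij − ⟨r_ij²⟩: couplings strengthen when the model
            # is too extended, consistent with the iterative-scaling direction
            step = gamma * (d2 - a)
            if config.ridge > 0:
                step -= 2.0 * gamma * config.ridge * off
        step = np.where(obs, step, 0.0)
        np.fill_diagonal(step, 0.0)
        off = off + step
        if frozen_mask is not None:
            off[frozen_mask] = frozen_values[frozen_mask]

    off, w, U = _repair_nsd(off, frozen_mask, frozen_values)
    return FitResult(
        connectivity=ConnectivityMatrix(offdiag=off),
        error_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace),
        config=config,
    )


def fit_iterative_scaling(target: SquaredDistanceMatrix, config: FitConfig | None = None) -> FitResult:
    """Fit k_ij by iterative scaling (log-ratio updates, learning rate γ = 10)."""
    config = config or FitConfig()
    if config.method != "iterative_scaling":
        raise ValidationError("config.method must be 'iterative_scaling'")
    return _fit(target, config)


def fit_gradient_descent(target: SquaredDistanceMatrix, config: FitConfig | None = None) -> FitResult:
    """Fit k_ij by plain gradient descent on the squared-distance residuals."""
    config = config or FitConfig(method="gradient_descent")
    if config.method != "gradient_descent":
        raise ValidationError("config.method must be 'gradient_descent'")
    return _fit(target, config)


def fit_with_mask(
    target: SquaredDistanceMatrix, config: FitConfig | None = None
) -> tuple[FitResult, SquaredDistanceMatrix]:
    """Fit with missing entries and predict them from the converged model.

    Masked pairs never enter the update (their couplings stay bitwise at the
    initialization value, which for the default ideal-chain init keeps the
    backbone connected).  The returned :class:`SquaredDistanceMatrix` is the
    fitted model's *complete* map, from which held-out entries are read.
    """
    config = config or FitConfig()
    result = _fit(target, config)
    w, U = result.connectivity.eigh()
    predicted = SquaredDistanceMatrix(d2=_pinv_from_eigh(w, U))
    return result, predicted


def fit(target: SquaredDistanceMatrix, config: FitConfig | None = None) -> FitResult:
    """Dispatch on ``config.method``."""
    config = config or FitConfig()
    return _fit(target, config)
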