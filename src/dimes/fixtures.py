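"""Synthetic ground truth: known coupling matrices with planted compartments
and imaging-like degraded coordinate tables.

These generators make every stage of the pipeline testable without external
data.  Defaults emulate a multiplexed-FISH tracing experiment on a ~2 Mbp
region: ~64 loci, nearest-neighbor spatial scale ~300 nm (backbone coupling
k = 3/300² nm⁻²), alternating A/B blocks of 8 loci with weak same-class
attraction and weaker cross-class repulsion, ~3000 cells, 10% of loci missing
at random per cell, and 20 nm isotropic localization noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model_core import ConnectivityMatrix, assemble_connectivity
from .sampling import sample_conformations

#: backbone coupling giving a ~300 nm nearest-neighbor scale (⟨r²⟩ = 3/k)
DEFAULT_BACKBONE_K = 3.0 / 300.0**2


def make_rouse_chain(n_loci: int, k: float = DEFAULT_BACKBONE_K) -> ConnectivityMatrix:
    """Uniform nearest-neighbor chain (the ideal-homopolymer limit).

    Analytically, ⟨r_ij²⟩ = 3|i−j|/k (graph resistance distance over the chain).
    """
    off = np.zeros((n_loci, n_loci))
    idx = np.arange(n_loci - 1)
    off[idx, idx + 1] = off[idx + 1, idx] = k
    return assemble_connectivity(off)


def block_labels(n_loci: int, block_size: int = 8) -> np.ndarray:
    """Alternating A/B block labels (A first)."""
    return np.asarray(
        ["A" if (i // block_size) % 2 == 0 else "B" for i in range(n_loci)], dtype=object
    )


def make_block_copolymer(
    n_loci: int = 64,
    block_size: int = 8,
    k_backbone: float = DEFAULT_BACKBONE_K,
    k_intra: float | None = None,
    k_inter: float | None = None,
    jitter: float = 0.2,
    seed: int = 0,
) -> tuple[ConnectivityMatrix, np.ndarray]:
    """Block copolymer with planted A/B compartments.

    Backbone chain plus same-class attraction (``k_intra``, default
    0.05·k_backbone) and cross-class repulsion (``k_inter``, default
    −0.005·k_backbone, much weaker than the attraction, as in fitted
    chromosome couplings) on all non-adjacent pairs, with ±``jitter`` relative
    multiplicative noise.  If the assembled K acquires a positive eigenvalue
    the non-backbone couplings are halved until negative semidefiniteness
    holds.  Returns ``(K, labels)``.
    """
    if k_intra is None:
        k_intra = 0.05 * k_backbone
    if k_inter is None:
        k_inter = -0.005 * k_backbone
    labels = block_labels(n_loci, block_size)
    rng = np.random.default_rng(seed)
    off = np.zeros((n_loci, n_loci))
    same = labels[:, None] == labels[None, :]
    iu, ju = np.triu_indices(n_loci, 1)
    base = np.where(same[iu, ju], k_intra, k_inter)
    base = base * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=base.shape))
    off[iu, ju] = base
    off = off + off.T
    # backbone overrides whatever class coupling the neighbors had
    idx = np.arange(n_loci - 1)
    off[idx, idx + 1] = off[idx + 1, idx] = k_backbone

    nonbackbone = np.ones((n_loci, n_loci), dtype=bool)
    nonbackbone[idx, idx + 1] = nonbackbone[idx + 1, idx] = False
    for _ in range(60):
        K = assemble_connectivity(off)
        w = np.linalg.eigvalsh(K.matrix)
        if w[-1] <= 1e-10 * np.abs(w).max():
            return K, labels
        off = np.where(nonbackbone, 0.5 * off, off)
    raise RuntimeError("could not scale couplings into the negative-semidefinite cone")


def make_synthetic_cell_coords(
    K: ConnectivityMatrix,
    n_cells: int,
    missing_rate: float = 0.1,
    noise_sd: float = 20.0,
    seed: int = 0,
) -> np.ndarray:
    """(M, N, 3) coordinates with localization noise and missing loci (NaN).

    Conformations are drawn from the model, isotropic Gaussian noise of
    standard deviation ``noise_sd`` (nm) is added per coordinate (inflating
    every ⟨r_ij²⟩ by 6·noise_sd² in expectation), and each locus is dropped
    independently per cell with probability ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    sample_seed, degrade_seed = (int(s) for s in rng.integers(2**31, size=2))
    ens = sample_conformations(K, n_cells, seed=sample_seed)
    coords = ens.coords.copy()
    drng = np.random.default_rng(degrade_seed)
    if noise_sd > 0:
        coords += drng.normal(0.0, noise_sd, size=coords.shape)
    if missing_rate > 0:
        drop = drng.random(coords.shape[:2]) < missing_rate
        coords[drop] = np.nan
    return coords


def make_synthetic_cells(
    K: ConnectivityMatrix,
    n_cells: int,
    missing_rate: float = 0.1,
    noise_sd: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Imaging-like per-cell coordinate table (cell_id, locus_index, x, y, z in nm)."""
    coords = make_synthetic_cell_coords(K, n_cells, missing_rate, noise_sd, seed)
    cells, loci = np.nonzero(np.all(np.isfinite(coords), axis=2))
    return pd.DataFrame(
        {
            "cell_id": cells,
            "locus_index": loci,
            "x": coords[cells, loci, 0],
            "y": coords[cells, loci, 1],
            "z": coords[cells, loci, 2],
        }
    )


def make_tad_chain(
    n_loci: int = 64,
    tad_size: int = 16,
    k_backbone: float = DEFAULT_BACKBONE_K,
    k_tad: float | None = None,
    k_anchor: float = 0.0,
) -> ConnectivityMatrix:
    """Chain with TAD-like domains: uniform attraction inside consecutive
    blocks of ``tad_size`` loci (default 0.1·k_backbone), optionally with
    extra anchor couplings bridging adjacent domain boundaries.

    Couplings are short-range and parsimonious, like those fitted to imaging
    data of Mbp-scale regions; this is the fixture of choice for missing-data
    cross-validation, where the held-out entries must be predictable from the
    couplings supported on the observed pairs.
    """
    if k_tad is None:
        k_tad = 0.1 * k_backbone
    off = make_rouse_chain(n_loci, k_backbone).offdiag.copy()
    for start in range(0, n_loci, tad_size):
        blk = np.arange(start, min(start + tad_size, n_loci))
        for a in blk:
            for b in blk:
                if b - a > 1:
                    off[a, b] = off[b, a] = k_tad
    if k_anchor > 0:
        for start in range(0, n_loci - tad_size, tad_size):
            off[start, start + tad_size] = off[start + tad_size, start] = k_anchor
    return assemble_connectivity(off)
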