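import numpy as np
import pytest

import dimes
from dimes import fixtures


@pytest.fixture(scope="session")
def chain6():
    """Uniform nearest-neighbor chain, k = 1 (model units), N = 6."""
    return fixtures.make_rouse_chain(6, 1.0)


@pytest.fixture(scope="session")
def dumbbell_half():
    """Two loci coupled with k = 0.5 → ⟨r²⟩ = 6."""
    return dimes.assemble_connectivity(np.array([[0.0, 0.5], [0.5, 0.0]]))


@pytest.fixture(scope="session")
def block16():
    """Small block copolymer with planted labels (N=16, blocks of 4)."""
    return fixtures.make_block_copolymer(16, block_size=4, seed=3)


@pytest.fixture(scope="session")
def small_ensemble():
    """Deterministic 3-conformation, 4-locus ensemble for brute-force oracles."""
    rng = np.random.default_rng(42)
    coords = rng.normal(0, 1.0, size=(3, 4, 3))
    return dimes.ConformationEnsemble(coords=coords, source="experimental")


def random_nsd_connectivity(n, seed, density=0.6):
    """Random connected NSD connectivity: K = -L(G) for a random weighted graph."""
    rng = np.random.default_rng(seed)
    off = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    weights = rng.uniform(0.2, 2.0, size=len(iu[0]))
    keep = rng.random(len(iu[0])) < density
    off[iu] = np.where(keep, weights, 0.0)
    off = off + off.T
    idx = np.arange(n - 1)
    off[idx, idx + 1] = np.maximum(off[idx, idx + 1], 0.5)  # keep connected
    off[idx + 1, idx] = off[idx, idx + 1]
    return dimes.assemble_connectivity(off)
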