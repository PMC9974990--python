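"""Reading/writing experimental inputs and contact↔distance conversion.

Supported formats: dense tab-separated matrices (with ``#`` comment header
lines), HDF5 containers (datasets ``/d2``, ``/K``, ``/sigma``, ``/coords``
with unit/convention attributes), per-cell coordinate tables (CSV/TSV), and
multi-model PDB / XYZ ensemble export.

The contact→distance map is the power law ``⟨r_ij²⟩ = (Λ p_ij^{−1/α})²`` with
Λ the length scale and α the decay exponent (α = 4 by default; Λ = 1 when the
physical scale is unknown — structures can simply be rescaled afterwards).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .estimation import FitConfig, FitResult
from .exceptions import UnidentifiableError, ValidationError
from .model_core import ConnectivityMatrix, SquaredDistanceMatrix
from .sampling import ConformationEnsemble

CONVENTION = "sigma=-pinv(K); d2=3*omega2; units nm, nm^2, nm^-2"


# ---------------------------------------------------------------------------
# contact maps and conversion
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Symmetric matrix of contact probabilities in [0, 1]; diagonal set to 1."""

    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        n = self.p.shape[0]
        if self.p.ndim != 2 or self.p.shape != (n, n):
            raise ValidationError("contact map must be square")
        if not np.allclose(np.nan_to_num(self.p), np.nan_to_num(self.p.T)):
            raise ValidationError("contact map must be symmetric")
        finite = np.isfinite(self.p)
        if np.any((self.p[finite] < 0) | (self.p[finite] > 1)):
            raise ValidationError("contact probabilities must lie in [0, 1]")
        np.fill_diagonal(self.p, 1.0)

    @property
    def n_loci(self) -> int:
        return self.p.shape[0]

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "ContactMap":
        """Normalize a raw-count matrix: divide by the maximum off-diagonal count."""
        counts = np.asarray(counts, dtype=float)
        off = counts[~np.eye(counts.shape[0], dtype=bool)]
        peak = np.nanmax(off)
        if not np.isfinite(peak) or peak <= 0:
            raise ValidationError("count matrix has no positive off-diagonal entries")
        p = np.clip(counts / peak, 0.0, 1.0)
        return cls(p=p)


@dataclass
class ConversionParams:
    """Power-law parameters: Λ (``lambda_scale``, nm) and exponent α."""

    lambda_scale: float = 1.0
    alpha: float = 4.0

    def __post_init__(self):
        if self.lambda_scale <= 0 or self.alpha <= 0:
            raise ValidationError("lambda_scale and alpha must be > 0")


def distances_from_contacts(cm: ContactMap, params: ConversionParams | None = None) -> SquaredDistanceMatrix:
    """⟨r_ij²⟩ = (Λ p_ij^{−1/α})²; zero/invalid probabilities become masked pairs."""
    params = params or ConversionParams()
    p = cm.p
    n = cm.n_loci
    valid = np.isfinite(p) & (p > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(valid, (params.lambda_scale * np.power(np.where(valid, p, 1.0), -1.0 / params.alpha)) ** 2, 0.0)
    np.fill_diagonal(d2, 0.0)
    mask = ~valid
    np.fill_diagonal(mask, False)
    return SquaredDistanceMatrix(d2=d2, mask=mask if mask.any() else None)


def contacts_from_distances(d2: SquaredDistanceMatrix, params: ConversionParams | None = None) -> ContactMap:
    """Inverse conversion ``p_ij = (r_ij/Λ)^{−α}`` capped at 1; round-trips the forward map."""
    params = params or ConversionParams()
    r = np.sqrt(np.maximum(d2.d2, 0.0))
    n = d2.n_loci
    offdiag = ~np.eye(n, dtype=bool)
    zero_r = offdiag & (r == 0)
    if zero_r.any():
        warnings.warn("zero off-diagonal distances: contact probability capped at 1", stacklevel=2)
    with np.errstate(divide="ignore"):
        p = np.where(r > 0, np.power(np.where(r > 0, r, 1.0) / params.lambda_scale, -params.alpha), np.inf)
    p = np.minimum(p, 1.0)
    if d2.mask is not None:
        p = np.where(d2.mask, np.nan, p)
    np.fill_diagonal(p, 1.0)
    return ContactMap(p=p)


def calibrate_conversion(cm: ContactMap, d2_ref: SquaredDistanceMatrix) -> ConversionParams:
    """Determine (Λ, α) by minimizing the mean squared deviation between the
    converted Hi-C distances and reference (imaging) mean distances,
    ``χ = (2/N(N−1)) Σ_{i<j} (Λ p_ij^{−1/α} − r_ij)²``.

    χ is separable in Λ (weighted least squares), so only α is searched:
    a deterministic log-space grid over α ∈ [2, 8] followed by a bounded local
    refinement around the best grid point.
    """
    n = cm.n_loci
    if d2_ref.n_loci != n:
        raise ValidationError("contact map and reference sizes differ")
    upper = np.triu(np.ones((n, n), dtype=bool), 1)
    ok = upper & np.isfinite(cm.p) & (cm.p > 0) & d2_ref.observed
    if ok.sum() < 10:
        raise ValidationError("need at least 10 overlapping unmasked pairs to calibrate")
    p = cm.p[ok]
    r = np.sqrt(np.maximum(d2_ref.d2[ok], 0.0))
    if np.ptp(p) == 0:
        raise UnidentifiableError("constant contact map: (Lambda, alpha) are unidentifiable")

    logp = np.log(p)

    def chi(alpha: float) -> float:
        q = np.exp(-logp / alpha)
        lam = (q @ r) / (q @ q)
        resid = lam * q - r
        return float(resid @ resid / resid.size)

    grid = np.exp(np.linspace(np.log(2.0), np.log(8.0), 121))
    vals = [chi(al) for al in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(chi, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
    alpha = float(res.x) if res.fun <= vals[i] else float(grid[i])
    q = np.exp(-logp / alpha)
    lam = float((q @ r) / (q @ q))
    return ConversionParams(lambda_scale=lam, alpha=alpha)


# ---------------------------------------------------------------------------
# per-cell coordinate tables
# ---------------------------------------------------------------------------

def read_cell_coordinates(
    table: str | Path | pd.DataFrame, n_loci: int
) -> tuple[np.ndarray, np.ndarray]:
    """Read a per-cell loci coordinate table into an (M, N, 3) array.

    The table needs columns ``cell_id, locus_index, x, y, z`` (nm; locus
    indices 0-based).  Missing loci are absent rows or non-finite coordinates;
    they come back as NaN.  Returns ``(coords, cell_ids)`` with cells ordered
    by first appearance-independent sorted id, so row order in the file is
    irrelevant.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, sep=None, engine="python", comment="#")
    else:
        df = table.copy()
    required = {"cell_id", "locus_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"coordinate table missing columns: {sorted(missing)}")
    loci = df["locus_index"].to_numpy()
    if np.any((loci < 0) | (loci >= n_loci)):
        bad = sorted(set(loci[(loci < 0) | (loci >= n_loci)]))
        raise ValidationError(f"unknown locus indices {bad[:5]} for a system of {n_loci} loci")
    dup = df.duplicated(subset=["cell_id", "locus_index"])
    if dup.any():
        raise ValidationError(
            f"duplicate (cell, locus) rows, e.g. {df.loc[dup.idxmax(), ['cell_id', 'locus_index']].tolist()}"
        )
    cell_ids = np.sort(df["cell_id"].unique())
    pos = {c: i for i, c in enumerate(cell_ids)}
    coords = np.full((len(cell_ids), n_loci, 3), np.nan)
    rows = df["cell_id"].map(pos).to_numpy()
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    xyz[~np.all(np.isfinite(xyz), axis=1)] = np.nan  # any bad axis drops the locus
    coords[rows, loci.astype(int)] = xyz
    return coords, cell_ids


def write_cell_coordinates(path: str | Path, coords: np.ndarray, cell_ids=None) -> None:
    """Write an (M, N, 3) coordinate array as a tidy CSV (missing loci omitted)."""
    m, n, _ = coords.shape
    cell_ids = np.arange(m) if cell_ids is None else np.asarray(cell_ids)
    cells, loci = np.nonzero(np.all(np.isfinite(coords), axis=2))
    df = pd.DataFrame(
        {
            "cell_id": cell_ids[cells],
            "locus_index": loci,
            "x": coords[cells, loci, 0],
            "y": coords[cells, loci, 1],
            "z": coords[cells, loci, 2],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dense matrices: TSV and HDF5
# ---------------------------------------------------------------------------

def write_matrix_tsv(path: str | Path, matrix: np.ndarray, comments: list[str] | None = None) -> None:
    header = "\n".join(comments or [])
    np.savetxt(path, np.asarray(matrix), delimiter="\t", header=header, comments="# ")


def read_matrix_tsv(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        first = ""
        for line in fh:
            if not line.startswith("#") and line.strip():
                first = line
                break
    delimiter = "," if ("," in first and "\t" not in first) else None
    return np.atleast_2d(np.loadtxt(path, comments="#", delimiter=delimiter))


def write_matrix_h5(path: str | Path, name: str, matrix: np.ndarray, units: str = "nm^2") -> None:
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        ds = fh.create_dataset(name, data=np.asarray(matrix))
        ds.attrs["units"] = units
        ds.attrs["convention"] = CONVENTION


def read_matrix_h5(path: str | Path, name: str) -> np.ndarray:
    with h5py.File(path, "r") as fh:
        return fh[name][()]


def read_matrix(path: str | Path, name: str = "d2") -> np.ndarray:
    """Dispatch on extension: .h5/.hdf5 → HDF5 dataset, else dense text."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return read_matrix_h5(path, name)
    return read_matrix_tsv(path)


def save_fit_result(path: str | Path, result: FitResult) -> None:
    with h5py.File(path, "w") as fh:
        k = fh.create_dataset("K", data=result.connectivity.matrix)
        k.attrs["units"] = "nm^-2"
        k.attrs["convention"] = CONVENTION
        fh.create_dataset("offdiag", data=result.connectivity.offdiag)
        fh.create_dataset("error_trace", data=result.error_trace)
        fh.attrs["converged"] = result.converged
        fh.attrs["n_iter"] = result.n_iter
        if result.config is not None:
            cfg = {k_: v for k_, v in vars(result.config).items() if not isinstance(v, np.ndarray)}
            fh.attrs["config"] = json.dumps(cfg)


def load_fit_result(path: str | Path) -> FitResult:
    with h5py.File(path, "r") as fh:
        off = fh["offdiag"][()]
        trace = fh["error_trace"][()]
        converged = bool(fh.attrs["converged"])
        n_iter = int(fh.attrs["n_iter"])
        config = None
        if "config" in fh.attrs:
            config = FitConfig(**json.loads(fh.attrs["config"]))
    return FitResult(
        connectivity=ConnectivityMatrix(offdiag=off),
        error_trace=trace,
        converged=converged,
        n_iter=n_iter,
        config=config,
    )


# ---------------------------------------------------------------------------
# ensemble export
# ---------------------------------------------------------------------------

def write_ensemble_h5(path: str | Path, ens: ConformationEnsemble) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("coords", data=ens.coords)
        ds.attrs["units"] = "nm"
        fh.attrs["source"] = ens.source
        if ens.seed is not None:
            fh.attrs["seed"] = ens.seed


def read_ensemble_h5(path: str | Path) -> ConformationEnsemble:
    with h5py.File(path, "r") as fh:
        coords = fh["coords"][()]
        source = str(fh.attrs.get("source", "sampled"))
        seed = int(fh.attrs["seed"]) if "seed" in fh.attrs else None
    return ConformationEnsemble(coords=coords, seed=seed, source=source)


def write_ensemble_pdb(path: str | Path, ens: ConformationEnsemble) -> None:
    """Multi-model PDB, one MODEL per conformation, loci as CA pseudo-atoms (Å)."""
    with open(path, "w") as fh:
        for m in range(ens.n_conformations):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for i, (x, y, z) in enumerate(ens.coords[m] * 10.0):  # nm → Å
                if not np.isfinite(x):
                    continue
                fh.write(
                    f"ATOM  {i + 1:5d}  CA  GLY A{(i + 1) % 10000:4d}    "
                    f"{x:8.2f}{y:8.2f}{z:8.2f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_ensemble_xyz(path: str | Path, ens: ConformationEnsemble) -> None:
    """Concatenated XYZ frames (nm) for lightweight viewers."""
    with open(path, "w") as fh:
        n = ens.n_loci
        for m in range(ens.n_conformations):
            fh.write(f"{n}\nconformation {m}\n")
            for x, y, z in ens.coords[m]:
                fh.write(f"C {x:.4f} {y:.4f} {z:.4f}\n")
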