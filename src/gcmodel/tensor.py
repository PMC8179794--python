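"""Tensor and matrix factorization of multiway cytokine-response data.

Dose-response predictions or measurements are arranged as a labeled
non-negative array over time x cell type x ligand condition (optionally with
separate ligand and concentration axes).  Before decomposition the tensor is
variance-scaled across each cell population so that no cell type dominates
by virtue of its absolute signal.  Non-negative canonical polyadic (CP)
decomposition expresses the tensor as a sum of rank-1 outer products, one
non-negative factor matrix per mode; non-negative Tucker decomposition
relaxes CP with a core tensor of interaction weights.  Reconstruction
quality is reported as R2X, the fraction of the tensor's squared Frobenius
norm captured.

The alternating-least-squares solvers here are exact per-block (each factor
update is a non-negative least-squares solve), so the objective is
monotone non-increasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import nnls

__all__ = [
    "CPFactors",
    "TuckerFactors",
    "PCAResult",
    "variance_scale",
    "r2x",
    "nncp",
    "ntucker",
    "pca_receptors",
    "factor_similarity",
]


def _as_dataarray(tensor) -> xr.DataArray:
    if isinstance(tensor, xr.DataArray):
        return tensor
    arr = np.asarray(tensor, dtype=float)
    return xr.DataArray(arr, dims=[f"mode{k}" for k in range(arr.ndim)])


def variance_scale(tensor, mode: str = "cell") -> xr.DataArray:
    """Divide each slice along ``mode`` by the standard deviation of its entries."""
    da = _as_dataarray(tensor)
    if mode not in da.dims:
        raise ValueError(f"mode {mode!r} not among tensor dims {da.dims}")
    sd = da.std(dim=[d for d in da.dims if d != mode])
    bad = np.asarray(sd.values <= 0).nonzero()[0]
    if bad.size:
        names = [str(da.coords[mode].values[b]) if mode in da.coords else str(b) for b in bad]
        raise ValueError(f"zero-variance slice(s) along {mode!r}: {', '.join(names)}")
    return da / sd


def r2x(tensor, reconstruction) -> float:
    """1 - ||T - That||_F^2 / ||T||_F^2."""
    t = np.asarray(getattr(tensor, "values", tensor), dtype=float)
    that = np.asarray(getattr(reconstruction, "values", reconstruction), dtype=float)
    if t.shape != that.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {that.shape}")
    denom = np.linalg.norm(t) ** 2
    if denom == 0:
        raise ValueError("cannot compute R2X of an all-zero tensor")
    return 1.0 - np.linalg.norm(t - that) ** 2 / denom


def _unfold(t: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


def _khatri_rao(mats) -> np.ndarray:
    """Column-wise Khatri-Rao product of a list of matrices."""
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, None, :] * m[None, :, :]).reshape(-1, out.shape[1])
    return out


def _cp_reconstruct(factors) -> np.ndarray:
    rank = factors[0].shape[1]
    shape = tuple(f.shape[0] for f in factors)
    out = np.zeros(shape)
    for r in range(rank):
        comp = factors[0][:, r]
        for f in factors[1:]:
            comp = np.multiply.outer(comp, f[:, r])
        out += comp
    return out


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x - b||, x >= 0 for every column b of B; returns (ncols, k)."""
    X = np.empty((B.shape[1], A.shape[1]))
    for j in range(B.shape[1]):
        X[j], _ = nnls(A, B[:, j])
    return X


@dataclass
class CPFactors:
    """Non-negative CP decomposition result."""

    rank: int
    factors: list                 # one (dim, rank) array per mode
    mode_labels: list             # axis coordinate labels per mode
    dims: tuple
    r2x: float
    seed: int
    n_restarts: int
    n_iter: int = 0

    def reconstruct(self) -> np.ndarray:
        return _cp_reconstruct(self.factors)

    def factor_frames(self):
        """One tidy DataFrame per mode with component columns."""
        frames = []
        for dim, labels, f in zip(self.dims, self.mode_labels, self.factors):
            df = pd.DataFrame(f, columns=[f"component_{r + 1}" for r in range(self.rank)])
            df.insert(0, dim, labels)
            frames.append(df)
        return frames


@dataclass
class TuckerFactors:
    """Non-negative Tucker decomposition result."""

    ranks: tuple
    core: np.ndarray
    factors: list
    mode_labels: list
    dims: tuple
    r2x: float
    seed: int

    def reconstruct(self) -> np.ndarray:
        out = self.core
        for mode, f in enumerate(self.factors):
            out = np.moveaxis(np.tensordot(f, out, axes=(1, mode)), 0, mode)
        return out


def _nncp_single(t: np.ndarray, rank: int, rng, tol: float, max_iter: int,
                 factors0=None):
    scale = (t.mean() / max(rank, 1)) ** (1.0 / t.ndim) if t.mean() > 0 else 1.0
    if factors0 is None:
        factors = [rng.uniform(0.1, 1.0, size=(d, rank)) * scale for d in t.shape]
    else:
        factors = [f.copy() for f in factors0]
    unfolds = [_unfold(t, m) for m in range(t.ndim)]
    norm2 = np.linalg.norm(t) ** 2
    prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for m in range(t.ndim):
            others = [factors[k] for k in range(t.ndim) if k != m][::-1]
            kr = _khatri_rao(others[::-1])   # matches unfolding column order
            factors[m] = _nnls_rows(kr, unfolds[m].T)
        err = np.linalg.norm(t - _cp_reconstruct(factors)) ** 2 / norm2
        if prev - err < tol * max(prev, 1e-300):
            prev = err
            break
        prev = err
    return factors, 1.0 - prev, it


def nncp(tensor, rank: int, seed: int = 0, restarts: int = 5, tol: float = 1e-7,
         max_iter: int = 10_000) -> CPFactors:
    """Best-of-restarts non-negative CP decomposition.

    Alternating exact non-negative least squares over the modes, with
    ``restarts`` seeded random initializations; the best final fit is kept.
    """
    da = _as_dataarray(tensor)
    t = np.asarray(da.values, dtype=float)
    if np.any(t < 0):
        raise ValueError("tensor must be non-negative")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if any(rank > d for d in t.shape):
        raise ValueError(f"rank {rank} exceeds a mode dimension of shape {t.shape}")

    best = None
    root = np.random.default_rng(seed)
    for _ in range(restarts):
        rng = np.random.default_rng(root.integers(2**31))
        factors, fit, it = _nncp_single(t, rank, rng, tol, max_iter)
        if best is None or fit > best[1]:
            best = (factors, fit, it)

    labels = [
        list(da.coords[d].values) if d in da.coords else list(range(s))
        for d, s in zip(da.dims, t.shape)
    ]
    return CPFactors(rank=rank, factors=best[0], mode_labels=labels,
                     dims=tuple(str(d) for d in da.dims), r2x=best[1],
                     seed=seed, n_restarts=restarts, n_iter=best[2])


def ntucker(tensor, ranks, seed: int = 0, tol: float = 1e-7,
            max_iter: int = 500) -> TuckerFactors:
    """Non-negative Tucker decomposition (ALS with exact NNLS blocks).

    When all mode ranks are equal the solver is warm-started from the
    rank-matched CP solution (superdiagonal core), so its fit is at least as
    good as CP's at the same rank.
    """
    da = _as_dataarray(tensor)
    t = np.asarray(da.values, dtype=float)
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != t.ndim or any(r < 1 or r > d for r, d in zip(ranks, t.shape)):
        raise ValueError(f"invalid Tucker ranks {ranks} for shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("tensor must be non-negative")

    # warm start from the CP solution at the common rank, padding extra
    # columns with small random entries; the starting fit is then at least
    # CP's, and each exact-NNLS block update is monotone.
    rng = np.random.default_rng(seed)
    r0 = min(ranks)
    cp = nncp(da, r0, seed=seed, restarts=3)
    scale = max(float(t.mean()), 1e-6)
    factors = []
    for m, r in enumerate(ranks):
        f = cp.factors[m]
        if r > r0:
            f = np.hstack([f, 1e-3 * scale * rng.uniform(size=(t.shape[m], r - r0))])
        factors.append(f)
    core = np.zeros(ranks)
    core[tuple(np.arange(r0) for _ in ranks)] = 1.0

    norm2 = np.linalg.norm(t) ** 2
    prev = np.linalg.norm(t - TuckerFactors(ranks, core, factors, [], (), 0.0, seed).reconstruct()) ** 2 / norm2
    for _ in range(max_iter):
        for m in range(t.ndim):
            # unfold the core-times-other-factors operator along mode m
            g = core
            for k in range(t.ndim):
                if k == m:
                    continue
                g = np.moveaxis(np.tensordot(factors[k], g, axes=(1, k)), 0, k)
            A = _unfold(g, m).T                      # (prod other dims, rank_m)
            factors[m] = _nnls_rows(A, _unfold(t, m).T)
        # core update: vec(T) ~ (kron of factors) vec(G), non-negative
        K = factors[0]
        for f in factors[1:]:
            K = np.kron(K, f)
        core = _nnls_rows(K, t.reshape(-1, 1))[0].reshape(ranks)
        err = np.linalg.norm(t - TuckerFactors(ranks, core, factors, [], (), 0.0, seed).reconstruct()) ** 2 / norm2
        if prev - err < tol * max(prev, 1e-300):
            prev = err
            break
        prev = err

    labels = [
        list(da.coords[d].values) if d in da.coords else list(range(s))
        for d, s in zip(da.dims, t.shape)
    ]
    return TuckerFactors(ranks=ranks, core=core, factors=factors, mode_labels=labels,
                         dims=tuple(str(d) for d in da.dims), r2x=1.0 - prev, seed=seed)


@dataclass
class PCAResult:
    scores: pd.DataFrame          # cells x components
    loadings: pd.DataFrame        # receptors x components (orthonormal columns)
    explained: np.ndarray         # variance fractions, non-increasing


def pca_receptors(matrix) -> PCAResult:
    """PCA of a cells x receptors abundance matrix.

    Receptor counts span decades, so entries are log10(1 + count) transformed
    and centered per receptor before the eigendecomposition.
    """
    df = pd.DataFrame(matrix)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 receptors")
    x = np.log10(1.0 + df.to_numpy(dtype=float))
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0):
        raise ValueError("constant matrix has no principal components")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    comps = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=df.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=df.columns, columns=comps),
        explained=var / var.sum(),
    )


def factor_similarity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cosine similarity of greedily best-matched factor columns.

    Components are paired by repeatedly taking the highest-cosine unmatched
    (column of a, column of b) pair; returns the cosine per matched pair of
    ``a``'s columns, in ``a``'s column order.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("factor matrices must share their dimension length")
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero factor column")
    cos = (a / na).T @ (b / nb)
    out = np.full(a.shape[1], np.nan)
    free_a = set(range(a.shape[1]))
    free_b = set(range(b.shape[1]))
    while free_a and free_b:
        i, j = max(((i, j) for i in free_a for j in free_b), key=lambda ij: cos[ij])
        out[i] = cos[i, j]
        free_a.discard(i)
        free_b.discard(j)
    return out
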