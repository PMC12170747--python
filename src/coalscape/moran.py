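"""Global and local Moran's I with permutation inference and LISA labels.

Global Moran's I over n spatial units with weights w_ij:

    I = n * ΣΣ w_ij (x_i - x̄)(x_j - x̄) / (S0 * Σ (x_i - x̄)²),  S0 = ΣΣ w_ij

with expectation -1/(n-1) under the randomization null.  Local Moran's I_i
uses σ² = Σ(x_i - x̄)²/n:

    I_i = ((x_i - x̄) / σ²) * Σ_j w_ij (x_j - x̄)

Inference follows the GeoDA convention: 999 random permutations by default,
two-sided pseudo p-values; local p-values use conditional permutation (unit
i held fixed, the remaining values permuted among its neighbors).  LISA
cluster labels (HH/LL/HL/LH) are assigned only to units significant at α.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = [
    "SpatialWeights",
    "GlobalMoranResult",
    "LocalMoranResult",
    "DegenerateInputError",
    "build_queen_weights",
    "global_moran",
    "local_moran",
    "lisa_classify",
]


class DegenerateInputError(ValueError):
    """Zero-variance attribute vector: Moran statistics are undefined."""


@dataclass
class SpatialWeights:
    """Sparse neighbor structure with optional row standardization."""

    neighbors: list[np.ndarray]  # neighbor indices per unit
    weights: list[np.ndarray]  # matching weights per unit
    row_standardized: bool = True

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def islands(self) -> list[int]:
        return [i for i, nb in enumerate(self.neighbors) if len(nb) == 0]

    def to_sparse(self) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            rows.extend([i] * len(nb))
            cols.extend(nb.tolist())
            vals.extend(w.tolist())
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))


def build_queen_weights(cells: np.ndarray, row_standardize: bool = True) -> SpatialWeights:
    """Queen contiguity on a (possibly holey) regular lattice.

    ``cells`` is an (n, 2) array of integer (row, col) lattice positions; the
    i-th output row corresponds to the i-th input cell.  Neighbors are the
    up-to-8 surrounding lattice cells that exist.  Isolated units keep an
    empty (zero-weight) row.
    """
    cells = np.asarray(cells, dtype=int)
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(cells)}
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    neighbors, weights = [], []
    for r, c in cells:
        nb = [index[(r + dr, c + dc)] for dr, dc in offsets if (r + dr, c + dc) in index]
        nb = np.asarray(sorted(nb), dtype=int)
        if row_standardize and len(nb):
            w = np.full(len(nb), 1.0 / len(nb))
        else:
            w = np.ones(len(nb))
        neighbors.append(nb)
        weights.append(w)
    return SpatialWeights(neighbors, weights, row_standardized=row_standardize)


def build_rook_weights(cells: np.ndarray, row_standardize: bool = True) -> SpatialWeights:
    """Rook contiguity on a regular lattice (edge-sharing neighbors only)."""
    cells = np.asarray(cells, dtype=int)
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(cells)}
    offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    neighbors, weights = [], []
    for r, c in cells:
        nb = [index[(r + dr, c + dc)] for dr, dc in offsets if (r + dr, c + dc) in index]
        nb = np.asarray(sorted(nb), dtype=int)
        w = np.full(len(nb), 1.0 / len(nb)) if (row_standardize and len(nb)) else np.ones(len(nb))
        neighbors.append(nb)
        weights.append(w)
    return SpatialWeights(neighbors, weights, row_standardized=row_standardize)


@dataclass
class GlobalMoranResult:
    I: float
    expected: float
    z_score: float  # from permutation moments
    p_perm: float
    z_analytic: float
    n_perm: int


@dataclass
class LocalMoranResult:
    I_local: np.ndarray
    p_perm: np.ndarray
    labels: np.ndarray  # HH / LL / HL / LH / ns
    alpha: float


def _check_x(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 units")
    if np.ptp(x) == 0:
        raise DegenerateInputError("attribute vector has zero variance")
    return x


def _moran_stat(z: np.ndarray, w: sparse.csr_matrix, s0: float) -> float:
    num = float(z @ (w @ z))
    den = float(z @ z)
    return len(z) * num / (s0 * den)


def global_moran(
    x: np.ndarray, W: SpatialWeights, n_perm: int = 999, seed: int = 0
) -> GlobalMoranResult:
    """Global Moran's I with two-sided permutation inference.

    The pseudo p-value counts permuted statistics at least as far from the
    null expectation -1/(n-1) as the observed one; the z-score uses the
    permutation mean and standard deviation.  An analytic z-score under the
    randomization-null variance is reported alongside.
    """
    x = _check_x(x)
    n = x.size
    w = W.to_sparse()
    s0 = float(w.sum())
    z = x - x.mean()
    i_obs = _moran_stat(z, w, s0)
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    sims = np.empty(n_perm)
    for b in range(n_perm):
        sims[b] = _moran_stat(rng.permutation(z), w, s0)
    extreme = int(np.sum(np.abs(sims - expected) >= np.abs(i_obs - expected)))
    p_perm = (1 + extreme) / (n_perm + 1)
    sd = sims.std(ddof=0)
    z_score = (i_obs - sims.mean()) / sd if sd > 0 else np.nan
    return GlobalMoranResult(
        I=i_obs,
        expected=expected,
        z_score=float(z_score),
        p_perm=float(p_perm),
        z_analytic=_analytic_z(z, w, i_obs, expected),
        n_perm=n_perm,
    )


def _analytic_z(z: np.ndarray, w: sparse.csr_matrix, i_obs: float, e_i: float) -> float:
    # Classical randomization-null variance (Cliff & Ord).
    n = z.size
    s0 = float(w.sum())
    wt = w + w.T
    s1 = 0.5 * float(wt.multiply(wt).sum())
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(((row + col) ** 2).sum())
    m2 = float((z**2).sum()) / n
    m4 = float((z**4).sum()) / n
    b2 = m4 / m2**2
    a = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
    c = b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    var = (a - c) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    return float((i_obs - e_i) / np.sqrt(var)) if var > 0 else np.nan


def local_moran(
    x: np.ndarray, W: SpatialWeights, n_perm: int = 999, seed: int = 0
) -> LocalMoranResult:
    """Local Moran's I_i with conditional-permutation pseudo p-values."""
    x = _check_x(x)
    n = x.size
    z = x - x.mean()
    sigma2 = float((z**2).sum()) / n
    lag = np.array([float(w @ z[nb]) if len(nb) else 0.0 for nb, w in zip(W.neighbors, W.weights)])
    i_local = (z / sigma2) * lag

    rng = np.random.default_rng(seed)
    p = np.ones(n)
    for i in range(n):
        nb = W.neighbors[i]
        k = len(nb)
        if k == 0:
            continue
        others = np.delete(z, i)
        # draw k neighbor values per permutation from the n-1 other units
        picks = rng.random((n_perm, others.size)).argsort(axis=1)[:, :k]
        sims = (others[picks] * W.weights[i]).sum(axis=1) * (z[i] / sigma2)
        center = sims.mean()
        extreme = int(np.sum(np.abs(sims - center) >= np.abs(i_local[i] - center)))
        p[i] = (1 + extreme) / (n_perm + 1)
    labels = lisa_classify(x, i_local, p)
    return LocalMoranResult(I_local=i_local, p_perm=p, labels=labels, alpha=0.05)


def lisa_classify(
    x: np.ndarray, i_local: np.ndarray, p: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """HH / LL / HL / LH labels for significant units, 'ns' otherwise.

    The quadrant follows the sign of the own deviation and of the spatial
    lag deviation (whose sign equals sign(I_i)/sign(x_i - x̄)).
    """
    x = np.asarray(x, dtype=float)
    z = x - x.mean()
    labels = np.full(x.size, "ns", dtype=object)
    sig = np.asarray(p) <= alpha
    for i in np.flatnonzero(sig):
        if z[i] == 0 or i_local[i] == 0:
            continue
        high_own = z[i] > 0
        high_lag = (i_local[i] > 0) == high_own
        labels[i] = ("H" if high_own else "L") + ("H" if high_lag else "L")
    return labels.astype(str)
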