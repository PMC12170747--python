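"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: patch
delineation is a hand-written flood fill, contiguity/adjacency counts are
explicit neighbor loops, and Moran's I is an exhaustive double sum.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from coalscape.raster import LandCoverRaster, Raster


def make_lc(values, cell_size=30.0, origin=None, year=2000, nodata=255) -> LandCoverRaster:
    values = np.asarray(values)
    if origin is None:
        origin = (0.0, values.shape[0] * cell_size)
    return LandCoverRaster(values, cell_size, origin, year, nodata)


@pytest.fixture
def lc_factory():
    return make_lc


# ---------------------------------------------------------------------------
# brute-force landscape-metric oracles
# ---------------------------------------------------------------------------


def flood_fill_patches(values: np.ndarray, nodata, connectivity: int = 8):
    """Patch labels by explicit stack-based flood fill; labels from 1."""
    nrow, ncol = values.shape
    labels = np.zeros((nrow, ncol), dtype=int)
    if connectivity == 8:
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    nxt = 1
    for r0 in range(nrow):
        for c0 in range(ncol):
            if values[r0, c0] == nodata or labels[r0, c0]:
                continue
            stack = [(r0, c0)]
            labels[r0, c0] = nxt
            while stack:
                r, c = stack.pop()
                for dr, dc in offs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrow and 0 <= cc < ncol and not labels[rr, cc]:
                        if values[rr, cc] == values[r0, c0]:
                            labels[rr, cc] = nxt
                            stack.append((rr, cc))
            nxt += 1
    return labels, nxt - 1


def contig_oracle(mask: np.ndarray) -> float:
    """Contiguity of one patch by explicit per-cell neighbor sums."""
    cells = list(zip(*np.nonzero(mask)))
    a = len(cells)
    if a == 1:
        return 0.0
    cellset = set(cells)
    total = 0.0
    for r, c in cells:
        val = 1.0
        for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
            if (r + dr, c + dc) in cellset:
                val += 2.0
        for dr, dc in [(-1, -1), (-1, 1), (1, -1), (1, 1)]:
            if (r + dr, c + dc) in cellset:
                val += 1.0
        total += val
    return (total / a - 1.0) / 12.0


def metrics_oracle(values: np.ndarray, nodata) -> dict:
    """NP / CONTIG_MN / SHDI / AI by direct enumeration."""
    labels, n_patches = flood_fill_patches(values, nodata, connectivity=8)
    contigs = [contig_oracle(labels == i) for i in range(1, n_patches + 1)]
    valid = values != nodata
    total = int(valid.sum())
    codes, counts = np.unique(values[valid], return_counts=True)
    shdi = -sum((c / total) * math.log(c / total) for c in counts)
    ai = 0.0
    nrow, ncol = values.shape
    for code, area in zip(codes, counts):
        gii = 0
        for r in range(nrow):
            for c in range(ncol):
                if values[r, c] != code:
                    continue
                if c + 1 < ncol and values[r, c + 1] == code:
                    gii += 1
                if r + 1 < nrow and values[r + 1, c] == code:
                    gii += 1
        n = int(math.isqrt(int(area)))
        m = int(area) - n * n
        if m == 0:
            gmax = 2 * n * (n - 1)
        elif m <= n:
            gmax = 2 * n * (n - 1) + 2 * m - 1
        else:
            gmax = 2 * n * (n - 1) + 2 * m - 2
        if gmax > 0:
            ai += (gii / gmax) * (area / total)
    return {
        "NP": n_patches,
        "CONTIG_MN": float(np.mean(contigs)) if contigs else 0.0,
        "SHDI": shdi,
        "AI": 100.0 * ai,
    }


# ---------------------------------------------------------------------------
# Moran's I oracle
# ---------------------------------------------------------------------------


def moran_double_sum(x: np.ndarray, w_dense: np.ndarray) -> float:
    """Global Moran's I by the explicit double sum over all (i, j) pairs."""
    n = len(x)
    z = x - x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w_dense[i, j] * z[i] * z[j]
    return n * num / (w_dense.sum() * (z**2).sum())


def local_moran_oracle(x: np.ndarray, w_dense: np.ndarray) -> np.ndarray:
    n = len(x)
    z = x - x.mean()
    sigma2 = (z**2).sum() / n
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j != i:
                s += w_dense[i, j] * z[j]
        out[i] = z[i] / sigma2 * s
    return out


def ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form OLS (normal equations via lstsq); the global-limit oracle."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta
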