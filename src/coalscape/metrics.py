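"""Landscape-level pattern metrics on categorical raster windows.

Implements the four landscape-level metrics used throughout the pipeline —
number of patches (NP), mean contiguity index (CONTIG_MN), Shannon's
diversity index (SHDI) and the aggregation index (AI) — with FRAGSTATS
semantics: 8-neighbor patch delineation, the 3×3 contiguity template with
template sum v = 13, and like-adjacency AI counted once per rook pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PatchTable",
    "MetricVector",
    "UndefinedMetricsError",
    "label_patches",
    "patch_contig",
    "cell_metrics",
    "vif_screen",
]

_STRUCT_8 = np.ones((3, 3), dtype=int)
_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)

# 3×3 contiguity template: center 1, orthogonal neighbors 2, diagonals 1.
_CONTIG_TEMPLATE = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]], dtype=float)
_CONTIG_V = 13.0


class UndefinedMetricsError(ValueError):
    """Raised when a window has no valid cells to compute metrics on."""


@dataclass
class PatchTable:
    """Patch-level table: one row per connected same-class region."""

    table: pd.DataFrame  # columns: patch_id, class_code, area, contig

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MetricVector:
    NP: int
    CONTIG_MN: float
    SHDI: float
    AI: float

    def as_dict(self) -> dict[str, float]:
        return {"NP": self.NP, "CONTIG_MN": self.CONTIG_MN, "SHDI": self.SHDI, "AI": self.AI}


def label_patches(window, connectivity: int = 8) -> tuple[PatchTable, np.ndarray]:
    """Delineate patches (connected same-class regions) in a window.

    Returns a :class:`PatchTable` and a label grid with labels contiguous
    from 1; nodata cells are labeled 0.  An all-nodata window yields an
    empty table, not an error.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    values = window.values
    valid = window.valid_mask()
    labels = np.zeros(values.shape, dtype=np.int32)
    rows = []
    next_label = 1
    for code in np.unique(values[valid]):
        mask = (values == code) & valid
        lab, n = ndimage.label(mask, structure=struct)
        for i in range(1, n + 1):
            patch = lab == i
            labels[patch] = next_label
            rows.append(
                {
                    "patch_id": next_label,
                    "class_code": int(code),
                    "area": int(patch.sum()),
                    "contig": _contig_of_mask(patch),
                }
            )
            next_label += 1
    cols = ["patch_id", "class_code", "area", "contig"]
    table = pd.DataFrame(rows, columns=cols)
    return PatchTable(table), labels


def _contig_of_mask(mask: np.ndarray) -> float:
    """CONTIG = [(Σ_r c_r / a) − 1] / (v − 1) over a single patch mask."""
    a = mask.sum()
    if a == 1:
        return 0.0
    m = mask.astype(float)
    c = ndimage.correlate(m, _CONTIG_TEMPLATE, mode="constant", cval=0.0)
    total = float(c[mask].sum())
    return (total / a - 1.0) / (_CONTIG_V - 1.0)


def patch_contig(labels: np.ndarray, patch_id: int) -> float:
    """Contiguity index of one patch in a label grid, in [0, 1]."""
    mask = labels == patch_id
    if not mask.any():
        raise KeyError(f"patch_id {patch_id} not present in label grid")
    return _contig_of_mask(mask)


def _max_like_adjacencies(area: int) -> int:
    """Largest possible rook like-adjacency count for a class of given area."""
    n = int(np.floor(np.sqrt(area)))
    m = area - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def cell_metrics(window, connectivity: int = 8) -> MetricVector:
    """NP, CONTIG_MN, SHDI, and AI for one raster window.

    SHDI uses natural logs over class proportions of the valid area; AI is
    the area-weighted percentage of realized like-adjacencies, with
    single-cell classes contributing zero.
    """
    valid = window.valid_mask()
    total = int(valid.sum())
    if total == 0:
        raise UndefinedMetricsError("window has no valid cells")
    patches, _ = label_patches(window, connectivity)
    np_count = len(patches)
    contig_mn = float(patches.table["contig"].mean()) if np_count else 0.0

    values = window.values
    codes, counts = np.unique(values[valid], return_counts=True)
    p = counts / total
    shdi = float(-(p * np.log(p)).sum())

    ai = 0.0
    for code, area, pi in zip(codes, counts, p):
        gmax = _max_like_adjacencies(int(area))
        if gmax == 0:
            continue
        mask = (values == code) & valid
        gii = int((mask[:, :-1] & mask[:, 1:]).sum() + (mask[:-1, :] & mask[1:, :]).sum())
        ai += (gii / gmax) * pi
    return MetricVector(NP=np_count, CONTIG_MN=contig_mn, SHDI=shdi, AI=100.0 * ai)


def vif_screen(features: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Variance inflation factor per column, flagging VIF ≥ threshold.

    VIF_k = 1 / (1 − R²_k) from an OLS (with intercept) of column k on the
    remaining columns.  A perfectly collinear column reports ``inf`` and is
    flagged rather than raising.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least two feature columns")
    if features.shape[0] <= features.shape[1]:
        raise ValueError("need more rows than columns")
    x = features.to_numpy(dtype=float)
    n, k = x.shape
    rows = []
    for j in range(k):
        yj = x[:, j]
        others = np.delete(x, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ beta
        tss = float(((yj - yj.mean()) ** 2).sum())
        rss = float((resid**2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"variable": features.columns[j], "vif": vif, "flagged": bool(vif >= threshold)})
    return pd.DataFrame(rows).set_index("variable")
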