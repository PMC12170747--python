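"""Raster containers, land-cover bookkeeping, and minimal GeoTIFF / GeoJSON I/O.

Conventions: projected coordinates in meters, grid origin at the upper-left
corner, row index increasing southward.  All geometric predicates use
cell-center semantics, so a cell belongs to a polygon iff its center does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

__all__ = [
    "Raster",
    "LandCoverRaster",
    "TransitionMatrix",
    "GridMismatchError",
    "UnmappedCodeError",
    "reclassify",
    "class_areas",
    "transition_matrix",
    "rasterize_geometries",
    "cell_centers",
    "read_geotiff",
    "write_geotiff",
    "read_geojson",
    "write_geojson",
]


class GridMismatchError(ValueError):
    """Two rasters do not share shape, cell size, and origin."""


class UnmappedCodeError(KeyError):
    """A class code present in the raster is missing from a reclass table."""


@dataclass
class Raster:
    """A single-band grid in a projected coordinate system.

    Parameters
    ----------
    values : ndarray
        2-D array of cell values (integer class codes or floats).
    cell_size : float
        Cell edge length in meters; cells are square.
    origin : tuple of float
        (x, y) of the grid's upper-left corner in meters.
    year : int
        Epoch label attached to the band.
    nodata : int or float
        Reserved value marking cells outside the valid domain.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    year: int = 0
    nodata: float = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        if np.issubdtype(self.values.dtype, np.floating):
            mask = ~np.isnan(self.values)
            if not np.isnan(self.nodata):
                mask &= self.values != self.nodata
            return mask
        return self.values != self.nodata

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def copy_with(self, values: np.ndarray, **kw) -> "Raster":
        return replace(self, values=values, **kw)


class LandCoverRaster(Raster):
    """Categorical land-cover grid; values are integer class codes."""

    def class_codes(self) -> np.ndarray:
        vals = self.values[self.valid_mask()]
        return np.unique(vals)


@dataclass
class TransitionMatrix:
    """Square area-transfer table between two epochs, in km².

    ``areas[i, j]`` is the area classed ``labels[i]`` in the first epoch and
    ``labels[j]`` in the second.  Cells that are nodata in either epoch are
    excluded, so row sums equal the first epoch's per-class areas restricted
    to the jointly valid domain.
    """

    labels: list
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        k = len(self.labels)
        if self.areas.shape != (k, k):
            raise ValueError("areas must be square over labels")
        if (self.areas < 0).any():
            raise ValueError("transition areas must be non-negative")

    @property
    def total(self) -> float:
        return float(self.areas.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.areas, index=self.labels, columns=self.labels)


def _require_same_grid(a: Raster, b: Raster) -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            f"grids differ: shape {a.shape} vs {b.shape}, "
            f"cell {a.cell_size} vs {b.cell_size}, origin {a.origin} vs {b.origin}"
        )


def reclassify(raster: LandCoverRaster, mapping: Mapping[int, int]) -> LandCoverRaster:
    """Map every class code through a reclass table.

    Nodata maps to nodata implicitly.  Any valid code absent from the table
    raises :class:`UnmappedCodeError` naming the offending code.
    """
    present = set(int(c) for c in raster.class_codes())
    missing = sorted(present - set(int(k) for k in mapping))
    if missing:
        raise UnmappedCodeError(f"codes {missing} present in raster but not in mapping")
    out = np.full_like(raster.values, raster.nodata)
    valid = raster.valid_mask()
    lut = {int(k): int(v) for k, v in mapping.items()}
    vals = raster.values
    for code in present:
        out[(vals == code) & valid] = lut[code]
    return raster.copy_with(out)


def class_areas(raster: LandCoverRaster) -> pd.Series:
    """Per-class area in km² (cell count × cell_size² / 10⁶); nodata excluded."""
    vals = raster.values[raster.valid_mask()]
    codes, counts = np.unique(vals, return_counts=True)
    km2 = counts * raster.cell_size**2 / 1e6
    return pd.Series(km2, index=[int(c) for c in codes], name="area_km2")


def transition_matrix(a: Raster, b: Raster, labels: Sequence | None = None) -> TransitionMatrix:
    """Cross-tabulate two co-registered categorical rasters into km² transfers."""
    _require_same_grid(a, b)
    valid = a.valid_mask() & b.valid_mask()
    va, vb = a.values[valid], b.values[valid]
    if labels is None:
        labels = sorted(set(np.unique(va)) | set(np.unique(vb)))
    labels = list(labels)
    index = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    ia = np.fromiter((index[c] for c in va), count=va.size, dtype=np.int64)
    ib = np.fromiter((index[c] for c in vb), count=vb.size, dtype=np.int64)
    np.add.at(counts, (ia, ib), 1)
    areas = counts * a.cell_size**2 / 1e6
    return TransitionMatrix(labels=labels, areas=areas)


def cell_centers(raster: Raster) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) coordinates of every cell center, each shaped like the grid."""
    nrow, ncol = raster.shape
    ox, oy = raster.origin
    cs = raster.cell_size
    xs = ox + (np.arange(ncol) + 0.5) * cs
    ys = oy - (np.arange(nrow) + 0.5) * cs
    return np.meshgrid(xs, ys)


def rasterize_geometries(geoms: Iterable, template: Raster) -> Raster:
    """Burn polygons/polylines into a binary raster on the template grid.

    A cell is 1 iff its center lies inside a polygon or within half a cell of
    a polyline.  An empty geometry iterable yields an all-zero raster.
    """
    if template.values.size == 0:
        raise ValueError("empty template raster")
    xx, yy = cell_centers(template)
    out = np.zeros(template.shape, dtype=np.uint8)
    half = template.cell_size / 2.0
    pts = None
    for geom in geoms:
        if geom is None or geom.is_empty:
            continue
        gtype = geom.geom_type
        if gtype in ("Polygon", "MultiPolygon"):
            hit = shapely.contains_xy(geom, xx.ravel(), yy.ravel())
            out |= hit.reshape(template.shape).astype(np.uint8)
        elif gtype in ("LineString", "MultiLineString"):
            if pts is None:
                pts = shapely.points(np.column_stack([xx.ravel(), yy.ravel()]))
            hit = shapely.dwithin(pts, geom, half)
            out |= hit.reshape(template.shape).astype(np.uint8)
        elif gtype == "GeometryCollection":
            sub = rasterize_geometries(list(geom.geoms), template)
            out |= sub.values.astype(np.uint8)
        else:
            raise ValueError(f"unsupported geometry type: {gtype}")
    return Raster(out, template.cell_size, template.origin, template.year, nodata=255)


# ---------------------------------------------------------------------------
# GeoTIFF I/O (single band, integer or float, georeferencing via GeoTIFF tags)
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(path: str | Path, raster: Raster) -> None:
    """Write a single-band GeoTIFF with pixel scale, tiepoint, and nodata tags."""
    cs = float(raster.cell_size)
    ox, oy = (float(v) for v in raster.origin)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(raster.nodata)),
    ]
    desc = json.dumps({"year": int(raster.year)})
    tifffile.imwrite(path, raster.values, extratags=extratags, description=desc)


def read_geotiff(path: str | Path, categorical: bool = True) -> Raster:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or similar)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        cs = 30.0
        origin = (0.0, 0.0)
        nodata: float = -1
        year = 0
        if _TAG_PIXEL_SCALE in tags:
            cs = float(tags[_TAG_PIXEL_SCALE].value[0])
        if _TAG_TIEPOINT in tags:
            tp = tags[_TAG_TIEPOINT].value
            origin = (float(tp[3]), float(tp[4]))
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            nodata = float(raw) if "." in str(raw) or "nan" in str(raw) else int(raw)
        if page.description:
            try:
                year = int(json.loads(page.description).get("year", 0))
            except (ValueError, json.JSONDecodeError):
                year = 0
    cls = LandCoverRaster if categorical else Raster
    return cls(values, cs, origin, year, nodata)


def write_geojson(path: str | Path, named_geoms: Mapping[str, Sequence]) -> None:
    """Write a FeatureCollection; each feature carries a ``kind`` property."""
    features = []
    for kind, geoms in named_geoms.items():
        for geom in geoms:
            features.append(
                {"type": "Feature", "properties": {"kind": kind}, "geometry": geom_mapping(geom)}
            )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_geojson(path: str | Path) -> dict[str, list]:
    """Read a FeatureCollection back into kind → list-of-shapely-geometries."""
    data = json.loads(Path(path).read_text())
    out: dict[str, list] = {}
    for feat in data["features"]:
        kind = feat.get("properties", {}).get("kind", "geometry")
        out.setdefault(kind, []).append(geom_shape(feat["geometry"]))
    return out
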