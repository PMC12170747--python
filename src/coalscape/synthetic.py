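"""Synthetic study systems with known ground truth.

Three generators emulate the inputs of a coal resource-exhausted city
analysis so that every downstream stage is testable without any download:

* :func:`generate_landcover_series` — a five-epoch categorical land-cover
  panel (cropland matrix, woodland/grassland hill blobs from a smoothed
  Gaussian random field, a river corridor, multi-center impervious growth,
  and fragmented mine-subsidence wetlands that consolidate into lakes over
  time);
* :func:`generate_threat_geometries` — mine industrial squares (polygons)
  and two railway classes (polylines);
* :func:`generate_regression_panel` — space-time observations
  y = β₀(u,v,t) + Σ β_k(u,v,t)·x_k + ε with analytically known coefficient
  surfaces, for exercising the varying-coefficient regressions.

Everything is deterministic for a fixed seed.  The land-cover generator
aims at structural realism (clustered hills, corridors, multicentric urban
form), not at matching any real region's statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Polygon, box

from .gtwr import PanelDataset
from .habitat import JIAWANG_CLASSES
from .raster import LandCoverRaster

__all__ = [
    "SyntheticLandscapeConfig",
    "CoefficientSurfaceSpec",
    "InvalidConfigError",
    "generate_landcover_series",
    "generate_threat_geometries",
    "generate_regression_panel",
]

NODATA = 255


class InvalidConfigError(ValueError):
    """Generator configuration violates its invariants."""


_DEFAULT_MIX = {
    # class -> proportion per epoch (2000, 2005, 2010, 2015, 2020)
    "cropland": (0.550, 0.540, 0.520, 0.495, 0.477),
    "woodland": (0.120, 0.120, 0.120, 0.120, 0.123),
    "grassland": (0.080, 0.080, 0.080, 0.080, 0.080),
    "water": (0.040, 0.042, 0.045, 0.050, 0.055),
    "impervious": (0.170, 0.180, 0.200, 0.220, 0.240),
    "barren": (0.040, 0.038, 0.035, 0.035, 0.025),
}


@dataclass
class SyntheticLandscapeConfig:
    """Parameters of the synthetic coal-city landscape.

    ``class_mix`` maps class name → one target area proportion per epoch;
    proportions must sum to one within 1e-9 at every epoch.
    ``subsidence_consolidation`` is the per-epoch fraction of fragmented
    subsidence-wetland patches already merged into contiguous lakes.
    """

    width: float = 6000.0
    height: float = 6000.0
    cell_size: float = 30.0
    epochs: tuple[int, ...] = (2000, 2005, 2010, 2015, 2020)
    class_mix: Mapping[str, Sequence[float]] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    n_urban_centers: int = 3
    n_mine_squares: int = 4
    subsidence_consolidation: Sequence[float] = (0.0, 0.2, 0.5, 0.8, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.cell_size <= 0:
            raise InvalidConfigError("cell_size must be positive")
        if self.ncol < 10 or self.nrow < 10:
            raise InvalidConfigError("extent must cover at least 10×10 cells")
        if any(b <= a for a, b in zip(self.epochs, self.epochs[1:])):
            raise InvalidConfigError("epochs must be strictly increasing")
        if self.n_mine_squares < 0:
            raise InvalidConfigError("n_mine_squares must be non-negative")
        ne = len(self.epochs)
        for cls, props in self.class_mix.items():
            if len(props) != ne:
                raise InvalidConfigError(f"class_mix[{cls}] must have one entry per epoch")
        for e in range(ne):
            total = sum(props[e] for props in self.class_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidConfigError(f"class_mix proportions at epoch {e} sum to {total}")
        if len(self.subsidence_consolidation) != ne:
            raise InvalidConfigError("subsidence_consolidation must have one entry per epoch")

    @property
    def nrow(self) -> int:
        return int(round(self.height / self.cell_size))

    @property
    def ncol(self) -> int:
        return int(round(self.width / self.cell_size))

    @property
    def origin(self) -> tuple[float, float]:
        return (0.0, self.height)


@dataclass
class CoefficientSurfaceSpec:
    """Ground-truth coefficient surface β(u, v, t) for the regression panel.

    Kinds: ``constant`` (amplitude everywhere), ``planar-gradient``
    (amplitude · ((u-u₀)+(v-v₀))/wavelength), ``gaussian-bump``
    (amplitude · exp(-r²/2λ²) around the domain center) and ``sinusoidal``
    (amplitude · sin(2πu/λ)·sin(2πv/λ)).  All kinds add
    ``temporal_trend · (t - t̄)`` per year.
    """

    kind: str = "constant"
    amplitude: float = 1.0
    spatial_wavelength: float = 1000.0
    temporal_trend: float = 0.0

    _KINDS = ("constant", "planar-gradient", "gaussian-bump", "sinusoidal")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise InvalidConfigError(f"unknown surface kind {self.kind!r}")
        if self.kind != "constant" and self.spatial_wavelength <= 0:
            raise InvalidConfigError("spatial_wavelength must be positive")

    def evaluate(self, u: np.ndarray, v: np.ndarray, t: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        t = np.asarray(t, dtype=float)
        cu, cv = u.mean(), v.mean()
        lam = self.spatial_wavelength
        if self.kind == "constant":
            base = np.full_like(u, self.amplitude)
        elif self.kind == "planar-gradient":
            base = self.amplitude * ((u - cu) + (v - cv)) / lam
        elif self.kind == "gaussian-bump":
            r2 = (u - cu) ** 2 + (v - cv) ** 2
            base = self.amplitude * np.exp(-r2 / (2.0 * lam**2))
        else:  # sinusoidal
            base = self.amplitude * np.sin(2 * np.pi * u / lam) * np.sin(2 * np.pi * v / lam)
        return base + self.temporal_trend * (t - t.mean())


# ---------------------------------------------------------------------------
# shared deterministic building blocks
# ---------------------------------------------------------------------------


def _rng(config: SyntheticLandscapeConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, salt])


def _smooth_field(shape, rng, sigma_cells: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells)


def _mine_rects(config: SyntheticLandscapeConfig) -> list[Polygon]:
    """Disjoint mine-square rectangles fully inside the extent (seeded)."""
    rng = _rng(config, 11)
    rects: list[Polygon] = []
    attempts = 0
    while len(rects) < config.n_mine_squares and attempts < 2000:
        attempts += 1
        w = rng.uniform(0.04, 0.09) * config.width
        h = rng.uniform(0.04, 0.09) * config.height
        x0 = rng.uniform(0.05 * config.width, 0.95 * config.width - w)
        y0 = rng.uniform(0.05 * config.height, 0.95 * config.height - h)
        cand = box(x0, y0, x0 + w, y0 + h)
        if all(cand.distance(r) > 4 * config.cell_size for r in rects):
            rects.append(cand)
    if len(rects) < config.n_mine_squares:
        raise InvalidConfigError("could not place the requested mine squares")
    return rects


def _urban_centers(config: SyntheticLandscapeConfig) -> np.ndarray:
    rng = _rng(config, 23)
    xs = rng.uniform(0.15, 0.85, config.n_urban_centers) * config.width
    ys = rng.uniform(0.15, 0.85, config.n_urban_centers) * config.height
    return np.column_stack([xs, ys])


def _river_path(config: SyntheticLandscapeConfig) -> LineString:
    """A meandering corridor crossing the extent from west to east."""
    rng = _rng(config, 37)
    nseg = 12
    xs = np.linspace(0.0, config.width, nseg)
    base = rng.uniform(0.3, 0.7) * config.height
    wiggle = np.cumsum(rng.normal(0, 0.05 * config.height, nseg))
    ys = np.clip(base + wiggle - wiggle.mean(), 0.05 * config.height, 0.95 * config.height)
    return LineString(np.column_stack([xs, ys]))


def _centers_xy(config: SyntheticLandscapeConfig) -> tuple[np.ndarray, np.ndarray]:
    cs = config.cell_size
    xs = (np.arange(config.ncol) + 0.5) * cs
    ys = config.height - (np.arange(config.nrow) + 0.5) * cs
    return np.meshgrid(xs, ys)


def _wetland_fragments(config: SyntheticLandscapeConfig, rects) -> list[np.ndarray]:
    """Small scattered wetland blobs near each mine square (flat cell indices)."""
    rng = _rng(config, 53)
    nrow, ncol = config.nrow, config.ncol
    xx, yy = _centers_xy(config)
    frags: list[np.ndarray] = []
    for rect in rects:
        cx, cy = rect.centroid.x, rect.centroid.y
        for _ in range(6):
            fx = cx + rng.normal(0, 0.06 * config.width)
            fy = cy + rng.normal(0, 0.06 * config.height)
            radius = rng.uniform(1.2, 2.6) * config.cell_size
            mask = (xx - fx) ** 2 + (yy - fy) ** 2 <= radius**2
            idx = np.flatnonzero(mask.ravel())
            if idx.size:
                frags.append(idx)
    return frags


def generate_landcover_series(config: SyntheticLandscapeConfig) -> list[LandCoverRaster]:
    """One land-cover raster per epoch on a shared grid, seed-deterministic.

    Class areas per epoch match ``class_mix`` up to integer rounding; the
    impervious set is nested across epochs (cells urbanize and stay urban
    when the target proportion is non-decreasing); fragmented subsidence
    wetlands merge into per-mine lakes according to
    ``subsidence_consolidation``.
    """
    nrow, ncol = config.nrow, config.ncol
    total = nrow * ncol
    codes = JIAWANG_CLASSES
    xx, yy = _centers_xy(config)

    # fixed (epoch-independent) structure
    rects = _mine_rects(config) if config.n_mine_squares else []
    centers = _urban_centers(config)
    river = _river_path(config)
    hills = _smooth_field((nrow, ncol), _rng(config, 71), sigma_cells=6.0)

    # impervious priority: distance to nearest urban center plus smooth noise
    if len(centers):
        d_urban = np.min(
            [(xx - cx) ** 2 + (yy - cy) ** 2 for cx, cy in centers], axis=0
        )
    else:
        d_urban = (xx - config.width / 2) ** 2 + (yy - config.height / 2) ** 2
    urban_score = np.sqrt(d_urban) + 600.0 * _smooth_field(
        (nrow, ncol), _rng(config, 83), 4.0
    )
    urban_order = np.argsort(urban_score.ravel(), kind="stable")

    # water priority pieces
    from shapely import dwithin, points as mk_points

    pts = mk_points(np.column_stack([xx.ravel(), yy.ravel()]))
    river_mask = dwithin(pts, river, 1.2 * config.cell_size)
    river_idx = np.flatnonzero(river_mask)
    d_river = ndimage.distance_transform_edt(
        ~river_mask.reshape(nrow, ncol), sampling=config.cell_size
    ).ravel()
    river_fill_order = np.argsort(d_river, kind="stable")
    frags = _wetland_fragments(config, rects)
    lake_orders = []
    for rect in rects:
        cx, cy = rect.centroid.x, rect.centroid.y
        off = rect.bounds[3] - cy + 6 * config.cell_size  # lake just north of the square
        d_lake = ((xx - cx) ** 2 + (yy - (cy + off)) ** 2).ravel()
        lake_orders.append(np.argsort(d_lake, kind="stable"))

    hill_order = np.argsort(-hills.ravel(), kind="stable")
    if rects:
        d_mine = np.min(
            [((xx - r.centroid.x) ** 2 + (yy - r.centroid.y) ** 2) for r in rects], axis=0
        )
    else:
        d_mine = np.full((nrow, ncol), np.inf)
    barren_score = np.sqrt(d_mine).ravel() + 400.0 * _smooth_field(
        (nrow, ncol), _rng(config, 97), 3.0
    ).ravel()
    barren_order = np.argsort(barren_score, kind="stable")

    frag_cells_all = np.concatenate(frags) if frags else np.empty(0, dtype=int)

    rasters = []
    for e, year in enumerate(config.epochs):
        counts = {
            cls: int(round(config.class_mix[cls][e] * total)) for cls in config.class_mix
        }
        assigned = np.zeros(total, dtype=bool)
        out = np.full(total, codes["cropland"], dtype=np.uint8)

        def take(order: np.ndarray, k: int) -> np.ndarray:
            sel = order[~assigned[order]][:k]
            assigned[sel] = True
            return sel

        # 1. impervious: nested radial growth around the urban centers
        out[take(urban_order, counts.get("impervious", 0))] = codes["impervious"]

        # 2. water: river first, then consolidated lakes, remaining fragments,
        #    then widening of the river corridor up to the target count
        k_water = counts.get("water", 0)
        c = float(config.subsidence_consolidation[e])
        n_merge = int(round(c * len(frags)))
        per_mine = len(frags) // max(len(rects), 1) if rects else 0
        merged_area = sum(len(f) for f in frags[: n_merge]) if frags else 0
        water_order_parts = [river_idx]
        if rects and merged_area:
            # split merged area across mine lakes proportionally
            for m, lake_order in enumerate(lake_orders):
                share = merged_area // len(lake_orders) + (
                    1 if m < merged_area % len(lake_orders) else 0
                )
                water_order_parts.append(lake_order[:share])
        for f in frags[n_merge:]:
            water_order_parts.append(f)
        water_order_parts.append(river_fill_order)
        water_order = np.concatenate(water_order_parts) if water_order_parts else river_fill_order
        # de-duplicate preserving priority
        water_order = pd.unique(water_order)
        out[take(water_order, k_water)] = codes["water"]

        # 3-4. woodland then grassland from the same hill field (grass rings wood)
        out[take(hill_order, counts.get("woodland", 0))] = codes["woodland"]
        out[take(hill_order, counts.get("grassland", 0))] = codes["grassland"]

        # 5. barren near the mines
        out[take(barren_order, counts.get("barren", 0))] = codes["barren"]
        # remainder stays cropland

        rasters.append(
            LandCoverRaster(
                out.reshape(nrow, ncol),
                config.cell_size,
                config.origin,
                year=year,
                nodata=NODATA,
            )
        )
    return rasters


def generate_threat_geometries(config: SyntheticLandscapeConfig) -> dict[str, list]:
    """Mine-square polygons and two railway polyline classes, seed-deterministic.

    Every coal-mine-dedicated railway touches at least one mine square; with
    zero mine squares the polygon set is empty but railways are still drawn.
    """
    rects = _mine_rects(config) if config.n_mine_squares else []
    rng = _rng(config, 101)
    dedicated = []
    if rects:
        for rect in rects:
            cx, cy = rect.centroid.x, rect.centroid.y
            edge_x = rng.uniform(0.2, 0.8) * config.width
            dedicated.append(LineString([(cx, cy), (edge_x, 0.0)]))
    else:
        x = rng.uniform(0.3, 0.7) * config.width
        dedicated.append(LineString([(x, 0.0), (x * 0.8, config.height)]))
    y1 = rng.uniform(0.2, 0.8) * config.height
    y2 = rng.uniform(0.2, 0.8) * config.height
    other = [LineString([(0.0, y1), (config.width, y2)])]
    return {"mine_squares": rects, "dedicated_railways": dedicated, "other_railways": other}


def generate_regression_panel(
    surfaces: Mapping[str, CoefficientSurfaceSpec],
    n_points: int,
    epochs: Sequence[int] = (2000, 2005, 2010, 2015, 2020),
    noise_sd: float = 0.1,
    seed: int = 0,
    extent: float = 10000.0,
) -> tuple[PanelDataset, pd.DataFrame]:
    """Space-time observations with known varying-coefficient ground truth.

    ``surfaces`` maps variable names to coefficient surfaces; the reserved
    name ``intercept`` supplies β₀ (default: zero).  Covariates are drawn
    independently standard-normal, locations uniformly over a square of side
    ``extent``, epochs cycled across observations.  Returns the panel and
    the true β evaluated at every observation.
    """
    if n_points < 10:
        raise InvalidConfigError("n_points must be at least 10")
    if noise_sd < 0:
        raise InvalidConfigError("noise_sd must be non-negative")
    for name, spec in surfaces.items():
        if not isinstance(spec, CoefficientSurfaceSpec):
            raise InvalidConfigError(f"surface for {name!r} is not a CoefficientSurfaceSpec")
    rng = np.random.default_rng(seed)
    covs = [name for name in surfaces if name != "intercept"]
    u = rng.uniform(0, extent, n_points)
    v = rng.uniform(0, extent, n_points)
    t = np.array([epochs[i % len(epochs)] for i in range(n_points)], dtype=float)
    x = {name: rng.standard_normal(n_points) for name in covs}

    beta = {}
    if "intercept" in surfaces:
        beta["intercept"] = surfaces["intercept"].evaluate(u, v, t)
    else:
        beta["intercept"] = np.zeros(n_points)
    for name in covs:
        beta[name] = surfaces[name].evaluate(u, v, t)

    signal = beta["intercept"] + sum(beta[name] * x[name] for name in covs)
    y = signal + rng.normal(0, noise_sd, n_points)

    df = pd.DataFrame({"id": np.arange(n_points), "u": u, "v": v, "t": t, "y": y})
    for name in covs:
        df[name] = x[name]
    panel = PanelDataset(df, covariates=covs)
    truth = pd.DataFrame(beta)
    truth["signal"] = signal
    return panel, truth
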