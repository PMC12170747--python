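"""InVEST-style habitat-quality model with coal-mining threat sources.

Habitat quality at pixel x of land-cover class j is

    Q_xj = H_j * [1 - D_xj^z / (D_xj^z + k^z)]

where H_j is the habitat suitability of class j, D_xj the accumulated
degradation from all threat sources, z a scaling exponent (2.5 here) and k
the half-saturation constant (0.5): the degradation level at which quality
drops to half the suitability.  Degradation is a weight-normalized sum over
threats of distance-decayed impact times the class's sensitivity:

    D_xj = Σ_r (w_r / Σ w_r) * i_rxy * S_jr

with exponential decay i = exp(-(2.99 / d_max) * d) or linear decay
i = max(0, 1 - d/d_max), cut to zero beyond d_max.  Accessibility is fixed
at 1 (no access layer).

Threat sources here follow a coal resource-exhausted city: cropland,
barren and impervious surfaces (from the land cover itself), coal-mine
industrial squares (polygons), coal-mine-dedicated railways and other
railways (polylines).  Mine squares can be deactivated for epochs after
mine closure via ``active_years``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .raster import LandCoverRaster, Raster, rasterize_geometries, transition_matrix, TransitionMatrix

__all__ = [
    "ThreatSpec",
    "SensitivityTable",
    "HQParams",
    "ConfigurationError",
    "JIAWANG_CLASSES",
    "default_threats",
    "default_sensitivity",
    "build_threat_rasters",
    "decay_distance",
    "degradation",
    "habitat_quality",
    "hq_transition",
    "load_params_yaml",
    "HQ_BINS",
    "HQ_BIN_LABELS",
]

_EXP_DECAY_CONST = 2.99  # impact falls to ~5% of its source value at d_max


class ConfigurationError(ValueError):
    """Inconsistent threat / sensitivity parameterization."""


@dataclass(frozen=True)
class ThreatSpec:
    """One threat source: reach (km), relative weight, and decay shape."""

    name: str
    max_dist: float  # kilometers
    weight: float
    decay: str = "exponential"
    active_years: frozenset | None = None  # None = active in every epoch
    source: str = "landcover"  # "landcover" (class name) or "geometry"

    def __post_init__(self):
        if self.max_dist <= 0:
            raise ConfigurationError(f"threat {self.name}: max_dist must be positive")
        if not 0 < self.weight <= 1:
            raise ConfigurationError(f"threat {self.name}: weight must be in (0, 1]")
        if self.decay not in ("exponential", "linear"):
            raise ConfigurationError(f"threat {self.name}: unknown decay {self.decay!r}")

    def active_in(self, year: int) -> bool:
        return self.active_years is None or year in self.active_years


@dataclass
class SensitivityTable:
    """Habitat suitability H_j per class and sensitivity S_jr per (class, threat)."""

    suitability: dict[str, float]
    sensitivity: dict[str, dict[str, float]]  # class -> threat -> S

    def __post_init__(self):
        for cls, h in self.suitability.items():
            if not 0 <= h <= 1:
                raise ConfigurationError(f"suitability of {cls} outside [0, 1]")
            for thr, s in self.sensitivity.get(cls, {}).items():
                if not 0 <= s <= 1:
                    raise ConfigurationError(f"sensitivity ({cls}, {thr}) outside [0, 1]")

    def is_habitat(self, cls: str) -> bool:
        return self.suitability.get(cls, 0.0) > 0

    def threats(self) -> set[str]:
        out: set[str] = set()
        for d in self.sensitivity.values():
            out |= set(d)
        return out


@dataclass(frozen=True)
class HQParams:
    """Scaling exponent z and half-saturation constant k of the quality curve."""

    z: float = 2.5
    k: float = 0.5

    def __post_init__(self):
        if self.z <= 0 or self.k <= 0:
            raise ConfigurationError("z and k must be positive")


# --- default parameterization for a coal resource-exhausted city -----------

JIAWANG_CLASSES: dict[str, int] = {
    "cropland": 1,
    "woodland": 2,
    "grassland": 3,
    "water": 4,
    "impervious": 5,
    "barren": 6,
}

_THREAT_ORDER = [
    "cropland",
    "barren",
    "impervious",
    "mine_squares",
    "dedicated_railways",
    "other_railways",
]


def default_threats(mine_closure_year: int | None = 2020, epochs: Sequence[int] = (2000, 2005, 2010, 2015, 2020)) -> list[ThreatSpec]:
    """Threat table for the coal-city study system.

    Mine industrial squares stop acting as a threat from ``mine_closure_year``
    on (all mines closed); pass ``None`` to keep them active throughout.
    """
    if mine_closure_year is None:
        mine_years = None
    else:
        mine_years = frozenset(y for y in epochs if y < mine_closure_year)
    return [
        ThreatSpec("cropland", 1.5, 0.7, "exponential", None, "landcover"),
        ThreatSpec("barren", 1.0, 0.4, "exponential", None, "landcover"),
        ThreatSpec("impervious", 4.0, 1.0, "exponential", None, "landcover"),
        ThreatSpec("mine_squares", 6.0, 1.0, "exponential", mine_years, "geometry"),
        ThreatSpec("dedicated_railways", 2.0, 0.8, "exponential", None, "geometry"),
        ThreatSpec("other_railways", 1.5, 0.6, "exponential", None, "geometry"),
    ]


def default_sensitivity() -> SensitivityTable:
    """Suitability and sensitivity of each land-cover class to each threat."""
    rows = {
        # class: (H, S_cropland, S_barren, S_impervious, S_mine, S_ded_rail, S_other_rail)
        "cropland": (0.4, 0.3, 0.1, 0.5, 0.6, 0.45, 0.3),
        "woodland": (0.95, 0.45, 0.3, 0.6, 0.7, 0.6, 0.4),
        "grassland": (0.65, 0.4, 0.25, 0.5, 0.6, 0.4, 0.25),
        "water": (0.8, 0.65, 0.2, 0.7, 0.75, 0.6, 0.4),
        "impervious": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        "barren": (0.2, 0.2, 0.2, 0.1, 0.5, 0.4, 0.2),
    }
    suit = {cls: vals[0] for cls, vals in rows.items()}
    sens = {
        cls: dict(zip(_THREAT_ORDER, vals[1:])) for cls, vals in rows.items()
    }
    return SensitivityTable(suitability=suit, sensitivity=sens)


def build_threat_rasters(
    landcover: LandCoverRaster,
    geoms: Mapping[str, Sequence],
    year: int,
    specs: Sequence[ThreatSpec],
    sens: SensitivityTable | None = None,
    class_codes: Mapping[str, int] = JIAWANG_CLASSES,
) -> dict[str, Raster]:
    """Binary source raster per threat active in the given epoch.

    Land-cover threats come from class membership; geometry threats are
    rasterized from the supplied polygon/polyline sets.  Threats whose
    ``active_years`` exclude the epoch are omitted entirely.
    """
    by_name = {s.name: s for s in specs}
    if sens is not None:
        missing = sens.threats() - set(by_name)
        if missing:
            raise ConfigurationError(
                f"threats named in sensitivity table but absent from specs: {sorted(missing)}"
            )
    out: dict[str, Raster] = {}
    for spec in specs:
        if not spec.active_in(year):
            continue
        if spec.source == "landcover":
            code = class_codes.get(spec.name)
            if code is None:
                raise ConfigurationError(f"no class code for land-cover threat {spec.name}")
            vals = ((landcover.values == code) & landcover.valid_mask()).astype(np.uint8)
            out[spec.name] = landcover.copy_with(vals, nodata=255)
        else:
            out[spec.name] = rasterize_geometries(geoms.get(spec.name, []), landcover)
    return out


def decay_distance(threat: Raster, spec: ThreatSpec) -> Raster:
    """Distance-decayed impact i_rxy in [0, 1] from a binary source raster.

    Distance is exact Euclidean between cell centers; impact is 1 on source
    cells, decays per the spec's shape, and is clamped to 0 beyond
    ``max_dist`` (given in kilometers).
    """
    src = threat.values.astype(bool)
    d_max = spec.max_dist * 1000.0  # km -> m
    if not src.any():
        return threat.copy_with(np.zeros(threat.shape, dtype=float), nodata=np.nan)
    # EDT measures each zero cell's distance to the nearest nonzero cell.
    dist = ndimage.distance_transform_edt(~src, sampling=threat.cell_size)
    if spec.decay == "exponential":
        impact = np.exp(-(_EXP_DECAY_CONST / d_max) * dist)
    else:
        impact = 1.0 - dist / d_max
    impact = np.where(dist > d_max, 0.0, np.clip(impact, 0.0, 1.0))
    return threat.copy_with(impact.astype(float), nodata=np.nan)


def degradation(
    impacts: Mapping[str, Raster],
    specs: Sequence[ThreatSpec],
    sens: SensitivityTable,
    landcover: LandCoverRaster,
    class_codes: Mapping[str, int] = JIAWANG_CLASSES,
) -> Raster:
    """Total degradation D_xj: weight-normalized, sensitivity-scaled impacts.

    Weights are normalized over the full threat table (``specs``), not only
    the threats with impact rasters, so deactivating a threat (e.g. mine
    squares after closure) removes its term without re-weighting the rest —
    quality can then only rise.
    """
    by_name = {s.name: s for s in specs}
    active = [name for name in impacts if name in by_name]
    wsum = sum(s.weight for s in specs)
    code_to_class = {v: k for k, v in class_codes.items()}
    d = np.zeros(landcover.shape, dtype=float)
    valid = landcover.valid_mask()
    for name in active:
        spec = by_name[name]
        impact = impacts[name].values
        s_map = np.zeros(landcover.shape, dtype=float)
        for code in np.unique(landcover.values[valid]):
            cls = code_to_class.get(int(code))
            if cls is None:
                raise ConfigurationError(f"land-cover code {code} has no registered class")
            try:
                s = sens.sensitivity[cls][name]
            except KeyError:
                raise ConfigurationError(
                    f"missing sensitivity entry for class {cls!r}, threat {name!r}"
                ) from None
            s_map[(landcover.values == code) & valid] = s
        d += (spec.weight / wsum) * impact * s_map
    d[~valid] = np.nan
    return landcover.copy_with(d, nodata=np.nan)


def habitat_quality(
    d: Raster,
    landcover: LandCoverRaster,
    sens: SensitivityTable,
    params: HQParams = HQParams(),
    class_codes: Mapping[str, int] = JIAWANG_CLASSES,
) -> Raster:
    """Quality raster Q = H_j * [1 - D^z / (D^z + k^z)]; nodata is NaN."""
    code_to_class = {v: k for k, v in class_codes.items()}
    valid = landcover.valid_mask()
    h = np.zeros(landcover.shape, dtype=float)
    for code in np.unique(landcover.values[valid]):
        cls = code_to_class.get(int(code))
        if cls is None:
            raise ConfigurationError(f"land-cover code {code} has no registered class")
        h[(landcover.values == code) & valid] = sens.suitability.get(cls, 0.0)
    dz = np.power(np.clip(d.values, 0.0, None), params.z)
    q = h * (1.0 - dz / (dz + params.k**params.z))
    q[~valid] = np.nan
    return landcover.copy_with(q, nodata=np.nan)


HQ_BINS = (0.2, 0.4, 0.6, 0.75)
HQ_BIN_LABELS = ("<0.2", "0.2-0.4", "0.4-0.6", "0.6-0.75", ">0.75")


def hq_transition(
    qa: Raster, qb: Raster, bins: Sequence[float] = HQ_BINS
) -> TransitionMatrix:
    """Bin two quality rasters and cross-tabulate the binned areas (km²).

    Bins are left-closed/right-open with the top bin closed above, e.g. the
    default edges give <0.2, 0.2-0.4, 0.4-0.6, 0.6-0.75, >0.75.
    """
    bins = list(bins)
    if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
        raise ValueError("bin edges must be strictly increasing")
    labels = _bin_labels(bins)

    def binned(q: Raster) -> Raster:
        idx = np.digitize(q.values, bins, right=False)
        idx = np.where(np.isnan(q.values), -1, idx).astype(np.int32)
        return q.copy_with(idx, nodata=-1)

    tm = transition_matrix(binned(qa), binned(qb), labels=list(range(len(bins) + 1)))
    return TransitionMatrix(labels=labels, areas=tm.areas)


def _bin_labels(bins: Sequence[float]) -> list[str]:
    labels = [f"<{bins[0]}"]
    labels += [f"{a}-{b}" for a, b in zip(bins, bins[1:])]
    labels.append(f">{bins[-1]}")
    return labels


def load_params_yaml(path) -> tuple[list[ThreatSpec], SensitivityTable, HQParams]:
    """Read threats / sensitivity / scoring parameters from a YAML file.

    Layout::

        threats:
          - {name: impervious, max_dist: 4, weight: 1, decay: exponential,
             source: landcover, active_years: null}
        sensitivity:
          woodland: {habitat: 0.95, impervious: 0.6, ...}
        params: {z: 2.5, k: 0.5}
    """
    data = yaml.safe_load(open(path))
    threats = []
    for row in data.get("threats", []):
        years = row.get("active_years")
        threats.append(
            ThreatSpec(
                name=row["name"],
                max_dist=float(row["max_dist"]),
                weight=float(row["weight"]),
                decay=row.get("decay", "exponential"),
                active_years=None if years is None else frozenset(int(y) for y in years),
                source=row.get("source", "landcover"),
            )
        )
    suit, sens = {}, {}
    for cls, row in data.get("sensitivity", {}).items():
        row = dict(row)
        suit[cls] = float(row.pop("habitat"))
        sens[cls] = {k: float(v) for k, v in row.items()}
    p = data.get("params", {})
    params = HQParams(z=float(p.get("z", 2.5)), k=float(p.get("k", 0.5)))
    return threats, SensitivityTable(suit, sens), params
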