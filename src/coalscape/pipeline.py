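"""End-to-end orchestration: generate → metrics → habitat quality → panel →
spatial autocorrelation → spatiotemporal regression.

The pipeline mirrors a grid-based landscape study: land cover is summarized
on a coarse sampling grid (500 m by default), each grid cell contributing
the four landscape metrics as covariates and mean habitat quality as the
response, with the cell centroid and epoch year as (u, v, t).
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gtwr import (
    PanelDataset,
    coefficient_summary,
    compare_models,
    gtwr_fit,
    mgtwr_fit,
    search_bandwidth,
    standardize,
)
from .habitat import (
    HQParams,
    build_threat_rasters,
    decay_distance,
    default_sensitivity,
    default_threats,
    degradation,
    habitat_quality,
    hq_transition,
)
from .metrics import UndefinedMetricsError, cell_metrics, vif_screen
from .moran import build_queen_weights, global_moran, local_moran
from .raster import (
    LandCoverRaster,
    Raster,
    class_areas,
    transition_matrix,
    write_geojson,
    write_geotiff,
)
from .synthetic import (
    SyntheticLandscapeConfig,
    generate_landcover_series,
    generate_threat_geometries,
)

__all__ = ["GridSpec", "build_grid_panel", "compute_quality_series", "run_pipeline", "default_config"]

log = logging.getLogger("coalscape")


@dataclass
class GridSpec:
    """Coarse sampling grid laid over the raster, aligned to its origin."""

    cell: float = 500.0
    keep_rule: float = 0.5  # minimum valid-pixel fraction for a cell to survive

    def cells_per_side(self, raster: Raster) -> tuple[int, int]:
        ratio = self.cell / raster.cell_size
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("grid cell must be an integer multiple of raster cell_size")
        k = int(round(ratio))
        return raster.shape[0] // k, raster.shape[1] // k


def build_grid_panel(
    landcover_series: Sequence[LandCoverRaster],
    quality_series: Sequence[Raster],
    grid: GridSpec = GridSpec(),
) -> tuple[PanelDataset, pd.DataFrame]:
    """Per-cell × per-epoch panel of landscape metrics and mean quality.

    Covariates are NP, CONTIG_MN, SHDI, AI computed inside each grid cell;
    the response y is the mean habitat quality over the cell's valid pixels;
    (u, v) is the cell centroid and t the epoch year.  Cells falling below
    ``keep_rule`` valid-pixel fraction in any epoch are dropped from all
    epochs.  Also returns the surviving-cell table.
    """
    first = landcover_series[0]
    k = int(round(grid.cell / first.cell_size))
    ngr, ngc = grid.cells_per_side(first)
    if ngr == 0 or ngc == 0:
        raise ValueError("raster smaller than one grid cell")
    ox, oy = first.origin

    keep = np.ones((ngr, ngc), dtype=bool)
    for lc in landcover_series:
        valid = lc.valid_mask()
        for gr in range(ngr):
            for gc in range(ngc):
                block = valid[gr * k : (gr + 1) * k, gc * k : (gc + 1) * k]
                if block.mean() < grid.keep_rule:
                    keep[gr, gc] = False
    if not keep.any():
        raise ValueError("no grid cells survive the keep rule")

    rows = []
    for lc, q in zip(landcover_series, quality_series):
        for gr in range(ngr):
            for gc in range(ngc):
                if not keep[gr, gc]:
                    continue
                sl = (slice(gr * k, (gr + 1) * k), slice(gc * k, (gc + 1) * k))
                window = lc.copy_with(lc.values[sl])
                try:
                    mv = cell_metrics(window)
                except UndefinedMetricsError:
                    continue
                qblock = q.values[sl]
                y = float(np.nanmean(qblock))
                rows.append(
                    {
                        "id": gr * ngc + gc,
                        "u": ox + (gc + 0.5) * grid.cell,
                        "v": oy - (gr + 0.5) * grid.cell,
                        "t": lc.year,
                        "y": y,
                        "row": gr,
                        "col": gc,
                        **mv.as_dict(),
                    }
                )
    df = pd.DataFrame(rows)
    cells = df[df["t"] == df["t"].iloc[0]][["id", "row", "col", "u", "v"]].reset_index(drop=True)
    panel = PanelDataset(
        df.drop(columns=["row", "col"]), covariates=["NP", "CONTIG_MN", "SHDI", "AI"]
    )
    return panel, cells


def compute_quality_series(
    landcover_series: Sequence[LandCoverRaster],
    geoms: Mapping[str, Sequence],
    threats=None,
    sens=None,
    params: HQParams = HQParams(),
) -> list[Raster]:
    """Habitat-quality raster per epoch from land cover and threat geometries."""
    epochs = [lc.year for lc in landcover_series]
    if threats is None:
        threats = default_threats(epochs=epochs)
    if sens is None:
        sens = default_sensitivity()
    out = []
    for lc in landcover_series:
        sources = build_threat_rasters(lc, geoms, lc.year, threats, sens)
        impacts = {
            name: decay_distance(src, next(s for s in threats if s.name == name))
            for name, src in sources.items()
        }
        d = degradation(impacts, threats, sens, lc)
        out.append(habitat_quality(d, lc, sens, params))
    return out


def default_config(seed: int = 0) -> dict:
    """Small demo configuration exercising every stage in seconds."""
    return {
        "landscape": {
            "width": 6000.0,
            "height": 6000.0,
            "cell_size": 30.0,
            "epochs": [2000, 2005, 2010, 2015, 2020],
            "n_urban_centers": 3,
            "n_mine_squares": 4,
            "subsidence_consolidation": [0.0, 0.2, 0.5, 0.8, 1.0],
            "seed": seed,
        },
        # closest block-aligned analogue of a 500 m sampling grid on 30 m cells
        "grid": {"cell": 480.0, "keep_rule": 0.5},
        "habitat": {"z": 2.5, "k": 0.5, "mine_closure_year": 2020},
        "moran": {"n_perm": 999, "alpha": 0.05},
        # metric covariates are strongly correlated, so the frozen-smoother
        # backfitting phase needs a larger sweep budget than sparse panels
        "regression": {"max_sweeps": 200, "soc_tol": 1.0e-5},
        "seed": seed,
    }


def _landscape_config(cfg: dict, seed: int) -> SyntheticLandscapeConfig:
    ls = dict(cfg.get("landscape", {}))
    ls.setdefault("seed", seed)
    if "epochs" in ls:
        ls["epochs"] = tuple(int(y) for y in ls["epochs"])
    if "class_mix" in ls:
        ls["class_mix"] = {k: tuple(v) for k, v in ls["class_mix"].items()}
    return SyntheticLandscapeConfig(**ls)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle under ``outdir``.

    Produces land-cover and quality GeoTIFFs per epoch, threat geometries,
    land-cover and habitat-quality transition tables, per-epoch global Moran
    summaries and LISA tables, a VIF report, GTWR and MGTWR diagnostics,
    a coefficient summary, local coefficients, and a run log.  Returns a
    dict of the in-memory results.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    t0 = time.time()
    stage = "setup"
    results: dict = {}
    try:
        stage = "generate"
        ls_config = _landscape_config(config, seed)
        landcover = generate_landcover_series(ls_config)
        geoms = generate_threat_geometries(ls_config)
        for lc in landcover:
            write_geotiff(outdir / f"landcover_{lc.year}.tif", lc)
        write_geojson(outdir / "threat_geometries.geojson", geoms)
        lc_trans = transition_matrix(landcover[0], landcover[-1])
        lc_trans.to_frame().to_csv(outdir / "landcover_transition.csv")
        pd.DataFrame({lc.year: class_areas(lc) for lc in landcover}).to_csv(
            outdir / "class_areas.csv"
        )

        stage = "habitat_quality"
        hq_cfg = config.get("habitat", {})
        params = HQParams(z=float(hq_cfg.get("z", 2.5)), k=float(hq_cfg.get("k", 0.5)))
        threats = default_threats(
            mine_closure_year=hq_cfg.get("mine_closure_year", 2020),
            epochs=ls_config.epochs,
        )
        quality = compute_quality_series(landcover, geoms, threats, params=params)
        for q in quality:
            write_geotiff(outdir / f"quality_{q.year}.tif", q)
        hq_trans = hq_transition(quality[0], quality[-1])
        hq_trans.to_frame().to_csv(outdir / "hq_transition.csv")
        results["mean_quality"] = {
            int(q.year): float(np.nanmean(q.values)) for q in quality
        }

        stage = "grid_panel"
        grid_cfg = config.get("grid", {})
        grid = GridSpec(
            cell=float(grid_cfg.get("cell", 500.0)),
            keep_rule=float(grid_cfg.get("keep_rule", 0.5)),
        )
        panel, cells = build_grid_panel(landcover, quality, grid)
        panel.to_csv(outdir / "grid_panel.csv")
        vif = vif_screen(panel.data[panel.covariates])
        vif.to_csv(outdir / "vif_report.csv")
        results["vif"] = vif

        stage = "moran"
        moran_cfg = config.get("moran", {})
        n_perm = int(moran_cfg.get("n_perm", 999))
        w = build_queen_weights(cells[["row", "col"]].to_numpy())
        moran_rows, lisa_frames = [], []
        for year, sub in panel.data.groupby("t"):
            sub = sub.sort_values("id")
            gm = global_moran(sub["y"].to_numpy(), w, n_perm=n_perm, seed=seed)
            moran_rows.append(
                {
                    "year": int(year),
                    "moran_I": gm.I,
                    "z_score": gm.z_score,
                    "p_score": gm.p_perm,
                }
            )
            lm = local_moran(sub["y"].to_numpy(), w, n_perm=n_perm, seed=seed)
            lisa_frames.append(
                pd.DataFrame(
                    {
                        "year": int(year),
                        "id": sub["id"].to_numpy(),
                        "I_local": lm.I_local,
                        "p": lm.p_perm,
                        "label": lm.labels,
                    }
                )
            )
        moran_summary = pd.DataFrame(moran_rows)
        moran_summary.to_csv(outdir / "moran_summary.csv", index=False)
        pd.concat(lisa_frames).to_csv(outdir / "lisa.csv", index=False)
        results["moran"] = moran_summary

        stage = "regression"
        reg_cfg = config.get("regression", {})
        spanel = standardize(panel)
        bws, bt = search_bandwidth(spanel)
        fit_g = gtwr_fit(spanel, bws, bt)
        fit_m = mgtwr_fit(
            spanel,
            init=fit_g,
            max_sweeps=int(reg_cfg.get("max_sweeps", 50)),
            tol=float(reg_cfg.get("soc_tol", 1.0e-5)),
        )
        diag = compare_models([fit_g, fit_m])
        diag.to_csv(outdir / "model_diagnostics.csv")
        (outdir / "model_diagnostics.json").write_text(
            json.dumps(
                {
                    "GTWR": {"R2": fit_g.r2, "AICc": fit_g.aicc, "RSS": fit_g.rss,
                             "bws": bws, "bt": bt},
                    "MGTWR": {"R2": fit_m.r2, "AICc": fit_m.aicc, "RSS": fit_m.rss,
                              "bws": fit_m.bandwidths.bws, "bt": fit_m.bandwidths.bt,
                              "converged": fit_m.converged, "sweeps": fit_m.n_sweeps},
                },
                indent=2,
            )
        )
        summary = pd.concat(
            {
                "GTWR": coefficient_summary(fit_g),
                "MGTWR": coefficient_summary(fit_m),
            },
            names=["model"],
        )
        summary.to_csv(outdir / "coefficient_summary.csv")
        coef = fit_m.coefficients.copy()
        coef.insert(0, "id", panel.data["id"].to_numpy())
        coef.insert(1, "t", panel.data["t"].to_numpy())
        coef.to_csv(outdir / "local_coefficients.csv", index=False)
        results.update(
            panel=panel, cells=cells, diagnostics=diag, gtwr=fit_g, mgtwr=fit_m,
            coefficient_summary=summary, hq_transition=hq_trans, quality=quality,
            landcover=landcover,
        )
    except Exception as exc:
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "run_log.json").write_text(
        json.dumps(
            {
                "seed": seed,
                "coalscape_version": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "elapsed_s": round(time.time() - t0, 2),
            },
            indent=2,
        )
    )
    return results
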