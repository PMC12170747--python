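# coalscape

Tools for studying how landscape patterns shape **habitat quality** in
mining-impacted regions — built around the analysis chain used for coal
resource–exhausted cities, where decades of extraction leave a distinctive
landscape of mine industrial squares, dedicated railways, subsidence
wetlands, and rapidly transforming urban land.

The package is aimed at landscape ecologists and spatial analysts who want
that chain as reusable, tested code rather than a sequence of GUI tools:

1. **Landscape metrics** per sampling-grid cell: number of patches (NP),
   mean contiguity (CONTIG_MN), Shannon diversity (SHDI) and the
   aggregation index (AI), with a VIF collinearity screen.
2. **Habitat quality** per pixel, InVEST-style:
   `Q_xj = H_j [1 − D^z/(D^z + k^z)]` with weight-normalized,
   distance-decayed threat degradation `D`, a coal-city threat table
   (cropland, barren, impervious, mine squares, two railway classes), and
   epoch-aware threat deactivation (mine squares stop degrading habitat
   once all mines close).
3. **Spatial autocorrelation**: global and local Moran's I with
   permutation inference and LISA cluster labels on queen-contiguity grid
   weights.
4. **Spatiotemporal regression**: GTWR — locally weighted regression with
   a separable Gaussian kernel in space (bandwidth in meters) and time
   (bandwidth in years) — and multiscale GTWR, which backfits one additive
   term per covariate, each with its own AICc-selected bandwidth pair,
   until the relative RSS change drops below 1e-5.
5. **Synthetic study systems** with known ground truth (land-cover
   panels, threat geometries, regression panels from analytic coefficient
   surfaces), so the whole chain runs and is testable without any
   download.

See `docs/methods.md` for the models, conventions, and design decisions.

## Worked example

Run the bundled demo pipeline (a 3 km synthetic coal-city scene, five
epochs 2000–2020, 480 m sampling grid):

```python
from coalscape.pipeline import default_config, run_pipeline

cfg = default_config(seed=1)
cfg["landscape"].update(width=3000.0, height=3000.0)
res = run_pipeline(cfg, "demo_out")
print({y: round(v, 3) for y, v in res["mean_quality"].items()})
print(res["moran"].round(3).to_string(index=False))
print(res["diagnostics"].round(3).to_string())
```

which prints (seed 1):

```
{2000: 0.338, 2005: 0.335, 2010: 0.33, 2015: 0.325, 2020: 0.372}
 year  moran_I  z_score  p_score
 2000    0.367    4.461    0.001
 2005    0.385    4.677    0.001
 2010    0.421    5.073    0.001
 2015    0.443    5.321    0.001
 2020    0.462    5.554    0.001
          R2     AICc     RSS
model
GTWR   0.942  113.896  10.354
MGTWR  0.940  209.589  10.853
```

Reading the output: mean habitat quality erodes through 2015 as impervious
surface spreads, then jumps in 2020 when the mine-square threat is
deactivated (all mines closed) and the subsidence wetlands have
consolidated into lakes. Moran's I rises steadily — habitat quality
becomes more spatially clustered — and every epoch is significant at the
permutation floor p = 0.001. The diagnostics table compares the
single-bandwidth GTWR fit with the multiscale fit; the coefficient
summary written to `demo_out/coefficient_summary.csv` adds per-variable
bandwidths and the min/median/max of the local standardized coefficients.

`run_pipeline` writes the full bundle — land-cover and quality GeoTIFFs
per epoch, threat geometries (GeoJSON), land-cover and habitat-quality
transition matrices (km²), per-epoch Moran summaries and LISA tables, the
VIF report, model diagnostics, local coefficients, and a run log.

The same stages are available as CLI verbs:

```bash
coalscape pipeline --outdir demo_out --seed 1
coalscape generate --outdir data --seed 1
coalscape metrics data/landcover_2020.tif --grid-cell 480 --out metrics.csv
coalscape mgtwr demo_out/grid_panel.csv --out mgtwr.json
```

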