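# Methods

`coalscape` implements the computational chain used to study how landscape
patterns drive habitat quality in a post-mining (coal resource–exhausted)
city: landscape pattern metrics on a coarse sampling grid, a raster
habitat-quality model with coal-mining threat sources, spatial
autocorrelation diagnostics, and spatially-and-temporally varying
coefficient regression with per-variable bandwidths. This note records the
models, the parameters that matter, and the design choices made where the
methods literature leaves the design open.

## Habitat-quality model

Per-pixel habitat quality for a pixel x of land-cover class j is

    Q_xj = H_j · [1 − D_xj^z / (D_xj^z + k^z)]

with habitat suitability `H_j ∈ [0, 1]`, scaling exponent `z = 2.5`, and
half-saturation constant `k = 0.5` (the degradation level at which quality
falls to half the suitability; used as an absolute constant, never rescaled
to the scene's maximum degradation). Degradation accumulates over threat
sources r:

    D_xj = Σ_r (w_r / Σ w_r) · i_rxy · S_jr

where `i_rxy` is the distance-decayed impact of the nearest source cell and
`S_jr` the sensitivity of class j to threat r. Exponential decay uses
`i = exp(−2.99 d / d_max)` so the impact falls to ≈5% at the threat's
maximum reach `d_max` (given in kilometers) and is clamped to zero beyond
it; a linear option `i = max(0, 1 − d/d_max)` is provided for completeness.
Distances are exact Euclidean between cell centers
(`scipy.ndimage.distance_transform_edt`). Accessibility multipliers are
fixed at 1 — the study system has no access layer.

The default parameterization is the coal-city threat table: cropland
(1.5 km, 0.7), barren (1 km, 0.4), impervious (4 km, 1.0), coal-mine
industrial squares (6 km, 1.0), coal-mine-dedicated railways (2 km, 0.8)
and other railways (1.5 km, 0.6), all exponential; suitabilities range from
0 (impervious) through 0.2 (barren), 0.4 (cropland), 0.65 (grassland), 0.8
(water) to 0.95 (woodland). Because all mines in the system closed before
the final epoch, the mine-square threat carries an `active_years` set and
is dropped when scoring 2020.

**Weight normalization.** `Σ w_r` runs over the full threat table, not just
the threats active in a given epoch. Under active-only normalization,
deactivating the mine threat would silently up-weight every other threat
and could *lower* quality far from the mines — the opposite of what mine
closure means. Full-table normalization makes deactivation a pure removal:
per-pixel quality can only rise, which is the model's intended semantics
and is asserted as a test invariant.

Quality change between epochs is summarized by binning Q at
0.2 / 0.4 / 0.6 / 0.75 (left-closed bins, top bin closed) and
cross-tabulating binned areas in km²; land-cover change uses the same
transition machinery on the raw classes.

## Landscape metrics

Four landscape-level metrics are computed inside each sampling-grid cell
(not a moving window), with FRAGSTATS conventions:

- **NP** — number of patches, where a patch is an 8-connected same-class
  region (8-neighbor is the FRAGSTATS default rule).
- **CONTIG_MN** — unweighted mean over patches of the contiguity index
  `CONTIG = [(Σ_r c_r / a) − 1]/(v − 1)`, using the 3×3 template (center 1,
  orthogonal neighbors 2, diagonals 1; template sum v = 13). A one-cell
  patch scores 0.
- **SHDI** — Shannon entropy `−Σ P_i ln P_i` over class proportions of the
  valid area, in nats.
- **AI** — aggregation index `100 · Σ_i (g_ii / max_g_ii) · P_i`, with
  `g_ii` the rook like-adjacency count (each pair counted once) and
  `max_g_ii` from the largest-square construction
  (`n = ⌊√A_i⌋, m = A_i − n²`). Classes of one cell (max_g = 0) contribute
  0, penalizing maximal disaggregation without dividing by zero.

Collinearity among metric columns is screened with the variance inflation
factor, `VIF_k = 1/(1 − R²_k)`, flagging columns at VIF ≥ 5; a perfectly
collinear column reports infinity rather than raising.

Every metric is verified against independent brute-force enumeration
(flood-fill patch labeling, explicit neighbor sums) on hundreds of random
windows up to 12×12.

## Spatial autocorrelation

Global Moran's I uses queen contiguity on the sampling grid,
row-standardized — the default for lattice data in the GeoDA tradition.
Inference is by random permutation (999 draws by default, two-sided pseudo
p-values against the null expectation −1/(n−1)); the z-score reported is
from permutation moments, with the classical Cliff–Ord randomization-null
z-score computed alongside. Local Moran's I_i uses conditional permutation
(unit i fixed, neighbors drawn from the remaining values) and the usual
LISA quadrant labels HH/LL/HL/LH at α = 0.05, `ns` otherwise. Small-lattice
results are tested against an exhaustive double-sum oracle to 1e-12, and
the row-standardized identity mean(I_i) = I is asserted.

## Spatiotemporal regression

GTWR solves a weighted least-squares problem at every observation with a
**separable Gaussian kernel**

    w_ij = exp(−d_s(i,j)²/bws²) · exp(−(t_i−t_j)²/bt²)

with a fixed spatial bandwidth `bws` in meters and temporal bandwidth `bt`
in years. Separability (rather than a fused spatiotemporal distance with a
space-time scaling ratio) makes the two bandwidths independently
identifiable, which the multiscale variant needs. Fixed distance bandwidths
are used, not adaptive neighbor counts, so reported bandwidths are in
physical units.

Model selection minimizes the corrected Akaike criterion

    AICc = 2n ln σ̂ + n ln 2π + n (n + ν)/(n − 2 − ν),

with ν the hat-matrix trace, by nested golden-section search on the log
scale (outer loop spatial, inner temporal; 16 iterations per level, i.e.
sub-1% bandwidth resolution). Bounds default to [extent/50, 10·extent] in
space and [0.1 yr, 10·max(time range, 1)] in time. Near-ties in the search
prefer the larger bandwidth: a flat criterion means the data carry no
information at that scale, and the smoother fit is the right default (this
also sends the temporal bandwidth to its upper bound on single-epoch data).

**MGTWR** gives every covariate — the intercept included, as variable 0
with x ≡ 1 — its own `(bws_k, bt_k)` via backfitting of additive terms
`f_k = β_k ⊙ x_k`: terms are initialized from a GTWR fit, then refit one at
a time against partial residuals `e_k = y − Σ_{l≠k} f_l` with a
single-regressor locally weighted fit whose bandwidth pair is re-selected
by AICc each sweep (full bounds on the first sweep, an 8×-window warm start
after). Convergence is declared when the relative RSS change between sweeps,
`SOC_RSS = |RSS_new − RSS_old|/RSS_new`, drops to 1e-5, with a 50-sweep cap;
hitting the cap flags the fit unconverged rather than raising.

Numerical choices worth knowing:

- **Bandwidth hysteresis.** A freshly searched bandwidth pair replaces the
  current one only if it improves that term's AICc by a relative 1e-6
  margin, and searches stop after a sweep adopts nothing. Without this, the
  sweep-to-sweep re-search can oscillate between near-equivalent bandwidths
  and hold SOC_RSS in a small limit cycle above the criterion.
- **Ridge guard.** Local normal matrices receive a 1e-8·trace ridge, so
  extreme bandwidths degrade gracefully instead of raising on
  near-singular weighted designs; `local_wls` itself raises on truly
  rank-deficient designs.
- **Effective degrees of freedom of the additive fit** are taken as the sum
  of per-term smoother traces — the standard additive-model approximation —
  when computing the MGTWR AICc.
- **Standardization** is pooled over all epochs (z-scores of y and each
  covariate), so standardized coefficients are comparable across time; the
  scaling record supports exact back-transformation, verified against
  raw-scale OLS in the global-bandwidth limit.

Diagnostics per fit: R² = 1 − RSS/TSS, AICc, RSS, hat trace, per-variable
bandwidths and min/median/max of the local standardized coefficients.

## Synthetic study systems

The generators exist so that every stage has inputs with known ground
truth. They are first-class, tested code.

`generate_landcover_series` builds a five-epoch (2000–2020, 5-year steps)
categorical panel at 30 m resolution: a cropland matrix; woodland with a
grassland fringe thresholded from one smoothed Gaussian random field (so
hills cluster and persist across epochs); a meandering river corridor;
impervious surface growing radially around several urban centers by a fixed
priority order, making urbanization *nested* (cells never de-urbanize);
mine industrial squares with scattered subsidence-wetland fragments nearby
that progressively merge into per-mine lakes according to a per-epoch
consolidation fraction. Per-epoch class proportions hit their targets
exactly up to integer rounding because cells are assigned by per-class
priority orderings with exact counts. Default proportions follow a
shrinking-cropland / growing-impervious / slowly-expanding-water
trajectory typical of a transforming mining city.

What the generator does **not** emulate: real class-boundary geometry
(field edges, road networks), registration error, classification noise, or
any particular region's statistics. Tests passing on these scenes show the
machinery is correct and the qualitative dynamics (threat growth, wetland
consolidation, closure effects) propagate as designed — not that any
real-world coefficient estimate would take a particular value.

`generate_regression_panel` draws locations uniformly, cycles epochs,
draws covariates i.i.d. standard normal, and builds
`y = β₀(u,v,t) + Σ β_k(u,v,t)x_k + ε` from analytic coefficient surfaces
(constant, planar gradient, Gaussian bump, sinusoidal, each with an
optional linear temporal trend). Independence of the covariates gives the
regression tests exact ground truth; the pipeline separately exercises
real metric→quality panels where covariates are correlated.

## Pipeline

The sampling grid aggregates the land-cover and quality rasters into a
panel: per grid cell and epoch, the four metrics as covariates, mean
quality over the cell's valid pixels as the response, the cell centroid
and epoch year as (u, v, t). Cells with under 50% valid pixels in any
epoch are dropped from all epochs, keeping the panel balanced. The grid
edge must be an integer multiple of the pixel size so blocks are exact; the
demo configuration uses 480 m (16 pixels of 30 m) as the closest
block-aligned analogue of a 500 m sampling grid. Metrics and mean quality
use the same cell masks so the regression inputs are internally
consistent; mean quality is over all valid pixels (a habitat-only mean is
a one-line switch at the aggregation call).

Problem sizes in the test and demo configurations — 3–6 km scenes
(100×100 to 200×200 pixels), 36–144 grid cells over five epochs, and
regression panels of 300–1000 observations — were chosen as the smallest
sizes at which every statistical property under test (oracle equivalence,
bandwidth scale separation, permutation inference) is comfortably
resolved.

## Known limitations

- No reprojection or resampling: all rasters and geometries must share one
  projected, meter-based grid.
- The habitat model omits the habitat-rarity term and accessibility layers
  found in fuller implementations.
- MGTWR reports no uncertainty on local coefficients (no bootstrap), and
  the AICc of the additive fit relies on the trace-sum approximation.
- The nested golden-section search assumes a unimodal criterion in each
  bandwidth; a strongly multimodal criterion could trap it, as with any
  local bandwidth optimizer.
- Permutation p-values are lower-bounded at 1/(n_perm+1); detecting
  significance below 0.001 needs more than 999 permutations.
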