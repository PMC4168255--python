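# Methods

This note documents the models, conventions and numerical choices
behind `consenm`, in the spirit of the model documentation shipped by
packages like msprime or statsmodels: what is computed, under which
assumptions, and which decisions were genuinely open.

## Grid and gridding conventions

All spatial layers are vectors indexed by 0-based **row-major cell
id** on an equal-area lattice; **row 0 is the southernmost row**. Cell
intervals are **half-open** `[x, x+cs) × [y, y+cs)`, so a point on a
shared edge belongs to the cell to its east/north and every point maps
to exactly one cell. Coordinates are assumed to be in an equal-area
planar projection already; reprojection is reader-level concern, not
core logic.

The **study-region mask** marks a cell inside the region iff its
*center* falls inside the mask geometry — simple, unambiguous and
reproducible. The **protected-area overlay deliberately uses a
different rule**: a PA claims every cell its polygon intersects with
positive area ("any portion protected"), because a species occupying a
partially protected cell can still benefit from the reserve. The
positive-area test uses a relative tolerance of 1e-9 × cell area to
ignore floating-point slivers.

Occurrence records carry a collection year for provenance, but no
temporal filter is applied anywhere. Species occupying fewer than
**5 cells** after deduplication are dropped as unmodellable (the
conventional minimum-record filter; duplicate records within a cell
collapse to one presence first).

## Climate standardization

The four bioclimatic variables (annual mean temperature °C;
temperature seasonality, SD × 100; annual precipitation, mm;
precipitation seasonality, CV) are centered and scaled by the masked
mean and SD of the **current scenario only**, and those same statistics
are applied to every future scenario. This keeps future climate from
leaking into model space and makes a future uniform delta appear as a
clean shift of `delta/SD` in standardized units. A zero-variance
variable is a configuration error and is reported by name.

## The six presence-only methods

All methods emit a continuous suitability surface clipped to [0, 1]
over the masked cells and can project onto any scenario.

* **Euclidean** — `suit(c) = 1 − d(c)/d_max`, `d` the Euclidean
  distance in standardized climate space to the presence centroid,
  `d_max` the maximum over the projected scenario's masked cells. The
  surface reaches 0 at the farthest cell by construction; it reaches 1
  only where a cell sits exactly at the centroid (the distance
  formula, not a max-rescaling, fixes the scale).
* **Gower (DOMAIN)** — nearest-record rule:
  `suit(c) = 1 − min_p (1/4) Σ_v |x_cv − x_pv| / range_v`, ranges taken
  over masked *current* cells on the raw (unstandardized) variables,
  clipped to [0, 1]. Adding a presence can only raise suitability.
* **ENFA** — the marginality factor is the normalized displacement of
  the presence mean from the global mean in standardized space (where
  the global mean is 0 and SD 1); specialization factors are the
  principal axes of the presence covariance restricted to the
  orthogonal complement (via QR). All four factors are retained.
  Suitability is `1 − D/D_max` with `D` the per-factor-scaled distance
  to the presence **median** in factor space (scales = presence SD per
  factor). Zero marginality degrades gracefully to plain principal
  axes; a rank-deficient presence covariance falls back to its
  diagonal with a warning. Of the several published ENFA suitability
  variants, this one was chosen because it is fully deterministic.
* **MaxEnt (Gibbs)** — `P(c) ∝ exp(λ·f(c))` over background cells
  (default: all masked cells) with **linear + quadratic** features of
  the standardized variables; λ maximizes the presence log-likelihood
  minus an L1 penalty (default 0.01). The penalty is smoothed as
  `sqrt(λ²+1e-8)` so L-BFGS-B applies; exact zeros are not produced,
  but the defining behaviours hold: at zero penalty the fitted
  distribution's feature expectations match the presence feature
  means (the maxent moment conditions), and a large penalty drives all
  λ to 0 (uniform surface). Projection rescales `exp(λ·f)` so the best
  masked cell scores 1. Hinge/threshold features and clamping of the
  reference desktop implementation are intentionally out of scope.
* **GARP-like rule-set GA** — individuals are sets of 8 rules; each
  rule is a climate envelope (or its negation) over a random subset of
  standardized variables, predicting presence or absence. A rule
  *applies* where its condition holds; suitability is the fraction of
  applicable rules predicting presence (0 where none applies), and the
  binary prediction is suitability ≥ 0.5. Fitness is training accuracy
  on presences + pseudo-absences. Defaults: population 40, 60
  generations, tournament selection (size 2), uniform rule-level
  crossover, per-rule point mutation (rate 0.25) of bounds/variable
  sets/polarity, 2 elites. Initial envelopes are seeded from pairs of
  training points and, with probability 0.4, from the tight presence
  bounding box — so a box-separable problem is solvable from
  generation 0. This is a deliberately simplified "GARP-like" method:
  no atomic/logistic rule types and no internal resampling.
* **ANN** — one hidden layer (5 logistic units), trained by full-batch
  gradient descent on cross-entropy against pseudo-absences; defaults
  2000 epochs, learning rate 1.0, N(0, 0.1) initial weights. The
  defaults are sized so the network both separates its training
  classes and ranks the niche optimum sharply (see recovery tests);
  with zero epochs the outputs sit in the initialization's ≈0.5 band.

Every stochastic fit takes an explicit seed; there is no global RNG
state, and identical seeds give bitwise-identical fits.

## Evaluation

Pseudo-absences are drawn uniformly **without replacement** from
masked non-presence cells; the default count equals the presence count
(prevalence 0.5 — the literature states no standard and this is the
neutral choice). Cross-validation stratifies each class independently:
75% calibration (floor rounding) / 25% validation, repeated 10 times,
which preserves prevalence by construction; each class needs ≥ 4
cells.

The binarization threshold maximizes sensitivity + specificity over
candidate thresholds at the **midpoints between consecutive distinct
scores** plus below-minimum and above-maximum caps; classification is
*presence iff score ≥ threshold*; ties break toward the **lower**
threshold (the larger predicted range — omission-averse, the
conservation-conservative direction). Both threshold and TSS are
computed on the **held-out validation** cells under current climate,
and future projections reuse the current threshold unchanged (no
future truth exists to re-score against). AUC is intentionally absent
from the package: it weighs omission and commission equally and
depends on study extent, which is why TSS is the only skill score.

## Ensemble consensus

Projections vote per cell with weight = TSS, **negative weights
clipped to zero** (a worse-than-random model should not vote); if no
model in a pool has positive skill that is an error, not a silent
empty range. The presence rule is weighted frequency **≥ 0.5
(inclusive)**. Current consensus pools 3 methods × 10 partitions = 30
projections per species per method set; future consensus pools
methods × climate models × partitions (3 × 3 × 10 = 90) in **one flat
vote** — climate models are not hierarchically averaged first, which
keeps the arithmetic identical to the printed pool sizes — and each
future projection carries its model's current-climate TSS. Distance
and machine-learning sets are kept separate end to end; no
cross-method-set grand ensemble is formed.

## Diversity statistics

Richness is the count of consensus ranges overlapping a cell, so
`Σ_cells richness = Σ_species |range|` is an exact conservation
identity checked on every run. Turnover is `(G+L)/(S+G)` — 0 for an
unchanged assemblage, 1 for complete replacement, bounded in [0, 1]
because `L ≤ S`; cells with `S+G = 0` are reported as **missing**, not
0. (Printed renderings of this statistic elsewhere sometimes garble
the expression; the implementation is the standard form with exactly
these limiting behaviours.) Range contraction is
`100·(|current| − |future|)/|current|`, negative for expansions and
undefined for an empty current range.

## Protected-area null model

Footprints store cell offsets from their north-westernmost cell and
are relocated **rigidly** — anchors drawn uniformly from masked cells,
rejecting placements where any offset cell leaves the grid or the
mask; no rotation or reflection, so size, shape and orientation are
exactly preserved. Per replicate (default 1,000), every footprint is
relocated **independently**, and relocated footprints may overlap each
other and the real reserve sites — the simplest null consistent with
"random location". Per-PA richness is the **union rule**: a species
inside any of the PA's cells counts once. The classification baseline
is the ordinary least-squares line of null future on null present
means across PAs; then

* `gain` — future > present richness;
* `severe_loss` — future below the null line's prediction;
* `mild_loss` — everything else,

an exhaustive and mutually exclusive three-way rule.

## The synthetic world

The generator emulates the statistical structure the analysis assumes,
not any particular region's physics:

* **Climate** — per variable, smooth north-south and east-west linear
  gradients plus a Gaussian random field (white noise smoothed with a
  Gaussian kernel, correlation length 3 cells, rescaled to a
  per-variable noise SD). Defaults are subtropical-forest magnitudes
  (base 22 °C, 8 °C cooler at the north edge, 1,400 mm precipitation,
  etc.). Futures are exact additive deltas, optionally graded
  north-south (mimicking the typical meridional contrast of downscaled
  GCM anomalies); delta magnitudes are free configuration, not
  calibrated to any GCM.
* **Species** — Gaussian (bell) niches: suitability
  `p_max · exp(−½ Σ_v ((x_v−μ_v)/σ_v)²)` with optima anchored on
  realized current climate at random masked cells (so every species
  has habitat), breadths 0.3–0.9 × the climate SD per variable, and
  `p_max` ∈ 0.6–0.95.
* **Occurrences** — per species, a fixed collection effort allocated
  multinomially over cells with probability ∝ suitability × an
  optional east-west effort surface (accessibility bias), points
  jittered within cells, years 1920–2008.
* **Protected areas** — connected footprints grown by seeded accretion
  on the mask; synthetic PAs never overlap each other (real reserve
  polygons may; the relocation logic does not care).

What the generator does **not** emulate: sampling gaps correlated with
climate itself, spatially aggregated (clustered) collection,
positional/taxonomic error, niche asymmetry or bimodality, dispersal
limitation, and biotic interactions. Passing tests therefore
demonstrate the pipeline's internal correctness and its ability to
recover known Gaussian niches from effort-biased presence samples —
not predictive skill on real survey data.

## Problem sizes and determinism

The demo world used by the acceptance-style tests is an 18 × 18 grid
(324 cells), 16 species, 3 future pseudo-GCMs (+1.1 to +1.9 °C,
north-graded, wetter south), 24 protected areas and 200 null
replicates — chosen as the smallest world in which per-cell richness,
consensus pooling (30/90 projections) and the geographic contrast of
the null-model classification are all well resolved. Calibration
checks of the null model use 1,000 replicates and a 3-SE band. The
full survey-scale magnitudes the defaults are styled after (hundreds
of species, ~11,461-cell masks, 187 reserves over 820 cells) are
exercised structurally in the generator tests.

The pipeline derives per-species sub-seeds by hashing the master seed
with the species id (CRC32, kept below 2³¹), so results are
independent of species processing order, and identical (config, seed)
pairs reproduce every product file bit for bit. Stage manifests record
config and file hashes; a corrupted product invalidates only its stage
and those downstream.

## Known limitations

* The MaxEnt variant is a convex desk-scale log-linear model; it lacks
  hinge features, clamping and extrapolation diagnostics, so its
  surfaces are smoother than the reference implementation's.
* The GARP-like GA explores a reduced rule grammar; its suitability
  surface is a coarse step function, which makes fine rank-order
  statistics (e.g. top-percentile placement of the niche optimum)
  sensitive to the rule-set size.
* ENFA's suitability algorithm has several published variants; results
  are comparable in rank order but not numerically interchangeable
  with other implementations.
* The null model treats every masked cell as an eligible reserve
  location; real siting constraints (land tenure, altitude, cost) are
  out of scope.
* GeoTIFF raster I/O is not included; layers are exchanged as plain
  text grids and CSV (one value per cell id), and polygons as GeoJSON.
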