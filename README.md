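# consenm

**Consensus ecological niche modelling and protected-area effectiveness
under climate change.**

Climate change displaces species' climatically suitable areas, and a
reserve network drawn for today's distributions may protect much less
tomorrow. `consenm` is a tested, reusable implementation of the
classic presence-only ensemble workflow used in conservation
biogeography to quantify that erosion:

1. **Gridding** — point occurrence records are rasterized onto an
   equal-area lattice (e.g. 10 km × 10 km) into a species × cell
   presence matrix; species with fewer than five occupied cells are
   excluded as unmodellable.
2. **Niche models** — six presence-only methods, in two sets.
   *Distance methods*: Euclidean distance to the presence centroid,
   Gower distance to the nearest record (DOMAIN rule), and Ecological
   Niche Factor Analysis (marginality + specialization factors).
   *Machine-learning methods*: a maximum-entropy Gibbs model (linear +
   quadratic features, L1 penalty), a GARP-like envelope-rule genetic
   algorithm, and a single-hidden-layer neural network. Distance
   methods use presences only; ENFA/MaxEnt contrast presences with the
   background; GARP/ANN train against randomly drawn pseudo-absences.
3. **Evaluation** — per species, a stratified 75/25
   calibration/validation split repeated 10 times. Continuous
   predictions are thresholded at the ROC point maximizing
   sensitivity + specificity, and skill is scored by the True Skill
   Statistic, TSS = sensitivity + specificity − 1 ∈ [−1, 1]
   (AUC is deliberately not used).
4. **Ensemble** — binary projections are pooled per species and method
   set into a TSS-weighted vote: 3 methods × 10 partitions = 30
   current projections; with 3 future climate models, 3 × 3 × 10 = 90
   future projections. A cell enters the consensus range at ≥ 50%
   weighted frequency.
5. **Diversity** — per-cell richness (sum of overlapping ranges),
   temporal turnover (G + L)/(S + G), and per-species percent range
   contraction 100·(|current| − |future|)/|current|.
6. **Protected areas** — reserve polygons claim every grid cell they
   touch (any-portion rule). A null model rigidly relocates each PA
   footprint (size, shape, orientation preserved) to uniformly random
   positions 1,000 times; the regression of null future on null
   present richness is the random-placement baseline. Each PA is then
   classified: **gain** (future > present richness), **severe loss**
   (future below even the null baseline), or **mild loss** (the rest).

Because real occurrence compilations of this kind are rarely
redistributable, the package ships a first-class synthetic-data module
(`consenm.synthetic`) generating climates with spatial autocorrelation,
species with known Gaussian niches, effort-biased occurrence samples,
and protected-area footprints — so the entire pipeline is testable
end to end with known ground truth.

## Worked example

```python
from consenm import *

grid = build_grid((0, 0, 200, 200), cell_size=10)
climate = generate_climate(grid, seed=11, deltas=[
    ScenarioDelta("warm", (1.5, 80.0, -50.0, 2.0), ns_gradient=(0.5, 0, 100.0, 0)),
])
truth = generate_species(6, grid, climate, seed=23)
occ = sample_occurrences(truth, climate, grid, effort_per_species=80, seed=7)
matrix = build_presence_matrix(occ, grid)
print(f"{len(matrix)} modellable species ({matrix.n_dropped} dropped by the 5-cell filter)")

env = standardize_climate(climate)
sp = matrix.species_ids[0]
cells = matrix.cells[sp]
pseudo = draw_pseudo_absences(grid, cells, seed=1)
parts = partition_data(cells, pseudo, seed=2, species_id=sp)

store = ProjectionStore()
for method in [m for ms in METHOD_SETS.values() for m in ms]:
    for part in parts:
        contrast = part.calib_absence if method in ("garp", "ann") else None
        model = fit_model(method, part.calib_presence, contrast, env, seed=part.replicate)
        for scenario in ("current", "warm"):
            store.add(evaluate_projection(model, part, env, scenario, sp))

cur = assemble_current(store, sp, "distance", mask=grid.mask)
fut = assemble_future(store, sp, "distance", ["warm"], mask=grid.mask)
print(f"{sp}: current range {cur.range_size} cells, future {fut.range_size} cells, "
      f"contraction {range_contraction(cur.range_size, fut.range_size):.1f}%")
```

prints

```
6 modellable species (0 dropped by the 5-cell filter)
sp1: current range 69 cells, future 49 cells, contraction 29.0%
```

i.e. under a +1.5 °C (north-graded) warming scenario this species'
TSS-weighted consensus range shrinks from 69 to 49 cells, a 29% range
contraction. The same store pools 30 current and 30 future projections
(one configured climate model) per method set; the distance-method
models average TSS ≈ 0.98 on this cleanly separable synthetic species.

## Command line

The whole analysis runs from one YAML config and a master seed:

```sh
consenm all -c config.yml -o runs/demo
```

Subcommands (`simulate`, `grid`, `fit`, `ensemble`, `diversity`,
`protect`, `classify`, `all`) execute the pipeline through the named
stage. Each stage writes CSV/JSON/plain-text products plus a manifest
with input hashes; reruns skip up-to-date stages, and identical
(config, seed) pairs reproduce outputs bit for bit.

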