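"""Synthetic world generator: climate, species niches, occurrence
sampling and protected-area footprints.

Real occurrence datasets of the kind this pipeline targets (museum and
field records of hundreds of species) are rarely redistributable, so
every downstream stage is exercised against a generated world with
known ground truth:

* a current climate of four bioclimatic variables (annual mean
  temperature, temperature seasonality, annual precipitation,
  precipitation seasonality) built from smooth spatial gradients plus a
  spatially autocorrelated Gaussian random field;
* future scenarios as additive deltas per pseudo-GCM, optionally graded
  north-to-south;
* species with Gaussian (bell-shaped) niches in climate space, whose
  true suitability in cell ``c`` for species ``s`` is
  ``p_max * exp(-0.5 * sum_v ((clim_cv - opt_sv) / breadth_sv)**2)``;
* presence-only occurrence records sampled proportionally to true
  suitability times an optional collection-effort surface;
* connected protected-area footprints grown by seeded accretion.

Every generator is a pure function of its inputs and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import Grid, OccurrenceSet
from .protected import PAFootprint

#: Canonical variable order used throughout the package.
VARIABLES: tuple[str, ...] = (
    "temp_mean",
    "temp_seasonality",
    "precip_annual",
    "precip_seasonality",
)

N_VARS = len(VARIABLES)


@dataclass(frozen=True)
class ClimateLayers:
    """Per-scenario climate values per cell.

    ``scenarios[name]`` is an ``(n_cells, 4)`` array in the
    :data:`VARIABLES` order, NaN outside the study-region mask.
    Exactly one scenario is flagged current.
    """

    grid: Grid
    scenarios: Mapping[str, np.ndarray]
    current: str = "current"
    variables: tuple[str, ...] = VARIABLES

    def __post_init__(self) -> None:
        if self.current not in self.scenarios:
            raise ValueError(f"current scenario {self.current!r} missing")
        for name, arr in self.scenarios.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.grid.n_cells, N_VARS):
                raise ValueError(f"scenario {name!r} has shape {arr.shape}")
            if np.isnan(arr[self.grid.mask]).any():
                raise ValueError(f"scenario {name!r} has missing values inside the mask")

    @property
    def future_names(self) -> list[str]:
        return [s for s in self.scenarios if s != self.current]

    def values(self, scenario: str) -> np.ndarray:
        return np.asarray(self.scenarios[scenario], dtype=float)

    def masked_values(self, scenario: str) -> np.ndarray:
        """``(n_masked, 4)`` climate at mask-true cells."""
        return self.values(scenario)[self.grid.mask]


@dataclass(frozen=True)
class ScenarioDelta:
    """Additive climate shift of one pseudo-GCM future.

    ``shift`` applies uniformly; ``ns_gradient`` adds a component that
    varies linearly from ``-g/2`` at the south edge to ``+g/2`` at the
    north edge, imitating the north-south contrast of downscaled GCM
    anomalies.
    """

    name: str
    shift: tuple[float, float, float, float]
    ns_gradient: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.shift)) or not np.all(np.isfinite(self.ns_gradient)):
            raise ValueError("delta components must be finite")

    def field_on(self, grid: Grid) -> np.ndarray:
        """Realize the delta as an ``(n_cells, 4)`` array."""
        rows = np.arange(grid.n_cells) // grid.n_cols
        frac = (rows + 0.5) / grid.n_rows - 0.5  # -0.5 south .. +0.5 north
        return np.asarray(self.shift) + frac[:, None] * np.asarray(self.ns_gradient)


@dataclass(frozen=True)
class NicheTruth:
    """Ground-truth Gaussian niches for synthetic species."""

    species_ids: tuple[str, ...]
    optima: np.ndarray  # (n_species, 4), climate units
    breadths: np.ndarray  # (n_species, 4), tolerance SDs, > 0
    max_occupancy: np.ndarray  # (n_species,), in (0, 1]

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.breadths) <= 0):
            raise ValueError("niche breadths must be positive")
        p = np.asarray(self.max_occupancy)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("max_occupancy must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.species_ids)

    def true_suitability(self, climate: ClimateLayers, scenario: str | None = None) -> np.ndarray:
        """``(n_species, n_cells)`` true occupancy probability; NaN
        outside the mask."""
        scenario = scenario or climate.current
        clim = climate.values(scenario)  # (n_cells, 4)
        z = (clim[None, :, :] - self.optima[:, None, :]) / self.breadths[:, None, :]
        suit = self.max_occupancy[:, None] * np.exp(-0.5 * np.nansum(z**2, axis=2))
        suit[:, ~climate.grid.mask] = np.nan
        return suit


# Default spatial structure of the current climate: rough magnitudes of
# the four bioclimatic variables over a subtropical forest domain.
DEFAULT_GRADIENT_PARAMS: dict = {
    "base": (22.0, 2500.0, 1400.0, 45.0),
    "ns_gradient": (-8.0, 1500.0, -300.0, 20.0),  # cooler, more seasonal north->south
    "ew_gradient": (1.5, -500.0, 500.0, -10.0),
    "noise_sd": (0.8, 150.0, 120.0, 4.0),
    "correlation_length": 3.0,  # cells; Gaussian-filter sigma of the random field
}


def generate_climate(
    grid: Grid,
    seed: int,
    gradient_params: Mapping | None = None,
    deltas: Sequence[ScenarioDelta] = (),
) -> ClimateLayers:
    """Generate a current climate plus one future scenario per delta.

    The current layer of each variable is ``base + gradients + GRF``
    where the Gaussian random field is white noise smoothed with a
    Gaussian kernel of ``correlation_length`` cells and rescaled to
    ``noise_sd``. Each future scenario is exactly ``current + delta``.
    """
    if not deltas:
        raise ValueError("at least one future delta must be supplied")
    p = dict(DEFAULT_GRADIENT_PARAMS)
    if gradient_params:
        p.update(gradient_params)
    rng = np.random.default_rng(seed)

    rows = np.arange(grid.n_cells) // grid.n_cols
    cols = np.arange(grid.n_cells) % grid.n_cols
    ns = (rows + 0.5) / grid.n_rows - 0.5
    ew = (cols + 0.5) / grid.n_cols - 0.5

    current = np.empty((grid.n_cells, N_VARS))
    sigma = float(p["correlation_length"])
    for v in range(N_VARS):
        white = rng.standard_normal((grid.n_rows, grid.n_cols))
        smooth = gaussian_filter(white, sigma=sigma, mode="reflect")
        sd = smooth.std()
        noise = smooth.ravel() / sd * p["noise_sd"][v] if sd > 0 else 0.0
        current[:, v] = (
            p["base"][v] + p["ns_gradient"][v] * ns + p["ew_gradient"][v] * ew + noise
        )
    current[~grid.mask] = np.nan

    scenarios: dict[str, np.ndarray] = {"current": current}
    for delta in deltas:
        fut = current + delta.field_on(grid)
        fut[~grid.mask] = np.nan
        scenarios[delta.name] = fut
    return ClimateLayers(grid, scenarios)


DEFAULT_NICHE_HYPERPARAMS: dict = {
    "breadth_factor_range": (0.3, 0.9),  # niche SD as a fraction of the climate SD
    "max_occupancy_range": (0.6, 0.95),
}


def generate_species(
    n_species: int,
    grid: Grid,
    climate: ClimateLayers,
    niche_hyperparams: Mapping | None = None,
    seed: int = 0,
) -> NicheTruth:
    """Draw Gaussian niches anchored on realized current climate.

    Optima are the current climate values of randomly chosen mask-true
    cells, guaranteeing each species has suitable habitat somewhere in
    the region. Breadths are per-variable fractions of the masked
    climate SD, drawn uniformly from ``breadth_factor_range``.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    hp = dict(DEFAULT_NICHE_HYPERPARAMS)
    if niche_hyperparams:
        hp.update(niche_hyperparams)
    rng = np.random.default_rng(seed)

    masked = climate.masked_values(climate.current)
    clim_sd = masked.std(axis=0)
    clim_sd[clim_sd == 0] = 1.0
    anchor = rng.integers(0, masked.shape[0], size=n_species)
    optima = masked[anchor]
    factors = rng.uniform(*hp["breadth_factor_range"], size=(n_species, N_VARS))
    breadths = factors * clim_sd
    pmax = rng.uniform(*hp["max_occupancy_range"], size=n_species)
    width = len(str(n_species))
    ids = tuple(f"sp{i + 1:0{width}d}" for i in range(n_species))
    return NicheTruth(ids, optima, breadths, pmax)


def sample_occurrences(
    truth: NicheTruth,
    climate: ClimateLayers,
    grid: Grid,
    effort_per_species: int = 60,
    bias_params: Mapping | None = None,
    seed: int = 0,
) -> OccurrenceSet:
    """Sample presence-only records under uneven collection effort.

    For each species, ``effort_per_species`` records are allocated over
    mask-true cells with probability proportional to true suitability
    times an optional spatial effort surface (``bias_params`` may give
    an ``ew_bias`` b: effort multiplied by ``exp(b * ew)`` with ew in
    [-0.5, 0.5], emulating accessibility bias). Points are jittered
    uniformly within their cell; collection years span 1920-2008.
    """
    if effort_per_species < 1:
        raise ValueError("effort_per_species must be >= 1")
    rng = np.random.default_rng(seed)
    suit = truth.true_suitability(climate)  # (n_species, n_cells)
    masked_ids = grid.masked_ids

    effort = np.ones(masked_ids.size)
    if bias_params and bias_params.get("ew_bias"):
        cols = masked_ids % grid.n_cols
        ew = (cols + 0.5) / grid.n_cols - 0.5
        effort = np.exp(float(bias_params["ew_bias"]) * ew)

    records: list[tuple[str, float, float, int]] = []
    half = grid.cell_size / 2.0
    for i, sp in enumerate(truth.species_ids):
        w = suit[i, masked_ids] * effort
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            continue
        counts = rng.multinomial(effort_per_species, w / total)
        hit = np.nonzero(counts)[0]
        for j in hit:
            cid = int(masked_ids[j])
            cx, cy = grid.cell_center(cid)
            for _ in range(int(counts[j])):
                x = float(cx) + rng.uniform(-half, half)
                y = float(cy) + rng.uniform(-half, half)
                records.append((sp, x, y, int(rng.integers(1920, 2009))))
    return OccurrenceSet(tuple(records))


def generate_protected_areas(
    grid: Grid,
    n_pa: int,
    size_distribution: Sequence[int] | Mapping | None = None,
    seed: int = 0,
    max_retries: int = 1000,
) -> list[PAFootprint]:
    """Grow ``n_pa`` non-overlapping connected footprints on the mask.

    ``size_distribution`` is either an explicit sequence of cell counts
    (length ``n_pa``) or a mapping ``{"lognormal": {"mean_log": m,
    "sd_log": s}}``; sizes are clipped to at least 1 cell. Footprints
    are grown by seeded accretion: a random free mask cell is the seed,
    then free 4-neighbours of the growing set are added at random until
    the target size is reached. A blocked growth attempt is restarted
    elsewhere; after ``max_retries`` failed attempts an error is raised.
    """
    if n_pa < 1:
        raise ValueError("n_pa must be >= 1")
    rng = np.random.default_rng(seed)
    if size_distribution is None:
        sizes = np.maximum(1, np.round(rng.lognormal(1.2, 0.7, size=n_pa))).astype(int)
    elif isinstance(size_distribution, Mapping):
        p = size_distribution["lognormal"]
        sizes = np.maximum(
            1, np.round(rng.lognormal(p["mean_log"], p["sd_log"], size=n_pa))
        ).astype(int)
    else:
        sizes = np.asarray(list(size_distribution), dtype=int)
        if sizes.size != n_pa:
            raise ValueError("size_distribution length must equal n_pa")
        if np.any(sizes < 1):
            raise ValueError("footprint sizes must be >= 1")

    occupied = np.zeros(grid.n_cells, dtype=bool)
    footprints: list[PAFootprint] = []
    width = len(str(n_pa))
    for k, size in enumerate(sizes):
        cells = _grow_footprint(grid, occupied, int(size), rng, max_retries)
        occupied[list(cells)] = True
        footprints.append(
            PAFootprint.from_cells(f"pa{k + 1:0{width}d}", cells, grid, source="synthetic")
        )
    return footprints


def _grow_footprint(
    grid: Grid, occupied: np.ndarray, size: int, rng: np.random.Generator, max_retries: int
) -> set[int]:
    free = np.flatnonzero(grid.mask & ~occupied)
    for _ in range(max_retries):
        if free.size < size:
            break
        seed_cell = int(rng.choice(free))
        cells = {seed_cell}
        frontier = set(_free_neighbours(seed_cell, grid, occupied, cells))
        ok = True
        while len(cells) < size:
            if not frontier:
                ok = False
                break
            nxt = int(rng.choice(sorted(frontier)))
            cells.add(nxt)
            frontier.discard(nxt)
            frontier.update(_free_neighbours(nxt, grid, occupied, cells))
        if ok:
            return cells
    raise RuntimeError(f"could not place a footprint of {size} cells after {max_retries} retries")


def _free_neighbours(cid: int, grid: Grid, occupied: np.ndarray, taken: set[int]):
    row, col = cid // grid.n_cols, cid % grid.n_cols
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        r, c = row + dr, col + dc
        if 0 <= r < grid.n_rows and 0 <= c < grid.n_cols:
            n = r * grid.n_cols + c
            if grid.mask[n] and not occupied[n] and n not in taken:
                yield n
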