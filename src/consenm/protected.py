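"""Protected-area overlay, richness, relocation null model, and
gain/loss classification.

A protected area (PA) lives on the analysis grid as a *footprint*: the
set of cells any portion of which its polygon touches (deliberately
more inclusive than the cell-center rule used for the study-region
mask — a species in a partially protected cell can still benefit from
the reserve). Footprints are stored as offsets from an anchor cell so
they can be relocated rigidly — same size, shape and orientation — for
the null model: each PA is repeatedly dropped at a uniformly random
position inside the study region, and the richness it would capture
there gives the expectation under arbitrary placement. A PA whose
projected future richness falls below even that random-placement
expectation is flagged as a severe loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import Grid

try:
    from shapely.geometry import box as _box
except ImportError:  # pragma: no cover
    _box = None

#: Relative area tolerance for the any-portion intersection rule, as a
#: fraction of the cell area; guards against floating-point slivers.
AREA_TOLERANCE = 1e-9

GAIN = "gain"
MILD_LOSS = "mild_loss"
SEVERE_LOSS = "severe_loss"


@dataclass(frozen=True)
class PAFootprint:
    """A protected area as cell offsets around an anchor cell.

    ``offsets`` are ``(d_row, d_col)`` pairs including ``(0, 0)``;
    connectivity is not required (real reserves can be multi-part).
    """

    pa_id: str
    anchor_cell: int
    offsets: frozenset
    source: str = "real-polygon"

    def __post_init__(self) -> None:
        if (0, 0) not in self.offsets:
            raise ValueError("offsets must include the anchor (0, 0)")

    def __len__(self) -> int:
        return len(self.offsets)

    @classmethod
    def from_cells(cls, pa_id: str, cells: Iterable[int], grid: Grid,
                   source: str = "real-polygon") -> "PAFootprint":
        """Build a footprint from realized cell ids.

        The anchor is the north-westernmost cell (northernmost row,
        then westernmost column; row 0 is south).
        """
        cells = sorted(set(int(c) for c in cells))
        if not cells:
            raise ValueError("footprint needs at least one cell")
        rc = [(c // grid.n_cols, c % grid.n_cols) for c in cells]
        anchor_row, anchor_col = max(rc, key=lambda t: (t[0], -t[1]))
        offsets = frozenset((r - anchor_row, c - anchor_col) for r, c in rc)
        return cls(pa_id, anchor_row * grid.n_cols + anchor_col, offsets, source)

    def cells_on(self, grid: Grid, anchor_cell: int | None = None) -> np.ndarray:
        """Realized cell ids at ``anchor_cell`` (default: home anchor).

        Raises ``ValueError`` if any cell falls off the grid or on a
        mask-false cell.
        """
        anchor = self.anchor_cell if anchor_cell is None else int(anchor_cell)
        ar, ac = anchor // grid.n_cols, anchor % grid.n_cols
        ids = []
        for dr, dc in self.offsets:
            r, c = ar + dr, ac + dc
            if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                raise ValueError(f"footprint {self.pa_id} leaves the grid at anchor {anchor}")
            cid = r * grid.n_cols + c
            if not grid.mask[cid]:
                raise ValueError(f"footprint {self.pa_id} touches a mask-false cell")
            ids.append(cid)
        return np.array(sorted(ids), dtype=np.int64)

    def fits_at(self, grid: Grid, anchor_cell: int) -> bool:
        ar, ac = anchor_cell // grid.n_cols, anchor_cell % grid.n_cols
        for dr, dc in self.offsets:
            r, c = ar + dr, ac + dc
            if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                return False
            if not grid.mask[r * grid.n_cols + c]:
                return False
        return True


@dataclass(frozen=True)
class NullRegression:
    """Least-squares line ``future ~ present`` over per-PA null means."""

    intercept: float
    slope: float

    def predict(self, present_richness: float) -> float:
        return self.intercept + self.slope * float(present_richness)


@dataclass(frozen=True)
class PARichnessRecord:
    pa_id: str
    n_cells: int
    present_richness: int
    future_richness: int
    null_present_mean: float
    null_future_mean: float
    category: str | None = None


def overlay_pas(polygons: Sequence, grid: Grid) -> list[PAFootprint]:
    """Rasterize PA polygons to footprints with the any-portion rule.

    A cell belongs to a PA iff the polygon intersects the cell's
    rectangle with positive area (> ``AREA_TOLERANCE`` x cell area).
    Cells outside the study-region mask are not part of footprints.
    Polygons yielding no cells are dropped with a warning.

    ``polygons`` is a sequence of shapely geometries or
    ``(geometry, properties)`` pairs as returned by
    :func:`consenm.grid.read_geojson_geometries`; a ``pa_id`` or
    ``name`` property names the footprint.
    """
    footprints: list[PAFootprint] = []
    min_area = AREA_TOLERANCE * grid.cell_size**2
    x0, y0 = grid.origin
    for k, item in enumerate(polygons):
        geom, props = item if isinstance(item, tuple) else (item, {})
        pa_id = str(props.get("pa_id") or props.get("name") or f"pa{k + 1:03d}")
        gxmin, gymin, gxmax, gymax = geom.bounds
        c0 = max(0, int(np.floor((gxmin - x0) / grid.cell_size)))
        c1 = min(grid.n_cols - 1, int(np.floor((gxmax - x0) / grid.cell_size)))
        r0 = max(0, int(np.floor((gymin - y0) / grid.cell_size)))
        r1 = min(grid.n_rows - 1, int(np.floor((gymax - y0) / grid.cell_size)))
        cells = []
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                cid = r * grid.n_cols + c
                if not grid.mask[cid]:
                    continue
                xmin, ymin, xmax, ymax = grid.cell_bounds(cid)
                if geom.intersection(_box(xmin, ymin, xmax, ymax)).area > min_area:
                    cells.append(cid)
        if not cells:
            warnings.warn(f"protected area {pa_id!r} covers no study-region cell; dropped")
            continue
        footprints.append(PAFootprint.from_cells(pa_id, cells, grid))
    return footprints


def pa_richness(footprint: PAFootprint, occupancy: np.ndarray, grid: Grid,
                anchor_cell: int | None = None) -> int:
    """Species richness a footprint captures: the number of species
    whose binary range intersects any of its cells (union rule).

    ``occupancy`` is a boolean species-by-cell matrix, e.g. from
    :func:`consenm.ensemble.binary_stack`.
    """
    cells = footprint.cells_on(grid, anchor_cell)
    if cells.size == 0:
        return 0
    return int(occupancy[:, cells].any(axis=1).sum())


def relocate_footprint(footprint: PAFootprint, grid: Grid,
                       seed: int | np.random.Generator = 0,
                       max_retries: int = 10_000) -> PAFootprint:
    """Rigidly relocate a footprint to a uniformly random valid anchor.

    Anchor cells are drawn uniformly from mask-true cells by rejection
    sampling: the first draw at which every offset cell is inside the
    grid and mask-true is accepted. No rotation or reflection — size,
    shape and orientation are preserved exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    masked = grid.masked_ids
    for _ in range(max_retries):
        anchor = int(rng.choice(masked))
        if footprint.fits_at(grid, anchor):
            return replace(footprint, anchor_cell=anchor)
    raise RuntimeError(
        f"footprint {footprint.pa_id} could not be placed after {max_retries} draws"
    )


def null_model(
    footprints: Sequence[PAFootprint],
    occupancy_current: np.ndarray,
    occupancy_future: np.ndarray,
    grid: Grid,
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[list[PARichnessRecord], NullRegression]:
    """Random-relocation null model of protected-area placement.

    Per replicate, every footprint is independently relocated (relocated
    footprints may overlap one another) and its present and future
    richness recorded; per PA, the mean over replicates is the null
    expectation. A least-squares line ``future ~ present`` through the
    per-PA null means is returned alongside — the baseline that
    classification compares observed future richness against.

    The returned records carry the *observed* (home-position) richness
    together with the null means; ``category`` is left unset until
    :func:`classify_pas`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n_pa = len(footprints)
    sum_p = np.zeros(n_pa)
    sum_f = np.zeros(n_pa)
    for _ in range(n_reps):
        for i, fp in enumerate(footprints):
            moved = relocate_footprint(fp, grid, rng)
            cells = moved.cells_on(grid)
            sum_p[i] += occupancy_current[:, cells].any(axis=1).sum()
            sum_f[i] += occupancy_future[:, cells].any(axis=1).sum()
    null_p = sum_p / n_reps
    null_f = sum_f / n_reps

    A = np.column_stack([np.ones(n_pa), null_p])
    coef, *_ = np.linalg.lstsq(A, null_f, rcond=None)
    regression = NullRegression(intercept=float(coef[0]), slope=float(coef[1]))

    records = []
    for i, fp in enumerate(footprints):
        records.append(
            PARichnessRecord(
                pa_id=fp.pa_id,
                n_cells=len(fp),
                present_richness=pa_richness(fp, occupancy_current, grid),
                future_richness=pa_richness(fp, occupancy_future, grid),
                null_present_mean=float(null_p[i]),
                null_future_mean=float(null_f[i]),
            )
        )
    return records, regression


def classify_pas(records: Sequence[PARichnessRecord],
                 null_regression: NullRegression) -> list[PARichnessRecord]:
    """Assign each PA to gain / mild_loss / severe_loss.

    * ``gain`` — future richness exceeds present richness;
    * ``severe_loss`` — future richness is below even the null
      regression's prediction for a randomly placed PA of the same
      present richness;
    * ``mild_loss`` — everything else (losing species, but no worse
      than random placement).
    """
    out = []
    for rec in records:
        if rec.future_richness > rec.present_richness:
            cat = GAIN
        elif rec.future_richness < null_regression.predict(rec.present_richness):
            cat = SEVERE_LOSS
        else:
            cat = MILD_LOSS
        out.append(replace(rec, category=cat))
    return out


def write_pa_records_csv(records: Sequence[PARichnessRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "pa_id": r.pa_id,
                "n_cells": r.n_cells,
                "present_richness": r.present_richness,
                "future_richness": r.future_richness,
                "null_present_mean": r.null_present_mean,
                "null_future_mean": r.null_future_mean,
                "category": r.category,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
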