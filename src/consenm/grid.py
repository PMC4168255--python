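"""Analysis grid, occurrence gridding, and plain-text spatial I/O.

The whole pipeline works on an equal-area lattice of square cells
(10 km x 10 km in the motivating study system). Every spatial layer —
climate, suitability, richness — is a vector indexed by 0-based
row-major cell id, with row 0 at the *south* edge. Cell intervals are
half-open, ``[x, x + cell_size) x [y, y + cell_size)``, so each point
belongs to exactly one cell. The study region is a boolean mask over
the lattice: a cell is inside the region iff its *center* falls inside
the mask geometry (the protected-area overlay deliberately uses a
different, any-portion rule; see :mod:`consenm.protected`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

try:  # shapely is only needed for polygon mask sources / GeoJSON
    from shapely.geometry import Point, shape as _geojson_shape
    from shapely.geometry.base import BaseGeometry
except ImportError:  # pragma: no cover
    BaseGeometry = ()  # type: ignore[assignment]

#: Sentinel returned by :func:`point_to_cell` for points outside the
#: grid extent or on mask-false cells.
OUTSIDE: int = -1


@dataclass(frozen=True)
class Grid:
    """Equal-area analysis lattice with a study-region mask.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions; row 0 is the southernmost row.
    cell_size
        Cell edge length in projected map units (meters, km, ...).
    origin
        ``(x0, y0)`` of the lower-left (south-west) corner.
    mask
        Flat boolean array of length ``n_rows * n_cols`` in row-major
        order; True marks cells inside the study region.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        mask = np.asarray(self.mask, dtype=bool).ravel()
        if mask.size != self.n_rows * self.n_cols:
            raise ValueError("mask length does not match n_rows * n_cols")
        if not mask.any():
            raise ValueError("no study-region cells")
        object.__setattr__(self, "mask", mask)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def masked_ids(self) -> np.ndarray:
        """Ids of the mask-true cells, ascending."""
        return np.flatnonzero(self.mask)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def rowcol(self, cell_id: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_id(self, row: int | np.ndarray, col: int | np.ndarray) -> np.ndarray:
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def cell_center(self, cell_id: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        row, col = self.rowcol(cell_id)
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.cell_size,
            y0 + (row + 0.5) * self.cell_size,
        )

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """``(xmin, ymin, xmax, ymax)`` of a cell's rectangle."""
        row, col = self.rowcol(cell_id)
        x0, y0 = self.origin
        xmin = x0 + float(col) * self.cell_size
        ymin = y0 + float(row) * self.cell_size
        return xmin, ymin, xmin + self.cell_size, ymin + self.cell_size


@dataclass(frozen=True)
class OccurrenceSet:
    """Point occurrence records: ``(species_id, x, y, year)`` tuples.

    The collection year is carried through for provenance but applies
    no temporal filter anywhere in the pipeline.
    """

    records: tuple[tuple[str, float, float, int], ...]

    def __post_init__(self) -> None:
        for sp, x, y, _year in self.records:
            if not sp:
                raise ValueError("species_id must be non-empty")
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite coordinate for species {sp!r}")

    @property
    def species_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp, *_ in self.records:
            seen.setdefault(sp)
        return list(seen)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class PresenceMatrix:
    """Species-by-cell binary occurrence matrix after gridding.

    ``cells[sp]`` is the sorted array of mask-true cell ids where
    species ``sp`` was recorded; every retained species occupies at
    least ``min_occurrences`` cells. ``n_dropped`` counts the species
    excluded by that filter.
    """

    species_ids: tuple[str, ...]
    cells: Mapping[str, np.ndarray]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.species_ids)

    def occupancy(self, grid: Grid) -> np.ndarray:
        """Dense boolean matrix, species x cells."""
        out = np.zeros((len(self.species_ids), grid.n_cells), dtype=bool)
        for i, sp in enumerate(self.species_ids):
            out[i, self.cells[sp]] = True
        return out

    def to_occurrences(self, grid: Grid, year: int = 2000) -> OccurrenceSet:
        """Re-express the matrix as point records at cell centers."""
        recs = []
        for sp in self.species_ids:
            xs, ys = grid.cell_center(self.cells[sp])
            recs.extend(
                (sp, float(x), float(y), year) for x, y in zip(np.atleast_1d(xs), np.atleast_1d(ys))
            )
        return OccurrenceSet(tuple(recs))


def build_grid(
    extent: tuple[float, float, float, float],
    cell_size: float,
    mask_source=None,
) -> Grid:
    """Lay an equal-area cell lattice over ``extent`` and mask it.

    Parameters
    ----------
    extent
        ``(xmin, ymin, xmax, ymax)`` in projected coordinates.
    cell_size
        Cell edge length; the lattice is extended with partial cells if
        the extent is not an exact multiple.
    mask_source
        ``None`` (whole extent in-region), a shapely geometry (a cell is
        in-region iff its center is covered by the geometry), or a
        boolean array of shape ``(n_rows, n_cols)`` / flat length.

    Raises
    ------
    ValueError
        On a degenerate extent or cell size, or if the mask leaves no
        study-region cells.
    """
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent must satisfy xmax > xmin and ymax > ymin")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    n_cols = int(math.ceil((xmax - xmin) / cell_size - 1e-12))
    n_rows = int(math.ceil((ymax - ymin) / cell_size - 1e-12))

    if mask_source is None:
        mask = np.ones(n_rows * n_cols, dtype=bool)
    elif isinstance(mask_source, BaseGeometry):
        ids = np.arange(n_rows * n_cols)
        rows, cols = ids // n_cols, ids % n_cols
        cx = xmin + (cols + 0.5) * cell_size
        cy = ymin + (rows + 0.5) * cell_size
        mask = np.fromiter(
            (mask_source.covers(Point(x, y)) for x, y in zip(cx, cy)),
            dtype=bool,
            count=ids.size,
        )
    else:
        mask = np.asarray(mask_source, dtype=bool).ravel()
        if mask.size != n_rows * n_cols:
            raise ValueError("boolean mask_source has the wrong size")
    if not mask.any():
        raise ValueError("no study-region cells")
    return Grid(n_rows, n_cols, float(cell_size), (float(xmin), float(ymin)), mask)


def point_to_cell(x: float, y: float, grid: Grid) -> int:
    """Cell id containing ``(x, y)``, or :data:`OUTSIDE`.

    Half-open cells: a point on the shared edge of two cells belongs to
    the cell on its east/north side. Mask-false cells also map to
    :data:`OUTSIDE`.
    """
    x0, y0 = grid.origin
    col = math.floor((x - x0) / grid.cell_size)
    row = math.floor((y - y0) / grid.cell_size)
    if not (0 <= col < grid.n_cols and 0 <= row < grid.n_rows):
        return OUTSIDE
    cid = row * grid.n_cols + col
    return cid if grid.mask[cid] else OUTSIDE


def build_presence_matrix(
    occ: OccurrenceSet,
    grid: Grid,
    min_occurrences: int = 5,
) -> PresenceMatrix:
    """Grid occurrence points into a presence matrix.

    Duplicate records within a cell collapse to a single presence, and
    species occupying fewer than ``min_occurrences`` cells are dropped
    (the classic minimum-record filter against unmodellable species).
    Records falling outside the grid or the study-region mask are
    ignored.

    Raises
    ------
    ValueError
        If every species is dropped ("no modellable species").
    """
    by_species: dict[str, set[int]] = {}
    for sp, x, y, _year in occ.records:
        by_species.setdefault(sp, set())
        cid = point_to_cell(x, y, grid)
        if cid != OUTSIDE:
            by_species[sp].add(cid)

    retained: dict[str, np.ndarray] = {}
    n_dropped = 0
    for sp, cids in by_species.items():
        if len(cids) >= min_occurrences:
            retained[sp] = np.array(sorted(cids), dtype=np.int64)
        else:
            n_dropped += 1
    if not retained:
        raise ValueError("no modellable species")
    return PresenceMatrix(tuple(retained), retained, n_dropped)


# ---------------------------------------------------------------------------
# Plain-text I/O

def read_occurrences_csv(path) -> OccurrenceSet:
    """Read a ``species_id,x,y,year`` CSV into an :class:`OccurrenceSet`."""
    df = pd.read_csv(path, dtype={"species_id": str})
    required = {"species_id", "x", "y", "year"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    return OccurrenceSet(
        tuple(
            (str(r.species_id), float(r.x), float(r.y), int(r.year))
            for r in df.itertuples(index=False)
        )
    )


def write_occurrences_csv(occ: OccurrenceSet, path) -> None:
    pd.DataFrame(occ.records, columns=["species_id", "x", "y", "year"]).to_csv(
        path, index=False
    )


def write_grid_text(values: np.ndarray, grid: Grid, path) -> None:
    """Dump a per-cell layer as the internal plain-text grid format.

    Header line ``n_rows,n_cols,x0,y0,cell_size`` followed by the
    row-major values (NaN for cells outside the mask), one row per line.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size != grid.n_cells:
        raise ValueError("layer length does not match grid")
    with open(path, "w") as fh:
        x0, y0 = grid.origin
        fh.write(f"{grid.n_rows},{grid.n_cols},{x0},{y0},{grid.cell_size}\n")
        for row in values.reshape(grid.n_rows, grid.n_cols):
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")


def read_grid_text(path) -> tuple[np.ndarray, Grid]:
    """Inverse of :func:`write_grid_text`.

    The returned grid's mask is inferred as the non-NaN cells.
    """
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        n_rows, n_cols = int(header[0]), int(header[1])
        x0, y0, cell_size = float(header[2]), float(header[3]), float(header[4])
        values = np.loadtxt(fh, dtype=float).reshape(n_rows * n_cols)
    mask = ~np.isnan(values)
    grid = Grid(n_rows, n_cols, cell_size, (x0, y0), mask)
    return values, grid


def read_geojson_geometries(path) -> list:
    """Load the shapely geometries of a GeoJSON file (Feature,
    FeatureCollection or bare geometry), with feature properties
    attached as ``(geometry, properties)`` pairs."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        feats = doc["features"]
    elif doc.get("type") == "Feature":
        feats = [doc]
    else:
        feats = [{"geometry": doc, "properties": {}}]
    return [(_geojson_shape(f["geometry"]), f.get("properties") or {}) for f in feats]


def write_surface_csv(values: np.ndarray, path, column: str = "value") -> None:
    """Write a per-cell layer as ``cell_id,<column>`` CSV (masked cells only)."""
    values = np.asarray(values, dtype=float).ravel()
    keep = ~np.isnan(values)
    pd.DataFrame({"cell_id": np.flatnonzero(keep), column: values[keep]}).to_csv(
        path, index=False
    )
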