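"""Community summaries of consensus ranges: richness, temporal
turnover, and per-species range contraction.

Richness in a cell is simply the number of consensus ranges overlapping
it. Turnover between the current and future assemblage of a cell is

    turnover = (G + L) / (S + G)

with S the current richness, G the species gained and L the species
lost: 0 means an unchanged assemblage, 1 complete replacement, and the
statistic is undefined (reported as missing, not zero) where a cell
hosts no species in either timeframe. Range contraction per species is
the percent reduction of the occupied-cell count from the current to
the future consensus range; negative values are expansions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import ConsensusSurface, binary_stack


@dataclass(frozen=True)
class RichnessMap:
    counts: np.ndarray  # per-cell int
    timeframe: str
    method_set: str


@dataclass(frozen=True)
class TurnoverMap:
    """Per-cell turnover in [0, 1]; NaN where S + G = 0."""

    values: np.ndarray
    S: np.ndarray
    G: np.ndarray
    L: np.ndarray


def richness(consensus_list: Sequence[ConsensusSurface]) -> RichnessMap:
    """Sum of overlapping consensus ranges per cell.

    All surfaces must share a timeframe and method set. An empty list
    is legal only through the explicit empty-assemblage constructor
    below, so mixed inputs are caught rather than silently pooled.
    """
    if not consensus_list:
        raise ValueError("empty consensus list; use empty_richness for a zero map")
    timeframes = {c.timeframe for c in consensus_list}
    method_sets = {c.method_set for c in consensus_list}
    if len(timeframes) > 1:
        raise ValueError(f"mixed timeframes {sorted(timeframes)} in one richness map")
    if len(method_sets) > 1:
        raise ValueError(f"mixed method sets {sorted(method_sets)} in one richness map")
    counts = binary_stack(consensus_list).sum(axis=0).astype(int)
    return RichnessMap(counts, timeframes.pop(), method_sets.pop())


def empty_richness(n_cells: int, timeframe: str = "current", method_set: str = "") -> RichnessMap:
    return RichnessMap(np.zeros(n_cells, dtype=int), timeframe, method_set)


def turnover(
    current: Sequence[ConsensusSurface] | np.ndarray,
    future: Sequence[ConsensusSurface] | np.ndarray,
) -> TurnoverMap:
    """Per-cell compositional turnover (G + L) / (S + G).

    Accepts either matching lists of consensus surfaces (same species
    order) or precomputed boolean species-by-cell matrices.
    """
    cur = current if isinstance(current, np.ndarray) else binary_stack(current)
    fut = future if isinstance(future, np.ndarray) else binary_stack(future)
    if cur.shape != fut.shape:
        raise ValueError("current and future stacks must have identical shape")
    S = cur.sum(axis=0)
    G = (fut & ~cur).sum(axis=0)
    L = (cur & ~fut).sum(axis=0)
    denom = S + G
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, (G + L) / np.maximum(denom, 1), np.nan)
    return TurnoverMap(values=values, S=S, G=G, L=L)


def range_contraction(current_range: np.ndarray | int, future_range: np.ndarray | int) -> float:
    """Percent range contraction, ``100 * (|current| - |future|) /
    |current|``; negative for expansions.

    Arguments may be boolean range arrays or occupied-cell counts.
    """
    n_cur = int(current_range.sum()) if isinstance(current_range, np.ndarray) else int(current_range)
    n_fut = int(future_range.sum()) if isinstance(future_range, np.ndarray) else int(future_range)
    if n_cur < 1:
        raise ValueError("range contraction undefined for an empty current range")
    return 100.0 * (n_cur - n_fut) / n_cur


def turnover_table(tm: TurnoverMap) -> pd.DataFrame:
    """Per-cell table (cell_id, S, G, L, turnover), masked cells only."""
    keep = (tm.S + tm.G) > 0
    return pd.DataFrame(
        {
            "cell_id": np.flatnonzero(keep),
            "S": tm.S[keep],
            "G": tm.G[keep],
            "L": tm.L[keep],
            "turnover": tm.values[keep],
        }
    )


def contraction_table(
    current: Sequence[ConsensusSurface], future: Sequence[ConsensusSurface]
) -> pd.DataFrame:
    """Per-species range sizes and percent contraction."""
    rows = []
    for c, f in zip(current, future):
        if c.species_id != f.species_id:
            raise ValueError("current/future surfaces must be paired by species")
        n_cur = c.range_size
        rows.append(
            {
                "species_id": c.species_id,
                "current_range": n_cur,
                "future_range": f.range_size,
                "contraction_pct": range_contraction(n_cur, f.range_size) if n_cur else np.nan,
            }
        )
    return pd.DataFrame(rows)
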