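"""TSS-weighted consensus of many binary projections.

Per species and method set (distance vs machine-learning), every
thresholded projection casts a vote for each cell, weighted by its TSS
so that more skilful models count for more; negative-TSS models
(worse than random) are clipped to weight zero. A cell belongs to the
consensus range when the weighted frequency of votes reaches 50%
(inclusive), and the continuous weighted frequency is retained there.

The bookkeeping mirrors the ensemble arithmetic of the underlying
design: with 3 methods x 10 data partitions the current-climate
consensus pools exactly 30 projections per species per method set, and
with 3 future climate models the future consensus pools 90 — one flat
TSS-weighted vote, with each future projection carrying its model's
current-climate TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evaluation import EvaluatedProjection
from .models import METHOD_SETS

CONSENSUS_THRESHOLD = 0.5  # "50% or more": inclusive


@dataclass(frozen=True)
class ConsensusSurface:
    """TSS-weighted projection frequency and the >= 50% binary range."""

    species_id: str
    method_set: str
    timeframe: str  # "current" | "future"
    weighted_frequency: np.ndarray  # per cell in [0, 1], NaN off-mask
    binary_range: np.ndarray  # boolean per cell

    @property
    def retained_continuous(self) -> np.ndarray:
        """Weighted frequency kept only inside the binary range."""
        out = np.where(self.binary_range, self.weighted_frequency, np.nan)
        return out

    @property
    def range_size(self) -> int:
        return int(self.binary_range.sum())


def weighted_consensus(
    projections: Sequence[EvaluatedProjection],
    weights: Sequence[float],
    species_id: str | None = None,
    method_set: str = "",
    timeframe: str = "current",
    mask: np.ndarray | None = None,
) -> ConsensusSurface:
    """Weighted vote of binary projections.

    ``weighted_frequency(c) = sum_j w_j * [c in range_j] / sum_j w_j``
    with weights (TSS values) clipped below at zero; raises if no
    model has positive skill.
    """
    if len(projections) == 0 or len(projections) != len(weights):
        raise ValueError("need equally many projections and weights, at least one")
    w = np.clip(np.asarray(weights, dtype=float), 0.0, None)
    if w.sum() <= 0:
        raise ValueError("no skilful model: all weights <= 0")
    votes = np.stack([p.binary_range for p in projections]).astype(float)
    freq = np.clip((w[:, None] * votes).sum(axis=0) / w.sum(), 0.0, 1.0)
    if mask is None:
        mask = ~np.isnan(projections[0].continuous)
    freq = np.where(mask, freq, np.nan)
    with np.errstate(invalid="ignore"):
        binary = np.nan_to_num(freq, nan=-1.0) >= CONSENSUS_THRESHOLD
    return ConsensusSurface(
        species_id=species_id or projections[0].species_id,
        method_set=method_set,
        timeframe=timeframe,
        weighted_frequency=freq,
        binary_range=binary,
    )


class ProjectionStore:
    """Keyed archive of evaluated projections:
    ``(species_id, method, replicate, scenario)`` -> projection."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, str, int, str], EvaluatedProjection] = {}

    def add(self, proj: EvaluatedProjection) -> None:
        self._store[(proj.species_id, proj.method, proj.replicate, proj.scenario)] = proj

    def get(self, species_id: str, method: str, replicate: int, scenario: str):
        return self._store.get((species_id, method, replicate, scenario))

    def __len__(self) -> int:
        return len(self._store)

    def collect(
        self,
        species_id: str,
        methods: Sequence[str],
        replicates: Sequence[int],
        scenarios: Sequence[str],
    ) -> list[EvaluatedProjection]:
        """All projections for the cross product, erroring on any gap."""
        out, missing = [], []
        for m in methods:
            for r in replicates:
                for s in scenarios:
                    p = self.get(species_id, m, r, s)
                    (out if p is not None else missing).append(
                        p if p is not None else (species_id, m, r, s)
                    )
        if missing:
            raise ValueError(f"missing projections: {missing}")
        return out


def assemble_current(
    store: ProjectionStore,
    species_id: str,
    method_set: str,
    n_reps: int = 10,
    current_scenario: str = "current",
    mask: np.ndarray | None = None,
) -> ConsensusSurface:
    """Consensus of the full methods x replicates pool under current
    climate (3 methods x 10 replicates = 30 projections by default)."""
    methods = METHOD_SETS[method_set]
    pool = store.collect(species_id, methods, range(n_reps), [current_scenario])
    return weighted_consensus(
        pool, [p.tss for p in pool],
        species_id=species_id, method_set=method_set, timeframe="current", mask=mask,
    )


def assemble_future(
    store: ProjectionStore,
    species_id: str,
    method_set: str,
    future_scenarios: Sequence[str],
    n_reps: int = 10,
    mask: np.ndarray | None = None,
) -> ConsensusSurface:
    """One flat consensus pooling methods x climate models x replicates
    (3 x 3 x 10 = 90 projections with three future GCMs).

    Each projection's weight is its model's current-climate TSS.
    """
    if not future_scenarios:
        raise ValueError("at least one future scenario required")
    methods = METHOD_SETS[method_set]
    pool = store.collect(species_id, methods, range(n_reps), list(future_scenarios))
    return weighted_consensus(
        pool, [p.tss for p in pool],
        species_id=species_id, method_set=method_set, timeframe="future", mask=mask,
    )


def binary_stack(consensus_list: Sequence[ConsensusSurface]) -> np.ndarray:
    """Species-by-cell boolean occupancy matrix from consensus ranges."""
    return np.stack([c.binary_range for c in consensus_list])


def consensus_manifest(surface: ConsensusSurface,
                       pool: Sequence[EvaluatedProjection]) -> dict:
    """Provenance record of a consensus: the projection pool and weights."""
    return {
        "species_id": surface.species_id,
        "method_set": surface.method_set,
        "timeframe": surface.timeframe,
        "n_projections": len(pool),
        "pool": [
            {"method": p.method, "replicate": p.replicate,
             "scenario": p.scenario, "tss": p.tss}
            for p in pool
        ],
    }
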