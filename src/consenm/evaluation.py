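"""Model evaluation: pseudo-absence drawing, stratified
cross-validation, ROC threshold selection and the True Skill Statistic.

Continuous suitability surfaces are converted to binary ranges at the
score threshold that maximizes sensitivity + specificity on the ROC
curve (the Youden point), and skill is summarized by

    TSS = sensitivity + specificity - 1
        = tp/(tp+fn) + tn/(tn+fp) - 1,

which runs from -1 to +1 (+1 = perfect; <= 0 = no better than random)
and, unlike AUC, does not reward discrimination far from the chosen
threshold nor depend on study-area extent. AUC is deliberately not
computed anywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import Grid
from .models import NicheModel, StandardizedClimate


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def tss(cc: ConfusionCounts) -> float:
    """True Skill Statistic: sensitivity + specificity - 1."""
    if cc.tp + cc.fn == 0 or cc.tn + cc.fp == 0:
        raise ValueError("TSS undefined: one observed class is empty")
    return cc.sensitivity + cc.specificity - 1.0


@dataclass(frozen=True)
class Partition:
    """One replicate of the stratified 75/25 calibration/validation split."""

    replicate: int
    calib_presence: np.ndarray
    calib_absence: np.ndarray
    valid_presence: np.ndarray
    valid_absence: np.ndarray


@dataclass(frozen=True)
class EvaluatedProjection:
    """A thresholded projection of one fitted model onto one scenario.

    The threshold and TSS always come from the *current*-climate
    validation data; future scenarios reuse them unchanged (no future
    truth exists to re-score against).
    """

    species_id: str
    method: str
    replicate: int
    scenario: str
    threshold: float
    tss: float
    binary_range: np.ndarray  # boolean per cell
    continuous: np.ndarray  # suitability per cell, NaN off-mask

    def __post_init__(self) -> None:
        if not -1.0 <= self.tss <= 1.0:
            raise ValueError(f"TSS {self.tss} outside [-1, 1]")


def draw_pseudo_absences(
    grid: Grid,
    presence_cells: Sequence[int],
    n: int | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample pseudo-absence cells uniformly, without replacement, from
    the masked cells not occupied by the species.

    ``n`` defaults to the presence count (prevalence 0.5).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    presence = np.asarray(list(presence_cells), dtype=np.int64)
    if n is None:
        n = presence.size
    candidates = np.setdiff1d(grid.masked_ids, presence)
    if n > candidates.size:
        raise ValueError(
            f"requested {n} pseudo-absences but only {candidates.size} cells available"
        )
    return np.sort(rng.choice(candidates, size=n, replace=False))


def partition_data(
    presences: Sequence[int],
    absences: Sequence[int],
    train_frac: float = 0.75,
    n_reps: int = 10,
    seed: int = 0,
    species_id: str = "?",
) -> list[Partition]:
    """Stratified random splits, repeated ``n_reps`` times.

    Each class is split independently at ``train_frac`` (floor on the
    calibration side), which preserves the observed prevalence by
    construction. Both sides of both classes must be non-empty, hence
    the >= 4 cells-per-class precondition at the default fractions.
    """
    presences = np.asarray(list(presences), dtype=np.int64)
    absences = np.asarray(list(absences), dtype=np.int64)
    for name, cells in (("presence", presences), ("absence", absences)):
        if cells.size < 4:
            raise ValueError(
                f"species {species_id}: {name} class too small "
                f"({cells.size} cells; at least 4 required for a stratified split)"
            )
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_reps):
        parts = {}
        for name, cells in (("presence", presences), ("absence", absences)):
            n_cal = int(np.floor(train_frac * cells.size))
            if n_cal < 1 or cells.size - n_cal < 1:
                raise ValueError(
                    f"species {species_id}: {name} class too small to split "
                    f"({cells.size} cells at train_frac={train_frac})"
                )
            perm = rng.permutation(cells)
            parts[name] = (np.sort(perm[:n_cal]), np.sort(perm[n_cal:]))
        out.append(
            Partition(
                replicate=rep,
                calib_presence=parts["presence"][0],
                calib_absence=parts["absence"][0],
                valid_presence=parts["presence"][1],
                valid_absence=parts["absence"][1],
            )
        )
    return out


def _confusion(scores: np.ndarray, labels: np.ndarray, threshold: float) -> ConfusionCounts:
    pred = scores >= threshold
    pos = labels.astype(bool)
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
    )


def roc_threshold(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, ConfusionCounts]:
    """Threshold maximizing sensitivity + specificity (Youden point).

    Candidate thresholds are the midpoints between consecutive distinct
    scores, plus caps below the minimum (predict everything present)
    and above the maximum (predict everything absent). The
    classification rule is *presence iff score >= threshold*; ties in
    the objective break toward the lower threshold, i.e. the larger
    predicted range (omission-averse).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.astype(bool).all() or not labels.astype(bool).any():
        raise ValueError("both classes must be present to set a threshold")
    distinct = np.unique(scores)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    best_t, best_cc, best_obj = None, None, -np.inf
    for t in candidates:  # ascending: strict > keeps the lowest tied threshold
        cc = _confusion(scores, labels, t)
        obj = cc.sensitivity + cc.specificity
        if obj > best_obj + 1e-12:
            best_t, best_cc, best_obj = float(t), cc, obj
    return best_t, best_cc


def evaluate_projection(
    model: NicheModel,
    partition: Partition,
    std_climate: StandardizedClimate,
    scenario: str = "current",
    species_id: str = "?",
) -> EvaluatedProjection:
    """Threshold a model on held-out data and binarize a scenario.

    The threshold is chosen (and TSS scored) on the partition's
    *validation* presences and absences under the current climate; the
    same threshold then binarizes the projection onto ``scenario``.
    """
    current = model.project(std_climate, std_climate.climate.current)
    val_cells = np.concatenate([partition.valid_presence, partition.valid_absence])
    val_labels = np.concatenate(
        [np.ones(partition.valid_presence.size, int), np.zeros(partition.valid_absence.size, int)]
    )
    threshold, cc = roc_threshold(current[val_cells], val_labels)
    score = tss(cc)

    surface = current if scenario == std_climate.climate.current else model.project(
        std_climate, scenario
    )
    with np.errstate(invalid="ignore"):
        binary = np.nan_to_num(surface, nan=-np.inf) >= threshold
    return EvaluatedProjection(
        species_id=species_id,
        method=model.method,
        replicate=partition.replicate,
        scenario=scenario,
        threshold=threshold,
        tss=score,
        binary_range=binary,
        continuous=surface,
    )


def evaluations_to_frame(projections: Sequence[EvaluatedProjection]) -> pd.DataFrame:
    """Tabulate evaluations as the per-model skill table
    (species, method, replicate, scenario, threshold, TSS)."""
    return pd.DataFrame(
        [
            {
                "species_id": p.species_id,
                "method": p.method,
                "replicate": p.replicate,
                "scenario": p.scenario,
                "threshold": p.threshold,
                "tss": p.tss,
            }
            for p in projections
        ]
    )
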