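"""End-to-end pipeline: synthetic world -> gridding -> per-species
model fitting and evaluation -> consensus -> diversity summaries ->
protected-area null model and classification.

Each stage writes its products plus a JSON manifest recording a hash
of the relevant configuration, of its input files and of its outputs.
On rerun, a stage whose manifest still matches is skipped and its
outputs are reloaded; corrupting or deleting a product invalidates only
that stage and anything downstream of it. All randomness descends from
the single master seed; per-species sub-seeds are derived by hashing
the species id, so species-level results do not depend on processing
order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tempfile
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import ensemble as ens
from . import evaluation as ev
from . import models as md
from . import protected as pa
from . import synthetic as syn
from .grid import (
    Grid,
    build_grid,
    build_presence_matrix,
    write_occurrences_csv,
    write_grid_text,
    write_surface_csv,
)

log = logging.getLogger("consenm")

STAGES = ("simulate", "grid", "fit", "ensemble", "diversity", "protect", "classify")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "grid": {"extent": [0, 0, 300, 300], "cell_size": 10.0},
    "synthetic": {
        "n_species": 20,
        "effort_per_species": 60,
        "bias_params": {},
        "gradient_params": {},
        "niche_hyperparams": {},
        "deltas": [
            {"name": "gcm1", "shift": [3.0, 150.0, -80.0, 4.0], "ns_gradient": [1.0, 0.0, 120.0, 0.0]},
            {"name": "gcm2", "shift": [2.2, 100.0, -40.0, 2.0], "ns_gradient": [1.5, 0.0, 80.0, 0.0]},
        ],
        "n_pa": 12,
        "pa_sizes": None,
    },
    "min_occurrences": 5,
    "cv": {"train_frac": 0.75, "n_reps": 10},
    "method_sets": {
        "distance": ["euclidean", "gower", "enfa"],
        "machine_learning": ["maxent", "garp", "ann"],
    },
    "garp": {"population_size": 40, "generations": 60, "n_rules": 8},
    "ann": {"hidden": 5, "epochs": 2000, "learning_rate": 1.0},
    "maxent": {"regularization": 0.01},
    "null_model": {"n_reps": 100},
}


def load_config(path_or_mapping) -> dict:
    """Merge a YAML file or mapping over the defaults (shallow per-section)."""
    if isinstance(path_or_mapping, Mapping):
        user = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if "seed" not in cfg or cfg["seed"] is None:
        raise ValueError("config must set a master seed")
    return cfg


def species_seed(master_seed: int, species_id: str, purpose: str = "") -> int:
    """Deterministic per-species sub-seed, independent of species order."""
    return zlib.crc32(f"{master_seed}:{species_id}:{purpose}".encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Manifest plumbing

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cfg_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()


def _stage_fresh(rundir: Path, stage: str, cfg_hash: str, inputs: Sequence[Path]) -> bool:
    mpath = rundir / f"manifest_{stage}.json"
    if not mpath.exists():
        return False
    try:
        man = json.loads(mpath.read_text())
    except json.JSONDecodeError:
        return False
    if man.get("config_hash") != cfg_hash:
        return False
    recorded_inputs = man.get("inputs", {})
    for p in inputs:
        if recorded_inputs.get(p.name) != _sha256(p):
            return False
    for name, h in man.get("outputs", {}).items():
        p = rundir / name
        if not p.exists() or _sha256(p) != h:
            return False
    return True


def _write_manifest(rundir: Path, stage: str, cfg_hash: str,
                    inputs: Sequence[Path], outputs: Sequence[Path]) -> None:
    man = {
        "stage": stage,
        "config_hash": cfg_hash,
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (rundir / f"manifest_{stage}.json").write_text(json.dumps(man, indent=1))


# ---------------------------------------------------------------------------
# Stages. Each returns the list of files it owns; `world` is the shared
# in-memory state rebuilt either by computing or by reloading.

def _grid_from_cfg(cfg: dict) -> Grid:
    g = cfg["grid"]
    return build_grid(tuple(g["extent"]), g["cell_size"], g.get("mask"))


def _stage_simulate(world: dict, cfg: dict, rundir: Path) -> list[Path]:
    seed = int(cfg["seed"])
    grid = _grid_from_cfg(cfg)
    s = cfg["synthetic"]
    deltas = [
        syn.ScenarioDelta(d["name"], tuple(d["shift"]), tuple(d.get("ns_gradient", (0, 0, 0, 0))))
        for d in s["deltas"]
    ]
    climate = syn.generate_climate(grid, species_seed(seed, "climate"),
                                   s.get("gradient_params"), deltas)
    truth = syn.generate_species(s["n_species"], grid, climate,
                                 s.get("niche_hyperparams"), species_seed(seed, "species"))
    occ = syn.sample_occurrences(truth, climate, grid, s["effort_per_species"],
                                 s.get("bias_params"), species_seed(seed, "occurrences"))
    footprints = syn.generate_protected_areas(grid, s["n_pa"], s.get("pa_sizes"),
                                              species_seed(seed, "pas"))
    world.update(grid=grid, climate=climate, truth=truth, occurrences=occ,
                 footprints=footprints)

    outputs = [rundir / "occurrences.csv", rundir / "footprints.json"]
    write_occurrences_csv(occ, outputs[0])
    outputs[1].write_text(json.dumps(
        [
            {"pa_id": f.pa_id, "anchor_cell": f.anchor_cell,
             "offsets": sorted(map(list, f.offsets)), "source": f.source}
            for f in footprints
        ], indent=1,
    ))
    for name in climate.scenarios:
        for v, var in enumerate(climate.variables):
            p = rundir / f"climate_{name}_{var}.txt"
            write_grid_text(climate.values(name)[:, v], grid, p)
            outputs.append(p)
    return outputs


def _stage_grid(world: dict, cfg: dict, rundir: Path) -> list[Path]:
    matrix = build_presence_matrix(world["occurrences"], world["grid"],
                                   cfg["min_occurrences"])
    world["presence"] = matrix
    rows = [
        {"species_id": sp, "cell_id": int(c)}
        for sp in matrix.species_ids for c in matrix.cells[sp]
    ]
    out = rundir / "presence_matrix.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    meta = rundir / "presence_meta.json"
    meta.write_text(json.dumps(
        {"n_species": len(matrix), "n_dropped": matrix.n_dropped}))
    return [out, meta]


def _stage_fit(world: dict, cfg: dict, rundir: Path) -> list[Path]:
    grid: Grid = world["grid"]
    matrix = world["presence"]
    env = md.standardize_climate(world["climate"])
    future_names = world["climate"].future_names
    cv = cfg["cv"]
    seed = int(cfg["seed"])
    store = ens.ProjectionStore()

    for sp in matrix.species_ids:
        presences = matrix.cells[sp]
        pseudo = ev.draw_pseudo_absences(grid, presences,
                                         seed=species_seed(seed, sp, "pseudo"))
        partitions = ev.partition_data(presences, pseudo, cv["train_frac"], cv["n_reps"],
                                       seed=species_seed(seed, sp, "cv"), species_id=sp)
        for mset, methods in cfg["method_sets"].items():
            for method in methods:
                for part in partitions:
                    model = _fit_one(method, part, env, cfg, seed, sp)
                    for scenario in ["current", *future_names]:
                        store.add(ev.evaluate_projection(model, part, env, scenario, sp))
        log.info("fitted %s: %d presence cells", sp, presences.size)

    world["store"] = store
    world["env"] = env
    table = ev.evaluations_to_frame(
        [store.get(sp, m, r, s)
         for sp in matrix.species_ids
         for m in md.ALL_METHODS
         for r in range(cv["n_reps"])
         for s in ["current", *future_names]]
    )
    out_csv = rundir / "evaluations.csv"
    table.to_csv(out_csv, index=False)
    out_cache = rundir / "projection_cache.npz"
    _save_store(store, out_cache)
    return [out_csv, out_cache]


def _fit_one(method: str, part: ev.Partition, env: md.StandardizedClimate,
             cfg: dict, seed: int, sp: str) -> md.NicheModel:
    sub = species_seed(seed, sp, f"{method}:{part.replicate}")
    contrast = None
    kwargs: dict = {}
    need = md.METHOD_DATA_NEEDS[method]
    if need == "pseudo_absence":
        contrast = part.calib_absence
    elif method == "maxent":
        kwargs["regularization"] = cfg["maxent"]["regularization"]
    if method == "garp":
        kwargs["ga_params"] = md.GAParams(seed=sub, **cfg["garp"])
    elif method == "ann":
        kwargs["net_params"] = md.NetParams(seed=sub, **cfg["ann"])
    return md.fit_model(method, part.calib_presence, contrast, env, seed=sub, **kwargs)


def _save_store(store: ens.ProjectionStore, path: Path) -> None:
    keys = sorted(store._store)
    ranges = np.stack([store._store[k].binary_range for k in keys])
    meta = [
        {"species_id": k[0], "method": k[1], "replicate": k[2], "scenario": k[3],
         "threshold": store._store[k].threshold, "tss": store._store[k].tss}
        for k in keys
    ]
    np.savez_compressed(path, ranges=ranges, meta=json.dumps(meta))


def _load_store(path: Path, mask: np.ndarray) -> ens.ProjectionStore:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    store = ens.ProjectionStore()
    for m, rng_row in zip(meta, data["ranges"]):
        cont = np.where(mask, rng_row.astype(float), np.nan)
        store.add(ev.EvaluatedProjection(
            species_id=m["species_id"], method=m["method"], replicate=m["replicate"],
            scenario=m["scenario"], threshold=m["threshold"], tss=m["tss"],
            binary_range=rng_row.astype(bool), continuous=cont,
        ))
    return store


def _stage_ensemble(world: dict, cfg: dict, rundir: Path) -> list[Path]:
    grid: Grid = world["grid"]
    store: ens.ProjectionStore = world["store"]
    matrix = world["presence"]
    future_names = world["climate"].future_names
    n_reps = cfg["cv"]["n_reps"]
    consensus: dict[tuple[str, str], list[ens.ConsensusSurface]] = {}
    outputs = []
    for mset in cfg["method_sets"]:
        for timeframe in ("current", "future"):
            surfaces = []
            for sp in matrix.species_ids:
                if timeframe == "current":
                    surf = ens.assemble_current(store, sp, mset, n_reps, mask=grid.mask)
                else:
                    surf = ens.assemble_future(store, sp, mset, future_names, n_reps,
                                               mask=grid.mask)
                surfaces.append(surf)
            consensus[(mset, timeframe)] = surfaces
            out = rundir / f"consensus_{mset}_{timeframe}.csv"
            frames = []
            for surf in surfaces:
                keep = ~np.isnan(surf.weighted_frequency)
                frames.append(pd.DataFrame({
                    "species_id": surf.species_id,
                    "cell_id": np.flatnonzero(keep),
                    "weighted_frequency": surf.weighted_frequency[keep],
                    "in_range": surf.binary_range[keep].astype(int),
                }))
            pd.concat(frames, ignore_index=True).to_csv(out, index=False)
            outputs.append(out)
            scen = ["current"] if timeframe == "current" else future_names
            manifest = {
                surf.species_id: ens.consensus_manifest(
                    surf,
                    store.collect(surf.species_id, cfg["method_sets"][mset],
                                  range(n_reps), scen),
                )
                for surf in surfaces
            }
            mout = rundir / f"consensus_{mset}_{timeframe}_pool.json"
            mout.write_text(json.dumps(manifest, indent=1))
            outputs.append(mout)
    world["consensus"] = consensus
    return outputs


def _stage_diversity(world: dict, cfg: dict, rundir: Path) -> list[Path]:
    consensus = world["consensus"]
    outputs = []
    for (mset, timeframe), surfaces in consensus.items():
        rich = dv.richness(surfaces)
        world[f"richness_{mset}_{timeframe}"] = rich
        out = rundir / f"richness_{mset}_{timeframe}.csv"
        counts = rich.counts.astype(float)
        counts[~world["grid"].mask] = np.nan
        write_surface_csv(counts, out, column="richness")
        outputs.append(out)
    for mset in cfg["method_sets"]:
        tm = dv.turnover(consensus[(mset, "current")], consensus[(mset, "future")])
        out = rundir / f"turnover_{mset}.csv"
        dv.turnover_table(tm).to_csv(out, index=False)
        outputs.append(out)
        ct = dv.contraction_table(consensus[(mset, "current")], consensus[(mset, "future")])
        out2 = rundir / f"contraction_{mset}.csv"
        ct.to_csv(out2, index=False)
        outputs.append(out2)
    return outputs


def _stage_protect(world: dict, cfg: dict, rundir: Path) -> list[Path]:
    grid: Grid = world["grid"]
    outputs = []
    world["pa_results"] = {}
    for mset in cfg["method_sets"]:
        occ_cur = ens.binary_stack(world["consensus"][(mset, "current")])
        occ_fut = ens.binary_stack(world["consensus"][(mset, "future")])
        records, regression = pa.null_model(
            world["footprints"], occ_cur, occ_fut, grid,
            n_reps=cfg["null_model"]["n_reps"],
            seed=species_seed(int(cfg["seed"]), mset, "null"),
        )
        world["pa_results"][mset] = (records, regression)
        out = rundir / f"pa_null_{mset}.json"
        out.write_text(json.dumps({
            "regression": {"intercept": regression.intercept, "slope": regression.slope},
            "records": [
                {"pa_id": r.pa_id, "n_cells": r.n_cells,
                 "present_richness": r.present_richness,
                 "future_richness": r.future_richness,
                 "null_present_mean": r.null_present_mean,
                 "null_future_mean": r.null_future_mean}
                for r in records
            ],
        }, indent=1))
        outputs.append(out)
    return outputs


def _stage_classify(world: dict, cfg: dict, rundir: Path) -> list[Path]:
    outputs = []
    for mset, (records, regression) in world["pa_results"].items():
        classified = pa.classify_pas(records, regression)
        world["pa_results"][mset] = (classified, regression)
        out = rundir / f"pa_records_{mset}.csv"
        pa.write_pa_records_csv(classified, out)
        outputs.append(out)
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "grid": _stage_grid,
    "fit": _stage_fit,
    "ensemble": _stage_ensemble,
    "diversity": _stage_diversity,
    "protect": _stage_protect,
    "classify": _stage_classify,
}

# configuration sections a stage's products depend on
_STAGE_CFG_KEYS = {
    "simulate": ("seed", "grid", "synthetic"),
    "grid": ("seed", "grid", "synthetic", "min_occurrences"),
    "fit": ("seed", "grid", "synthetic", "min_occurrences", "cv", "method_sets",
            "garp", "ann", "maxent"),
    "ensemble": ("seed", "grid", "synthetic", "min_occurrences", "cv", "method_sets",
                 "garp", "ann", "maxent"),
    "diversity": ("seed", "grid", "synthetic", "min_occurrences", "cv", "method_sets",
                  "garp", "ann", "maxent"),
    "protect": ("seed", "grid", "synthetic", "min_occurrences", "cv", "method_sets",
                "garp", "ann", "maxent", "null_model"),
    "classify": ("seed", "grid", "synthetic", "min_occurrences", "cv", "method_sets",
                 "garp", "ann", "maxent", "null_model"),
}


def run_pipeline(config, outdir, upto: str = "classify") -> Path:
    """Execute the pipeline through stage ``upto``; returns the run dir.

    Already up-to-date stages (matching manifests, intact outputs) are
    skipped; their in-memory state is rebuilt deterministically.
    """
    cfg = load_config(config)
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    rundir = Path(outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    world: dict = {}
    executed: list[str] = []
    prev_outputs: list[Path] = []
    for stage in STAGES[: STAGES.index(upto) + 1]:
        cfg_hash = _cfg_hash({k: cfg.get(k) for k in _STAGE_CFG_KEYS[stage]})
        if _stage_fresh(rundir, stage, cfg_hash, prev_outputs):
            log.info("stage %s up to date; skipping", stage)
            _reload_stage(stage, world, cfg, rundir)
            man = json.loads((rundir / f"manifest_{stage}.json").read_text())
            prev_outputs = [rundir / n for n in man["outputs"]]
            continue
        log.info("running stage %s", stage)
        try:
            outputs = _STAGE_FUNCS[stage](world, cfg, rundir)
        except Exception as exc:  # surface which stage died
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _write_manifest(rundir, stage, cfg_hash, prev_outputs, outputs)
        executed.append(stage)
        prev_outputs = outputs
    (rundir / "run_summary.json").write_text(json.dumps(
        {"stages_run": executed,
         "stages_skipped": [s for s in STAGES[: STAGES.index(upto) + 1] if s not in executed]}))
    return rundir


def _reload_stage(stage: str, world: dict, cfg: dict, rundir: Path) -> None:
    """Rebuild the in-memory state of a skipped stage."""
    if stage == "simulate":
        # regenerate deterministically rather than parsing text dumps
        seed = int(cfg["seed"])
        grid = _grid_from_cfg(cfg)
        s = cfg["synthetic"]
        deltas = [syn.ScenarioDelta(d["name"], tuple(d["shift"]),
                                    tuple(d.get("ns_gradient", (0, 0, 0, 0))))
                  for d in s["deltas"]]
        climate = syn.generate_climate(grid, species_seed(seed, "climate"),
                                       s.get("gradient_params"), deltas)
        truth = syn.generate_species(s["n_species"], grid, climate,
                                     s.get("niche_hyperparams"),
                                     species_seed(seed, "species"))
        occ = syn.sample_occurrences(truth, climate, grid, s["effort_per_species"],
                                     s.get("bias_params"),
                                     species_seed(seed, "occurrences"))
        footprints = syn.generate_protected_areas(grid, s["n_pa"], s.get("pa_sizes"),
                                                  species_seed(seed, "pas"))
        world.update(grid=grid, climate=climate, truth=truth, occurrences=occ,
                     footprints=footprints)
    elif stage == "grid":
        world["presence"] = build_presence_matrix(world["occurrences"], world["grid"],
                                                  cfg["min_occurrences"])
    elif stage == "fit":
        world["env"] = md.standardize_climate(world["climate"])
        world["store"] = _load_store(rundir / "projection_cache.npz", world["grid"].mask)
    elif stage == "ensemble":
        with tempfile.TemporaryDirectory() as tmp:
            _stage_ensemble(world, cfg, Path(tmp))
    elif stage == "diversity":
        pass  # map products live on disk; nothing downstream needs them in memory
    elif stage == "protect":
        with tempfile.TemporaryDirectory() as tmp:
            _stage_protect(world, cfg, Path(tmp))
    elif stage == "classify":
        pass
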