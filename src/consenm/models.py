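"""The six presence-only niche modelling methods.

Three families, differing in what they learn from:

* **presence-only distances** — Euclidean distance to the presence
  centroid, and Gower distance to the nearest presence record (the
  DOMAIN rule): no reference to the rest of the study area;
* **background methods** — ENFA (marginality/specialization factor
  analysis) and a maximum-entropy Gibbs model, which contrast presence
  climate with the climate available across the whole region;
* **pseudo-absence methods** — a rule-set genetic algorithm
  ("GARP-like") and a single-hidden-layer neural network, trained to
  discriminate presences from randomly drawn pseudo-absences.

All methods produce a continuous suitability surface in [0, 1] over the
study-region mask and can project onto any climate scenario. Variables
are standardized against the *current* scenario only; the same
statistics are reused for futures so that future climate never leaks
into model space.

The MaxEnt, GARP and ANN implementations here are deliberately compact
re-implementations of the published ideas (log-linear Gibbs model with
linear+quadratic features; envelope-rule GA; logistic MLP), not
feature-complete ports of the original desktop tools.
"""

from __future__ import annotations

import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .grid import Grid
from .synthetic import ClimateLayers, N_VARS

DISTANCE_METHODS = ("euclidean", "gower", "enfa")
MACHINE_LEARNING_METHODS = ("maxent", "garp", "ann")
METHOD_SETS: dict[str, tuple[str, ...]] = {
    "distance": DISTANCE_METHODS,
    "machine_learning": MACHINE_LEARNING_METHODS,
}
ALL_METHODS = DISTANCE_METHODS + MACHINE_LEARNING_METHODS

#: Which auxiliary data each method consumes besides presences.
METHOD_DATA_NEEDS: dict[str, str] = {
    "euclidean": "presence_only",
    "gower": "presence_only",
    "enfa": "background",
    "maxent": "background",
    "garp": "pseudo_absence",
    "ann": "pseudo_absence",
}


@dataclass(frozen=True)
class StandardizedClimate:
    """Climate layers centered/scaled by the current scenario's masked
    mean and SD; the raw layers stay reachable via ``climate``."""

    climate: ClimateLayers
    means: np.ndarray
    sds: np.ndarray

    @property
    def grid(self) -> Grid:
        return self.climate.grid

    def values(self, scenario: str) -> np.ndarray:
        return (self.climate.values(scenario) - self.means) / self.sds

    def masked_values(self, scenario: str) -> np.ndarray:
        return self.values(scenario)[self.grid.mask]


def standardize_climate(climate: ClimateLayers,
                        reference_scenario: str | None = None) -> StandardizedClimate:
    """Center/scale every scenario by the reference (current) scenario.

    Raises ``ValueError`` naming the variable if one has zero variance
    over the masked reference cells.
    """
    reference_scenario = reference_scenario or climate.current
    ref = climate.masked_values(reference_scenario)
    means = ref.mean(axis=0)
    sds = ref.std(axis=0)
    for v, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(f"variable {climate.variables[v]!r} has zero variance")
    return StandardizedClimate(climate, means, sds)


class NicheModel(ABC):
    """A fitted presence-only model projectable onto any scenario."""

    method: str = ""

    @abstractmethod
    def project(self, env: StandardizedClimate, scenario: str = "current") -> np.ndarray:
        """Continuous suitability per cell in [0, 1]; NaN off-mask."""

    @abstractmethod
    def to_dict(self) -> dict: ...


def _finish_surface(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.full(mask.size, np.nan)
    out[mask] = np.clip(values, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Distance methods

@dataclass(frozen=True)
class EuclideanModel(NicheModel):
    """Suitability = 1 - d/d_max, with d the Euclidean distance in
    standardized climate space to the presence centroid and d_max the
    farthest masked cell of the projected scenario."""

    centroid: np.ndarray
    method: str = "euclidean"

    def project(self, env: StandardizedClimate, scenario: str = "current") -> np.ndarray:
        mask = env.grid.mask
        z = env.masked_values(scenario)
        d = np.linalg.norm(z - self.centroid, axis=1)
        dmax = d.max()
        suit = np.ones_like(d) if dmax == 0 else 1.0 - d / dmax
        return _finish_surface(suit, mask)

    def to_dict(self) -> dict:
        return {"method": self.method, "centroid": self.centroid.tolist()}


def fit_euclidean(presence_cells: Sequence[int], std_climate: StandardizedClimate) -> EuclideanModel:
    cells = np.asarray(list(presence_cells), dtype=np.int64)
    if cells.size < 1:
        raise ValueError("at least one presence cell required")
    centroid = std_climate.values("current")[cells].mean(axis=0)
    return EuclideanModel(centroid=centroid)


@dataclass(frozen=True)
class GowerModel(NicheModel):
    """Nearest-record (DOMAIN) Gower distance model on raw climate.

    ``d(c, p) = mean_v |clim_cv - clim_pv| / range_v`` with per-variable
    ranges taken over the masked current cells;
    ``suitability = 1 - min_p d(c, p)`` clipped to [0, 1].
    """

    presence_climate: np.ndarray  # (n_presences, 4), raw units
    ranges: np.ndarray  # (4,)
    method: str = "gower"

    def project(self, env: StandardizedClimate, scenario: str = "current") -> np.ndarray:
        mask = env.grid.mask
        clim = env.climate.values(scenario)[mask]
        # (cells, presences) pairwise mean scaled absolute difference
        diff = np.abs(clim[:, None, :] - self.presence_climate[None, :, :]) / self.ranges
        d = diff.mean(axis=2).min(axis=1)
        return _finish_surface(1.0 - d, mask)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "presence_climate": self.presence_climate.tolist(),
            "ranges": self.ranges.tolist(),
        }


def fit_gower(presence_cells: Sequence[int], climate: ClimateLayers) -> GowerModel:
    cells = np.asarray(list(presence_cells), dtype=np.int64)
    if cells.size < 1:
        raise ValueError("at least one presence cell required")
    masked = climate.masked_values(climate.current)
    ranges = masked.max(axis=0) - masked.min(axis=0)
    for v, r in enumerate(ranges):
        if r == 0:
            raise ValueError(f"variable {climate.variables[v]!r} has zero range")
    return GowerModel(presence_climate=climate.values(climate.current)[cells], ranges=ranges)


@dataclass(frozen=True)
class ENFAModel(NicheModel):
    """Ecological Niche Factor Analysis, deterministic variant.

    The marginality factor is the (normalized) displacement of the
    presence mean from the global mean in standardized climate space;
    specialization factors are the principal axes of the presence
    covariance restricted to the orthogonal complement. All four
    factors are retained. Suitability is ``1 - D/D_max`` with D a
    per-factor-scaled distance to the presence *median* in factor
    space.
    """

    factors: np.ndarray  # (4, 4) columns = factor directions
    center: np.ndarray  # (4,) presence median in factor space
    scales: np.ndarray  # (4,) presence SD per factor
    marginality: np.ndarray  # (4,) normalized marginality vector (may be 0)
    method: str = "enfa"

    def project(self, env: StandardizedClimate, scenario: str = "current") -> np.ndarray:
        mask = env.grid.mask
        z = env.masked_values(scenario) @ self.factors  # factor scores
        D = np.sqrt((((z - self.center) / self.scales) ** 2).sum(axis=1))
        dmax = D.max()
        suit = np.ones_like(D) if dmax == 0 else 1.0 - D / dmax
        return _finish_surface(suit, mask)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "factors": self.factors.tolist(),
            "center": self.center.tolist(),
            "scales": self.scales.tolist(),
            "marginality": self.marginality.tolist(),
        }


def fit_enfa(presence_cells: Sequence[int], std_climate: StandardizedClimate,
             zero_tol: float = 1e-10) -> ENFAModel:
    cells = np.asarray(list(presence_cells), dtype=np.int64)
    if cells.size < 5:
        raise ValueError("ENFA requires at least 5 presence cells")
    P = std_climate.values("current")[cells]
    if (P.std(axis=0) > 0).sum() < 2:
        raise ValueError("ENFA requires >= 2 variables with presence variance")

    # global mean is 0 and SD is 1 in standardized space
    m = P.mean(axis=0)
    cov = np.cov(P, rowvar=False)
    if not np.all(np.isfinite(cov)) or np.linalg.matrix_rank(cov) < N_VARS:
        warnings.warn("singular presence covariance; falling back to diagonal covariance")
        cov = np.diag(np.maximum(P.var(axis=0, ddof=1), zero_tol))

    norm_m = np.linalg.norm(m)
    if norm_m < zero_tol:
        # zero marginality: factors default to the principal axes
        evals, evecs = np.linalg.eigh(cov)
        factors = evecs[:, ::-1]
        marginality = np.zeros(N_VARS)
    else:
        m_unit = m / norm_m
        # orthonormal complement of the marginality axis via QR
        Q, _ = np.linalg.qr(np.column_stack([m_unit, np.eye(N_VARS)]))
        B = Q[:, 1:N_VARS]  # (4, 3)
        sub = B.T @ cov @ B
        evals, evecs = np.linalg.eigh(sub)
        spec = B @ evecs[:, ::-1]  # specialization directions, decreasing variance
        factors = np.column_stack([m_unit, spec])
        marginality = m_unit

    scores = P @ factors
    center = np.median(scores, axis=0)
    scales = scores.std(axis=0, ddof=0)
    scales = np.where(scales > zero_tol, scales, 1.0)
    return ENFAModel(factors=factors, center=center, scales=scales, marginality=marginality)


# ---------------------------------------------------------------------------
# Machine-learning methods

def _maxent_features(z: np.ndarray) -> np.ndarray:
    """Linear + quadratic features of the standardized variables."""
    return np.column_stack([z, z**2])


@dataclass(frozen=True)
class MaxEntModel(NicheModel):
    """Penalized log-linear (Gibbs) maximum-entropy model.

    ``P(c) ∝ exp(λ·f(c))`` over background cells with linear and
    quadratic features; λ maximizes the presence log-likelihood minus
    an L1 penalty. Projection rescales ``exp(λ·f)`` so the best masked
    cell scores 1.
    """

    lambdas: np.ndarray  # (8,)
    regularization: float = 0.0
    method: str = "maxent"

    def project(self, env: StandardizedClimate, scenario: str = "current") -> np.ndarray:
        mask = env.grid.mask
        eta = _maxent_features(env.masked_values(scenario)) @ self.lambdas
        eta = eta - eta.max()  # rescale so max suitability is 1
        return _finish_surface(np.exp(eta), mask)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "lambdas": self.lambdas.tolist(),
            "regularization": self.regularization,
        }


def fit_maxent(
    presence_cells: Sequence[int],
    std_climate: StandardizedClimate,
    background_cells: Sequence[int] | None = None,
    regularization: float = 0.01,
    max_iter: int = 500,
    smooth_eps: float = 1e-8,
) -> MaxEntModel:
    """Fit the Gibbs model by penalized maximum likelihood (L-BFGS).

    The L1 penalty is smoothed as ``sqrt(λ² + eps)`` to keep the
    objective differentiable; the penalty-limit behaviour (large
    regularization drives every λ to 0, i.e. a uniform surface) is
    preserved. Background defaults to all masked cells.
    """
    cells = np.asarray(list(presence_cells), dtype=np.int64)
    if cells.size < 1:
        raise ValueError("at least one presence cell required")
    grid = std_climate.grid
    bg = (
        grid.masked_ids
        if background_cells is None
        else np.asarray(list(background_cells), dtype=np.int64)
    )
    z = std_climate.values("current")
    F_pres = _maxent_features(z[cells])
    F_bg = _maxent_features(z[bg])
    pres_mean = F_pres.mean(axis=0)

    def objective(lam: np.ndarray):
        eta = F_bg @ lam
        lse = logsumexp(eta)
        p = np.exp(eta - lse)
        nll = lse - pres_mean @ lam
        grad = F_bg.T @ p - pres_mean
        pen = np.sqrt(lam**2 + smooth_eps)
        return (
            nll + regularization * pen.sum(),
            grad + regularization * lam / pen,
        )

    res = minimize(
        objective,
        np.zeros(F_bg.shape[1]),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        raise RuntimeError(f"MaxEnt fit did not converge: {res.message}")
    return MaxEntModel(lambdas=res.x, regularization=regularization)


# --- GARP-like rule-set genetic algorithm ----------------------------------

@dataclass(frozen=True)
class GAParams:
    seed: int
    population_size: int = 40
    generations: int = 60
    n_rules: int = 8
    mutation_rate: float = 0.25
    elite: int = 2


@dataclass(frozen=True)
class GARPModel(NicheModel):
    """Best rule set found by the genetic algorithm.

    Each rule is a climate envelope (or its negation) over a subset of
    the standardized variables, predicting presence or absence. A rule
    *applies* to a cell when the cell satisfies its condition;
    suitability is the fraction of applicable rules that predict
    presence (0 when no rule applies), and the binary training
    prediction is suitability >= 0.5.
    """

    lows: np.ndarray  # (k, 4)
    highs: np.ndarray  # (k, 4)
    used: np.ndarray  # (k, 4) bool, which variables the rule constrains
    negated: np.ndarray  # (k,) bool
    predicts: np.ndarray  # (k,) bool, True = presence
    fitness: float = np.nan
    method: str = "garp"

    def _suitability(self, z: np.ndarray) -> np.ndarray:
        inside = np.ones((z.shape[0], self.lows.shape[0]), dtype=bool)
        for k in range(self.lows.shape[0]):
            u = self.used[k]
            if u.any():
                inside[:, k] = np.all(
                    (z[:, u] >= self.lows[k, u]) & (z[:, u] <= self.highs[k, u]), axis=1
                )
        applies = np.where(self.negated[None, :], ~inside, inside)
        n_app = applies.sum(axis=1)
        n_pres = (applies & self.predicts[None, :]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            suit = np.where(n_app > 0, n_pres / np.maximum(n_app, 1), 0.0)
        return suit

    def project(self, env: StandardizedClimate, scenario: str = "current") -> np.ndarray:
        mask = env.grid.mask
        return _finish_surface(self._suitability(env.masked_values(scenario)), mask)

    def training_accuracy(self, z: np.ndarray, labels: np.ndarray) -> float:
        pred = self._suitability(z) >= 0.5
        return float((pred == labels.astype(bool)).mean())

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "lows": self.lows.tolist(),
            "highs": self.highs.tolist(),
            "used": self.used.tolist(),
            "negated": self.negated.tolist(),
            "predicts": self.predicts.tolist(),
            "fitness": self.fitness,
        }


def _random_rule_set(X: np.ndarray, y: np.ndarray, k: int, rng: np.random.Generator):
    n = X.shape[0]
    lows = np.empty((k, N_VARS))
    highs = np.empty((k, N_VARS))
    used = np.zeros((k, N_VARS), dtype=bool)
    negated = rng.random(k) < 0.2
    predicts = rng.random(k) < 0.7
    pres_idx = np.flatnonzero(y)
    for j in range(k):
        if predicts[j] and not negated[j] and pres_idx.size >= 2 and rng.random() < 0.4:
            # seed from the tight presence bounding box: the exact
            # envelope when classes are box-separable
            lo = X[pres_idx].min(axis=0) - 1e-9
            hi = X[pres_idx].max(axis=0) + 1e-9
            lows[j], highs[j] = lo, hi
        else:
            # otherwise from a random pair of training points, biased
            # toward presences so useful boxes exist at generation 0
            pool = pres_idx if (predicts[j] and pres_idx.size >= 2 and rng.random() < 0.8) else np.arange(n)
            a, b = X[rng.choice(pool)], X[rng.choice(pool)]
            lo, hi = np.minimum(a, b), np.maximum(a, b)
            pad = 0.05 * (1.0 + hi - lo)
            lows[j], highs[j] = lo - pad, hi + pad
        u = rng.random(N_VARS) < 0.7
        if not u.any():
            u[rng.integers(N_VARS)] = True
        used[j] = u
    return lows, highs, used, negated, predicts


def fit_garp(
    presence_cells: Sequence[int],
    pseudo_absence_cells: Sequence[int],
    std_climate: StandardizedClimate,
    ga_params: GAParams | Mapping,
) -> GARPModel:
    """Evolve envelope rule sets by selection/crossover/mutation.

    Fitness is training accuracy on the presence + pseudo-absence
    cells. Fully deterministic for a given ``ga_params.seed``.
    """
    if isinstance(ga_params, Mapping):
        ga_params = GAParams(**ga_params)
    pres = np.asarray(list(presence_cells), dtype=np.int64)
    absc = np.asarray(list(pseudo_absence_cells), dtype=np.int64)
    if pres.size == 0 or absc.size == 0:
        raise ValueError("both presence and pseudo-absence cells required")
    rng = np.random.default_rng(ga_params.seed)
    z = std_climate.values("current")
    X = np.vstack([z[pres], z[absc]])
    y = np.concatenate([np.ones(pres.size, bool), np.zeros(absc.size, bool)])

    def make(parts) -> GARPModel:
        m = GARPModel(*parts)
        return GARPModel(*parts, fitness=m.training_accuracy(X, y))

    pop = [make(_random_rule_set(X, y, ga_params.n_rules, rng))
           for _ in range(ga_params.population_size)]
    k = ga_params.n_rules
    for _ in range(ga_params.generations):
        pop.sort(key=lambda m: m.fitness, reverse=True)
        new = pop[: ga_params.elite]
        while len(new) < ga_params.population_size:
            # tournament selection
            pa = max(rng.choice(pop, 2, replace=False), key=lambda m: m.fitness)
            pb = max(rng.choice(pop, 2, replace=False), key=lambda m: m.fitness)
            take = rng.random(k) < 0.5  # uniform rule-level crossover
            lows = np.where(take[:, None], pa.lows, pb.lows).copy()
            highs = np.where(take[:, None], pa.highs, pb.highs).copy()
            used = np.where(take[:, None], pa.used, pb.used).copy()
            negated = np.where(take, pa.negated, pb.negated).copy()
            predicts = np.where(take, pa.predicts, pb.predicts).copy()
            for j in range(k):  # point mutation
                if rng.random() < ga_params.mutation_rate:
                    what = rng.integers(4)
                    v = rng.integers(N_VARS)
                    if what == 0:
                        lows[j, v] += rng.normal(0, 0.3)
                    elif what == 1:
                        highs[j, v] += rng.normal(0, 0.3)
                    elif what == 2:
                        used[j, v] = not used[j, v]
                        if not used[j].any():
                            used[j, v] = True
                    else:
                        if rng.random() < 0.5:
                            negated[j] = not negated[j]
                        else:
                            predicts[j] = not predicts[j]
                    lo = np.minimum(lows[j], highs[j])
                    hi = np.maximum(lows[j], highs[j])
                    lows[j], highs[j] = lo, hi
            new.append(make((lows, highs, used, negated, predicts)))
        pop = new
    return max(pop, key=lambda m: m.fitness)


# --- single-hidden-layer neural network ------------------------------------

@dataclass(frozen=True)
class NetParams:
    seed: int
    hidden: int = 5
    epochs: int = 2000
    learning_rate: float = 1.0
    init_scale: float = 0.1


@dataclass(frozen=True)
class ANNModel(NicheModel):
    """One-hidden-layer logistic network trained by full-batch
    gradient descent on cross-entropy; the output probability is the
    suitability."""

    W1: np.ndarray  # (4, hidden)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float
    method: str = "ann"

    def _forward(self, z: np.ndarray) -> np.ndarray:
        h = expit(z @ self.W1 + self.b1)
        return expit(h @ self.W2 + self.b2)

    def project(self, env: StandardizedClimate, scenario: str = "current") -> np.ndarray:
        mask = env.grid.mask
        return _finish_surface(self._forward(env.masked_values(scenario)), mask)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2,
        }


def fit_ann(
    presence_cells: Sequence[int],
    pseudo_absence_cells: Sequence[int],
    std_climate: StandardizedClimate,
    net_params: NetParams | Mapping,
) -> ANNModel:
    if isinstance(net_params, Mapping):
        net_params = NetParams(**net_params)
    pres = np.asarray(list(presence_cells), dtype=np.int64)
    absc = np.asarray(list(pseudo_absence_cells), dtype=np.int64)
    if pres.size == 0 or absc.size == 0:
        raise ValueError("both presence and pseudo-absence cells required")
    rng = np.random.default_rng(net_params.seed)
    z = std_climate.values("current")
    X = np.vstack([z[pres], z[absc]])
    y = np.concatenate([np.ones(pres.size), np.zeros(absc.size)])
    n = X.shape[0]

    H = net_params.hidden
    W1 = rng.normal(0, net_params.init_scale, size=(N_VARS, H))
    b1 = np.zeros(H)
    W2 = rng.normal(0, net_params.init_scale, size=H)
    b2 = 0.0
    lr = net_params.learning_rate
    for _ in range(net_params.epochs):
        h = expit(X @ W1 + b1)
        p = expit(h @ W2 + b2)
        delta_out = (p - y) / n  # d(cross-entropy)/d(logit)
        gW2 = h.T @ delta_out
        gb2 = delta_out.sum()
        delta_h = np.outer(delta_out, W2) * h * (1 - h)
        gW1 = X.T @ delta_h
        gb1 = delta_h.sum(axis=0)
        W1 -= lr * gW1
        b1 -= lr * gb1
        W2 -= lr * gW2
        b2 -= lr * gb2
    return ANNModel(W1=W1, b1=b1, W2=W2, b2=float(b2))


# ---------------------------------------------------------------------------
# Serialization & dispatch

_MODEL_CLASSES = {
    "euclidean": EuclideanModel,
    "gower": GowerModel,
    "enfa": ENFAModel,
    "maxent": MaxEntModel,
    "garp": GARPModel,
    "ann": ANNModel,
}

_ARRAY_FIELDS = {
    "euclidean": {"centroid": 1},
    "gower": {"presence_climate": 2, "ranges": 1},
    "enfa": {"factors": 2, "center": 1, "scales": 1, "marginality": 1},
    "maxent": {"lambdas": 1},
    "garp": {"lows": 2, "highs": 2, "used": 2, "negated": 1, "predicts": 1},
    "ann": {"W1": 2, "b1": 1, "W2": 1},
}


def model_from_dict(d: Mapping) -> NicheModel:
    """Inverse of ``NicheModel.to_dict`` for every method tag."""
    d = dict(d)
    method = d.pop("method")
    cls = _MODEL_CLASSES[method]
    arrays = _ARRAY_FIELDS[method]
    kwargs = {}
    for key, val in d.items():
        if key in arrays:
            dtype = bool if key in ("used", "negated", "predicts") else float
            kwargs[key] = np.asarray(val, dtype=dtype)
        else:
            kwargs[key] = val
    return cls(**kwargs)


def fit_model(
    method: str,
    presence_cells: Sequence[int],
    contrast_cells: Sequence[int] | None,
    std_climate: StandardizedClimate,
    seed: int = 0,
    **kwargs,
) -> NicheModel:
    """Uniform dispatcher used by the pipeline.

    ``contrast_cells`` are ignored by the distance-only methods, used
    as background by MaxEnt, and as pseudo-absences by GARP/ANN —
    matching the three-way presence-only taxonomy.
    """
    if method == "euclidean":
        return fit_euclidean(presence_cells, std_climate)
    if method == "gower":
        return fit_gower(presence_cells, std_climate.climate)
    if method == "enfa":
        return fit_enfa(presence_cells, std_climate)
    if method == "maxent":
        return fit_maxent(presence_cells, std_climate,
                          background_cells=contrast_cells, **kwargs)
    if method == "garp":
        params = kwargs.pop("ga_params", None) or GAParams(seed=seed)
        return fit_garp(presence_cells, contrast_cells, std_climate, params)
    if method == "ann":
        params = kwargs.pop("net_params", None) or NetParams(seed=seed)
        return fit_ann(presence_cells, contrast_cells, std_climate, params)
    raise ValueError(f"unknown method {method!r}")
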