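"""The six presence-only niche models: closed-form toys, independent
oracles, determinism contracts, and truth recovery on synthetic
species."""

import json

import numpy as np
import pytest
from scipy.stats import spearmanr

from consenm import (
    ClimateLayers,
    build_grid,
    draw_pseudo_absences,
    fit_ann,
    fit_enfa,
    fit_euclidean,
    fit_garp,
    fit_gower,
    fit_maxent,
    fit_model,
    standardize_climate,
)
from consenm.models import (
    ALL_METHODS,
    GAParams,
    NetParams,
    _maxent_features,
    model_from_dict,
)


def toy_climate(values: np.ndarray, n_rows: int = 1) -> ClimateLayers:
    """Wrap explicit per-cell climate values in single-scenario layers."""
    n_cells = values.shape[0]
    grid = build_grid((0, 0, n_cells // n_rows * 10, n_rows * 10), 10)
    return ClimateLayers(grid, {"current": np.asarray(values, dtype=float)})


def iid_climate(n_cells: int, seed: int = 0) -> ClimateLayers:
    """Spatially uncorrelated climate: each variable iid standard
    normal (shifted/scaled per variable), for tests that must not pick
    up cross-variable correlation."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 1, size=(n_cells, 4)) * [2.0, 300.0, 150.0, 5.0] + [
        20.0,
        2500.0,
        1400.0,
        45.0,
    ]
    side = int(np.sqrt(n_cells))
    assert side * side == n_cells
    grid = build_grid((0, 0, side * 10, side * 10), 10)
    return ClimateLayers(grid, {"current": vals})


class TestStandardize:
    def test_reference_scenario_becomes_zero_mean_unit_sd(self, climate):
        env = standardize_climate(climate)
        z = env.masked_values("current")
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1, atol=1e-12)

    def test_constant_variable_is_rejected_by_name(self):
        vals = np.random.default_rng(0).normal(size=(9, 4))
        vals[:, 2] = 7.0
        with pytest.raises(ValueError, match="precip_annual"):
            standardize_climate(toy_climate(vals))

    def test_uniform_delta_shifts_standardized_future_by_delta_over_sd(self, climate):
        env = standardize_climate(climate)
        cur = env.masked_values("current")
        fut = env.masked_values("gcm1")
        delta = climate.masked_values("gcm1") - climate.masked_values("current")
        assert np.allclose(fut, cur + delta / env.sds, atol=1e-9)


class TestEuclidean:
    def test_centroid_cell_scores_one_and_farthest_zero(self, env):
        cells = env.grid.masked_ids[:1]
        model = fit_euclidean(cells, env)
        surf = model.project(env)
        assert surf[cells[0]] == pytest.approx(1.0)
        assert np.nanmin(surf) == pytest.approx(0.0)

    def test_symmetric_presences_peak_at_midpoint(self):
        # 3x3 lattice with linear climate: centroid of opposite corners
        # is the center cell
        rows, cols = np.divmod(np.arange(9), 3)
        vals = np.column_stack([cols, rows, cols + 2 * rows, 2 * cols - rows]).astype(float)
        env = standardize_climate(toy_climate(vals, n_rows=3))
        model = fit_euclidean([0, 8], env)
        surf = model.project(env)
        assert int(np.nanargmax(surf)) == 4


class TestGower:
    def test_presence_cell_scores_one(self, env):
        cells = env.grid.masked_ids[5:8]
        surf = fit_gower(cells, env.climate).project(env)
        assert np.allclose(surf[cells], 1.0)

    def test_full_range_difference_scores_zero(self):
        vals = np.array([[0, 0, 0, 0], [5, 5, 5, 5], [10, 20, 30, 40]], dtype=float)
        clim = toy_climate(vals)
        env = standardize_climate(clim)
        surf = fit_gower([0], clim).project(env)
        assert surf[2] == pytest.approx(0.0)  # differs by the full range everywhere

    def test_adding_a_presence_never_decreases_suitability(self, env):
        cells = env.grid.masked_ids
        small = fit_gower(cells[:3], env.climate).project(env)
        large = fit_gower(cells[:6], env.climate).project(env)
        mask = env.grid.mask
        assert np.all(large[mask] >= small[mask] - 1e-12)


class TestENFA:
    def test_presence_median_cell_scores_one(self):
        # comonotonic variables: the component-wise presence median is
        # itself a cell
        i = np.arange(9, dtype=float)
        vals = np.column_stack([i, 2 * i, -i, 10 + 3 * i])
        env = standardize_climate(toy_climate(vals))
        with pytest.warns(UserWarning, match="singular presence covariance"):
            surf = fit_enfa([4, 5, 6, 7, 8], env).project(env)
        assert surf[6] == pytest.approx(1.0)

    def test_zero_marginality_falls_back_to_principal_axes(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(100, 4))
        env = standardize_climate(toy_climate(vals, n_rows=10))
        model = fit_enfa(list(range(100)), env)  # presences = everything
        assert np.allclose(model.marginality, 0.0)
        surf = model.project(env)
        assert np.nanmin(surf) >= 0 and np.nanmax(surf) <= 1

    def test_marginality_recovers_temperature_displacement(self):
        # species displaced +2 global SD on temperature only
        clim = iid_climate(400, seed=12)
        env = standardize_climate(clim)
        z = env.masked_values("current")
        weight = np.exp(-0.5 * ((z[:, 0] - 2.0) / 0.5) ** 2)
        rng = np.random.default_rng(99)
        cells = rng.choice(clim.grid.masked_ids, size=500, replace=True,
                           p=weight / weight.sum())
        model = fit_enfa(cells, env)
        assert np.abs(model.marginality - np.array([1, 0, 0, 0])).max() < 0.15

    def test_too_few_presences_rejected(self, env):
        with pytest.raises(ValueError):
            fit_enfa(env.grid.masked_ids[:4], env)


class TestMaxEnt:
    def test_infinite_penalty_gives_uniform_surface(self, env):
        model = fit_maxent(env.grid.masked_ids[:10], env, regularization=1e4)
        assert np.allclose(model.lambdas, 0, atol=1e-4)
        surf = model.project(env)
        assert np.nanstd(surf) < 1e-3

    def test_moment_matching_at_zero_penalty(self, env):
        """The unpenalized maxent solution reproduces the presence
        feature means as the fitted distribution's expectations."""
        cells = env.grid.masked_ids[::7][:40]
        model = fit_maxent(cells, env, regularization=0.0)
        z_bg = env.masked_values("current")
        eta = _maxent_features(z_bg) @ model.lambdas
        p = np.exp(eta - eta.max())
        p /= p.sum()
        fitted_means = p @ _maxent_features(z_bg)
        presence_means = _maxent_features(env.values("current")[cells]).mean(axis=0)
        assert np.allclose(fitted_means, presence_means, atol=1e-3)

    def test_warm_adapted_species_gets_positive_temperature_weight(self):
        clim = iid_climate(100, seed=5)
        env = standardize_climate(clim)
        z = env.masked_values("current")
        presences = clim.grid.masked_ids[np.argsort(z[:, 0])[-15:]]
        model = fit_maxent(presences, env, regularization=0.01)
        assert model.lambdas[0] > 0


def separable_toy(n_cells: int = 50, seed: int = 17):
    """Presences inside a temperature box, absences outside: a single
    envelope rule suffices for perfect accuracy."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 1, size=(n_cells, 4)) + [20, 2500, 1400, 45]
    clim = toy_climate(vals, n_rows=5)
    env = standardize_climate(clim)
    z = env.masked_values("current")[:, 0]
    inside = (z > -0.4) & (z < 0.6)
    presences = np.flatnonzero(inside)
    absences = np.flatnonzero(~inside)
    return env, presences, absences


def envelope_search_accuracy(env, presences, absences) -> float:
    """Brute-force oracle: best training accuracy achievable by a
    single one-variable envelope rule (inside -> presence)."""
    z = env.masked_values("current")
    labels = np.zeros(z.shape[0], dtype=bool)
    labels[presences] = True
    keep = np.zeros(z.shape[0], dtype=bool)
    keep[presences] = keep[absences] = True
    best = 0.0
    for v in range(4):
        cuts = np.unique(z[keep, v])
        edges = np.concatenate([[cuts[0] - 1], (cuts[:-1] + cuts[1:]) / 2, [cuts[-1] + 1]])
        for i, lo in enumerate(edges):
            for hi in edges[i:]:
                pred = (z[:, v] >= lo) & (z[:, v] <= hi)
                best = max(best, (pred[keep] == labels[keep]).mean())
    return float(best)


class TestGARP:
    def test_reaches_envelope_search_optimum_on_separable_toy(self):
        env, pres, absn = separable_toy()
        oracle = envelope_search_accuracy(env, pres, absn)
        assert oracle == 1.0
        model = fit_garp(pres, absn, env, GAParams(seed=21))
        assert model.fitness == pytest.approx(oracle)

    def test_same_seed_identical_rule_set(self):
        env, pres, absn = separable_toy()
        a = fit_garp(pres, absn, env, GAParams(seed=4, generations=10))
        b = fit_garp(pres, absn, env, GAParams(seed=4, generations=10))
        assert np.array_equal(a.lows, b.lows) and np.array_equal(a.highs, b.highs)
        assert np.array_equal(a.predicts, b.predicts)

    def test_suitability_values_are_small_rational_fractions(self):
        env, pres, absn = separable_toy()
        model = fit_garp(pres, absn, env, GAParams(seed=1, generations=5, n_rules=4))
        surf = model.project(env)
        vals = surf[~np.isnan(surf)]
        # fractions a/b with b <= the rule-set size
        achievable = {a / b for b in range(1, 5) for a in range(b + 1)} | {0.0}
        assert all(any(abs(v - f) < 1e-12 for f in achievable) for v in vals)


class TestANN:
    def test_separable_toy_reaches_high_accuracy(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, size=(40, 4)) + [20, 2500, 1400, 45]
        env = standardize_climate(toy_climate(vals, n_rows=4))
        z = env.masked_values("current")[:, 0]
        pres, absn = np.flatnonzero(z > 0), np.flatnonzero(z <= 0)
        model = fit_ann(pres, absn, env, NetParams(seed=0))
        surf = model.project(env)
        pred = surf[env.grid.mask] >= 0.5
        truth = z > 0
        assert (pred == truth).mean() >= 0.95

    def test_zero_epochs_outputs_near_half(self, env):
        cells = env.grid.masked_ids
        model = fit_ann(cells[:10], cells[10:20], env, NetParams(seed=0, epochs=0))
        surf = model.project(env)
        vals = surf[~np.isnan(surf)]
        assert np.all((vals > 0.4) & (vals < 0.6))

    def test_same_seed_identical_weights(self, env):
        cells = env.grid.masked_ids
        a = fit_ann(cells[:10], cells[10:20], env, NetParams(seed=6, epochs=50))
        b = fit_ann(cells[:10], cells[10:20], env, NetParams(seed=6, epochs=50))
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)


def _contrast_for(method, grid, cells):
    """Pseudo-absences only where the method consumes them; background
    methods keep their default (all masked cells)."""
    from consenm.models import METHOD_DATA_NEEDS

    if METHOD_DATA_NEEDS[method] == "pseudo_absence":
        return draw_pseudo_absences(grid, cells, seed=13)
    return None


@pytest.mark.parametrize("method", ALL_METHODS)
def test_truth_recovery_and_bounds(method, grid20, climate, env, wide_species):
    """Each method, fitted to an abundantly sampled synthetic species,
    ranks cells consistently with the true suitability surface
    (Spearman rho > 0.5) and stays inside [0, 1]."""
    truth, cells = wide_species
    assert cells.size >= 150  # abundant sampling premise
    contrast = _contrast_for(method, grid20, cells)
    model = fit_model(method, cells, contrast, env, seed=31)
    surf = model.project(env)
    mask = grid20.mask
    assert np.nanmin(surf[mask]) >= 0.0 and np.nanmax(surf[mask]) <= 1.0
    true = truth.true_suitability(climate)[0][mask]
    rho = spearmanr(surf[mask], true).statistic
    assert rho > 0.5, f"{method}: rho={rho:.3f}"
    # true-optimum cell ranks in the top 5% of projected suitability
    best_cell = np.nanargmax(truth.true_suitability(climate)[0])
    frac_above = np.mean(surf[mask] > surf[best_cell])
    assert frac_above <= 0.05, f"{method}: optimum at quantile {1 - frac_above:.3f}"


@pytest.mark.parametrize("method", ALL_METHODS)
def test_serialization_round_trip(method, grid20, env, wide_species):
    _, cells = wide_species
    contrast = _contrast_for(method, grid20, cells)
    model = fit_model(method, cells, contrast, env, seed=31)
    clone = model_from_dict(json.loads(json.dumps(model.to_dict())))
    a, b = model.project(env), clone.project(env)
    assert np.allclose(a[grid20.mask], b[grid20.mask], atol=1e-12)
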