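"""Pseudo-absence sampling, stratified cross-validation, ROC
thresholding and the True Skill Statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consenm import (
    ConfusionCounts,
    draw_pseudo_absences,
    evaluate_projection,
    partition_data,
    roc_threshold,
    tss,
)
from consenm.models import NicheModel


class TestPseudoAbsences:
    def test_default_count_and_disjointness(self, grid20):
        presences = grid20.masked_ids[:10]
        pa = draw_pseudo_absences(grid20, presences, seed=0)
        assert pa.size == 10
        assert not np.intersect1d(pa, presences).size

    def test_same_seed_identical_draw(self, grid20):
        presences = grid20.masked_ids[:10]
        assert np.array_equal(
            draw_pseudo_absences(grid20, presences, seed=4),
            draw_pseudo_absences(grid20, presences, seed=4),
        )

    def test_overdraw_errors(self, grid20):
        with pytest.raises(ValueError):
            draw_pseudo_absences(grid20, grid20.masked_ids[:10], n=10_000)

    def test_uniformity_over_small_candidate_pool(self):
        """Over many draws from a 4-cell pool, per-cell selection
        frequency is binomial-uniform within 3 SE."""
        from consenm import build_grid

        grid = build_grid((0, 0, 60, 10), 10)  # 6 cells
        presences = [0, 1]  # candidates: cells 2..5
        n_draws, per_draw = 1000, 2
        counts = np.zeros(6)
        rng = np.random.default_rng(7)
        for _ in range(n_draws):
            for c in draw_pseudo_absences(grid, presences, n=per_draw, seed=rng):
                counts[c] += 1
        p = per_draw / 4  # inclusion probability per candidate cell
        se = np.sqrt(n_draws * p * (1 - p))
        assert np.all(np.abs(counts[2:] - n_draws * p) < 3 * se)


class TestPartition:
    def test_exact_75_25_split(self):
        parts = partition_data(range(8), range(100, 108), seed=0)
        assert len(parts) == 10
        for p in parts:
            assert p.calib_presence.size == 6 and p.valid_presence.size == 2
            assert p.calib_absence.size == 6 and p.valid_absence.size == 2

    def test_splits_are_disjoint_and_exhaustive(self):
        parts = partition_data(range(13), range(100, 111), seed=3)
        for p in parts:
            assert not np.intersect1d(p.calib_presence, p.valid_presence).size
            assert set(p.calib_presence) | set(p.valid_presence) == set(range(13))

    def test_prevalence_preserved_for_multiples_of_four(self):
        parts = partition_data(range(12), range(100, 136), seed=1)
        for p in parts:
            calib_prev = p.calib_presence.size / (p.calib_presence.size + p.calib_absence.size)
            valid_prev = p.valid_presence.size / (p.valid_presence.size + p.valid_absence.size)
            assert calib_prev == valid_prev == 12 / 48

    def test_small_class_errors_with_species_name(self):
        with pytest.raises(ValueError, match="moth_sp_1"):
            partition_data(range(3), range(100, 110), species_id="moth_sp_1")


def brute_force_threshold(scores, labels):
    """Independent oracle: exhaustively score every midpoint candidate."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    distinct = np.unique(scores)
    candidates = np.concatenate(
        [[distinct[0] - 1], (distinct[:-1] + distinct[1:]) / 2, [distinct[-1] + 1]]
    )
    best_t, best_obj = None, -np.inf
    for t in candidates:
        pred = scores >= t
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        if sens + spec > best_obj + 1e-12:
            best_t, best_obj = t, sens + spec
    return best_t, best_obj


class TestRocThreshold:
    def test_separable_scores_split_at_midpoint(self):
        t, cc = roc_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.5)
        assert cc.sensitivity == cc.specificity == 1.0

    def test_constant_scores_degenerate_optimum(self):
        t, cc = roc_threshold([0.3, 0.3, 0.3, 0.3], [0, 1, 0, 1])
        assert cc.sensitivity + cc.specificity == pytest.approx(1.0)

    def test_ties_break_toward_lower_threshold(self):
        # both caps achieve sens+spec = 1; the lower (all-presence) wins
        t, cc = roc_threshold([0.5, 0.5], [0, 1])
        assert t < 0.5
        assert cc.sensitivity == 1.0

    def test_matches_exhaustive_search_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n) + rng.normal(0, 0.05, n)
            labels = rng.integers(0, 2, size=n)
            if labels.all() or not labels.any():
                continue
            t, cc = roc_threshold(scores, labels)
            t_oracle, obj_oracle = brute_force_threshold(scores, labels)
            assert cc.sensitivity + cc.specificity == pytest.approx(obj_oracle)
            assert t == pytest.approx(t_oracle)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_threshold([0.1, 0.9], [1, 1])


class TestTSS:
    def test_perfect_prediction_scores_one(self):
        assert tss(ConfusionCounts(tp=10, fp=0, fn=0, tn=10)) == 1.0

    def test_all_presence_prediction_scores_zero(self):
        assert tss(ConfusionCounts(tp=10, fp=10, fn=0, tn=0)) == 0.0

    def test_arithmetic_example(self):
        assert tss(ConfusionCounts(tp=40, fp=10, fn=5, tn=45)) == pytest.approx(
            40 / 45 + 45 / 55 - 1
        )

    def test_undefined_denominator_errors(self):
        with pytest.raises(ValueError):
            tss(ConfusionCounts(tp=0, fp=5, fn=0, tn=5))

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    @settings(derandomize=True, max_examples=200)
    def test_bounded_in_minus_one_one(self, tp, fp, fn, tn):
        if tp + fn == 0 or tn + fp == 0:
            return
        assert -1.0 <= tss(ConfusionCounts(tp, fp, fn, tn)) <= 1.0


class _ScriptedModel(NicheModel):
    """Test double: projects fixed per-scenario surfaces."""

    method = "scripted"

    def __init__(self, surfaces):
        self.surfaces = surfaces

    def project(self, env, scenario="current"):
        return self.surfaces[scenario]

    def to_dict(self):
        return {"method": self.method}


class TestEvaluateProjection:
    def _partition(self, presences, absences):
        return partition_data(presences, absences, n_reps=1, seed=0)[0]

    def test_perfect_model_gets_tss_one_and_covers_presences(self, grid20, env):
        presences = grid20.masked_ids[:8]
        absences = grid20.masked_ids[8:16]
        surface = np.zeros(grid20.n_cells)
        surface[presences] = 1.0
        part = self._partition(presences, absences)
        ep = evaluate_projection(_ScriptedModel({"current": surface}), part, env)
        assert ep.tss == 1.0
        assert np.all(ep.binary_range[part.valid_presence])

    def test_constant_surface_has_zero_skill(self, grid20, env):
        surface = np.full(grid20.n_cells, 0.4)
        part = self._partition(grid20.masked_ids[:8], grid20.masked_ids[8:16])
        ep = evaluate_projection(_ScriptedModel({"current": surface}), part, env)
        assert ep.tss == 0.0

    def test_future_binary_range_reuses_current_threshold(self, grid20, env):
        presences, absences = grid20.masked_ids[:8], grid20.masked_ids[8:16]
        current = np.zeros(grid20.n_cells)
        current[presences] = 1.0
        future = np.full(grid20.n_cells, 0.8)  # everywhere above the threshold
        part = self._partition(presences, absences)
        model = _ScriptedModel({"current": current, "gcm1": future})
        ep_cur = evaluate_projection(model, part, env, "current")
        ep_fut = evaluate_projection(model, part, env, "gcm1")
        assert ep_fut.threshold == ep_cur.threshold
        assert ep_fut.tss == ep_cur.tss  # skill is a current-climate property
        assert ep_fut.binary_range[grid20.mask].all()
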