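import numpy as np
import pytest

from tvcgnet.optimize import (
    Particle,
    StageResult,
    SwarmConfig,
    bpso_maximize,
    final_evaluate,
    inertia,
    pso_maximize,
    pso_step,
    repair_threshold_order,
    sigmoid,
    stage1_optimize_cn,
    stage2_optimize_weights,
    stage3_select_features,
    STAGE1_BOUNDS,
    STAGE2_BOUNDS,
    validation_fitness,
)
from tvcgnet.complex_network import CNParams, DEFAULT_CN_PARAMS
from tvcgnet import pipeline
from tvcgnet.pipeline import beats_from_records, full_feature_matrix, labels_of

from conftest import make_corpus


class TestInertia:
    def test_endpoints_and_midpoint(self):
        assert inertia(1, 100) == pytest.approx(0.9)
        assert inertia(100, 100) == pytest.approx(0.4)
        assert inertia(51, 101) == pytest.approx(0.65)

    def test_single_iteration(self):
        assert inertia(1, 1) == 0.9


def _cfg(**kw):
    defaults = dict(n_particles=5, n_iterations=10,
                    bounds=np.tile([-5.0, 5.0], (3, 1)), seed=0)
    defaults.update(kw)
    return SwarmConfig(**defaults)


class TestPSOStep:
    def test_converged_particle_is_fixed_point(self):
        cfg = _cfg()
        x = np.array([1.0, 2.0, 3.0])
        p = Particle(x.copy(), np.zeros(3), x.copy(), 0.0)
        pso_step([p], x.copy(), cfg, t=1, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(p.position, x)
        np.testing.assert_array_equal(p.velocity, 0.0)

    def test_pure_inertia_halves_velocity(self):
        # with c1 = c2 = 0 the update reduces to geometric decay
        cfg = _cfg(c1=0.0, c2=0.0, w_start=0.5, w_end=0.5)
        p = Particle(np.zeros(3), np.ones(3), np.zeros(3), 0.0)
        pso_step([p], np.zeros(3), cfg, t=1, rng=np.random.default_rng(0))
        np.testing.assert_allclose(p.velocity, 0.5)

    def test_velocity_clamped(self):
        cfg = _cfg(v_max=np.full(3, 0.1))
        p = Particle(np.full(3, -5.0), np.zeros(3), np.full(3, -5.0), 0.0)
        pso_step([p], np.full(3, 5.0), cfg, t=1, rng=np.random.default_rng(1))
        assert (np.abs(p.velocity) <= 0.1 + 1e-12).all()


class TestPSOMaximize:
    def test_sphere_seeded_runs_identically(self):
        obj = lambda x: -float(np.sum(x**2))
        cfg1 = _cfg(n_particles=10, n_iterations=20, seed=3)
        cfg2 = _cfg(n_particles=10, n_iterations=20, seed=3)
        r1, r2 = pso_maximize(obj, cfg1), pso_maximize(obj, cfg2)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        assert r1.trace == r2.trace

    def test_trace_monotone_non_decreasing(self):
        obj = lambda x: -float(np.sum(x**2))
        res = pso_maximize(obj, _cfg(n_particles=8, n_iterations=30, seed=1))
        assert (np.diff(res.trace) >= 0).all()

    def test_single_iteration_returns_best_initial(self):
        obj = lambda x: -float(np.sum(x**2))
        cfg = _cfg(n_particles=6, n_iterations=1, seed=2)
        res = pso_maximize(obj, cfg)
        rng = np.random.default_rng(2)
        lo, hi = cfg.bounds[:, 0], cfg.bounds[:, 1]
        init_best = max(obj(rng.uniform(lo, hi)) for _ in range(6))
        assert res.trace[0] == pytest.approx(init_best)

    def test_non_finite_objective_treated_as_worst(self):
        def obj(x):
            return np.nan if x[0] > 0 else -float(np.sum(x**2))
        res = pso_maximize(obj, _cfg(n_particles=8, n_iterations=10, seed=4))
        assert np.isfinite(res.best_fitness)
        assert res.best_position[0] <= 0


class TestBPSO:
    def test_sigmoid_values(self):
        assert sigmoid(np.array([0.0]))[0] == 0.5
        assert sigmoid(np.array([30.0]))[0] == pytest.approx(1.0)
        assert sigmoid(np.array([-30.0]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_seeded_determinism(self):
        obj = lambda bits: float(bits.sum())
        r1 = bpso_maximize(obj, 12, 8, 15, seed=5)
        r2 = bpso_maximize(obj, 12, 8, 15, seed=5)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    def test_all_ones_in_initial_population(self):
        # objective rewarding all-ones: already optimal at initialization
        obj = lambda bits: float(bits.sum())
        res = bpso_maximize(obj, 10, 5, 1, seed=0)
        assert res.trace[0] == 10.0


class TestRepair:
    def test_inverted_thresholds_swapped(self):
        x = repair_threshold_order(np.array([5.0, 0.19, 0.11]), STAGE1_BOUNDS)
        assert x[1] <= x[2]
        assert STAGE1_BOUNDS[1, 0] <= x[1] <= STAGE1_BOUNDS[1, 1]
        assert STAGE1_BOUNDS[2, 0] <= x[2] <= STAGE1_BOUNDS[2, 1]

    def test_valid_position_untouched(self):
        x = np.array([3.0, 0.05, 0.5])
        np.testing.assert_array_equal(repair_threshold_order(x, STAGE1_BOUNDS), x)


@pytest.fixture(scope="module")
def stage_corpus(default_config):
    train = make_corpus(2, 30, seed=21, config=default_config)
    valid = make_corpus(2, 30, seed=22, config=default_config)
    tb = beats_from_records(train, synthetic_config=default_config)
    vb = beats_from_records(valid, synthetic_config=default_config)
    return train, valid, tb, vb


class TestStages:
    def test_stage1_smoke_and_reevaluation(self, stage_corpus, default_config):
        _, _, tb, vb = stage_corpus
        params, res = stage1_optimize_cn(tb, vb, n_particles=5,
                                         n_iterations=3, seed=1)
        assert 1 <= params.m <= 10
        assert 0.001 <= params.t0 <= 0.2
        assert 0.1 <= params.tq <= 1.0
        # returned fitness must equal re-evaluating the returned params
        tw = pipeline.precompute_weight_matrices(tb)
        vw = pipeline.precompute_weight_matrices(vb)
        Xt = pipeline.tvcg_rr_matrix(tb, tw, params)
        Xv = pipeline.tvcg_rr_matrix(vb, vw, params)
        redo = validation_fitness(Xt, labels_of(tb), Xv, labels_of(vb),
                                  (6.0, 100.0, 15.0))
        assert redo == pytest.approx(res.best_fitness)

    def test_stage1_seeded_reproducibility(self, stage_corpus):
        _, _, tb, vb = stage_corpus
        p1, _ = stage1_optimize_cn(tb, vb, n_particles=4, n_iterations=2, seed=9)
        p2, _ = stage1_optimize_cn(tb, vb, n_particles=4, n_iterations=2, seed=9)
        assert p1 == p2

    def test_stage2_bounds_and_reevaluation(self, stage_corpus):
        _, _, tb, vb = stage_corpus
        Xt, _ = full_feature_matrix(tb, DEFAULT_CN_PARAMS)
        Xv, _ = full_feature_matrix(vb, DEFAULT_CN_PARAMS)
        yt, yv = labels_of(tb), labels_of(vb)
        w, res = stage2_optimize_weights(Xt, yt, Xv, yv, n_particles=5,
                                         n_iterations=3, seed=2)
        for val, (lo, hi) in zip(w, STAGE2_BOUNDS):
            assert lo <= val <= hi
        assert validation_fitness(Xt, yt, Xv, yv, w) == \
            pytest.approx(res.best_fitness)

    def test_stage3_mask_contract(self, stage_corpus):
        _, _, tb, vb = stage_corpus
        Xt, _ = full_feature_matrix(tb, DEFAULT_CN_PARAMS)
        Xv, _ = full_feature_matrix(vb, DEFAULT_CN_PARAMS)
        yt, yv = labels_of(tb), labels_of(vb)
        mask, res = stage3_select_features(Xt, yt, Xv, yv, (6.0, 100.0, 15.0),
                                           n_particles=6, n_iterations=3, seed=3)
        assert mask.shape == (Xt.shape[1],)
        assert mask.dtype == bool
        assert mask.any()
        # masked training really uses only the selected columns
        redo = validation_fitness(Xt[:, mask], yt, Xv[:, mask], yv,
                                  (6.0, 100.0, 15.0))
        assert redo == pytest.approx(res.best_fitness)


class TestFinalEvaluate:
    def test_inter_patient_guard(self, small_corpus, default_config):
        with pytest.raises(ValueError, match="inter-patient"):
            final_evaluate(small_corpus[:2], small_corpus[1:3],
                           DEFAULT_CN_PARAMS, (6.0, 100.0, 15.0),
                           synthetic_config=default_config)

    def test_disjoint_split_evaluates(self, small_corpus, default_config):
        metrics, cm, fit = final_evaluate(
            small_corpus[:2], small_corpus[2:], DEFAULT_CN_PARAMS,
            (6.0, 100.0, 15.0), synthetic_config=default_config)
        assert cm.total == sum(len(r.beats) for r in small_corpus[2:])
        assert 0.0 <= fit.mean <= 1.0
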