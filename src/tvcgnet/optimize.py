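"""Particle swarm optimization of the classification pipeline.

Continuous PSO with a linearly decreasing inertia weight drives two tuning
stages -- the complex-network threshold parameters (T_0, T_Q, m) and the
per-class SVM penalty weights (w1, w2, w3) -- and a binary PSO (sigmoid
velocity transfer, no inertia) performs wrapper feature selection.  The
velocity update is

    v = w(t) v + c1 r1 (pbest - x) + c2 r2 (gbest - x)

with fresh uniform(0,1) draws r1, r2 per particle component, c1 = c2 = 2.05
and w(t) falling linearly from 0.9 to 0.4 over the run.  Velocities are
clamped componentwise; continuous positions are clipped to their bounds.
The fitness everywhere is the mean per-class F-score of the weighted SVM on
a validation split whose patients are disjoint from training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classify_eval import AAMIMetrics, ConfusionMatrix, FitnessValue, \
    SVMConfig, aami_metrics, confusion, fitness, predict, train_classifier
from .complex_network import CNParams, round_m
from .io_data import ECGRecord
from .preprocessing import FilterSpec
from .reference_features import FeatureStandardizer
from .synthetic_ecg import SyntheticBeatConfig
from .tvcg import BeatWindow, DEFAULT_SUBSAMPLE_STEP
from . import pipeline

logger = logging.getLogger(__name__)

#: Search boxes.  The threshold limits live on the normalized weight scale
#: [0, 1]; m is an integer iteration count.
STAGE1_BOUNDS = np.array([[1.0, 10.0],    # m (rounded at evaluation)
                          [0.001, 0.2],   # T_0
                          [0.1, 1.0]])    # T_Q
STAGE2_BOUNDS = np.array([[1.0, 5.0],     # w1 (N)
                          [10.0, 200.0],  # w2 (S)
                          [5.0, 100.0]])  # w3 (V)
STAGE1_FIXED_WEIGHTS = (6.0, 100.0, 15.0)


@dataclass
class SwarmConfig:
    """PSO hyperparameters; defaults follow the canonical constricted
    swarm (c1 = c2 = 2.05, inertia 0.9 -> 0.4)."""

    n_particles: int
    n_iterations: int
    bounds: np.ndarray  # (d, 2)
    seed: int = 0
    c1: float = 2.05
    c2: float = 2.05
    w_start: float = 0.9
    w_end: float = 0.4
    v_max: np.ndarray | None = None  # default 0.5 * (upper - lower)

    def __post_init__(self) -> None:
        self.bounds = np.atleast_2d(np.asarray(self.bounds, float))
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if (self.bounds[:, 0] >= self.bounds[:, 1]).any():
            raise ValueError("each lower bound must be below its upper bound")
        if self.v_max is None:
            self.v_max = 0.5 * (self.bounds[:, 1] - self.bounds[:, 0])

    @property
    def dim(self) -> int:
        return len(self.bounds)


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class StageResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[float] = field(default_factory=list)  # best-so-far per iteration


def inertia(t: int, total: int, w_start: float = 0.9, w_end: float = 0.4) -> float:
    """Linearly decreasing inertia weight; iteration t in 1..total."""
    if not 1 <= t <= total:
        raise ValueError(f"iteration {t} outside 1..{total}")
    if total == 1:
        return w_start
    return w_start - (t - 1) / (total - 1) * (w_start - w_end)


def pso_step(
    swarm: list[Particle],
    gbest: np.ndarray,
    cfg: SwarmConfig,
    t: int,
    rng: np.random.Generator,
) -> None:
    """One synchronous velocity/position update of the whole swarm."""
    w = inertia(t, cfg.n_iterations, cfg.w_start, cfg.w_end)
    for p in swarm:
        r1 = rng.uniform(size=cfg.dim)
        r2 = rng.uniform(size=cfg.dim)
        p.velocity = (
            w * p.velocity
            + cfg.c1 * r1 * (p.pbest_position - p.position)
            + cfg.c2 * r2 * (gbest - p.position)
        )
        p.velocity = np.clip(p.velocity, -cfg.v_max, cfg.v_max)
        p.position = np.clip(p.position + p.velocity,
                             cfg.bounds[:, 0], cfg.bounds[:, 1])


def _safe_fitness(objective, x: np.ndarray) -> float:
    val = float(objective(x))
    if not np.isfinite(val):
        logger.warning("non-finite objective at %s; treated as -inf", x)
        return -np.inf
    return val


def pso_maximize(objective, cfg: SwarmConfig) -> StageResult:
    """Maximize ``objective`` over the box with inertia-weighted PSO.

    gbest is updated after each full swarm evaluation (synchronous).
    Deterministic for a fixed (config, seed).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds[:, 0], cfg.bounds[:, 1]
    swarm = []
    for _ in range(cfg.n_particles):
        x = rng.uniform(lo, hi)
        f = _safe_fitness(objective, x)
        swarm.append(Particle(x, np.zeros(cfg.dim), x.copy(), f))
    best = max(swarm, key=lambda p: p.pbest_fitness)
    gbest, gbest_f = best.pbest_position.copy(), best.pbest_fitness
    trace = [gbest_f]
    for t in range(1, cfg.n_iterations + 1):
        pso_step(swarm, gbest, cfg, t, rng)
        for p in swarm:
            f = _safe_fitness(objective, p.position)
            if f > p.pbest_fitness:
                p.pbest_fitness = f
                p.pbest_position = p.position.copy()
        best = max(swarm, key=lambda p: p.pbest_fitness)
        if best.pbest_fitness > gbest_f:
            gbest_f = best.pbest_fitness
            gbest = best.pbest_position.copy()
        trace.append(gbest_f)
    return StageResult(gbest, gbest_f, trace)


def sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def bpso_step(
    swarm: list[Particle],
    gbest: np.ndarray,
    cfg: SwarmConfig,
    rng: np.random.Generator,
    w: float = 1.0,
) -> None:
    """One binary-PSO update: real velocities, bit positions re-sampled with
    probability s(v).  No inertia by default (w = 1)."""
    for p in swarm:
        r1 = rng.uniform(size=cfg.dim)
        r2 = rng.uniform(size=cfg.dim)
        p.velocity = (
            w * p.velocity
            + cfg.c1 * r1 * (p.pbest_position - p.position)
            + cfg.c2 * r2 * (gbest - p.position)
        )
        p.velocity = np.clip(p.velocity, -cfg.v_max, cfg.v_max)
        p.position = (rng.uniform(size=cfg.dim) < sigmoid(p.velocity)).astype(float)


def bpso_maximize(
    objective,
    n_bits: int,
    n_particles: int,
    n_iterations: int,
    seed: int = 0,
    init_all_ones: bool = True,
    init_flip_prob: float = 0.05,
    v_max: float = 4.0,
    use_inertia: bool = False,
) -> StageResult:
    """Maximize a bit-mask objective with binary PSO.

    The initial population includes the all-ones mask; the remaining
    particles start from all-ones with small seeded bit-flip noise to
    create diversity.
    """
    cfg = SwarmConfig(
        n_particles=n_particles,
        n_iterations=n_iterations,
        bounds=np.tile([0.0, 1.0], (n_bits, 1)),
        seed=seed,
        v_max=np.full(n_bits, v_max),
    )
    rng = np.random.default_rng(seed)
    swarm = []
    for k in range(n_particles):
        if init_all_ones:
            x = np.ones(n_bits)
            if k > 0:
                x[rng.uniform(size=n_bits) < init_flip_prob] = 0.0
        else:
            x = (rng.uniform(size=n_bits) < 0.5).astype(float)
        f = _safe_fitness(objective, x)
        swarm.append(Particle(x, np.zeros(n_bits), x.copy(), f))
    best = max(swarm, key=lambda p: p.pbest_fitness)
    gbest, gbest_f = best.pbest_position.copy(), best.pbest_fitness
    trace = [gbest_f]
    for t in range(1, n_iterations + 1):
        w = inertia(t, n_iterations) if use_inertia else 1.0
        bpso_step(swarm, gbest, cfg, rng, w=w)
        for p in swarm:
            f = _safe_fitness(objective, p.position)
            if f > p.pbest_fitness:
                p.pbest_fitness = f
                p.pbest_position = p.position.copy()
        best = max(swarm, key=lambda p: p.pbest_fitness)
        if best.pbest_fitness > gbest_f:
            gbest_f = best.pbest_fitness
            gbest = best.pbest_position.copy()
        trace.append(gbest_f)
    return StageResult(gbest, gbest_f, trace)


# ---------------------------------------------------------------------------
# validation-fitness objectives


def validation_fitness(
    train_X: np.ndarray,
    train_y: np.ndarray,
    valid_X: np.ndarray,
    valid_y: np.ndarray,
    class_weights: tuple[float, float, float],
) -> float:
    """Mean per-class F-score of the weighted SVM on the validation split.
    Features are standardized with training statistics only."""
    std = FeatureStandardizer().fit(train_X)
    Xt, Xv = std.transform(train_X), std.transform(valid_X)
    model = train_classifier(Xt, train_y, SVMConfig(class_weights=class_weights))
    cm = confusion(valid_y, predict(model, Xv))
    return fitness(cm).mean


def repair_threshold_order(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Swap (T_0, T_Q) when a particle proposes T_0 > T_Q, then re-clip each
    component to its own box."""
    x = x.copy()
    if x[1] > x[2]:
        x[1], x[2] = x[2], x[1]
        x[1:] = np.clip(x[1:], bounds[1:, 0], bounds[1:, 1])
        if x[1] > x[2]:  # still inverted after clipping: collapse the span
            x[1] = x[2]
    return x


def stage1_optimize_cn(
    train_beats: list[BeatWindow],
    valid_beats: list[BeatWindow],
    n_particles: int = 100,
    n_iterations: int = 50,
    seed: int = 0,
    subsample_step: int = DEFAULT_SUBSAMPLE_STEP,
    class_weights: tuple[float, float, float] = STAGE1_FIXED_WEIGHTS,
) -> tuple[CNParams, StageResult]:
    """Stage 1: find the threshold-evolution parameters (T_0, T_Q, m).

    Only the TVCG descriptors and the three RR features feed the classifier
    at this stage; the SVM class weights are held fixed.
    """
    train_w = pipeline.precompute_weight_matrices(train_beats, subsample_step)
    valid_w = pipeline.precompute_weight_matrices(valid_beats, subsample_step)
    train_y = pipeline.labels_of(train_beats)
    valid_y = pipeline.labels_of(valid_beats)
    cache: dict[tuple, float] = {}

    def params_of(x: np.ndarray) -> CNParams:
        return CNParams(t0=float(x[1]), tq=float(x[2]), m=round_m(float(x[0])))

    def objective(x: np.ndarray) -> float:
        x = repair_threshold_order(x, STAGE1_BOUNDS)
        p = params_of(x)
        key = (p.m, round(p.t0, 6), round(p.tq, 6))
        if key not in cache:
            Xt = pipeline.tvcg_rr_matrix(train_beats, train_w, p)
            Xv = pipeline.tvcg_rr_matrix(valid_beats, valid_w, p)
            cache[key] = validation_fitness(Xt, train_y, Xv, valid_y,
                                            class_weights)
        return cache[key]

    cfg = SwarmConfig(n_particles=n_particles, n_iterations=n_iterations,
                      bounds=STAGE1_BOUNDS, seed=seed)
    result = pso_maximize(objective, cfg)
    best = repair_threshold_order(result.best_position, STAGE1_BOUNDS)
    return params_of(best), result


def stage2_optimize_weights(
    train_X: np.ndarray,
    train_y: np.ndarray,
    valid_X: np.ndarray,
    valid_y: np.ndarray,
    n_particles: int = 100,
    n_iterations: int = 100,
    seed: int = 0,
) -> tuple[tuple[float, float, float], StageResult]:
    """Stage 2: tune the per-class SVM penalty weights (w1, w2, w3) on the
    full feature matrix."""
    cache: dict[tuple, float] = {}

    def objective(x: np.ndarray) -> float:
        key = tuple(np.round(x, 4))
        if key not in cache:
            cache[key] = validation_fitness(train_X, train_y, valid_X,
                                            valid_y, tuple(float(v) for v in x))
        return cache[key]

    cfg = SwarmConfig(n_particles=n_particles, n_iterations=n_iterations,
                      bounds=STAGE2_BOUNDS, seed=seed)
    result = pso_maximize(objective, cfg)
    w = tuple(float(v) for v in result.best_position)
    return w, result


def stage3_select_features(
    train_X: np.ndarray,
    train_y: np.ndarray,
    valid_X: np.ndarray,
    valid_y: np.ndarray,
    class_weights: tuple[float, float, float],
    n_particles: int = 300,
    n_iterations: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, StageResult]:
    """Stage 3: wrapper feature selection by binary PSO.  The all-zero mask
    is infeasible (fitness -inf)."""
    cache: dict[bytes, float] = {}

    def objective(bits: np.ndarray) -> float:
        mask = bits.astype(bool)
        if not mask.any():
            return -np.inf
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = validation_fitness(train_X[:, mask], train_y,
                                            valid_X[:, mask], valid_y,
                                            class_weights)
        return cache[key]

    result = bpso_maximize(objective, train_X.shape[1], n_particles,
                           n_iterations, seed=seed)
    return result.best_position.astype(bool), result


def final_evaluate(
    train_records: list[ECGRecord],
    test_records: list[ECGRecord],
    cn_params: CNParams,
    class_weights: tuple[float, float, float],
    mask: np.ndarray | None = None,
    filter_spec: FilterSpec | None = None,
    synthetic_config: SyntheticBeatConfig | None = None,
    subsample_step: int = DEFAULT_SUBSAMPLE_STEP,
) -> tuple[AAMIMetrics, ConfusionMatrix, FitnessValue]:
    """Train once on the training records, evaluate on the test records.

    Raises ``ValueError`` if any record id appears in both splits (the
    inter-patient guard).
    """
    overlap = {r.record_id for r in train_records} & \
        {r.record_id for r in test_records}
    if overlap:
        raise ValueError(
            f"inter-patient guard: records in both splits: {sorted(overlap)}"
        )
    train_beats = pipeline.beats_from_records(
        train_records, synthetic_config=synthetic_config, filter_spec=filter_spec)
    test_beats = pipeline.beats_from_records(
        test_records, synthetic_config=synthetic_config, filter_spec=filter_spec)
    Xt, _ = pipeline.full_feature_matrix(train_beats, cn_params, subsample_step)
    Xe, _ = pipeline.full_feature_matrix(test_beats, cn_params, subsample_step)
    if mask is not None:
        mask = np.asarray(mask, bool)
        Xt, Xe = Xt[:, mask], Xe[:, mask]
    std = FeatureStandardizer().fit(Xt)
    model = train_classifier(std.transform(Xt), pipeline.labels_of(train_beats),
                             SVMConfig(class_weights=class_weights))
    pred = predict(model, std.transform(Xe))
    cm = confusion(pipeline.labels_of(test_beats), pred)
    return aami_metrics(cm), cm, fitness(cm)
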