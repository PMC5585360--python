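"""Complex-network shape descriptors of the TVCG point cloud.

The beat's 3-D point set is turned into a complete weighted graph whose edge
weights are pairwise Euclidean distances normalized to [0, 1] by their
maximum.  A dynamic threshold evolution then sweeps a limit T_l from an
initial value T_0 to a final value T_Q in m equally spaced steps,

    T_l = T_0 + l (T_Q - T_0) / (m - 1),      l = 0 .. m-1,

keeping at each step only the edges with weight <= T_l (all vertices
remain).  Five degree-based descriptors are extracted from each thresholded
graph and concatenated into an m x 5 feature vector:

1. mean connectivity degree  -- sum of degrees / n_v^2;
2. maximum connectivity degree -- max degree / n_v;
3. joint degree entropy (bits) -- entropy of the distribution J(a, b) of
   unordered endpoint-degree pairs over the edges;
4. joint degree energy -- sum of J^2;
5. mean joint degree -- sum of J(a, b) (a + b)/2, divided by n_v.

Normalization by n_v keeps all five descriptors in [0, 1] and comparable
across beats with different point counts.  An empty graph yields all zeros.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .tvcg import TVCGPoints, round_half_up

logger = logging.getLogger(__name__)

DESCRIPTOR_NAMES = (
    "mean_degree",
    "max_degree",
    "joint_entropy",
    "joint_energy",
    "mean_joint_degree",
)


@dataclass(frozen=True)
class CNParams:
    """Threshold-evolution parameters: initial limit T_0, final limit T_Q,
    and iteration count m."""

    t0: float
    tq: float
    m: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.t0 <= 1.0 or not 0.0 <= self.tq <= 1.0:
            raise ValueError(f"thresholds must lie in [0, 1], got {self}")
        if self.t0 > self.tq:
            raise ValueError(f"T_0 must not exceed T_Q, got {self}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")


#: Default parameters (m = 2 yields the 10 TVCG features of the full
#: 178-dimensional vector).
DEFAULT_CN_PARAMS = CNParams(t0=0.1, tq=0.6, m=2)


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric matrix of max-normalized pairwise distances."""

    w: np.ndarray

    @property
    def n_v(self) -> int:
        return len(self.w)


def weight_matrix(points: TVCGPoints | np.ndarray) -> WeightMatrix:
    """Pairwise Euclidean distances of the point set, divided by their
    maximum.  If all distances are zero the matrix is all zeros."""
    pts = points.points if isinstance(points, TVCGPoints) else np.asarray(points, float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    d = pdist(pts)
    dmax = d.max()
    if dmax == 0:
        logger.debug("all pairwise distances zero; weight matrix is all zeros")
        return WeightMatrix(np.zeros((len(pts), len(pts))))
    return WeightMatrix(squareform(d / dmax))


def threshold_schedule(params: CNParams) -> np.ndarray:
    """Equally spaced limits from T_0 to T_Q; m = 1 returns [T_0]."""
    if params.m == 1:
        return np.array([params.t0])
    l = np.arange(params.m)
    return params.t0 + l * (params.tq - params.t0) / (params.m - 1)


def threshold_graph(w: WeightMatrix, t: float) -> np.ndarray:
    """Boolean adjacency keeping the edges with weight <= t (edges above the
    limit are removed; all vertices remain)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    adj = w.w <= t
    np.fill_diagonal(adj, False)
    return adj


def cn_descriptors(adj: np.ndarray, n_v: int | None = None) -> np.ndarray:
    """The five degree-based descriptors of a thresholded graph."""
    adj = np.asarray(adj, bool)
    if n_v is None:
        n_v = len(adj)
    if n_v < 2:
        raise ValueError("need at least 2 vertices")
    deg = adj.sum(axis=1)
    ii, jj = np.nonzero(np.triu(adj, 1))
    if len(ii) == 0:
        return np.zeros(5)
    pairs = Counter(
        (min(a, b), max(a, b)) for a, b in zip(deg[ii], deg[jj])
    )
    j = np.array(list(pairs.values()), float) / len(ii)
    pair_means = np.array([(a + b) / 2.0 for a, b in pairs], float)
    entropy = float(-(j * np.log2(j)).sum())
    return np.array([
        deg.sum() / n_v**2,
        deg.max() / n_v,
        entropy,
        float((j**2).sum()),
        float((j * pair_means).sum() / n_v),
    ])


def features_from_weights(w: WeightMatrix, params: CNParams) -> np.ndarray:
    """Descriptor vector from a precomputed weight matrix.  The weight
    matrix is threshold-independent, so sweeping (T_0, T_Q, m) during
    optimization reuses it."""
    return np.concatenate([
        cn_descriptors(threshold_graph(w, t), w.n_v)
        for t in threshold_schedule(params)
    ])


def tvcg_features(points: TVCGPoints, params: CNParams) -> np.ndarray:
    """Flattened m x 5 descriptor vector over the threshold schedule
    (ascending l; descriptor order as in ``DESCRIPTOR_NAMES``)."""
    return features_from_weights(weight_matrix(points), params)


def tvcg_feature_names(params: CNParams) -> list[str]:
    return [
        f"tvcg_l{l}_{name}"
        for l in range(params.m)
        for name in DESCRIPTOR_NAMES
    ]


def round_m(m_continuous: float) -> int:
    """Continuous-to-integer handling of m for the PSO: round half-up,
    clamped to [1, 10]."""
    return int(np.clip(round_half_up(m_continuous), 1, 10))
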