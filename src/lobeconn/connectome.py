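"""Weighted functional connectome construction.

A connectome passes through three stages: the Pearson correlation matrix
(``r``), its Fisher Z transform (``z``), and the absolute-weight network
``w = |Z|``.  Proportional cost thresholding keeps the strongest edges so
that the retained fraction of all possible edges equals the requested cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cohort import RoiTimeSeries

__all__ = [
    "WeightedConnectome",
    "correlation_matrix",
    "fisher_z",
    "to_weights",
    "n_edges_at_cost",
    "threshold_by_cost",
    "min_cost_for_component",
]

_STAGES = ("r", "z", "w")


@dataclass(frozen=True)
class WeightedConnectome:
    """N x N symmetric matrix with zero diagonal at one lifecycle stage."""

    stage: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"stage must be one of {_STAGES}, got {self.stage!r}")
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectome matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("connectome matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("connectome diagonal must be zero")
        if self.stage == "r" and np.any(np.abs(m) > 1):
            raise ValueError("stage-r entries must lie in [-1, 1]")
        if self.stage == "w" and np.any(m < 0):
            raise ValueError("stage-w entries must be nonnegative")

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]


def correlation_matrix(ts: RoiTimeSeries, roi_names=None) -> WeightedConnectome:
    """Pearson correlation between every pair of regional series.

    Exact symmetry is enforced and the diagonal zeroed.  A zero-variance
    column is an error naming the offending region.
    """
    data = ts.data
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        i = int(dead[0])
        name = roi_names[i] if roi_names is not None else f"column {i}"
        raise ValueError(f"zero-variance ROI: {name}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return WeightedConnectome("r", r)


def fisher_z(conn: WeightedConnectome, clip: float = 1.0 - 1e-7) -> WeightedConnectome:
    """Fisher's Z transform, with |r| clipped below 1 so atanh stays finite."""
    if conn.stage != "r":
        raise ValueError(f"fisher_z expects stage 'r', got {conn.stage!r}")
    z = np.arctanh(np.clip(conn.matrix, -clip, clip))
    np.fill_diagonal(z, 0.0)
    return WeightedConnectome("z", z)


def to_weights(conn: WeightedConnectome, clip: float = 1.0 - 1e-7) -> WeightedConnectome:
    """Absolute Fisher-Z edge weights w = |atanh(r)|."""
    if conn.stage == "r":
        conn = fisher_z(conn, clip=clip)
    if conn.stage != "z":
        raise ValueError(f"to_weights expects stage 'r' or 'z', got {conn.stage!r}")
    return WeightedConnectome("w", np.abs(conn.matrix))


def n_edges_at_cost(n_rois: int, cost: float) -> int:
    """Edge count retained at a proportional cost (nearest-integer rounding)."""
    m_possible = n_rois * (n_rois - 1) // 2
    return int(np.floor(cost * m_possible + 0.5))


def threshold_by_cost(conn: WeightedConnectome, cost: float) -> np.ndarray:
    """Keep the strongest edges so the retained fraction equals ``cost``.

    Returns the thresholded N x N weight matrix (zeros elsewhere).  Ties at
    the cut are broken by ascending (i, j) lexicographic order so the result
    is deterministic.
    """
    if conn.stage != "w":
        raise ValueError(f"threshold_by_cost expects stage 'w', got {conn.stage!r}")
    if not 0 < cost <= 1:
        raise ValueError(f"cost must lie in (0, 1], got {cost}")
    w = conn.matrix
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = w[iu, ju]
    k = n_edges_at_cost(n, cost)
    # sort by descending weight, then ascending (i, j); lexsort keys are
    # least-significant first
    order = np.lexsort((ju, iu, -weights))[:k]
    out = np.zeros_like(w)
    out[iu[order], ju[order]] = weights[order]
    out[ju[order], iu[order]] = weights[order]
    return out


def largest_component_size(w_thresholded: np.ndarray) -> int:
    n_comp, labels = connected_components(csr_matrix(w_thresholded), directed=False)
    if labels.size == 0:
        return 0
    return int(np.bincount(labels).max())


def min_cost_for_component(
    connectomes,
    cost_grid,
    target_fraction: float = 0.95,
) -> float:
    """Smallest grid cost at which every network's largest connected component
    exceeds ``target_fraction`` of its nodes.

    Raises with the best achievable fraction if no grid cost suffices.
    """
    connectomes = list(connectomes)
    if not connectomes:
        raise ValueError("need at least one connectome")
    cost_grid = sorted(cost_grid)
    best = 0.0
    for cost in cost_grid:
        frac = min(
            largest_component_size(threshold_by_cost(c, cost)) / c.n_rois
            for c in connectomes
        )
        best = max(best, frac)
        if frac > target_fraction or target_fraction == 0:
            return float(cost)
    raise ValueError(
        f"no grid cost reaches a largest-component fraction > {target_fraction}; "
        f"maximum achieved was {best:.3f}"
    )
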