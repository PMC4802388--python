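"""Weighted network measures on cost-thresholded connectomes.

Conventions (stated once, used everywhere):

* **Clustering** is the Onnela geometric-mean form with weights normalised by
  the network-wide maximum; nodes of degree < 2 contribute 0, and the network
  coefficient is the mean over all nodes.  Scale-invariant under uniform
  weight multiplication.
* **Path lengths** use edge lengths ``1/w`` (stronger connections are
  shorter); shortest paths come from Dijkstra.
* **Nodal efficiency** of node i is the mean inverse distance to every other
  node, unreachable nodes contributing 0; **global efficiency** is its mean.
* **Betweenness** is unnormalised Brandes betweenness on the same lengths,
  endpoints excluded, each unordered pair counted once.
* **Small-worldness** Sigma = (C/C_rand) / (L/L_rand) against degree-
  preserving (Maslov-Sneppen) rewired nulls whose edge weights are randomly
  permuted over the rewired topology; L is the mean finite shortest-path
  distance over reachable ordered pairs.

Graphs are plain N x N symmetric weight matrices (zero = no edge), as
produced by :func:`lobeconn.connectome.threshold_by_cost`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "strength_total",
    "clustering",
    "efficiency",
    "betweenness",
    "distance_matrix",
    "char_path_length",
    "largest_component",
    "rewire_preserving_degree",
    "small_worldness",
    "auc",
    "MetricCurve",
    "CostProfile",
    "metrics_over_costs",
    "DEFAULT_COST_GRID",
]

DEFAULT_COST_GRID = np.round(np.arange(0.10, 0.35 + 1e-9, 0.01), 2)


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("graph must be a square weight matrix")
    if np.any(w < 0):
        raise ValueError("edge weights must be nonnegative")
    return w


def strength_total(w: np.ndarray) -> float:
    """Total connection strength: sum of weights over undirected edges."""
    w = _check_weights(w)
    return float(w.sum() / 2.0)


def clustering(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering, max-normalised. Returns (C_i, C_net)."""
    w = _check_weights(w)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n), 0.0
    a = np.cbrt(w / wmax)
    triangles = np.diag(a @ a @ a)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    c_i = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return c_i, float(c_i.mean())


def distance_matrix(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances over edge lengths 1/w (inf if unreachable)."""
    w = _check_weights(w)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


def efficiency(w: np.ndarray, dist: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Nodal and global efficiency. Returns (E_i, E_net)."""
    w = _check_weights(w)
    n = w.shape[0]
    if n < 2:
        return np.zeros(n), 0.0
    d = distance_matrix(w) if dist is None else dist
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    e_i = inv.sum(axis=1) / (n - 1)
    return e_i, float(e_i.mean())


def char_path_length(w: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Mean finite shortest-path distance over reachable ordered pairs."""
    d = distance_matrix(w) if dist is None else dist
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        return float("inf")
    return float(d[finite].mean())


def largest_component(w: np.ndarray) -> int:
    """Number of nodes in the largest connected component."""
    w = _check_weights(w)
    if w.shape[0] == 0:
        return 0
    _, labels = connected_components(csr_matrix(w), directed=False)
    return int(np.bincount(labels).max())


def _edge_list(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.nonzero(np.triu(w, k=1))
    return np.column_stack([iu, ju]), w[iu, ju]


def betweenness(w: np.ndarray) -> np.ndarray:
    """Unnormalised shortest-path betweenness on lengths 1/w."""
    w = _check_weights(w)
    n = w.shape[0]
    edges, weights = _edge_list(w)
    if len(edges) == 0:
        return np.zeros(n)
    g = ig.Graph(n=n, edges=edges.tolist())
    return np.asarray(g.betweenness(weights=(1.0 / weights).tolist()), dtype=float)


def _rewire_core(ea, adj, pick, flip):
    """Sequential Maslov-Sneppen swaps over precomputed random proposals.

    ``ea`` is the (m, 2) edge array (i < j) mutated in place; ``adj`` the
    boolean adjacency matrix kept in sync.  Degree sequence is invariant.
    """
    for t in range(pick.shape[0]):
        e1 = pick[t, 0]
        e2 = pick[t, 1]
        if e1 == e2:
            continue
        a = ea[e1, 0]
        b = ea[e1, 1]
        c = ea[e2, 0]
        d = ea[e2, 1]
        if flip[t]:
            c, d = d, c
        # propose replacing (a,b),(c,d) with (a,d),(c,b)
        if a == d or c == b or a == c and b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        if a < d:
            ea[e1, 0], ea[e1, 1] = a, d
        else:
            ea[e1, 0], ea[e1, 1] = d, a
        if c < b:
            ea[e2, 0], ea[e2, 1] = c, b
        else:
            ea[e2, 0], ea[e2, 1] = b, c


try:  # jit-compile the swap loop when numba is available (pure speed-up)
    from numba import njit

    _rewire_core = njit(cache=True)(_rewire_core)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


def rewire_preserving_degree(
    w: np.ndarray, rng: np.random.Generator, swap_factor: int = 10
) -> np.ndarray:
    """Degree-preserving edge rewiring with the weight multiset permuted over
    the rewired topology (Maslov-Sneppen, ``swap_factor * |E|`` swap attempts).
    """
    w = _check_weights(w)
    n = w.shape[0]
    edges, weights = _edge_list(w)
    m = len(edges)
    if m < 2:
        return w.copy()
    attempts = swap_factor * m
    pick = rng.integers(0, m, size=(attempts, 2))
    flip = rng.random(attempts) < 0.5
    ea = edges.astype(np.int64).copy()
    adj = w > 0
    _rewire_core(ea, adj, pick.astype(np.int64), flip)

    out = np.zeros_like(w)
    perm = rng.permutation(weights)
    out[ea[:, 0], ea[:, 1]] = perm
    out[ea[:, 1], ea[:, 0]] = perm
    return out


def small_worldness(
    w: np.ndarray,
    n_null: int = 100,
    rng: np.random.Generator | int | None = None,
    swap_factor: int = 10,
) -> float:
    """Sigma = (C/C_rand) / (L/L_rand) against rewired null networks."""
    w = _check_weights(w)
    rng = np.random.default_rng(rng)
    if n_null < 1:
        raise ValueError("need at least one null network")
    _, c_net = clustering(w)
    l_net = char_path_length(w)
    if not np.isfinite(l_net):
        raise ValueError("graph has no finite paths; Sigma is undefined")
    c_rand = np.empty(n_null)
    l_rand = np.empty(n_null)
    for k in range(n_null):
        null = rewire_preserving_degree(w, rng, swap_factor=swap_factor)
        _, c_rand[k] = clustering(null)
        l_rand[k] = char_path_length(null)
    c_bar = c_rand.mean()
    l_bar = l_rand[np.isfinite(l_rand)].mean() if np.isfinite(l_rand).any() else np.nan
    if c_bar == 0 or not np.isfinite(l_bar):
        raise ValueError(
            "degenerate null model (no triangles or no finite paths); "
            "use a denser cost threshold"
        )
    return float((c_net / c_bar) / (l_net / l_bar))


def auc(x, y) -> float:
    """Trapezoidal integral of a metric curve over its grid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape[-1:] and x.shape != y.shape:
        raise ValueError("x and y must be 1-D and aligned")
    if len(x) < 2:
        raise ValueError("need at least two grid points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("grid must be strictly increasing")
    return float(np.trapezoid(y, x))


@dataclass(frozen=True)
class MetricCurve:
    x: np.ndarray
    y: np.ndarray
    auc: float


@dataclass
class CostProfile:
    """Global and nodal metric curves across a cost grid, with AUCs."""

    costs: np.ndarray
    global_curves: dict[str, MetricCurve] = field(default_factory=dict)
    nodal_curves: dict[str, np.ndarray] = field(default_factory=dict)  # n_costs x N
    nodal_auc: dict[str, np.ndarray] = field(default_factory=dict)     # N


def metrics_over_costs(
    conn_w,
    cost_grid=None,
    n_null: int = 0,
    rng: np.random.Generator | int | None = None,
    nodal: bool = True,
    include_betweenness: bool = True,
) -> CostProfile:
    """Evaluate global (and optionally nodal) measures at every grid cost.

    ``conn_w`` is a stage-w :class:`~lobeconn.connectome.WeightedConnectome`.
    Sigma is computed only when ``n_null > 0`` (it needs null networks).
    A single-point grid yields zero AUCs with a logged warning.
    """
    from .connectome import threshold_by_cost  # local import to avoid a cycle

    costs = np.asarray(DEFAULT_COST_GRID if cost_grid is None else cost_grid, dtype=float)
    if costs.ndim != 1 or len(costs) == 0:
        raise ValueError("cost grid must be a non-empty 1-D array")
    if np.any(np.diff(costs) <= 0):
        raise ValueError("cost grid must be strictly increasing")
    rng = np.random.default_rng(rng)
    n = conn_w.n_rois

    global_names = ["S_net", "C_net", "E_net"] + (["Sigma"] if n_null > 0 else [])
    gvals = {name: np.empty(len(costs)) for name in global_names}
    nodal_names = (["E_i", "C_i"] + (["BC_i"] if include_betweenness else [])) if nodal else []
    nvals = {name: np.empty((len(costs), n)) for name in nodal_names}

    for k, cost in enumerate(costs):
        wt = threshold_by_cost(conn_w, float(cost))
        gvals["S_net"][k] = strength_total(wt)
        c_i, c_net = clustering(wt)
        e_i, e_net = efficiency(wt)
        gvals["C_net"][k] = c_net
        gvals["E_net"][k] = e_net
        if n_null > 0:
            gvals["Sigma"][k] = small_worldness(wt, n_null=n_null, rng=rng)
        if nodal:
            nvals["C_i"][k] = c_i
            nvals["E_i"][k] = e_i
            if include_betweenness:
                nvals["BC_i"][k] = betweenness(wt)

    if len(costs) < 2:
        logger.warning("single-point cost grid: AUCs are zero-width and set to 0")
        curves = {name: MetricCurve(costs, y, 0.0) for name, y in gvals.items()}
        nodal_auc = {name: np.zeros(n) for name in nvals}
    else:
        curves = {name: MetricCurve(costs, y, auc(costs, y)) for name, y in gvals.items()}
        nodal_auc = {name: np.trapezoid(v, costs, axis=0) for name, v in nvals.items()}
    return CostProfile(costs, curves, nvals, nodal_auc)
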