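"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own code paths: shortest paths are
found by exhaustive simple-path enumeration, betweenness by direct geodesic
counting, clustering by the triple loop, and the attack oracle leans on
networkx.  They are feasible only on tiny graphs.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def all_simple_paths(n: int, lengths: np.ndarray, s: int, t: int):
    """Every simple s-t path as a node tuple (edges where lengths finite)."""
    for k in range(n):
        for mid in itertools.permutations([v for v in range(n) if v not in (s, t)], k):
            path = (s, *mid, t)
            if all(np.isfinite(lengths[a, b]) for a, b in zip(path, path[1:])):
                yield path


def brute_shortest(n: int, lengths: np.ndarray, s: int, t: int):
    """(distance, list of geodesics) by exhaustive enumeration."""
    best = np.inf
    geodesics = []
    for path in all_simple_paths(n, lengths, s, t):
        d = sum(lengths[a, b] for a, b in zip(path, path[1:]))
        if d < best:
            best = d
            geodesics = [path]
        elif d == best:
            geodesics.append(path)
    return best, geodesics


def _lengths(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)


def brute_efficiency(w: np.ndarray) -> tuple[np.ndarray, float]:
    n = w.shape[0]
    lengths = _lengths(w)
    e = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d, _ = brute_shortest(n, lengths, i, j)
            if np.isfinite(d) and d > 0:
                e[i] += 1.0 / d
    e /= n - 1
    return e, float(e.mean())


def brute_betweenness(w: np.ndarray) -> np.ndarray:
    """Endpoint-excluded betweenness, each unordered pair counted once."""
    n = w.shape[0]
    lengths = _lengths(w)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        d, geos = brute_shortest(n, lengths, s, t)
        if not np.isfinite(d) or not geos:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for g in geos if v in g)
            bc[v] += through / len(geos)
    return bc


def brute_clustering(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Onnela form, max-normalised, by the direct triple loop."""
    n = w.shape[0]
    wmax = w.max()
    c = np.zeros(n)
    if wmax == 0:
        return c, 0.0
    what = w / wmax
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                acc += (what[i, j] * what[i, h] * what[j, h]) ** (1.0 / 3.0)
        c[i] = acc / (k * (k - 1))
    return c, float(c.mean())


def naive_targeted_attack(w: np.ndarray):
    """Independent attack re-implementation on networkx.

    Same rule: remove the highest-betweenness node each step (ties by higher
    strength then lower id), recompute, record absolute largest component,
    Onnela C_net and global efficiency, then normalise by step 0.
    """
    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(i, j, weight=w[i, j], length=1.0 / w[i, j])

    def snapshot(graph):
        if graph.number_of_nodes() == 0:
            return 0.0, 0.0, 0.0
        lcc = max((len(c) for c in nx.connected_components(graph)), default=0)
        cs = nx.clustering(graph, weight="weight")
        c_net = float(np.mean(list(cs.values()))) if cs else 0.0
        m = graph.number_of_nodes()
        eff = 0.0
        if m > 1:
            for _, dists in nx.all_pairs_dijkstra_path_length(graph, weight="length"):
                eff += sum(1.0 / d for d in dists.values() if d > 0)
            eff /= m * (m - 1)
        return float(lcc), c_net, eff

    curves = [snapshot(g)]
    while g.number_of_nodes() > 1:
        bc = nx.betweenness_centrality(g, normalized=False, weight="length")
        strength = {v: sum(d["weight"] for _, _, d in g.edges(v, data=True)) for v in g.nodes}
        victim = min(g.nodes, key=lambda v: (-bc[v], -strength[v], v))
        g.remove_node(victim)
        curves.append(snapshot(g))
    arr = np.array(curves)
    out = {}
    for col, name in enumerate(("largest_component", "C_net", "E_net")):
        y = arr[:, col]
        out[name] = y / y[0] if y[0] != 0 else y
    return out


def random_connected_graph(rng: np.random.Generator, n: int, dyadic: bool = False) -> np.ndarray:
    """Random connected weighted graph on n nodes.

    ``dyadic=True`` draws weights from powers of two so path-length sums are
    exact in floating point (geodesic counting is then tie-stable across
    implementations).
    """
    for _ in range(200):
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.55:
                    if dyadic:
                        val = float(2.0 ** rng.integers(-2, 3))
                    else:
                        val = float(rng.uniform(0.2, 1.5))
                    w[i, j] = w[j, i] = val
        g = nx.from_numpy_array(w)
        if nx.is_connected(g):
            return w
    raise RuntimeError("failed to draw a connected graph")
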