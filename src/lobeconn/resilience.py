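"""Network resilience: random failure and targeted attack.

Nodes are deleted step by step from a fixed-cost network — uniformly at
random (averaged over many repetitions) or by highest betweenness with
recomputation after every step — and the surviving network's largest
connected component, clustering coefficient and global efficiency are
tracked, each normalised by its intact (step-0) value.  The curve's x-axis
is the fraction of nodes removed, so parcellations of different sizes are
comparable, and each measure is summarised by its area under the curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import clustering, efficiency, largest_component

logger = logging.getLogger(__name__)

__all__ = ["AttackConfig", "ResilienceCurve", "targeted_attack", "random_failure", "compare_groups"]

MEASURES = ("largest_component", "C_net", "E_net")


@dataclass(frozen=True)
class AttackConfig:
    cost: float = 0.14
    mode: str = "targeted"          # "targeted" | "random"
    n_random_reps: int = 1000
    nodes_per_step: int = 1         # 4 for the fine parcellation
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("targeted", "random"):
            raise ValueError(f"mode must be 'targeted' or 'random', got {self.mode!r}")
        if self.n_random_reps < 1:
            raise ValueError("n_random_reps must be >= 1")
        if self.nodes_per_step < 1:
            raise ValueError("nodes_per_step must be >= 1")


@dataclass
class ResilienceCurve:
    """Normalised degradation curves; step 0 is the intact network."""

    frac_removed: np.ndarray
    values: dict[str, np.ndarray]      # measure -> curve, aligned with frac_removed
    auc: dict[str, float] = field(default_factory=dict)
    absolute: tuple[str, ...] = ()     # measures left unnormalised (intact value was 0)

    def __post_init__(self) -> None:
        for name, y in self.values.items():
            if len(y) != len(self.frac_removed):
                raise ValueError(f"curve {name} misaligned with the step axis")
        if not self.auc:
            self.auc = {
                name: float(np.trapezoid(y, self.frac_removed))
                for name, y in self.values.items()
            }


def _measure_snapshot(w: np.ndarray) -> dict[str, float]:
    _, c_net = clustering(w)
    _, e_net = efficiency(w)
    return {
        "largest_component": float(largest_component(w)),
        "C_net": c_net,
        "E_net": e_net,
    }


def _removal_steps(n: int, per_step: int) -> list[int]:
    """Nodes removed at each step, until at most one node remains."""
    steps = []
    alive = n
    while alive > 1:
        k = min(per_step, alive - 1)
        steps.append(k)
        alive -= k
    return steps


def _raw_curves(w: np.ndarray, order: np.ndarray, per_step: int) -> dict[str, np.ndarray]:
    """Absolute measure curves for one removal order (step 0 = intact)."""
    n = w.shape[0]
    steps = _removal_steps(n, per_step)
    out = {m: np.empty(len(steps) + 1) for m in MEASURES}
    snap = _measure_snapshot(w)
    for m in MEASURES:
        out[m][0] = snap[m]
    alive = np.ones(n, dtype=bool)
    pos = 0
    for s, k in enumerate(steps, start=1):
        alive[order[pos : pos + k]] = False
        pos += k
        sub = w[np.ix_(alive, alive)]
        snap = _measure_snapshot(sub)
        for m in MEASURES:
            out[m][s] = snap[m]
    return out


def _normalise(curves: dict[str, np.ndarray], n: int, per_step: int) -> ResilienceCurve:
    steps = _removal_steps(n, per_step)
    frac = np.concatenate([[0.0], np.cumsum(steps) / n])
    values = {}
    absolute = []
    for m, y in curves.items():
        if y[0] == 0:
            logger.warning("intact %s is 0; reporting the curve unnormalised", m)
            absolute.append(m)
            values[m] = y.copy()
        else:
            values[m] = y / y[0]
    return ResilienceCurve(frac, values, absolute=tuple(absolute))


def targeted_attack(w: np.ndarray, config: AttackConfig | None = None) -> ResilienceCurve:
    """Remove the highest-betweenness nodes, recomputing betweenness each step.

    Ties are broken by higher strength, then lower node id, so the trajectory
    is fully deterministic.
    """
    from .metrics import betweenness  # local import keeps module load cheap

    config = config or AttackConfig(mode="targeted")
    if config.mode != "targeted":
        raise ValueError("targeted_attack requires mode='targeted'")
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    steps = _removal_steps(n, config.nodes_per_step)
    curves = {m: np.empty(len(steps) + 1) for m in MEASURES}
    snap = _measure_snapshot(w)
    for m in MEASURES:
        curves[m][0] = snap[m]

    alive_ids = np.arange(n)
    sub = w
    for s, k in enumerate(steps, start=1):
        bc = betweenness(sub)
        strength = sub.sum(axis=1)
        # order: highest BC first, ties by higher strength, then lower id
        rank = np.lexsort((alive_ids, -strength, -bc))
        doomed = rank[:k]
        keep = np.ones(len(alive_ids), dtype=bool)
        keep[doomed] = False
        alive_ids = alive_ids[keep]
        sub = sub[np.ix_(keep, keep)]
        snap = _measure_snapshot(sub)
        for m in MEASURES:
            curves[m][s] = snap[m]
    return _normalise(curves, n, config.nodes_per_step)


def random_failure(w: np.ndarray, config: AttackConfig | None = None) -> ResilienceCurve:
    """Mean degradation curve over independent uniformly random removal orders."""
    config = config or AttackConfig(mode="random")
    if config.mode != "random":
        raise ValueError("random_failure requires mode='random'")
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(config.rng_seed)
    acc: dict[str, np.ndarray] | None = None
    for _ in range(config.n_random_reps):
        order = rng.permutation(n)
        raw = _raw_curves(w, order, config.nodes_per_step)
        if acc is None:
            acc = {m: y.astype(float) for m, y in raw.items()}
        else:
            for m in MEASURES:
                acc[m] += raw[m]
    mean = {m: y / config.n_random_reps for m, y in acc.items()}
    return _normalise(mean, n, config.nodes_per_step)


def compare_groups(
    curves_a: list[ResilienceCurve],
    curves_b: list[ResilienceCurve],
    labels: tuple[str, str] = ("SF", "NSF"),
    variant: str = "pooled",
) -> dict:
    """Per-step two-sample t-tests plus a t-test on per-subject AUCs.

    The per-step significance threshold is ``1 / n_steps`` (the false-positive
    adjustment: under the null, less than one significant step is expected per
    analysis).
    """
    from .stats import two_sample_t

    if len(curves_a) < 2 or len(curves_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    n_steps = len(curves_a[0].frac_removed) - 1
    for c in curves_a + curves_b:
        if len(c.frac_removed) - 1 != n_steps:
            raise ValueError("all curves must share the same step structure")
    threshold = 1.0 / n_steps

    step_rows = []
    auc_rows = []
    for m in MEASURES:
        a = np.array([c.values[m] for c in curves_a])
        b = np.array([c.values[m] for c in curves_b])
        for s in range(n_steps + 1):
            with warnings.catch_warnings():
                # step 0 is identically 1.0 in both groups after normalisation
                warnings.simplefilter("ignore", RuntimeWarning)
                t, df, p = two_sample_t(a[:, s], b[:, s], variant=variant)
            step_rows.append(
                {
                    "measure": m,
                    "step": s,
                    "frac_removed": curves_a[0].frac_removed[s],
                    f"mean_{labels[0]}": a[:, s].mean(),
                    f"mean_{labels[1]}": b[:, s].mean(),
                    "t": t,
                    "df": df,
                    "p": p,
                    "significant": bool(np.isfinite(p) and p < threshold),
                }
            )
        auc_a = np.array([c.auc[m] for c in curves_a])
        auc_b = np.array([c.auc[m] for c in curves_b])
        t, df, p = two_sample_t(auc_a, auc_b, variant=variant)
        auc_rows.append(
            {
                "measure": m,
                f"auc_mean_{labels[0]}": auc_a.mean(),
                f"auc_mean_{labels[1]}": auc_b.mean(),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return {
        "per_step": pd.DataFrame(step_rows),
        "auc": pd.DataFrame(auc_rows),
        "threshold": threshold,
        "n_steps": n_steps,
    }
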