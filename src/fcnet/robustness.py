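"""Network robustness: targeted attack, random failure, giant-component
trajectories, robustness AUC and disintegration detection.

Targeted attack removes nodes in decreasing order of their *initial*
degree centrality (ties broken by ascending node index); an adaptive mode
that recomputes degree after every removal is available behind a flag.
Random failure averages full sequential random ablations over ``n_reps``
replicates.  Robustness is the trapezoidal AUC of giant-connected-component
(GCC) size against the number of nodes removed.  Disintegration is the
first removal step where the mean |change in GCC| over the trailing window
is at least ``factor`` (default 1.5) times the mean over the window before
it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from .connectivity import BinaryGraph

__all__ = [
    "AttackTrajectory",
    "DisintegrationResult",
    "gcc_size",
    "targeted_attack",
    "random_failure",
    "robustness_auc",
    "select_min_threshold",
    "disintegration_point",
]


@dataclass
class AttackTrajectory:
    removed_counts: np.ndarray  # 0..N
    gcc_sizes: np.ndarray  # float for mean trajectories
    mode: str  # "targeted" | "random"
    density: float = np.nan
    robustness_auc: float = np.nan

    def __post_init__(self):
        self.removed_counts = np.asarray(self.removed_counts)
        self.gcc_sizes = np.asarray(self.gcc_sizes, dtype=float)
        if self.removed_counts.shape != self.gcc_sizes.shape:
            raise ValueError("removed_counts and gcc_sizes must align")
        if np.isnan(self.robustness_auc):
            self.robustness_auc = robustness_auc(self)


@dataclass
class DisintegrationResult:
    index: int  # removal count at first detection
    window: int
    change_ratio: float


def _adj(g) -> np.ndarray:
    if isinstance(g, BinaryGraph):
        return np.asarray(g.adjacency)
    return BinaryGraph(np.asarray(g)).adjacency


def gcc_size(g) -> int:
    """Node count of the largest connected component (1 for an edgeless
    non-empty graph, 0 for an empty one)."""
    adj = _adj(g)
    n = adj.shape[0]
    if n == 0:
        return 0
    _, labels = connected_components(csr_array(adj), directed=False)
    return int(np.bincount(labels).max())


def _gcc_of_subset(adj: np.ndarray, alive: np.ndarray) -> int:
    idx = np.flatnonzero(alive)
    if idx.size == 0:
        return 0
    sub = adj[np.ix_(idx, idx)]
    _, labels = connected_components(csr_array(sub), directed=False)
    return int(np.bincount(labels).max())


def _replay(adj: np.ndarray, order: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    alive = np.ones(n, dtype=bool)
    sizes = np.empty(n + 1, dtype=float)
    sizes[0] = _gcc_of_subset(adj, alive)
    for k, node in enumerate(order, start=1):
        alive[node] = False
        sizes[k] = _gcc_of_subset(adj, alive)
    return sizes


def targeted_attack(
    g, dc_order: Sequence[float] | None = None, adaptive: bool = False
) -> AttackTrajectory:
    """Remove nodes in decreasing degree-centrality order, tracking GCC.

    ``dc_order`` defaults to the graph's own degree sequence.  Static
    initial-degree ordering by default; ``adaptive=True`` recomputes the
    degree on the surviving subgraph before every removal.
    """
    adj = _adj(g)
    n = adj.shape[0]
    density = g.density_used if isinstance(g, BinaryGraph) else np.nan
    if not adaptive:
        dc = (
            adj.sum(axis=1).astype(float)
            if dc_order is None
            else np.asarray(dc_order, dtype=float)
        )
        if dc.shape[0] != n:
            raise ValueError("dc_order length does not match node count")
        order = np.lexsort((np.arange(n), -dc))
        sizes = _replay(adj, order)
    else:
        alive = np.ones(n, dtype=bool)
        sizes = np.empty(n + 1, dtype=float)
        sizes[0] = _gcc_of_subset(adj, alive)
        for k in range(1, n + 1):
            deg = (adj[:, alive].sum(axis=1)).astype(float)
            deg[~alive] = -1
            node = int(np.lexsort((np.arange(n), -deg))[0])
            alive[node] = False
            sizes[k] = _gcc_of_subset(adj, alive)
    return AttackTrajectory(np.arange(n + 1), sizes, "targeted", density)


def random_failure(g, n_reps: int, seed) -> AttackTrajectory:
    """Element-wise mean GCC trajectory over ``n_reps`` uniformly random
    sequential removal orders; deterministic per seed."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    adj = _adj(g)
    n = adj.shape[0]
    density = g.density_used if isinstance(g, BinaryGraph) else np.nan
    rng = np.random.default_rng(seed)
    total = np.zeros(n + 1)
    for _ in range(n_reps):
        total += _replay(adj, rng.permutation(n))
    return AttackTrajectory(np.arange(n + 1), total / n_reps, "random", density)


def robustness_auc(traj: AttackTrajectory) -> float:
    """Trapezoidal integral of GCC size against nodes removed
    (units: node removals x nodes)."""
    return float(np.trapezoid(traj.gcc_sizes, traj.removed_counts))


def select_min_threshold(trajectories: Mapping[float, AttackTrajectory]) -> float:
    """Density where the attack had the greatest impact: minimum robustness
    AUC normalized by the intact GCC size; ties go to the smallest density."""
    if not trajectories:
        raise ValueError("no trajectories supplied")
    best_density = None
    best_score = np.inf
    for dens in sorted(trajectories):
        traj = trajectories[dens]
        initial = traj.gcc_sizes[0]
        score = traj.robustness_auc / initial if initial > 0 else np.inf
        if score < best_score:
            best_score = score
            best_density = dens
    return best_density


def disintegration_point(
    traj: AttackTrajectory, window: int = 5, factor: float = 1.5
) -> DisintegrationResult | None:
    """First removal step where mean |dGCC| over the trailing ``window``
    removals is >= ``factor`` times the mean over the window before it.

    Returns None when no step qualifies.  A zero prior-window mean counts
    as disintegration only if the trailing mean is positive.
    """
    gcc = np.asarray(traj.gcc_sizes, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if gcc.shape[0] <= 2 * window:
        raise ValueError(
            f"trajectory of length {gcc.shape[0]} too short for window {window}"
        )
    deltas = np.abs(np.diff(gcc))
    for k in range(2 * window, gcc.shape[0]):
        current = deltas[k - window : k].mean()
        prior = deltas[k - 2 * window : k - window].mean()
        if prior == 0:
            if current > 0:
                return DisintegrationResult(k, window, float("inf"))
            continue
        ratio = current / prior
        if ratio >= factor:
            return DisintegrationResult(k, window, float(ratio))
    return None
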