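"""Global and nodal metrics on binary graphs, degree-matched nulls, and
AUC aggregation over a density grid.

Metric conventions:

* ``Lp`` averages shortest-path length over *reachable* ordered pairs, so a
  fragmenting sparse graph keeps a finite value and AUC curves stay
  integrable; the harmonic-mean view of disconnection is carried by ``Eg``.
* Local clustering of nodes with degree < 2 is 0 and those nodes stay in
  the mean (they are not dropped).
* Betweenness is Brandes' fractional count, reported unnormalized by
  default; pass ``normalized=True`` to divide by (N-1)(N-2)/2 per node for
  cross-tool comparison.
* Normalized metrics gamma = Cp/<Cp_null>, lambda = Lp/<Lp_null> and
  small-worldness sigma = gamma/lambda use Maslov-Sneppen degree-preserving
  rewired nulls (10 x |E| swap attempts per null by default).
* AUC is the trapezoidal integral over the actual density values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .connectivity import BinaryGraph, DensityGrid, FCMatrix, threshold_at_density

__all__ = [
    "MetricProfile",
    "degree_centrality",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "betweenness_centrality",
    "nodal_efficiency",
    "random_null_graphs",
    "normalized_metrics",
    "auc_over_densities",
    "metric_profile",
    "distance_matrix",
]

GLOBAL_METRICS = ("Cp", "Lp", "Eg", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRICS = ("Dc", "Bc", "Ne")


def _adj(g) -> np.ndarray:
    if isinstance(g, BinaryGraph):
        return np.asarray(g.adjacency)
    return BinaryGraph(np.asarray(g)).adjacency


def distance_matrix(g) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf when unreachable)."""
    adj = _adj(g)
    return shortest_path(csr_array(adj.astype(float)), method="D", unweighted=True)


def degree_centrality(g) -> np.ndarray:
    """Dc(i): number of edges incident to node i."""
    return _adj(g).sum(axis=1).astype(int)


def clustering_coefficient(g) -> tuple[np.ndarray, float]:
    """Watts-Strogatz local clustering per node and its mean over all nodes."""
    adj = _adj(g).astype(float)
    deg = adj.sum(axis=1)
    triangles = np.diag(adj @ adj @ adj) / 2.0
    denom = deg * (deg - 1) / 2.0
    per_node = np.zeros(adj.shape[0])
    ok = denom > 0
    per_node[ok] = triangles[ok] / denom[ok]
    return per_node, float(per_node.mean())


def characteristic_path_length(g) -> float:
    """Mean shortest-path length over reachable ordered pairs (i != j)."""
    adj = _adj(g)
    if adj.sum() == 0:
        raise ValueError("characteristic path length undefined for an edgeless graph")
    d = distance_matrix(adj)
    mask = np.isfinite(d) & ~np.eye(adj.shape[0], dtype=bool)
    return float(d[mask].mean())


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def global_efficiency(g) -> float:
    """Mean inverse shortest-path length over all distinct pairs (1/inf = 0)."""
    adj = _adj(g)
    if adj.shape[0] < 2:
        return 0.0
    return _efficiency_from_distances(distance_matrix(adj))


def local_efficiency(g) -> tuple[np.ndarray, float]:
    """Per node: global efficiency of the subgraph induced by its
    neighbours (0 for degree < 2); plus the mean over all nodes."""
    adj = _adj(g)
    n = adj.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        per_node[i] = global_efficiency(BinaryGraph(sub))
    return per_node, float(per_node.mean())


def betweenness_centrality(g, normalized: bool = False) -> np.ndarray:
    """Brandes betweenness; unnormalized pair-path fractions by default."""
    adj = _adj(g)
    G = nx.from_numpy_array(adj)
    bc = nx.betweenness_centrality(G, normalized=normalized)
    return np.array([bc[i] for i in range(adj.shape[0])])


def nodal_efficiency(g) -> np.ndarray:
    """Ne(i): mean over j != i of 1/d(i, j), with 1/inf = 0."""
    adj = _adj(g)
    n = adj.shape[0]
    if n < 2:
        return np.zeros(n)
    d = distance_matrix(adj)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


class RewiringError(RuntimeError):
    """Degree-preserving rewiring made no successful swap."""


def _maslov_sneppen(
    adj: np.ndarray, rng: np.random.Generator, n_attempts: int
) -> np.ndarray:
    a = adj.copy().astype(bool)
    n = a.shape[0]
    ii, jj = np.nonzero(np.triu(a, k=1))
    edges = np.column_stack([ii, jj])
    n_edges = edges.shape[0]
    successes = 0
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, n_edges, size=2)
        if e1 == e2:
            continue
        a1, b1 = edges[e1]
        c1, d1 = edges[e2]
        if rng.random() < 0.5:
            c1, d1 = d1, c1
        if len({a1, b1, c1, d1}) < 4:
            continue
        if a[a1, d1] or a[c1, b1]:
            continue
        a[a1, b1] = a[b1, a1] = False
        a[c1, d1] = a[d1, c1] = False
        a[a1, d1] = a[d1, a1] = True
        a[c1, b1] = a[b1, c1] = True
        edges[e1] = (min(a1, d1), max(a1, d1))
        edges[e2] = (min(c1, b1), max(c1, b1))
        successes += 1
    density = 2 * n_edges / (n * (n - 1)) if n > 1 else 1.0
    if successes == 0 and density < 1.0:
        raise RewiringError(
            f"no successful degree-preserving swap in {n_attempts} attempts "
            f"({n} nodes, {n_edges} edges, density {density:.3f})"
        )
    return a.astype(np.int8)


def random_null_graphs(
    g, n_rand: int, seed, attempts_factor: int = 10
) -> list[BinaryGraph]:
    """Maslov-Sneppen degree-preserving rewired nulls.

    Each null runs ``attempts_factor * |E|`` swap attempts.  A complete
    graph has a unique degree realization, so its nulls are copies.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    adj = _adj(g)
    n_edges = int(adj.sum()) // 2
    if n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    density = g.density_used if isinstance(g, BinaryGraph) else np.nan
    return [
        BinaryGraph(
            _maslov_sneppen(adj, rng, attempts_factor * n_edges), density_used=density
        )
        for _ in range(n_rand)
    ]


def normalized_metrics(g, nulls) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) of ``g`` against a list of null graphs."""
    if not nulls:
        raise ValueError("null list is empty")
    cp = clustering_coefficient(g)[1]
    lp = characteristic_path_length(g)
    cp_null = float(np.mean([clustering_coefficient(h)[1] for h in nulls]))
    lp_null = float(np.mean([characteristic_path_length(h) for h in nulls]))
    if cp_null == 0 or lp_null == 0:
        raise ValueError("null-model mean metric is zero; cannot normalize")
    gamma = cp / cp_null
    lam = lp / lp_null
    return gamma, lam, gamma / lam


def auc_over_densities(curve, grid) -> float:
    """Trapezoidal integral of a metric curve over the density axis."""
    x = grid.asarray() if isinstance(grid, DensityGrid) else np.asarray(grid, float)
    y = np.asarray(curve, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError(
            f"curve length {y.shape[0]} does not match grid length {x.shape[0]}"
        )
    if x.shape[0] < 2:
        raise ValueError("AUC needs at least 2 densities")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("AUC inputs must be finite")
    return float(np.trapezoid(y, x, axis=0))


@dataclass
class MetricProfile:
    """All metric curves over a density grid for one subject, plus AUCs.

    ``global_curves[m]`` has one value per density; ``nodal_curves[m]`` is
    (n_densities, n_nodes); ``nodal_auc[m]`` is per-node.
    """

    densities: np.ndarray
    global_curves: dict[str, np.ndarray]
    nodal_curves: dict[str, np.ndarray]
    global_auc: dict[str, float] = field(default_factory=dict)
    nodal_auc: dict[str, np.ndarray] = field(default_factory=dict)


def metric_profile(
    fc,
    grid: DensityGrid | None = None,
    null_count: int = 100,
    seed: int = 0,
    include_normalized: bool = True,
    use_absolute: bool = True,
) -> MetricProfile:
    """Threshold an FC matrix at every grid density and assemble all global
    and nodal metric curves with their AUCs.

    ``null_count`` rewired nulls per density feed gamma/lambda/sigma; set
    ``include_normalized=False`` (or ``null_count=0``) to skip them.
    """
    if grid is None:
        grid = DensityGrid.default()
    fcm = fc if isinstance(fc, FCMatrix) else FCMatrix(np.asarray(fc, float))
    n = fcm.n
    nd = len(grid)
    use_nulls = include_normalized and null_count > 0
    glob = {m: np.full(nd, np.nan) for m in GLOBAL_METRICS}
    nodal = {m: np.zeros((nd, n)) for m in NODAL_METRICS}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    null_seeds = ss.spawn(nd)
    for di, dens in enumerate(grid):
        g = threshold_at_density(fcm, dens, use_absolute=use_absolute)
        glob["Cp"][di] = clustering_coefficient(g)[1]
        glob["Lp"][di] = characteristic_path_length(g)
        glob["Eg"][di] = global_efficiency(g)
        glob["Eloc"][di] = local_efficiency(g)[1]
        nodal["Dc"][di] = degree_centrality(g)
        nodal["Bc"][di] = betweenness_centrality(g)
        nodal["Ne"][di] = nodal_efficiency(g)
        if use_nulls:
            nulls = random_null_graphs(g, null_count, null_seeds[di])
            try:
                gamma, lam, sigma = normalized_metrics(g, nulls)
            except ValueError:
                # e.g. zero null clustering on very sparse graphs: the
                # normalized metric is undefined at this density
                gamma = lam = sigma = np.nan
            glob["gamma"][di] = gamma
            glob["lambda"][di] = lam
            glob["sigma"][di] = sigma
    if not use_nulls:
        for m in ("gamma", "lambda", "sigma"):
            del glob[m]
    densities = grid.asarray()
    profile = MetricProfile(densities, glob, nodal)
    for m, curve in glob.items():
        profile.global_auc[m] = (
            auc_over_densities(curve, densities)
            if np.isfinite(curve).all()
            else float("nan")
        )
    for m, curves in nodal.items():
        profile.nodal_auc[m] = np.array(
            [auc_over_densities(curves[:, i], densities) for i in range(n)]
        )
    return profile
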