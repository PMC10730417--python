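"""Network-Based Statistic (NBS) with covariate adjustment.

Edge-wise general linear models (edge FC ~ group + covariates) yield a t
statistic for a directional two-group contrast or an omnibus F across >= 3
groups.  Edges exceeding the cluster-defining threshold are clustered into
connected components, and each observed component's family-wise-error
corrected p-value is the fraction of permutations whose *maximum* component
size reaches the observed size.

Covariates are handled by Freedman-Lane permutation: the reduced model
(covariates only) is fitted once, its residuals are permuted across
subjects, re-added to the reduced fit, and the full-model statistic is
recomputed — the standard scheme for GLM permutation inference.  The
p-value uses the add-one convention (the observed statistic counts as one
member of its null), so p is never exactly 0.

Component size is extent (edge count) by default, matching the usual
"k edges between m nodes" reporting; intensity (sum of suprathreshold
statistic values) is available via ``size_stat="intensity"``.  Raw signed
edge values are used by default; ``use_absolute=True`` analyzes |r|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components as _cc

__all__ = [
    "Design",
    "design_matrix",
    "NBSConfig",
    "Component",
    "NBSResult",
    "edge_stats",
    "suprathreshold_components",
    "nbs_test",
    "median_threshold",
    "posthoc_pairwise",
    "component_mask_strength",
    "nodal_strength_in_component",
]


# ---------------------------------------------------------------- design


@dataclass
class Design:
    """Subjects x predictors design: intercept, group indicators, covariates."""

    matrix: np.ndarray
    columns: list[str]
    interest: list[int]  # indices of the group-indicator columns
    groups: list[str]  # group levels, first = baseline
    group_of: np.ndarray  # per-subject group label

    def __post_init__(self):
        x = np.asarray(self.matrix, dtype=float)
        n, p = x.shape
        if n <= p:
            raise ValueError(f"{n} subjects cannot identify {p} design columns")
        if np.linalg.matrix_rank(x) < p:
            raise ValueError("design matrix is rank deficient")
        self.matrix = x

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def reduced(self) -> np.ndarray:
        keep = [i for i in range(self.matrix.shape[1]) if i not in self.interest]
        return self.matrix[:, keep]

    def contrast_vector(self, pair: tuple[str, str]) -> np.ndarray:
        """Directional contrast: positive statistic means pair[1] > pair[0]."""
        low, high = pair
        for g in pair:
            if g not in self.groups:
                raise ValueError(f"unknown group label {g!r}; levels: {self.groups}")
        c = np.zeros(self.matrix.shape[1])
        for g, sign in ((high, 1.0), (low, -1.0)):
            if g != self.groups[0]:
                c[self.columns.index(f"group[{g}]")] += sign
        return c


def _encode_covariate(series: pd.Series, name: str) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(series):
        return series.to_numpy(dtype=float)
    levels = sorted(series.dropna().unique().tolist())
    if len(levels) != 2:
        raise ValueError(
            f"covariate {name!r} is non-numeric with {len(levels)} levels; "
            "only binary categorical covariates are supported"
        )
    return (series == levels[1]).to_numpy(dtype=float)


def design_matrix(
    metadata: pd.DataFrame,
    group_col: str = "group",
    covariates: Sequence[str] = ("age", "sex"),
    groups: Sequence[str] | None = None,
) -> Design:
    """Build intercept + group indicators (first level = baseline) +
    covariate columns from a metadata table."""
    if group_col not in metadata.columns:
        raise ValueError(f"metadata lacks group column {group_col!r}")
    labels = metadata[group_col].astype(str).to_numpy()
    if groups is None:
        groups = list(dict.fromkeys(labels.tolist()))
    else:
        groups = list(groups)
        unknown = set(labels) - set(groups)
        if unknown:
            raise ValueError(f"metadata contains unlisted groups {sorted(unknown)}")
    cols: list[np.ndarray] = [np.ones(len(metadata))]
    names = ["intercept"]
    for g in groups[1:]:
        cols.append((labels == g).astype(float))
        names.append(f"group[{g}]")
    interest = list(range(1, len(groups)))
    for cov in covariates:
        if cov not in metadata.columns:
            raise ValueError(f"metadata lacks covariate column {cov!r}")
        cols.append(_encode_covariate(metadata[cov], cov))
        names.append(cov)
    return Design(np.column_stack(cols), names, interest, groups, labels)


# ---------------------------------------------------------------- statistics


def _stack_to_edges(fc_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    stack = np.asarray(fc_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("fc_stack must be subjects x N x N")
    if not np.allclose(stack, stack.transpose(0, 2, 1), atol=1e-10):
        raise ValueError("subject FC matrices must be symmetric")
    n = stack.shape[1]
    ii, jj = np.triu_indices(n, k=1)
    return stack[:, ii, jj], ii, jj


class _GLM:
    """Precomputed pieces for repeated t/F evaluation on many edge vectors."""

    def __init__(self, X: np.ndarray, cvec: np.ndarray | None, interest: list[int]):
        self.X = X
        self.n, self.p = X.shape
        self.df = self.n - self.p
        self.xtx_inv = np.linalg.inv(X.T @ X)
        self.pinv = self.xtx_inv @ X.T
        self.cvec = cvec
        if cvec is not None:
            self.c_var = float(cvec @ self.xtx_inv @ cvec)
        keep = [i for i in range(self.p) if i not in interest]
        self.q = self.p - len(keep)
        Z = X[:, keep]
        self.Z = Z
        self.hz = Z @ np.linalg.pinv(Z)

    def t_stats(self, Y: np.ndarray) -> np.ndarray:
        B = self.pinv @ Y
        resid = Y - self.X @ B
        s2 = np.einsum("ij,ij->j", resid, resid) / self.df
        denom = np.sqrt(self.c_var * s2)
        num = self.cvec @ B
        out = np.zeros_like(num)
        ok = denom > 0
        out[ok] = num[ok] / denom[ok]
        return out

    def f_stats(self, Y: np.ndarray) -> np.ndarray:
        B = self.pinv @ Y
        resid = Y - self.X @ B
        rss_full = np.einsum("ij,ij->j", resid, resid)
        resid_red = Y - self.hz @ Y
        rss_red = np.einsum("ij,ij->j", resid_red, resid_red)
        out = np.zeros(Y.shape[1])
        ok = rss_full > 0
        out[ok] = ((rss_red[ok] - rss_full[ok]) / self.q) / (rss_full[ok] / self.df)
        np.clip(out, 0.0, None, out=out)
        return out


def edge_stats(
    fc_stack: np.ndarray,
    design: Design,
    contrast: tuple[str, str] | np.ndarray | None = None,
    stat_family: str = "t",
    use_absolute: bool = False,
) -> np.ndarray:
    """Per-edge GLM statistic matrix (symmetric N x N, zero diagonal).

    ``stat_family="t"`` needs a contrast (defaults to (baseline, second
    level) for a two-group design); ``"F"`` is the omnibus group test.
    """
    Y, ii, jj = _stack_to_edges(fc_stack)
    if Y.shape[0] != design.n:
        raise ValueError(
            f"fc_stack has {Y.shape[0]} subjects but design has {design.n} rows"
        )
    if use_absolute:
        Y = np.abs(Y)
    if stat_family == "t":
        if contrast is None:
            if len(design.groups) != 2:
                raise ValueError("a contrast pair is required with >2 groups")
            contrast = (design.groups[0], design.groups[1])
        cvec = (
            np.asarray(contrast, dtype=float)
            if isinstance(contrast, np.ndarray)
            else design.contrast_vector(contrast)
        )
        glm = _GLM(design.matrix, cvec, design.interest)
        vec = glm.t_stats(Y)
    elif stat_family == "F":
        glm = _GLM(design.matrix, None, design.interest)
        vec = glm.f_stats(Y)
    else:
        raise ValueError(f"unknown stat_family {stat_family!r}")
    n = fc_stack.shape[1]
    mat = np.zeros((n, n))
    mat[ii, jj] = vec
    mat += mat.T
    return mat


# ---------------------------------------------------------------- components


@dataclass
class Component:
    edges: np.ndarray  # (k, 2) node pairs
    nodes: np.ndarray
    n_edges: int
    n_nodes: int
    size: float  # extent or intensity, per config
    p_value: float | None = None


def _components_from_mask(
    stat_vec: np.ndarray,
    mask: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    n: int,
    size_stat: str,
) -> list[Component]:
    if not mask.any():
        return []
    mi, mj = ii[mask], jj[mask]
    sub = csr_array(
        (np.ones(mi.size), (mi, mj)),
        shape=(n, n),
    )
    _, labels = _cc(sub + sub.T, directed=False)
    comps: dict[int, list[int]] = {}
    for e, lab in enumerate(labels[mi]):
        comps.setdefault(int(lab), []).append(e)
    out = []
    for lab, edge_idx in comps.items():
        edges = np.column_stack([mi[edge_idx], mj[edge_idx]])
        nodes = np.unique(edges)
        size = (
            float(len(edge_idx))
            if size_stat == "extent"
            else float(stat_vec[mask][edge_idx].sum())
        )
        out.append(Component(edges, nodes, len(edge_idx), nodes.size, size))
    out.sort(key=lambda c: (-c.size, c.nodes.min()))
    return out


def _max_component_size(
    stat_vec: np.ndarray,
    threshold: float,
    ii: np.ndarray,
    jj: np.ndarray,
    n: int,
    size_stat: str,
) -> float:
    mask = stat_vec > threshold
    if not mask.any():
        return 0.0
    mi, mj = ii[mask], jj[mask]
    sub = csr_array((np.ones(mi.size), (mi, mj)), shape=(n, n))
    _, labels = _cc(sub + sub.T, directed=False)
    edge_labels = labels[mi]
    if size_stat == "extent":
        return float(np.bincount(edge_labels).max())
    return float(np.bincount(edge_labels, weights=stat_vec[mask]).max())


def suprathreshold_components(
    stat_matrix: np.ndarray, threshold: float, size_stat: str = "extent"
) -> list[Component]:
    """Connected components of the graph of edges with statistic > threshold,
    sorted by descending size (empty list when nothing survives)."""
    mat = np.asarray(stat_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("statistic matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("statistic matrix must be symmetric")
    n = mat.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    vec = mat[ii, jj]
    return _components_from_mask(vec, vec > threshold, ii, jj, n, size_stat)


# ---------------------------------------------------------------- NBS test


@dataclass
class NBSConfig:
    threshold: float
    stat_family: str = "t"  # "t" for 2 groups, "F" for >= 3
    n_perm: int = 5000
    alpha: float = 0.05
    signed: bool = True  # raw edge values; False analyzes |r|
    size_stat: str = "extent"  # or "intensity"

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("cluster-defining threshold must be positive")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.stat_family not in ("t", "F"):
            raise ValueError("stat_family must be 't' or 'F'")
        if self.size_stat not in ("extent", "intensity"):
            raise ValueError("size_stat must be 'extent' or 'intensity'")


@dataclass
class NBSResult:
    components: list[Component]
    threshold_used: float
    n_perm: int
    null_max_sizes: np.ndarray
    alpha: float
    warnings: list[str] = field(default_factory=list)

    def significant(self, alpha: float | None = None) -> list[Component]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.components if c.p_value is not None and c.p_value <= a]


def nbs_test(
    fc_stack: np.ndarray,
    design: Design,
    contrast: tuple[str, str] | np.ndarray | None,
    config: NBSConfig,
    seed,
) -> NBSResult:
    """Run the NBS: observed suprathreshold components against the
    permutation null of the maximum component size (Freedman-Lane)."""
    Y, ii, jj = _stack_to_edges(fc_stack)
    if Y.shape[0] != design.n:
        raise ValueError(
            f"fc_stack has {Y.shape[0]} subjects but design has {design.n} rows"
        )
    if not config.signed:
        Y = np.abs(Y)
    n_nodes = fc_stack.shape[1]
    if config.stat_family == "t":
        if contrast is None:
            if len(design.groups) != 2:
                raise ValueError("a contrast pair is required with >2 groups")
            contrast = (design.groups[0], design.groups[1])
        cvec = (
            np.asarray(contrast, dtype=float)
            if isinstance(contrast, np.ndarray)
            else design.contrast_vector(contrast)
        )
        glm = _GLM(design.matrix, cvec, design.interest)
        stat = glm.t_stats
    else:
        glm = _GLM(design.matrix, None, design.interest)
        stat = glm.f_stats

    obs_vec = stat(Y)
    comps = _components_from_mask(
        obs_vec, obs_vec > config.threshold, ii, jj, n_nodes, config.size_stat
    )

    fitted_red = glm.hz @ Y
    resid_red = Y - fitted_red
    rng = np.random.default_rng(seed)
    null_max = np.empty(config.n_perm)
    for b in range(config.n_perm):
        perm = rng.permutation(design.n)
        y_star = fitted_red + resid_red[perm]
        null_max[b] = _max_component_size(
            stat(y_star), config.threshold, ii, jj, n_nodes, config.size_stat
        )
    for c in comps:
        c.p_value = float((1 + np.sum(null_max >= c.size)) / (config.n_perm + 1))

    warn = []
    if 1.0 / (config.n_perm + 1) > config.alpha:
        warn.append(
            f"n_perm={config.n_perm} cannot resolve alpha={config.alpha}; "
            f"smallest attainable p is {1 / (config.n_perm + 1):.4f}"
        )
    return NBSResult(comps, config.threshold, config.n_perm, null_max, config.alpha, warn)


def median_threshold(range_low: float, range_high: float, step: float = 0.1) -> float:
    """Median of the inclusive evenly spaced threshold grid."""
    if step <= 0:
        raise ValueError("step must be positive")
    if range_high < range_low:
        raise ValueError("range_high must be >= range_low")
    n = (range_high - range_low) / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"step {step} does not divide the range [{range_low}, {range_high}]"
        )
    grid = range_low + step * np.arange(int(round(n)) + 1)
    return float(np.median(grid))


def posthoc_pairwise(
    fc_stack: np.ndarray,
    metadata: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    thresholds: Mapping[tuple[str, str], float],
    n_perm: int = 5000,
    alpha: float = 0.05 / 3,
    seed=0,
    group_col: str = "group",
    covariates: Sequence[str] = ("age", "sex"),
    signed: bool = True,
) -> dict[tuple[str, str], NBSResult]:
    """Pairwise two-group NBS runs at Bonferroni-adjusted alpha.

    Each pair gets its own cluster-defining threshold and an independent
    permutation stream derived from ``seed``.
    """
    labels = set(metadata[group_col].astype(str))
    for pair in pairs:
        for g in pair:
            if g not in labels:
                raise ValueError(f"unknown group label {g!r} in pair {pair}")
    stack = np.asarray(fc_stack, dtype=float)
    seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    out: dict[tuple[str, str], NBSResult] = {}
    for pair, child in zip(pairs, seeds):
        sel = metadata[group_col].astype(str).isin(pair).to_numpy()
        sub_meta = metadata.loc[sel].reset_index(drop=True)
        design = design_matrix(
            sub_meta, group_col=group_col, covariates=covariates, groups=list(pair)
        )
        config = NBSConfig(
            threshold=thresholds[pair],
            stat_family="t",
            n_perm=n_perm,
            alpha=alpha,
            signed=signed,
        )
        out[pair] = nbs_test(stack[sel], design, pair, config, child)
    return out


# ------------------------------------------------------- component summaries


def _component_edges(component) -> np.ndarray:
    edges = component.edges if isinstance(component, Component) else component
    edges = np.asarray(edges, dtype=int)
    if edges.ndim != 2 or edges.shape[1] != 2 or edges.shape[0] == 0:
        raise ValueError("component must supply a non-empty (k, 2) edge list")
    return edges


def component_mask_strength(fc_stack: np.ndarray, component) -> np.ndarray:
    """Per subject, the mean raw FC over the component's edges."""
    stack = np.asarray(fc_stack, dtype=float)
    edges = _component_edges(component)
    return stack[:, edges[:, 0], edges[:, 1]].mean(axis=1)


def nodal_strength_in_component(
    fc_stack: np.ndarray, component, nodes: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per subject and per component node, the sum of raw FC over that
    node's component-incident edges.

    Returns ``(values, nodes)`` with ``values`` of shape
    (n_subjects, n_nodes_in_component).
    """
    stack = np.asarray(fc_stack, dtype=float)
    edges = _component_edges(component)
    comp_nodes = np.unique(edges)
    if nodes is None:
        nodes = comp_nodes
    else:
        nodes = np.asarray(nodes, dtype=int)
        outside = np.setdiff1d(nodes, comp_nodes)
        if outside.size:
            raise ValueError(
                f"nodes {outside.tolist()} are not part of the component"
            )
    vals = np.zeros((stack.shape[0], len(nodes)))
    for k, node in enumerate(nodes):
        inc = edges[(edges[:, 0] == node) | (edges[:, 1] == node)]
        vals[:, k] = stack[:, inc[:, 0], inc[:, 1]].sum(axis=1)
    return vals, np.asarray(nodes)
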