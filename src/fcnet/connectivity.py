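"""Motion QC, Pearson functional connectivity and density thresholding.

Conventions (documented because the source literature leaves them open):

* Framewise displacement follows Power's formula — the sum of absolute
  backward differences of the six realignment parameters, rotations
  converted to arc length on a 50 mm sphere.  FD of the first volume is 0
  by convention, so the series has one entry per volume.
* Both exclusion inequalities are strict: a volume is flagged when
  FD > 0.5 mm, a subject excluded when flagged/total > 10%.
* Density thresholding keeps the k = round-half-away-from-zero of
  density * N(N-1)/2 largest off-diagonal weights by |r| (raw r in signed
  mode).  Ties are broken by (|weight| desc, node pair lexicographic), a
  stable total order, so edge sets are nested across densities and every
  subject's graph at a given density has the same edge count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "FCMatrix",
    "DensityGrid",
    "BinaryGraph",
    "MotionQCResult",
    "framewise_displacement",
    "qc_exclude",
    "pearson_fc",
    "global_fc_strength",
    "threshold_at_density",
    "n_edges_at_density",
    "DEFAULT_HEAD_RADIUS_MM",
    "DEFAULT_FD_THRESHOLD_MM",
    "DEFAULT_MAX_FLAGGED_FRACTION",
]

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_MAX_FLAGGED_FRACTION = 0.10


@dataclass
class FCMatrix:
    """Symmetric N x N Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    node_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("FC matrix contains non-finite values")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("FC matrix diagonal must be 1")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-10 or off.max() > 1 + 1e-10):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        self.values = v
        if self.node_ids is None:
            self.node_ids = tuple(f"n{i}" for i in range(v.shape[0]))
        else:
            self.node_ids = tuple(self.node_ids)
            if len(self.node_ids) != v.shape[0]:
                raise ValueError("node_ids length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DensityGrid:
    """Strictly increasing sparsity values in (0, 1)."""

    densities: tuple[float, ...]

    def __post_init__(self):
        d = tuple(float(x) for x in self.densities)
        if len(d) == 0:
            raise ValueError("density grid is empty")
        if any(not 0 < x < 1 for x in d):
            raise ValueError("densities must lie in (0, 1)")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("densities must be strictly increasing")
        object.__setattr__(self, "densities", d)

    @classmethod
    def default(cls) -> "DensityGrid":
        """The 0.06..0.37 grid in steps of 0.01 (32 values)."""
        return cls(tuple(np.round(np.arange(6, 38) / 100.0, 2)))

    @classmethod
    def from_range(cls, low: float, high: float, step: float) -> "DensityGrid":
        if step <= 0:
            raise ValueError("step must be positive")
        n = int(round((high - low) / step))
        vals = np.round(low + step * np.arange(n + 1), 10)
        vals = vals[vals <= high + 1e-12]
        return cls(tuple(vals))

    @property
    def step(self) -> float:
        if len(self.densities) < 2:
            return 0.0
        return self.densities[1] - self.densities[0]

    def asarray(self) -> np.ndarray:
        return np.asarray(self.densities)

    def __iter__(self):
        return iter(self.densities)

    def __len__(self):
        return len(self.densities)


@dataclass
class BinaryGraph:
    """Symmetric 0/1 adjacency matrix with zero diagonal."""

    adjacency: np.ndarray
    density_used: float = np.nan

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.int8)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class MotionQCResult:
    fd_series: np.ndarray  # one value per volume; fd[0] == 0
    flagged_volumes: np.ndarray
    excluded: bool
    flagged_fraction: float


def framewise_displacement(
    motion: np.ndarray, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Power-style FD: sum of |Delta| over 3 translations (mm) and 3
    rotations converted to arc length at ``head_radius`` mm.

    Returns one value per volume; the first is 0 by convention.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(
            f"motion must be T x 6 (3 translations, 3 rotations); got shape {m.shape}"
        )
    if m.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    if not np.isfinite(m).all():
        raise ValueError("motion parameters contain non-finite values")
    d = np.abs(np.diff(m, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def qc_exclude(
    fd_series: np.ndarray,
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
    max_fraction: float = DEFAULT_MAX_FLAGGED_FRACTION,
) -> MotionQCResult:
    """Flag volumes with FD > threshold (strict); exclude the subject when
    the flagged fraction exceeds ``max_fraction`` (strict)."""
    fd = np.asarray(fd_series, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    if not np.isfinite(fd).all():
        raise ValueError("FD series contains non-finite values")
    flagged = np.flatnonzero(fd > fd_threshold)
    fraction = flagged.size / fd.size
    return MotionQCResult(fd, flagged, fraction > max_fraction, fraction)


def pearson_fc(
    timeseries: np.ndarray, node_ids: Iterable[str] | None = None
) -> FCMatrix:
    """Pearson correlation matrix over the columns of a T x N series."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a T x N matrix")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 time points for Pearson correlation")
    if not np.isfinite(ts).all():
        raise ValueError("timeseries contains non-finite values")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        ids = list(node_ids) if node_ids is not None else None
        bad = int(np.flatnonzero(sd == 0)[0])
        name = ids[bad] if ids is not None else f"n{bad}"
        raise ValueError(f"node {name} has constant signal (zero variance)")
    r = np.corrcoef(ts, rowvar=False)
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r, tuple(node_ids) if node_ids is not None else None)


def _as_values(fc) -> np.ndarray:
    if isinstance(fc, FCMatrix):
        return fc.values
    return FCMatrix(np.asarray(fc, dtype=float)).values


def global_fc_strength(fc) -> float:
    """Mean of all pairwise raw (signed) correlations — the strict upper
    triangle of the FC matrix, diagonal excluded."""
    v = _as_values(fc)
    n = v.shape[0]
    if n < 2:
        raise ValueError("global FC strength needs at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    return float(v[iu].mean())


def n_edges_at_density(n_nodes: int, density: float) -> int:
    """Edge count retained at a target density: round-half-away-from-zero
    of density * N(N-1)/2."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(density * m + 0.5))


def threshold_at_density(fc, density: float, use_absolute: bool = True) -> BinaryGraph:
    """Binarize an FC matrix by keeping the top-k edges at ``density``.

    Ranking is by |r| in absolute mode (default) or raw r in signed mode;
    ties break by ascending node pair so edge sets nest across densities.
    """
    v = _as_values(fc)
    if not 0 < density < 1:
        raise ValueError(f"density must lie in (0, 1), got {density}")
    n = v.shape[0]
    m = n * (n - 1) // 2
    k = n_edges_at_density(n, density)
    if k == 0:
        raise ValueError(
            f"density {density} keeps zero edges on a {n}-node graph"
        )
    if k > m:
        raise ValueError(
            f"density {density} requests {k} edges but only {m} exist"
        )
    ii, jj = np.triu_indices(n, k=1)
    w = v[ii, jj]
    rank_w = np.abs(w) if use_absolute else w
    order = np.lexsort((jj, ii, -rank_w))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ii[keep], jj[keep]] = 1
    adj |= adj.T
    return BinaryGraph(adj, density_used=k / m)
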