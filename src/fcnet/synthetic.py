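"""Synthetic multi-subject rs-fMRI cohorts with known correlation structure.

The generator is a Gaussian latent-factor surrogate for ROI-level BOLD
signal.  Each node's time series is a weighted sum of

* one global factor shared by all nodes (sets between-community correlation),
* one factor per subnetwork community (raises within-community correlation),
* optional per-edge factors implementing a planted hyperconnected component
  in one designated group,
* an extra global-factor loading on planted hub nodes, and
* independent Gaussian noise completing each node's variance to 1.

With unit node variance the population correlation between two nodes is the
sum of the products of their shared-factor loadings, so the target
correlations are hit in closed form: within-community pairs have
``base_within_r + delta``, between-community pairs ``base_between_r +
delta``, where ``delta`` is the per-group offset of global FC strength.
Planted edges gain exactly ``effect_r`` on top.

Everything is deterministic given ``(spec.seed, subject_seed)``; the cohort
seed ladder derives per-subject seeds from a splittable ``(group index,
subject index)`` counter so adding subjects or groups never perturbs
existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import atlas as atlas_mod

__all__ = [
    "CohortSpec",
    "PlantedComponent",
    "SubjectRecord",
    "ToyGraph",
    "generate_subject_timeseries",
    "generate_cohort",
    "generate_toy_graphs",
    "generate_motion_params",
    "write_cohort",
    "study_like_spec",
]

#: Demographic moments per group, matched to the study's cohort tables
#: (age in years; female proportion).
DEFAULT_COVARIATE_MODEL: dict[str, dict[str, float]] = {
    "HC": {"age_mean": 33.4, "age_sd": 10.0, "female_prop": 0.64},
    "RP": {"age_mean": 34.2, "age_sd": 10.1, "female_prop": 0.70},
    "RP-M": {"age_mean": 29.7, "age_sd": 6.2, "female_prop": 0.54},
    "RP-R": {"age_mean": 36.6, "age_sd": 11.3, "female_prop": 0.92},
}
_FALLBACK_COVARIATES = {"age_mean": 34.0, "age_sd": 10.0, "female_prop": 0.6}

#: Per-group offsets of mean FC strength relative to HC, in correlation
#: units, matching the reported group means of global FC strength
#: (HC 0.223, RP 0.240, RP-M 0.216, RP-R 0.290).
DEFAULT_GLOBAL_OFFSET: dict[str, float] = {
    "HC": 0.0,
    "RP": 0.017,
    "RP-M": -0.007,
    "RP-R": 0.067,
}


@dataclass(frozen=True)
class PlantedComponent:
    """A set of edges whose correlation is raised by ``effect_r`` in ``group``."""

    edges: tuple[tuple[int, int], ...]
    effect_r: float
    group: str

    def __post_init__(self):
        object.__setattr__(
            self,
            "edges",
            tuple((int(i), int(j)) for i, j in self.edges),
        )
        if not 0 < self.effect_r < 1:
            raise ValueError(f"effect_r must lie in (0, 1), got {self.effect_r}")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"planted edge ({i}, {j}) is a self-loop")


@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults emulate the study conditions: 160 nodes in six subnetworks,
    140 retained volumes (150 acquired minus 10 discarded), and group
    offsets of global FC strength matching the reported group means.
    """

    n_per_group: Mapping[str, int]
    n_nodes: int = 160
    n_timepoints: int = 140
    subnetwork_partition: Sequence[str] | None = None
    base_within_r: float = 0.5
    base_between_r: float = 0.16
    global_offset: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GLOBAL_OFFSET)
    )
    planted_component: PlantedComponent | None = None
    planted_hubs: tuple[int, ...] = ()
    hub_boost: float = 0.0
    noise_sd: float | None = None
    covariate_model: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_MODEL.items()}
    )
    age_fc_slope: float = 0.0  # optional confounding knob: d(mean FC)/d(age year)
    seed: int = 0

    def partition(self) -> np.ndarray:
        if self.subnetwork_partition is None:
            return atlas_mod.default_partition(self.n_nodes)
        return np.asarray(self.subnetwork_partition)

    def validate(self) -> None:
        if not self.n_per_group:
            raise ValueError("n_per_group must name at least one group")
        for g, n in self.n_per_group.items():
            if n < 0:
                raise ValueError(f"negative subject count for group {g!r}")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        part = self.partition()
        if part.shape[0] != self.n_nodes:
            raise ValueError(
                f"partition labels {part.shape[0]} nodes but n_nodes={self.n_nodes}"
            )
        for r, name in [
            (self.base_within_r, "base_within_r"),
            (self.base_between_r, "base_between_r"),
        ]:
            if not -1 < r < 1:
                raise ValueError(f"{name}={r} outside (-1, 1)")
        if self.base_between_r < 0:
            raise ValueError("base_between_r must be non-negative")
        if self.base_within_r < self.base_between_r:
            raise ValueError("base_within_r must be >= base_between_r")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.hub_boost < 0:
            raise ValueError("hub_boost must be non-negative")
        for i in self.planted_hubs:
            if not 0 <= i < self.n_nodes:
                raise ValueError(f"planted hub index {i} outside 0..{self.n_nodes - 1}")
        if self.planted_component is not None:
            for i, j in self.planted_component.edges:
                if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                    raise ValueError(
                        f"planted edge ({i}, {j}) references a node outside "
                        f"0..{self.n_nodes - 1}"
                    )
            if self.planted_component.group not in self.n_per_group:
                raise ValueError(
                    f"planted component targets unknown group "
                    f"{self.planted_component.group!r}"
                )


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    timeseries: np.ndarray  # T x N
    motion: np.ndarray | None = None  # T x 6

    def __post_init__(self):
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2:
            raise ValueError("timeseries must be a T x N matrix")
        if not np.isfinite(ts).all():
            raise ValueError("timeseries contains non-finite values")
        self.timeseries = ts


def _covariates_for(spec: CohortSpec, group: str) -> dict[str, float]:
    model = dict(_FALLBACK_COVARIATES)
    model.update(spec.covariate_model.get(group, {}))
    return model


def generate_subject_timeseries(
    spec: CohortSpec,
    group: str,
    subject_seed: int,
    subject_id: str | None = None,
) -> SubjectRecord:
    """Simulate one subject's T x N ROI time-series matrix.

    Deterministic given ``(spec.seed, subject_seed)``.
    """
    spec.validate()
    if group not in spec.n_per_group:
        raise ValueError(
            f"unknown group label {group!r}; known groups: "
            f"{sorted(spec.n_per_group)}"
        )
    ss = np.random.SeedSequence(entropy=int(spec.seed), spawn_key=(int(subject_seed),))
    rng = np.random.default_rng(ss)

    cov = _covariates_for(spec, group)
    age = float(rng.normal(cov["age_mean"], cov["age_sd"]))
    sex = "F" if rng.random() < cov["female_prop"] else "M"

    labels = spec.partition()
    communities, comm_idx = np.unique(labels, return_inverse=True)
    T, N = spec.n_timepoints, spec.n_nodes

    delta = float(spec.global_offset.get(group, 0.0))
    delta += spec.age_fc_slope * (age - cov["age_mean"])
    r_within = spec.base_within_r + delta
    r_between = spec.base_between_r + delta
    if not 0 <= r_between <= r_within < 1:
        raise ValueError(
            f"group {group!r}: offset correlations (within={r_within:.3f}, "
            f"between={r_between:.3f}) fall outside [0, 1)"
        )

    g_factor = rng.standard_normal(T)
    c_factors = rng.standard_normal((T, communities.size))

    load_global = np.full(N, np.sqrt(r_between))
    shared_var = np.full(N, r_within)  # r_between + (r_within - r_between)
    for hub in spec.planted_hubs:
        load_global[hub] = np.sqrt(r_between + spec.hub_boost)
        shared_var[hub] += spec.hub_boost

    x = load_global * g_factor[:, None]
    x += np.sqrt(r_within - r_between) * c_factors[:, comm_idx]

    comp = spec.planted_component
    if comp is not None and comp.group == group:
        load = np.sqrt(comp.effect_r)
        for i, j in comp.edges:
            z = rng.standard_normal(T)
            x[:, i] += load * z
            x[:, j] += load * z
            shared_var[i] += comp.effect_r
            shared_var[j] += comp.effect_r

    if spec.noise_sd is not None:
        noise_var = np.full(N, spec.noise_sd**2)
    else:
        noise_var = 1.0 - shared_var
        if np.any(noise_var <= 0):
            bad = int(np.argmin(noise_var))
            raise ValueError(
                f"node {bad}: shared-factor variance {shared_var[bad]:.3f} >= 1; "
                "reduce correlations, hub_boost or planted effect"
            )
    x += np.sqrt(noise_var) * rng.standard_normal((T, N))

    if subject_id is None:
        subject_id = f"{group}-s{int(subject_seed)}"
    return SubjectRecord(subject_id, group, age, sex, x)


def generate_cohort(
    spec: CohortSpec, with_motion: bool = False
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate all subjects plus a one-row-per-subject metadata table.

    Per-subject seeds come from a splittable counter over (group index,
    subject index); the metadata rows match the record list one-to-one.
    """
    spec.validate()
    records: list[SubjectRecord] = []
    for gi, (group, n) in enumerate(spec.n_per_group.items()):
        for k in range(n):
            rec = generate_subject_timeseries(
                spec,
                group,
                subject_seed=gi * 1_000_000 + k,
                subject_id=f"{group}-{k:03d}",
            )
            if with_motion:
                rec.motion = generate_motion_params(
                    spec.n_timepoints,
                    seed=int(
                        np.random.SeedSequence(
                            entropy=int(spec.seed),
                            spawn_key=(gi * 1_000_000 + k, 7),
                        ).generate_state(1)[0]
                        % 2**31
                    ),
                )
            records.append(rec)
    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "age": [round(r.age, 2) for r in records],
            "sex": [r.sex for r in records],
        }
    )
    return records, meta


@dataclass(frozen=True)
class ToyGraph:
    name: str
    adjacency: np.ndarray
    description: str


def _from_nx(g: nx.Graph, name: str, description: str) -> ToyGraph:
    adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes()), dtype=int)
    return ToyGraph(name, adj, description)


def generate_toy_graphs(er_seed: int = 1234) -> dict[str, ToyGraph]:
    """Named binary adjacency fixtures used as metric and attack oracles."""
    graphs = {}
    for n in (4, 5):
        graphs[f"complete_k{n}"] = _from_nx(
            nx.complete_graph(n), f"complete_k{n}", f"complete graph on {n} nodes"
        )
    graphs["star_k1_5"] = _from_nx(
        nx.star_graph(5), "star_k1_5", "star with hub node 0 and 5 leaves"
    )
    graphs["path_p3"] = _from_nx(nx.path_graph(3), "path_p3", "3-node path")
    graphs["path_p4"] = _from_nx(nx.path_graph(4), "path_p4", "4-node path")
    graphs["ring_lattice_20_4"] = _from_nx(
        nx.circulant_graph(20, [1, 2]),
        "ring_lattice_20_4",
        "ring lattice, 20 nodes, each joined to 4 nearest neighbours",
    )
    graphs["er_100_p10"] = _from_nx(
        nx.gnp_random_graph(100, 0.1, seed=er_seed),
        "er_100_p10",
        f"Erdos-Renyi G(100, 0.1), seed {er_seed}",
    )
    two = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(3))
    graphs["two_components_4_3"] = _from_nx(
        two, "two_components_4_3", "disconnected K4 plus K3"
    )
    return graphs


def generate_motion_params(
    T: int,
    spike_volumes: Sequence[int] = (),
    spike_mm: float = 0.0,
    baseline_mm: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """T x 6 motion parameters: smooth low-amplitude drift plus spikes.

    Columns are 3 translations (mm) then 3 rotations (radians).  Each spike
    is a persistent x-translation step of ``spike_mm`` at the listed volume,
    so it produces exactly one framewise-displacement excursion.  Volume 0
    cannot host a spike (FD is a backward difference).
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    for v in spike_volumes:
        if v == 0:
            raise ValueError(
                "spike at volume 0 is undefined: FD compares a volume with its "
                "predecessor"
            )
        if not 0 < v < T:
            raise ValueError(f"spike volume {v} outside 1..{T - 1}")
    rng = np.random.default_rng(seed)
    t = np.arange(T)
    motion = np.zeros((T, 6))
    if baseline_mm > 0:
        for col in range(6):
            amp = baseline_mm if col < 3 else baseline_mm / 50.0
            freqs = rng.uniform(0.5, 2.0, 3)
            phases = rng.uniform(0, 2 * np.pi, 3)
            drift = sum(
                np.sin(2 * np.pi * f * t / T + ph) for f, ph in zip(freqs, phases)
            )
            motion[:, col] = amp * drift / 3.0
    for v in spike_volumes:
        motion[v:, 0] += spike_mm
    return motion


def write_cohort(
    records: Sequence[SubjectRecord],
    meta: pd.DataFrame,
    outdir,
    atlas: pd.DataFrame | None = None,
) -> None:
    """Write a cohort in the plain-text exchange layout.

    ``timeseries/<subject>.tsv`` (T rows x N columns, node-id header),
    ``motion/<subject>.tsv`` (T x 6, when present), ``metadata.tsv`` and
    optionally ``atlas.tsv``.
    """
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    node_ids = None
    for rec in records:
        n = rec.timeseries.shape[1]
        if node_ids is None or len(node_ids) != n:
            node_ids = [f"n{i}" for i in range(n)]
        pd.DataFrame(rec.timeseries, columns=node_ids).to_csv(
            outdir / "timeseries" / f"{rec.subject_id}.tsv",
            sep="\t",
            index=False,
            float_format="%.6f",
        )
        if rec.motion is not None:
            (outdir / "motion").mkdir(exist_ok=True)
            cols = ["tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad"]
            pd.DataFrame(rec.motion, columns=cols).to_csv(
                outdir / "motion" / f"{rec.subject_id}.tsv",
                sep="\t",
                index=False,
                float_format="%.6f",
            )
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    if atlas is not None:
        atlas_mod.write_atlas(atlas, outdir / "atlas.tsv")


def study_like_spec(
    n_nodes: int = 160,
    n_timepoints: int = 140,
    n_hc: int = 50,
    n_rp_m: int = 13,
    n_rp_r: int = 12,
    seed: int = 0,
    **overrides,
) -> CohortSpec:
    """A three-group spec mirroring the study design (HC / RP-M / RP-R)."""
    return CohortSpec(
        n_per_group={"HC": n_hc, "RP-M": n_rp_m, "RP-R": n_rp_r},
        n_nodes=n_nodes,
        n_timepoints=n_timepoints,
        seed=seed,
        **overrides,
    )
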