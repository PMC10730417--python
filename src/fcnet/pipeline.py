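"""End-to-end orchestration: simulate/ingest -> QC -> FC -> metrics ->
hubs -> robustness -> NBS -> statistics -> report.

Every stage communicates only through delimited-text files (plus JSON
sidecars) inside the run directory, so stages can be re-run in isolation
and diffs stay reviewable.  A single master seed drives all stochastic
stages through named SeedSequence derivations, and a run manifest records
the config hash and SHA-256 digests of every output.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import atlas as atlas_mod
from . import connectivity as conn
from . import hubs as hubs_mod
from . import metrics as metrics_mod
from . import nbs as nbs_mod
from . import robustness as rob
from . import stats as stats_mod
from . import synthetic

log = logging.getLogger("fcnet")

STAGES = (
    "simulate",
    "qc",
    "connectivity",
    "metrics",
    "hubs",
    "robustness",
    "nbs",
    "stats",
    "report",
)

_DEFAULTS: dict[str, Any] = {
    "outdir": "fcnet-run",
    "seed": 0,
    "log_level": "INFO",
    "inputs": {"cohort_dir": None},
    "synthetic": {
        "n_per_group": {"HC": 10, "RP": 10},
        "n_nodes": 40,
        "n_timepoints": 140,
        "base_within_r": 0.5,
        "base_between_r": 0.16,
        "global_offset": None,
        "planted_hubs": [],
        "hub_boost": 0.0,
        "with_motion": False,
    },
    "density": {"min": 0.06, "max": 0.37, "step": 0.01},
    "qc": {"fd_threshold": 0.5, "max_fraction": 0.10, "head_radius": 50.0},
    "connectivity": {"use_absolute": True},
    "metrics": {"null_count": 100, "include_normalized": True},
    "robustness": {"n_reps": 100, "window": 5, "factor": 1.5},
    "nbs": {
        "contrast": ["HC", "RP"],
        "stat_family": "t",
        "threshold": 3.9,
        "n_perm": 5000,
        "alpha": 0.05,
        "signed": True,
    },
    "stats": {"n_perm": 10000, "covariates": ["age", "sex"]},
}


@dataclass
class PipelineConfig:
    """Validated nested configuration; unknown keys are rejected."""

    values: dict[str, Any]

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        merged = copy.deepcopy(_DEFAULTS)
        for key, val in raw.items():
            if key not in merged:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(merged[key], dict) and isinstance(val, dict):
                for sub, sval in val.items():
                    if sub not in merged[key]:
                        raise ValueError(f"unknown config key {key}.{sub}")
                    merged[key][sub] = sval
            else:
                merged[key] = val
        cfg = cls(merged)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        d = self.values["density"]
        if not (0 < d["min"] < d["max"] < 1):
            raise ValueError(
                f"density range ({d['min']}, {d['max']}) must lie inside (0, 1)"
            )
        if d["step"] <= 0:
            raise ValueError("density.step must be positive")
        if self.values["qc"]["fd_threshold"] <= 0:
            raise ValueError("qc.fd_threshold must be positive")
        if not 0 <= self.values["qc"]["max_fraction"] < 1:
            raise ValueError("qc.max_fraction must lie in [0, 1)")
        if self.values["nbs"]["n_perm"] < 100:
            raise ValueError("nbs.n_perm must be >= 100")
        int(self.values["seed"])

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def grid(self) -> conn.DensityGrid:
        d = self.values["density"]
        return conn.DensityGrid.from_range(d["min"], d["max"], d["step"])

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
        return np.random.SeedSequence(
            entropy=int(self.values["seed"]), spawn_key=(tag,)
        )

    def hash(self) -> str:
        blob = json.dumps(self.values, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: list[dict[str, Any]] = field(default_factory=list)

    def record(self, name: str, outputs: dict[str, str], started: float) -> None:
        self.stages.append(
            {
                "stage": name,
                "outputs": outputs,
                "started": started,
                "finished": time.time(),
            }
        )

    def to_json(self) -> dict[str, Any]:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "stages": self.stages,
        }


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _digest_outputs(outdir: Path, paths: Sequence[Path]) -> dict[str, str]:
    return {str(p.relative_to(outdir)): _digest(p) for p in paths if p.exists()}


def read_atlas(path) -> pd.DataFrame:
    """Validated atlas table (id, name, x, y, z, subnetwork)."""
    return atlas_mod.read_atlas(path)


# ------------------------------------------------------------------ stages


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    syn = dict(cfg["synthetic"])
    with_motion = bool(syn.pop("with_motion", False))
    if syn.get("global_offset") is None:
        syn.pop("global_offset", None)
    syn["planted_hubs"] = tuple(syn.get("planted_hubs", ()))
    seed = int(cfg.stage_seed("simulate").generate_state(1)[0] % 2**31)
    spec = synthetic.CohortSpec(seed=seed, **syn)
    records, meta = synthetic.generate_cohort(spec, with_motion=with_motion)
    atlas = atlas_mod.make_atlas(spec.n_nodes)
    synthetic.write_cohort(records, meta, outdir, atlas=atlas)
    out = [outdir / "metadata.tsv", outdir / "atlas.tsv"]
    out += sorted((outdir / "timeseries").glob("*.tsv"))
    if with_motion:
        out += sorted((outdir / "motion").glob("*.tsv"))
    return out


def _stage_qc(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t")
    qc_cfg = cfg["qc"]
    rows = []
    motion_dir = outdir / "motion"
    for sid in meta["subject_id"]:
        mfile = motion_dir / f"{sid}.tsv"
        if mfile.exists():
            motion = pd.read_csv(mfile, sep="\t").to_numpy()
            fd = conn.framewise_displacement(motion, qc_cfg["head_radius"])
            res = conn.qc_exclude(fd, qc_cfg["fd_threshold"], qc_cfg["max_fraction"])
            rows.append(
                {
                    "subject_id": sid,
                    "n_volumes": fd.size,
                    "n_flagged": res.flagged_volumes.size,
                    "flagged_fraction": round(res.flagged_fraction, 4),
                    "excluded": res.excluded,
                }
            )
        else:
            rows.append(
                {
                    "subject_id": sid,
                    "n_volumes": 0,
                    "n_flagged": 0,
                    "flagged_fraction": 0.0,
                    "excluded": False,
                }
            )
    qc_path = outdir / "qc.tsv"
    pd.DataFrame(rows).to_csv(qc_path, sep="\t", index=False)
    return [qc_path]


def _stage_connectivity(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t")
    qc = pd.read_csv(outdir / "qc.tsv", sep="\t")
    retained = set(qc.loc[~qc["excluded"], "subject_id"])
    fc_dir = outdir / "fc"
    fc_dir.mkdir(exist_ok=True)
    rows = []
    out = []
    for _, row in meta.iterrows():
        sid = row["subject_id"]
        if sid not in retained:
            continue
        ts = pd.read_csv(outdir / "timeseries" / f"{sid}.tsv", sep="\t")
        fcm = conn.pearson_fc(ts.to_numpy(), node_ids=ts.columns)
        path = fc_dir / f"{sid}.tsv"
        pd.DataFrame(fcm.values, columns=fcm.node_ids).to_csv(
            path, sep="\t", index=False, float_format="%.6f"
        )
        out.append(path)
        rows.append(
            {
                "subject_id": sid,
                "group": row["group"],
                "global_fc_strength": round(conn.global_fc_strength(fcm), 6),
            }
        )
    prov = {
        "density_grid": list(cfg.grid()),
        "use_absolute": bool(cfg["connectivity"]["use_absolute"]),
        "n_subjects": len(rows),
    }
    (fc_dir / "provenance.json").write_text(json.dumps(prov, indent=2))
    table = outdir / "connectivity.tsv"
    pd.DataFrame(rows).to_csv(table, sep="\t", index=False)
    return out + [fc_dir / "provenance.json", table]


def _load_fc_stack(outdir: Path) -> tuple[np.ndarray, pd.DataFrame]:
    table = pd.read_csv(outdir / "connectivity.tsv", sep="\t")
    stack = np.stack(
        [
            pd.read_csv(outdir / "fc" / f"{sid}.tsv", sep="\t").to_numpy()
            for sid in table["subject_id"]
        ]
    )
    stack = (stack + stack.transpose(0, 2, 1)) / 2.0
    for s in stack:
        np.fill_diagonal(s, 1.0)
    return stack, table


def _stage_metrics(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    stack, table = _load_fc_stack(outdir)
    grid = cfg.grid()
    use_abs = bool(cfg["connectivity"]["use_absolute"])
    seeds = cfg.stage_seed("metrics").spawn(len(table))
    curve_rows, gauc_rows, nauc_rows = [], [], []
    for (sid, child), fcv in zip(zip(table["subject_id"], seeds), stack):
        prof = metrics_mod.metric_profile(
            fcv,
            grid,
            null_count=int(cfg["metrics"]["null_count"]),
            seed=child,
            include_normalized=bool(cfg["metrics"]["include_normalized"]),
            use_absolute=use_abs,
        )
        for m, curve in prof.global_curves.items():
            for dens, val in zip(prof.densities, curve):
                curve_rows.append(
                    {"subject_id": sid, "metric": m, "density": dens, "value": val}
                )
            gauc_rows.append(
                {"subject_id": sid, "metric": m, "auc": prof.global_auc[m]}
            )
        for m, auc in prof.nodal_auc.items():
            for node, val in enumerate(auc):
                nauc_rows.append(
                    {"subject_id": sid, "metric": m, "node": node, "auc": val}
                )
    paths = [
        outdir / "metrics_global_curves.tsv",
        outdir / "metrics_global_auc.tsv",
        outdir / "metrics_nodal_auc.tsv",
    ]
    pd.DataFrame(curve_rows).to_csv(paths[0], sep="\t", index=False, float_format="%.6f")
    pd.DataFrame(gauc_rows).to_csv(paths[1], sep="\t", index=False, float_format="%.6f")
    pd.DataFrame(nauc_rows).to_csv(paths[2], sep="\t", index=False, float_format="%.6f")
    return paths


def _stage_hubs(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    nodal = pd.read_csv(outdir / "metrics_nodal_auc.tsv", sep="\t")
    meta = pd.read_csv(outdir / "connectivity.tsv", sep="\t")
    atlas = atlas_mod.read_atlas(outdir / "atlas.tsv")
    dc = nodal[nodal["metric"] == "Dc"].pivot(
        index="subject_id", columns="node", values="auc"
    )
    dc = dc.loc[meta["subject_id"]]
    groups = meta["group"].to_numpy()
    hub_sets = hubs_mod.group_mean_hub_sets(dc.to_numpy(), groups)
    hub_rows, count_rows, mean_rows = [], [], []
    for g, hs in hub_sets.items():
        counts = hubs_mod.hub_subnetwork_counts(
            hs, atlas, label_set=atlas_mod.SUBNETWORKS
        )
        mean_vec = dc.to_numpy()[groups == g].mean(axis=0)
        is_hub = np.zeros(dc.shape[1], dtype=bool)
        is_hub[hs.hub_nodes] = True
        for node in range(dc.shape[1]):
            hub_rows.append(
                {
                    "group": g,
                    "node": node,
                    "name": atlas["name"].iloc[node],
                    "subnetwork": atlas["subnetwork"].iloc[node],
                    "auc_dc": round(float(mean_vec[node]), 6),
                    "is_hub": bool(is_hub[node]),
                }
            )
        for lab, cnt in counts.items():
            count_rows.append(
                {"group": g, "subnetwork": lab, "n_hubs": cnt, "basis": "group-mean"}
            )
        for sid, vec in zip(dc.index[groups == g], dc.to_numpy()[groups == g]):
            if len(hs):
                mean_rows.append(
                    {
                        "subject_id": sid,
                        "group": g,
                        "mean_hub_dc": round(hubs_mod.mean_hub_dc(vec, hs), 6),
                    }
                )
    per_subj = hubs_mod.per_subject_hub_counts(
        dc.to_numpy(), groups, atlas, label_set=atlas_mod.SUBNETWORKS
    )
    per_subj["basis"] = "per-subject"
    counts_table = pd.concat(
        [pd.DataFrame(count_rows), per_subj], ignore_index=True
    )
    paths = [outdir / "hubs.tsv", outdir / "hub_counts.tsv", outdir / "mean_hub_dc.tsv"]
    pd.DataFrame(hub_rows).to_csv(paths[0], sep="\t", index=False)
    counts_table.to_csv(paths[1], sep="\t", index=False, float_format="%.4f")
    pd.DataFrame(mean_rows).to_csv(paths[2], sep="\t", index=False)
    return paths


def _stage_robustness(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    stack, table = _load_fc_stack(outdir)
    grid = cfg.grid()
    use_abs = bool(cfg["connectivity"]["use_absolute"])
    rcfg = cfg["robustness"]
    seeds = cfg.stage_seed("robustness").spawn(len(table))
    summary_rows, traj_rows = [], []
    for (idx, row), child in zip(table.iterrows(), seeds):
        sid, group = row["subject_id"], row["group"]
        trajs = {}
        for dens in grid:
            g = conn.threshold_at_density(stack[idx], dens, use_absolute=use_abs)
            trajs[dens] = rob.targeted_attack(g)
        min_dens = rob.select_min_threshold(trajs)
        tgt = trajs[min_dens]
        g_min = conn.threshold_at_density(stack[idx], min_dens, use_absolute=use_abs)
        rnd = rob.random_failure(g_min, int(rcfg["n_reps"]), child)
        for traj in (tgt, rnd):
            dis = rob.disintegration_point(
                traj, window=int(rcfg["window"]), factor=float(rcfg["factor"])
            )
            summary_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "density": min_dens,
                    "mode": traj.mode,
                    "robustness_auc": round(traj.robustness_auc, 4),
                    "gcc_initial": traj.gcc_sizes[0],
                    "disintegration_index": -1 if dis is None else dis.index,
                    "disintegration_window": int(rcfg["window"]),
                }
            )
            for k, size in zip(traj.removed_counts, traj.gcc_sizes):
                traj_rows.append(
                    {
                        "subject_id": sid,
                        "density": min_dens,
                        "mode": traj.mode,
                        "removed": int(k),
                        "gcc": round(float(size), 4),
                    }
                )
    paths = [outdir / "robustness.tsv", outdir / "robustness_trajectories.tsv"]
    pd.DataFrame(summary_rows).to_csv(paths[0], sep="\t", index=False)
    pd.DataFrame(traj_rows).to_csv(paths[1], sep="\t", index=False)
    return paths


def _stage_nbs(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    stack, table = _load_fc_stack(outdir)
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t")
    meta = meta.set_index("subject_id").loc[table["subject_id"]].reset_index()
    ncfg = cfg["nbs"]
    config = nbs_mod.NBSConfig(
        threshold=float(ncfg["threshold"]),
        stat_family=str(ncfg["stat_family"]),
        n_perm=int(ncfg["n_perm"]),
        alpha=float(ncfg["alpha"]),
        signed=bool(ncfg["signed"]),
    )
    contrast = tuple(ncfg["contrast"]) if ncfg["contrast"] else None
    if config.stat_family == "t" and contrast is not None:
        sel = meta["group"].isin(contrast).to_numpy()
        meta_sel = meta.loc[sel].reset_index(drop=True)
        design = nbs_mod.design_matrix(meta_sel, groups=list(contrast))
        result = nbs_mod.nbs_test(
            stack[sel], design, contrast, config, cfg.stage_seed("nbs")
        )
    else:
        design = nbs_mod.design_matrix(meta)
        result = nbs_mod.nbs_test(stack, design, None, config, cfg.stage_seed("nbs"))
    stat_mat = nbs_mod.edge_stats(
        stack if contrast is None or config.stat_family != "t" else stack[sel],
        design,
        contrast if config.stat_family == "t" else None,
        stat_family=config.stat_family,
    )
    edge_rows = []
    for cid, comp in enumerate(result.components):
        for i, j in comp.edges:
            edge_rows.append(
                {
                    "component_id": cid,
                    "node_i": int(i),
                    "node_j": int(j),
                    "statistic": round(float(stat_mat[i, j]), 4),
                }
            )
    summary = {
        "threshold": result.threshold_used,
        "stat_family": config.stat_family,
        "contrast": list(contrast) if contrast else "omnibus",
        "n_perm": result.n_perm,
        "alpha": result.alpha,
        "components": [
            {
                "id": cid,
                "n_edges": c.n_edges,
                "n_nodes": c.n_nodes,
                "p_fwer": c.p_value,
            }
            for cid, c in enumerate(result.components)
        ],
        "warnings": result.warnings,
    }
    paths = [outdir / "nbs_edges.tsv", outdir / "nbs_summary.json"]
    pd.DataFrame(
        edge_rows, columns=["component_id", "node_i", "node_j", "statistic"]
    ).to_csv(paths[0], sep="\t", index=False)
    paths[1].write_text(json.dumps(summary, indent=2))
    return paths


def _stage_stats(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t").set_index("subject_id")
    covars = list(cfg["stats"]["covariates"])
    n_perm = int(cfg["stats"]["n_perm"])
    seeds = cfg.stage_seed("stats").spawn(8)
    measures: list[tuple[str, pd.DataFrame, str]] = []
    conn_table = pd.read_csv(outdir / "connectivity.tsv", sep="\t")
    measures.append(("global_fc_strength", conn_table, "global_fc_strength"))
    hub_path = outdir / "mean_hub_dc.tsv"
    if hub_path.exists():
        measures.append(("mean_hub_dc", pd.read_csv(hub_path, sep="\t"), "mean_hub_dc"))
    rob_path = outdir / "robustness.tsv"
    if rob_path.exists():
        rtab = pd.read_csv(rob_path, sep="\t")
        rtab = rtab[rtab["mode"] == "targeted"].rename(
            columns={"robustness_auc": "value"}
        )
        measures.append(("robustness_auc_targeted", rtab, "value"))
    rows = []
    for k, (name, tab, col) in enumerate(measures):
        vals = tab[col].to_numpy(dtype=float)
        groups = tab["group"].tolist()
        cov = meta.loc[tab["subject_id"], covars] if covars else None
        res = stats_mod.adjusted_group_compare(vals, groups, cov, measure=name)
        p_perm = stats_mod.permutation_pvalue(
            vals, groups, cov, n_perm=n_perm, seed=seeds[k]
        )
        rows.append(
            {
                "measure": name,
                "contrast": " vs ".join(res.groups),
                "stat_name": res.stat_name,
                "statistic": round(res.statistic, 4),
                "p_param": res.p_param,
                "p_perm": p_perm,
                "method": res.method,
                "n": res.n,
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"] = stats_mod.fdr_adjust(table["p_param"].to_numpy())
    table["p_bonferroni"] = stats_mod.bonferroni_adjust(table["p_param"].to_numpy())
    summary = stats_mod.summarize_cohort(meta.reset_index())
    paths = [outdir / "stats.tsv", outdir / "cohort_summary.tsv"]
    table.to_csv(paths[0], sep="\t", index=False, float_format="%.6g")
    summary.demographics.to_csv(paths[1], sep="\t", index=False)
    if summary.relapse is not None:
        rel_path = outdir / "relapse_rates.tsv"
        summary.relapse.to_csv(rel_path, sep="\t", index=False)
        paths.append(rel_path)
    return paths


def write_report(outdir: Path) -> Path:
    """Assemble a human-readable markdown summary from stage outputs;
    missing stages are marked skipped rather than fatal."""
    outdir = Path(outdir)
    lines = ["# fcnet run report", ""]

    def section(title: str, path: str, render) -> None:
        lines.append(f"## {title}")
        full = outdir / path
        if not full.exists():
            lines.append("_stage skipped (no output found)_")
            lines.append("")
            return
        render(full)
        lines.append("")

    def table_md(df: pd.DataFrame, max_rows: int = 20) -> None:
        df = df.head(max_rows)
        lines.append("| " + " | ".join(map(str, df.columns)) + " |")
        lines.append("|" + "---|" * len(df.columns))
        for _, r in df.iterrows():
            lines.append("| " + " | ".join(str(v) for v in r.tolist()) + " |")

    section(
        "Cohort",
        "cohort_summary.tsv",
        lambda p: table_md(pd.read_csv(p, sep="\t")),
    )
    section("QC", "qc.tsv", lambda p: table_md(pd.read_csv(p, sep="\t")))
    section(
        "Group comparisons",
        "stats.tsv",
        lambda p: table_md(pd.read_csv(p, sep="\t")),
    )
    section(
        "Hub counts",
        "hub_counts.tsv",
        lambda p: table_md(pd.read_csv(p, sep="\t"), max_rows=30),
    )
    section(
        "Robustness",
        "robustness.tsv",
        lambda p: table_md(pd.read_csv(p, sep="\t")),
    )

    def nbs_render(p: Path) -> None:
        summary = json.loads(p.read_text())
        lines.append(
            f"Threshold {summary['threshold']} ({summary['stat_family']}), "
            f"{summary['n_perm']} permutations, contrast {summary['contrast']}."
        )
        if summary["components"]:
            for c in summary["components"]:
                lines.append(
                    f"- component {c['id']}: {c['n_edges']} edges between "
                    f"{c['n_nodes']} nodes, FWER p = {c['p_fwer']:.4f}"
                )
        else:
            lines.append("- no suprathreshold components")

    section("NBS", "nbs_summary.json", nbs_render)
    lines.append("---")
    lines.append(f"Generated by fcnet {__version__}.")
    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "connectivity": _stage_connectivity,
    "metrics": _stage_metrics,
    "hubs": _stage_hubs,
    "robustness": _stage_robustness,
    "nbs": _stage_nbs,
    "stats": _stage_stats,
}


def run_pipeline(
    config: PipelineConfig | dict, stages: Sequence[str] | None = None
) -> RunManifest:
    """Execute the requested stages in order and write ``manifest.json``.

    A stage failure is recorded in the manifest (with completed-stage
    outputs left in place) and re-raised.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_dict(config)
    logging.basicConfig(level=getattr(logging, cfg["log_level"], logging.INFO))
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    wanted = list(STAGES) if stages is None else list(stages)
    for s in wanted:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; stages: {STAGES}")
    manifest = RunManifest(cfg.hash(), __version__)
    for stage in wanted:
        started = time.time()
        log.info("stage %s", stage)
        try:
            if stage == "report":
                outputs = [write_report(outdir)]
            else:
                outputs = _STAGE_FUNCS[stage](cfg, outdir)
        except Exception as exc:
            manifest.record(stage, {"error": f"{type(exc).__name__}: {exc}"}, started)
            (outdir / "manifest.json").write_text(
                json.dumps(manifest.to_json(), indent=2)
            )
            log.error("stage %s failed: %s", stage, exc)
            raise
        manifest.record(stage, _digest_outputs(outdir, outputs), started)
    (outdir / "manifest.json").write_text(json.dumps(manifest.to_json(), indent=2))
    return manifest
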