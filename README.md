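# fcnet

Graph-theoretic and network-based-statistic analysis of resting-state
functional connectomes, built for studies that compare patient groups —
for example recovered-psychosis cohorts split into relapsed and maintained
subgroups against healthy controls — on the topology of their functional
brain networks.

`fcnet` is aimed at researchers who have per-subject ROI time series (any
parcellation; a 160-region, six-subnetwork atlas table is bundled) and want
a reproducible, fully scriptable version of the classic binary-graph
pipeline:

1. **Motion QC** — framewise displacement FD(t) = Σ|Δd| + r·Σ|Δθ|
   (translations in mm, rotations as arc length on an r = 50 mm sphere);
   volumes with FD > 0.5 mm are flagged and subjects with > 10 % flagged
   volumes are excluded (both inequalities strict).
2. **Functional connectivity** — the N×N Pearson correlation matrix per
   subject; *global FC strength* is the mean of all pairwise coefficients
   (raw, signed).
3. **Density thresholding** — |r| matrices binarized over a sparsity grid
   (default 0.06–0.37, step 0.01) keeping the top-k edges so every subject
   has the same edge count at each density.
4. **Graph metrics** — Cp, Lp, Eg, Eloc and normalized γ = Cp/⟨Cp_rand⟩,
   λ = Lp/⟨Lp_rand⟩, σ = γ/λ against degree-preserving rewired nulls; nodal
   Dc, Bc, Ne; each curve summarized as its trapezoidal AUC over the grid.
5. **Hubs** — nodes whose AUC-of-Dc is ≥ 1 SD above the node mean; hub
   counts per subnetwork and per-subject mean hub Dc for group comparison.
6. **Robustness** — targeted attack (nodes removed in decreasing-Dc order)
   and random failure (averaged random ablations); giant-connected-component
   trajectories, their AUC, the most-impacted density, and the
   disintegration point (windowed |ΔGCC| ratio ≥ 1.5).
7. **NBS** — edge-wise GLMs (edge FC ~ group + age + sex), suprathreshold
   connected components, and FWER-corrected component p-values from the
   permutation null of the maximum component size (Freedman–Lane).
8. **Group statistics** — t/ANCOVA with age and sex covariates, matching
   10,000-permutation p-values, BH-FDR and Bonferroni corrections, Spearman
   correlations with clinical scores, and cohort summaries including
   interval relapse rates.

A synthetic cohort generator (`fcnet.synthetic`) produces multi-subject
time series with known correlation structure — subnetwork communities,
planted hubs, a planted hyperconnected component in one group, group
offsets in global FC strength, and motion traces with controllable spikes —
so the entire pipeline is testable end to end without any scan data.

## Worked example

```python
import numpy as np
from fcnet import synthetic, connectivity, metrics, hubs, nbs

spec = synthetic.CohortSpec(
    n_per_group={"HC": 15, "RP": 15}, n_nodes=40, n_timepoints=140,
    planted_component=synthetic.PlantedComponent(
        edges=tuple((i, i + 1) for i in range(25, 31)), effect_r=0.2, group="RP"),
    seed=11,
)
records, meta = synthetic.generate_cohort(spec)
stack = np.stack([connectivity.pearson_fc(r.timeseries).values for r in records])

strength = [connectivity.global_fc_strength(s) for s in stack]
grp = meta["group"].to_numpy()
print(f"global FC strength  HC {np.mean(np.array(strength)[grp=='HC']):.3f}"
      f"  RP {np.mean(np.array(strength)[grp=='RP']):.3f}")

design = nbs.design_matrix(meta)                 # intercept + group + age + sex
result = nbs.nbs_test(stack, design, ("HC", "RP"),
                      nbs.NBSConfig(threshold=3.5, n_perm=1000), seed=0)
for c in result.components[:1]:
    print(f"largest component: {c.n_edges} edges between {c.n_nodes} nodes, "
          f"FWER p = {c.p_value:.4f}")
```

Output:

```
global FC strength  HC 0.216  RP 0.227
largest component: 6 edges between 7 nodes, FWER p = 0.0140
```

The RP group's mean FC strength is elevated (its configured group offset is
+0.017 over the healthy-control baseline of ≈ 0.22), and the NBS recovers
the planted 6-edge path as a family-wise-significant component: only
14 of 1000 permutation maxima matched or exceeded its size.

There is also a CLI over a YAML config
(`fcnet run-all --config run.yaml`, or individual stages `simulate`, `qc`,
`connectivity`, `metrics`, `hubs`, `robustness`, `nbs`, `stats`, `report`),
which writes every intermediate artifact as delimited text plus a run
manifest with config hash and output digests.

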