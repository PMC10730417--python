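# Methods

## The analysis model

`fcnet` analyzes binary brain graphs built from per-subject Pearson
functional-connectivity (FC) matrices. An N×N FC matrix is thresholded at
each density d in a sparsity grid by keeping the ⌊d·N(N−1)/2⌉ strongest
off-diagonal weights (by |r| by default), which guarantees every subject's
graph has the same edge count at a given density — the comparison is then
about topology, not overall connectivity level. Metrics are computed at
every density and summarized as the trapezoidal area under the
metric-versus-density curve (AUC), avoiding commitment to a single
threshold.

Global metrics: mean Watts–Strogatz clustering Cp, characteristic path
length Lp, global efficiency Eg, local efficiency Eloc, and the normalized
quantities γ = Cp/⟨Cp_rand⟩, λ = Lp/⟨Lp_rand⟩, σ = γ/λ (σ > 1 indicates
small-world organization). Nodal metrics: degree centrality Dc, betweenness
centrality Bc (Brandes, unnormalized), nodal efficiency Ne.

Hubs are nodes whose AUC-of-Dc is at least one standard deviation above
the mean over nodes (inclusive ≥). Robustness is assessed by removing
nodes one at a time — in decreasing order of initial Dc (targeted attack)
or uniformly at random, averaged over replicates (random failure) — and
integrating the size of the giant connected component (GCC) against the
number of nodes removed. The disintegration point is the first removal
step where the mean |ΔGCC| over the trailing window is ≥ 1.5× the mean over
the window before it.

The network-based statistic (NBS) fits an edge-wise linear model
(edge FC ~ group + age + sex), thresholds the group statistic, extracts
connected components of suprathreshold edges, and assigns each observed
component a family-wise-error-corrected p-value: the fraction of
permutations whose *maximum* component size reaches the observed size.

## Statistical machinery and its conventions

* **Permutation scheme.** Covariates are handled by Freedman–Lane: the
  reduced model (covariates only) is fitted once, its residuals are
  permuted across subjects and re-added to the reduced fit, and the
  full-model statistic is recomputed. This is the standard scheme for GLM
  permutation inference and is used both for the NBS and for scalar
  network measures. P-values use the add-one convention
  (p = (1 + #{null ≥ observed}) / (n_perm + 1)), so p is never exactly 0.
* **Sidedness.** Two-group NBS contrasts are directional (second group
  greater); omnibus comparisons across ≥ 3 groups use F. Raw signed edge
  values are analyzed by default; an absolute-value mode exists for
  sensitivity analysis.
* **Component size.** Extent (edge count) by default; intensity (summed
  suprathreshold statistic) behind a flag.
* **Parametric inference.** Scalar measures get a linear model
  value ~ group + age + sex (t for two groups, type-II ANCOVA F for
  three or more) alongside the permutation p, so both can be reported.
  Multiple-testing corrections: Benjamini–Hochberg FDR and Bonferroni.
* **Cluster-defining threshold.** When a threshold range is scanned, the
  median of the inclusive grid is used (e.g. median of 3.6…4.2 by 0.1 is
  3.9; of 7.0…7.8 is 7.4).

## Conventions where the field leaves choices open

* **Framewise displacement** is Power's sum of absolute backward
  differences of the six realignment parameters, with rotations converted
  to arc length at head radius 50 mm (configurable). FD of the first
  volume is 0, so the series has one entry per volume and flagged
  fractions use T as the denominator. Flagging (FD > 0.5 mm) and
  exclusion (> 10 % of volumes) are strict inequalities.
* **Edge-count rounding** at a density is round-half-away-from-zero of
  d·N(N−1)/2. Ties at the cutoff break by (|weight| desc, node pair
  lexicographic), a stable total order that makes edge sets nested across
  densities; real-valued correlations tie with probability zero but
  synthetic data can tie exactly.
* **Disconnected graphs.** Lp averages over reachable pairs only (an
  infinite Lp at the sparse end of the grid would destroy the AUC); the
  harmonic-mean view of disconnection is retained in Eg, where 1/∞ = 0.
  Clustering of degree-<2 nodes is 0 and stays in the mean.
* **Null models.** Degree-preserving Maslov–Sneppen rewiring with
  10·|E| swap attempts per null; 100 nulls per density by default
  (reduced in fast runs — γ/λ/σ then carry larger Monte-Carlo error of
  the null mean, which is noted in provenance). A complete graph has a
  unique degree realization, so its nulls are copies rather than an error.
  On very sparse graphs a rewired null can have zero triangles; the
  normalized metrics are then undefined at that density and recorded as
  NaN (their AUC is NaN as well).
* **Hub SD convention.** Sample SD (n−1) by default, population SD
  available. If all nodes tie, the hub set is empty (nothing is *above*
  the mean) — returning "all nodes are hubs" would be pathological.
  Group-level hub sets use the group-mean AUC-of-Dc vector by default;
  a per-subject basis (identify hubs per subject, average counts) is also
  provided since both appear in practice.
* **Attack order** is static initial-Dc order with ascending-index tie
  break; adaptive recomputation after each removal is behind a flag.
  "Greatest impact" threshold selection minimizes robustness AUC
  normalized by intact GCC size, ties to the smallest density; the
  largest-single-drop alternative can be derived from the stored
  trajectories. Random failure averages n_reps = 100 full random ablation
  sequences by default.
* **Targeted-vs-random dominance** (targeted damage ≥ random damage)
  holds for connected heterogeneous-degree graphs. It can invert on
  disconnected graphs: a targeted attack exhausts the current giant
  component while another component survives intact as a GCC floor,
  whereas random removals damage all components simultaneously.
* **Relapse rates.** The k-year denominator is the number of subjects
  followed at least k years (after excluding follow-up < 6 months), and
  the numerator counts relapses within k years among them. This is the
  only reading under which interval event counts may be non-monotone in k
  (subjects relapsing early but leaving follow-up before year k drop out
  of later denominators), and it reproduces the reference arithmetic
  9/27 = 33.33 %, 12/24 = 50.00 %, 9/21 = 42.86 % exactly.

## The synthetic cohort generator

The generator is a Gaussian latent-factor surrogate for ROI time series,
chosen because it yields closed-form expected correlations and therefore
calibratable tests. Node i's signal is a weighted sum of a global factor,
its subnetwork's community factor, optional per-edge factors (the planted
component), an optional extra global loading (planted hubs), and
independent noise completing the variance to 1. With unit variances the
population correlation of a pair is the sum of products of shared
loadings, so:

* within-community pairs have r = `base_within_r` + δ,
* between-community pairs r = `base_between_r` + δ,
* planted edges gain exactly `effect_r` on top,

where δ is the per-group offset of global FC strength.

Defaults emulate the study design the package targets: 160 nodes in six
subnetworks with the canonical 34/21/32/33/22/18 split (DMN, FPN, CON,
Sens, Occi, Cere), 140 volumes (150 acquired minus 10 discarded at a 2 s
TR), `base_within_r = 0.5`, `base_between_r = 0.16` — which puts
healthy-control global FC strength near 0.22 — and group offsets
HC 0, RP +0.017, RP-M −0.007, RP-R +0.067, matching the reported group
means of global FC strength relative to a 0.223 control baseline. Age and
sex are drawn from per-group moments taken from the cohort tables
(e.g. HC age 33.4 ± 10.0, 64 % female) and are exchangeable with FC by
default, so covariate adjustment is testable under the null; an
`age_fc_slope` knob adds an age→FC-strength confound when one is wanted.
Seeds are laddered — cohort seed → per-subject seeds via a (group index,
subject index) counter — so adding subjects or groups never perturbs
existing records.

What the generator does *not* emulate: BOLD hemodynamics and autocorrelated
scanner noise, spatial smoothness, preprocessing artifacts, distance-
dependent motion contamination, or the inter-subject variance components
of real cohorts. Passing tests therefore demonstrate that the estimators
and inference are correct and calibrated under the assumed correlation
structure, not that real data meet those assumptions. One visible
consequence: in synthetic cohorts the most-impacted attack threshold
tends to sit in the lower-middle of the density grid rather than at its
sparse end, because block-structured graphs at very low density consist
of tight communities whose GCC decays gradually under attack.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which the statistical properties are still sharply
testable: NBS FWER calibration uses 200 null cohorts of 20 nodes and
15 subjects/group at 500 permutations (empirical type-I error compared
with the binomial 99 % band around α = 0.05); NBS power uses a planted
10-edge path at +1.5 pooled-SD effect with 20 subjects/group and 1000
permutations; hub recovery uses 40-node cohorts with 4 planted hubs; the
synthetic study emulation in `scripts/acceptance.py` uses 60 nodes with
25/13/12 subjects per group. Graph-metric correctness is checked to 1e-9
against hand-written brute-force oracles (pure-Python BFS, triangle
counting, explicit shortest-path enumeration) on all fixture graphs of
≤ 12 nodes.

Degenerate inputs are errors, not silences: constant time-series columns
(undefined Pearson r), densities keeping zero or more-than-available
edges, empty FD series, empty hub sets where a mean is requested,
rank-deficient designs, and permutation counts too small to resolve the
requested α (a warning carried in the result).

## Known limitations

* Weighted-graph metrics, modularity/community detection, rich-club
  analysis, edge-removal attacks and percolation thresholds are out of
  scope.
* The NBS threshold-range endpoints are user inputs; only the median rule
  is built in.
* γ/λ/σ inherit Monte-Carlo noise from the null ensemble; at very sparse
  densities they can be undefined (NaN) on small graphs.
* The ANCOVA uses type-II sums of squares by default (configurable);
  with the balanced synthetic designs type II and III coincide.
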