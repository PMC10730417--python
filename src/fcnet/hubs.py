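"""Hub identification from AUC-of-degree-centrality.

A node is a hub when its AUC of degree centrality over the density grid is
at least ``sd_multiplier`` standard deviations above the mean across nodes
(inclusive ">=", one SD by default).  The SD uses the sample convention
(n-1 denominator) by default; pass ``ddof=0`` for the population SD.  When
every node has the same value the hub set is empty (nothing is *above* the
mean) and a warning is issued.

Hub sets can be computed from a group-mean AUC-of-Dc vector (the default
basis for group comparisons) or per subject; both helpers are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HubSet",
    "identify_hubs",
    "hub_subnetwork_counts",
    "mean_hub_dc",
    "group_mean_hub_sets",
    "per_subject_hub_counts",
]


@dataclass
class HubSet:
    hub_nodes: np.ndarray
    threshold_value: float
    basis: str = ""
    subnetwork_counts: dict[str, int] | None = None

    def __len__(self) -> int:
        return int(self.hub_nodes.size)


def identify_hubs(
    auc_dc: Sequence[float],
    sd_multiplier: float = 1.0,
    ddof: int = 1,
    basis: str = "group-mean",
) -> HubSet:
    """Nodes with AUC-of-Dc >= mean + sd_multiplier * SD."""
    x = np.asarray(auc_dc, dtype=float)
    if x.size < 2:
        raise ValueError("hub identification needs at least 2 nodes")
    if not np.isfinite(x).all():
        raise ValueError("AUC-of-Dc values must be finite")
    mean = x.mean()
    sd = x.std(ddof=ddof)
    if sd == 0:
        warnings.warn(
            "all AUC-of-Dc values are equal; no node is above the mean, "
            "returning an empty hub set",
            stacklevel=2,
        )
        return HubSet(np.array([], dtype=int), float(mean), basis)
    cutoff = mean + sd_multiplier * sd
    hubs = np.flatnonzero(x >= cutoff)
    return HubSet(hubs, float(cutoff), basis)


def _labels_array(atlas) -> np.ndarray:
    if isinstance(atlas, pd.DataFrame):
        return atlas["subnetwork"].to_numpy()
    return np.asarray(atlas)


def hub_subnetwork_counts(
    hubs: HubSet,
    atlas,
    label_set: Sequence[str] | None = None,
) -> dict[str, int]:
    """Count hubs per subnetwork; zero-count labels are included.

    ``atlas`` is a node->subnetwork label sequence or an atlas table.
    """
    labels = _labels_array(atlas)
    if label_set is None:
        label_set = list(dict.fromkeys(labels))
    counts = {lab: 0 for lab in label_set}
    for node in hubs.hub_nodes:
        if node >= labels.shape[0]:
            raise ValueError(f"hub node {int(node)} has no atlas label")
        lab = labels[node]
        if not isinstance(lab, str) or lab not in counts:
            raise ValueError(
                f"hub node {int(node)} carries unknown subnetwork label {lab!r}"
            )
        counts[lab] += 1
    hubs.subnetwork_counts = counts
    return counts


def mean_hub_dc(subject_auc_dc: Sequence[float], hubs: HubSet) -> float:
    """A subject's mean AUC-of-Dc restricted to the hub nodes."""
    if len(hubs) == 0:
        raise ValueError("hub set is empty")
    x = np.asarray(subject_auc_dc, dtype=float)
    return float(x[hubs.hub_nodes].mean())


def group_mean_hub_sets(
    auc_dc_by_subject: np.ndarray,
    groups: Sequence[str],
    sd_multiplier: float = 1.0,
    ddof: int = 1,
) -> dict[str, HubSet]:
    """One hub set per group from the group-mean AUC-of-Dc vector.

    ``auc_dc_by_subject`` is (n_subjects, n_nodes) aligned with ``groups``.
    """
    x = np.asarray(auc_dc_by_subject, dtype=float)
    groups = np.asarray(groups)
    out: dict[str, HubSet] = {}
    for g in dict.fromkeys(groups.tolist()):
        mean_vec = x[groups == g].mean(axis=0)
        out[g] = identify_hubs(
            mean_vec, sd_multiplier=sd_multiplier, ddof=ddof, basis=f"group-mean:{g}"
        )
    return out


def per_subject_hub_counts(
    auc_dc_by_subject: np.ndarray,
    groups: Sequence[str],
    atlas,
    sd_multiplier: float = 1.0,
    ddof: int = 1,
    label_set: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Alternative basis: hubs per subject, then mean counts per group.

    Returns a tidy table (group, subnetwork, n_hubs) where ``n_hubs`` is
    the group mean of per-subject counts.
    """
    labels = _labels_array(atlas)
    if label_set is None:
        label_set = list(dict.fromkeys(labels))
    x = np.asarray(auc_dc_by_subject, dtype=float)
    rows = []
    for vec, g in zip(x, groups):
        hs = identify_hubs(vec, sd_multiplier=sd_multiplier, ddof=ddof, basis="subject")
        counts = hub_subnetwork_counts(hs, labels, label_set=label_set)
        rows.append({"group": g, **counts})
    wide = pd.DataFrame(rows).groupby("group", sort=False).mean()
    tidy = (
        wide.reset_index()
        .melt(id_vars="group", var_name="subnetwork", value_name="n_hubs")
        .sort_values(["group", "subnetwork"], kind="stable")
        .reset_index(drop=True)
    )
    return tidy
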