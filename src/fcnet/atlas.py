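"""Node tables: region ids, coordinates and subnetwork labels.

The default table emulates a 160-region meta-analytic parcellation grouped
into six functional subnetworks: default mode (DMN), fronto-parietal (FPN),
cingulo-opercular (CON), sensorimotor (Sens), occipital (Occi) and
cerebellum (Cere).  The per-subnetwork region counts follow the published
160-region split (34/21/32/33/22/18); smaller tables for fast tests are
apportioned proportionally.  Coordinates are synthetic MNI-like positions
used only for table plumbing and plotting, never for analysis.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

#: Canonical subnetwork labels, in reporting order.
SUBNETWORKS: tuple[str, ...] = ("DMN", "FPN", "CON", "Sens", "Occi", "Cere")

#: Region counts of the 160-node six-network parcellation.
_SUBNETWORK_SIZES: dict[str, int] = {
    "DMN": 34,
    "FPN": 21,
    "CON": 32,
    "Sens": 33,
    "Occi": 22,
    "Cere": 18,
}

ATLAS_COLUMNS: tuple[str, ...] = ("id", "name", "x", "y", "z", "subnetwork")


def subnetwork_sizes(n_nodes: int) -> dict[str, int]:
    """Apportion ``n_nodes`` over the six subnetworks (largest remainder).

    For ``n_nodes == 160`` this reproduces the canonical 34/21/32/33/22/18
    split exactly.  Every subnetwork receives at least one node when
    ``n_nodes >= 6``.
    """
    if n_nodes < len(SUBNETWORKS):
        raise ValueError(
            f"n_nodes={n_nodes} is smaller than the number of subnetworks "
            f"({len(SUBNETWORKS)})"
        )
    total = sum(_SUBNETWORK_SIZES.values())
    quotas = {k: v * n_nodes / total for k, v in _SUBNETWORK_SIZES.items()}
    sizes = {k: int(np.floor(q)) for k, q in quotas.items()}
    remainder = n_nodes - sum(sizes.values())
    order = sorted(SUBNETWORKS, key=lambda k: quotas[k] - sizes[k], reverse=True)
    for k in order[:remainder]:
        sizes[k] += 1
    for k in SUBNETWORKS:  # guarantee non-empty subnetworks
        if sizes[k] == 0:
            donor = max(SUBNETWORKS, key=lambda d: sizes[d])
            sizes[donor] -= 1
            sizes[k] = 1
    return {k: sizes[k] for k in SUBNETWORKS}


def default_partition(n_nodes: int = 160) -> np.ndarray:
    """Node -> subnetwork label array (contiguous blocks, canonical order)."""
    sizes = subnetwork_sizes(n_nodes)
    return np.array([lab for lab in SUBNETWORKS for _ in range(sizes[lab])])


def make_atlas(n_nodes: int = 160, seed: int = 2023) -> pd.DataFrame:
    """Build a synthetic atlas table (id, name, x, y, z, subnetwork).

    Deterministic for a given seed; coordinates are drawn in MNI-like
    ranges purely as placeholders.
    """
    labels = default_partition(n_nodes)
    rng = np.random.default_rng(seed)
    xyz = np.column_stack(
        [
            rng.uniform(-70, 70, n_nodes),
            rng.uniform(-100, 70, n_nodes),
            rng.uniform(-50, 80, n_nodes),
        ]
    ).round(1)
    within = pd.Series(labels).groupby(labels).cumcount() + 1
    names = [f"{lab}_{k:02d}" for lab, k in zip(labels, within)]
    return pd.DataFrame(
        {
            "id": np.arange(n_nodes),
            "name": names,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "subnetwork": labels,
        }
    )


def write_atlas(atlas: pd.DataFrame, path) -> None:
    atlas.to_csv(path, sep="\t", index=False)


def read_atlas(path, allowed_labels: Sequence[str] = SUBNETWORKS) -> pd.DataFrame:
    """Read and validate a delimited atlas table.

    Raises ``ValueError`` (naming the offending row) for missing columns,
    duplicate node ids, or subnetwork labels outside ``allowed_labels``.
    """
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"atlas file {path} is empty") from exc
    missing = [c for c in ATLAS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"atlas file {path} is missing columns {missing}")
    if table.empty:
        raise ValueError(f"atlas file {path} has no rows")
    dup = table["id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"duplicate node id {table['id'].iloc[row]!r} at row {row + 2} of {path}"
        )
    allowed = set(allowed_labels)
    bad = ~table["subnetwork"].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown subnetwork label {table['subnetwork'].iloc[row]!r} "
            f"at row {row + 2} of {path}; allowed: {sorted(allowed)}"
        )
    return table.reset_index(drop=True)
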