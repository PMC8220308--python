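"""Presence-absence patterns (PAPs) and deterministic matrix ordering.

A PAP is a boolean families x taxa (or families x groups) matrix.  Two
orderings reproduce the figure conventions of phylogenetic-profile
heat maps: rows sorted by their distribution over the six eukaryotic
supergroups, and leaf orders from average-linkage hierarchical
clustering on Jaccard (boolean) or Euclidean (count) distances with a
fully deterministic tie rule, so shuffled inputs give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .clustering import FamilyCluster
from .data_model import SUPERGROUPS, TaxonRegistry

OTHER_ARCHAEA = "Other Archaea"


@dataclass
class PAPMatrix:
    """Boolean presence matrix with explicit row/column orders."""

    data: pd.DataFrame  # bool, rows = family/EPC keys, columns = taxa/groups
    row_order: list[str] = field(default_factory=list)
    column_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("PAP row/column keys must be unique")
        if not self.row_order:
            self.row_order = list(self.data.index)
        if not self.column_order:
            self.column_order = list(self.data.columns)

    def ordered(self) -> pd.DataFrame:
        return self.data.loc[self.row_order, self.column_order]


def build_pap(
    clusters: Sequence[FamilyCluster],
    registry: TaxonRegistry,
    column_mode: str = "taxon",
    min_group_members: int = 15,
) -> PAPMatrix:
    """Presence matrix of clusters over taxa or group labels.

    In group mode archaeal groups with fewer than ``min_group_members``
    registry taxa are pooled into the "Other Archaea" column.
    """
    if column_mode not in ("taxon", "group"):
        raise ValueError("column_mode must be 'taxon' or 'group'")

    if column_mode == "taxon":
        column_of = {t.taxon_id: t.taxon_id for t in registry}
    else:
        arch_sizes = registry.group_sizes("archaea")
        column_of = {}
        for t in registry:
            if t.domain == "archaea" and arch_sizes[t.group] < min_group_members:
                column_of[t.taxon_id] = OTHER_ARCHAEA
            else:
                column_of[t.taxon_id] = t.group
    columns = sorted(set(column_of.values()))
    rows = []
    index = []
    for cluster in clusters:
        if cluster.cluster_id in index:
            raise ValueError(f"duplicate cluster id {cluster.cluster_id!r}")
        present = set()
        for taxon_id in cluster.taxa:
            if taxon_id not in registry:
                raise KeyError(f"member taxon {taxon_id!r} missing from registry")
            present.add(column_of[taxon_id])
        rows.append([c in present for c in columns])
        index.append(cluster.cluster_id)
    data = pd.DataFrame(rows, index=index, columns=columns, dtype=bool)
    return PAPMatrix(data)


def sort_rows_by_supergroup_pattern(
    pap: PAPMatrix, supergroup_columns: Sequence[str] = SUPERGROUPS
) -> list[str]:
    """Rows ordered by their eukaryotic supergroup distribution.

    Key: number of supergroups present (descending), then the 6-bit
    presence pattern read as a binary number (descending), then the row
    key (ascending).
    """
    missing = [c for c in supergroup_columns if c not in pap.data.columns]
    if missing:
        raise KeyError(f"supergroup columns absent from PAP: {missing}")
    sub = pap.data[list(supergroup_columns)].to_numpy(dtype=bool)
    weights = 2 ** np.arange(len(supergroup_columns) - 1, -1, -1)
    counts = sub.sum(axis=1)
    patterns = sub @ weights
    order = sorted(
        range(len(pap.data)),
        key=lambda i: (-counts[i], -patterns[i], pap.data.index[i]),
    )
    return [pap.data.index[i] for i in order]


def hierarchical_order(
    matrix: pd.DataFrame,
    axis: str = "columns",
    method: str = "average",
    metric: str = "jaccard",
) -> list[str]:
    """Dendrogram leaf order for one axis of a profile matrix.

    Average linkage on Jaccard (boolean) or Euclidean (count) distances.
    The input is canonicalised by key sort before linkage, and at each
    merge the subtree containing the lexicographically smallest key goes
    left, so the order is invariant to input shuffling.  Identical
    vectors sit at distance 0 and end up adjacent.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    frame = matrix if axis == "rows" else matrix.T
    if frame.shape[0] == 0:
        raise ValueError("cannot order an empty axis")
    frame = frame.sort_index()
    keys = list(frame.index)
    if len(keys) == 1:
        return keys
    values = frame.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        distances = pdist(values, metric=metric)
    distances = np.nan_to_num(distances, nan=0.0)  # jaccard of two zero rows
    tree = linkage(distances, method=method)

    n = len(keys)
    min_key: dict[int, str] = {i: keys[i] for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for step, (left, right, _, _) in enumerate(tree):
        node = n + step
        left, right = int(left), int(right)
        children[node] = (left, right)
        min_key[node] = min(min_key[left], min_key[right])

    order: list[str] = []

    def visit(node: int) -> None:
        if node < n:
            order.append(keys[node])
            return
        left, right = children[node]
        if min_key[left] <= min_key[right]:
            visit(left)
            visit(right)
        else:
            visit(right)
            visit(left)

    visit(n + len(tree) - 1)
    return order


def write_pap_tsv(pap: PAPMatrix, path) -> None:
    pap.ordered().astype(int).to_csv(path, sep="\t")


def save_heatmap(pap: PAPMatrix, path) -> None:
    """Thin optional raster export of the ordered matrix (requires
    matplotlib); all ordering logic lives in the functions above."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(pap.ordered().to_numpy(dtype=float), aspect="auto", cmap="Greys")
    ax.set_xlabel("taxa / groups")
    ax.set_ylabel("families")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
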