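"""Protein family construction: RBH similarity graphs and Markov Clustering.

Families are found by running MCL on an undirected graph whose nodes are
proteins, whose edges are reciprocal best hits (RBH), and whose edge
weights are global percent identities (0-100].  MCL alternates
*expansion* (squaring the column-stochastic flow matrix) with
*inflation* (entrywise powering and renormalisation) until the flow
stabilises; dense flow regions become clusters.

Proteins with no RBH never enter the graph and are reported separately
as unclustered rather than as singleton families.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import ProteinRecord, TaxonRegistry, taxon_of
from .search import PairwiseIndex, SearchThresholds, best_hits, reciprocal_best_hits

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FamilyCluster:
    """A protein family: a content-addressed id plus its member ids."""

    cluster_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a FamilyCluster must have at least one member")

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(taxon_of(pid) for pid in self.members)

    def cells(self, registry: TaxonRegistry) -> frozenset[tuple[str, str]]:
        """(domain, group) combinations represented among the members."""
        return frozenset(
            (registry[t].domain, registry[t].group) for t in self.taxa
        )


def make_cluster(members: Iterable[str]) -> FamilyCluster:
    """Build a cluster with a content-addressed id (stable across runs)."""
    member_set = frozenset(members)
    digest = hashlib.sha1("\n".join(sorted(member_set)).encode()).hexdigest()[:12]
    return FamilyCluster(f"fam-{digest}", member_set)


@dataclass(frozen=True)
class MclParams:
    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if not self.inflation > 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion power must be an integer >= 2")
        if self.prune_threshold < 0 or self.tolerance <= 0 or self.max_iterations < 1:
            raise ValueError("invalid MCL parameters")


class MclConvergenceWarning(UserWarning):
    pass


def build_similarity_graph(
    rbh_pairs: Iterable[tuple[str, str]], hit_table: pd.DataFrame
) -> nx.Graph:
    """Weight each RBH pair by 100x its global identity.

    The hit table must contain the pair in at least one direction.
    Isolated proteins are not nodes; duplicate pairs are idempotent.
    """
    identity: dict[tuple[str, str], float] = {}
    for q, s, ident in zip(
        hit_table["query_id"], hit_table["subject_id"], hit_table["global_identity"]
    ):
        identity[(q, s) if q <= s else (s, q)] = float(ident)
    graph = nx.Graph()
    for a, b in rbh_pairs:
        key = (a, b) if a <= b else (b, a)
        if key not in identity:
            raise KeyError(f"RBH pair {key} has no identity in the hit table")
        graph.add_edge(a, b, weight=100.0 * identity[key])
    return graph


def mcl_cluster(graph: nx.Graph, params: MclParams = MclParams()) -> list[FamilyCluster]:
    """Markov Clustering of a weighted similarity graph.

    Self-loops are added with weight equal to the node's maximum incident
    edge weight (standard regularisation against bipartite oscillation),
    columns are normalised to a stochastic flow matrix, and expansion /
    inflation iterate until the flow changes by less than the tolerance.
    Clusters are attractor systems (rows keeping positive diagonal mass)
    plus the nodes they attract; a node attracted by several systems goes
    to the one receiving the most flow, ties to the system with the
    lexicographically smallest attractor id.  Every node lands in exactly
    one cluster.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}

    matrix = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data["weight"])
        matrix[idx[a], idx[b]] = w
        matrix[idx[b], idx[a]] = w
    max_incident = matrix.max(axis=0)
    np.fill_diagonal(matrix, np.where(max_incident > 0, max_incident, 1.0))
    matrix /= matrix.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(params.max_iterations):
        expanded = np.linalg.matrix_power(matrix, params.expansion)
        inflated = expanded**params.inflation
        inflated[inflated < params.prune_threshold] = 0.0
        sums = inflated.sum(axis=0, keepdims=True)
        # A column zeroed by pruning regains self flow (cannot happen at
        # sane prune thresholds; guard keeps the matrix stochastic).
        dead = sums[0] == 0
        if dead.any():
            inflated[dead, dead] = 1.0
            sums = inflated.sum(axis=0, keepdims=True)
        inflated /= sums
        change = np.abs(inflated - matrix).max()
        matrix = inflated
        if change < params.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {params.max_iterations} iterations; "
            "reading clusters from the final matrix",
            MclConvergenceWarning,
        )
        logger.warning("MCL non-convergence after %d iterations", params.max_iterations)

    attractors = [i for i in range(n) if matrix[i, i] > 0]
    if not attractors:  # degenerate; treat every node as its own attractor
        attractors = list(range(n))

    # Union attractors into systems: i and k belong together when either
    # attracts the other (positive flow in the attractor rows).
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, k: int) -> None:
        ri, rk = find(i), find(k)
        if ri != rk:
            parent[rk] = ri

    attractor_set = set(attractors)
    for i in attractors:
        for k in np.nonzero(matrix[i])[0]:
            if k in attractor_set:
                union(i, int(k))

    systems: dict[int, list[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), []).append(i)
    # Deterministic system key: lexicographically smallest attractor node id.
    system_key = {
        root: min(nodes[i] for i in members) for root, members in systems.items()
    }

    assignment: dict[int, int] = {}
    for j in range(n):
        flows: dict[int, float] = {}
        for root, members in systems.items():
            mass = float(sum(matrix[i, j] for i in members))
            if mass > 0:
                flows[root] = mass
        if not flows:
            continue  # handled below as a singleton
        top_mass = max(flows.values())
        contenders = [root for root, mass in flows.items() if mass == top_mass]
        assignment[j] = min(contenders, key=lambda root: system_key[root])

    clusters: dict[int, set[str]] = {}
    for j, root in assignment.items():
        clusters.setdefault(root, set()).add(nodes[j])
    result = [make_cluster(members) for members in clusters.values()]
    for j in range(n):
        if j not in assignment:
            result.append(make_cluster([nodes[j]]))
    result.sort(key=lambda c: min(c.members))
    return result


def unclustered_proteins(
    records: Sequence[ProteinRecord], clusters: Sequence[FamilyCluster]
) -> list[str]:
    """Proteins that ended up in no cluster (no RBH partner)."""
    clustered = set().union(*(c.members for c in clusters)) if clusters else set()
    return sorted(r.protein_id for r in records if r.protein_id not in clustered)


def rbh_graph(
    records: Sequence[ProteinRecord],
    thresholds: SearchThresholds,
    index: PairwiseIndex | None = None,
) -> nx.Graph:
    """Reciprocal-best-hit similarity graph over a pool of proteomes.

    Best hits are computed per ordered proteome pair (the classic RBH
    orthology construction): a protein can hold one RBH partner in every
    other proteome, so a family shared by many taxa becomes a densely
    connected subgraph.  Proteins of the same taxon are never linked.
    """
    if index is None:
        index = PairwiseIndex(records)
    by_taxon: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        by_taxon.setdefault(rec.taxon_id, []).append(rec)
    taxa = sorted(by_taxon)
    graph = nx.Graph()
    for i, tx in enumerate(taxa):
        for ty in taxa[i + 1 :]:
            fwd = best_hits(by_taxon[tx], by_taxon[ty], thresholds, index)
            rev = best_hits(by_taxon[ty], by_taxon[tx], thresholds, index)
            pairs = reciprocal_best_hits(fwd, rev)
            table = pd.concat([fwd, rev], ignore_index=True) if len(fwd) or len(rev) else fwd
            identity = {}
            for q, s, ident in zip(table["query_id"], table["subject_id"], table["global_identity"]):
                identity[(q, s) if q <= s else (s, q)] = float(ident)
            for a, b in pairs:
                graph.add_edge(a, b, weight=100.0 * identity[(a, b) if a <= b else (b, a)])
    return graph


def cluster_proteins(
    records: Sequence[ProteinRecord],
    thresholds: SearchThresholds,
    params: MclParams = MclParams(),
    index: PairwiseIndex | None = None,
) -> list[FamilyCluster]:
    """Per-proteome-pair RBH -> similarity graph -> MCL for one pool."""
    graph = rbh_graph(records, thresholds, index)
    return mcl_cluster(graph, params)


def cluster_within_group(
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    thresholds: SearchThresholds,
    params: MclParams = MclParams(),
    index: PairwiseIndex | None = None,
) -> tuple[list[FamilyCluster], pd.DataFrame]:
    """Cluster the pooled proteomes of a taxon subset (>= 2 taxa).

    Returns the clusters plus a per-taxon presence count table
    (cluster_id x taxon_id -> member count), the inventory used for
    within-group family distribution figures.
    """
    if len(proteomes) < 2:
        raise ValueError("within-group clustering needs at least 2 taxa")
    pooled = [rec for records in proteomes.values() for rec in records]
    clusters = cluster_proteins(pooled, thresholds, params, index)
    taxa = sorted(proteomes)
    counts = pd.DataFrame(
        0, index=[c.cluster_id for c in clusters], columns=taxa, dtype=int
    )
    for cluster in clusters:
        for pid in cluster.members:
            counts.loc[cluster.cluster_id, taxon_of(pid)] += 1
    counts.index.name = "cluster_id"
    return clusters, counts


# ---------------------------------------------------------------------------
# ABC graph interchange (node node weight), the format the original MCL
# binary consumes.


def write_abc(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted((min(e), max(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\t{graph[a][b]['weight']:g}\n")


def read_abc(path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'node node weight'")
            a, b, w = parts
            graph.add_edge(a, b, weight=float(w))
    return graph
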