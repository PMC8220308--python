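"""Eukaryote-prokaryote cluster (EPC) integration and contribution stats.

Eukaryotic families are merged with prokaryotic ones by the *reciprocal
best cluster* (RBC) rule: a eukaryotic cluster E and a prokaryotic
cluster P merge when at least 50% of E's members have their best
cross-set hit in P and vice versa (inclusive at exactly 50%; members
without a passing hit abstain but stay in the denominator).  Because
bacterial and archaeal families are clustered separately, a eukaryotic
cluster can link to an archaeal cluster, a bacterial one, or both,
giving the EPC categories EA, EB and EAB.

The LECA filter keeps eukaryotic families with members in all six
supergroups; the asgard-unique subset of EA EPCs is the quantity of
interest: EA EPCs whose archaeal partner contains asgard taxa only.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clustering import FamilyCluster
from .data_model import ASGARD_GROUP, SUPERGROUPS, TaxonRegistry

logger = logging.getLogger(__name__)

EPC_CATEGORIES = ("EA", "EB", "EAB")


@dataclass(frozen=True)
class ClusterLinkVote:
    """Fraction of a source cluster best-hitting into one target cluster."""

    source: str
    target: str
    support: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.support <= 1.0:
            raise ValueError("support must be a fraction in [0,1]")


@dataclass(frozen=True)
class MergedLink:
    euk_cluster: str
    prok_cluster: str
    euk_support: float
    prok_support: float


@dataclass(frozen=True)
class EPC:
    epc_id: str
    euk_cluster: str
    arch_cluster: str | None
    bact_cluster: str | None
    category: str
    arch_supports: tuple[float, float] | None = None
    bact_supports: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        has_arch = self.arch_cluster is not None
        has_bact = self.bact_cluster is not None
        if not (has_arch or has_bact):
            raise ValueError("an EPC needs an archaeal or bacterial partner")
        expected = {(True, False): "EA", (False, True): "EB", (True, True): "EAB"}[
            (has_arch, has_bact)
        ]
        if self.category != expected:
            raise ValueError(
                f"category {self.category!r} inconsistent with partners "
                f"(expected {expected!r})"
            )


def best_cluster_votes(
    source_clusters: Sequence[FamilyCluster],
    target_clusters: Sequence[FamilyCluster],
    cross_hit_table: pd.DataFrame,
) -> list[ClusterLinkVote]:
    """Per (source, target) cluster pair, the fraction of source members
    whose best cross-set hit lands in that target cluster.

    ``cross_hit_table`` is a best-hit table (one row per source protein).
    Best hits pointing at proteins outside every target cluster count as
    abstentions, as do members without any row.
    """
    target_of: dict[str, str] = {}
    for cluster in target_clusters:
        for pid in cluster.members:
            target_of[pid] = cluster.cluster_id
    best = dict(zip(cross_hit_table["query_id"], cross_hit_table["subject_id"]))

    votes: list[ClusterLinkVote] = []
    for cluster in source_clusters:
        tally: dict[str, int] = {}
        for pid in cluster.members:
            subject = best.get(pid)
            if subject is None:
                continue
            target = target_of.get(subject)
            if target is None:
                continue  # best hit is unclustered -> abstention
            tally[target] = tally.get(target, 0) + 1
        total = len(cluster.members)
        for target, count in sorted(tally.items()):
            votes.append(ClusterLinkVote(cluster.cluster_id, target, count / total))
    return votes


def candidate_links(votes: Iterable[ClusterLinkVote]) -> dict[str, ClusterLinkVote]:
    """Maximum-support target per source; ties yield no candidate."""
    by_source: dict[str, list[ClusterLinkVote]] = {}
    for vote in votes:
        by_source.setdefault(vote.source, []).append(vote)
    candidates: dict[str, ClusterLinkVote] = {}
    for source, source_votes in by_source.items():
        top = max(v.support for v in source_votes)
        winners = [v for v in source_votes if v.support == top]
        if len(winners) > 1:
            logger.info(
                "cluster %s: tie between %d equally supported targets; no link",
                source,
                len(winners),
            )
            continue
        candidates[source] = winners[0]
    return candidates


def reciprocal_best_cluster_merge(
    votes_fwd: Iterable[ClusterLinkVote],
    votes_rev: Iterable[ClusterLinkVote],
    min_support: float = 0.5,
) -> list[MergedLink]:
    """Accept (E, P) links that are mutual candidates with support >=
    ``min_support`` in both directions ("at least 50%" is inclusive)."""
    fwd = candidate_links(votes_fwd)
    rev = candidate_links(votes_rev)
    links: list[MergedLink] = []
    for source, vote in sorted(fwd.items()):
        if vote.support < min_support:
            continue
        back = rev.get(vote.target)
        if back is None or back.target != source or back.support < min_support:
            continue
        links.append(MergedLink(source, vote.target, vote.support, back.support))
    return links


def assemble_epcs(
    euk_clusters: Sequence[FamilyCluster],
    arch_links: Sequence[MergedLink],
    bact_links: Sequence[MergedLink],
) -> list[EPC]:
    """One EPC per eukaryotic cluster holding at least one accepted link."""
    arch_by_euk = {link.euk_cluster: link for link in arch_links}
    bact_by_euk = {link.euk_cluster: link for link in bact_links}
    epcs: list[EPC] = []
    for cluster in sorted(euk_clusters, key=lambda c: c.cluster_id):
        arch = arch_by_euk.get(cluster.cluster_id)
        bact = bact_by_euk.get(cluster.cluster_id)
        if arch is None and bact is None:
            continue
        category = "EAB" if (arch and bact) else ("EA" if arch else "EB")
        digest = hashlib.sha1(cluster.cluster_id.encode()).hexdigest()[:12]
        epcs.append(
            EPC(
                epc_id=f"epc-{digest}",
                euk_cluster=cluster.cluster_id,
                arch_cluster=arch.prok_cluster if arch else None,
                bact_cluster=bact.prok_cluster if bact else None,
                category=category,
                arch_supports=(arch.euk_support, arch.prok_support) if arch else None,
                bact_supports=(bact.euk_support, bact.prok_support) if bact else None,
            )
        )
    return epcs


def summarize_epcs(epcs_or_counts: Sequence[EPC] | Mapping[str, int]) -> dict:
    """EA/EB/EAB counts plus the share of EPCs with an archaeal component.

    Accepts either assembled EPCs or a pre-counted {"EA": n, ...} mapping
    (useful for arithmetic on published counts).  ``pct_with_archaea`` is
    reported to one decimal, half-up; ``None`` when there are no EPCs.
    """
    if isinstance(epcs_or_counts, Mapping):
        counts = {cat: int(epcs_or_counts.get(cat, 0)) for cat in EPC_CATEGORIES}
    else:
        counts = {cat: 0 for cat in EPC_CATEGORIES}
        for epc in epcs_or_counts:
            counts[epc.category] += 1
    total = sum(counts.values())
    with_archaea = counts["EA"] + counts["EAB"]
    if total == 0:
        logger.warning("summarize_epcs: zero EPCs; percentage undefined")
        pct = None
    else:
        pct = _round_half_up(100.0 * with_archaea / total, 1)
    return {
        "EA": counts["EA"],
        "EB": counts["EB"],
        "EAB": counts["EAB"],
        "total": total,
        "with_archaea": with_archaea,
        "pct_with_archaea": pct,
    }


def filter_leca(
    euk_clusters: Sequence[FamilyCluster],
    registry: TaxonRegistry,
    required_groups: Sequence[str] = SUPERGROUPS,
) -> list[FamilyCluster]:
    """Keep clusters whose eukaryotic members span every required supergroup."""
    required = set(required_groups)
    present_overall = registry.supergroups_present()
    if not required <= present_overall:
        warnings.warn(
            "registry does not cover all required supergroups "
            f"({sorted(required - present_overall)} missing); "
            "the LECA filter can only return an empty set",
            UserWarning,
        )
    kept = []
    for cluster in euk_clusters:
        groups = {
            registry[t].group
            for t in cluster.taxa
            if registry[t].domain == "eukaryote"
        }
        if required <= groups:
            kept.append(cluster)
    return kept


def asgard_unique_ea(
    epcs: Sequence[EPC],
    prok_clusters: Mapping[str, FamilyCluster] | Sequence[FamilyCluster],
    registry: TaxonRegistry,
) -> list[EPC]:
    """EA-category EPCs whose archaeal partner contains asgard taxa only."""
    if not isinstance(prok_clusters, Mapping):
        prok_clusters = {c.cluster_id: c for c in prok_clusters}
    unique: list[EPC] = []
    for epc in epcs:
        if epc.category != "EA":
            continue
        arch = prok_clusters[epc.arch_cluster]
        groups = {registry[t].group for t in arch.taxa}
        if groups == {ASGARD_GROUP}:
            unique.append(epc)
    return unique


def contribution_percent(n_unique: int, n_reference: int, decimals: int) -> float:
    """100 * n_unique / n_reference, rounded half-up to ``decimals``."""
    if n_reference <= 0:
        raise ValueError("n_reference must be positive")
    if not 0 <= n_unique <= n_reference:
        raise ValueError("n_unique must satisfy 0 <= n_unique <= n_reference")
    return _round_half_up(100.0 * n_unique / n_reference, decimals)


def _round_half_up(value: float, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def epc_table(epcs: Sequence[EPC]) -> pd.DataFrame:
    rows = []
    for epc in epcs:
        rows.append(
            {
                "epc_id": epc.epc_id,
                "euk_cluster": epc.euk_cluster,
                "arch_cluster": epc.arch_cluster or "",
                "bact_cluster": epc.bact_cluster or "",
                "category": epc.category,
                "euk_arch_support": epc.arch_supports[0] if epc.arch_supports else "",
                "arch_support": epc.arch_supports[1] if epc.arch_supports else "",
                "euk_bact_support": epc.bact_supports[0] if epc.bact_supports else "",
                "bact_support": epc.bact_supports[1] if epc.bact_supports else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "epc_id",
            "euk_cluster",
            "arch_cluster",
            "bact_cluster",
            "category",
            "euk_arch_support",
            "arch_support",
            "euk_bact_support",
            "bact_support",
        ],
    )
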