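"""End-to-end pipeline: inputs -> families -> EPCs -> statistics.

Stage order follows the analysis: (generate or load proteomes) ->
all-vs-all search -> reciprocal best hits -> MCL per domain (bacteria
and archaea clustered separately; eukaryotes with the same method) ->
cross-domain best hits -> reciprocal-best-cluster merge (eukaryote vs
archaea and vs bacteria) -> EPC assembly and summary -> LECA filter ->
asgard-unique contribution -> hit-category profiles and length
statistics -> presence-absence matrices.

Every numeric knob lives in :class:`PipelineConfig`; a fixed seed gives
a bit-identical result bundle.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .clustering import (
    FamilyCluster,
    MclParams,
    cluster_proteins,
    unclustered_proteins,
)
from .data_model import (
    SUPERGROUPS,
    ProteinRecord,
    TaxonRegistry,
    ValidationError,
    read_proteome_dir,
    read_taxon_table,
    taxon_of,
    write_clusters_tsv,
    write_fasta,
    write_taxon_table,
)
from .epc import (
    EPC,
    asgard_unique_ea,
    assemble_epcs,
    best_cluster_votes,
    contribution_percent,
    epc_table,
    filter_leca,
    reciprocal_best_cluster_merge,
    summarize_epcs,
)
from .pap import PAPMatrix, build_pap, hierarchical_order, sort_rows_by_supergroup_pattern, write_pap_tsv
from .profiles import (
    HitProfile,
    classify_proteome,
    length_report,
    profile_proteome,
    profiles_table,
)
from .search import (
    PairwiseIndex,
    SearchThresholds,
    best_hits,
    passing_hits,
    write_hit_table,
)
from .synthetic import SynthConfig, SynthTruth, default_config, generate_community, read_truth_tsv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.record = {"stage": stage, "error": message}


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | fasta-dir
    input_dir: str | None = None
    seed: int = 0
    synthetic: SynthConfig | None = None
    clustering: SearchThresholds = SearchThresholds(0.25, 1e-10)
    hit_analysis: SearchThresholds = SearchThresholds(0.25, 1e-5)
    mcl: MclParams = MclParams()
    rbc_min_support: float = 0.5
    supergroups: tuple[str, ...] = SUPERGROUPS
    exclusion_rank: str = "genus"
    pap_min_group_members: int = 15
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "fasta-dir"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "fasta-dir" and not self.input_dir:
            raise ValidationError("fasta-dir mode requires input_dir")
        if not 0.0 < self.rbc_min_support <= 1.0:
            raise ValidationError("rbc_min_support must be in (0, 1]")
        if self.exclusion_rank not in ("genus", "phylum"):
            raise ValidationError("exclusion_rank must be 'genus' or 'phylum'")

    def resolved_synth(self) -> SynthConfig:
        cfg = self.synthetic if self.synthetic is not None else default_config()
        return dataclasses.replace(cfg, seed=self.seed)


@dataclass
class ResultBundle:
    registry: TaxonRegistry
    proteomes: dict[str, list[ProteinRecord]]
    clusters: dict[str, list[FamilyCluster]]  # per domain
    unclustered: dict[str, list[str]]
    epcs: list[EPC]
    summary: dict
    leca_clusters: list[FamilyCluster]
    asgard_unique: list[EPC]
    contributions: dict
    hit_table: pd.DataFrame  # all passing hits at hit-analysis thresholds
    profiles: list[HitProfile]
    length_summary: pd.DataFrame
    ks_table: pd.DataFrame
    pap_epc: PAPMatrix | None
    truth: SynthTruth | None
    recovery: dict
    manifest: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        # internal consistency: the stored summary must re-derive from the table
        recount = summarize_epcs(self.epcs)
        if recount != self.summary:
            raise PipelineError("save", "summary counts do not match the EPC table")
        write_taxon_table(self.registry, out / "taxa.tsv")
        for taxon_id, records in self.proteomes.items():
            write_fasta(records, out / f"{taxon_id}.fasta")
        for domain, clusters in self.clusters.items():
            write_clusters_tsv(clusters, out / f"clusters_{domain}.tsv", self.registry)
        epc_table(self.epcs).to_csv(out / "epcs.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2))
        (out / "leca_clusters.txt").write_text(
            "".join(c.cluster_id + "\n" for c in self.leca_clusters)
        )
        (out / "asgard_unique.txt").write_text(
            "".join(e.epc_id + "\n" for e in self.asgard_unique)
        )
        (out / "contributions.json").write_text(json.dumps(self.contributions, indent=2))
        write_hit_table(self.hit_table, out / "hits_analysis.tsv")
        profiles_table(self.profiles).to_csv(out / "profiles.tsv", sep="\t", index=False)
        self.length_summary.to_csv(out / "lengths.tsv", sep="\t", index=False)
        self.ks_table.to_csv(out / "ks_tests.tsv", sep="\t", index=False)
        if self.pap_epc is not None and len(self.pap_epc.data):
            write_pap_tsv(self.pap_epc, out / "pap_epc.tsv")
        (out / "recovery.json").write_text(json.dumps(self.recovery, indent=2))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _content_hash(bundle_parts: Sequence[bytes]) -> str:
    digest = hashlib.sha256()
    for part in bundle_parts:
        digest.update(part)
        digest.update(b"\x00")
    return digest.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    def encode(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, Mapping):
            return {str(k): encode(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    canonical = json.dumps(encode(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def recovery_ari(
    truth: SynthTruth,
    clusters: Mapping[str, Sequence[FamilyCluster]],
    registry: TaxonRegistry,
) -> float:
    """Adjusted Rand index of recovered vs planted memberships.

    Families are planted across domains but clustered per domain, so the
    planted label is (family, domain); recovered labels are cluster ids,
    with unclustered proteins as their own singletons.  Orphans are
    excluded (they have no planted family)."""
    recovered: dict[str, str] = {}
    for domain_clusters in clusters.values():
        for cluster in domain_clusters:
            for pid in cluster.members:
                recovered[pid] = cluster.cluster_id
    proteins = sorted(truth.family_of)
    if not proteins:
        return 1.0
    planted_labels = [
        f"{truth.family_of[p]}::{registry[taxon_of(p)].domain}" for p in proteins
    ]
    recovered_labels = [recovered.get(p, f"single::{p}") for p in proteins]
    return float(adjusted_rand_score(planted_labels, recovered_labels))


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> ResultBundle:
    """Run every stage and return (and optionally persist) the bundle."""
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                wall = time.perf_counter() - self_inner.t0
                timings[name] = round(wall, 3)
                if exc is not None:
                    logger.error("stage=%s failed after %.2fs: %s", name, wall, exc)
                    raise PipelineError(name, str(exc)) from exc
                logger.info("stage=%s wall=%.2fs", name, wall)
                return False

        return _Timer()

    with stage("input"):
        truth: SynthTruth | None = None
        if config.mode == "synthetic":
            registry, proteomes, truth = generate_community(config.resolved_synth())
        else:
            registry = read_taxon_table(Path(config.input_dir) / "taxa.tsv")
            proteomes = read_proteome_dir(config.input_dir, registry)
            truth_path = Path(config.input_dir) / "truth.tsv"
            if truth_path.exists():
                truth = read_truth_tsv(truth_path)
        logger.info(
            "input: %d taxa, %d proteins",
            len(registry),
            sum(len(v) for v in proteomes.values()),
        )

    all_records = [rec for recs in proteomes.values() for rec in recs]
    by_domain: dict[str, list[ProteinRecord]] = {"eukaryote": [], "bacteria": [], "archaea": []}
    for rec in all_records:
        by_domain[registry[rec.taxon_id].domain].append(rec)
    index = PairwiseIndex(all_records)

    with stage("family_clustering"):
        clusters: dict[str, list[FamilyCluster]] = {}
        unclustered: dict[str, list[str]] = {}
        for domain, records in by_domain.items():
            clusters[domain] = (
                cluster_proteins(records, config.clustering, config.mcl, index)
                if records
                else []
            )
            unclustered[domain] = unclustered_proteins(records, clusters[domain])
            logger.info(
                "clustered domain=%s proteins=%d clusters=%d unclustered=%d",
                domain,
                len(records),
                len(clusters[domain]),
                len(unclustered[domain]),
            )

    with stage("epc_merge"):
        links: dict[str, list] = {}
        for prok_domain in ("archaea", "bacteria"):
            euk, prok = by_domain["eukaryote"], by_domain[prok_domain]
            if euk and prok:
                fwd_hits = best_hits(euk, prok, config.clustering, index)
                rev_hits = best_hits(prok, euk, config.clustering, index)
                votes_fwd = best_cluster_votes(clusters["eukaryote"], clusters[prok_domain], fwd_hits)
                votes_rev = best_cluster_votes(clusters[prok_domain], clusters["eukaryote"], rev_hits)
                links[prok_domain] = reciprocal_best_cluster_merge(
                    votes_fwd, votes_rev, config.rbc_min_support
                )
            else:
                links[prok_domain] = []
        epcs = assemble_epcs(clusters["eukaryote"], links["archaea"], links["bacteria"])
        summary = summarize_epcs(epcs)
        logger.info("epcs: %s", summary)

    with stage("leca_contribution"):
        leca_clusters = filter_leca(clusters["eukaryote"], registry, config.supergroups)
        unique = asgard_unique_ea(epcs, clusters["archaea"], registry)
        contributions = {
            "asgard_unique_ea": len(unique),
            "leca_clusters": len(leca_clusters),
            "euk_clusters": len(clusters["eukaryote"]),
            "pct_of_leca": (
                contribution_percent(len(unique), len(leca_clusters), 4)
                if leca_clusters
                else None
            ),
            "pct_of_all_euk": (
                contribution_percent(len(unique), len(clusters["eukaryote"]), 4)
                if clusters["eukaryote"]
                else None
            ),
        }
        logger.info("contributions: %s", contributions)

    with stage("hit_profiles"):
        hit_parts = []
        for domain, db_records in by_domain.items():
            if not db_records:
                continue
            hit_parts.append(
                passing_hits(all_records, db_records, config.hit_analysis, index)
            )
        hit_table = (
            pd.concat(hit_parts, ignore_index=True)
            if hit_parts
            else pd.DataFrame(columns=["query_id", "subject_id", "bit_score", "evalue", "global_identity"])
        )
        profiles = []
        categories: dict[str, str] = {}
        for taxon_id in sorted(proteomes):
            records = proteomes[taxon_id]
            if not records:
                continue
            taxon_hits = hit_table[hit_table["query_id"].str.startswith(taxon_id + "|")]
            cats = classify_proteome(
                records, taxon_hits, registry, config.hit_analysis, config.exclusion_rank
            )
            categories.update(cats)
            profiles.append(
                profile_proteome(
                    taxon_id, records, taxon_hits, registry, config.hit_analysis, config.exclusion_rank
                )
            )

    with stage("length_stats"):
        length_summary, ks_table = length_report(all_records, categories)

    with stage("pap"):
        pap_epc = None
        arch_epcs = [e for e in epcs if e.category in ("EA", "EAB")]
        if arch_epcs:
            cluster_by_id = {
                c.cluster_id: c for domain in clusters.values() for c in domain
            }
            merged = []
            for e in arch_epcs:
                members = set(cluster_by_id[e.euk_cluster].members)
                if e.arch_cluster:
                    members |= cluster_by_id[e.arch_cluster].members
                if e.bact_cluster:
                    members |= cluster_by_id[e.bact_cluster].members
                merged.append(FamilyCluster(e.epc_id, frozenset(members)))
            pap_epc = build_pap(
                merged, registry, column_mode="group", min_group_members=config.pap_min_group_members
            )
            pap_epc.row_order = sort_rows_by_supergroup_pattern(pap_epc)
            pap_epc.column_order = hierarchical_order(pap_epc.data, axis="columns")

    with stage("recovery"):
        recovery: dict = {}
        if truth is not None:
            ari = recovery_ari(truth, clusters, registry)
            recovered_unique = len(asgard_unique_ea(epcs, clusters["archaea"], registry))
            leca_ids = {c.cluster_id for c in leca_clusters}
            recovery = {
                "ari": ari,
                "planted_families": len(truth.profile_of),
                "planted_asgard_unique": len(truth.asgard_unique),
                "recovered_asgard_unique": recovered_unique,
                "planted_leca_complete": len(truth.leca_complete),
                "recovered_leca": len(leca_ids),
            }
            logger.info("recovery: %s", recovery)

    parts = []
    for domain in sorted(clusters):
        for cluster in sorted(clusters[domain], key=lambda c: c.cluster_id):
            parts.append(cluster.cluster_id.encode())
            parts.append(",".join(sorted(cluster.members)).encode())
    parts.append(epc_table(epcs).to_csv(index=False).encode())
    parts.append(json.dumps(summary, sort_keys=True).encode())
    parts.append(json.dumps(contributions, sort_keys=True).encode())
    parts.append(profiles_table(profiles).to_csv(index=False).encode())
    parts.append(length_summary.to_csv(index=False).encode())
    parts.append(ks_table.to_csv(index=False).encode())
    if pap_epc is not None:
        parts.append(pap_epc.ordered().to_csv().encode())

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "lecatrace": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timings": timings,
        "content_hash": _content_hash(parts),
    }

    bundle = ResultBundle(
        registry=registry,
        proteomes=proteomes,
        clusters=clusters,
        unclustered=unclustered,
        epcs=epcs,
        summary=summary,
        leca_clusters=leca_clusters,
        asgard_unique=unique,
        contributions=contributions,
        hit_table=hit_table,
        profiles=profiles,
        length_summary=length_summary,
        ks_table=ks_table,
        pap_epc=pap_epc,
        truth=truth,
        recovery=recovery,
        manifest=manifest,
    )
    if out_dir is not None:
        bundle.save(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Config file handling (YAML, sectioned; unknown keys are errors)

_TOP_LEVEL_KEYS = {
    "mode",
    "input_dir",
    "seed",
    "synthetic",
    "clustering",
    "hit_analysis",
    "mcl",
    "rbc_min_support",
    "supergroups",
    "exclusion_rank",
    "pap_min_group_members",
    "verbosity",
}

_SECTION_FIELDS = {
    "clustering": {"min_identity", "max_evalue"},
    "hit_analysis": {"min_identity", "max_evalue"},
    "mcl": {"inflation", "expansion", "prune_threshold", "max_iterations", "tolerance"},
    "synthetic": {
        "within_family_identity",
        "between_family_identity_ceiling",
        "family_length_range",
        "orphan_fraction",
        "leca_complete_fraction",
        "family_profile_counts",
    },
}


def _check_keys(given: Mapping[str, Any], allowed: set[str], where: str) -> None:
    for key in given:
        if key not in allowed:
            suggestion = difflib.get_close_matches(key, allowed, n=1)
            hint = f"; did you mean {suggestion[0]!r}?" if suggestion else ""
            raise ValidationError(f"unknown config key {key!r} in {where}{hint}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and fully validate a YAML pipeline config.

    Unknown keys raise (with a nearest-key suggestion); every section
    left out falls back to its documented default, and each applied
    default is logged.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ValidationError(f"{path}: config must be a mapping of sections")
    _check_keys(raw, _TOP_LEVEL_KEYS, "top level")
    for section, allowed in _SECTION_FIELDS.items():
        if section in raw and raw[section] is not None:
            if not isinstance(raw[section], Mapping):
                raise ValidationError(f"{path}: section {section!r} must be a mapping")
            _check_keys(raw[section], allowed, f"section {section!r}")

    kwargs: dict[str, Any] = {}
    for key in ("mode", "input_dir", "seed", "rbc_min_support", "exclusion_rank", "pap_min_group_members", "verbosity"):
        if key in raw:
            kwargs[key] = raw[key]
        else:
            logger.info("config: %s defaulted", key)
    if "supergroups" in raw:
        kwargs["supergroups"] = tuple(raw["supergroups"])
    for section, cls in (("clustering", SearchThresholds), ("hit_analysis", SearchThresholds), ("mcl", MclParams)):
        if section in raw and raw[section]:
            try:
                kwargs[section] = cls(**raw[section])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{path}: section {section!r}: {exc}") from exc
        else:
            logger.info("config: section %s defaulted", section)
    if "synthetic" in raw and raw["synthetic"]:
        base = default_config()
        section = dict(raw["synthetic"])
        if "family_length_range" in section:
            section["family_length_range"] = tuple(section["family_length_range"])
        try:
            synth = dataclasses.replace(base, **section)
            synth.validate()
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: section 'synthetic': {exc}") from exc
        kwargs["synthetic"] = synth
    return PipelineConfig(**kwargs)
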