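"""Core domain types and file I/O.

A *taxon registry* maps opaque taxon ids to their domain of life
(eukaryote / bacteria / archaea), a group label and a genus.  For
eukaryotes the group must be one of the six supergroups used for the
LECA (last eukaryotic common ancestor) filter; for archaea the reserved
group value ``"asgard"`` marks asgard archaea.

Protein ids are global: the local FASTA id is prefixed with the taxon id
as ``"<taxon_id>|<local_id>"`` so that pooling many proteomes can never
collide, and so the owning taxon can be recovered from the id alone.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The six eukaryotic supergroups required by the LECA filter.
SUPERGROUPS: tuple[str, ...] = (
    "Archaeplastida",
    "Opisthokonta",
    "SAR",
    "Hacrobia",
    "Excavata",
    "Mycetozoa",
)

DOMAINS: tuple[str, ...] = ("eukaryote", "bacteria", "archaea")

#: Reserved archaeal group label for asgard archaea.
ASGARD_GROUP = "asgard"

#: 20 standard amino acids plus the ambiguity code X.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

TAXON_TABLE_COLUMNS = ("taxon_id", "name", "domain", "group", "genus")
CLUSTER_TABLE_COLUMNS = ("cluster_id", "protein_id", "taxon_id", "domain", "group")


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


@dataclass(frozen=True)
class Taxon:
    """One genome/proteome with its taxonomic labels."""

    taxon_id: str
    name: str
    domain: str
    group: str
    genus: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: unknown domain {self.domain!r}; "
                f"expected one of {DOMAINS}"
            )
        if self.domain == "eukaryote" and self.group not in SUPERGROUPS:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: eukaryote group {self.group!r} is not "
                f"one of the six supergroups {SUPERGROUPS}"
            )


class TaxonRegistry:
    """Mapping of taxon_id -> :class:`Taxon` with uniqueness enforced."""

    def __init__(self, taxa: Iterable[Taxon] = ()) -> None:
        self._taxa: dict[str, Taxon] = {}
        for taxon in taxa:
            self.add(taxon)

    def add(self, taxon: Taxon) -> None:
        if taxon.taxon_id in self._taxa:
            raise ValidationError(f"duplicate taxon_id {taxon.taxon_id!r}")
        self._taxa[taxon.taxon_id] = taxon

    def __getitem__(self, taxon_id: str) -> Taxon:
        return self._taxa[taxon_id]

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._taxa

    def __iter__(self) -> Iterator[Taxon]:
        return iter(self._taxa.values())

    def __len__(self) -> int:
        return len(self._taxa)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonRegistry):
            return NotImplemented
        return self._taxa == other._taxa

    def ids(self) -> list[str]:
        return list(self._taxa)

    def by_domain(self, domain: str) -> list[Taxon]:
        return [t for t in self if t.domain == domain]

    def supergroups_present(self) -> set[str]:
        return {t.group for t in self if t.domain == "eukaryote"}

    def group_sizes(self, domain: str) -> dict[str, int]:
        """Number of taxa per group label within one domain."""
        sizes: dict[str, int] = {}
        for t in self.by_domain(domain):
            sizes[t.group] = sizes.get(t.group, 0) + 1
        return sizes


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with taxon provenance.

    ``protein_id`` is the global ``taxon|local`` id; ``taxon_id`` is kept
    explicitly so records remain self-describing outside a registry.
    """

    protein_id: str
    taxon_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValidationError(
                f"protein {self.protein_id!r}: invalid residues {sorted(bad)}; "
                "only the 20 standard amino acids plus X are accepted"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def taxon_of(protein_id: str) -> str:
    """Recover the taxon id from a global ``taxon|local`` protein id."""
    taxon_id, _, rest = protein_id.partition("|")
    if not rest:
        raise ValueError(f"protein id {protein_id!r} has no 'taxon|local' structure")
    return taxon_id


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, taxon_id: str) -> list[ProteinRecord]:
    """Read an amino-acid FASTA file into :class:`ProteinRecord` objects.

    Ids take the first whitespace-delimited header token and are prefixed
    with ``taxon_id``; sequences are upper-cased and stop-codon asterisks
    stripped.  File order is preserved.
    """
    path = Path(path)
    # Pre-scan for data before the first header so the error can name a line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValidationError(
                    f"{path}:{lineno}: sequence data before the first FASTA header"
                )
            break
        else:
            return []

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(path, "fasta"):
        local_id = entry.id
        protein_id = f"{taxon_id}|{local_id}"
        if protein_id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {local_id!r}")
        seen.add(protein_id)
        sequence = str(entry.seq).upper().replace("*", "")
        if not sequence:
            raise ValidationError(f"{path}: entry {local_id!r} has an empty sequence")
        records.append(ProteinRecord(protein_id, taxon_id, sequence))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, *, local_ids: bool = True) -> None:
    """Write records as FASTA, wrapped at 60 columns.

    With ``local_ids`` the taxon prefix is dropped from headers, which
    makes the file round-trip exactly through :func:`read_fasta` for the
    same taxon.
    """
    seq_records = []
    for rec in records:
        header = rec.protein_id.partition("|")[2] if local_ids else rec.protein_id
        seq_records.append(SeqRecord(Seq(rec.sequence), id=header, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


def read_proteome_dir(directory: str | Path, registry: TaxonRegistry) -> dict[str, list[ProteinRecord]]:
    """Load ``<taxon_id>.fasta`` files for every registry taxon."""
    directory = Path(directory)
    proteomes: dict[str, list[ProteinRecord]] = {}
    for taxon in registry:
        fasta = directory / f"{taxon.taxon_id}.fasta"
        if not fasta.exists():
            raise FileNotFoundError(f"missing proteome file {fasta}")
        proteomes[taxon.taxon_id] = read_fasta(fasta, taxon.taxon_id)
    return proteomes


# ---------------------------------------------------------------------------
# Tabular I/O


def read_taxon_table(path: str | Path) -> TaxonRegistry:
    """Read the tab-separated taxon metadata table into a registry.

    Expected header: taxon_id, name, domain, group, genus.  Validation
    (legal domain, eukaryote supergroups, unique ids) happens on load.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TAXON_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: taxon table missing columns {missing}")
    registry = TaxonRegistry()
    for row in df.itertuples(index=False):
        registry.add(Taxon(row.taxon_id, row.name, row.domain, row.group, row.genus))
    return registry


def write_taxon_table(registry: TaxonRegistry, path: str | Path) -> None:
    df = pd.DataFrame(
        [(t.taxon_id, t.name, t.domain, t.group, t.genus) for t in registry],
        columns=list(TAXON_TABLE_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def write_clusters_tsv(clusters: Iterable["FamilyClusterLike"], path: str | Path, registry: TaxonRegistry) -> None:
    """Write cluster membership as a TSV, one row per member protein.

    Rows are sorted by (cluster_id, protein_id) so output is stable and
    re-reading reproduces the same membership mapping.
    """
    rows = []
    seen_ids: set[str] = set()
    for cluster in clusters:
        if cluster.cluster_id in seen_ids:
            raise ValidationError(f"duplicate cluster_id {cluster.cluster_id!r}")
        seen_ids.add(cluster.cluster_id)
        for protein_id in cluster.members:
            tid = taxon_of(protein_id)
            taxon = registry[tid]
            rows.append((cluster.cluster_id, protein_id, tid, taxon.domain, taxon.group))
    rows.sort(key=lambda r: (r[0], r[1]))
    df = pd.DataFrame(rows, columns=list(CLUSTER_TABLE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_clusters_tsv(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a cluster TSV back into a cluster_id -> member-set mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mapping: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(row.cluster_id, set()).add(row.protein_id)
    return {cid: frozenset(members) for cid, members in mapping.items()}


class FamilyClusterLike:
    """Structural protocol: anything with ``cluster_id`` and ``members``."""

    cluster_id: str
    members: frozenset[str]
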