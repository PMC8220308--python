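"""Synthetic proteome communities with planted family structure.

The generator emits a taxon registry, one proteome per taxon and a
ground-truth object, so every downstream stage (search, clustering, EPC
merging, LECA filtering, hit profiling) can be scored against known
answers.  Families are planted with controlled sharing profiles:

======================  ==================================================
profile                 seeded into
======================  ==================================================
``E``                   eukaryotes only
``A`` / ``B``           archaea only / bacteria only
``EA`` / ``EB``         eukaryotes + archaea / + bacteria
``EAB``                 all three domains
``EA_asgard_only``      eukaryotes + asgard archaea exclusively -- the
                        planted analogue of an asgard-unique contribution
======================  ==================================================

Sequence evolution is star-shaped: one ancestral sequence per family,
one substitution-mutated descendant per seeded taxon, no indels.  The
configured ``within_family_identity`` is the target *pairwise* identity
between two family members; under the star model two leaves at ancestor
identity ``a`` match at a position when both kept the ancestral residue
(``a**2``) or both mutated to the same of 19 alternatives
(``(1-a)**2/19``), so the generator solves ``t = a**2 + (1-a)**2/19``
for the per-leaf ancestor identity ``a``.

Orphans (proteins in no family) are drawn independently per taxon with
log-normal lengths, parameterised separately for asgard vs all other
taxa so that the "no database hit" length contrast is present by
construction.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ASGARD_GROUP,
    SUPERGROUPS,
    ProteinRecord,
    Taxon,
    TaxonRegistry,
    ValidationError,
    write_fasta,
    write_taxon_table,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PROFILES = ("E", "A", "B", "EA", "EB", "EAB", "EA_asgard_only")

#: Identity threshold the default configs must separate around.
_CLUSTERING_MIN_IDENTITY = 0.25


@dataclass(frozen=True)
class CellSpec:
    """Taxon count (and genus count) for one (domain, group) cell."""

    domain: str
    group: str
    n_taxa: int
    n_genera: int = 1


@dataclass(frozen=True)
class OrphanLengthParams:
    """Log-normal length law (ln-scale location / spread) for orphans."""

    mu: float
    sigma: float


@dataclass(frozen=True)
class SynthConfig:
    cells: tuple[CellSpec, ...]
    family_profile_counts: Mapping[str, int]
    within_family_identity: float = 0.7
    between_family_identity_ceiling: float = 0.1
    family_length_range: tuple[int, int] = (80, 160)
    orphan_fraction: float = 0.1
    orphan_lengths_asgard: OrphanLengthParams = OrphanLengthParams(5.6, 0.45)
    orphan_lengths_other: OrphanLengthParams = OrphanLengthParams(5.0, 0.35)
    leca_complete_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        euk_groups = {c.group for c in self.cells if c.domain == "eukaryote" and c.n_taxa > 0}
        missing = set(SUPERGROUPS) - euk_groups
        if missing:
            raise ValidationError(f"config must seed all six supergroups; missing {sorted(missing)}")
        bact_genera = sum(min(c.n_genera, c.n_taxa) for c in self.cells if c.domain == "bacteria")
        if bact_genera < 2:
            raise ValidationError("config must cover at least 2 bacterial genera")
        nonasgard = {c.group for c in self.cells if c.domain == "archaea" and c.group != ASGARD_GROUP and c.n_taxa > 0}
        if len(nonasgard) < 2:
            raise ValidationError("config must cover at least 2 non-asgard archaeal groups")
        asgard_taxa = sum(c.n_taxa for c in self.cells if c.domain == "archaea" and c.group == ASGARD_GROUP)
        if asgard_taxa < 2:
            raise ValidationError("config must cover at least 2 asgard taxa")
        unknown = set(self.family_profile_counts) - set(PROFILES)
        if unknown:
            raise ValidationError(f"unknown family profiles {sorted(unknown)}")
        if any(n < 0 for n in self.family_profile_counts.values()):
            raise ValidationError("family profile counts must be nonnegative")
        if not _CLUSTERING_MIN_IDENTITY < self.within_family_identity <= 1.0:
            raise ValidationError(
                "within_family_identity must exceed the clustering identity "
                f"threshold ({_CLUSTERING_MIN_IDENTITY}) and be <= 1"
            )
        if not 0.0 <= self.between_family_identity_ceiling < _CLUSTERING_MIN_IDENTITY:
            raise ValidationError(
                "between_family_identity_ceiling must stay below the clustering "
                f"identity threshold ({_CLUSTERING_MIN_IDENTITY})"
            )
        lo, hi = self.family_length_range
        if not (1 <= lo <= hi):
            raise ValidationError("family_length_range must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.orphan_fraction < 1.0:
            raise ValidationError("orphan_fraction must be in [0, 1)")
        if not 0.0 <= self.leca_complete_fraction <= 1.0:
            raise ValidationError("leca_complete_fraction must be in [0, 1]")


def default_config(seed: int = 0) -> SynthConfig:
    """The standard study community: 12 eukaryotes over the six
    supergroups, 6 bacteria across 3 genera, 6 non-asgard archaea in two
    classes and 6 asgard archaea, with 60 planted families."""
    cells = tuple(
        [CellSpec("eukaryote", sg, 2, 2) for sg in SUPERGROUPS]
        + [
            CellSpec("bacteria", "Proteobacteria", 3, 2),
            CellSpec("bacteria", "Firmicutes", 3, 1),
            CellSpec("archaea", "Euryarchaeota", 3, 1),
            CellSpec("archaea", "Crenarchaeota", 3, 1),
            CellSpec("archaea", ASGARD_GROUP, 6, 6),
        ]
    )
    return SynthConfig(
        cells=cells,
        family_profile_counts={
            "E": 10,
            "A": 8,
            "B": 8,
            "EA": 10,
            "EB": 10,
            "EAB": 10,
            "EA_asgard_only": 4,
        },
        seed=seed,
    )


@dataclass(frozen=True)
class SynthTruth:
    """Planted ground truth for recovery tests."""

    family_of: Mapping[str, str]  # non-orphan protein -> family id
    orphans: frozenset[str]
    profile_of: Mapping[str, str]  # family -> sharing profile
    cells_of: Mapping[str, frozenset[tuple[str, str]]]
    asgard_unique: frozenset[str]
    leca_complete: frozenset[str]

    def members_of(self, family_id: str) -> frozenset[str]:
        return frozenset(p for p, f in self.family_of.items() if f == family_id)


def mutate_sequence(seq: str, target_identity: float, rng: np.random.Generator) -> str:
    """Substitute a Bernoulli(1 - target_identity) fraction of positions
    with a uniformly chosen *different* residue.  No indels."""
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    if target_identity == 1.0:
        return seq
    mask = rng.random(len(seq)) < (1.0 - target_identity)
    out = list(seq)
    for i in np.nonzero(mask)[0]:
        alternatives = AMINO_ACIDS.replace(out[i], "")
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def ancestor_identity_for_pairwise(t: float) -> float:
    """Per-leaf ancestor identity a with E[pairwise identity] = t under
    the star model: t = a**2 + (1-a)**2 / 19."""
    if not 0.0 < t <= 1.0:
        raise ValueError("pairwise identity target must be in (0, 1]")
    # (1 + 1/19) a^2 - (2/19) a + (1/19 - t) = 0, larger root.
    A, B, C = 1 + 1 / 19, -2 / 19, 1 / 19 - t
    disc = B * B - 4 * A * C
    return (-B + math.sqrt(disc)) / (2 * A)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _family_rng(seed: int, family_id: str) -> np.random.Generator:
    # keyed on the stable family id so adding families of one profile
    # never perturbs the streams of others
    key = zlib.crc32(family_id.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, key)))


def _taxon_rng(seed: int, taxon_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, taxon_index)))


def build_registry(config: SynthConfig) -> TaxonRegistry:
    """Deterministic registry from the cell specification; genus labels
    are assigned round-robin within each cell."""
    registry = TaxonRegistry()
    for ci, cell in enumerate(config.cells):
        for k in range(cell.n_taxa):
            taxon_id = f"{cell.domain[0].upper()}{ci:02d}{k:02d}"
            genus = f"{cell.group}_g{k % max(cell.n_genera, 1)}"
            registry.add(Taxon(taxon_id, f"{cell.group} taxon {k}", cell.domain, cell.group, genus))
    return registry


def _seed_taxa_for_family(
    profile: str,
    registry: TaxonRegistry,
    rng: np.random.Generator,
    leca_complete_fraction: float,
) -> tuple[list[str], bool]:
    """Choose the member taxa for one planted family.

    Every participating domain gets >= 2 members so each domain side can
    form a within-domain cluster; EA/EAB archaeal sides always include a
    non-asgard taxon so only EA_asgard_only families are asgard-unique.
    """
    euks = sorted(t.taxon_id for t in registry.by_domain("eukaryote"))
    bacts = sorted(t.taxon_id for t in registry.by_domain("bacteria"))
    archs = sorted(t.taxon_id for t in registry.by_domain("archaea"))
    asgard = sorted(
        t.taxon_id for t in registry.by_domain("archaea") if t.group == ASGARD_GROUP
    )
    non_asgard = sorted(set(archs) - set(asgard))
    by_group: dict[str, list[str]] = {}
    for t in registry.by_domain("eukaryote"):
        by_group.setdefault(t.group, []).append(t.taxon_id)

    chosen: list[str] = []
    leca = False
    if "E" in profile.split("_")[0]:
        if rng.random() < leca_complete_fraction:
            leca = True
            for sg in SUPERGROUPS:
                pool = sorted(by_group[sg])
                k = int(rng.integers(1, len(pool) + 1))
                chosen += list(rng.choice(pool, size=k, replace=False))
        else:
            n_groups = int(rng.integers(2, 6))  # 2..5 supergroups: never complete
            groups = rng.choice(list(SUPERGROUPS), size=n_groups, replace=False)
            for sg in groups:
                pool = sorted(by_group[sg])
                k = int(rng.integers(1, len(pool) + 1))
                chosen += list(rng.choice(pool, size=k, replace=False))
    if profile == "EA_asgard_only":
        k = int(rng.integers(2, min(4, len(asgard)) + 1))
        chosen += list(rng.choice(asgard, size=k, replace=False))
    elif "A" in profile:
        k = int(rng.integers(2, min(4, len(archs)) + 1))
        first = non_asgard[int(rng.integers(len(non_asgard)))]
        rest_pool = sorted(set(archs) - {first})
        chosen += [first] + list(rng.choice(rest_pool, size=k - 1, replace=False))
    if "B" in profile:
        k = int(rng.integers(2, min(4, len(bacts)) + 1))
        chosen += list(rng.choice(bacts, size=k, replace=False))
    return sorted(set(chosen)), leca


def generate_community(
    config: SynthConfig,
) -> tuple[TaxonRegistry, dict[str, list[ProteinRecord]], SynthTruth]:
    """Generate (registry, proteomes, truth); deterministic per seed.

    Each family uses an independent RNG stream derived from
    (seed, family index), so adding families never perturbs existing
    ones; orphan streams hang off (seed, taxon index) the same way.
    """
    config.validate()
    registry = build_registry(config)
    proteomes: dict[str, list[ProteinRecord]] = {t.taxon_id: [] for t in registry}

    leaf_identity = ancestor_identity_for_pairwise(config.within_family_identity)
    lo, hi = config.family_length_range

    family_of: dict[str, str] = {}
    profile_of: dict[str, str] = {}
    cells_of: dict[str, frozenset[tuple[str, str]]] = {}
    asgard_unique: set[str] = set()
    leca_complete: set[str] = set()

    for profile in PROFILES:
        for k in range(int(config.family_profile_counts.get(profile, 0))):
            family_id = f"{profile}.{k:03d}"
            rng = _family_rng(config.seed, family_id)
            members, leca = _seed_taxa_for_family(
                profile, registry, rng, config.leca_complete_fraction
            )
            length = int(rng.integers(lo, hi + 1))
            ancestor = _random_sequence(length, rng)
            for taxon_id in members:
                protein_id = f"{taxon_id}|{family_id}"
                seq = mutate_sequence(ancestor, leaf_identity, rng)
                proteomes[taxon_id].append(ProteinRecord(protein_id, taxon_id, seq))
                family_of[protein_id] = family_id
            profile_of[family_id] = profile
            cells_of[family_id] = frozenset(
                (registry[t].domain, registry[t].group) for t in members
            )
            if profile == "EA_asgard_only":
                asgard_unique.add(family_id)
            if leca:
                leca_complete.add(family_id)

    orphans: set[str] = set()
    for ti, taxon in enumerate(sorted(registry, key=lambda t: t.taxon_id)):
        rng = _taxon_rng(config.seed, ti)
        n_family = len(proteomes[taxon.taxon_id])
        n_orphans = int(rng.binomial(n_family, config.orphan_fraction)) if n_family else 0
        params = (
            config.orphan_lengths_asgard
            if taxon.group == ASGARD_GROUP
            else config.orphan_lengths_other
        )
        lengths = orphan_lengths(params, n_orphans, rng)
        for k, length in enumerate(lengths):
            protein_id = f"{taxon.taxon_id}|o{k:03d}"
            proteomes[taxon.taxon_id].append(
                ProteinRecord(protein_id, taxon.taxon_id, _random_sequence(length, rng))
            )
            orphans.add(protein_id)

    truth = SynthTruth(
        family_of=family_of,
        orphans=frozenset(orphans),
        profile_of=profile_of,
        cells_of=cells_of,
        asgard_unique=frozenset(asgard_unique),
        leca_complete=frozenset(leca_complete),
    )
    return registry, proteomes, truth


def orphan_lengths(
    params: OrphanLengthParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer log-normal lengths, floored at 30 residues."""
    if n == 0:
        return np.zeros(0, dtype=int)
    raw = np.exp(rng.normal(params.mu, params.sigma, size=n))
    return np.maximum(np.round(raw).astype(int), 30)


# ---------------------------------------------------------------------------
# Persistence: standard FASTA per taxon + taxon TSV + truth TSV, consumed
# unchanged by the pipeline CLI.


def write_community(
    registry: TaxonRegistry,
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    truth: SynthTruth,
    out_dir: str | Path,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_taxon_table(registry, out_dir / "taxa.tsv")
    for taxon_id, records in proteomes.items():
        write_fasta(records, out_dir / f"{taxon_id}.fasta")
    write_truth_tsv(truth, proteomes, out_dir / "truth.tsv")


def write_truth_tsv(
    truth: SynthTruth,
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    path: str | Path,
) -> None:
    rows = []
    for taxon_id in sorted(proteomes):
        for rec in proteomes[taxon_id]:
            fam = truth.family_of.get(rec.protein_id, "")
            profile = truth.profile_of.get(fam, "") if fam else ""
            rows.append(
                (
                    rec.protein_id,
                    taxon_id,
                    fam,
                    profile,
                    int(fam in truth.asgard_unique) if fam else 0,
                    int(fam in truth.leca_complete) if fam else 0,
                )
            )
    pd.DataFrame(
        rows,
        columns=["protein_id", "taxon_id", "family_id", "profile", "asgard_unique", "leca_complete"],
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> SynthTruth:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    family_of = {}
    orphans = set()
    profile_of: dict[str, str] = {}
    asgard_unique = set()
    leca_complete = set()
    for row in df.itertuples(index=False):
        if row.family_id:
            family_of[row.protein_id] = row.family_id
            profile_of[row.family_id] = row.profile
            if row.asgard_unique == "1":
                asgard_unique.add(row.family_id)
            if row.leca_complete == "1":
                leca_complete.add(row.family_id)
        else:
            orphans.add(row.protein_id)
    return SynthTruth(
        family_of=family_of,
        orphans=frozenset(orphans),
        profile_of=profile_of,
        cells_of={},
        asgard_unique=frozenset(asgard_unique),
        leca_complete=frozenset(leca_complete),
    )
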