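"""All-versus-all protein comparison.

Local Smith-Waterman bit scores with analytic Karlin-Altschul E-values
stand in for a BLAST-style search, while percent identity comes from a
full Needleman-Wunsch global alignment.  Both use BLOSUM62 with affine
gap costs of 11 to open and 1 to extend (a gap of length k costs
11 + k), i.e. the default blastp regime, and end gaps are penalized in
the global alignment.

Identity is defined as identical aligned residue pairs divided by the
total number of alignment columns, gap columns included -- the strictest
of the common conventions.

E-values use E = m * n * 2**(-S') with S' = (lambda*S - ln K)/ln 2 and
the published gapped BLOSUM62 constants lambda = 0.267, K = 0.041; the
database size n is the total residue count of the subject set at call
time, which keeps the statistic deterministic and self-contained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .data_model import ProteinRecord

GAP_OPEN = 11
GAP_EXTEND = 1
#: Gapped BLOSUM62 Karlin-Altschul parameters (blastp defaults).
KA_LAMBDA = 0.267
KA_K = 0.041

HIT_TABLE_COLUMNS = ("query_id", "subject_id", "bit_score", "evalue", "global_identity")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        substitution_matrix=_BLOSUM62,
        # Biopython scores the first gap position with open+extend.
        open_gap_score=-(GAP_OPEN + GAP_EXTEND),
        extend_gap_score=-GAP_EXTEND,
        mode=mode,
    )
    return aligner


_GLOBAL = _make_aligner("global")
_LOCAL = _make_aligner("local")


@dataclass(frozen=True)
class SearchThresholds:
    """Identity / E-value cutoffs; both must pass for a hit to count."""

    min_identity: float = 0.25
    max_evalue: float = 1e-10

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError(f"min_identity must be in [0,1], got {self.min_identity}")
        if not self.max_evalue > 0:
            raise ValueError(f"max_evalue must be > 0, got {self.max_evalue}")


#: Cutoffs used for family clustering: >=25% identity, E <= 1e-10.
CLUSTERING_THRESHOLDS = SearchThresholds(0.25, 1e-10)
#: Looser cutoffs used for the per-proteome hit-category analysis.
HIT_ANALYSIS_THRESHOLDS = SearchThresholds(0.25, 1e-5)


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    bit_score: float
    evalue: float
    global_identity: float


def global_identity(a: str, b: str) -> float:
    """Global percent identity of two sequences, as a fraction in [0,1].

    Among co-optimal alignments the traceback is made symmetric by
    aligning the lexicographically smaller sequence first, so
    ``global_identity(a, b) == global_identity(b, a)`` exactly.
    """
    if not a or not b:
        raise ValueError("global_identity requires two non-empty sequences")
    if b < a:
        a, b = b, a
    alignment = _GLOBAL.align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    matches = sum(x == y for x, y in zip(ga, gb))
    return matches / len(ga)


def local_score(a: str, b: str) -> float:
    """Smith-Waterman score in bits.

    A raw score of 0 (no positive-scoring local alignment exists) is
    reported as 0.0 bits; the Karlin-Altschul transform is not
    meaningful there.
    """
    if not a or not b:
        raise ValueError("local_score requires two non-empty sequences")
    raw = _LOCAL.score(a, b)
    if raw <= 0:
        return 0.0
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2)


def evalue(bit_score: float, query_len: int, db_residues: int) -> float:
    """Karlin-Altschul expectation E = m * n * 2**(-S')."""
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("query_len and db_residues must be positive")
    return float(query_len) * float(db_residues) * 2.0 ** (-bit_score)


class PairwiseIndex:
    """Memoized pairwise scores/identities over a pool of proteins.

    Both statistics are symmetric, so each unordered pair is aligned at
    most once no matter how many search calls reuse the index.  Sharing
    one index across a whole pipeline run is the supported way to avoid
    re-aligning the same pair in different stages.
    """

    def __init__(self, records: Iterable[ProteinRecord] = ()) -> None:
        self._seqs: dict[str, str] = {}
        self._scores: dict[tuple[str, str], float] = {}
        self._idents: dict[tuple[str, str], float] = {}
        self.add(records)

    def add(self, records: Iterable[ProteinRecord]) -> None:
        for rec in records:
            existing = self._seqs.get(rec.protein_id)
            if existing is not None and existing != rec.sequence:
                raise ValueError(f"conflicting sequences for {rec.protein_id!r}")
            self._seqs[rec.protein_id] = rec.sequence

    def sequence(self, protein_id: str) -> str:
        return self._seqs[protein_id]

    def length(self, protein_id: str) -> int:
        return len(self._seqs[protein_id])

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def bit_score(self, a: str, b: str) -> float:
        key = self._key(a, b)
        score = self._scores.get(key)
        if score is None:
            score = local_score(self._seqs[a], self._seqs[b])
            self._scores[key] = score
        return score

    def identity(self, a: str, b: str) -> float:
        key = self._key(a, b)
        ident = self._idents.get(key)
        if ident is None:
            ident = global_identity(self._seqs[a], self._seqs[b])
            self._idents[key] = ident
        return ident


def _hit_rows(
    queries: Sequence[ProteinRecord],
    subjects: Sequence[ProteinRecord],
    thresholds: SearchThresholds,
    index: PairwiseIndex,
    best_only: bool,
) -> pd.DataFrame:
    if not queries or not subjects:
        raise ValueError("query and subject sets must be non-empty")
    db_residues = sum(rec.length for rec in subjects)
    subject_list = sorted(subjects, key=lambda r: r.protein_id)
    rows: list[tuple[str, str, float, float, float]] = []
    for query in queries:
        candidates: list[tuple[str, float, float, float]] = []
        for subject in subject_list:
            if subject.protein_id == query.protein_id:
                continue  # self-hits never compete
            score = index.bit_score(query.protein_id, subject.protein_id)
            e = evalue(score, query.length, db_residues)
            if e > thresholds.max_evalue:
                continue
            ident = index.identity(query.protein_id, subject.protein_id)
            if ident < thresholds.min_identity:
                continue
            candidates.append((subject.protein_id, score, e, ident))
        if not candidates:
            continue
        if best_only:
            # Highest bit score; ties by lower E-value, then smaller id.
            candidates = [min(candidates, key=lambda c: (-c[1], c[2], c[0]))]
        for sid, score, e, ident in candidates:
            rows.append((query.protein_id, sid, score, e, ident))
    return pd.DataFrame(rows, columns=list(HIT_TABLE_COLUMNS))


def passing_hits(
    queries: Sequence[ProteinRecord],
    subjects: Sequence[ProteinRecord],
    thresholds: SearchThresholds,
    index: PairwiseIndex | None = None,
) -> pd.DataFrame:
    """All query->subject hits passing both thresholds (self-hits excluded)."""
    if index is None:
        index = PairwiseIndex([*queries, *subjects])
    return _hit_rows(queries, subjects, thresholds, index, best_only=False)


def best_hits(
    queries: Sequence[ProteinRecord],
    subjects: Sequence[ProteinRecord],
    thresholds: SearchThresholds,
    index: PairwiseIndex | None = None,
) -> pd.DataFrame:
    """Best passing hit per query.

    The best hit is chosen by highest bit score among subjects passing
    both thresholds, ties broken by lower E-value then lexicographically
    smaller subject id; queries with no passing subject are absent.
    """
    if index is None:
        index = PairwiseIndex([*queries, *subjects])
    return _hit_rows(queries, subjects, thresholds, index, best_only=True)


def reciprocal_best_hits(hit_table_ab: pd.DataFrame, hit_table_ba: pd.DataFrame) -> set[tuple[str, str]]:
    """Unordered pairs {a, b} that are each other's best hit.

    Pairs are returned as sorted 2-tuples.
    """
    fwd = dict(zip(hit_table_ab["query_id"], hit_table_ab["subject_id"]))
    rev = dict(zip(hit_table_ba["query_id"], hit_table_ba["subject_id"]))
    pairs: set[tuple[str, str]] = set()
    for a, b in fwd.items():
        if rev.get(b) == a:
            pairs.add((a, b) if a <= b else (b, a))
    return pairs


def write_hit_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["evalue"] = out["evalue"].map(lambda e: f"{e:.3e}")
    out.to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "subject_id": str})
    return df[list(HIT_TABLE_COLUMNS)]
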