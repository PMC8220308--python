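"""Per-proteome hit-category profiles and protein-length statistics.

Every protein of a query proteome is classified by where its significant
homologs live: eukaryotes (E), archaea (A), bacteria (B) or any
combination, or ``none`` when no hit survives.  Hits must pass the
hit-analysis thresholds (>=25% identity, E <= 1e-5) and hits from the
query's own genus are excluded to counter database composition bias
(phylum-level exclusion is available as a stricter variant).

Length distributions of proteins with vs without hits are compared with
two-sided two-sample Kolmogorov-Smirnov tests, Benjamini-Hochberg
corrected across all pairwise contrasts of one report.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from statsmodels.stats.multitest import multipletests

from .data_model import ProteinRecord, TaxonRegistry, taxon_of
from .search import HIT_ANALYSIS_THRESHOLDS, SearchThresholds

logger = logging.getLogger(__name__)

#: Category codes in canonical E, A, B spelling order.
CATEGORIES = ("E", "A", "B", "EA", "EB", "AB", "EAB", "none")

_DOMAIN_CODE = {"eukaryote": "E", "archaea": "A", "bacteria": "B"}


@dataclass(frozen=True)
class HitProfile:
    taxon_id: str
    counts: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("category counts must sum to the proteome size")


@dataclass(frozen=True)
class LengthTestResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    pvalue: float
    qvalue: float


def classify_protein(
    protein: ProteinRecord,
    hits: pd.DataFrame,
    registry: TaxonRegistry,
    thresholds: SearchThresholds = HIT_ANALYSIS_THRESHOLDS,
    exclusion_rank: str = "genus",
) -> str:
    """Domain-combination category of one protein's hits.

    ``hits`` holds this protein's rows of a hit table (subject_id,
    evalue, global_identity at minimum).  All passing hits contribute,
    not just the best one; same-genus (or, for ``exclusion_rank=
    'phylum'``, same-group) subjects are discarded first.
    """
    if exclusion_rank not in ("genus", "phylum"):
        raise ValueError("exclusion_rank must be 'genus' or 'phylum'")
    query_taxon = registry[protein.taxon_id]
    domains: set[str] = set()
    for row in hits.itertuples(index=False):
        if row.evalue > thresholds.max_evalue:
            continue
        if row.global_identity < thresholds.min_identity:
            continue
        subject_taxon = registry[taxon_of(row.subject_id)]
        if exclusion_rank == "genus":
            if subject_taxon.genus == query_taxon.genus:
                continue
        else:
            if subject_taxon.group == query_taxon.group:
                continue
        domains.add(subject_taxon.domain)
    if not domains:
        return "none"
    return "".join(code for dom, code in _DOMAIN_CODE.items() if dom in domains)


def classify_proteome(
    records: Sequence[ProteinRecord],
    all_hits: pd.DataFrame,
    registry: TaxonRegistry,
    thresholds: SearchThresholds = HIT_ANALYSIS_THRESHOLDS,
    exclusion_rank: str = "genus",
) -> dict[str, str]:
    """protein_id -> category for every record of one proteome."""
    grouped = dict(tuple(all_hits.groupby("query_id", sort=False)))
    empty = all_hits.iloc[0:0]
    return {
        rec.protein_id: classify_protein(
            rec, grouped.get(rec.protein_id, empty), registry, thresholds, exclusion_rank
        )
        for rec in records
    }


def profile_proteome(
    taxon_id: str,
    records: Sequence[ProteinRecord],
    all_hits: pd.DataFrame,
    registry: TaxonRegistry,
    thresholds: SearchThresholds = HIT_ANALYSIS_THRESHOLDS,
    exclusion_rank: str = "genus",
) -> HitProfile:
    """Category counts over one proteome; counts always sum to its size."""
    categories = classify_proteome(records, all_hits, registry, thresholds, exclusion_rank)
    counts = {cat: 0 for cat in CATEGORIES}
    for cat in categories.values():
        counts[cat] += 1
    return HitProfile(taxon_id, counts, len(records))


def mean_category_count(profiles: Sequence[HitProfile], category: str) -> float:
    if not profiles:
        raise ValueError("mean_category_count needs at least one profile")
    return float(np.mean([p.counts.get(category, 0) for p in profiles]))


def profiles_table(profiles: Sequence[HitProfile]) -> pd.DataFrame:
    """Long-format (taxon, category, count) table, stacked-bar ready."""
    rows = [
        (p.taxon_id, cat, p.counts.get(cat, 0)) for p in profiles for cat in CATEGORIES
    ]
    return pd.DataFrame(rows, columns=["taxon_id", "category", "count"])


# ---------------------------------------------------------------------------
# Length statistics


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample KS test.

    D is the exact supremum over pooled points of |ECDF_x - ECDF_y|;
    the p-value comes from the asymptotic Kolmogorov distribution with
    effective sample size n_x*n_y/(n_x+n_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    cdf_y = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    d = float(np.abs(cdf_x - cdf_y).max())
    n_eff = x.size * y.size / (x.size + y.size)
    p = float(kolmogorov(np.sqrt(n_eff) * d))
    return d, min(1.0, max(0.0, p))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def length_report(
    records: Sequence[ProteinRecord],
    categories: Mapping[str, str],
    pooled_by: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box-plot summaries and pairwise KS tests of protein lengths.

    Lengths are split into ``with_hit`` (category != none) vs ``no_hit``
    per taxon (default) or per pooled group when ``pooled_by`` maps
    taxon_id -> group label.  Quartiles use linear interpolation between
    order statistics; whiskers sit at the most extreme data points
    within 1.5 IQR of the quartiles.  All pairwise KS contrasts between
    the emitted groups form one BH correction family.
    """
    samples: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        unit = rec.taxon_id if pooled_by is None else pooled_by[rec.taxon_id]
        status = "no_hit" if categories.get(rec.protein_id, "none") == "none" else "with_hit"
        samples.setdefault((unit, status), []).append(rec.length)

    summary_rows = []
    for (unit, status), lengths in sorted(samples.items()):
        if not lengths:
            logger.info("length_report: empty group (%s, %s) omitted", unit, status)
            continue
        arr = np.asarray(lengths, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        lo = float(arr[arr >= q1 - 1.5 * iqr].min())
        hi = float(arr[arr <= q3 + 1.5 * iqr].max())
        summary_rows.append((unit, status, arr.size, med, q1, q3, lo, hi))
    summary = pd.DataFrame(
        summary_rows,
        columns=["group", "status", "n", "median", "q1", "q3", "whisker_lo", "whisker_hi"],
    )

    keys = sorted(samples)
    ks_rows = []
    for (ka, kb) in itertools.combinations(keys, 2):
        d, p = ks_two_sample(samples[ka], samples[kb])
        ks_rows.append(
            ("/".join(ka), "/".join(kb), len(samples[ka]), len(samples[kb]), d, p)
        )
    ks = pd.DataFrame(
        ks_rows, columns=["group_a", "group_b", "n_a", "n_b", "D", "p"]
    )
    ks["q"] = bh_fdr(ks["p"].to_numpy()) if len(ks) else []
    return summary, ks
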