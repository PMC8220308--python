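from __future__ import annotations

import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lecatrace.data_model import ProteinRecord
from lecatrace.profiles import (
    CATEGORIES,
    HitProfile,
    bh_fdr,
    classify_protein,
    ks_two_sample,
    length_report,
    mean_category_count,
    profile_proteome,
)
from .oracles import bh_stepup, ks_statistic

COLS = ["query_id", "subject_id", "bit_score", "evalue", "global_identity"]


def _hits(rows):
    return pd.DataFrame(
        [(r[0], r[1], 50.0, r[2] if len(r) > 2 else 1e-20, r[3] if len(r) > 3 else 0.8) for r in rows],
        columns=COLS,
    )


@pytest.fixture
def query(small_registry):
    return ProteinRecord("A1|q", "A1", "MKVLWAALLV")  # asgard archaeon


class TestClassify:
    def test_bacteria_only(self, small_registry, query):
        hits = _hits([("A1|q", "B0|s1"), ("A1|q", "B1|s2")])
        assert classify_protein(query, hits, small_registry) == "B"

    def test_same_genus_hit_excluded(self, small_registry):
        # both A1 taxa... single-taxon genus: query's own genus subject
        query = ProteinRecord("A1|q", "A1", "MKVLWAALLV")
        hits = _hits([("A1|q", "A1|other")])
        assert classify_protein(query, hits, small_registry) == "none"

    def test_eukaryote_plus_archaeon(self, small_registry, query):
        hits = _hits([("A1|q", "E0|s"), ("A1|q", "A0|s")])
        assert classify_protein(query, hits, small_registry) == "EA"

    def test_threshold_boundaries_inclusive(self, small_registry, query):
        at_bound = _hits([("A1|q", "E0|s", 1e-5, 0.25)])
        assert classify_protein(query, at_bound, small_registry) == "E"
        below = _hits([("A1|q", "E0|s", 1e-4, 0.25)])
        assert classify_protein(query, below, small_registry) == "none"
        weak = _hits([("A1|q", "E0|s", 1e-20, 0.24)])
        assert classify_protein(query, weak, small_registry) == "none"

    def test_phylum_exclusion_stricter(self, small_registry):
        # same group (asgard) subject survives genus exclusion but not
        # phylum exclusion
        query = ProteinRecord("A1|q", "A1", "MKVLWAALLV")
        from lecatrace.data_model import Taxon, TaxonRegistry

        registry = TaxonRegistry(list(small_registry) + [Taxon("A2", "x", "archaea", "asgard", "Odinarchaeum")])
        hits = _hits([("A1|q", "A2|s")])
        assert classify_protein(query, hits, registry, exclusion_rank="genus") == "A"
        assert classify_protein(query, hits, registry, exclusion_rank="phylum") == "none"

    def test_tightening_thresholds_shrinks_category(self, small_registry, query):
        from lecatrace.search import SearchThresholds

        hits = _hits([("A1|q", "E0|s", 1e-20, 0.9), ("A1|q", "B0|s", 1e-6, 0.3)])
        loose = classify_protein(query, hits, small_registry, SearchThresholds(0.25, 1e-5))
        tight = classify_protein(query, hits, small_registry, SearchThresholds(0.5, 1e-10))
        assert loose == "EB" and tight == "E"  # only toward smaller sets


class TestProfile:
    def test_orphan_proteome_all_none(self, small_registry):
        records = [ProteinRecord(f"A1|o{i}", "A1", "MKVL") for i in range(3)]
        profile = profile_proteome("A1", records, _hits([]), small_registry)
        assert profile.counts["none"] == 3
        assert sum(profile.counts.values()) == profile.total == 3

    def test_hit_row_order_invariance(self, small_registry):
        records = [ProteinRecord("A1|q", "A1", "MKVL")]
        rows = [("A1|q", "E0|s"), ("A1|q", "B0|s"), ("A1|q", "A0|s")]
        fwd = profile_proteome("A1", records, _hits(rows), small_registry)
        rev = profile_proteome("A1", records, _hits(rows[::-1]), small_registry)
        assert fwd == rev

    def test_counts_partition_proteome(self, default_bundle):
        for profile in default_bundle.profiles:
            assert sum(profile.counts.values()) == profile.total

    def test_orphans_receive_none(self, default_bundle):
        bundle = default_bundle
        cats = {}
        from lecatrace.profiles import classify_proteome

        for taxon_id, records in bundle.proteomes.items():
            taxon_hits = bundle.hit_table[
                bundle.hit_table["query_id"].str.startswith(taxon_id + "|")
            ]
            cats.update(classify_proteome(records, taxon_hits, bundle.registry))
        for orphan in bundle.truth.orphans:
            assert cats[orphan] == "none"


class TestMeanCategoryCount:
    def test_mean(self, small_registry):
        profiles = [
            HitProfile("A0", {**{c: 0 for c in CATEGORIES}, "E": 2, "none": 0}, 2),
            HitProfile("A1", {**{c: 0 for c in CATEGORIES}, "E": 4}, 4),
        ]
        assert mean_category_count(profiles, "E") == 3.0
        assert mean_category_count(profiles[:1], "E") == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_category_count([], "E")


class TestKs:
    def test_identical_samples(self):
        assert ks_two_sample([1, 2, 3], [1, 2, 3])[0] == 0.0

    def test_disjoint_supports(self):
        d, p = ks_two_sample([1, 2, 3, 4], [5, 6, 7, 8])
        assert d == 1.0

    def test_interleaved(self):
        assert ks_two_sample([1, 3], [2, 4])[0] == 0.5

    def test_symmetry_and_bruteforce_on_random_pairs(self):
        rng = random.Random(0)
        for _ in range(100):
            x = [rng.randint(0, 20) for _ in range(rng.randint(1, 15))]
            y = [rng.randint(0, 20) for _ in range(rng.randint(1, 15))]
            d_xy, p_xy = ks_two_sample(x, y)
            d_yx, p_yx = ks_two_sample(y, x)
            assert d_xy == d_yx and p_xy == p_yx
            assert d_xy == pytest.approx(ks_statistic(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestBh:
    def test_single_p(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_stepup_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_direct_stepup_on_random_vectors(self):
        rng = random.Random(1)
        for _ in range(50):
            p = [rng.random() for _ in range(rng.randint(1, 12))]
            assert bh_fdr(p) == pytest.approx(bh_stepup(p), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10), st.randoms())
    def test_permutation_equivariance(self, pvals, pyrandom):
        perm = list(range(len(pvals)))
        pyrandom.shuffle(perm)
        q = bh_fdr(pvals)
        q_perm = bh_fdr([pvals[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm])

    def test_q_at_least_p(self):
        rng = random.Random(2)
        p = [rng.random() for _ in range(20)]
        assert all(qi >= pi - 1e-12 for qi, pi in zip(bh_fdr(p), p))


class TestLengthReport:
    def test_quartiles_linear_interpolation(self, small_registry):
        records = [
            ProteinRecord("A1|a", "A1", "A" * 100),
            ProteinRecord("A1|b", "A1", "A" * 200),
            ProteinRecord("A1|c", "A1", "A" * 300),
        ]
        summary, _ = length_report(records, {p.protein_id: "none" for p in records})
        row = summary.iloc[0]
        assert (row["median"], row["q1"], row["q3"]) == (200, 150, 250)

    def test_all_with_hit_omits_no_hit_group(self):
        records = [ProteinRecord("A1|a", "A1", "A" * 50)]
        summary, _ = length_report(records, {"A1|a": "E"})
        assert list(summary["status"]) == ["with_hit"]

    def test_planted_length_contrast_detected(self, default_bundle):
        """Asgard no-hit proteins are planted longer than asgard
        proteins with hits; that pooled contrast must reach q < 0.05."""
        bundle = default_bundle
        pooled_by = {
            t.taxon_id: ("asgard" if t.group == "asgard" else "other")
            for t in bundle.registry
        }
        from lecatrace.profiles import classify_proteome

        cats = {}
        for taxon_id, records in bundle.proteomes.items():
            taxon_hits = bundle.hit_table[
                bundle.hit_table["query_id"].str.startswith(taxon_id + "|")
            ]
            cats.update(classify_proteome(records, taxon_hits, bundle.registry))
        all_records = [r for recs in bundle.proteomes.values() for r in recs]
        _, ks = length_report(all_records, cats, pooled_by)
        pair = {"asgard/no_hit", "asgard/with_hit"}
        contrast = ks[ks.apply(lambda r: {r["group_a"], r["group_b"]} == pair, axis=1)]
        assert len(contrast) == 1
        assert float(contrast["D"].iloc[0]) > 0.5
        assert float(contrast["q"].iloc[0]) < 0.05
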