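from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from lecatrace.data_model import ValidationError
from lecatrace.search import global_identity
from lecatrace.synthetic import (
    CellSpec,
    SynthConfig,
    ancestor_identity_for_pairwise,
    default_config,
    generate_community,
    mutate_sequence,
    orphan_lengths,
    write_community,
)


def _minimal_cells():
    from lecatrace.data_model import SUPERGROUPS

    return tuple(
        [CellSpec("eukaryote", sg, 1) for sg in SUPERGROUPS]
        + [
            CellSpec("bacteria", "Proteobacteria", 2, 2),
            CellSpec("archaea", "Euryarchaeota", 1),
            CellSpec("archaea", "Crenarchaeota", 1),
            CellSpec("archaea", "asgard", 2, 2),
        ]
    )


class TestConfigValidation:
    def test_default_config_valid(self):
        default_config().validate()

    def test_missing_supergroup_rejected(self):
        cells = tuple(c for c in _minimal_cells() if c.group != "SAR")
        cfg = SynthConfig(cells=cells, family_profile_counts={"EA": 1})
        with pytest.raises(ValidationError, match="supergroups"):
            cfg.validate()

    def test_single_bacterial_genus_rejected(self):
        cells = tuple(
            CellSpec(c.domain, c.group, c.n_taxa, 1) if c.domain == "bacteria" else c
            for c in _minimal_cells()
            if c.domain != "bacteria"
        ) + (CellSpec("bacteria", "Proteobacteria", 2, 1),)
        cfg = SynthConfig(cells=cells, family_profile_counts={"EA": 1})
        with pytest.raises(ValidationError, match="genera"):
            cfg.validate()

    def test_within_identity_must_exceed_clustering_threshold(self):
        cfg = SynthConfig(
            cells=_minimal_cells(),
            family_profile_counts={"EA": 1},
            within_family_identity=0.2,
        )
        with pytest.raises(ValidationError, match="within_family_identity"):
            cfg.validate()

    def test_between_ceiling_must_stay_below_threshold(self):
        cfg = SynthConfig(
            cells=_minimal_cells(),
            family_profile_counts={"EA": 1},
            between_family_identity_ceiling=0.3,
        )
        with pytest.raises(ValidationError, match="ceiling"):
            cfg.validate()

    def test_generation_validates_first(self):
        cfg = SynthConfig(cells=_minimal_cells(), family_profile_counts={"XX": 1})
        with pytest.raises(ValidationError):
            generate_community(cfg)


class TestMutateSequence:
    def test_identity_one_returns_input(self):
        rng = np.random.default_rng(0)
        assert mutate_sequence("MKVLW", 1.0, rng) == "MKVLW"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mutate_sequence("", 0.9, np.random.default_rng(0))

    def test_substitution_fraction_concentrates(self):
        """Realized substitution fraction on a length-1000 sequence at
        target 0.7 stays within +-0.05 of 0.3 (binomial sd ~0.014, so
        +-0.05 is a >3-sigma band; checked over 20 seeds)."""
        base = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(1000))
        for seed in range(20):
            out = mutate_sequence(base, 0.7, np.random.default_rng(seed))
            frac = sum(a != b for a, b in zip(base, out)) / 1000
            assert abs(frac - 0.3) < 0.05

    def test_alignment_identity_matches_target(self):
        """Cross-module consistency: global alignment identity of the
        mutated sequence against its input lands near the target."""
        rng = np.random.default_rng(5)
        base = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 500))
        out = mutate_sequence(base, 0.7, rng)
        assert global_identity(base, out) == pytest.approx(0.7, abs=0.05)


class TestStarModelCalibration:
    def test_ancestor_identity_solves_pairwise_target(self):
        for t in (0.35, 0.5, 0.7, 0.9, 1.0):
            a = ancestor_identity_for_pairwise(t)
            assert 0 < a <= 1
            assert a * a + (1 - a) ** 2 / 19 == pytest.approx(t, abs=1e-12)

    def test_pairwise_identity_between_leaves(self):
        """Two leaves mutated independently from one ancestor realize the
        configured pairwise identity (long sequence, tight tolerance)."""
        rng = np.random.default_rng(3)
        ancestor = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 2000))
        a = ancestor_identity_for_pairwise(0.7)
        leaf1 = mutate_sequence(ancestor, a, rng)
        leaf2 = mutate_sequence(ancestor, a, rng)
        matches = sum(x == y for x, y in zip(leaf1, leaf2)) / 2000
        assert matches == pytest.approx(0.7, abs=0.04)


class TestGenerateCommunity:
    def test_minimal_ea_family(self):
        cfg = SynthConfig(
            cells=_minimal_cells(),
            family_profile_counts={"EA": 1},
            orphan_fraction=0.0,
            seed=0,
        )
        registry, proteomes, truth = generate_community(cfg)
        records = [r for recs in proteomes.values() for r in recs]
        assert len(truth.profile_of) == 1
        assert set(truth.family_of.values()) == set(truth.profile_of)
        assert truth.orphans == frozenset()
        # every emitted protein belongs to the planted family
        assert {r.protein_id for r in records} == set(truth.family_of)

    def test_determinism_byte_identical(self, tmp_path):
        cfg = default_config(seed=9)
        for sub in ("a", "b"):
            registry, proteomes, truth = generate_community(cfg)
            write_community(registry, proteomes, truth, tmp_path / sub)
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_adding_families_does_not_perturb_existing(self):
        base = default_config(seed=4)
        more = SynthConfig(
            cells=base.cells,
            family_profile_counts={**base.family_profile_counts, "EAB": 20},
            seed=4,
        )
        _, prot_a, truth_a = generate_community(base)
        _, prot_b, truth_b = generate_community(more)
        seqs_b = {r.protein_id: r.sequence for recs in prot_b.values() for r in recs}
        for recs in prot_a.values():
            for rec in recs:
                if rec.protein_id in truth_a.family_of:
                    assert seqs_b[rec.protein_id] == rec.sequence

    def test_truth_consistent_with_records(self, default_community):
        registry, proteomes, truth = default_community
        all_ids = {r.protein_id for recs in proteomes.values() for r in recs}
        assert set(truth.family_of) | truth.orphans == all_ids
        assert set(truth.family_of).isdisjoint(truth.orphans)
        assert truth.asgard_unique == {
            f for f, p in truth.profile_of.items() if p == "EA_asgard_only"
        }
        for fam in truth.leca_complete:
            groups = {g for d, g in truth.cells_of[fam] if d == "eukaryote"}
            assert len(groups) == 6

    def test_orphan_counts_follow_binomial_law(self):
        """Pooled over taxa and 200 seeds, orphan counts behave as
        Binomial(n_family_proteins, fraction): the pooled total stays in
        a 4.5-sigma band and never exceeds its support."""
        cfg = SynthConfig(
            cells=_minimal_cells(),
            family_profile_counts={"E": 3, "EA": 3, "EB": 2, "EAB": 2},
            orphan_fraction=0.5,
            leca_complete_fraction=0.5,
        )
        total_orphans = 0
        total_trials = 0
        import dataclasses

        for seed in range(200):
            _, proteomes, truth = generate_community(dataclasses.replace(cfg, seed=seed))
            per_taxon_family = {
                t: sum(1 for r in recs if r.protein_id in truth.family_of)
                for t, recs in proteomes.items()
            }
            per_taxon_orphans = {
                t: sum(1 for r in recs if r.protein_id in truth.orphans)
                for t, recs in proteomes.items()
            }
            for t in proteomes:
                assert per_taxon_orphans[t] <= per_taxon_family[t]
            total_orphans += sum(per_taxon_orphans.values())
            total_trials += sum(per_taxon_family.values())
        mean = 0.5 * total_trials
        sd = np.sqrt(total_trials * 0.25)
        assert abs(total_orphans - mean) < 4.5 * sd

    def test_asgard_orphans_longer_than_others(self):
        rng = np.random.default_rng(0)
        cfg = default_config()
        asg = orphan_lengths(cfg.orphan_lengths_asgard, 500, rng)
        other = orphan_lengths(cfg.orphan_lengths_other, 500, rng)
        assert np.median(asg) > np.median(other)
        # planted contrast is large enough for downstream KS detection
        assert stats.ks_2samp(asg, other).pvalue < 1e-6
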