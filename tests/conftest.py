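from __future__ import annotations

import random

import pytest

from lecatrace.data_model import SUPERGROUPS, Taxon, TaxonRegistry
from lecatrace.pipeline import PipelineConfig, run_pipeline
from lecatrace.synthetic import default_config, generate_community

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(length: int, rng: random.Random) -> str:
    return "".join(rng.choice(AA) for _ in range(length))


@pytest.fixture(scope="session")
def small_registry() -> TaxonRegistry:
    """Three-domain toy registry: 6 eukaryotes (one per supergroup),
    2 bacteria of different genera, 2 archaea (one asgard)."""
    taxa = [
        Taxon(f"E{i}", f"euk{i}", "eukaryote", sg, f"Genus{i}")
        for i, sg in enumerate(SUPERGROUPS)
    ]
    taxa += [
        Taxon("B0", "bact0", "bacteria", "Proteobacteria", "Escherichia"),
        Taxon("B1", "bact1", "bacteria", "Firmicutes", "Bacillus"),
        Taxon("A0", "arch0", "archaea", "Crenarchaeota", "Sulfolobus"),
        Taxon("A1", "arch1", "archaea", "asgard", "Lokiarchaeum"),
    ]
    return TaxonRegistry(taxa)


@pytest.fixture(scope="session")
def default_community():
    """The standard synthetic community at seed 1 (registry, proteomes, truth)."""
    return generate_community(default_config(seed=1))


@pytest.fixture(scope="session")
def default_bundle():
    """One full pipeline run on the standard synthetic community, shared
    by the recovery/invariant tests (the expensive fixture)."""
    return run_pipeline(PipelineConfig(seed=1))
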