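import pytest

from mitobound.refstats import build_reference_statistics
from mitobound.synthetic import SimulationConfig, simulate_hits, simulate_reference_set

#: short-gene configuration for fast predictor tests (genomes ~1-2 kb)
SMALL_GENES = {"atp8": 55, "nad4l": 98, "nad3": 116}


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_species=40,
        seed=7,
        gene_lengths_aa=SMALL_GENES,
        trna_count=2,
        minus_strand_genes=frozenset({"nad3"}),
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    """(cfg, genomes, features, hits, stats) for a small simulated set."""
    genomes, features = simulate_reference_set(small_cfg)
    hits = simulate_hits(features, genomes, small_cfg)
    stats = build_reference_statistics(genomes, features)
    return small_cfg, genomes, features, hits, stats
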