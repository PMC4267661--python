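"""Shared fixtures: small synthetic datasets built once per session."""

import pytest

from gynngy.config import SimConfig
from gynngy.simulate import generate_genome_and_models, simulate_junction_reads


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset without decoys or read violations."""
    cfg = SimConfig(
        seed=11,
        n_genes=15,
        n_tissues=4,
        reads_per_site_per_tissue=40,
        fraction_as=0.6,
        fraction_regulated=0.3,
    )
    sim = generate_genome_and_models(cfg)
    return cfg, sim


@pytest.fixture(scope="session")
def small_sim_reads(small_sim, tmp_path_factory):
    """SAM files + emitted clean count table for the small dataset."""
    cfg, sim = small_sim
    out = tmp_path_factory.mktemp("sim_reads")
    sam_by_tissue, counts = simulate_junction_reads(cfg, sim, str(out))
    return cfg, sim, sam_by_tissue, counts


@pytest.fixture()
def toy_genome():
    """A hand-written two-contig genome for coordinate arithmetic tests."""
    #           0         1         2         3         4
    #           0123456789012345678901234567890123456789012345
    chr1 = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
    chr2 = "TTTTCCCCGGGGAAAATTTTCCCCGGGGAAAATTTTCCCCGGGGAAAA"
    return {"chr1": chr1, "chr2": chr2}
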