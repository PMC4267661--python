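"""Shared configuration of the analysis chain.

One master seed drives every stage; the simulation emulates a 16-tissue
bulk RNA-seq survey at moderate per-site depth so the whole chain runs
in minutes on one CPU.
"""

import pathlib

from gynngy.config import PipelineConfig, SimConfig

SEED = 1
RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"

SIM_CONFIG = SimConfig(
    seed=SEED,
    n_genes=40,
    exons_per_gene=(3, 5),
    n_tissues=16,
    reads_per_site_per_tissue=(40, 120),
    fraction_gynngy_donors=0.6,
    fraction_as=0.5,
    fraction_regulated=0.3,
    regulated_delta=0.4,
    fraction_strand_ambiguous_decoys=0.15,
    fraction_shift_ambiguous_decoys=0.25,
    anchor_violation_rate=0.05,
)

PIPE_CONFIG = PipelineConfig(
    seed=SEED,
    n_permutations=10_000,
    n_subsets=15,
    min_reads_per_tissue=10,
    fdr_threshold=0.01,
)
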