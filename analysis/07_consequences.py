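"""Coding consequences of AS at CDS tandem donors.

The 4-nt donor spacing makes the alternative isoform frameshifted; most
events are expected to introduce a premature stop in the immediately
downstream exon (the NMD-coupling route by which these events tune
expression rather than make new proteins).
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from common import PIPE_CONFIG, RESULTS  # noqa: E402

from gynngy.pipeline import run_consequences, run_summarize  # noqa: E402
from gynngy.summaries import GroupCounts  # noqa: E402


def main() -> None:
    cfg = PIPE_CONFIG
    cfg.genome = str(RESULTS / "sim" / "genome.fa")
    cfg.gene_models = str(RESULTS / "sim" / "models.gtf")
    path = run_consequences(
        cfg, str(RESULTS / "catalog.tsv"), str(RESULTS / "usage_profiles.tsv"), str(RESULTS)
    )
    cq = pd.read_csv(path, sep="\t")
    if cq.empty:
        print("no CDS AS sites to analyse")
        return
    print(f"{len(cq)} CDS AS sites analysed")
    print(f"  {GroupCounts('frameshift', int(cq.frameshift.sum()), len(cq), 0)}")
    print(f"  {GroupCounts('stop in next exon', int(cq.stop_next_exon.sum()), len(cq), 0)}")
    print("  decile occupancy:", cq.decile.value_counts().sort_index().to_dict())

    run_summarize(
        str(RESULTS / "catalog.tsv"),
        str(RESULTS / "regulation.tsv"),
        path,
        str(RESULTS / "ums_by_tissue.tsv"),
        str(RESULTS),
    )
    print("summary -> results/summary.txt")


if __name__ == "__main__":
    main()
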