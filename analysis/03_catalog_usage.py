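"""Catalog GYNNGY tandem donors, classify AS status and compute UMS.

Reports the AS proportion by region (the CDS-vs-UTR contrast that
separates the splicing-noise and regulation models) and the usage
profiles that feed the regulation test.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from common import PIPE_CONFIG, RESULTS  # noqa: E402

from gynngy.pipeline import run_catalog, run_usage  # noqa: E402
from gynngy.summaries import contingency_test, format_p, proportion_summary  # noqa: E402


def main() -> None:
    sim_dir = RESULTS / "sim"
    cfg = PIPE_CONFIG
    cfg.genome = str(sim_dir / "genome.fa")
    cfg.gene_models = str(sim_dir / "models.gtf")
    cat_path, counts_path = run_catalog(cfg, str(RESULTS / "junctions.tsv"), str(RESULTS))
    prof_path, _ = run_usage(counts_path, str(RESULTS))

    catalog = pd.read_csv(cat_path, sep="\t")
    print(f"{len(catalog)} GYNNGY sites, {int(catalog.as_flag.sum())} AS")
    assigned = catalog[catalog.region.isin(["CDS", "UTR"])]
    for gc in proportion_summary(assigned, "region", "as_flag"):
        print(f"  AS proportion, {gc}")
    if assigned.region.nunique() == 2:
        tab = [
            [
                int(((assigned.region == r) & assigned.as_flag).sum()),
                int(((assigned.region == r) & ~assigned.as_flag).sum()),
            ]
            for r in ("CDS", "UTR")
        ]
        chi2, p = contingency_test(tab)
        print(f"  CDS-vs-UTR AS chi-squared = {chi2:.2f}, p = {format_p(p)}")

    profiles = pd.read_csv(prof_path, sep="\t")
    print(f"usage profiles for {len(profiles)} sites; "
          f"median mean-UMS = {profiles.mean_ums.median():.3f}")


if __name__ == "__main__":
    main()
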