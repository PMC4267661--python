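"""Published count-table fixtures and their verification.

The published survey of GYNNGY tandem donors in human and mouse reports
its results as count tables with printed percentages (AS frequency by
region, regulation strength by region, splicing-status conservation by
class, protein-change categories).  The counts are shipped here as TSV
data files so the proportion machinery can be verified cell by cell:
every printed percentage must equal the half-up-rounded recomputation
from its own numerator and denominator.

The companion `printed_stats.tsv` records the published test statistics
for the same tables, including the one internal inconsistency (the
mouse AS-by-region chi-squared p is printed differently in the table
and in the text); both values are recorded without adjudication.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from gynngy.summaries import GroupCounts


def load_printed_tables() -> pd.DataFrame:
    """The published count tables, one row per printed percentage."""
    with resources.files("gynngy.data").joinpath("printed_tables.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_printed_stats() -> pd.DataFrame:
    """Published test statistics accompanying the count tables."""
    with resources.files("gynngy.data").joinpath("printed_stats.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def verify_printed_percentages(fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute every printed percentage from its counts.

    Returns the fixture with `recomputed` and `match` columns; a cell
    passes when the half-up-rounded recomputation equals the printed
    value exactly.
    """
    df = (load_printed_tables() if fixture is None else fixture).copy()
    recomputed = []
    for row in df.itertuples():
        gc = GroupCounts(
            label=row.cell,
            numerator=int(row.numerator),
            denominator=int(row.denominator),
            decimals=int(row.decimals),
        )
        recomputed.append(gc.proportion)
    df["recomputed"] = recomputed
    df["match"] = df["recomputed"] == df["printed_percent"]
    return df
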