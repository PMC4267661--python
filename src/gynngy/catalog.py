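"""GYNNGY tandem-donor catalog and minor-isoform usage (UMS).

A GYNNGY site is reported wherever a used donor sits at position 1 or 5
of a genomic 6-mer matching G[CT]NNG[CT] in transcript orientation; the
donor at position 1 is *distal*, the one at position 5 *proximal* (4 nt
downstream, lengthening the exon).  A site is alternatively spliced (AS)
when both donors carry at least `min_support` filtered reads summed over
tissues, constitutive otherwise.

UMS (usage of the minor splicing isoform) in a tissue is the minor-donor
read count over the total reads at the site; the minor donor is the one
with the lower unweighted mean usage across tissues with defined usage,
fixed across tissues even where it locally dominates.  Delta-UMS is the
max minus min UMS across tissues with defined UMS.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from gynngy.models import TranscriptModel
from gynngy.util import tx_fetch

logger = logging.getLogger(__name__)

GYNNGY_RE = re.compile(r"G[CT][ACGT][ACGT]G[CT]")


def is_gynngy(sixmer: str) -> bool:
    return len(sixmer) == 6 and bool(GYNNGY_RE.fullmatch(sixmer.upper()))


def _donor_context(genome, chrom: str, strand: str, donor: int, length: int = 6) -> str | None:
    """Transcript-oriented `length`-mer starting at the donor; None if it
    would run off the contig."""
    chrom_len = len(genome[chrom])
    if strand == "+":
        if donor + length > chrom_len:
            return None
        return tx_fetch(genome, chrom, strand, donor, donor + length)
    if donor - length + 1 < 0:
        return None
    return tx_fetch(genome, chrom, strand, donor - length + 1, donor + 1)


def _tx_offset(strand: str, pos: int, offset: int) -> int:
    """Genomic position `offset` nt downstream (transcript sense) of pos."""
    return pos + offset if strand == "+" else pos - offset


def find_gynngy_sites(
    junctions: pd.DataFrame,
    genome,
    gene_models: list[TranscriptModel] | None = None,
    min_support: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Catalog GYNNGY tandem donors from a strand-resolved junction table.

    `junctions` is the extraction output (shift-ambiguous rows are
    dropped here).  Returns (catalog, counts): one row per site with the
    6-mer, donor coordinates, region and AS flag; and a long table of
    per-tissue distal/proximal read counts.
    """
    usable = junctions[~junctions["ambiguous"]] if "ambiguous" in junctions else junctions
    # per-donor per-tissue usage, donor = first intronic base (tx sense)
    rows = usable.assign(
        donor=np.where(
            usable["strand"] == "+", usable["intron_start"], usable["intron_end"] - 1
        )
    )
    donor_counts = (
        rows.groupby(["chrom", "strand", "donor", "tissue"])["reads"].sum().to_dict()
    )
    donor_totals = rows.groupby(["chrom", "strand", "donor"])["reads"].sum().to_dict()
    tissues = sorted(usable["tissue"].unique())

    candidates: dict[tuple[str, str, int], str] = {}
    for chrom, strand, donor in donor_totals:
        for lag in (0, 4):  # donor at 6-mer position 1 (lag 0) or 5 (lag 4)
            distal = _tx_offset(strand, donor, -lag)
            ctx = _donor_context(genome, chrom, strand, distal)
            if ctx is None:
                logger.warning(
                    "donor %s:%s%d within 6 nt of contig end; skipped", chrom, strand, donor
                )
                continue
            if is_gynngy(ctx):
                candidates[(chrom, strand, distal)] = ctx

    cat_rows, count_rows = [], []
    for (chrom, strand, distal), sixmer in sorted(candidates.items()):
        proximal = _tx_offset(strand, distal, 4)
        distal_total = donor_totals.get((chrom, strand, distal), 0)
        proximal_total = donor_totals.get((chrom, strand, proximal), 0)
        as_flag = distal_total >= min_support and proximal_total >= min_support
        site_id = f"{chrom}:{strand}:{distal}"
        region = (
            annotate_region(chrom, strand, distal, gene_models)
            if gene_models is not None
            else "unassigned"
        )
        cat_rows.append(
            {
                "site_id": site_id,
                "chrom": chrom,
                "strand": strand,
                "distal_donor": distal,
                "proximal_donor": proximal,
                "sixmer": sixmer,
                "region": region,
                "as_flag": as_flag,
                "distal_total": distal_total,
                "proximal_total": proximal_total,
            }
        )
        for tissue in tissues:
            count_rows.append(
                {
                    "site_id": site_id,
                    "tissue": tissue,
                    "distal_reads": donor_counts.get((chrom, strand, distal, tissue), 0),
                    "proximal_reads": donor_counts.get(
                        (chrom, strand, proximal, tissue), 0
                    ),
                }
            )
    catalog = pd.DataFrame(
        cat_rows,
        columns=[
            "site_id",
            "chrom",
            "strand",
            "distal_donor",
            "proximal_donor",
            "sixmer",
            "region",
            "as_flag",
            "distal_total",
            "proximal_total",
        ],
    )
    counts = pd.DataFrame(
        count_rows, columns=["site_id", "tissue", "distal_reads", "proximal_reads"]
    )
    return catalog, counts


def annotate_region(
    chrom: str, strand: str, distal_donor: int, transcripts: list[TranscriptModel]
) -> str:
    """CDS / UTR / unassigned for the exonic side of the distal donor.

    Among transcripts whose exons contain the donor's exonic edge (the
    last exonic base upstream of the distal donor), the one with the
    longest CDS decides; a donor in no annotated transcript, or only in
    transcripts without a CDS, is 'unassigned'.
    """
    edge = _tx_offset(strand, distal_donor, -1)
    containing = [
        t
        for t in transcripts
        if t.chrom == chrom and t.strand == strand and t.contains(edge)
    ]
    coding = [t for t in containing if t.has_cds]
    if not coding:
        return "unassigned"
    best = max(coding, key=lambda t: t.cds_length())
    return "CDS" if best.cds_start <= edge < best.cds_end else "UTR"


def compute_ums(minor_reads: int, total_reads: int) -> float:
    """minor_reads / total_reads; NaN (undefined) when total is zero."""
    if minor_reads < 0 or total_reads < 0:
        raise ValueError("read counts must be non-negative")
    if minor_reads > total_reads:
        raise ValueError(
            f"minor_reads ({minor_reads}) exceeds total_reads ({total_reads})"
        )
    if total_reads == 0:
        return float("nan")
    return minor_reads / total_reads


def designate_minor_site(
    distal_usage: np.ndarray, proximal_usage: np.ndarray
) -> str | None:
    """Donor with the lower unweighted mean usage across defined tissues.

    The designation is fixed across tissues even if the minor donor
    dominates in some of them.  Exact tie -> proximal (the distal GY is
    the generally preferred donor).  All-undefined -> None.
    """
    d = np.asarray(distal_usage, dtype=float)
    p = np.asarray(proximal_usage, dtype=float)
    if np.all(np.isnan(d)):
        return None
    dm, pm = np.nanmean(d), np.nanmean(p)
    if pm <= dm:
        return "proximal"
    return "distal"


def compute_delta_ums(ums: np.ndarray) -> float:
    """max - min UMS over tissues with defined UMS (0 if only one)."""
    u = np.asarray(ums, dtype=float)
    u = u[~np.isnan(u)]
    if u.size == 0:
        return float("nan")
    return float(u.max() - u.min())


def usage_profiles(
    counts: pd.DataFrame, min_tissue_reads: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site usage profiles from the catalog's long count table.

    Tissues with fewer than `min_tissue_reads` total reads at a site have
    undefined UMS there.  Returns (profiles, ums_long): per-site minor
    designation with mean/max/delta UMS, and the per-tissue UMS values.
    Sites where usage is defined in no tissue are dropped (logged).
    """
    prof_rows, ums_rows = [], []
    for site_id, grp in counts.groupby("site_id", sort=True):
        total = (grp["distal_reads"] + grp["proximal_reads"]).to_numpy(float)
        defined = total >= max(1, min_tissue_reads)
        with np.errstate(invalid="ignore", divide="ignore"):
            d_usage = np.where(defined, grp["distal_reads"].to_numpy(float) / total, np.nan)
        p_usage = 1.0 - d_usage
        minor = designate_minor_site(d_usage, p_usage)
        if minor is None:
            logger.info("site %s has no tissue with defined usage; dropped", site_id)
            continue
        ums = d_usage if minor == "distal" else p_usage
        for tissue, u in zip(grp["tissue"], ums):
            ums_rows.append({"site_id": site_id, "tissue": tissue, "ums": u})
        prof_rows.append(
            {
                "site_id": site_id,
                "minor": minor,
                "mean_ums": float(np.nanmean(ums)),
                "max_ums": float(np.nanmax(ums)),
                "delta_ums": compute_delta_ums(ums),
                "n_defined_tissues": int(defined.sum()),
            }
        )
    profiles = pd.DataFrame(
        prof_rows,
        columns=["site_id", "minor", "mean_ums", "max_ums", "delta_ums", "n_defined_tissues"],
    )
    ums_long = pd.DataFrame(ums_rows, columns=["site_id", "tissue", "ums"])
    return profiles, ums_long
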