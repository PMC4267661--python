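"""Gene models and genome I/O.

Internally all coordinates are 0-based half-open genomic intervals;
1-based inclusive coordinates appear only at the GTF boundary.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field

import gffutils

from gynngy.util import fetch_seq, revcomp


@dataclass
class TranscriptModel:
    """A transcript: ordered exons plus an optional genomic CDS span."""

    chrom: str
    strand: str
    transcript_id: str
    gene_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int | None = None  # genomic span of the CDS, half-open
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)

    @property
    def has_cds(self) -> bool:
        return (
            self.cds_start is not None
            and self.cds_end is not None
            and self.cds_end > self.cds_start
        )

    def tx_exons(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def contains(self, gpos: int) -> bool:
        return any(s <= gpos < e for s, e in self.exons)

    def genomic_to_tx(self, gpos: int) -> int:
        """Transcript coordinate of an exonic genomic base."""
        offset = 0
        for s, e in self.tx_exons():
            if s <= gpos < e:
                return offset + (gpos - s if self.strand == "+" else e - 1 - gpos)
            offset += e - s
        raise ValueError(f"{gpos} is not exonic in {self.transcript_id}")

    def cds_tx_interval(self) -> tuple[int, int]:
        """CDS as a half-open interval in transcript coordinates."""
        if not self.has_cds:
            raise ValueError(f"{self.transcript_id} has no CDS")
        g_first = self.cds_start if self.strand == "+" else self.cds_end - 1
        g_last = self.cds_end - 1 if self.strand == "+" else self.cds_start
        lo = self.genomic_to_tx(g_first)
        hi = self.genomic_to_tx(g_last)
        return lo, hi + 1

    def cds_length(self) -> int:
        lo, hi = self.cds_tx_interval()
        return hi - lo

    def spliced_seq(self, genome) -> str:
        parts = [fetch_seq(genome, self.chrom, s, e) for s, e in self.exons]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_seq(self, genome) -> str:
        lo, hi = self.cds_tx_interval()
        return self.spliced_seq(genome)[lo:hi]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals (half-open), sorted by start."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def donor_positions(self) -> list[int]:
        """First intronic base of every donor, in genomic coordinates.

        On '+' this is the intron start; on '-' the intron's last base.
        """
        if self.strand == "+":
            return [s for s, _ in self.introns()]
        return [e - 1 for _, e in self.introns()]


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(str(genome[name]), width) + "\n")


def read_fasta(path: str) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


def write_gtf(transcripts: list[TranscriptModel], path: str) -> None:
    """Write gene/transcript/exon/CDS records (1-based inclusive)."""
    lines = []
    for tx in transcripts:
        attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
        g_start = min(s for s, _ in tx.exons) + 1
        g_end = max(e for _, e in tx.exons)
        lines.append(
            f"{tx.chrom}\tgynngy\ttranscript\t{g_start}\t{g_end}\t.\t{tx.strand}\t.\t{attrs}"
        )
        for s, e in tx.exons:
            lines.append(
                f"{tx.chrom}\tgynngy\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}"
            )
        if tx.has_cds:
            for s, e in tx.exons:
                cs, ce = max(s, tx.cds_start), min(e, tx.cds_end)
                if cs < ce:
                    lines.append(
                        f"{tx.chrom}\tgynngy\tCDS\t{cs + 1}\t{ce}\t.\t{tx.strand}\t.\t{attrs}"
                    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gtf(path: str) -> list[TranscriptModel]:
    """Parse transcript models from a GTF file via gffutils."""
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts = []
    for feat in db.features_of_type("transcript"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(feat, featuretype="exon", order_by="start")
        ]
        cds = [
            (c.start - 1, c.end)
            for c in db.children(feat, featuretype="CDS", order_by="start")
        ]
        transcripts.append(
            TranscriptModel(
                chrom=feat.seqid,
                strand=feat.strand,
                transcript_id=feat.attributes["transcript_id"][0],
                gene_id=feat.attributes["gene_id"][0],
                exons=exons,
                cds_start=min(s for s, _ in cds) if cds else None,
                cds_end=max(e for _, e in cds) if cds else None,
            )
        )
    return transcripts
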