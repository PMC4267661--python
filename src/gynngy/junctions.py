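"""Splice-junction extraction from spliced alignments.

Introns are recovered as N-gaps in the CIGAR of spliced reads; terminal
dinucleotides read from the genome decide the transcript strand for
non-strand-specific libraries (GT-AG / GC-AG / AT-AC forward, their
reverse complements on the opposite strand, anything else undetermined
and discarded).  Supporting reads must align perfectly, carry >= 6 nt
error-free anchors on both joined exons, and junctions whose placement
can slide (exon-terminal sequence equal to intron-terminal sequence) are
flagged ambiguous and excluded from all downstream counting.

Coordinates are 0-based half-open internally; 1-based only in TSV/BED
exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import pysam

from gynngy.util import fetch_seq, revcomp

FORWARD_PAIRS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
# reverse complements seen when the read maps to the non-coding strand
REVERSE_PAIRS = {(revcomp(a), revcomp(d)) for d, a in FORWARD_PAIRS}

ANCHOR = 6  # error-free exonic nucleotides required on each side


@dataclass
class JunctionRead:
    """One spliced read: aligned blocks plus alignment-error positions."""

    read_id: str
    chrom: str
    mapped_strand: str
    blocks: list[tuple[int, int]]  # reference intervals between N gaps
    mismatches: list[int] = field(default_factory=list)  # genomic positions
    indels: list[int] = field(default_factory=list)  # genomic positions
    mapq: int = 60

    def gaps(self) -> list[tuple[int, int]]:
        """Intron intervals implied by consecutive blocks."""
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]


def infer_transcript_strand(
    donor_dinuc: str, acceptor_dinuc: str, mapped_strand: str
) -> str | None:
    """Transcript strand from intron-terminal dinucleotides.

    ``donor_dinuc``/``acceptor_dinuc`` are the two intron-end 2-mers as
    read on the mapped strand.  Canonical pairs assign the mapped strand,
    their reverse complements the opposite strand; anything else (incl.
    N-containing dinucleotides) returns None (undetermined).
    """
    pair = (donor_dinuc.upper(), acceptor_dinuc.upper())
    other = {"+": "-", "-": "+"}
    if pair in FORWARD_PAIRS:
        return mapped_strand
    if pair in REVERSE_PAIRS:
        return other[mapped_strand]
    return None


def filter_junction_read(
    read: JunctionRead, junction: tuple[int, int], anchor: int = ANCHOR
) -> tuple[bool, str | None]:
    """Apply the three read-support filters to one junction of a read.

    (i) the read aligns perfectly (no mismatches or indels anywhere),
    (ii) it has >= `anchor` nucleotides on both joined exons and
    (iii) no mismatches or indels within those anchor nucleotides.

    Checked in the order ii, iii, i so the reported reason names the most
    specific violated criterion.  Returns (True, None) on pass.
    """
    start, end = junction
    left = next((b for b in read.blocks if b[1] == start), None)
    right = next((b for b in read.blocks if b[0] == end), None)
    if left is None or right is None:
        raise ValueError(f"read {read.read_id} does not span junction {junction}")
    if (left[1] - left[0]) < anchor or (right[1] - right[0]) < anchor:
        return False, "ii"
    anchor_zone = lambda p: (start - anchor <= p < start) or (end <= p < end + anchor)
    if any(anchor_zone(p) for p in read.mismatches + read.indels):
        return False, "iii"
    if read.mismatches or read.indels:
        return False, "i"
    return True, None


def detect_shift_ambiguity(
    genome, chrom: str, intron_start: int, intron_end: int, max_shift: int = 10
) -> bool:
    """True if the intron can slide by 1..max_shift nt with an identical
    spliced product.

    Sliding right by s keeps the product iff the first s intronic bases
    equal the first s bases of the downstream exon; sliding left iff the
    last s exonic bases equal the last s intronic bases.  Shifts that run
    past a contig end are treated as non-shiftable in that direction.
    """
    chrom_len = len(genome[chrom])
    for s in range(1, max_shift + 1):
        if intron_end + s <= chrom_len and fetch_seq(
            genome, chrom, intron_start, intron_start + s
        ) == fetch_seq(genome, chrom, intron_end, intron_end + s):
            return True
        if intron_start - s >= 0 and fetch_seq(
            genome, chrom, intron_start - s, intron_start
        ) == fetch_seq(genome, chrom, intron_end - s, intron_end):
            return True
    return False


def _read_to_junction_read(aln, genome) -> JunctionRead | None:
    """Convert a pysam alignment into a JunctionRead (None if unspliced)."""
    if aln.is_unmapped or aln.cigartuples is None:
        return None
    blocks: list[tuple[int, int]] = []
    mismatches: list[int] = []
    indels: list[int] = []
    rpos = aln.reference_start
    qpos = 0
    block_start = rpos
    seq = aln.query_sequence or ""
    chrom = aln.reference_name
    for op, length in aln.cigartuples:
        if op in (0, 7, 8):  # M, =, X consume both
            if seq:
                ref = fetch_seq(genome, chrom, rpos, rpos + length)
                for k in range(length):
                    if seq[qpos + k].upper() != ref[k]:
                        mismatches.append(rpos + k)
            rpos += length
            qpos += length
        elif op == 1:  # insertion to reference
            indels.append(rpos)
            qpos += length
        elif op == 2:  # deletion from reference
            indels.extend(range(rpos, rpos + length))
            rpos += length
        elif op == 3:  # N: splice gap closes the current block
            blocks.append((block_start, rpos))
            rpos += length
            block_start = rpos
        elif op == 4:  # soft clip: never counts toward anchors
            qpos += length
        # H/P consume nothing we track
    blocks.append((block_start, rpos))
    if len(blocks) < 2:
        return None
    return JunctionRead(
        read_id=aln.query_name,
        chrom=chrom,
        mapped_strand="-" if aln.is_reverse else "+",
        blocks=blocks,
        mismatches=mismatches,
        indels=indels,
        mapq=aln.mapping_quality,
    )


def parse_spliced_alignments(sam_path: str, genome) -> list[JunctionRead]:
    """All spliced reads of one SAM file, with per-read error positions.

    Raises if the SAM references a sequence absent from the genome.
    """
    reads = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for ref in sam.references:
            if ref not in genome:
                raise KeyError(f"reference {ref!r} in {sam_path} absent from genome")
        for aln in sam:
            jr = _read_to_junction_read(aln, genome)
            if jr is not None:
                reads.append(jr)
    return reads


def _junction_strand_and_dinucs(
    genome, chrom: str, start: int, end: int
) -> tuple[str | None, str, str]:
    """Transcript strand plus transcript-oriented terminal dinucleotides."""
    left = fetch_seq(genome, chrom, start, start + 2)
    right = fetch_seq(genome, chrom, end - 2, end)
    strand = infer_transcript_strand(left, right, "+")
    if strand == "+" or strand is None:
        return strand, left, right
    return "-", revcomp(right), revcomp(left)


def extract_junction_counts(
    sam_by_tissue: dict[str, str],
    genome,
    strand_specific: bool = False,
    max_shift: int = 10,
    anchor: int = ANCHOR,
) -> pd.DataFrame:
    """Filtered, strand-resolved per-tissue junction counts.

    Returns a tidy table (chrom, strand, intron_start, intron_end,
    donor_dinuc, acceptor_dinuc, tissue, reads, ambiguous).  Reads whose
    transcript strand cannot be determined contribute to no junction;
    shift-ambiguous junctions are flagged and must be excluded from all
    downstream counting.
    """
    counts: dict[tuple, int] = {}
    for tissue, path in sam_by_tissue.items():
        for read in parse_spliced_alignments(path, genome):
            for gap in read.gaps():
                ok, _ = filter_junction_read(read, gap, anchor=anchor)
                if not ok:
                    continue
                start, end = gap
                if strand_specific:
                    strand = read.mapped_strand
                else:
                    strand, _, _ = _junction_strand_and_dinucs(
                        genome, read.chrom, start, end
                    )
                if strand is None:
                    continue
                key = (read.chrom, strand, start, end, tissue)
                counts[key] = counts.get(key, 0) + 1
    rows = []
    ambiguity_cache: dict[tuple, bool] = {}
    for (chrom, strand, start, end, tissue), n in sorted(counts.items()):
        jkey = (chrom, start, end)
        if jkey not in ambiguity_cache:
            ambiguity_cache[jkey] = detect_shift_ambiguity(
                genome, chrom, start, end, max_shift=max_shift
            )
        left = fetch_seq(genome, chrom, start, start + 2)
        right = fetch_seq(genome, chrom, end - 2, end)
        donor = left if strand == "+" else revcomp(right)
        acceptor = right if strand == "+" else revcomp(left)
        rows.append(
            {
                "chrom": chrom,
                "strand": strand,
                "intron_start": start,
                "intron_end": end,
                "donor_dinuc": donor,
                "acceptor_dinuc": acceptor,
                "tissue": tissue,
                "reads": n,
                "ambiguous": ambiguity_cache[jkey],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "strand",
            "intron_start",
            "intron_end",
            "donor_dinuc",
            "acceptor_dinuc",
            "tissue",
            "reads",
            "ambiguous",
        ],
    )


def junction_table_to_tsv(table: pd.DataFrame, path: str) -> None:
    """Write the junction table with 1-based donor/acceptor positions."""
    out = table.copy()
    plus = out["strand"] == "+"
    out["donor_pos_1based"] = (out["intron_start"] + 1).where(plus, out["intron_end"])
    out["acceptor_pos_1based"] = out["intron_end"].where(plus, out["intron_start"] + 1)
    cols = [
        "chrom",
        "strand",
        "donor_pos_1based",
        "acceptor_pos_1based",
        "donor_dinuc",
        "acceptor_dinuc",
        "tissue",
        "reads",
        "ambiguous",
    ]
    out[cols].to_csv(path, sep="\t", index=False)


def junction_table_from_tsv(path: str) -> pd.DataFrame:
    """Read a junction TSV back into the internal 0-based representation."""
    out = pd.read_csv(path, sep="\t")
    plus = out["strand"] == "+"
    out["intron_start"] = (out["donor_pos_1based"] - 1).where(
        plus, out["acceptor_pos_1based"] - 1
    )
    out["intron_end"] = out["acceptor_pos_1based"].where(plus, out["donor_pos_1based"])
    return out.drop(columns=["donor_pos_1based", "acceptor_pos_1based"])


def junctions_to_bed12(table: pd.DataFrame, path: str, flank: int = 10) -> None:
    """BED12 export of distinct junctions (blocks = `flank`-nt anchors)."""
    seen = table.drop_duplicates(["chrom", "strand", "intron_start", "intron_end"])
    with open(path, "w") as fh:
        for _, row in seen.iterrows():
            s = int(row.intron_start) - flank
            e = int(row.intron_end) + flank
            name = f"{row.chrom}:{row.intron_start}-{row.intron_end}"
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            row.chrom,
                            max(0, s),
                            e,
                            name,
                            0,
                            row.strand,
                            max(0, s),
                            e,
                            0,
                            2,
                            f"{flank},{flank}",
                            f"0,{int(row.intron_end) + flank - max(0, s) - flank}",
                        ],
                    )
                )
                + "\n"
            )
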