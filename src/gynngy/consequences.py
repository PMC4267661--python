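"""Coding consequences of tandem-donor alternative splicing.

Using the proximal instead of the distal donor lengthens the upstream
exon by the 4 nt between the donors; 4 mod 3 = 1, so inside a CDS the
alternative isoform is frameshifted unless a downstream alternative
acceptor restores the frame.  The frameshifted isoform typically meets
a premature stop codon; when that stop falls in the exon immediately
downstream of the affected junction the event is counted as
stop-codon-introducing (a canonical nonsense-mediated-decay trigger).

Isoform sequences here run from the annotated start codon to the end of
the transcript so that frameshifted translation can continue past the
annotated stop; the standard nuclear genetic code applies throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Seq import Seq

from gynngy.models import TranscriptModel
from gynngy.util import tx_fetch

STOPS = {"TAA", "TAG", "TGA"}
CATEGORY_LT10 = "change_lt_10aa"
CATEGORY_GT10 = "change_gt_10aa"
CATEGORY_FRAMESHIFT = "frameshift"


@dataclass
class IsoformPair:
    """Both splice variants of one tandem site on one transcript.

    Sequences start at the annotated start codon and extend to the end
    of the transcript; `boundaries_*` are the exon-junction offsets in
    those coordinates, and `junction_*` the offset at which the affected
    junction sits in each variant (the proximal variant carries the 4-nt
    inter-donor insertion just before it).
    """

    transcript_id: str
    cds_distal: str
    cds_proximal: str
    boundaries_distal: list[int]
    boundaries_proximal: list[int]
    junction_distal: int
    junction_proximal: int
    annotated_cds_length: int


def build_isoform_pair(
    transcript: TranscriptModel, distal_donor: int, genome
) -> IsoformPair:
    """Construct the distal- and proximal-donor isoforms of a CDS site.

    The transcript's annotation is taken to use the distal donor; the
    proximal variant inserts the 4 intron-start bases at the affected
    junction.  Raises if the site is not inside the transcript's CDS
    (UTR sites have no coding consequence and are handled elsewhere).
    """
    if not transcript.has_cds:
        raise ValueError(f"{transcript.transcript_id} has no annotated CDS")
    donors = transcript.donor_positions()
    if distal_donor not in donors:
        raise ValueError(
            f"donor {distal_donor} is not a junction of {transcript.transcript_id}"
        )
    # exon-boundary offsets in spliced-transcript coordinates
    tx_exons = transcript.tx_exons()
    cum = []
    total = 0
    for s, e in tx_exons:
        total += e - s
        cum.append(total)
    boundaries_tx = cum[:-1]
    if transcript.strand == "+":
        junction_index = [e for _, e in tx_exons[:-1]].index(distal_donor)
    else:
        junction_index = [s - 1 for s, _ in tx_exons[:-1]].index(distal_donor)
    pj_tx = boundaries_tx[junction_index]

    clo, chi = transcript.cds_tx_interval()
    edge_tx = pj_tx - 1  # last exonic base before the donor
    if not (clo <= edge_tx < chi):
        raise ValueError(
            f"site at donor {distal_donor} lies outside the CDS of "
            f"{transcript.transcript_id}; treat as UTR"
        )
    spliced = transcript.spliced_seq(genome)
    insert = tx_fetch(
        genome,
        transcript.chrom,
        transcript.strand,
        *(
            (distal_donor, distal_donor + 4)
            if transcript.strand == "+"
            else (distal_donor - 3, distal_donor + 1)
        ),
    )
    cds_distal = spliced[clo:]
    cds_proximal = spliced[clo:pj_tx] + insert + spliced[pj_tx:]
    rel = lambda b: b - clo
    b_dist = [rel(b) for b in boundaries_tx if b > clo]
    b_prox = [rel(b) + (4 if b >= pj_tx else 0) for b in boundaries_tx if b > clo]
    return IsoformPair(
        transcript_id=transcript.transcript_id,
        cds_distal=cds_distal,
        cds_proximal=cds_proximal,
        boundaries_distal=b_dist,
        boundaries_proximal=b_prox,
        junction_distal=rel(pj_tx),
        junction_proximal=rel(pj_tx) + 4,
        annotated_cds_length=chi - clo,
    )


def detect_premature_stop(
    cds: str,
    boundaries: list[int],
    junction_pos: int,
    annotated_stop: int | None = None,
) -> bool:
    """True iff translation from the start codon meets a stop codon
    within the exon immediately downstream of the affected junction.

    `boundaries` are exon-junction offsets within `cds`; the downstream
    exon spans [junction_pos, next boundary) (or to the sequence end for
    a last exon).  A stop at `annotated_stop` is the transcript's normal
    terminator and never counts as premature.
    """
    later = [b for b in boundaries if b > junction_pos]
    exon_end = min(later) if later else len(cds)
    for i in range(0, len(cds) - 2, 3):
        if cds[i : i + 3].upper() in STOPS:
            if annotated_stop is not None and i == annotated_stop:
                return False
            # translation terminates at the first stop; the event counts
            # only if that stop sits in the downstream exon
            return junction_pos <= i < exon_end
    return False


def first_stop_in_interval(cds: str, start: int, end: int) -> bool:
    """Any in-frame stop codon whose first base lies in [start, end)."""
    return any(
        cds[i : i + 3].upper() in STOPS
        for i in range(0, len(cds) - 2, 3)
        if start <= i < end
    )


def _translate_to_stop(cds: str) -> str:
    aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate(to_stop=True))
    return aa


def classify_protein_change(
    pair: IsoformPair, downstream_acceptor_shifts: list[int] | None = None
) -> str:
    """Protein-change category of the proximal (insertion) variant.

    `downstream_acceptor_shifts` lists annotated alternative acceptors
    of the immediately downstream exon, as the number of nucleotides
    each trims from that exon's start in the proximal variant (4 means
    the acceptor moves 4 nt into the exon, cancelling the donor's 4-nt
    insertion).  If some shift restores the frame (net edit a multiple
    of 3), both isoforms are translated and the number of differing
    amino acids decides the category; otherwise the event is a
    frameshift.
    """
    shifts = downstream_acceptor_shifts or []
    for shift in shifts:
        if (4 - shift) % 3 != 0:
            continue
        j = pair.junction_proximal
        recovered = pair.cds_proximal[:j] + pair.cds_proximal[j + shift :]
        aa_ref = _translate_to_stop(pair.cds_distal)
        aa_alt = _translate_to_stop(recovered)
        n_diff = sum(
            1 for a, b in zip(aa_ref, aa_alt) if a != b
        ) + abs(len(aa_ref) - len(aa_alt))
        return CATEGORY_LT10 if n_diff < 10 else CATEGORY_GT10
    return CATEGORY_FRAMESHIFT


def relative_cds_position(
    chrom: str,
    strand: str,
    distal_donor: int,
    transcripts: list[TranscriptModel],
) -> tuple[float, int]:
    """Relative CDS position of a site and its decile bin (1..10).

    Distance is measured in spliced (CDS) coordinates from the start
    codon to the distal donor's exonic edge, divided by the CDS length
    of the longest-CDS transcript containing the site.
    """
    edge = distal_donor - 1 if strand == "+" else distal_donor + 1
    coding = [
        t
        for t in transcripts
        if t.chrom == chrom and t.strand == strand and t.has_cds and t.contains(edge)
    ]
    if not coding:
        raise ValueError(f"no coding transcript contains donor {chrom}:{strand}:{distal_donor}")
    best = max(coding, key=lambda t: t.cds_length())
    clo, chi = best.cds_tx_interval()
    pos = best.genomic_to_tx(edge)
    if not (clo <= pos < chi):
        raise ValueError(f"donor {distal_donor} not inside the CDS of {best.transcript_id}")
    fraction = (pos - clo) / (chi - clo)
    decile = min(10, max(1, math.ceil(fraction * 10)))
    return fraction, decile


def consequence_record(
    transcript: TranscriptModel,
    distal_donor: int,
    genome,
    minor: str = "proximal",
    downstream_acceptor_shifts: list[int] | None = None,
) -> dict:
    """Full consequence annotation of one CDS site.

    The premature-stop scan runs on the minor isoform; a separate flag
    reports stops in the affected exon's extended tail (the 4 inserted
    bases and the remainder of that exon), a region outside the
    canonical next-exon rule.
    """
    pair = build_isoform_pair(transcript, distal_donor, genome)
    stop_d = pair.annotated_cds_length - 3  # annotated terminator offset
    if minor == "proximal":
        cds, bounds, j = pair.cds_proximal, pair.boundaries_proximal, pair.junction_proximal
        stop_p = stop_d + (4 if stop_d >= pair.junction_distal else 0)
        stop_next = detect_premature_stop(cds, bounds, j, annotated_stop=stop_p)
    else:
        # the distal variant is the annotated isoform: its only stop is
        # the annotated one, which is never premature
        cds, bounds, j = pair.cds_distal, pair.boundaries_distal, pair.junction_distal
        stop_next = False
    stop_tail = first_stop_in_interval(cds, max(0, j - 4), j)
    category = classify_protein_change(pair, downstream_acceptor_shifts)
    fraction, decile = relative_cds_position(
        transcript.chrom, transcript.strand, distal_donor, [transcript]
    )
    return {
        "transcript_id": pair.transcript_id,
        "frameshift": category == CATEGORY_FRAMESHIFT,
        "stop_next_exon": stop_next,
        "stop_affected_tail": stop_tail,
        "category": category,
        "rel_pos": fraction,
        "decile": decile,
    }
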