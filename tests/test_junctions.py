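"""Strand inference, read filters, shift ambiguity, SAM parsing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gynngy.junctions import (
    JunctionRead,
    detect_shift_ambiguity,
    extract_junction_counts,
    filter_junction_read,
    infer_transcript_strand,
    junction_table_from_tsv,
    junction_table_to_tsv,
    parse_spliced_alignments,
)
from gynngy.util import revcomp


@pytest.mark.parametrize(
    "donor, acceptor, mapped, expected",
    [
        ("GT", "AG", "+", "+"),
        ("GC", "AG", "+", "+"),
        ("AT", "AC", "+", "+"),
        ("GT", "AG", "-", "-"),
        ("CT", "AC", "+", "-"),  # revcomp of GT-AG
        ("CT", "GC", "+", "-"),  # revcomp of GC-AG
        ("GT", "AT", "+", "-"),  # revcomp of AT-AC
        ("CT", "AC", "-", "+"),
        ("AA", "TT", "+", None),
        ("GT", "AA", "+", None),
        ("NT", "AG", "+", None),
    ],
)
def test_strand_inference(donor, acceptor, mapped, expected):
    assert infer_transcript_strand(donor, acceptor, mapped) == expected


def _read(blocks, mismatches=(), indels=()):
    return JunctionRead(
        read_id="r1",
        chrom="chr1",
        mapped_strand="+",
        blocks=list(blocks),
        mismatches=list(mismatches),
        indels=list(indels),
    )


class TestReadFilters:
    def test_perfect_read_with_long_anchors_passes(self):
        ok, reason = filter_junction_read(_read([(92, 100), (200, 212)]), (100, 200))
        assert ok and reason is None

    def test_short_anchor_fails_criterion_ii(self):
        ok, reason = filter_junction_read(_read([(95, 100), (200, 212)]), (100, 200))
        assert not ok and reason == "ii"

    def test_mismatch_inside_anchor_fails_criterion_iii(self):
        read = _read([(90, 100), (200, 212)], mismatches=[97])  # 3 nt from junction
        ok, reason = filter_junction_read(read, (100, 200))
        assert not ok and reason == "iii"

    def test_mismatch_outside_anchor_fails_criterion_i(self):
        read = _read([(90, 100), (200, 212)], mismatches=[91])
        ok, reason = filter_junction_read(read, (100, 200))
        assert not ok and reason == "i"

    def test_indel_in_anchor_fails_criterion_iii(self):
        read = _read([(90, 100), (200, 212)], indels=[203])
        ok, reason = filter_junction_read(read, (100, 200))
        assert not ok and reason == "iii"


class TestShiftAmbiguity:
    def test_matching_exon_tail_and_intron_tail_permits_shift(self):
        # exon ends ...AG and intron ends ...AG with matching upstream
        # context: sliding the intron left by 2 keeps the product
        genome = {"c": "TTTTTCAGGTAAAACAGTTTTTTT"}
        #                exon...^ intron [8,17) = GTAAAACAG; left 2:
        #                genome[6:8]='AG' == genome[15:17]='AG'
        assert detect_shift_ambiguity(genome, "c", 8, 17, max_shift=5)

    def test_unique_junction_is_not_ambiguous(self):
        genome = {"c": "TTTTTCAAGTCCCCCAGTTTTTTT"}
        # intron [8,17): no prefix/suffix self-match within 5
        assert not detect_shift_ambiguity(genome, "c", 8, 17, max_shift=5)

    def test_three_nt_duplication_detected_by_resplicing(self):
        # exon tail 'CAG' duplicated at the intron end: sliding the
        # intron left by 3 re-splices to the identical product
        exon = "TTTTTCAG"
        intron = "GTTTTCAG"  # last 3 intronic == last 3 exonic
        seq = exon + intron + "AAAAAAAA"
        genome = {"c": seq}
        d, a = 8, 16
        # brute-force check that the shifted placement is equivalent
        assert seq[:d] + seq[a:] == seq[: d - 3] + seq[a - 3 :]
        assert detect_shift_ambiguity(genome, "c", d, a, max_shift=3)

    def test_contig_end_is_nonshiftable(self):
        genome = {"c": "GTAAAG"}
        # intron is the whole contig: no room to slide either way
        assert not detect_shift_ambiguity(genome, "c", 0, 6, max_shift=4)

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=30, max_size=60), st.data())
    def test_agrees_with_brute_force_resplicing(self, seq, data):
        """Oracle: re-splice at every shifted intron placement and
        compare the joined exon products directly."""
        start = data.draw(st.integers(8, len(seq) - 16))
        end = data.draw(st.integers(start + 4, len(seq) - 8))
        genome = {"c": seq}
        max_shift = 5

        def spliced(s, e):
            return seq[:s] + seq[e:]

        oracle = any(
            spliced(start + d, end + d) == spliced(start, end)
            for d in range(-max_shift, max_shift + 1)
            if d != 0 and start + d >= 0 and end + d <= len(seq)
        )
        assert detect_shift_ambiguity(genome, "c", start, end, max_shift) == oracle


class TestParsing:
    def test_two_block_read_yields_one_junction(self, small_sim_reads, tmp_path):
        import pysam

        header = {"SQ": [{"SN": "chr1", "LN": 48}]}
        genome = {"chr1": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"}
        path = str(tmp_path / "r.sam")
        with pysam.AlignmentFile(path, "wh", header=header) as sam:
            a = pysam.AlignedSegment()
            a.query_name = "spliced"
            a.reference_id = 0
            a.reference_start = 2
            a.cigartuples = [(0, 8), (3, 20), (0, 8)]
            a.query_sequence = genome["chr1"][2:10] + genome["chr1"][30:38]
            sam.write(a)
            b = pysam.AlignedSegment()
            b.query_name = "unspliced"
            b.reference_id = 0
            b.reference_start = 0
            b.cigartuples = [(0, 16)]
            b.query_sequence = genome["chr1"][0:16]
            sam.write(b)
        reads = parse_spliced_alignments(path, genome)
        assert len(reads) == 1  # the unspliced read yields no junction
        assert reads[0].gaps() == [(10, 30)]
        assert reads[0].mismatches == []

    def test_read_spanning_two_introns_yields_two_junctions(self):
        read = _read([(0, 10), (50, 60), (100, 110)])
        assert read.gaps() == [(10, 50), (60, 100)]

    def test_reference_mismatch_is_hard_error(self, tmp_path):
        import pysam

        path = str(tmp_path / "bad.sam")
        with pysam.AlignmentFile(
            path, "wh", header={"SQ": [{"SN": "chrX", "LN": 100}]}
        ) as sam:
            pass
        with pytest.raises(KeyError, match="chrX"):
            parse_spliced_alignments(path, {"chr1": "ACGT" * 30})


class TestExtraction:
    def test_counts_match_simulator_exactly(self, small_sim_reads):
        """Round-trip identity: extracted filtered counts equal the
        simulator's emitted clean counts row for row."""
        cfg, sim, sam_by_tissue, emitted = small_sim_reads
        extracted = extract_junction_counts(sam_by_tissue, sim.genome)
        key = ["chrom", "strand", "intron_start", "intron_end", "tissue"]
        ext = (
            extracted[~extracted.ambiguous][key + ["reads"]]
            .sort_values(key)
            .reset_index(drop=True)
        )
        emi = emitted[key + ["reads"]].sort_values(key).reset_index(drop=True)
        assert ext.equals(emi)

    def test_extraction_is_idempotent(self, small_sim_reads):
        cfg, sim, sam_by_tissue, _ = small_sim_reads
        one = extract_junction_counts(sam_by_tissue, sim.genome)
        two = extract_junction_counts(sam_by_tissue, sim.genome)
        assert one.equals(two)

    def test_tsv_round_trip_preserves_coordinates(self, small_sim_reads, tmp_path):
        cfg, sim, sam_by_tissue, _ = small_sim_reads
        table = extract_junction_counts(sam_by_tissue, sim.genome)
        path = str(tmp_path / "junctions.tsv")
        junction_table_to_tsv(table, path)
        back = junction_table_from_tsv(path)
        for col in ("chrom", "strand", "intron_start", "intron_end", "reads"):
            assert list(back[col]) == list(table[col])


def test_strand_decoys_and_violations_are_excluded(tmp_path):
    """Junctions with non-canonical terminal dinucleotides contribute no
    counts, anchor-violating reads are filtered, and deliberately
    shift-ambiguous junctions are flagged."""
    from gynngy.config import SimConfig
    from gynngy.simulate import generate_genome_and_models, simulate_junction_reads

    cfg = SimConfig(
        seed=7,
        n_genes=12,
        n_tissues=3,
        reads_per_site_per_tissue=25,
        fraction_strand_ambiguous_decoys=0.5,
        fraction_shift_ambiguous_decoys=0.5,
        anchor_violation_rate=0.3,
    )
    sim = generate_genome_and_models(cfg)
    assert sim.strand_decoys and any(s.decoy_shift for s in sim.sites)
    sams, emitted = simulate_junction_reads(cfg, sim, str(tmp_path))
    extracted = extract_junction_counts(sams, sim.genome)

    decoy_keys = {(c, s, e) for c, s, e in sim.strand_decoys}
    found = set(
        zip(extracted.chrom, extracted.intron_start, extracted.intron_end)
    )
    assert not decoy_keys & found, "undetermined-strand junctions were counted"

    for site in sim.sites:
        if not site.decoy_shift:
            continue
        gi = sim.genomic_intron(site)
        rows = extracted[
            (extracted.chrom == site.chrom)
            & (extracted.intron_start == gi[0])
            & (extracted.intron_end == gi[1])
        ]
        assert rows.empty or rows.ambiguous.all()

    key = ["chrom", "strand", "intron_start", "intron_end", "tissue"]
    ext = (
        extracted[~extracted.ambiguous][key + ["reads"]]
        .sort_values(key)
        .reset_index(drop=True)
    )
    emi = emitted[key + ["reads"]].sort_values(key).reset_index(drop=True)
    assert ext.equals(emi)
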