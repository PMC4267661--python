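"""Synthetic tandem-donor data generator.

Builds a toy genome of single-transcript multi-exon genes whose introns
start GT/GC and end AG, places GYNNGY 6-mers (two candidate donors 4 nt
apart) at a configured fraction of donors, and simulates per-tissue
spliced reads: at every AS site the proximal-donor read count in tissue
t is Binomial(n_t, theta_t).  Regulated sites follow a two-level step
profile across tissues (span = the configured delta-UMS target),
unregulated AS sites keep theta constant, and noise sites use a constant
near-zero theta.  Optional decoys exercise the extraction filters:
junction reads with non-canonical terminal dinucleotides (undetermined
strand), deliberately shift-ambiguous junctions, and reads violating the
anchor rules.

Genes are constructed so that no genuine junction is shift-ambiguous:
the transcript base on each side of every junction point is never 'G',
which makes both the 1-nt and therefore every longer slide impossible
for distal and proximal introns alike.  The emitted count table records
exactly the clean (filter-passing, non-decoy) reads, so junction
extraction recovers it verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from gynngy.config import SimConfig
from gynngy.models import TranscriptModel, write_fasta, write_gtf
from gynngy.util import revcomp

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES if a + b + c not in STOPS]

CLASS_REGULATED = "regulated"
CLASS_UNREGULATED_AS = "unregulated_as"
CLASS_CONSTITUTIVE = "constitutive"
CLASS_NOISE = "noise"


@dataclass
class SimSite:
    """One donor site of the toy genome, in gene-layout coordinates."""

    site_id: str
    gene: str
    chrom: str
    strand: str
    layout_intron: tuple[int, int]  # distal intron, layout orientation
    sixmer: str | None  # None for non-GYNNGY donors
    cls: str
    region: str
    theta: np.ndarray  # per-tissue proximal-donor usage
    decoy_shift: bool = False
    left_avail: int = 0  # exonic nt upstream of the distal donor
    right_avail: int = 0  # exonic nt downstream of the acceptor

    @property
    def is_gynngy(self) -> bool:
        return self.sixmer is not None


@dataclass
class SimData:
    """Everything the generator knows: genome, models and ground truth."""

    config: SimConfig
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    sites: list[SimSite]
    strand_decoys: list[tuple[str, int, int]] = field(default_factory=list)
    chrom_len: dict[str, int] = field(default_factory=dict)

    @property
    def tissues(self) -> list[str]:
        return [f"t{i + 1:02d}" for i in range(self.config.n_tissues)]

    def genomic_intron(self, site: SimSite, donor: str = "distal") -> tuple[int, int]:
        """Genomic interval of the site's (distal|proximal) intron."""
        d, a = site.layout_intron
        if donor == "proximal":
            d += 4
        if site.strand == "+":
            return d, a
        length = self.chrom_len[site.chrom]
        return length - a, length - d

    def ground_truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            gi = self.genomic_intron(s)
            row = {
                "site_id": s.site_id,
                "gene": s.gene,
                "chrom": s.chrom,
                "strand": s.strand,
                "intron_start": gi[0],
                "intron_end": gi[1],
                "sixmer": s.sixmer or "",
                "class": s.cls,
                "region": s.region,
                "decoy_shift": s.decoy_shift,
            }
            for t, th in zip(self.tissues, s.theta):
                row[f"theta_{t}"] = th
            rows.append(row)
        return pd.DataFrame(rows)


def _rand_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _draw_theta(cfg: SimConfig, cls: str, rng) -> np.ndarray:
    """Per-tissue proximal-donor usage for one site."""
    T = cfg.n_tissues
    if cls == CLASS_CONSTITUTIVE:
        return np.zeros(T)
    if cls == CLASS_NOISE:
        theta = np.full(T, rng.uniform(*cfg.noise_ums_range))
    elif cls == CLASS_UNREGULATED_AS:
        theta = np.full(T, rng.uniform(0.1, 0.5))
    elif cls == CLASS_REGULATED:
        low_max = max(0.021, min(0.3, 0.95 - cfg.regulated_delta))
        low = rng.uniform(0.02, low_max)
        theta = np.full(T, low)
        high_tissues = rng.permutation(T)[: T // 2]
        theta[high_tissues] = low + cfg.regulated_delta
    else:  # pragma: no cover
        raise ValueError(cls)
    if rng.uniform() < 0.3:  # sometimes the proximal donor is the major one
        theta = 1.0 - theta
    return theta


def _assign_class(cfg: SimConfig, is_gynngy: bool, rng) -> str:
    if not is_gynngy or rng.uniform() >= cfg.fraction_as:
        return CLASS_CONSTITUTIVE
    if rng.uniform() < cfg.fraction_regulated:
        return CLASS_REGULATED
    # remaining AS sites: half genuine unregulated AS, half splicing noise
    return CLASS_UNREGULATED_AS if rng.uniform() < 0.5 else CLASS_NOISE


def _gynngy_sixmer(rng) -> str:
    """A G[CT]NNG[CT] 6-mer whose proximal donor can never slide left.

    Position 4 (the second N) is kept != G so the proximal intron's 1-nt
    left shift is impossible (its last exonic base would have to match
    the intron-terminal G).
    """
    y1, y2 = rng.choice(["C", "T"]), rng.choice(["C", "T"])
    n1 = rng.choice(list(BASES))
    n2 = rng.choice(["A", "C", "T"])
    return f"G{y1}{n1}{n2}G{y2}"


def _plain_donor_sixmer(rng) -> str:
    """An intron-start 6-mer that does not match G[CT]NNG[CT]."""
    y = rng.choice(["C", "T"])
    while True:
        tail = _rand_seq(rng, 2)
        if not (tail[0] == "G" and tail[1] in "CT"):
            return f"G{y}" + _rand_seq(rng, 2) + tail


def _pick_junction_positions(rng, length: int, k: int, min_exon: int, tx: str) -> list[int]:
    """k junction points inside the transcript, >= min_exon apart.

    A junction at p splits between tx[p-1] and tx[p]; neither flanking
    base may be 'G' (that is what rules out shift ambiguity).
    """
    candidates = [
        p
        for p in range(min_exon, length - min_exon)
        if tx[p] != "G" and tx[p - 1] != "G"
    ]
    for _ in range(200):
        picks = sorted(rng.choice(len(candidates), size=k, replace=False))
        pos = [candidates[i] for i in picks]
        if all(b - a >= min_exon for a, b in zip(pos, pos[1:])):
            return pos
    raise RuntimeError("could not place junctions; transcript too short")


def generate_genome_and_models(config: SimConfig):
    """Build the toy genome, gene models and ground-truth skeleton.

    Deterministic for a fixed seed.  Returns a SimData bundle; use
    write_simulation() to materialise FASTA/GTF/TSV files.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    genome: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    sites: list[SimSite] = []
    strand_decoys: list[tuple[str, int, int]] = []
    chrom_len: dict[str, int] = {}
    min_exon = max(40, config.read_length - 6)

    for g in range(config.n_genes):
        chrom = f"chr{g + 1}"
        gene_id = f"gene{g + 1}"
        strand = "+" if rng.uniform() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))

        # spliced transcript: 5'UTR + ATG + stop-free codons + TAA + 3'UTR
        u5 = int(rng.integers(40, 81))
        n_codons = int(rng.integers(50, 91))
        u3 = int(rng.integers(60, 121))
        cds = "ATG" + "".join(rng.choice(_CODONS, size=n_codons)) + "TAA"
        tx = _rand_seq(rng, u5) + cds + _rand_seq(rng, u3)
        junctions = _pick_junction_positions(rng, len(tx), n_exons - 1, min_exon, tx)

        # per-intron site plan
        plan = []
        for j, p in enumerate(junctions):
            is_gynngy = rng.uniform() < config.fraction_gynngy_donors
            cls = _assign_class(config, is_gynngy, rng)
            sixmer = _gynngy_sixmer(rng) if is_gynngy else None
            decoy_shift = (
                not is_gynngy
                and cls == CLASS_CONSTITUTIVE
                and rng.uniform() < config.fraction_shift_ambiguous_decoys
            )
            plan.append([p, is_gynngy, cls, sixmer, decoy_shift])

        # shift-ambiguous decoys duplicate the intron head ('GT') into the
        # start of the downstream exon so the junction can slide; skip the
        # decoy if the exon edit would write a stop codon into the CDS
        for item in plan:
            p, _, _, _, decoy_shift = item
            if not decoy_shift:
                continue
            mutated = tx[:p] + "GT" + tx[p + 2 :]
            new_cds = mutated[u5 : u5 + len(cds)]
            internal_stops = any(
                new_cds[i : i + 3] in STOPS for i in range(0, len(new_cds) - 3, 3)
            )
            if internal_stops:
                item[4] = False
            else:
                tx = mutated

        # assemble layout: flank + exon1 + intron1 + ... + exonK + flank
        flank5, flank3 = _rand_seq(rng, 60), _rand_seq(rng, 60)
        layout_parts = [flank5]
        exon_layout: list[tuple[int, int]] = []
        cursor = len(flank5)
        prev_tx = 0
        site_records = []
        for j, (p, is_gynngy, cls, sixmer, decoy_shift) in enumerate(plan):
            exon_seq = tx[prev_tx:p]
            layout_parts.append(exon_seq)
            exon_layout.append((cursor, cursor + len(exon_seq)))
            cursor += len(exon_seq)
            d = cursor  # first intronic base (distal donor), layout coords
            intron_len = int(rng.integers(80, 141))
            head = sixmer if is_gynngy else _plain_donor_sixmer(rng)
            if decoy_shift:
                # the downstream exon was edited to start 'GT' like the
                # intron, so this canonical junction slides right
                head = "GT" + head[2:]
            filler = _rand_seq(rng, intron_len - 8)
            intron_seq = head + filler + "AG"
            if rng.uniform() < config.fraction_strand_ambiguous_decoys:
                # reserve a non-canonical sub-intron (AA...TT) inside the
                # filler; reads over it have undetermined strand
                off = 15
                dlen = max(30, intron_len // 2)
                dlen = min(dlen, intron_len - 30)
                s0 = d + off
                intron_seq = (
                    intron_seq[:off]
                    + "AA"
                    + intron_seq[off + 2 : off + dlen - 2]
                    + "TT"
                    + intron_seq[off + dlen :]
                )
                strand_decoys.append((chrom, strand, s0, s0 + dlen))
            layout_parts.append(intron_seq)
            cursor += len(intron_seq)
            theta = _draw_theta(config, cls, rng)
            region = "CDS" if u5 <= p - 1 < u5 + len(cds) else "UTR"
            site_records.append(
                SimSite(
                    site_id=f"{gene_id}_j{j + 1}",
                    gene=gene_id,
                    chrom=chrom,
                    strand=strand,
                    layout_intron=(d, d + len(intron_seq)),
                    sixmer=sixmer,
                    cls=cls,
                    region=region,
                    theta=theta,
                    decoy_shift=decoy_shift,
                    left_avail=len(exon_seq),
                    right_avail=min(
                        (junctions[j + 1] - p) if j + 1 < len(junctions) else len(tx) - p,
                        10**9,
                    ),
                )
            )
            prev_tx = p
        last_exon = tx[prev_tx:]
        layout_parts.append(last_exon)
        exon_layout.append((cursor, cursor + len(last_exon)))
        cursor += len(last_exon)
        layout_parts.append(flank3)
        layout_seq = "".join(layout_parts)

        # CDS span in layout coordinates (transcript is contiguous in tx
        # space; map its CDS interval through the exon blocks)
        cds_lo_tx, cds_hi_tx = u5, u5 + len(cds)
        tx_off = 0
        cds_lo_layout = cds_hi_layout = None
        for (es, ee) in exon_layout:
            elen = ee - es
            if tx_off <= cds_lo_tx < tx_off + elen:
                cds_lo_layout = es + (cds_lo_tx - tx_off)
            if tx_off < cds_hi_tx <= tx_off + elen:
                cds_hi_layout = es + (cds_hi_tx - tx_off)
            tx_off += elen

        L = len(layout_seq)
        if strand == "+":
            genome[chrom] = layout_seq
            exons = exon_layout
            cds_span = (cds_lo_layout, cds_hi_layout)
        else:
            genome[chrom] = revcomp(layout_seq)
            exons = [(L - e, L - s) for s, e in exon_layout]
            cds_span = (L - cds_hi_layout, L - cds_lo_layout)
        chrom_len[chrom] = L
        transcripts.append(
            TranscriptModel(
                chrom=chrom,
                strand=strand,
                transcript_id=f"tx{g + 1}",
                gene_id=gene_id,
                exons=exons,
                cds_start=cds_span[0],
                cds_end=cds_span[1],
            )
        )
        sites.extend(site_records)

    # fix up strand decoy coordinates for minus-strand genes
    fixed_decoys = []
    for chrom, strand, s0, s1 in strand_decoys:
        if strand == "+":
            fixed_decoys.append((chrom, s0, s1))
        else:
            L = chrom_len[chrom]
            fixed_decoys.append((chrom, L - s1, L - s0))
    return SimData(
        config=config,
        genome=genome,
        transcripts=transcripts,
        sites=sites,
        strand_decoys=fixed_decoys,
        chrom_len=chrom_len,
    )


def _emit_read(
    sam, header_ids, sim: SimData, chrom: str, intron: tuple[int, int],
    left_len: int, read_len: int, name: str, violation: str | None, rng
):
    """Write one spliced read over `intron` with a `left_len` genomic
    left anchor; `violation` in {None, 'short', 'mismatch'}."""
    gs, ge = intron
    if violation == "short":
        left_len = 5
    right_len = read_len - left_len
    seq = (
        sim.genome[chrom][gs - left_len : gs] + sim.genome[chrom][ge : ge + right_len]
    )
    nm = 0
    if violation == "mismatch":
        k = left_len - 3  # 3 nt from the junction, inside the 6-nt anchor
        orig = seq[k]
        sub = {"A": "C", "C": "A", "G": "T", "T": "G"}[orig]
        seq = seq[:k] + sub + seq[k + 1 :]
        nm = 1
    a = pysam.AlignedSegment()
    a.query_name = name
    a.flag = 0
    a.reference_id = header_ids[chrom]
    a.reference_start = gs - left_len
    a.mapping_quality = 50
    a.cigartuples = [(0, left_len), (3, ge - gs), (0, right_len)]
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    a.set_tag("NM", nm)
    sam.write(a)


def simulate_junction_reads(
    config: SimConfig, sim: SimData, out_dir: str, write_sam: bool = True
):
    """Simulate per-tissue spliced alignments and the clean count table.

    Writes one SAM per tissue under `out_dir` and returns
    (sam_by_tissue, counts) where `counts` lists the filter-passing,
    non-decoy junction reads per tissue — i.e. exactly what junction
    extraction should recover.  With ``write_sam=False`` only the count
    table is produced (read-level details are skipped), which is the
    cheap path for deep-coverage simulations.
    """
    import os

    if not write_sam:
        return {}, _simulate_counts_only(config, sim)

    rng = np.random.default_rng([config.seed, 2])
    os.makedirs(out_dir, exist_ok=True)
    tissues = sim.tissues
    read_len = config.read_length
    v = config.anchor_violation_rate

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(sim.genome[c])} for c in sim.genome],
    }
    header_ids = {c: i for i, c in enumerate(sim.genome)}

    count_rows = []
    sam_by_tissue = {}
    for ti, tissue in enumerate(tissues):
        path = os.path.join(out_dir, f"{tissue}.sam")
        sam_by_tissue[tissue] = path
        with pysam.AlignmentFile(path, "wh", header=header) as sam:
            serial = 0
            for site in sim.sites:
                n_t = config.draw_depth(rng)
                theta = float(site.theta[ti])
                n_prox = int(rng.binomial(n_t, theta)) if site.is_gynngy else 0
                for donor, n_reads in (("distal", n_t - n_prox), ("proximal", n_prox)):
                    if n_reads == 0:
                        continue
                    gi = sim.genomic_intron(site, donor)
                    # exonic room on each genomic side of the junction; the
                    # proximal donor extends the upstream exon by 4 nt
                    extra = 4 if donor == "proximal" else 0
                    if site.strand == "+":
                        lav, rav = site.left_avail + extra, site.right_avail
                    else:
                        lav, rav = site.right_avail, site.left_avail + extra
                    lo = max(6, read_len - min(rav, read_len))
                    hi = min(read_len - 6, lav)
                    clean = 0
                    for _ in range(n_reads):
                        left_len = int(rng.integers(lo, hi + 1))
                        violation = None
                        if v > 0 and rng.uniform() < v:
                            violation = "short" if rng.uniform() < 0.5 else "mismatch"
                        else:
                            clean += 1
                        serial += 1
                        _emit_read(
                            sam, header_ids, sim, site.chrom, gi, left_len,
                            read_len, f"{site.site_id}_{donor}_{tissue}_{serial}",
                            violation, rng,
                        )
                    if clean > 0 and not site.decoy_shift:
                        count_rows.append(
                            {
                                "chrom": site.chrom,
                                "strand": site.strand,
                                "intron_start": gi[0],
                                "intron_end": gi[1],
                                "tissue": tissue,
                                "reads": clean,
                            }
                        )
            # strand-undetermined decoy junctions: a few reads each
            for chrom, ds, de in sim.strand_decoys:
                for _ in range(3):
                    serial += 1
                    _emit_read(
                        sam, header_ids, sim, chrom, (ds, de),
                        int(rng.integers(8, read_len - 8)), read_len,
                        f"decoy_{chrom}_{ds}_{tissue}_{serial}", None, rng,
                    )
    counts = pd.DataFrame(
        count_rows,
        columns=["chrom", "strand", "intron_start", "intron_end", "tissue", "reads"],
    )
    counts = (
        counts.groupby(
            ["chrom", "strand", "intron_start", "intron_end", "tissue"], as_index=False
        )["reads"]
        .sum()
        .sort_values(["chrom", "strand", "intron_start", "intron_end", "tissue"])
        .reset_index(drop=True)
    )
    return sam_by_tissue, counts


def _simulate_counts_only(config: SimConfig, sim: SimData) -> pd.DataFrame:
    """Count-table-only path: per-donor clean reads are binomial draws
    (depth split by theta, thinned by the anchor-violation rate)."""
    rng = np.random.default_rng([config.seed, 2])
    v = config.anchor_violation_rate
    rows = []
    for tissue_idx, tissue in enumerate(sim.tissues):
        for site in sim.sites:
            n_t = config.draw_depth(rng)
            theta = float(site.theta[tissue_idx])
            n_prox = int(rng.binomial(n_t, theta)) if site.is_gynngy else 0
            for donor, n_reads in (("distal", n_t - n_prox), ("proximal", n_prox)):
                if n_reads == 0:
                    continue
                clean = int(rng.binomial(n_reads, 1.0 - v)) if v > 0 else n_reads
                if clean > 0 and not site.decoy_shift:
                    gi = sim.genomic_intron(site, donor)
                    rows.append(
                        {
                            "chrom": site.chrom,
                            "strand": site.strand,
                            "intron_start": gi[0],
                            "intron_end": gi[1],
                            "tissue": tissue,
                            "reads": clean,
                        }
                    )
    counts = pd.DataFrame(
        rows,
        columns=["chrom", "strand", "intron_start", "intron_end", "tissue", "reads"],
    )
    return (
        counts.groupby(
            ["chrom", "strand", "intron_start", "intron_end", "tissue"], as_index=False
        )["reads"]
        .sum()
        .sort_values(["chrom", "strand", "intron_start", "intron_end", "tissue"])
        .reset_index(drop=True)
    )


def counts_to_site_table(sim: SimData, counts: pd.DataFrame) -> pd.DataFrame:
    """Long per-site distal/proximal count table straight from the
    simulator's junction counts (catalog-compatible schema)."""
    idx = {}
    for site in sim.sites:
        if not site.is_gynngy:
            continue
        idx[(site.chrom, *sim.genomic_intron(site, "distal"))] = (site.site_id, "distal_reads")
        idx[(site.chrom, *sim.genomic_intron(site, "proximal"))] = (site.site_id, "proximal_reads")
    acc: dict[tuple[str, str], dict[str, int]] = {}
    for row in counts.itertuples():
        hit = idx.get((row.chrom, row.intron_start, row.intron_end))
        if hit is None:
            continue
        site_id, col = hit
        acc.setdefault((site_id, row.tissue), {})[col] = row.reads
    rows = [
        {
            "site_id": site_id,
            "tissue": tissue,
            "distal_reads": cols.get("distal_reads", 0),
            "proximal_reads": cols.get("proximal_reads", 0),
        }
        for (site_id, tissue), cols in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows, columns=["site_id", "tissue", "distal_reads", "proximal_reads"]
    )


def write_simulation(sim: SimData, out_dir: str) -> dict[str, str]:
    """Write FASTA, GTF and ground-truth TSV; returns the paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, "genome.fa"),
        "gtf": os.path.join(out_dir, "models.gtf"),
        "truth": os.path.join(out_dir, "ground_truth.tsv"),
    }
    write_fasta(sim.genome, paths["fasta"])
    write_gtf(sim.transcripts, paths["gtf"])
    sim.ground_truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
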