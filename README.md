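# gynngy — alternative splicing at GYNNGY tandem 5′ splice sites

A GYNNGY (Y = C or T) is a 6-mer at an intron start that contains two
usable 5′ splice sites 4 nt apart: the **distal** donor at position 1
and the **proximal** donor at position 5. Because 4 mod 3 = 1, choosing
the proximal donor inside a coding region shifts the reading frame —
most such events introduce a premature stop codon in the next exon and
couple splicing to nonsense-mediated decay (NMD) instead of making a
new protein. The central scientific question is whether alternative
splicing (AS) at these tandem donors is *regulation* or *splicing
noise*; the discriminating signal is tissue-dependent variation in
isoform usage.

This package is a tested re-implementation of that analysis for
transcriptomicists working from spliced RNA-seq alignments:

- **junction extraction** — introns from N-gapped CIGARs; transcript
  strand from terminal dinucleotides (GT-AG / GC-AG / AT-AC forward,
  reverse complements opposite, others discarded); reads must align
  perfectly with ≥ 6 error-free nt on both joined exons; junctions
  whose placement can slide (exon-terminal = intron-terminal sequence)
  are excluded as ambiguous.
- **tandem catalog & UMS** — a site is AS when both donors carry
  filtered reads. Usage of the minor splicing isoform per tissue is
  `UMS_t = minor reads / total reads`; the minor donor is the one with
  the lower unweighted mean usage across tissues, and
  `ΔUMS = max_t UMS_t − min_t UMS_t` is the effect size.
- **regulation test** — per site, a 2 × T table (donors × tissues with
  ≥ 10 reads) is scored with Pearson's χ²; the null distribution comes
  from shuffles preserving both margins (sampled as a multivariate
  hypergeometric in O(T) per permutation), `p = M/N` with M the number
  of permuted χ² strictly above the observed. Benjamini–Hochberg FDR,
  then classes: strong (ΔUMS ≥ 0.25), medium [0.1, 0.25), weak
  [0.05, 0.1), very weak (< 0.05) at FDR ≤ 0.01, else unregulated.
- **tissue-subsampling extrapolation** — the strongly regulated
  proportion as a function of tissue count k, fitted with
  `y = a + b·exp(c·x)` and `y = a·x/(b + x)` and compared by AIC
  (`n·log(RSS/n) + 2k`); the asymptote `a` is the inferred upper bound.
- **donor scoring** — 9-mers (3 exonic + 6 intronic nt) scored by a
  weight-matrix model and a first-order Markov model trained on
  constitutive donors (log₂ odds, uniform background, pseudocount 0.5);
  |ΔSS| between the two donors of a site, plus consensus matrices.
- **coding consequences** — in-silico re-splicing of both isoforms,
  premature-stop detection in the exon immediately downstream of the
  affected junction, frame-recovery classification through annotated
  alternative acceptors, and relative CDS position deciles.
- **synthetic data** — a generator that emulates the statistical
  structure the analysis assumes: canonical GT/GC–AG introns, GYNNGY
  donors at a configured rate, per-tissue proximal-donor counts drawn
  `Binomial(n_t, θ_t)` with step-profile θ for regulated sites,
  constant θ for unregulated AS, near-zero θ for noise, plus
  strand-ambiguous decoy junctions, deliberately shift-ambiguous
  junctions and anchor-violating reads to exercise every filter.

Published count tables of the human/mouse GYNNGY survey ship as data
fixtures (`gynngy.tables`) and every printed percentage is verified
against the package's own proportion machinery.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a
simulated 16-tissue survey (seed 1, 40 genes) and write their tables
under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_extract_junctions.py
python analysis/03_catalog_usage.py
python analysis/04_test_regulation.py
python analysis/05_extrapolate_tissues.py
python analysis/06_score_sites.py
python analysis/07_consequences.py
python analysis/08_verify_printed_tables.py
```

Output of the chain (abridged):

```
site classes: {'constitutive': 91, 'regulated': 12, 'unregulated_as': 11, 'noise': 9}
round-trip identity with simulator counts: True
95 GYNNGY sites, 32 AS
32 testable sites of 32
classes: {'unregulated': 20, 'strong': 12}
power (regulated called strong): 1.00 on 12 sites
false strong calls on constant-usage sites: 0.000 on 20 sites
inferred upper bound of the strongly regulated proportion: 0.376 (model 1)
stop in next exon: 18/26 = 69.0%
30/30 printed percentages recompute exactly
```

Reading this: junction extraction reproduces the simulator's clean
counts exactly despite injected decoys; all 12 truly regulated sites
(usage step 0.4) are recovered as *strong* while none of the 31
constant-usage AS sites is; the saturation fit's asymptote (0.376)
matches the true regulated fraction among testable sites (12/32); and
69 % of coding AS sites put a stop codon in the next exon, the
NMD-coupling signature.

The same pipeline is available as a CLI
(`gynngy simulate|extract|catalog|usage|test|extrapolate|score|consequences|summarize|all`),
e.g. `gynngy all --seed 5 --out results/demo`.

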