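# Methods

## The model

At a GYNNGY tandem 5′ splice site, reads supporting each donor in a
tissue are modelled as a binomial split of the site's junction reads:
the proximal-donor count in tissue *t* is `Binomial(n_t, θ_t)`, where
θ_t is the proximal usage. The analysis asks, per site, whether θ is
constant across tissues. The test conditions on both margins of the
2 × T donor-by-tissue table: under the null that reads are
exchangeable across tissues and isoforms, the first row of the table
follows a multivariate hypergeometric distribution given the row and
column totals. The permutation test samples from exactly that law
(column-by-column hypergeometric draws, O(T) per permutation rather
than relabelling individual reads) and compares Pearson χ² values;
`p = M/N` counts permuted statistics *strictly* above the observed
value, as stated in the original description of the procedure. An
optional `(M+1)/(N+1)` correction is available behind a flag (off by
default) for settings where `p = 0` is unacceptable. The tests verify
the estimator against exhaustive enumeration of the conditional law on
2 × 2 and 2 × 3 tables.

UMS (usage of the minor splicing isoform) is minor-donor reads over
total site reads in a tissue; the minor donor is fixed per site as the
one with the lower unweighted mean usage across tissues with defined
usage (ties go to the proximal donor, the generally disfavoured one).
UMS is undefined — not zero — in tissues with no reads at the site.
ΔUMS = max − min of the defined per-tissue UMS values; for
classification it is computed within the tissues that pass the
depth rule (≥ 10 reads), the same table the test uses.

## Tunable parameters

| parameter | default | role |
| --- | --- | --- |
| `min_support` | 1 read/donor | AS status requires both donors supported |
| `min_reads_per_tissue` | 10 | tissue inclusion in the 2 × T test table |
| `n_permutations` | 100 000 | permutation rounds (tests/scripts scale down) |
| `fdr_threshold` | 0.01 | regulated vs unregulated cut |
| `delta_bins` | 0.05 / 0.1 / 0.25 | very-weak/weak/medium/strong ΔUMS bins |
| `max_shift` | 10 nt | shift-ambiguity scan range (covers the 4-nt tandem spacing) |
| `anchor` | 6 nt | error-free exonic nucleotides required per side |
| `window` | 50 nt | downstream-intron conservation profile width |
| pseudocount | 0.5 | donor-model smoothing; uniform 0.25 background, log₂ |

Read filters are checked in the order anchors (ii), anchor errors
(iii), whole-read perfection (i) so the reported failure names the most
specific violated criterion. "Perfectly matched" is read strictly: no
mismatches or indels anywhere in the read, with mapper quality tags
treated only as a proxy. Soft-clipped bases never count toward
anchors.

## Shift ambiguity

A junction is ambiguous if moving the intron by 1..`max_shift` nt
yields an identical spliced product: sliding right by s requires the
first s intronic bases to equal the first s bases of the downstream
exon; sliding left requires the last s exonic bases to equal the last s
intronic bases. A consequence of comparing products is that ambiguity
at any s implies ambiguity at s = 1 (prefix/suffix equality nests), so
the detector is equivalent to a brute-force re-splice comparison — a
property test checks exactly that equivalence. Junctions within
`max_shift` of a contig end are non-shiftable in that direction.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not real transcriptomes. Each gene is one contig: a spliced transcript
(5′UTR, stop-free random CDS, 3′UTR) with introns inserted at junction
points, GT/GC-AG terminal dinucleotides throughout, and a GYNNGY 6-mer
at a configured fraction of donors. Usage profiles by class:

- **regulated** — two-level step: θ low in half the tissues, low + Δ in
  the other half (Δ = `regulated_delta`, default 0.4). The step is the
  simplest profile with a controllable ΔUMS; real tissue profiles are
  unknown and presumably richer.
- **unregulated AS** — constant θ drawn from [0.1, 0.5].
- **noise** — constant θ from `noise_ums_range` (default 0.005–0.05),
  matching the picture of low, unregulated minor usage. The
  config deliberately has no separate noise fraction: non-regulated AS
  sites split evenly between the two classes.
- **constitutive** — θ = 0. In ~30 % of AS sites the profile is
  reflected (θ → 1 − θ) so the proximal donor is the major one.

Junction neighbourhoods are constructed so no genuine junction is
shift-ambiguous: the transcript base on either side of every junction
point is never G, which blocks the 1-nt slide and therefore every
longer one (see above for why the shifts nest). Decoys are then added
deliberately: strand-ambiguous sub-introns (AA...TT termini, so the
transcript strand is undeterminable in non-strand-specific mode),
shift-ambiguous junctions (the downstream exon start is edited to
duplicate the intron's GT head, skipped if the edit would write a stop
codon into the CDS), and anchor-violating reads (short anchor or a
mismatch 3 nt from the junction). The emitted count table records
exactly the clean, non-decoy reads, so junction extraction must
reproduce it verbatim — the round-trip identity holds by construction
even with decoys enabled, and the tests assert it.

One RNG stream per stage, all derived from the master seed; outputs
are byte-identical for a fixed seed. Alignments are emitted
strand-nonspecific by default (flag for strand-specific mode). The
generator does not model sequencing errors, quality strings, paired
ends or expression-level variation beyond per-site depth — passing
tests therefore demonstrate correctness of the counting and inference
machinery, not robustness to alignment artefacts absent from the
simulation.

## Numerical choices

- Percentages round half away from zero at the printed precision
  (Python's built-in `round` is banker's rounding and would disagree on
  exact halves).
- Pearson χ² uses no continuity correction anywhere; cells with zero
  expectation cannot arise in testable tables (column sums ≥ 10, both
  row sums > 0 — a zero row sum means the site is not AS among the
  included tissues and is reported untestable).
- Strict `>` comparisons of permuted χ² use a relative tolerance of
  1e-12 so floating-point ties do not count as exceedances.
- Per-site permutation seeds derive from the master seed plus a CRC32
  of the site id, so results are reproducible under any execution
  order.
- AIC is `n·log(RSS/n) + 2k` (Gaussian residuals, σ profiled out);
  model 1 needs ≥ 4 distinct x values and c < 0 for a finite
  asymptote; non-convergence raises with diagnostics rather than
  falling back silently.
- Amino-acid change counts compare translations position-wise plus the
  length difference; an insertion therefore counts every displaced
  downstream residue, which is the conservative reading for the
  <10 / ≥10 split.
- The premature-stop scan reports the *first* in-frame stop of the
  minor isoform and asks whether it lies in the exon immediately
  downstream of the affected junction; the annotated terminator is
  never premature, and stops in the affected exon's extended tail are
  reported under a separate flag. An event whose first stop falls
  beyond the next exon is not counted (a deliberate undercount — stops
  in further downstream exons are outside the canonical rule).

## Design choices where the design was open

- Region annotation (CDS/UTR) uses the transcript with the longest CDS
  containing the donor's exonic edge, uniformly across analyses.
- Overlapping patterns (GYNNGYNNGY) yield two sites sharing a donor;
  downstream tables deduplicate by donor pair.
- Frame-recovery classification consults only annotated alternative
  acceptors of the immediately downstream exon.
- Tissue subsampling averages the strong proportion over random
  k-subsets (default 100/k; the analysis scripts use 15 and the
  acceptance script 6 to keep runtimes in minutes); k = T uses the
  single full subset and reproduces the full analysis exactly.
- Mean UMS is an unweighted tissue mean over tissues with ≥ 1 read
  (configurable), not a read-weighted mean.

## Problem sizes

The bundled analysis chain simulates 40 genes × 16 tissues at 40–120
reads per site per tissue with 10 000 permutations (2 000 within the
subsampling curve); the acceptance script uses the same survey with
5 000 permutations and 1 000 within the curve, plus a 500-site null
calibration at 10 000 permutations. These sizes give stable headline
numbers (binomial standard errors a few percent) while the whole chain
runs in a few minutes on one CPU; all of them scale up linearly via
configuration if tighter Monte-Carlo error is wanted.

## Known limitations

- The permutation p-value resolution is 1/N; FDR calls near the 0.01
  threshold need N well above 10³.
- Strict-`>` counting makes p slightly anti-conservative on tables
  with large conditional ties (e.g. perfectly uniform tables); the
  add-one flag is the remedy where that matters.
- The consequence module assumes the annotation uses the distal donor
  (true of the generator; real annotations can prefer the proximal
  one, in which case "insertion" and "deletion" swap roles).
- Conservation profiles, motif enrichment and orthology summaries
  consume externally produced tracks/hit calls/orthology tables; the
  package computes the statistics, not the alignments behind them.
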