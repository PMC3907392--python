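# Methods

This note documents the models and procedures `bsmeth` implements, the
parameters that matter, what the simulators do and do not emulate, and
the numerical choices made where the design was open.

## Three-letter alignment and the discard rules

Reads from a directional library are reduced to a three-letter
alphabet (T-rich reads C→T, A-rich reads G→A) and each read is searched
against exactly the two placements legitimate for its richness: the
converted read against the C→T reference (reporting Watson cytosines)
and its reverse complement against the G→A reference (reporting Crick
cytosines), with the roles of the two patterns swapped for A-rich
reads. Every record carries the read re-expressed along Watson
coordinates, so counting and mismatch restoration read straight off the
unconverted reference.

The built-in aligner is an exhaustive seeded Hamming search: k+1
disjoint 12-mer seeds guarantee (pigeonhole) that every placement with
≤ k mismatches is found whenever the read is at least 12·(k+1) bp.
Default k = 3; mapq is 40 for unique best hits and 0 otherwise.  It is
intended for genomes up to ~1 Mb; larger runs go through an external
aligner via the SAM adapter (`write_sam`/`read_sam`, with XR/XC/XH/XM
audit tags).

Post-alignment filtering, in order:

1. multi-hits (`n_hits > 1`);
2. wrong-strand hits — for a strand-specific library a T-rich read must
   have aligned against a C→T-converted strand and an A-rich read
   against a G→A-converted strand;
3. reads retaining C over a reference T (A-rich mirror: G over A),
   which cannot derive from a bisulfite-converted fragment at that
   locus.  One offending base discards the read (the rule is stated
   absolutely); `max_ct_mismatch` relaxes it for noisy data;
4. optional PCR-duplicate removal keyed on (chrom, leftmost position,
   strand) — plus mate span when known — keeping the record with the
   highest summed base quality, ties to the lexicographically smaller
   read id, which makes the result independent of input order.

Replaced read positions with base quality above Q (default 5) are
"marked" and carried as SAM tags for audit only; they do not influence
counting.

## Methylation calling

Counting is strand-separated: a plus-strand site lives at a Watson C
(informative bases C/T), a minus-strand site at a Watson G (informative
G/A); other bases do not enter *n*. Contexts are CG, CHG, CHH (H = A,
C, T), with CN for flanks that contain N or run off the contig.
Strands are never merged.

The null model is *m* ~ Binomial(*n*, *p*) with *p* the probability of
reading C at an unmethylated cytosine (non-conversion plus sequencing
error). *p* is estimated from the Lambda spike-in as
(#C)/(#C + #T) over its reference cytosines, strand-aware; without a
covered spike-in the user must supply *p*. The one-sided upper-tail
p-value is computed through the regularized incomplete beta function
(exact to machine precision; an enumeration oracle in the test suite
confirms agreement to 1e-12 for all m ≤ n ≤ 30 over a grid of p).
Benjamini–Hochberg runs over all covered sites; a site is called iff
q < FDR (strict), FDR default 0.01. Uncovered sites are excluded from
the BH family and keep missing p/q.

RRBS mode masks the artifactual cytosine filled in during end repair
of MspI fragments. The source text says only that the terminus effect
is eliminated, so the interpretation is isolated in one function
(`rrbs_end_repair_mask`): for a Watson-strand fragment the fill-in C is
taken as the second C of the 3'-terminal CCGG (mirror position for
Crick), masked only when the read actually covers it. The 5' read
start (the genuine C of the fragment-start CGG) is never masked. With
36-bp reads on ≥40-bp fragments the mask is usually empty.

## Annotation

* **Genic profile** — each *called* mC gets at most one label among
  upstream / first exon / first intron / internal exons / internal
  introns / last exon / downstream (strand-oriented; flanks default
  2000 bp). Gene-body labels take precedence over flanks; the first
  matching gene in genomic order wins. Single-exon genes contribute
  only "first exon"; two-exon genes have no internal categories.
* **Methylated CpG islands** — 200-bp windows stepping 1 bp must pass
  all of: GC > 0.5, CpG obs/exp > 0.6 (Gardiner–Garden
  N_CpG·L/(N_C·N_G)), and coverage-weighted CG level > 0.7. Overlapping
  passing windows merge, and the merged interval must itself pass all
  four criteria (preventing threshold dilution at the edges); merged
  intervals that fail are dropped. The scan is cumulative-sum based
  and independent of chromosome order.
* **Island region stats** — one label per island by midpoint, with
  precedence promoter > gene body > downstream > intergenic (promoter
  default 2000 bp).
* **Gene classes** — gene level is the weighted CG level over the gene
  body (CG only; non-CG contexts are excluded deliberately), high iff
  > 0.7, low iff < 0.3 (both strict, so 0.70 exactly is neither).
  Uncovered genes are excluded and reported.
* **TE profile** — per-TE weighted level over all contexts, histogram
  over [0,1]; uncovered TEs are tallied separately.
* **Sequence preference** — for each called mC the −k..+k flank
  (default k = 4), strand-oriented, is counted into a base×position
  matrix per context; flanks with N or crossing a contig edge are
  skipped and counted.
* **Expression metaplots** — genes with expression values are sorted
  ascending and split into 5 equal groups (remainder to the last);
  promoters and gene bodies are cut into 20 equal-width strand-oriented
  bins; the bin level is Σm/Σn and the group curve averages gene bins
  that have coverage (bins with Σn = 0 are omitted from the mean).

## DMR detection

Both methods operate on the sites covered in both samples, filtered to
a context class: CN (all cytosines), CG, or CH = CHG + CHH (static
only). A window is tested only when (a) coverage suffices and (b) the
weighted levels differ by at least `delta_min` = 0.2 — the one
threshold inherited from the method description; windows failing either
gate never enter the testing family.

The test is the paired Wilcoxon signed-rank over per-site levels at
shared positions (sites correspond across samples, making the paired
test the natural reading; an unpaired rank-sum variant is available).
Zero differences are dropped; ties get midranks. For n ≤ 25 the exact
two-sided null is built by convolution over doubled ranks — equivalent
to enumerating all 2^n sign assignments — and for larger n the normal
approximation with tie correction (no continuity correction) is used.

* **Static**: windows of fixed genomic length (default 1000 bp)
  anchored at successive shared mCs, one mC per step. Coverage
  requires depth ≥ `min_coverage` (default 4) in both samples at ≥
  `min_covered_frac` (default 0.8) of the window's shared sites. Runs
  of ≥ `n_adjacent` (default 3) consecutive significant windows with
  the same delta sign merge into one DMR spanning the first to last
  contributing mC. "Number of adjacent windows" is read as required
  run length, not merge distance. Optional BH correction over all
  tested windows.
* **Dynamic** (CN and CG only): seed windows of exactly `n_sites`
  (default 10) covered shared sites; a significant seed extends
  3'-ward by `step` (default 2) sites while the re-test (coverage,
  delta, p < alpha) stays significant with the same sign, then
  5'-ward likewise from the original window; the maximal extent is
  reported and overlapping same-sign results merge.

Swapping the samples negates every delta and changes nothing else.
Note the dynamic method has no adjacent-window confirmation: with
depth ~20, a region whose true difference is below the threshold (e.g.
0.1) can occasionally present a single 10-site window whose *sampled*
delta crosses 0.2 and test significant. The static method's run
requirement suppresses this. This is a property of the method, not of
the implementation.

DMR→gene annotation links every gene whose promoter (TSS−2000..TSS) or
body overlaps the DMR, recording the overlap class(es).

## Simulators and ground truth

The WGBS simulator emulates a directional paired-end library: fragments
uniform over both strands, insert ~ Normal(250, 30) truncated at the
read length, mate 1 the converted fragment strand (T-rich), mate 2 the
reverse complement of the fragment 3' end (A-rich; conversions appear
as G→A). Every reference cytosine receives a Bernoulli truth state
from per-context probabilities (defaults p_mCG = 0.7, p_mCHG = p_mCHH =
0.02 — a vertebrate-like methylome); an unmethylated C survives as C
with probability `nonconversion` (default 0.005); sequencing errors are
i.i.d. substitutions (default 0.5%); 5% uniform-random read pairs are
appended; base qualities are constant Q40. The pair count is
coverage·L/(2·read_len) with 80-bp reads at 10× by default. The Lambda
spike-in chromosome is forced fully unmethylated. A `SimTruth` object
records every site state and read origin for parameter-recovery tests.

The RRBS simulator scans CCGG on both strands (the site is its own
reverse complement, so Crick fragments mirror Watson ones), keeps
fragments whose adjacent start-to-start distance is 40–220 bp
("distance" is read start-to-start; the alternative —
fragment length including both sites — differs by 4 bp), and emits
36-bp single-end reads beginning at the cut so the first three
reference bases are CGG.

What the simulators do **not** emulate: quality-score decay along the
read, indels and structural variants, PCR amplification bias and
duplicates, non-directional (PBAT-style) libraries, mate overlap
effects at short inserts, CpG-density-dependent conversion efficiency,
and RRBS size-selection efficiency curves. Tests passing on this
synthetic data therefore validate the statistical machinery and the
bookkeeping (conversion, strand assignment, counting, thresholds), not
robustness to real-library artifacts.

Each RNG consumer (genome generation, truth states, read simulation)
derives its stream from the user seed plus a distinct fixed stream key,
so equal integer seeds across components never alias the same stream.

## Validation experiment sizes

The validation suite (`scripts/acceptance.py`, mirrored in
`tests/test_acceptance.py`) uses problem sizes chosen to make the
statistical assertions sharp while staying single-core friendly:
100-kb genomes at 10× for type-I error (~40k tested sites) and
sensitivity (sites at depth ≥ 10), a 48.5-kb Lambda at ~50× (~600k
informative observations) for non-conversion recovery, 100 random
10-kb sequences for the digestion oracle, a 50-CG planted region at
depth 20 for DMR recovery, and exhaustive-enumeration oracles for both
test statistics (all m ≤ n ≤ 30; 200 random vectors with n ≤ 12). The
non-conversion experiment uses error-free reads so the estimator
isolates conversion failures; with sequencing errors the estimate
absorbs the error frequency by design (the null *p* is defined as
non-conversion plus error).

## Degenerate inputs and tie-breaks

Empty FASTQ yields an empty QC report, not an error. Fully-trimmed
reads survive trimming and are dropped by the length filter (pairs drop
when either mate does). Windows with no nonzero paired differences
give p = 1. Sites with n = 0 are reported with missing level/p/q.
Islands shorter than the window, or chromosomes shorter than 200 bp,
cannot be reported. Adapter matches shorter than `min_overlap` are
accepted only when they cover the whole adapter; trimming iterates to a
fixed point, making it idempotent. All coordinate output is 1-based
inclusive; everything internal is 0-based half-open.
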