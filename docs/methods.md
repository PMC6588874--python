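# Methods

## Scope and model of the data

The package analyzes a bulk RNA-seq design with G groups (default three:
BS, WS, RS) and r replicate libraries per group (default 3, i.e. nine
libraries). Gene-level expected counts c(g,s) are modeled as negative
binomial with mean μ(g,s) and dispersion φ(g) (variance μ + φμ²).
Transcript models are exon lists on a chromosome/strand; all internal
coordinates are 0-based half-open, converted at the GTF boundary (GTF is
1-based inclusive).

## Read QC

Three discard rules, applied per read in fixed order with the first match
recorded as the reason:

1. adaptor: the supplied adaptor occurs as an exact substring (no mismatch
   tolerance — the rule must be deterministic and no trimmer is specified);
2. unknown bases: #N / length > 0.10 (strict);
3. low quality: fraction of bases with Phred Q ≤ 5 exceeds 0.50 (strict).

Mates are filtered independently; pair-aware discarding is a known
limitation. Phred+33 encoding is assumed.

## Transcript classification

Five class codes relative to a reference index:

* `=` — same strand and identical intron chain (single-exon pairs:
  identical exon within an end tolerance, default 0 bp);
* `o` — any other same-strand exonic overlap;
* `i` — entirely inside an intron of a same-strand reference transcript,
  with no exonic overlap on either strand;
* `x` — exonic overlap only on the opposite strand;
* `u` — no exonic overlap on either strand and not intronic (intergenic).

The priority order is `=`, `o`, `i`, `x`, `u`, so classification is a
total function. Randomized agreement with a base-set brute-force checker
is part of the test suite. Only these five codes exist; finer taxonomies
collapse into `o`.

## Novel-lncRNA cascade

For the cascade, class codes are computed against the reference
*excluding* lncRNA-biotype entries, mirroring a genome annotation that
carries no lncRNAs (known lncRNAs instead come from a similarity search);
known-lncRNA overlap is then a separate positional filter. Order of
decisions, with the first failing step recorded:

0. `=`-match to an excluded biotype (protein_coding, pseudogene, rRNA,
   tRNA, miRNA) → rejected:biotype;
1. known-lncRNA database hit at E ≤ 10⁻¹⁰ (inclusive) → known lncRNA;
2. class ≠ `u` → rejected:not_u;
3. spliced length < 200 nt → rejected:too_short;
4. exonic overlap with known lncRNA loci → rejected:known_lnc_overlap;
5. longest ORF > 300 bp (strict; stop codon counted, so 100 aa + stop =
   303 bp fails) → rejected:long_orf;
6. protein-database hit at E ≤ 10⁻⁵ (inclusive) → rejected:protein_hit;
7. coding-potential score S ≥ 0 → rejected:coding_score;
8. survivors → novel lncRNA.

All filters are conjunctive, so membership in the novel set is invariant
to step order; only the recorded reasons depend on it. ORFs are
ATG…{TAA,TAG,TGA} in frame with no internal stop, scanned on all six
frames; stop-less partial ORFs at transcript ends are not counted (a
deliberate divergence from tools that allow 5'/3'-partial ORFs, chosen for
determinism). Ties between equal-length ORFs resolve to the + strand, then
the smallest start.

### Coding-potential score

S = w₁·(L_ORF − 300)/300 + w₂·(coverage − 0.5) + w₃·(Fickett − 0.95)
  + w₄·hexamer-LLR,

all weights 1 by default. The centering constants make a transcript that
sits at the classical decision boundaries (300 bp ORF, 50% coverage,
Fickett 0.95 — the published TESTCODE coding threshold) score 0, so the
rule "S < 0 ⇒ noncoding" keeps the conventional sign semantics. Fickett's
statistic uses the published position/composition lookup tables; the
hexamer term is the mean log(f_coding/f_noncoding) over in-frame hexamers
of the longest ORF (0 when there is no ORF or the sequence is shorter than
6 nt), from a table trained on codon-biased coding versus uniform-random
noncoding sequence (Laplace-smoothed). The score is pluggable: weights,
centers and hexamer table are all arguments.

## Expression and differential expression

FPKM(g,s) = 10⁹ c(g,s) / (ℓ(g) N(s)) with N(s) the sample's total count.
TMM normalization follows the standard recipe: 30% two-sided trim on
M-values, 5% on A-values, inverse-asymptotic-variance weights, reference
sample chosen by upper-quartile proximity to the mean, factors rescaled to
geometric mean 1.

Dispersion is estimated on counts scaled to a common (geometric-mean)
effective library size. The default estimator maximizes the conditional
NB log-likelihood given each group's sum — conditioning removes the group
mean from the likelihood, which removes the main small-sample bias — on a
200-point log-spaced grid over [10⁻⁴, 10]. Per-gene ("tagwise") estimates
maximize the gene's conditional likelihood plus a prior worth n0 = 10
residual degrees of freedom of the all-gene average likelihood; this is
shrinkage with weight df/(df + n0). A moment estimator (within-group
mean/variance, floored at 0, shrunk toward the 10% trimmed mean of the raw
estimates) is retained as `method="moments"`; it is simpler but biased low
at three replicates, which makes the exact test anti-conservative —
calibration simulations drove the choice of the likelihood estimator as
default.

The exact test scales each sample's count by (reference/effective library
size), rounds the group sums, estimates the common mean from the total,
and computes the two-sided p-value as the conditional probability of all
splits (a, t−a) with joint probability ≤ that of the observed split (ties
included via a 10⁻¹⁰ log-tolerance). Sums of n i.i.d. NB(μ, φ) are treated
as NB(nμ, φ/n); φ = 0 falls back to Poisson, making the test the
conditional binomial exact test. The log₂ fold change is reported from
mean normalized counts with pseudo-count 0.125 (reporting only — the test
itself uses no pseudo-count). BH adjustment runs within each pairwise
comparison, and calls require FDR ≤ 0.05 and |log₂FC| ≥ 1.

## Targets and networks

Cis distance is the gap between nearest feature ends (0 when spans
overlap), not midpoints or TSSs — deterministic and orientation-free; the
sign marks the gene's side (negative = upstream on the reference strand).
The default window [10 kb, 100 kb] is an annulus; setting the minimum to 0
reproduces the common "within 100 kb" variant. Trans correlation runs on
log₂(FPKM+1) (variance-stabilizing; configurable), with r from the
product-moment formula and p from t = r√((n−2)/(1−r²)) on n−2 df,
two-sided; emission requires r ≥ 0.95 (signed by default; an absolute
option exists) and p < 0.05 (strict). No multiple-testing correction is
applied to correlation p-values, and same-chromosome pairs are not
excluded from trans candidates — both stated conventions, not defaults
hidden in code. Networks are bipartite with no self-loops; SIF and GraphML
exports carry node types and edge attributes.

## Enrichment

p = P(X ≥ k) for X ~ Hypergeometric(N, K, n), BH across tested terms. The
background defaults to all genes in the expression matrix. An EASE-style
conservative option evaluates the tail at k−1. Namespace summaries report
counts and percentages (2 decimals) over the significant set.

## qPCR

Reference Ct per sample is the arithmetic mean over reference genes of
replicate-mean Cts (equivalent to the geometric mean of reference
expression); ΔCt = mean target Ct − reference Ct. The calibrator group is
aggregated on the linear scale — ΔΔCt = ΔCt + log₂(mean over calibrator
samples of 2^−ΔCt) — so the calibrator group's arithmetic-mean relative
expression is exactly 1; with a single or noise-free calibrator this is
the textbook ΔΔCt. Fold changes are 2^−ΔΔCt. ANOVA is the classical
one-way decomposition; all-identical input returns (F=0, p=1) and zero
within-group variance with differing means returns the (∞, 0) limit.
Amplification-efficiency correction is out of scope.

## Synthetic-study generator

The generator emulates the study's inputs with planted truth:

* **Genome/annotation**: 4 chromosomes × 1.5 Mb at GC 0.44 (near the
  assembly GC the emulated study reports); 80 multi-exon coding genes with
  codon-biased CDS (ORF > 300 bp by construction), 40 known lncRNAs, and
  coding genes planted at exact offsets (20 kb, 50 kb; 3 pairs each) from
  designated lncRNA loci as cis positives.
* **Assembly** (~480 transcripts): 200 novel lncRNAs (intergenic, ≥ 200
  nt, ORFs broken to ≤ 300 bp, verified S < 0), 40 known-lncRNA copies and
  60 coding copies of reference transcripts, and 30 decoys per cascade
  filter: < 200 nt, ORF > 300 bp, reference-exon overlap, known-lncRNA
  overlap, planted protein hit (E = 10⁻⁶), and a designed high-score
  transcript (ORF exactly 300 bp of coding-biased codons) for the
  coding-score filter.
* **Counts**: per-gene base means are log-normal (log-mean 5, log-sd 1,
  floor 10 — moderately expressed genes typical of filtered bulk data);
  NB dispersion 0.1; 10% of genes are DE with group means differing by
  exactly 2^de_log2fc (default log₂FC = 2) in one group; 20 lncRNA–mRNA
  pairs share a latent per-sample log-normal profile (sd 1.5 log₂ units,
  own dispersion 0.01, base mean 500) rather than copied columns, so the
  realized correlation is high but below 1 and the r ≥ 0.95 threshold is
  genuinely exercised. Library-size spread is a parameter (default 0, as
  the emulated design states none).
* **Reads**: 480 clean reads plus 7/6/7 reads violating exactly one QC
  rule each (≈ 96% retention, inside the range the emulated study
  reports), Phred+33.
* **Term map / Ct table**: four namespaces with two terms biased toward
  planted DE coding genes; triplicate Cts with stable references
  (sd 0.05) and stage shifts up to ±2 cycles.

Everything derives from a single seed (independent numbered streams per
generator), and identical configurations produce byte-identical files.

What the generator does **not** emulate: alignment/assembly artifacts (no
SAM/BAM), multi-isoform genes, GC or length biases in counts, batch
effects, or sequencing error beyond the three QC rule classes. Passing
tests therefore demonstrate correctness of the implemented statistics and
filters under the stated models, not robustness to real-data pathologies.

## Numerical choices and degenerate inputs

* Exact-test tie tolerance 10⁻¹⁰ in log-probability; totals capped at
  5×10⁵ per gene to bound the O(t) enumeration.
* Dispersion grid [10⁻⁴, 10], 200 log-spaced points.
* ORF capping in the generator inserts mid-ORF TAA codons until all ORFs
  are ≤ 300 bp (provably terminating; TAA insertion cannot create an ATG).
* Empty inputs raise rather than return silent zeros (assembly stats,
  FPKM with a zero-total sample, correlation with < 3 samples); zero
  variance rows are skipped with a logged count in trans correlation.
* N50 is computed by descending-length accumulation and is always the
  length of an input sequence; GC% excludes ambiguity codes from the
  denominator.

## Problem sizes

Default test and acceptance problem sizes — ~500-transcript assemblies,
2,000-gene count matrices at 3×3, 1,000-instance oracle comparisons —
were chosen so the full suite exercises every claim in minutes on one
core while keeping binomial error on calibration fractions small relative
to the asserted bands.
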