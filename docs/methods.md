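# Methods

## Region model

Variants are assigned to exactly one category from transcript geometry,
using 1-based inclusive coordinates (VCF/GTF native) and anchoring indels
at the leftmost REF base. Per transcript:

* positions inside the transcript span are exonic/UTR (coding
  transcripts, split by the CDS bounds relative to strand) or
  ncRNA-exonic/ncRNA-intronic (transcripts without a CDS);
* intronic positions of a coding transcript within `splice_bp` (default
  2) bases of an exon–intron junction are *splicing*; the exonic side of a
  junction stays exonic, and noncoding transcripts get no splicing
  category;
* strand-aware windows of `upstream_bp`/`downstream_bp` (default 1000)
  bases beyond the transcription start/end sites are upstream/downstream,
  boundaries inclusive (distance exactly 1000 is upstream; 1001 is
  intergenic);
* anything else is intergenic, including positions on chromosomes absent
  from the gene model (logged once per contig).

When several overlapping transcripts explain one position, a fixed total
precedence decides: exonic > splicing > ncRNA-exonic > 5′ UTR > 3′ UTR >
intronic > ncRNA-intronic > upstream > downstream > intergenic. This
refines the usual gene-annotation precedence (exonic/splicing first,
flanking windows last, upstream over downstream); the orderings *within*
the pairs exonic/splicing and 5′/3′ UTR are free choices made for
determinism — classification is therefore independent of transcript
iteration order, and mirror-reflecting all coordinates while flipping
strand leaves every label unchanged.

Gene models load from GTF (via gffutils, after a line-level validation
pass so malformed records fail with a line number) or from a bin-less
refGene-style TSV (0-based half-open on disk, converted on parse).
Transcripts whose CDS falls outside their exon span are rejected with a
warning rather than aborting the load.

## Statistics

All test and cutpoint machinery is implemented in-package and
cross-checked in the test suite against scipy, statsmodels and
scikit-learn.

**Mann–Whitney U.** Mid-rank U statistic of the first sample. For total
n ≤ 10 the two-sided p is exact: all C(n, n1) label assignments are
enumerated and those whose U deviates from the null mean at least as much
as observed are counted; internally ranks are doubled so tie comparisons
are integer-exact. Larger samples use the normal approximation with
tie-corrected variance and a 0.5 continuity correction. The tail
underflows for |z| ≳ 38, so p is floored at the smallest positive float
to stay in (0, 1] (the score separation at archive scale genuinely
produces such values).

**BH FDR.** Standard step-up, returned in input order, clipped at 1. The
adjustment family is always the set of hypotheses actually tested in a
run — the regions with enough data, or the region pairs — never a fixed
nine.

**ROC and cutpoints.** The classification rule is score ≥ threshold ⇒
pathogenic throughout. Candidate thresholds are the distinct observed
scores (the Phred scale is a published discretized scale, so
observed-value cutpoints are reproducible), preceded by an +∞ sentinel so
the curve runs from (0,0) to (1,1); the AUC is the trapezoidal area and
equals the tie-corrected rank statistic U/(n₁n₂). Cutpoint ties break
toward the **higher** threshold (fewer false positives). Because float
rounding must not decide a tie (1 − 1/3 ≠ 2/3 − 0 in binary), the Youden
criterion is compared on the integer key tp·n₂ − fp·n₁ and the F1
criterion on exact fractions; the weighted blend w·J + (1−w)·F1 uses
float arithmetic but dispatches to the exact rules at w ∈ {0, 1}, so the
degenerate weights reproduce the named criteria exactly. The blend weight
defaults to 0.4 on Youden's J; which regions receive the F1 or weighted
treatment is configurable per region (`strategy_map`), with Youden the
default everywhere.

**Significance labels.** Strict cutoffs: p < 0.001 → `***`, < 0.01 →
`**`, < 0.05 → `*`, else `ns`.

## Threshold derivation and usability

Per region with at least `min_n` (default 2) benign and pathogenic
scores: MWU p, BH across the tested regions, cutpoint per the region's
strategy, trapezoidal AUC. Regions below `min_n` are reported with an
absent threshold and are never usable (sparse categories are reported,
not silently dropped). A record is *usable* iff AUC > 0.7 (strict) and
the adjusted significance is not `ns`; an AUC below 0.5 is reported as-is,
never inverted, and is unusable. The packaged default configuration
applies these rules to its printed AUC/significance columns, giving five
usable regions of nine; its nine threshold values are applied by the
filter in **every** region regardless of usability, mirroring how the
reference analysis tallied threshold-passing variants.

The benign-substitution mode replaces each region's benign scores with
the scores of common variants (allele frequency strictly above `af_min`,
default 1%), excluding any variant whose (chrom, pos, ref, alt) key
matches a supplied pathogenic set, and leaves pathogenic/VUS lists
untouched — a robustness check against mislabelled benign entries.

## Filtering cascade

Fixed stage order: exclude coding-exonic → allele frequency < `af_max`
(strict; missing frequency means novel, hence rare) → score ≥
threshold[region] (inclusive; a region missing from the map fails,
conservatively) → optionally de novo only (an input annotation, not a
genotype computation; requiring it on a dataset with no de novo flags is
an error). The report tallies every stage and the per-region counts at
the threshold stage. The median-split comparator retains, per region,
variants scoring at or above that region's median in the input set itself
(even sizes use the mean of the central pair); by construction it keeps
at least half of each region, so it is deliberately more permissive than
calibrated fixed thresholds.

## Synthetic data

The generators define the package's study conditions:

* **Gene models**: coding and noncoding genes on a toy chromosome, spaced
  so flanking windows never overlap; every position in each gene's
  neighborhood (including the exact window and junction boundaries) is
  painted into a ground-truth map by direct interval construction —
  deliberately a different algorithm from the classifier, so agreement is
  a real check. Coding genes have three exons with UTRs on both ends;
  intron lengths (60–250 bp) always exceed twice the splicing window.
* **Archive-like sets**: region composition defaults to the printed
  composition of noncoding clinically classified variants in a public
  archive, normalized to a simplex (the printed percentages sum to 1.05);
  class composition defaults to the archive's benign:pathogenic:VUS
  ratios (≈0.76/0.07/0.17). Class-conditional scores are truncated
  Normals on [0, 99] — chosen because the Phred scale is bounded and the
  family admits analytic oracles (the Youden-optimal cutpoint by direct
  maximization of F_benign − F_pathogenic, the AUC by numeric
  integration). Default means preserve the pathogenic > VUS > benign
  ordering per region; they are configuration, not claims about real
  score distributions.
* **Trio-WGS-like sets**: background scores follow the Phred scale's own
  defining distribution, −10·log₁₀(U) with U uniform (so P(score ≥ t) =
  10^(−t/10)); allele frequencies are 92% common / 8% rare; a chosen
  number of background variants (default 80) are flagged de novo with
  frequency 0. Exactly one extra de novo ncRNA-exonic insertion is
  planted with score 20.8 and labelled pathogenic. Under the packaged
  thresholds the expected de novo pass fraction is ≈11% — the planted
  needle plus a handful of background variants — which the acceptance
  experiment measures as a median over 20 seeds (individual seeds
  fluctuate binomially).

Every generator is a pure function of its arguments including the seed.
What the generators do **not** emulate: linkage and haplotypes,
genotypes, sequencing error, positional clustering of variants, or the
true shape of real score distributions beyond ordering and scale. Tests
passing on this synthetic data therefore validate the *machinery*
(classification, statistics, cutpoints, cascade bookkeeping), not the
clinical performance of any particular threshold set on real genomes.

## Problem sizes and numerical choices

The test suite and acceptance script use: exact-MWU oracle checks at
total n ≤ 10 (enumeration is C(10,5) = 252 assignments at worst), 1000
tied instances for the AUC identity, 20 seeds × 20 000 scores per class
for the truncated-Normal recovery (median cutpoint error ≈ 0.1–0.2 score
units against the analytic optimum on a 1 m-step grid), ~28 000
ground-truth positions for the classifier, and 20 seeds × 20 000 variants
for the planted-recovery experiment. These sizes make every run
deterministic-fast while keeping the binomial noise of each measured
quantity well inside its asserted bound.

VCF INFO floats are 32-bit, so scores and frequencies round-trip through
VCF to ~7 significant digits; the threshold report TSV writes floats with
`repr` and re-parses with round-trip precision, so it round-trips
bit-exactly.

## Known limitations

* The region model is transcript-geometric only: no protein consequences,
  no HGVS, no multi-allelic decomposition beyond one row per ALT.
* The splicing category follows the intron-side convention of gene-based
  annotators; tools using different conventions will disagree at
  junctions.
* Whether real archive-derived thresholds transfer to a given cohort
  depends on score version and annotation pipeline; the packaged defaults
  are reference values, not universal constants, and regions flagged
  unusable should be treated accordingly.
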