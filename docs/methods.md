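# Methods

## Overview

`mirededit` analyses A-to-I editing of mature microRNAs from small-RNA
sequencing reads. Inosine is read as guanosine, so editing of a genomic
adenosine appears as an A→G mismatch between a read and the genome. The
difficulty is that A→G mismatches also arise from sequencing error (~0.1%
per base at Q30), genomic polymorphism, and 5′/3′ end modifications of the
miRNA; the pipeline is a battery of filters designed to remove those
sources, followed by a remapping estimator that measures editing
frequencies without the detection filters' asymmetries, and a set of
downstream statistical analyses. Everything is driven and calibrated by a
synthetic-data generator with exact per-read truth.

## Read filtering and mapping

Reads are adapter-trimmed (exact match of the full adapter anywhere, or of
an adapter prefix ≥ 8 nt anchored at the read's 3′ end; the simulator
plants exact adapters, so error-tolerant trimming would add complexity
without coverage), then kept only at 15–28 nt with quality ≥ 30 at every
position (Q20 read-wide in the relaxed mode for low-quality datasets, with
Q30 re-imposed at any interrogated site). N bases count as quality 0. A
read failing both length and quality is tallied once, under length.

Mapping allows at most one substitution (no gaps) and enumerates **all**
alignments on both strands. Alignments with fewer mismatches form a better
stratum; a read is kept only when its best stratum holds at most
`multimap_limit` hits (1 by default; 5 in the relaxed mode, where hits are
returned with a multiplicity flag). Unmapped reads are retried with one and
then two bases removed from the 3′ end, to absorb non-templated additions;
the first (longest) mappable state wins, so a trimmed mapping never
overrides an untrimmed one and trimming never moves the 5′ coordinate.

The aligner is seed-and-extend over an exact k-mer index (k = 12). A read
with ≤ m mismatches contains m + 1 contiguous chunks of which at least one
is mismatch-free (pigeonhole), so exact occurrences of each chunk enumerate
every candidate locus; chunks shorter than k (short reads at m = 2) fall
back to exact substring scanning, keeping sensitivity complete rather than
heuristic. An independent brute-force sliding-window aligner with the same
return contract serves as an equivalence oracle in the test suite; the two
must agree on status, locus, strand and mismatch set for every read.

## Candidate-site filters

Mismatches are tallied per position inside annotated mature/star miRNAs, in
miRNA sense (a genomic T→C under a minus-strand annotation is recorded
A→G). A read is assigned to an annotation when it aligns on the same strand
and overlaps it by at least half the aligned length. Filters:

* **Edge exclusion.** Mismatches in the first one or last two bases of the
  (post-trim) read, or at the first one or last two positions of the
  annotated sequence, are never tallied — these are dominated by 5′/3′
  modification artifacts. The 3′-trim removed bases before mapping, so the
  read-edge rule applies to the post-trim read.
* **Perfect-read coverage.** A site must be covered by at least one read
  mapping with no mismatch at all.
* **Single mismatch type.** A site showing a second mismatch type that is
  distinguishable from sequencing error is rejected. "Distinguishable"
  means: frequency above the 0.1% error rate **and at least two supporting
  reads** — a singleton read always exceeds 0.1% at realistic coverage yet
  is fully expected under the error model (P ≈ 12% per site at 200×), so
  counting singletons would cap per-site sensitivity near 87% regardless of
  signal strength. With the two-read rule, measured sensitivity for a 10%
  edited site at 200× is 97.6% and the false-positive calibration is
  unchanged.
* **SNP overlap.** A known polymorphism at the same genomic position in the
  same species rejects the site.
* **Evidence tiers, per tissue.** *high*: ≥ 5 reads of each variant and a
  mismatch count of at least 5% of the miRNA's read total in that tissue
  (the 5% applies to the miRNA total; the per-site frequency reported to
  users uses site-spanning reads as denominator). *relaxed*: ≥ 1 read of
  each variant and ≥ 1% frequency at the site. *trace*: any mismatch read
  below 1% — reported, but indistinguishable from error in isolation. A
  site's tier is its best tissue tier; any rejection flag forces
  *rejected*.
* A site with two equally frequent change types is flagged and not
  classified as canonical editing — the data cannot say which change
  dominates.

## Conservation

miRNA families are multiple-aligned by progressive star alignment: the
first member is the center, every other member is aligned to it by global
pairwise alignment under unit match/mismatch/gap costs (via Biopython's
`PairwiseAligner`), and gaps introduced into the center are propagated to
all rows. Mature miRNAs are ~22 nt and near-identical across species, so
any optimal-cost aligner reproduces the same columns; a hand-written
Levenshtein dynamic program in the tests guards the pairwise costs. When a
species has several annotated orthologs, the one with the fewest
mismatches to the reference mature sequence is kept (ties broken
lexicographically, with a warning).

A conserved event requires (a) the alignment column to be a **non-gap A in
every claiming species** — relaxed constraint at non-conserved sites makes
them likelier to harbor polymorphisms — and (b) evidence in ≥ 2 species:
at the high tier in the stringent mode, or at the relaxed ≥ 1% tier in the
extended mode (both modes are exposed; the stringent set demands two
species at high tier). Species without data are recorded as *no-data* and
never change an event's status. For sparse additional-species datasets, the
ortholog locus is found by mapping the reference mature/star sequence to
the target genome with ≤ 2 mismatches (≤ 5 locations, best stratum), reads
are filtered at Q20 read-wide with Q30 required at the site, and the site
is tiered *relaxed* (both variants covered, mismatch ≥ 1% of reads over the
site), *trace*, *none* or *no-data*. Clade labels attached to events come
from a user-supplied Newick tree (smallest clade containing the claiming
species); divergence ages are configuration, never computed.

## Remapping estimator

For each conserved site, three variant references are built: the annotated
sequence plus 10 nt of genomic context on each side (unedited), the same
with the site A replaced by G (edited), and a decoy with the A *nearest* to
the genuine site replaced by G (fake-edited; ties between equidistant As go
to the 5′ side; if no other A exists the decoy is omitted with a warning).
A read is counted for a variant only when it matches it with **zero
mismatches** and its occurrence spans that variant's site; reads consistent
with more than one variant — i.e. not spanning the discriminating site —
are discarded. The frequency is `edited / (edited + unedited)`; the
fake-edit count estimates the estimator's error-driven background (≤ 0.5%
of reads at 0.1% error in calibration). A trimmed read must still span the
site to count. Cross-mapping is audited by searching every counted read
against the full genome for perfect matches outside the quantified loci.

Because a read either carries the site or not, the per-read counting is a
Bernoulli sample of the underlying editing state: the estimator is unbiased
(measured mean error 1.5 × 10⁻⁴ at 1250 spanning reads) and its estimates
fall inside exact binomial 99% intervals at the intervals' nominal rate.
Coverage rules for downstream use: ≥ 10 edited reads per species for the
age analysis, ≥ 100 reads per individual for the matched-pair analysis.

The 5′-isomiR breakdown classifies counted reads by start offset relative
to the annotated 5′ end; offsets {0, −1} × {edited, unedited} form a 2×2
table tested for independence by χ² with 1 df and no continuity correction
(a warning is attached when an expected cell is below 5; other offsets are
excluded from the test).

## Statistics

* **Seed region**: positions 2–8 (1-based, inclusive) by default,
  configurable to 2–7. Over the built-in 15-site catalog of conserved
  editing positions both conventions give 11/15 = 73% in-seed.
* **BH correction**: standard step-up (statsmodels), order-preserving and
  monotone.
* **Direction binomial test**: exact two-sided by minimum-likelihood
  summation (scipy); at p₀ = 0.5 this equals the doubled tail, capped at 1.
* **Matched pairs**: χ² (1 df, no continuity correction — matching the
  closed-form 2×2 statistic) on (edited, unedited) × (control, tumor),
  BH across all pairs in a run, significance at q < 0.05; direction by
  frequency comparison; binomial direction tests over all tested pairs and
  over the significant subset.
* **Age correlations**: Spearman rho of editing frequency vs age per miRNA
  (replicates merged first; miRNAs detected in all samples with ≥ 10 edited
  reads in total), BH across miRNAs; constant series are flagged, not
  tested. The same operation applies to expression rows (e.g. ADAR and
  ADARB1 mRNA levels).
* **Target comparison**: genes predicted as targets of both the edited and
  unedited form are excluded; per-gene Spearman rho of expression vs age;
  two-sided Mann–Whitney (exact for small samples) between the two rho
  distributions.
* **Group comparisons**: neural = {brain, cerebellum} vs non-neural =
  {heart, kidney, testis}, two-sided Mann–Whitney; paired cross-species
  comparison by Wilcoxon signed-rank; Ward hierarchical clustering (scipy,
  Euclidean distances, deterministic index tie-break) of per-tissue
  frequency profiles.

## Synthetic data

The generator defines the conditions under which everything is tested.

* **Reference bundles.** Per family, an ancestral 22-nt mature sequence
  with a designated editable adenosine away from both edges; orthologs
  substitute only at ≤ 3 fixed per-family variable positions (never the
  editable A), bounding pairwise divergence at 3. Star arms are the
  reverse complement of the mature with two family-level substitutions at
  positions shielded from species variation — real miRNA duplexes are
  imperfect, and this keeps arm-specific reads uniquely mappable. A
  configurable fraction (default 20%) of families is annotated in only a
  subset of species. Precursors (mature + 8–12 nt loop + star) are embedded
  in per-species contigs with 30–60 nt random spacers, ~30% on the minus
  strand; SNPs are planted with ref bases matching the genome.
* **Reads.** Counts per (sample, miRNA) are Poisson around the design
  expectation. Each read starts at the annotated 5′ end shifted by a
  cleavage offset drawn from {0: 0.54, −1: 0.45, +1: 0.01} (the observed
  proportions for an abundantly edited miRNA; when editing-coupled
  processing is enabled, edited transcripts draw from {0: 0.32, −1: 0.68}
  instead), carries programmed A→G edits per site and sample, gains a 1–2
  nt random 3′ tail with probability 0.1 (the true tail distribution is
  not established, so it is a parameter, not an assertion), and suffers
  uniform substitution errors at 0.001/base with constant qualities
  matching that rate (Q30). Errors are substitutions only, matching the
  gap-free mapping contract; quality strings are flat because the filters
  are threshold-based, not shape-based. Read ids encode sample, species,
  miRNA and serial, and a truth table records edited status, offset, tail
  and error count per read — enabling exact false-positive/negative
  accounting.
* **Time course.** Twelve postnatal ages from 0.25 to 60 years; expected
  editing frequency is `clip(0.15 + slope·τ, 0, 1)` with τ the age
  normalized to [0, 1] and slope 0.35 by default; realized counts are
  binomial at the stated coverage. Each miRNA gets disjoint edited-form and
  unedited-form target gene sets; edited-form targets decline linearly by
  the coupling effect (default 1.0 expression unit over the age range) with
  Gaussian noise (σ = 0.3), unedited-form targets stay flat.
* **Matched pairs.** Control frequencies vary across patients around
  per-miRNA baselines drawn from U(0.2, 0.7); tumor frequency = control +
  effect (default −0.15), clamped to [0, 1]; pairing is recorded in the
  sample metadata and validated (one normal + one tumor per patient).

What the generator does **not** emulate: hairpin thermodynamics and
structure-dependent ADAR site preference, platform-specific error and
quality-shape profiles, ligation and amplification biases of library
preparation, realistic genome repeat structure (cross-mapping is therefore
near zero by construction), and isomiR 3′-end biology beyond random tails.
Passing calibrations consequently demonstrate correctness of the
algorithms under the stated statistical model, not performance on any
particular real library.

## Calibration results the tests compute

* False positives: zero high-tier calls on editing-free data (50 miRNAs,
  1000× coverage, 0.1% error) across 20 seeds — the 5-read/5% rule leaves
  no room for error-driven sites.
* Sensitivity: a 10%-edited site at 200× coverage reaches the high tier in
  ≥ 95% of seeded runs (measured 97.6% per site).
* Estimator: unbiased, with 99%-interval misses at the nominal rate over
  200 seeded runs at ~1250 spanning reads.
* Aligner: zero discrepancies against the brute-force oracle over 1000
  simulated reads with errors and tails.
* Patterns: positive age trends, the editing × 5′-cleavage association,
  tumor-down direction, and clustering by miRNA identity are each
  recovered in ≥ 90% (clustering: ≥ 95%) of seeded Monte-Carlo runs at the
  default study conditions.

## Numerical and procedural choices

* Coordinates are 0-based half-open internally; all user-facing positions
  are 1-based within the mature miRNA, and result files say so in their
  headers. Qualities are Phred+33 throughout.
* Monte-Carlo checks for the age and cancer patterns draw binomial counts
  at the stated coverages rather than re-simulating FASTQ per seed: the
  statistical stages consume counts, and the read-level path is calibrated
  separately (detection, estimator, isomiR coupling all run on reads).
* Simulation sizes in the test suite (e.g. 5-miRNA bundles for per-site
  sensitivity, 1400 expected reads for estimator consistency) are chosen as
  the smallest scales at which the calibrated quantities are
  well-estimated.
* Determinism: every stochastic component takes a single integer seed;
  identical seeds give byte-identical FASTQ, truth tables and stage
  outputs. Pipeline stages are pure functions of (inputs, seed) and write
  JSON run reports with full read-attrition accounting
  (input = kept + each rejection class at every boundary).

## Known limitations

* The aligner targets the synthetic genomes it is tested on (tens of
  kilobases to megabases); the plain-dict k-mer index would need a
  compressed index for mammalian-scale genomes.
* Multiple editing sites within one mature miRNA are simulated but the
  caller evaluates sites independently; haplotype-style co-occurrence of
  edits within a read is not modelled.
* The relaxed additional-species scan assigns the ortholog locus from the
  best-stratum mapping of the reference sequence; truly ambiguous
  multi-copy loci are reported as multimapped rather than resolved.
* Expression matrices are consumed as already normalized; no normalization
  is performed or checked.
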