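# mirededit

Detection, cross-species conservation analysis and quantification of
adenosine-to-inosine (A-to-I) editing in microRNAs from small-RNA
sequencing data.

## The problem

ADAR enzymes deaminate adenosines in double-stranded RNA to inosine, which
base-pairs like guanosine. When this happens inside a miRNA precursor
hairpin, the mature miRNA read in a sequencer carries an A→G mismatch
against the genome. Editing inside the seed region (nucleotides 2–8 from
the 5′ end) can redirect the miRNA to an entirely different set of target
mRNAs, so distinguishing genuine editing from sequencing error, SNPs and
5′/3′ end modifications matters. This package implements that analysis for
multi-species small-RNA data:

1. **Detection** — reads are adapter-trimmed, kept only at 15–28 nt with
   Phred ≥ 30 at every position, and mapped with at most one mismatch,
   unique best-stratum only, retrying with 1–2 bases trimmed from the 3′
   end. Candidate sites inside annotated mature/star miRNAs must avoid read
   and annotation edges, be covered by a perfectly mapping read, show a
   single mismatch type above the sequencing error rate, not overlap a known
   SNP, and carry ≥ 5 reads of each variant at ≥ 5% of the miRNA's reads in
   some tissue.
2. **Conservation** — miRNA families are multiple-aligned; a site counts as
   a conserved editing event only if the alignment column is a non-gap A in
   every claiming species and at least two species show evidence (a relaxed
   ≥ 1% tier supports sparse datasets).
3. **Quantification** — editing frequencies come from remapping reads,
   without mismatches, against edited / unedited / fake-edited variant
   references (annotated sequence ± 10 nt of genomic context), because the
   detection pipeline treats edited and unedited reads asymmetrically. The
   frequency is `edited / (edited + unedited)` over site-spanning reads; a
   decoy reference with the nearest non-target A replaced by G estimates the
   error background, and a cross-mapping check counts reads with perfect
   genomic matches elsewhere.
4. **Statistics** — seed-region classification; χ² tests of matched
   tumor/normal pairs with Benjamini–Hochberg correction and exact binomial
   direction tests; Spearman correlations of editing frequency with age
   (miRNAs with ≥ 10 edited reads, BH-corrected); Mann–Whitney comparison of
   edited-form vs unedited-form target-gene age trends; neural vs non-neural
   tissue comparison; Ward clustering of per-tissue editing profiles.

A synthetic-data generator produces reference bundles and FASTQ reads with
programmed per-sample editing frequencies, quality-consistent sequencing
error (0.1% at Q30), 3′ non-templated additions, 5′ cleavage variation
(optionally coupled to editing status) and SNP confounders — with per-read
truth tables, so every stage is calibrated end to end without any download.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1):

```bash
python analysis/01_simulate.py 1          # reference bundle + FASTQ + truth
python analysis/02_detect.py 1            # detection + conservation
python analysis/03_quantify_tissues.py 1  # remapping frequencies + clustering
python analysis/04_timecourse.py 1        # editing vs age
python analysis/05_cancer.py 1            # matched tumor/normal pairs
```

which prints:

```
4 conserved editing events -> results/run_tissues/events.tsv
family_id  column  n_species            positions                 species_tiers
   fam001      17          2      sp01:18;sp02:18           sp01:high;sp02:high
   fam002       7          3 sp01:8;sp02:8;sp03:8 sp01:high;sp02:high;sp03:high
   fam003      15          2      sp01:16;sp02:16           sp01:high;sp02:high
   fam004      14          2      sp01:15;sp02:15           sp01:high;sp02:high
neural median frequency 0.38 vs non-neural 0.11 (Mann-Whitney p = 1.93e-08)
8/8 miRNAs with a significant positive editing-age correlation
editing lower in tumor in 30/30 pairs (binomial p = 1.9e-09)
significant pairs: 30 down, 0 up (binomial p = 1.9e-09)
```

Exactly the four families with planted editing are recovered as conserved
events (high tier in every species carrying the site; `fam002` is the only
one annotated in all three species). The planted tissue pattern — editing
at 0.40/0.35 in brain/cerebellum versus 0.05–0.15 elsewhere — appears in
the neural vs non-neural medians, the planted positive age slope is
significant for every miRNA after BH correction, and the −0.15 editing
shift planted in tumors is recovered as all pairs down.

The same stages are available as a CLI
(`mirededit simulate|preprocess|detect|quantify|timecourse|cancer|stats`),
e.g. `mirededit stats seedfrac` prints `11/15 sites in seed [2,8] = 73%`
for the built-in catalog of conserved editing sites.

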