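# Methods

## Scope and data model

The pipeline starts from assembled transcript models, not reads: a GTF of
exon structures, a FASTA of spliced sequences, and a transcript × sample
count matrix with a two-group design (three biological replicates per group
by default, mirroring a prepubertal vs pubertal comparison). Read QC,
alignment and assembly are out of scope. All internal coordinates are
0-based half-open; GTF I/O converts to/from the 1-based inclusive GTF
convention. The GTF dialect is Cufflinks-style `key "value";` attributes,
preserved on round-trip.

## Synthetic study generator

`caprilnc.simulate` emits a complete miniature study whose every planted
answer is recorded in a `GroundTruth` object. The seed fully determines all
outputs (every stage draws from its own seed-derived stream, so changing
e.g. the count model cannot silently shift the annotation).

**Genome and loci.** Coding genes are laid out left-to-right on each
chromosome without overlap, with intergenic gaps of 20–60 kb. Transcript
spliced lengths are log-normal (σ = 0.5 on the log scale) around the
configured means — 2869 nt for mRNAs and 1180 nt for lncRNAs, with a 105 nt
mean lncRNA ORF, the feature contrasts characteristic of mammalian
hypothalamus lncRNA catalogues. Exon counts are shifted Poisson
(1 + Pois(mean − 1), means 9.0 and 2.8), exon lengths Dirichlet splits with
a 30 bp floor, intron lengths uniform per class. The three lncRNA classes
are apportioned by largest remainder from the configured fractions
(default 0.8/0.1/0.1):

- *lincRNA* loci are placed in intergenic gaps with a 1.5 kb safety margin;
  the planted-cis subset instead sits at an exact span-gap distance drawn
  from `planted_cis_windows` downstream of an anchor gene.
- *antisense* loci overlap their host gene's first (or last) exon on the
  opposite strand and are kept inside the host span so they can touch no
  other gene.
- *intronic* loci are generated first, and their host gene's chosen intron
  is widened to hold them strictly inside with padding on both sides, same
  strand.

This construction makes the positional classifier's answer unambiguous by
design, which is what allows the 100%-label-recovery cross-module check.

**Sequences.** Coding transcripts carry a planted ORF covering ~66% of the
transcript (minimum 300 nt): ATG, codons drawn from a fixed GC-biased codon
table (weight exp(0.8 × GC) per non-stop codon), a stop, and one library
peptide motif encoded inside. Untranslated flanks are i.i.d. uniform.
lncRNA sequences are i.i.d. uniform with one ORF of a target length planted
explicitly and every longer incidental ORF disrupted by in-frame stop
insertion (never touching the planted ORF), so the longest complete ORF
equals the target exactly. Targets are gamma-distributed (shape 4) around
the configured 105 nt mean, capped at 35% of the transcript so the ORF
scorer's coverage rule cannot fire on short lncRNAs. The hexamer tables
shipped with the triplet scorer are derived analytically from the same
codon table (coding) and the uniform model (noncoding), smoothed with 2%
uniform mass so in-frame stop hexamers keep finite log-frequencies.

**Counts.** Per-transcript baseline expression is log-normal (σ = 0.8)
with medians 30 (mRNA) and 10 (lncRNA) on an FPKM-like scale; expected
counts scale with transcript length and library size (10⁶ per sample by
default) and are globally rescaled so the expected library size matches the
configured one. Counts are negative binomial with common dispersion
(default 0.1; Poisson below 10⁻⁶). Planted effects:

- *Differential expression*: a `de_fraction` (default 10%) of transcripts
  get the configured |log2 FC| (default 2) split symmetrically between
  groups, so the ratio of expected group means is exactly 2^lfc.
- *Group-specific lncRNAs*: zero expected counts in the off group,
  baseline floored at 5 so presence always clears the threshold.
- *Trans pairs*: lncRNA and partner gene receive max-normalised latent
  per-sample profiles constructed by Gram–Schmidt so their empirical
  correlation equals `trans_target_r` (default 0.99) exactly on the mean
  scale; baselines are floored at 20 so counting noise cannot mask the
  correlation at small dispersion. DE, group-specific and trans sets are
  disjoint.

**Term map and Ct table.** One planted term contains the full designated
10-gene query plus 5 extra genes; the other terms are random subsets of the
coding background. The Ct table assays one planted up- and one planted
down-regulated lncRNA with β-actin as reference: per-sample technical
offsets (σ = 0.3 cycles) shift target and reference together, replicate
noise is σ = 0.1 cycles, and the group ΔCt difference encodes the planted
fold change.

## Differential expression test

Cuffdiff's read-level NB machinery is not reproducible from a count matrix,
so the test here is a standard count-level stand-in, stated as such: counts
are normalised by library-size factors; per-transcript dispersions are
pooled within-group method-of-moments estimates shrunk toward a fitted
a/μ + b trend, weighted by the residual degrees of freedom against 10 prior
pseudo-observations; the Wald statistic on the difference of log group
means (with a 0.5 continuity offset, delta-method SE (1/μ̂ + α)/n per
group) is referred to the standard normal. On 2000 null NB transcripts
(3 vs 3, dispersion 0.1) this yields a p < 0.05 fraction of ~0.06 with
near-uniform p-values (KS ≈ 0.02) — slightly liberal, as plug-in Wald
tests at n = 3 are, but inside the calibration band the test suite
enforces. Fold changes use a pseudocount of 1 FPKM; significance is
thresholded on raw p = 0.05 (the BH q is reported alongside, since with a
two-sample pilot design an FDR threshold would be needlessly conservative
for a screen whose hits are validated by qPCR anyway).

All-zero rows are flagged untestable (p = 1, lfc = 0). Swapping group
labels negates every log2 FC and preserves every p exactly.

## Design choices on points the analysis convention leaves open

- **Screening defaults**: `min_exons` defaults to 1. The common lincRNA
  practice of requiring ≥ 2 exons is exposed as configuration rather than
  default because classification runs after screening (a biotype-aware exon
  rule cannot act at screen time) and because single-exon lncRNAs are a
  real, substantial class that a default should not silently drop.
  `min_fpkm` = 0.5 in ≥ 1 sample removes assembly noise; the 200 nt rule is
  strictly greater-than.
- **ORF definition**: ORFs require a terminal stop codon; an ATG run
  hitting the transcript end is reported but flagged incomplete and never
  chosen as the longest ORF. Only the three forward frames are scanned —
  the libraries emulated are strand-specific, so transcripts are oriented.
- **Biotype cascade order**: antisense (opposite-strand exonic overlap)
  beats intronic when both could apply, because exonic overlap is the
  stronger positional signal; lincRNA requires no span overlap with any
  coding gene on either strand; everything else (e.g. same-strand exonic
  overlap) is "ambiguous" and excluded with a logged count.
- **Cis distance**: the gap between spans (0 when overlapping), not
  TSS-to-TSS, with inclusive window boundaries; each pair is labelled with
  the smallest qualifying window (both 10 kb and 100 kb are computed).
- **Trans correlation**: computed on FPKM across all samples pooled over
  groups, thresholds strict (> 0.95 / < −0.95). With n = 6 samples this
  rule has a heavy multiple-testing burden: |r| of null pairs exceeds 0.95
  with probability ≈ 10⁻³, so a 200 × 300 screen yields tens of chance
  pairs, and at biological dispersion the planted-pair recall is
  noise-limited. The pipeline logs pair counts and leaves the convention as
  stated rather than silently correcting it; the recall guarantee is
  defined, and verified, in the dispersion → 0 limit.
- **Enrichment background**: all annotated protein-coding genes of the run,
  not a genome-wide universe. Significance is thresholded on the EASE p
  (the k − 1 jackknifed one-sided Fisher tail) with BH q reported;
  length-bias correction (GOseq-style) is out of scope and noted as a
  divergence from mixed-tool conventions.
- **qPCR test scale**: the t-test runs on ΔCt (approximately normal), not
  on fold changes, with equal variances and replicates averaged per
  biological sample first (n = 3 per group); the fold-change scale is
  available as an option.

## Numerical and degenerate-input conventions

Zero-variance expression rows are skipped (and counted) in trans
prediction rather than raising; identical constant groups with equal means
give t-test p = 1; hypergeometric tails clip at 1; Pearson r clips to
[−1, 1] against floating-point overshoot; FPKM requires positive lengths
and library sizes and satisfies FPKM = 0 ⟺ count = 0. Pipeline outputs are
pure functions of the config: two runs with the same config are
byte-identical (manifests differ only in timestamp).

## Problem sizes used in the checks

The default study is deliberately desk-scale: 3 chromosomes of 10 Mb,
300 coding genes, 200 lncRNA loci, 4 planted cis pairs, 20 trans pairs,
5 group-specific lncRNAs per group, 40 terms. Mean-recovery properties are
checked on a 1000-locus study; null calibration on 2000 simulated null
transcripts; oracle equivalence on an exhaustive hypergeometric sweep to
N = 30 and 1000 random interval/correlation fixtures. The realised feature
means on a 200-locus study sit within ~5% of the configured 1180/2869/105 nt
scales (sampling noise at that n); the 1000-locus check pins them within 5%.

## What passing tests do and do not show

The generator plants strong, well-separated signal: coding ORFs cover two
thirds of their transcript with a distinctive codon bias, lncRNA ORFs are
short by construction, classes are geometrically unambiguous, planted
correlations are exact on the mean scale. Passing recovery tests therefore
demonstrates the *correctness of the machinery* — filters, cascade,
statistics, window and correlation arithmetic — not the real-world accuracy
of lncRNA discovery, where coding signal is weaker (short ORFs, selenoproteins,
bicistronic transcripts), annotation is incomplete, classes overlap, and
expression noise is structured. Likewise the three coding-potential scorers
share thresholds with, but do not reproduce the numerics of, CPC/CNCI/Pfam;
real result tables from those tools can be substituted through the
external-calls hook.

## Known limitations

No isoform-resolution re-estimation or multi-factor designs; no six-frame
scanning; no amplification-efficiency (Pfaffl) correction in qPCR; no term
hierarchy or length-bias correction in enrichment; no sequence-based
(duplex) lncRNA–mRNA target prediction. FPKM magnitudes in the synthetic
study are inflated relative to real transcriptomes because a million-read
library is spread over only ~500 transcripts; thresholds are expressed in
FPKM units, so this changes no logic, only the absolute scale.
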