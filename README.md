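# caprilnc

Screening, classification and functional annotation of long noncoding RNAs
(lncRNAs) from assembled bulk RNA-seq transcripts, built around a two-group
(e.g. prepubertal vs pubertal goat hypothalamus) design — together with a
fully synthetic study generator that plants a recoverable ground truth for
every stage, so the whole pipeline is testable end to end without any
external data.

## What it computes

Starting from assembled transcript models (GTF + spliced FASTA) and a
transcript × sample count matrix with a 3-vs-3 two-group design:

1. **Screening** — candidates must be longer than 200 nt, expressed
   (FPKM ≥ 0.5 in ≥ 1 sample), and called *noncoding by all three* of:
   - an ORF extent/coverage scorer (longest ATG→stop ORF; coding iff
     ORF ≥ 300 nt or ORF/transcript coverage ≥ 0.5),
   - an adjoining-triplet (hexamer) log-likelihood-ratio scorer
     (score = mean in-frame log f_coding(h)/f_noncoding(h), maximised over
     the three forward frames; coding iff > 0),
   - a peptide motif scan over per-ORF translations.

   A transcript flagged coding by *any* scorer is filtered out (intersection
   rule). The scorers are transparent stand-ins for CPC, CNCI and Pfam Scan;
   externally computed calls can be imported to replace any of them.
2. **Biotype classification** — lincRNA (intergenic), antisense
   (≥ 1 bp exonic overlap with a coding gene on the opposite strand) or
   intronic (entirely inside one intron of a same-strand coding gene), with
   a deterministic cascade and an "ambiguous" overflow class.
3. **Differential expression** — per-transcript negative-binomial Wald test
   on library-size-normalised counts with trend-shrunk dispersions;
   log2 fold change on group-mean FPKM (+1 pseudocount); raw p < 0.05 calls
   with BH q reported alongside; group-specific calls (FPKM ≥ 1 in every
   sample of one group, ≤ 0.1 in every sample of the other).
4. **Target prediction** — *cis*: protein-coding genes within 10 kb/100 kb
   (inclusive) of the lncRNA span; *trans*: coding transcripts with
   Pearson r > 0.95 or r < −0.95 (strict) across all samples' FPKM.
5. **Enrichment** — EASE score (one-sided hypergeometric tail evaluated at
   k − 1, the jackknifed overlap) with BH correction, term maps as plain
   two-column TSV.
6. **qPCR validation** — 2^−ΔΔCt relative quantification normalised to
   β-actin with an equal-variance t-test on ΔCt per target.

## Worked example

Run the numbered analysis scripts in order (they chain through `results/`),
or the whole pipeline in one shot:

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_screen_lncrnas.py
python analysis/03_classify_biotypes.py
python analysis/04_differential_expression.py
python analysis/05_predict_targets.py
python analysis/06_enrichment.py
python analysis/07_feature_comparison.py
python analysis/08_qpcr_validation.py
# or: caprilnc run --seed 1 --out results/run --evaluate
```

At seed 1 the chain prints (abridged):

```
coding genes: 300; lncRNA loci: 200 (antisense=20, intronic=20, lincRNA=160)
lncRNA mean length 1232 nt vs mRNA 2977 nt
lncRNA mean longest ORF 105 nt
sensitivity 100.0% | coding contamination 0.0%
classified 200 lncRNAs (antisense=20, intronic=20, lincRNA=160), 0 ambiguous
planted-label agreement 100.0%
88 significant transcripts at p<0.05: 36 up-regulated, 52 down-regulated
power on the 50 planted DE transcripts: 100.0%
804 cis pairs, 306 trans pairs (200 lncRNAs with targets)
planted cis recall 100% | planted trans recall 5%
top term TERM_0028 is the planted term
TCONS_000006: pubertal fold change 3.81 +/- 0.17 (p = 2.7e-06 **)
```

Reading the numbers: the generator planted 200 lncRNAs with the configured
feature contrasts (lncRNAs ≈ 1.2 kb with ≈ 105 nt ORFs vs ≈ 3 kb mRNAs);
screening recovered all of them with no coding transcript leaking through;
the positional classifier reproduced every planted class label; the NB test
found all 50 planted DE transcripts (88 calls total — the extras are the
planted group-specific and trans-correlated transcripts, which genuinely
differ or vary between samples, plus ordinary type-I noise at p < 0.05);
all 4 planted cis neighbours were recovered at their exact distances; the
planted enrichment term ranked first with EASE p ≈ 1e−12; and the assayed
up-regulated lncRNA shows the planted fourfold change. Trans recall at the
default biological dispersion is noise-limited by design — with six samples
an |r| > 0.95 rule only recovers planted pairs reliably as dispersion → 0
(see `docs/methods.md`), which the evaluation at tiny dispersion confirms at
100%.

## Layout

- `src/caprilnc/` — the library: `simulate` (synthetic study + truth),
  `io` (GTF/FASTA/TSV/JSON), `screen`, `biotype`, `expression`, `targets`,
  `enrich`, `featurestats`, `qpcr`, `pipeline` (orchestration), `cli`.
- `analysis/` — the numbered study scripts above.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
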