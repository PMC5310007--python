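"""Positional classification: cascade rules, oracle equivalence, summaries."""

import numpy as np
import pytest

from caprilnc.biotype import (LncRNARecord, biotype_summary, classify_all,
                              classify_biotype)
from caprilnc.io import GeneAnnotation, TranscriptModel


def gene(gid, start, end, strand="+", exons=None):
    return GeneAnnotation(gene_id=gid, chrom="chr1", strand=strand,
                          span=(start, end), biotype="protein_coding",
                          exons=exons or [(start, end)])


def lnc(start, end, strand="+", exons=None, tid="lnc1"):
    return TranscriptModel(tid, "xg", "chr1", strand, exons or [(start, end)])


def brute_force_classify(tx, genes):
    """Direct all-genes scan, no interval index."""
    def exon_overlap(a, b):
        return sum(max(0, min(e1, e2) - max(s1, s2))
                   for s1, e1 in a for s2, e2 in b)

    span = tx.span
    same_chrom = [g for g in genes
                  if g.chrom == tx.chrom and g.biotype == "protein_coding"]
    anti = [g for g in same_chrom if g.strand != tx.strand
            and exon_overlap(tx.exons, g.exons) > 0]
    if anti:
        return "antisense"
    for g in same_chrom:
        if g.strand != tx.strand or exon_overlap(tx.exons, g.exons) > 0:
            continue
        for istart, iend in g.introns():
            if istart < span[0] and span[1] < iend:
                return "intronic"
    overlapping = [g for g in same_chrom
                   if g.span[0] < span[1] and span[0] < g.span[1]]
    return "lincRNA" if not overlapping else "ambiguous"


def test_one_bp_antisense_overlap_is_enough():
    g = gene("g1", 1000, 2000, strand="-")
    rec = classify_biotype(lnc(1999, 2500, strand="+"), [g])
    assert rec.biotype == "antisense" and rec.host_gene_id == "g1"


def test_lincrna_needs_one_bp_of_clearance():
    genes = [gene("g1", 0, 1000), gene("g2", 3000, 4000)]
    assert classify_biotype(lnc(1001, 2999), genes).biotype == "lincRNA"
    # touching a gene span (half-open adjacency) still counts as intergenic
    assert classify_biotype(lnc(1000, 2999), genes).biotype == "lincRNA"


def test_intronic_requires_strict_containment_same_strand():
    g = gene("g1", 0, 5000, exons=[(0, 1000), (4000, 5000)])
    assert classify_biotype(lnc(1500, 3500), [g]).biotype == "intronic"
    # same coordinates on the opposite strand are not intronic
    assert classify_biotype(lnc(1500, 3500, strand="-"), [g]).biotype == "ambiguous"
    # touching the intron boundary is not strictly inside
    assert classify_biotype(lnc(1000, 3500), [g]).biotype == "ambiguous"


def test_same_strand_exonic_overlap_is_ambiguous():
    g = gene("g1", 1000, 2000)
    assert classify_biotype(lnc(1500, 2500), [g]).biotype == "ambiguous"


def test_antisense_beats_intronic_when_both_apply():
    # lncRNA inside g1's intron, but its exon also overlaps g2's exon
    # antisense: the opposite-strand exonic overlap wins the cascade
    g1 = gene("g1", 0, 5000, strand="+", exons=[(0, 1000), (4000, 5000)])
    g2 = gene("g2", 1400, 1600, strand="-")
    rec = classify_biotype(lnc(1500, 3500, strand="+"), [g1, g2])
    assert rec.biotype == "antisense" and rec.host_gene_id == "g2"


def test_record_invariants():
    with pytest.raises(ValueError, match="host gene"):
        LncRNARecord(lnc(0, 10), "antisense", None)
    with pytest.raises(ValueError, match="host"):
        LncRNARecord(lnc(0, 10), "lincRNA", "g1")


def test_classification_matches_brute_force_on_random_fixtures():
    rng = np.random.default_rng(42)
    genes = []
    pos = 0
    for i in range(30):
        pos += int(rng.integers(500, 5000))
        n_ex = int(rng.integers(1, 4))
        exons, p = [], pos
        for _ in range(n_ex):
            length = int(rng.integers(100, 800))
            exons.append((p, p + length))
            p += length + int(rng.integers(200, 1500))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(gene(f"g{i}", exons[0][0], exons[-1][1], strand, exons))
        pos = exons[-1][1]
    for j in range(300):
        start = int(rng.integers(0, pos))
        length = int(rng.integers(100, 4000))
        strand = "+" if rng.random() < 0.5 else "-"
        tx = lnc(start, start + length, strand, tid=f"x{j}")
        assert classify_biotype(tx, genes).biotype == \
            brute_force_classify(tx, genes)


def test_truth_geometry_recovers_every_planted_label(default_study):
    truth = default_study.truth
    lncs = [tx for tx in default_study.transcripts
            if tx.transcript_id in set(truth.true_lnc_ids)]
    records, ambiguous = classify_all(lncs, default_study.genes)
    assert ambiguous == 0
    for rec in records:
        assert rec.biotype == truth.biotype[rec.transcript.transcript_id]


def test_summary_partitions_the_input(default_study):
    truth = default_study.truth
    lncs = [tx for tx in default_study.transcripts
            if tx.transcript_id in set(truth.true_lnc_ids)]
    records, ambiguous = classify_all(lncs, default_study.genes)
    summary = biotype_summary(records)
    assert sum(summary.values()) + ambiguous == len(lncs)
    assert biotype_summary([]) == {"lincRNA": 0, "antisense": 0, "intronic": 0}
    one_each = [LncRNARecord(lnc(0, 10, tid=f"t{i}"), b,
                             None if b == "lincRNA" else "g1")
                for i, b in enumerate(("lincRNA", "antisense", "intronic"))]
    assert biotype_summary(one_each) == {"lincRNA": 1, "antisense": 1,
                                         "intronic": 1}
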