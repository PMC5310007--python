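"""Positional classification of candidate lncRNAs.

Classes follow the usual lncRNA taxonomy relative to the protein-coding
annotation: lincRNA (intergenic), antisense (exonic overlap with a coding
gene on the opposite strand) and intronic (entirely inside one intron of a
same-strand coding gene). The decision cascade tries antisense first because
opposite-strand exonic overlap is the strongest positional signal, then
intronic, then lincRNA; anything left over (e.g. same-strand exonic overlap
with a coding gene) is labelled ambiguous and excluded from downstream
reports with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .io import GeneAnnotation, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = ["LncRNARecord", "GeneIndex", "classify_biotype", "classify_all",
           "biotype_summary"]

BIOTYPES = ("lincRNA", "antisense", "intronic")


@dataclass
class LncRNARecord:
    transcript: TranscriptModel
    biotype: str                   # lincRNA | antisense | intronic | ambiguous
    host_gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES + ("ambiguous",):
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.biotype in ("antisense", "intronic") and self.host_gene_id is None:
            raise ValueError(f"{self.biotype} record requires a host gene")
        if self.biotype == "lincRNA" and self.host_gene_id is not None:
            raise ValueError("lincRNA record must not have a host gene")


class GeneIndex:
    """Interval index of protein-coding gene spans, per chromosome."""

    def __init__(self, genes: Sequence[GeneAnnotation]):
        self.trees: dict[str, IntervalTree] = {}
        for gene in genes:
            if gene.biotype != "protein_coding":
                continue
            tree = self.trees.setdefault(gene.chrom, IntervalTree())
            tree.addi(gene.span[0], gene.span[1], gene)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneAnnotation]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda g: g.gene_id)


def _exonic_overlap(a_exons, b_exons) -> int:
    total = 0
    for s1, e1 in a_exons:
        for s2, e2 in b_exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def classify_biotype(lnc: TranscriptModel,
                     genes: Sequence[GeneAnnotation] | GeneIndex) -> LncRNARecord:
    """Assign lincRNA / antisense / intronic (or ambiguous) to one transcript."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    span = lnc.span
    hits = index.overlapping(lnc.chrom, span[0], span[1])

    # (1) antisense: >= 1 bp exonic overlap with an opposite-strand gene exon
    best_host, best_overlap = None, 0
    for gene in hits:
        if gene.strand == lnc.strand:
            continue
        ov = _exonic_overlap(lnc.exons, gene.exons)
        if ov > best_overlap:
            best_host, best_overlap = gene, ov
    if best_host is not None:
        return LncRNARecord(lnc, "antisense", best_host.gene_id)

    # (2) intronic: span entirely inside one intron of a same-strand gene,
    # with zero exonic overlap
    for gene in hits:
        if gene.strand != lnc.strand:
            continue
        if _exonic_overlap(lnc.exons, gene.exons) > 0:
            continue
        for istart, iend in gene.introns():
            if istart < span[0] and span[1] < iend:
                return LncRNARecord(lnc, "intronic", gene.gene_id)

    # (3) lincRNA: no span overlap with any coding gene on either strand
    if not hits:
        return LncRNARecord(lnc, "lincRNA", None)

    return LncRNARecord(lnc, "ambiguous", None)


def classify_all(lncs: Sequence[TranscriptModel],
                 genes: Sequence[GeneAnnotation]) -> tuple[list[LncRNARecord], int]:
    """Classify a transcript set; returns (classified records, n ambiguous).

    Ambiguous transcripts are excluded from the returned records.
    """
    index = GeneIndex(genes)
    records, ambiguous = [], 0
    for lnc in lncs:
        rec = classify_biotype(lnc, index)
        if rec.biotype == "ambiguous":
            ambiguous += 1
        else:
            records.append(rec)
    if ambiguous:
        logger.info("classify_all: %d transcripts were positionally ambiguous "
                    "and excluded", ambiguous)
    return records, ambiguous


def biotype_summary(records: Sequence[LncRNARecord]) -> dict[str, int]:
    """Counts per class; keys are always the three biotype names."""
    counts = {b: 0 for b in BIOTYPES}
    for rec in records:
        counts[rec.biotype] += 1
    return counts
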