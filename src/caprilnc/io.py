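"""Readers and writers for the formats the pipeline touches.

GTF is handled in the Cufflinks/Ensembl dialect (``key "value";`` attribute
pairs); coordinates are converted between GTF's 1-based inclusive convention
and the 0-based half-open intervals used everywhere inside the package.
FASTA goes through Biopython; matrices through pandas.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "GeneAnnotation",
    "GtfParseError",
    "ValidationError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_json",
    "write_json",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message carries the line number."""


class ValidationError(ValueError):
    """Raised when a matrix/design file violates the pipeline's contracts."""


@dataclass
class TranscriptModel:
    """An exon-structured transcript on a genome.

    Exons are 0-based half-open ``(start, end)`` intervals, stored sorted and
    non-overlapping. ``sequence``, when present, is the spliced sequence and
    must match the summed exon length.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    sequence: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"{self.transcript_id}: exon ({start}, {end}) has end <= start"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = end
        if self.sequence is not None and len(self.sequence) != self.spliced_length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= spliced length {self.spliced_length}"
            )

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class GeneAnnotation:
    """A reference gene: span, strand, biotype, and the union of its exons."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    biotype: str = "other"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biotype not in ("protein_coding", "other"):
            raise ValueError(f"unknown biotype {self.biotype!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        if self.exons:
            lo = min(s for s, _ in self.exons)
            hi = max(e for _, e in self.exons)
            if self.span[0] > lo or self.span[1] < hi:
                raise ValueError(f"{self.gene_id}: span does not cover exons")

    def introns(self) -> list[tuple[int, int]]:
        gaps = []
        merged = _merge_intervals(self.exons)
        for i in range(len(merged) - 1):
            gaps.append((merged[i][1], merged[i + 1][0]))
        return gaps


def _merge_intervals(ivals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"\s*;')


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(text))
    if not attrs:
        raise GtfParseError(f"line {lineno}: no parseable attributes in {text!r}")
    return attrs


def read_gtf(path: str | Path) -> tuple[list[GeneAnnotation], list[TranscriptModel]]:
    """Read a GTF file into gene and transcript models.

    Only ``exon`` features are used to build transcripts; other feature rows
    are ignored (a count is logged). Genes are reconstructed as the exon
    union over each gene_id; a ``gene_biotype`` attribute of
    ``protein_coding`` is honoured, anything else maps to ``other``.
    """
    path = Path(path)
    tx_exons: dict[str, dict] = {}
    gene_rows: dict[str, dict] = {}
    ignored = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_text = fields
            if feature != "exon":
                ignored += 1
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise GtfParseError(f"line {lineno}: end < start")
            attrs = _parse_attributes(attr_text, lineno)
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: missing transcript_id attribute")
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            tid, gid = attrs["transcript_id"], attrs["gene_id"]
            # 1-based inclusive -> 0-based half-open
            exon = (start_i - 1, end_i)
            rec = tx_exons.setdefault(
                tid, {"gene_id": gid, "chrom": chrom, "strand": strand,
                      "exons": [], "attributes": {}}
            )
            rec["exons"].append(exon)
            extra = {k: v for k, v in attrs.items()
                     if k not in ("transcript_id", "gene_id")}
            rec["attributes"].update(extra)
            grec = gene_rows.setdefault(
                gid, {"chrom": chrom, "strand": strand, "exons": [],
                      "biotype": "other"}
            )
            grec["exons"].append(exon)
            if attrs.get("gene_biotype") == "protein_coding":
                grec["biotype"] = "protein_coding"
    if ignored:
        logger.info("read_gtf(%s): ignored %d non-exon feature rows", path, ignored)
    transcripts = [
        TranscriptModel(transcript_id=tid, gene_id=rec["gene_id"],
                        chrom=rec["chrom"], strand=rec["strand"],
                        exons=rec["exons"], attributes=rec["attributes"])
        for tid, rec in tx_exons.items()
    ]
    genes = []
    for gid, rec in gene_rows.items():
        exons = _merge_intervals(rec["exons"])
        span = (exons[0][0], exons[-1][1])
        genes.append(GeneAnnotation(gene_id=gid, chrom=rec["chrom"],
                                    strand=rec["strand"], span=span,
                                    biotype=rec["biotype"], exons=exons))
    return genes, transcripts


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "caprilnc") -> None:
    """Write transcripts as exon rows in Cufflinks-dialect GTF.

    Extra per-transcript attributes are preserved, so read_gtf . write_gtf
    round-trips the transcript set.
    """
    with open(path, "w") as fh:
        for tx in transcripts:
            for start, end in tx.exons:
                attrs = [f'gene_id "{tx.gene_id}"', f'transcript_id "{tx.transcript_id}"']
                attrs += [f'{k} "{v}"' for k, v in sorted(tx.attributes.items())]
                fh.write(
                    "\t".join([
                        tx.chrom, source, "exon",
                        str(start + 1), str(end),  # back to 1-based inclusive
                        ".", tx.strand, ".",
                        " ".join(a + ";" for a in attrs),
                    ]) + "\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_counts(path: str | Path, design: Mapping[str, str] | str | Path):
    """Read a transcript x sample count TSV plus a design into ExpressionData.

    The TSV must carry the transcript id as its first column and may carry a
    ``length`` column (transcript length in bp), which is required to compute
    FPKM downstream. ``design`` is either a mapping sample -> group or a path
    to a two-column TSV.
    """
    from .expression import ExpressionData  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValidationError(f"{path}: empty count matrix")
    lengths = None
    if "length" in df.columns:
        lengths = df.pop("length").astype(int)
    if isinstance(design, (str, Path)):
        design = read_design(design)
    missing = [s for s in design if s not in df.columns]
    if missing:
        raise ValidationError(f"design samples missing from matrix: {missing}")
    df = df[list(design)]
    for col in df.columns:
        bad = df[col][~df[col].apply(lambda v: float(v).is_integer() and v >= 0)]
        if len(bad):
            raise ValidationError(
                f"non-integer or negative count at row {bad.index[0]!r}, column {col!r}"
            )
    return ExpressionData(counts=df.astype(int), lengths=lengths, design=dict(design))


def write_counts(expr, path: str | Path) -> None:
    df = expr.counts.copy()
    if expr.lengths is not None:
        df.insert(0, "length", expr.lengths)
    df.to_csv(path, sep="\t", index_label="transcript_id")


def read_design(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: design must have 2 columns (sample, group)")
    design = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if len(set(design.values())) != 2:
        raise ValidationError("design must define exactly two groups")
    return design


def write_design(design: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in design.items():
            fh.write(f"{sample}\t{group}\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
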