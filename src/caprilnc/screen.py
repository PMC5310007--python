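"""Candidate lncRNA screening.

Transcripts pass a basic structural/expression filter (spliced length
strictly greater than 200 nt, a minimum exon count, detectable expression),
are scored by three independent coding-potential scorers — an ORF
extent/coverage scorer, an in-frame hexamer log-likelihood-ratio scorer, and
a peptide motif scan — and survive as lncRNA candidates only if *all three*
scorers call them noncoding: a transcript flagged as coding by any scorer is
filtered out.

The three scorers are transparent stand-ins for CPC, CNCI and Pfam Scan
respectively; their thresholds are configuration, and externally computed
calls can be substituted for any of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .codonmodel import (
    DEFAULT_MOTIF_LIBRARY,
    coding_hexamer_logfreq,
    noncoding_hexamer_logfreq,
)
from .io import TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "OrfResult",
    "CodingVerdict",
    "ScreenConfig",
    "basic_filter",
    "find_orfs",
    "longest_orf",
    "orf_coding_score",
    "triplet_coding_score",
    "motif_scan",
    "consensus",
    "screen_transcripts",
]

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfResult:
    """An ATG-initiated reading frame segment on the spliced transcript.

    ``length`` counts nucleotides including the stop codon; ``complete`` is
    False when the frame ran off the transcript end without a stop (such
    ORFs are reported but never chosen as the longest ORF).
    """

    frame: int
    start: int
    end: int
    length: int
    peptide: str
    complete: bool = True


@dataclass
class CodingVerdict:
    transcript_id: str
    orf_score: float
    orf_call: str
    triplet_score: float
    triplet_call: str
    motif_hit: bool
    motif_call: str

    @property
    def consensus(self) -> str:
        calls = (self.orf_call, self.triplet_call, self.motif_call)
        return "noncoding" if all(c == "noncoding" for c in calls) else "coding"


@dataclass
class ScreenConfig:
    min_length: int = 200          # strictly greater-than, per the >200 nt rule
    min_exons: int = 1
    min_fpkm: float = 0.5          # in at least one sample
    orf_len_threshold: int = 300   # nt, inclusive
    coverage_threshold: float = 0.5
    orf_weight_length: float = 1.0
    orf_weight_coverage: float = 100.0
    motif_library: tuple[str, ...] = DEFAULT_MOTIF_LIBRARY


def basic_filter(transcripts: Sequence[TranscriptModel], expr,
                 min_length: int = 200, min_exons: int = 1,
                 min_fpkm: float = 0.5):
    """Keep transcripts with length > min_length, exon count >= min_exons and
    FPKM >= min_fpkm in at least one sample.

    Returns (surviving transcripts, attrition dict with per-rule counts).
    """
    missing = [t.transcript_id for t in transcripts
               if t.transcript_id not in expr.counts.index]
    if missing:
        raise ValueError(f"transcripts absent from expression matrix: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    fpkm_max = expr.fpkm.max(axis=1)
    kept = []
    attrition = {"input": len(transcripts), "length": 0, "exons": 0,
                 "expression": 0, "kept": 0}
    for tx in transcripts:
        if not tx.spliced_length > min_length:
            attrition["length"] += 1
        elif tx.n_exons < min_exons:
            attrition["exons"] += 1
        elif not fpkm_max[tx.transcript_id] >= min_fpkm:
            attrition["expression"] += 1
        else:
            kept.append(tx)
    attrition["kept"] = len(kept)
    return kept, attrition


def _translate(seq: str) -> str:
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def find_orfs(sequence: str, frames: int = 3) -> list[OrfResult]:
    """All ATG-initiated ORFs in the forward frames of a spliced sequence.

    Every ATG opens an ORF running to the first in-frame stop codon
    (included in the length); an ATG run that reaches the transcript end
    without a stop is reported with ``complete=False``. Codons containing N
    never match ATG or a stop.
    """
    sequence = sequence.upper()
    out: list[OrfResult] = []
    n = len(sequence)
    for frame in range(frames):
        codons = [(i, sequence[i:i + 3]) for i in range(frame, n - 2, 3)]
        open_starts: list[int] = []
        for pos, codon in codons:
            if codon in STOPS:
                for s in open_starts:
                    orf_seq = sequence[s:pos + 3]
                    out.append(OrfResult(
                        frame=frame, start=s, end=pos + 3, length=pos + 3 - s,
                        peptide=_translate(sequence[s:pos]), complete=True))
                open_starts = []
            elif codon == "ATG":
                open_starts.append(pos)
        for s in open_starts:  # ran off the end without a stop
            end = s + (n - s) // 3 * 3
            if end > s:
                out.append(OrfResult(frame=frame, start=s, end=end,
                                     length=end - s,
                                     peptide=_translate(sequence[s:end]),
                                     complete=False))
    out.sort(key=lambda o: (o.start, o.frame))
    return out


def longest_orf(sequence_or_orfs) -> OrfResult | None:
    """The longest *complete* ORF, or None. Ties break to the leftmost."""
    orfs = (find_orfs(sequence_or_orfs) if isinstance(sequence_or_orfs, str)
            else list(sequence_or_orfs))
    complete = [o for o in orfs if o.complete]
    if not complete:
        return None
    return max(complete, key=lambda o: (o.length, -o.start))


def orf_coding_score(transcript_length: int, orf: OrfResult | None,
                     orf_len_threshold: int = 300,
                     coverage_threshold: float = 0.5,
                     w_length: float = 1.0,
                     w_coverage: float = 100.0) -> tuple[float, str]:
    """ORF extent/quality scorer (CPC-like role).

    score = w_length * ORF length + w_coverage * (ORF length / transcript
    length); the call is coding iff ORF length >= orf_len_threshold or
    coverage >= coverage_threshold (both inclusive).
    """
    if orf is None:
        return 0.0, "noncoding"
    coverage = orf.length / transcript_length if transcript_length else 0.0
    score = w_length * orf.length + w_coverage * coverage
    call = ("coding" if orf.length >= orf_len_threshold
            or coverage >= coverage_threshold else "noncoding")
    return score, call


def triplet_coding_score(sequence: str,
                         coding_table: Mapping[str, float] | None = None,
                         noncoding_table: Mapping[str, float] | None = None,
                         ) -> tuple[float, str]:
    """Adjoining-triplet (hexamer) log-likelihood-ratio scorer (CNCI-like role).

    The score is the mean over in-frame sliding hexamers (step 3) of
    log(coding freq / noncoding freq), maximised over the three forward
    frames; the call is coding iff the score is strictly positive. Hexamers
    containing characters outside ACGT are skipped.
    """
    coding_table = coding_table or coding_hexamer_logfreq()
    noncoding_table = noncoding_table or noncoding_hexamer_logfreq()
    sequence = sequence.upper()
    if len(sequence) < 6:
        return 0.0, "noncoding"
    best = None
    for frame in range(3):
        total, count = 0.0, 0
        for i in range(frame, len(sequence) - 5, 3):
            hexamer = sequence[i:i + 6]
            if hexamer in coding_table:
                total += coding_table[hexamer] - noncoding_table[hexamer]
                count += 1
        if count:
            mean = total / count
            if best is None or mean > best:
                best = mean
    if best is None:
        return 0.0, "noncoding"
    return best, ("coding" if best > 0 else "noncoding")


def motif_scan(orfs: Iterable[OrfResult],
               motif_library: Sequence[str] = DEFAULT_MOTIF_LIBRARY,
               ) -> tuple[bool, str]:
    """Peptide motif scan (Pfam-like role) over per-ORF translations.

    Translations are the ORF peptides from all three frames, so a motif
    interrupted by a stop codon is never matched.
    """
    if not motif_library:
        logger.warning("motif_scan called with an empty motif library")
        return False, "noncoding"
    for orf in orfs:
        for motif in motif_library:
            if motif in orf.peptide:
                return True, "coding"
    return False, "noncoding"


def consensus(verdicts: Iterable[CodingVerdict]) -> list[str]:
    """Candidate lncRNA ids: transcripts called noncoding by all three scorers."""
    out = []
    for v in verdicts:
        for call in (v.orf_call, v.triplet_call, v.motif_call):
            if call not in ("coding", "noncoding"):
                raise ValueError(f"{v.transcript_id}: missing or invalid "
                                 f"scorer call {call!r}")
        if v.consensus == "noncoding":
            out.append(v.transcript_id)
    return out


def score_transcript(tx: TranscriptModel, config: ScreenConfig) -> CodingVerdict:
    if tx.sequence is None:
        raise ValueError(f"{tx.transcript_id}: sequence required for scoring")
    orfs = find_orfs(tx.sequence)
    best = longest_orf(orfs)
    orf_score, orf_call = orf_coding_score(
        tx.spliced_length, best,
        orf_len_threshold=config.orf_len_threshold,
        coverage_threshold=config.coverage_threshold,
        w_length=config.orf_weight_length,
        w_coverage=config.orf_weight_coverage)
    trip_score, trip_call = triplet_coding_score(tx.sequence)
    hit, motif_call = motif_scan(orfs, config.motif_library)
    return CodingVerdict(transcript_id=tx.transcript_id,
                         orf_score=orf_score, orf_call=orf_call,
                         triplet_score=trip_score, triplet_call=trip_call,
                         motif_hit=hit, motif_call=motif_call)


def screen_transcripts(transcripts: Sequence[TranscriptModel], expr,
                       config: ScreenConfig | None = None,
                       external_calls: Mapping[str, Mapping[str, str]] | None = None,
                       ):
    """Full screen: basic filter, three scorers, consensus.

    ``external_calls`` may map transcript_id -> {orf_call, triplet_call,
    motif_call} to override any internal scorer (hook for importing real
    CPC/CNCI/Pfam result tables).

    Returns (candidate transcript list, verdicts list, attrition dict).
    """
    config = config or ScreenConfig()
    surviving, attrition = basic_filter(
        transcripts, expr, min_length=config.min_length,
        min_exons=config.min_exons, min_fpkm=config.min_fpkm)
    verdicts = []
    for tx in surviving:
        v = score_transcript(tx, config)
        if external_calls and tx.transcript_id in external_calls:
            override = external_calls[tx.transcript_id]
            v.orf_call = override.get("orf_call", v.orf_call)
            v.triplet_call = override.get("triplet_call", v.triplet_call)
            v.motif_call = override.get("motif_call", v.motif_call)
        verdicts.append(v)
    keep_ids = set(consensus(verdicts))
    attrition["coding_potential"] = len(surviving) - len(keep_ids)
    attrition["candidates"] = len(keep_ids)
    candidates = [tx for tx in surviving if tx.transcript_id in keep_ids]
    return candidates, verdicts, attrition
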