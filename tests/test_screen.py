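"""ORF finding, the three coding-potential scorers, and the consensus rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caprilnc.codonmodel import (coding_hexamer_logfreq, encode_peptide,
                                 noncoding_hexamer_logfreq,
                                 sample_coding_codons)
from caprilnc.screen import (CodingVerdict, OrfResult, basic_filter, consensus,
                             find_orfs, longest_orf, motif_scan,
                             orf_coding_score, screen_transcripts,
                             triplet_coding_score)
from caprilnc.io import TranscriptModel

from conftest import toy_expression

STOPS = ("TAA", "TAG", "TGA")


def brute_force_orfs(seq: str) -> set:
    """Exhaustive position scan; independent of the scanning implementation."""
    seq = seq.upper()
    out = set()
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        j = i + 3
        complete = False
        while j + 3 <= len(seq):
            if seq[j:j + 3] in STOPS:
                out.add((i % 3, i, j + 3, j + 3 - i, True))
                complete = True
                break
            j += 3
        if not complete:
            end = i + (len(seq) - i) // 3 * 3
            if end > i:
                out.add((i % 3, i, end, end - i, False))
    return out


@pytest.mark.parametrize("seq, expected", [
    ("ATGAAATAG", [(0, 0, 9, 9, "MK", True)]),
    ("CCCCCC", []),
    ("", []),
    ("ATGATGTAA", [(0, 0, 9, 9, "MM", True), (0, 3, 9, 6, "M", True)]),
    ("ATGAAA", [(0, 0, 6, 6, "MK", False)]),       # runs off the end
    ("ATNAAATAG", []),                              # N never matches ATG
])
def test_find_orfs_hand_cases(seq, expected):
    got = [(o.frame, o.start, o.end, o.length, o.peptide, o.complete)
           for o in find_orfs(seq)]
    assert got == expected


def test_longest_orf_ignores_incomplete_runs():
    # the longer ATG run has no stop; the shorter complete ORF wins
    seq = "ATGAAAAAAAAAAAA" + "ATGTAA"
    best = longest_orf(seq)
    assert best is not None and best.complete


@settings(max_examples=300, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGTN", max_size=60))
def test_find_orfs_matches_exhaustive_scan(seq):
    got = {(o.frame, o.start, o.end, o.length, o.complete)
           for o in find_orfs(seq)}
    assert got == brute_force_orfs(seq)


@pytest.mark.parametrize("orf_len, tx_len, call", [
    (None, 1180, "noncoding"),
    (300, 600, "coding"),      # coverage exactly 0.5, inclusive boundary
    (300, 1200, "coding"),     # length exactly at the 300 nt threshold
    (105, 1180, "noncoding"),  # the typical planted lncRNA passes screening
    (297, 1200, "noncoding"),
])
def test_orf_scorer_thresholds(orf_len, tx_len, call):
    orf = None if orf_len is None else OrfResult(0, 0, orf_len, orf_len, "X")
    score, got = orf_coding_score(tx_len, orf)
    assert got == call
    if orf_len is None:
        assert score == 0.0


def test_triplet_score_zero_for_identical_tables():
    table = noncoding_hexamer_logfreq()
    score, call = triplet_coding_score("ACGTACGTACGT", table, table)
    assert score == 0.0 and call == "noncoding"


def test_triplet_score_short_sequence_is_noncoding():
    assert triplet_coding_score("ACGTA") == (0.0, "noncoding")


def test_triplet_scorer_separates_the_two_sequence_models():
    rng = np.random.default_rng(0)
    coding_calls, noncoding_calls = [], []
    for _ in range(100):
        seq = "".join(sample_coding_codons(rng, 100))
        coding_calls.append(triplet_coding_score(seq)[1])
        bg = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        noncoding_calls.append(triplet_coding_score(bg)[1])
    assert coding_calls.count("coding") >= 95
    assert noncoding_calls.count("noncoding") >= 95


def test_motif_scan_hits_verbatim_motifs_only():
    motif = "HEAGAWGH"
    seq = "ATG" + encode_peptide(motif) + "TAA"
    assert motif_scan(find_orfs(seq), (motif,)) == (True, "coding")
    assert motif_scan(find_orfs(seq), ()) == (False, "noncoding")
    # the same peptide split by an in-frame stop is never matched
    half = encode_peptide(motif[:4])
    rest = encode_peptide(motif[4:])
    split = "ATG" + half + "TAA" + "ATG" + rest + "TAA"
    assert motif_scan(find_orfs(split), (motif,)) == (False, "noncoding")


def _verdict(tid, calls):
    return CodingVerdict(transcript_id=tid, orf_score=0, orf_call=calls[0],
                         triplet_score=0, triplet_call=calls[1],
                         motif_hit=calls[2] == "coding", motif_call=calls[2])


@pytest.mark.parametrize("calls, kept", [
    (("noncoding", "noncoding", "noncoding"), True),
    (("coding", "noncoding", "noncoding"), False),
    (("noncoding", "coding", "noncoding"), False),
    (("noncoding", "noncoding", "coding"), False),
    (("coding", "coding", "coding"), False),
])
def test_consensus_is_the_intersection_rule(calls, kept):
    result = consensus([_verdict("t1", calls)])
    assert (result == ["t1"]) is kept


def test_consensus_rejects_missing_calls_and_empty_input():
    assert consensus([]) == []
    bad = _verdict("t1", ("noncoding", "noncoding", "noncoding"))
    bad.triplet_call = None
    with pytest.raises(ValueError, match="t1"):
        consensus([bad])


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.tuples(*[st.sampled_from(["coding", "noncoding"])] * 3),
                min_size=1, max_size=8),
       st.data())
def test_flipping_a_call_to_coding_never_adds_candidates(calls, data):
    verdicts = [_verdict(f"t{i}", c) for i, c in enumerate(calls)]
    before = set(consensus(verdicts))
    i = data.draw(st.integers(0, len(verdicts) - 1))
    attr = data.draw(st.sampled_from(["orf_call", "triplet_call", "motif_call"]))
    setattr(verdicts[i], attr, "coding")
    after = set(consensus(verdicts))
    assert after <= before


def _tx(tid, length, n_exons=1):
    exons, pos = [], 0
    per = length // n_exons
    for i in range(n_exons):
        size = per if i < n_exons - 1 else length - per * (n_exons - 1)
        exons.append((pos, pos + size))
        pos += size + 100
    return TranscriptModel(tid, f"g_{tid}", "chr1", "+", exons)


def test_basic_filter_rules():
    txs = [_tx("len200", 200), _tx("len201", 201), _tx("silent", 500),
           _tx("mono", 500, 1), _tx("multi", 500, 3)]
    expr = toy_expression(
        {t.transcript_id: [100] * 6 for t in txs} | {"silent": [0] * 6},
        {t.transcript_id: t.spliced_length for t in txs})
    kept, attrition = basic_filter(txs, expr, min_length=200, min_exons=1,
                                   min_fpkm=0.5)
    ids = {t.transcript_id for t in kept}
    assert "len200" not in ids          # strictly greater than 200 required
    assert "len201" in ids
    assert "silent" not in ids          # all-zero expression row
    assert attrition["length"] == 1 and attrition["expression"] == 1
    # neutral thresholds: only the length rule acts
    kept2, _ = basic_filter(txs, expr, min_exons=1, min_fpkm=0.0)
    assert {t.transcript_id for t in kept2} == ids | {"silent"}
    # exon rule
    kept3, _ = basic_filter(txs, expr, min_exons=2, min_fpkm=0.0)
    assert "mono" not in {t.transcript_id for t in kept3}
    with pytest.raises(ValueError, match="absent"):
        basic_filter([_tx("ghost", 300)], expr)


def test_screen_recovers_planted_lncrnas(default_study):
    truth = default_study.truth
    candidates, _verdicts, _attr = screen_transcripts(
        default_study.transcripts, default_study.expr)
    cand = {t.transcript_id for t in candidates}
    true_lnc = set(truth.true_lnc_ids)
    true_coding = set(truth.true_coding_ids)
    assert len(cand & true_lnc) / len(true_lnc) >= 0.95
    assert len(cand & true_coding) / len(true_coding) <= 0.05
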