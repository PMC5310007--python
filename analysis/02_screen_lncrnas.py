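#!/usr/bin/env python
"""Screen candidate lncRNAs from the assembled transcripts.

Reads the study files written by 01_simulate_study.py, applies the basic
filters (>200 nt, expression) and the three coding-potential scorers, keeps
transcripts that all three call noncoding, and writes the verdicts table and
candidate GTF under results/screen/. Prints the per-rule attrition and, since
the study is synthetic, the recovery against the planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from caprilnc import io as cio
from caprilnc.screen import screen_transcripts
from caprilnc.simulate import GroundTruth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    study = Path(args.out) / "study"

    _genes, transcripts = cio.read_gtf(study / "transcripts.gtf")
    seqs = cio.read_fasta(study / "transcripts.fa")
    for tx in transcripts:
        tx.sequence = seqs[tx.transcript_id]
    expr = cio.read_counts(study / "counts.tsv", study / "design.tsv")
    truth = GroundTruth.from_dict(cio.read_json(study / "truth.json"))

    candidates, verdicts, attrition = screen_transcripts(transcripts, expr)
    outdir = Path(args.out) / "screen"
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "transcript_id": v.transcript_id, "orf_score": v.orf_score,
        "orf_call": v.orf_call, "triplet_score": v.triplet_score,
        "triplet_call": v.triplet_call, "motif_hit": v.motif_hit,
        "motif_call": v.motif_call, "consensus": v.consensus,
    } for v in verdicts]).set_index("transcript_id").to_csv(
        outdir / "verdicts.tsv", sep="\t", float_format="%.6g")
    cio.write_gtf(candidates, outdir / "candidates.gtf")

    cand = {t.transcript_id for t in candidates}
    true_lnc, true_coding = set(truth.true_lnc_ids), set(truth.true_coding_ids)
    print("attrition:", attrition)
    print(f"candidates: {len(cand)}")
    print(f"sensitivity {100 * len(cand & true_lnc) / len(true_lnc):.1f}% | "
          f"coding contamination "
          f"{100 * len(cand & true_coding) / len(true_coding):.1f}%")


if __name__ == "__main__":
    main()
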