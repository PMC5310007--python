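"""lncRNA vs mRNA feature comparison.

Summarises four features per class — expression level (log10 of the maximum
FPKM across samples, plus a small offset), spliced transcript length, longest
complete ORF length, and exon number — with mean/median/quartiles, histogram
bins, and a two-sample Mann-Whitney rank test per feature.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import TranscriptModel
from .screen import longest_orf

__all__ = ["feature_summary", "feature_values"]

FEATURES = ("expression", "length", "orf_length", "exon_count")
EXPRESSION_OFFSET = 1e-3


def feature_values(transcripts: Sequence[TranscriptModel], expr,
                   sequences: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-transcript feature table (expression, length, orf_length, exon_count)."""
    if not transcripts:
        raise ValueError("empty transcript class")
    fp = expr.fpkm
    rows = {}
    for tx in transcripts:
        seq = tx.sequence if tx.sequence is not None else (
            sequences.get(tx.transcript_id) if sequences else None)
        if seq is None:
            raise ValueError(f"{tx.transcript_id}: sequence required for ORF length")
        orf = longest_orf(seq)
        rows[tx.transcript_id] = {
            "expression": float(np.log10(fp.loc[tx.transcript_id].max()
                                         + EXPRESSION_OFFSET)),
            "length": tx.spliced_length,
            "orf_length": orf.length if orf is not None else 0,
            "exon_count": tx.n_exons,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _summarise(values: np.ndarray, bins: int) -> dict:
    counts, edges = np.histogram(values, bins=bins)
    return {
        "mean": float(np.mean(values)),
        "median": float(np.median(values)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
        "hist_counts": counts.tolist(),
        "hist_edges": edges.tolist(),
    }


def feature_summary(lnc_transcripts: Sequence[TranscriptModel],
                    coding_transcripts: Sequence[TranscriptModel],
                    expr, sequences: Mapping[str, str] | None = None,
                    bins: int = 20) -> pd.DataFrame:
    """Per-class summaries of the four features, with a rank-test p per feature.

    Returns a table indexed by (feature, class) with summary columns and the
    Mann-Whitney p for the lncRNA vs mRNA comparison repeated on both rows of
    a feature.
    """
    if not lnc_transcripts or not coding_transcripts:
        raise ValueError("both classes must be non-empty")
    lnc = feature_values(lnc_transcripts, expr, sequences)
    mrna = feature_values(coding_transcripts, expr, sequences)
    rows = []
    for feature in FEATURES:
        a, b = lnc[feature].values, mrna[feature].values
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0    # identical distributions; rank test is uninformative
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        for cls, vals in (("lncRNA", a), ("mRNA", b)):
            row = {"feature": feature, "class": cls,
                   "n": len(vals), "rank_test_p": p}
            row.update(_summarise(vals, bins))
            rows.append(row)
    return pd.DataFrame(rows).set_index(["feature", "class"])
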