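"""Target-gene prediction for lncRNAs.

Cis targets are protein-coding genes whose span lies within a distance
window (10 kb / 100 kb by default, inclusive) of the lncRNA span on the same
chromosome, either side, strand-agnostic; distance is the gap between spans
(0 when they overlap) and each pair is labelled with the smallest qualifying
window. Trans targets are coding transcripts whose FPKM profile across all
samples correlates with the lncRNA's beyond a strict Pearson threshold
(|r| > 0.95 by default, strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneAnnotation, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = ["TargetPair", "cis_targets", "pearson_r", "trans_targets",
           "target_table"]

DEFAULT_WINDOWS = (10_000, 100_000)


@dataclass(frozen=True)
class TargetPair:
    lnc_id: str
    gene_id: str
    mode: str                    # "cis" | "trans"
    distance: int | None = None  # bp gap, 0 if overlapping (cis)
    window: int | None = None    # smallest qualifying window in bp (cis)
    r: float | None = None       # Pearson coefficient (trans)

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "cis":
            if self.distance is None or self.window is None:
                raise ValueError("cis pair needs distance and window")
            if self.distance > self.window:
                raise ValueError("cis distance exceeds its window")
        if self.mode == "trans":
            if self.r is None or not -1.0 <= self.r <= 1.0:
                raise ValueError("trans pair needs r in [-1, 1]")


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(b[0] - a[1], a[0] - b[1])


def cis_targets(lncs: Sequence[TranscriptModel],
                genes: Sequence[GeneAnnotation],
                windows: Sequence[int] = DEFAULT_WINDOWS) -> list[TargetPair]:
    """All (lncRNA, protein-coding gene) pairs with span gap <= max(windows)."""
    windows = sorted(windows)
    maxw = windows[-1]
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        if gene.biotype != "protein_coding":
            continue
        tree = trees.setdefault(gene.chrom, IntervalTree())
        # expand the gene span by the largest window (+1 so the inclusive
        # boundary survives the half-open tree) so one stab query finds
        # every candidate; the exact gap test below prunes over-inclusion
        tree.addi(gene.span[0] - maxw - 1, gene.span[1] + maxw + 1, gene)
    pairs: list[TargetPair] = []
    for lnc in lncs:
        tree = trees.get(lnc.chrom)
        if tree is None:
            continue
        span = lnc.span
        for iv in sorted(tree.overlap(span[0], span[1]),
                         key=lambda iv: iv.data.gene_id):
            gene = iv.data
            gap = _gap(span, gene.span)
            if gap > maxw:
                continue
            window = next(w for w in windows if gap <= w)
            pairs.append(TargetPair(lnc_id=lnc.transcript_id,
                                    gene_id=gene.gene_id, mode="cis",
                                    distance=gap, window=window))
    return pairs


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises on zero variance or length < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("zero variance")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def trans_targets(expr, lnc_ids: Sequence[str], coding_ids: Sequence[str],
                  threshold: float = 0.95,
                  gene_of: Mapping[str, str] | None = None) -> list[TargetPair]:
    """Coexpression pairs with r > threshold or r < -threshold (strict).

    Correlations are computed on FPKM across all samples pooled over groups.
    Rows with zero variance are skipped (count logged). ``gene_of``
    optionally maps coding transcript ids to gene ids for reporting.
    """
    if len(expr.samples) < 3:
        raise ValueError("trans target prediction needs at least 3 samples")
    fp = expr.fpkm
    missing = [t for t in list(lnc_ids) + list(coding_ids)
               if t not in fp.index]
    if missing:
        raise ValueError(f"ids absent from expression matrix: {missing[:5]}")

    def standardised(ids):
        mat = fp.loc[ids].values.astype(float)
        centred = mat - mat.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centred, axis=1)
        ok = norms > 0
        centred[ok] = centred[ok] / norms[ok, None]
        return centred, ok

    lnc_ids = list(lnc_ids)
    coding_ids = list(coding_ids)
    X, x_ok = standardised(lnc_ids)
    Y, y_ok = standardised(coding_ids)
    skipped = int((~x_ok).sum() + (~y_ok).sum())
    if skipped:
        logger.info("trans_targets: skipped %d zero-variance rows", skipped)
    R = np.clip(X @ Y.T, -1.0, 1.0)
    pairs: list[TargetPair] = []
    for i, lt in enumerate(lnc_ids):
        if not x_ok[i]:
            continue
        for j, gt in enumerate(coding_ids):
            if not y_ok[j]:
                continue
            r = float(R[i, j])
            if r > threshold or r < -threshold:
                gid = gene_of[gt] if gene_of else gt
                pairs.append(TargetPair(lnc_id=lt, gene_id=gid,
                                        mode="trans", r=r))
    return pairs


def target_table(cis_pairs: Sequence[TargetPair],
                 trans_pairs: Sequence[TargetPair]) -> pd.DataFrame:
    """Merged per-lncRNA report: cis and trans target lists side by side.

    lncRNAs with no pair of either kind are absent from the table.
    """
    per_lnc: dict[str, dict[str, list[str]]] = {}
    for p in cis_pairs:
        per_lnc.setdefault(p.lnc_id, {"cis": [], "trans": []})["cis"].append(p.gene_id)
    for p in trans_pairs:
        per_lnc.setdefault(p.lnc_id, {"cis": [], "trans": []})["trans"].append(p.gene_id)
    rows = []
    for lnc_id in sorted(per_lnc):
        entry = per_lnc[lnc_id]
        rows.append({
            "lnc_id": lnc_id,
            "n_cis": len(entry["cis"]),
            "n_trans": len(entry["trans"]),
            "cis_targets": ",".join(sorted(entry["cis"])),
            "trans_targets": ",".join(sorted(entry["trans"])),
        })
    return pd.DataFrame(rows, columns=["lnc_id", "n_cis", "n_trans",
                                       "cis_targets", "trans_targets"])
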