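"""Expression quantification and two-group differential expression.

Expression is summarised as FPKM (fragments per kilobase of transcript per
million mapped fragments). Differential expression between the two groups is
tested per transcript with a negative-binomial Wald test: group means are
estimated from library-size-normalised counts, the NB dispersion is a
per-transcript method-of-moments estimate shrunk toward a fitted
mean-dispersion trend, and the Wald statistic on the log-mean difference is
referred to the standard normal distribution. This is an
explicit stand-in for Cuffdiff's NB machinery, which operates on read-level
data this pipeline does not model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionData",
    "DiffExprResult",
    "fpkm",
    "estimate_dispersions",
    "nb_test",
    "differential_expression",
    "de_summary",
    "group_specific",
    "volcano_table",
]

#: pseudocount (in FPKM units) used when forming log2 fold changes
LOG2FC_PSEUDOCOUNT = 1.0


def fpkm(count: float, transcript_length_bp: float, library_size: float) -> float:
    """FPKM = 1e9 * count / (library_size * transcript_length_bp)."""
    if transcript_length_bp <= 0:
        raise ValueError("transcript length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return 1e9 * count / (library_size * transcript_length_bp)


@dataclass
class ExpressionData:
    """Counts, lengths and a two-group design, with FPKM derived on demand."""

    counts: pd.DataFrame
    lengths: pd.Series | None
    design: dict[str, str]
    _fpkm: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise ValueError("empty count matrix")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.design if s not in self.counts.columns]
        if missing:
            raise ValueError(f"design samples missing from matrix: {missing}")
        self.counts = self.counts[list(self.design)]
        groups = self.groups
        if len(groups) != 2:
            raise ValueError(f"need exactly two groups, got {sorted(groups)}")
        for g, samples in groups.items():
            if not samples:
                raise ValueError(f"group {g!r} has no samples")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                missing_len = self.lengths[self.lengths.isna()].index.tolist()[:5]
                raise ValueError(f"missing lengths for transcripts: {missing_len}")
            if (self.lengths <= 0).any():
                raise ValueError("transcript lengths must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, group in self.design.items():
            out.setdefault(group, []).append(sample)
        return out

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def fpkm(self) -> pd.DataFrame:
        if self._fpkm is None:
            if self.lengths is None:
                raise ValueError("transcript lengths are required for FPKM")
            lib = self.library_sizes.astype(float)
            self._fpkm = (
                1e9 * self.counts.astype(float) / lib
            ).div(self.lengths.astype(float), axis=0)
        return self._fpkm

    def subset(self, transcript_ids: Sequence[str]) -> "ExpressionData":
        ids = [t for t in transcript_ids]
        lengths = self.lengths.loc[ids] if self.lengths is not None else None
        return ExpressionData(counts=self.counts.loc[ids].copy(),
                              lengths=lengths, design=dict(self.design))


@dataclass
class DiffExprResult:
    transcript_id: str
    mean_fpkm: dict[str, float]
    log2fc: float
    pvalue: float
    qvalue: float | None
    direction: str  # "up" | "down" in the case group
    testable: bool = True


def _normalised_counts(expr: ExpressionData) -> pd.DataFrame:
    lib = expr.library_sizes.astype(float)
    size_factors = lib / lib.mean()
    return expr.counts.astype(float) / size_factors


def estimate_dispersions(expr: ExpressionData, prior_df: float = 10.0) -> pd.Series:
    """Per-transcript NB dispersions, shrunk toward a mean-dispersion trend.

    The raw estimate is the pooled within-group method-of-moments value
    ``(s^2 - m) / m^2``; the trend ``alpha(m) = a/m + b`` is fitted across
    transcripts by least squares and each raw value is averaged with the
    trend, weighted by the within-group residual degrees of freedom against
    ``prior_df`` pseudo-observations.
    """
    norm = _normalised_counts(expr)
    groups = expr.groups
    n_total = sum(len(s) for s in groups.values())
    df_resid = n_total - len(groups)

    mean_overall = norm.mean(axis=1)
    ss = pd.Series(0.0, index=norm.index)
    for samples in groups.values():
        sub = norm[samples]
        ss += ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1)
    var_within = ss / max(df_resid, 1)

    m = mean_overall.clip(lower=1e-8)
    raw = ((var_within - m) / m**2).clip(lower=0.0)

    # trend fit alpha = a/m + b over expressed transcripts
    expressed = mean_overall > 0.5
    if expressed.sum() >= 10:
        x = 1.0 / m[expressed].values
        y = raw[expressed].values
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a, b = max(coef[0], 0.0), max(coef[1], 1e-6)
    else:  # too few rows to fit a trend; fall back to the global mean
        a, b = 0.0, max(float(raw.mean()), 1e-6)
    trend = a / m + b

    w = df_resid / (df_resid + prior_df)
    shrunk = w * raw + (1 - w) * trend
    return shrunk.clip(lower=1e-8)


def nb_test(counts_row: pd.Series | np.ndarray, design: Mapping[str, str],
            dispersion_estimate: float, library_sizes: pd.Series | None = None,
            case_group: str | None = None,
            lengths_scale: tuple[float, float] | None = None,
            transcript_id: str = "") -> DiffExprResult:
    """NB Wald test of equal group means for one transcript.

    ``lengths_scale`` optionally provides (length_bp, total_library) so the
    per-group mean FPKM can be filled in; otherwise mean normalised counts
    are reported in its place.
    """
    samples = list(design)
    if isinstance(counts_row, pd.Series):
        counts_row = counts_row[samples]
        values = counts_row.values.astype(float)
    else:
        values = np.asarray(counts_row, dtype=float)
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        groups.setdefault(design[s], []).append(i)
    if len(groups) != 2 or min(len(ix) for ix in groups.values()) < 2:
        raise ValueError("nb_test requires two groups with >= 2 samples each")
    group_names = sorted(groups)
    if case_group is None:
        case_group = group_names[1]
    control_group = next(g for g in group_names if g != case_group)

    if library_sizes is not None:
        lib = np.asarray([library_sizes[s] for s in samples], dtype=float)
        sf = lib / lib.mean()
    else:
        sf = np.ones_like(values)
    norm = values / sf

    means = {g: float(norm[ix].mean()) for g, ix in groups.items()}
    ns = {g: len(ix) for g, ix in groups.items()}

    def to_fpkm(x: float) -> float:
        if lengths_scale is None:
            return x
        length_bp, total_lib = lengths_scale
        return 1e9 * x / (total_lib * length_bp)

    mean_fpkm = {g: to_fpkm(means[g]) for g in group_names}
    alpha = max(float(dispersion_estimate), 1e-8)

    if values.sum() == 0:
        return DiffExprResult(transcript_id=transcript_id, mean_fpkm=mean_fpkm,
                              log2fc=0.0, pvalue=1.0, qvalue=None,
                              direction="up", testable=False)

    eps = 0.5
    m1 = means[case_group] + eps
    m0 = means[control_group] + eps
    log_diff = np.log(m1) - np.log(m0)
    se2 = sum((1.0 / (means[g] + eps) + alpha) / ns[g] for g in group_names)
    se = np.sqrt(se2)
    wald = log_diff / se
    pvalue = float(2.0 * stats.norm.sf(abs(wald)))

    pc = LOG2FC_PSEUDOCOUNT
    log2fc = float(np.log2((mean_fpkm[case_group] + pc) / (mean_fpkm[control_group] + pc)))
    direction = "up" if log2fc >= 0 else "down"
    return DiffExprResult(transcript_id=transcript_id, mean_fpkm=mean_fpkm,
                          log2fc=log2fc, pvalue=pvalue, qvalue=None,
                          direction=direction)


def differential_expression(expr: ExpressionData, case_group: str | None = None,
                            prior_df: float = 10.0) -> pd.DataFrame:
    """Run the NB Wald test on every transcript; returns a tidy table.

    Columns: mean FPKM per group, log2fc (case over control, pseudocount
    1 FPKM), raw p, BH q, direction, testable flag.
    """
    if expr.lengths is None:
        raise ValueError("differential expression needs transcript lengths (FPKM)")
    group_names = sorted(expr.groups)
    if case_group is None:
        case_group = group_names[1]
    dispersions = estimate_dispersions(expr, prior_df=prior_df)
    lib = expr.library_sizes
    total_lib = float(lib.mean())

    rows = []
    for tid in expr.counts.index:
        res = nb_test(expr.counts.loc[tid], expr.design,
                      dispersions[tid], library_sizes=lib,
                      case_group=case_group,
                      lengths_scale=(float(expr.lengths[tid]), total_lib),
                      transcript_id=tid)
        rows.append(res)
    pvals = np.array([r.pvalue for r in rows])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    control_group = next(g for g in group_names if g != case_group)
    df = pd.DataFrame({
        "transcript_id": [r.transcript_id for r in rows],
        f"mean_fpkm_{control_group}": [r.mean_fpkm[control_group] for r in rows],
        f"mean_fpkm_{case_group}": [r.mean_fpkm[case_group] for r in rows],
        "log2fc": [r.log2fc for r in rows],
        "pvalue": pvals,
        "qvalue": qvals,
        "direction": [r.direction for r in rows],
        "testable": [r.testable for r in rows],
    }).set_index("transcript_id")
    return df


def de_summary(results: pd.DataFrame, alpha: float = 0.05,
               on: str = "pvalue") -> tuple[int, int, int]:
    """(n_significant, n_up, n_down) at threshold ``alpha`` on column ``on``."""
    sig = results[(results[on] < alpha) & results["testable"]]
    n_up = int((sig["direction"] == "up").sum())
    n_down = int((sig["direction"] == "down").sum())
    return n_up + n_down, n_up, n_down


def group_specific(expr: ExpressionData, presence_fpkm: float = 1.0,
                   absence_fpkm: float = 0.1) -> dict[str, list[str]]:
    """Transcripts expressed in every sample of one group and absent in the other.

    A transcript is group-A specific iff FPKM >= presence_fpkm in every A
    sample and <= absence_fpkm in every B sample. The two sets are disjoint
    because presence must exceed absence.
    """
    if presence_fpkm <= absence_fpkm:
        raise ValueError("presence_fpkm must be > absence_fpkm")
    fp = expr.fpkm
    out: dict[str, list[str]] = {}
    groups = expr.groups
    for g, samples in groups.items():
        other = [s for og, ss in groups.items() if og != g for s in ss]
        present = (fp[samples] >= presence_fpkm).all(axis=1)
        absent = (fp[other] <= absence_fpkm).all(axis=1)
        out[g] = fp.index[present & absent].tolist()
    return out


def volcano_table(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows of (log2fc, -log10 p, significance flag) for volcano plotting."""
    p = results["pvalue"].clip(lower=1e-300)
    return pd.DataFrame({
        "log2fc": results["log2fc"],
        "neg_log10_p": -np.log10(p),
        "significant": results["pvalue"] < alpha,
    }, index=results.index)
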