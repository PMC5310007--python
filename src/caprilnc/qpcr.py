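"""Relative qPCR quantification by the 2^-ddCt method.

Per sample, dCt is the mean replicate Ct of the target minus the mean
replicate Ct of the reference gene (beta-actin by default); ddCt subtracts
the calibrator group's mean dCt; relative expression is 2^-ddCt. Group
differences are tested with an equal-variance two-sided t-test on the dCt
values (the approximately normal scale), with significance stars at 0.05 and
0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CtTable", "ddct_fold_change", "group_ttest"]

REQUIRED_COLUMNS = ("sample_id", "group", "gene", "replicate", "ct")


@dataclass
class CtTable:
    """Long-format Ct measurements plus the reference gene name."""

    data: pd.DataFrame
    reference_gene: str = "beta-actin"

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        samples = set(self.data["sample_id"])
        ref_samples = set(
            self.data.loc[self.data["gene"] == self.reference_gene, "sample_id"])
        lacking = sorted(samples - ref_samples)
        if lacking:
            raise ValueError(
                f"reference gene {self.reference_gene!r} not measured in "
                f"samples: {lacking}")

    def mean_ct(self, gene: str) -> pd.Series:
        """Replicate-averaged Ct per sample for one gene."""
        sub = self.data[self.data["gene"] == gene]
        if sub.empty:
            raise ValueError(f"gene {gene!r} absent from Ct table")
        return sub.groupby("sample_id")["ct"].mean()

    @property
    def groups(self) -> pd.Series:
        return (self.data[["sample_id", "group"]]
                .drop_duplicates().set_index("sample_id")["group"])


def ddct_fold_change(ct: CtTable, target_gene: str,
                     calibrator_group: str) -> pd.DataFrame:
    """Per-sample dCt, ddCt and 2^-ddCt fold change for one target gene.

    The calibrator group's mean dCt is the baseline, so its mean fold change
    is 1 by construction. Returns one row per sample with group labels, plus
    group mean +/- SD retrievable by aggregation.
    """
    target = ct.mean_ct(target_gene)
    reference = ct.mean_ct(ct.reference_gene)
    missing = sorted(set(target.index) - set(reference.index))
    if missing:
        raise ValueError(f"reference measurements missing for samples: {missing}")
    dct = target - reference.loc[target.index]
    groups = ct.groups.loc[dct.index]
    if calibrator_group not in set(groups):
        raise ValueError(f"calibrator group {calibrator_group!r} not in table")
    baseline = dct[groups == calibrator_group].mean()
    ddct = dct - baseline
    fold = np.power(2.0, -ddct)
    return pd.DataFrame({"group": groups, "dct": dct,
                         "ddct": ddct, "fold_change": fold})


def group_ttest(per_sample: pd.DataFrame, on: str = "dct",
                ) -> tuple[float, str]:
    """Equal-variance two-sided t-test between the two groups.

    ``per_sample`` is the ddct_fold_change output; ``on`` selects the tested
    scale (dCt by default). Returns (p, stars) with stars '' / '*' / '**' at
    0.05 / 0.01. Two identical constant groups give p = 1.
    """
    groups = per_sample["group"].unique()
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    a = per_sample.loc[per_sample["group"] == groups[0], on].values
    b = per_sample.loc[per_sample["group"] == groups[1], on].values
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
    return p, stars
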