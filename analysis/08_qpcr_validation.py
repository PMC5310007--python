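#!/usr/bin/env python
"""qPCR validation: 2^-ddCt fold changes for the assayed lncRNAs.

Reads the Ct table from the study, normalises to beta-actin, calibrates on
the prepubertal group, tests group differences on dCt, and writes the fold
changes under results/qpcr/.
"""

import argparse
from pathlib import Path

import pandas as pd

from caprilnc.qpcr import CtTable, ddct_fold_change, group_ttest


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out)

    ct = CtTable(pd.read_csv(out / "study" / "ct_values.tsv", sep="\t"))
    rows = []
    for gene in sorted(set(ct.data["gene"]) - {ct.reference_gene}):
        res = ddct_fold_change(ct, gene, calibrator_group="prepubertal")
        p, stars = group_ttest(res)
        for group, sub in res.groupby("group"):
            rows.append({"gene": gene, "group": group,
                         "mean_fold": sub["fold_change"].mean(),
                         "sd_fold": sub["fold_change"].std(ddof=1),
                         "p": p, "stars": stars})
        pub = res.loc[res["group"] == "pubertal", "fold_change"]
        print(f"{gene}: pubertal fold change {pub.mean():.2f} "
              f"+/- {pub.std(ddof=1):.2f} (p = {p:.2g}{' ' + stars if stars else ''})")

    outdir = out / "qpcr"
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(outdir / "fold_changes.tsv", sep="\t",
                              index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
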