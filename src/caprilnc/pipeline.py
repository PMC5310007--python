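"""End-to-end pipeline orchestration.

``run_pipeline`` executes simulate -> screen -> classify -> differential
expression -> targets -> enrichment -> feature stats (-> qPCR) on a single
config, writing every stage's tables under the run directory plus a manifest
with the seed, parameters and per-stage attrition counts. Outputs are pure
functions of the config, so two runs with the same config produce
byte-identical tables. ``evaluate_recovery`` scores a synthetic run against
its planted ground truth.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .biotype import biotype_summary, classify_all
from .enrich import enrich
from .expression import (de_summary, differential_expression, group_specific,
                         volcano_table)
from .featurestats import feature_summary
from .qpcr import CtTable, ddct_fold_change, group_ttest
from .screen import ScreenConfig, screen_transcripts
from .simulate import SynthConfig, generate_study, write_study
from .targets import cis_targets, target_table, trans_targets

__all__ = ["default_config", "load_config", "run_pipeline", "evaluate_recovery"]

FLOAT_FORMAT = "%.6g"


def default_config() -> dict:
    """The shipped config: every stage's thresholds under named keys."""
    return {
        "seed": 0,
        "synth": {},          # SynthConfig overrides
        "screen": {
            "min_length": 200,     # candidates must be > 200 nt
            "min_exons": 1,
            "min_fpkm": 0.5,
            "orf_len_threshold": 300,
            "coverage_threshold": 0.5,
        },
        "expression": {
            "alpha": 0.05,         # raw p threshold for DE calls
            "presence_fpkm": 1.0,  # group-specific presence threshold
            "absence_fpkm": 0.1,
        },
        "targets": {
            "windows": [10_000, 100_000],
            "trans_threshold": 0.95,
        },
        "enrich": {"enabled": True, "alpha": 0.05},
        "qpcr": {"enabled": True, "calibrator_group": "prepubertal"},
        "evaluate": False,
    }


def load_config(path: str | Path | None = None, seed: int | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, **kw)


def run_pipeline(config: dict | str | Path | None, outdir: str | Path,
                 seed: int | None = None) -> dict:
    """Run every stage on a synthetic study; returns the manifest dict."""
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config, seed=seed)
    elif seed is not None:
        config = {**config, "seed": int(seed)}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "caprilnc",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config["seed"],
        "config": config,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # --- simulate -----------------------------------------------------------
    synth = SynthConfig(seed=config["seed"], **config.get("synth", {}))
    study = generate_study(synth)
    study_dir = outdir / "study"
    paths = write_study(study, study_dir)
    manifest["stages"]["simulate"] = {
        "n_genes": len(study.genes),
        "n_transcripts": len(study.transcripts),
        "outputs": {k: str(Path(v).relative_to(outdir))
                    for k, v in paths.items()},
    }

    # --- screen -------------------------------------------------------------
    sc = config.get("screen", {})
    screen_cfg = ScreenConfig(**{k: v for k, v in sc.items()
                                 if k in ScreenConfig.__dataclass_fields__})
    candidates, verdicts, attrition = screen_transcripts(
        study.transcripts, study.expr, screen_cfg)
    screen_dir = outdir / "screen"
    screen_dir.mkdir(exist_ok=True)
    vdf = pd.DataFrame([{
        "transcript_id": v.transcript_id, "orf_score": v.orf_score,
        "orf_call": v.orf_call, "triplet_score": v.triplet_score,
        "triplet_call": v.triplet_call, "motif_hit": v.motif_hit,
        "motif_call": v.motif_call, "consensus": v.consensus,
    } for v in verdicts]).set_index("transcript_id")
    _write(vdf, screen_dir / "verdicts.tsv")
    cio.write_gtf(candidates, screen_dir / "candidates.gtf")
    manifest["stages"]["screen"] = {"attrition": attrition}

    # --- classify -----------------------------------------------------------
    records, ambiguous = classify_all(candidates, study.genes)
    summary = biotype_summary(records)
    biotype_dir = outdir / "biotype"
    biotype_dir.mkdir(exist_ok=True)
    for rec in records:
        rec.transcript.attributes["biotype"] = rec.biotype
        if rec.host_gene_id:
            rec.transcript.attributes["host_gene"] = rec.host_gene_id
    cio.write_gtf([r.transcript for r in records], biotype_dir / "lncrna.gtf")
    _write(pd.DataFrame(sorted(summary.items()),
                        columns=["biotype", "count"]).set_index("biotype"),
           biotype_dir / "summary.tsv")
    manifest["stages"]["classify"] = {"counts": summary, "ambiguous": ambiguous}
    lnc_ids = [r.transcript.transcript_id for r in records]

    # --- differential expression ---------------------------------------------
    ec = config.get("expression", {})
    case_group = synth.group_names[1]
    de = differential_expression(study.expr, case_group=case_group)
    n_sig, n_up, n_down = de_summary(de, alpha=ec.get("alpha", 0.05))
    gs = group_specific(study.expr, presence_fpkm=ec.get("presence_fpkm", 1.0),
                        absence_fpkm=ec.get("absence_fpkm", 0.1))
    gs = {g: [t for t in ids if t in set(lnc_ids)] for g, ids in gs.items()}
    expr_dir = outdir / "expression"
    expr_dir.mkdir(exist_ok=True)
    _write(de, expr_dir / "de.tsv")
    _write(volcano_table(de, alpha=ec.get("alpha", 0.05)),
           expr_dir / "volcano.tsv")
    with open(expr_dir / "group_specific.json", "w") as fh:
        json.dump({g: sorted(ids) for g, ids in gs.items()}, fh, indent=2)
        fh.write("\n")
    de_lnc = de.loc[[t for t in lnc_ids if t in de.index]]
    n_sig_lnc = int(((de_lnc["pvalue"] < ec.get("alpha", 0.05))
                     & de_lnc["testable"]).sum())
    manifest["stages"]["expression"] = {
        "n_significant": n_sig, "n_up": n_up, "n_down": n_down,
        "n_significant_lnc": n_sig_lnc,
        "group_specific": {g: len(ids) for g, ids in gs.items()},
    }

    # --- targets -------------------------------------------------------------
    tc = config.get("targets", {})
    lnc_tx = [r.transcript for r in records]
    cis = cis_targets(lnc_tx, study.genes, windows=tc.get("windows",
                                                          [10_000, 100_000]))
    gene_of = {tx.transcript_id: tx.gene_id for tx in study.transcripts}
    coding_ids = sorted(set(study.truth.true_coding_ids))
    trans = trans_targets(study.expr, lnc_ids, coding_ids,
                          threshold=tc.get("trans_threshold", 0.95),
                          gene_of=gene_of)
    targets_dir = outdir / "targets"
    targets_dir.mkdir(exist_ok=True)
    pairs_df = pd.DataFrame(
        [{"lnc_id": p.lnc_id, "gene_id": p.gene_id, "mode": p.mode,
          "window": p.window if p.window is not None else "",
          "distance": p.distance if p.distance is not None else "",
          "r": f"{p.r:.6g}" if p.r is not None else ""}
         for p in list(cis) + list(trans)])
    pairs_df.to_csv(targets_dir / "pairs.tsv", sep="\t", index=False)
    _write(target_table(cis, trans).set_index("lnc_id"),
           targets_dir / "per_lncrna.tsv")
    manifest["stages"]["targets"] = {"n_cis": len(cis), "n_trans": len(trans)}

    # --- enrichment ------------------------------------------------------------
    enr = config.get("enrich", {})
    if enr.get("enabled", True):
        background = [g.gene_id for g in study.genes]
        cis_target_genes = sorted({p.gene_id for p in cis})
        query = study.truth.query_genes or cis_target_genes
        table = enrich(query, study.term_map, background,
                       alpha=enr.get("alpha", 0.05))
        enrich_dir = outdir / "enrich"
        enrich_dir.mkdir(exist_ok=True)
        _write(table, enrich_dir / "enrichment.tsv")
        manifest["stages"]["enrich"] = {
            "n_terms_tested": len(table),
            "n_significant": int(table["significant"].sum()) if len(table) else 0,
        }
    else:
        manifest["stages"]["enrich"] = {"skipped": True}

    # --- feature stats ---------------------------------------------------------
    coding_tx = [tx for tx in study.transcripts
                 if tx.transcript_id in set(study.truth.true_coding_ids)]
    features = feature_summary(lnc_tx, coding_tx, study.expr)
    features_dir = outdir / "features"
    features_dir.mkdir(exist_ok=True)
    flat = features.copy()
    flat["hist_counts"] = flat["hist_counts"].apply(
        lambda v: ",".join(map(str, v)))
    flat["hist_edges"] = flat["hist_edges"].apply(
        lambda v: ",".join(f"{x:.6g}" for x in v))
    _write(flat, features_dir / "feature_summary.tsv")
    manifest["stages"]["features"] = {"n_lnc": len(lnc_tx),
                                      "n_mrna": len(coding_tx)}

    # --- qPCR ------------------------------------------------------------------
    qc = config.get("qpcr", {})
    if qc.get("enabled", True) and len(study.ct_table):
        ct = CtTable(study.ct_table)
        calibrator = qc.get("calibrator_group", synth.group_names[0])
        rows = []
        for gene in sorted(set(ct.data["gene"]) - {ct.reference_gene}):
            per_sample = ddct_fold_change(ct, gene, calibrator)
            p, stars = group_ttest(per_sample)
            for grp, sub in per_sample.groupby("group"):
                rows.append({"gene": gene, "group": grp,
                             "mean_fold": sub["fold_change"].mean(),
                             "sd_fold": sub["fold_change"].std(ddof=1),
                             "p": p, "stars": stars})
        qpcr_dir = outdir / "qpcr"
        qpcr_dir.mkdir(exist_ok=True)
        _write(pd.DataFrame(rows).set_index(["gene", "group"]),
               qpcr_dir / "fold_changes.tsv")
        manifest["stages"]["qpcr"] = {"n_targets": len({r['gene'] for r in rows})}
    else:
        manifest["stages"]["qpcr"] = {"skipped": True}

    # --- evaluation against truth ----------------------------------------------
    if config.get("evaluate", False):
        report = evaluate_recovery(study, candidates, records, de, gs,
                                   cis, trans,
                                   alpha=ec.get("alpha", 0.05))
        cio.write_json(report, outdir / "recovery.json")
        manifest["stages"]["evaluate"] = report

    cio.write_json(manifest, outdir / "manifest.json")
    return manifest


def evaluate_recovery(study, candidates, records, de, gs, cis, trans,
                      alpha: float = 0.05) -> dict:
    """Recovery metrics of every stage against the planted ground truth."""
    truth = study.truth
    true_lnc = set(truth.true_lnc_ids)
    true_coding = set(truth.true_coding_ids)
    cand = {tx.transcript_id for tx in candidates}

    screen_sensitivity = len(cand & true_lnc) / len(true_lnc)
    coding_contamination = len(cand & true_coding) / len(true_coding)

    n_match = sum(1 for r in records
                  if truth.biotype.get(r.transcript.transcript_id) == r.biotype)
    n_truth_classified = sum(1 for r in records
                             if r.transcript.transcript_id in truth.biotype)
    biotype_accuracy = (n_match / n_truth_classified
                        if n_truth_classified else float("nan"))

    de_called = set(de.index[(de["pvalue"] < alpha) & de["testable"]])
    planted = set(truth.de)
    de_power = len(de_called & planted) / len(planted) if planted else float("nan")

    cis_found = {(p.lnc_id, p.gene_id) for p in cis}
    cis_truth = {(l, g) for l, g, _ in truth.cis_pairs}
    cis_recall = (len(cis_found & cis_truth) / len(cis_truth)
                  if cis_truth else float("nan"))

    trans_found = {(p.lnc_id, p.gene_id) for p in trans}
    trans_truth = {(l, g) for l, g, _ in truth.trans_pairs}
    trans_recall = (len(trans_found & trans_truth) / len(trans_truth)
                    if trans_truth else float("nan"))

    gs_recall = {}
    for group, planted_ids in truth.group_specific.items():
        found = set(gs.get(group, []))
        gs_recall[group] = (len(found & set(planted_ids)) / len(planted_ids)
                            if planted_ids else float("nan"))

    return {
        "screen_sensitivity": screen_sensitivity,
        "coding_contamination": coding_contamination,
        "biotype_accuracy": biotype_accuracy,
        "de_power": de_power,
        "cis_recall": cis_recall,
        "trans_recall": trans_recall,
        "group_specific_recall": gs_recall,
    }
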