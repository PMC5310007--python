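"""Generator contracts: determinism, placement geometry, planted parameters."""

import numpy as np
import pytest

from caprilnc.screen import longest_orf
from caprilnc.simulate import (DesignError, SizingError, SynthConfig,
                               generate_annotation, generate_counts,
                               generate_sequences, generate_study)
from caprilnc.targets import pearson_r

STOPS = {"TAA", "TAG", "TGA"}


def _small_cfg(**kw):
    base = dict(seed=5, n_coding_genes=40, n_lnc_loci=30,
                planted_trans_pairs=3, n_group_specific=2)
    base.update(kw)
    return SynthConfig(**base)


def test_identical_seeds_give_identical_studies():
    a = generate_study(_small_cfg())
    b = generate_study(_small_cfg())
    assert a.sequences == b.sequences
    assert a.expr.counts.equals(b.expr.counts)
    assert a.truth.to_dict() == b.truth.to_dict()
    assert a.term_map == b.term_map
    assert a.ct_table.equals(b.ct_table)


def test_different_seeds_move_locus_coordinates():
    a = generate_study(_small_cfg(seed=5))
    b = generate_study(_small_cfg(seed=6))
    spans_a = sorted(tx.span for tx in a.transcripts)
    spans_b = sorted(tx.span for tx in b.transcripts)
    assert spans_a != spans_b


def test_degenerate_fractions_make_every_lnc_intergenic():
    cfg = _small_cfg(lnc_class_fractions=(1.0, 0.0, 0.0))
    _genes, _txs, truth = generate_annotation(cfg)
    assert set(truth.biotype.values()) == {"lincRNA"}


def test_zero_window_plants_abutting_cis_neighbours():
    cfg = _small_cfg(planted_cis_windows=(0,))
    genes, txs, truth = generate_annotation(cfg)
    spans = {tx.transcript_id: tx.span for tx in txs}
    gene_spans = {g.gene_id: g.span for g in genes}
    for lnc, gene, dist in truth.cis_pairs:
        assert dist == 0
        ls, gs = spans[lnc], gene_spans[gene]
        gap = max(gs[0] - ls[1], ls[0] - gs[1])
        assert gap <= 0  # abuts or overlaps


def test_invalid_configs_are_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        SynthConfig(lnc_class_fractions=(0.5, 0.2, 0.2)).validate()
    with pytest.raises(DesignError):
        SynthConfig(n_samples_per_group=1).validate()
    with pytest.raises(SizingError, match="chromosome"):
        generate_annotation(_small_cfg(chrom_length=20_000))


def test_planted_means_recovered_at_scale(big_lnc_study):
    cfg = big_lnc_study.config
    truth = big_lnc_study.truth
    lnc = set(truth.true_lnc_ids)
    assert len(lnc) >= 1000
    lengths, exons = [], []
    for tx in big_lnc_study.transcripts:
        if tx.transcript_id in lnc:
            lengths.append(tx.spliced_length)
            exons.append(tx.n_exons)
    orf_lens = []
    for tid in truth.true_lnc_ids:
        orf = longest_orf(big_lnc_study.sequences[tid])
        orf_lens.append(orf.length if orf else 0)
    assert abs(np.mean(lengths) - cfg.lnc_length_mean) / cfg.lnc_length_mean < 0.05
    assert abs(np.mean(orf_lens) - cfg.lnc_orf_mean) / cfg.lnc_orf_mean < 0.05
    assert abs(np.mean(exons) - cfg.lnc_exon_mean) / cfg.lnc_exon_mean < 0.05


def test_class_proportions_within_binomial_bounds(big_lnc_study):
    # default fractions (0.8, 0.1, 0.1); 99% binomial interval at n loci
    truth = big_lnc_study.truth
    n = len(truth.true_lnc_ids)
    counts = {c: sum(1 for b in truth.biotype.values() if b == c)
              for c in ("lincRNA", "antisense", "intronic")}
    for cls, frac in zip(("lincRNA", "antisense", "intronic"),
                         big_lnc_study.config.lnc_class_fractions):
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(counts[cls] / n - frac) <= max(2.58 * se, 1.5 / n)


def test_coding_sequences_carry_complete_planted_orfs(default_study):
    truth = default_study.truth
    for tid in truth.true_coding_ids[:50]:
        seq = default_study.sequences[tid]
        orf = longest_orf(seq)
        assert orf is not None and orf.length >= 300
        assert seq[orf.start:orf.start + 3] == "ATG"
        assert seq[orf.end - 3:orf.end] in STOPS


def test_lnc_orfs_bounded_by_construction(default_study):
    truth = default_study.truth
    for tid in truth.true_lnc_ids[:50]:
        seq = default_study.sequences[tid]
        orf = longest_orf(seq)
        assert orf is not None
        assert orf.length <= max(30, int(0.35 * len(seq)))


def test_sequence_length_matches_spliced_length(default_study):
    for tx in default_study.transcripts[:50]:
        assert len(default_study.sequences[tx.transcript_id]) == tx.spliced_length


def test_null_de_config_plants_nothing():
    cfg = _small_cfg(de_fraction=0.0)
    _g, txs, truth = generate_annotation(cfg)
    generate_sequences(txs, truth, cfg)
    generate_counts(txs, truth, cfg)
    assert truth.de == {}


def test_log2fc_one_doubles_group_means():
    cfg = _small_cfg(de_log2fc=1.0, nb_dispersion=1e-8, de_fraction=0.3)
    _g, txs, truth = generate_annotation(cfg)
    expr = generate_counts(txs, truth, cfg)
    case = [s for s, g in expr.design.items() if g == "pubertal"]
    ctrl = [s for s, g in expr.design.items() if g == "prepubertal"]
    ratios = []
    for t, direction in truth.de.items():
        m_case = expr.counts.loc[t, case].mean()
        m_ctrl = expr.counts.loc[t, ctrl].mean()
        if min(m_case, m_ctrl) < 50:   # skip rows where Poisson noise dominates
            continue
        r = m_case / m_ctrl if direction == "up" else m_ctrl / m_case
        ratios.append(r)
    assert ratios and abs(np.median(ratios) - 2.0) < 0.2


def test_planted_trans_pair_correlation_approaches_target(quiet_study):
    truth = quiet_study.truth
    fp = quiet_study.expr.fpkm
    gene2tid = {tx.gene_id: tx.transcript_id for tx in quiet_study.transcripts}
    for lnc, gene, r_target in truth.trans_pairs:
        r = pearson_r(fp.loc[lnc], fp.loc[gene2tid[gene]])
        assert r > 0.95
        assert abs(r - r_target) < 0.05


def test_group_specific_lncs_silent_in_off_group(quiet_study):
    truth = quiet_study.truth
    counts = quiet_study.expr.counts
    groups = quiet_study.expr.groups
    for group, ids in truth.group_specific.items():
        off = [s for g, ss in groups.items() if g != group for s in ss]
        for t in ids:
            assert (counts.loc[t, off] == 0).all()


def test_truth_ids_exist_in_outputs(default_study):
    truth = default_study.truth
    tids = {tx.transcript_id for tx in default_study.transcripts}
    gids = {g.gene_id for g in default_study.genes}
    assert set(truth.true_lnc_ids) <= tids
    assert set(truth.true_coding_ids) <= tids
    assert set(truth.biotype) == set(truth.true_lnc_ids)
    assert set(truth.de) <= tids
    assert {g for _, g, _ in truth.cis_pairs} <= gids
    assert set(truth.query_genes) <= gids
    assert set(default_study.expr.counts.index) == tids
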