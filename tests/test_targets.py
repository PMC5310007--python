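"""Cis windows, Pearson correlation and trans coexpression targets."""

import numpy as np
import pytest
from scipy import stats

from caprilnc.io import GeneAnnotation, TranscriptModel
from caprilnc.targets import (TargetPair, cis_targets, pearson_r,
                              target_table, trans_targets)

from conftest import toy_expression


def gene(gid, start, end, chrom="chr1"):
    return GeneAnnotation(gene_id=gid, chrom=chrom, strand="+",
                          span=(start, end), biotype="protein_coding",
                          exons=[(start, end)])


def lnc(tid, start, end, chrom="chr1"):
    return TranscriptModel(tid, "xg", chrom, "+", [(start, end)])


def brute_force_cis(lncs, genes, windows=(10_000, 100_000)):
    windows = sorted(windows)
    out = set()
    for tx in lncs:
        for g in genes:
            if g.chrom != tx.chrom or g.biotype != "protein_coding":
                continue
            a, b = tx.span, g.span
            gap = 0 if (a[0] < b[1] and b[0] < a[1]) \
                else max(b[0] - a[1], a[0] - b[1])
            if gap <= windows[-1]:
                w = next(w for w in windows if gap <= w)
                out.add((tx.transcript_id, g.gene_id, gap, w))
    return out


@pytest.mark.parametrize("gene_start, distance, window", [
    (5_000, 0, 10_000),          # abutting
    (5_500, 500, 10_000),
    (15_000, 10_000, 10_000),    # inclusive 10 kb boundary
    (15_001, 10_001, 100_000),
    (105_000, 100_000, 100_000),  # inclusive 100 kb boundary
])
def test_cis_window_boundaries(gene_start, distance, window):
    pairs = cis_targets([lnc("l1", 1_000, 5_000)],
                        [gene("g1", gene_start, gene_start + 2_000)])
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.distance, p.window) == (distance, window)


def test_cis_excludes_beyond_the_largest_window():
    assert cis_targets([lnc("l1", 0, 1_000)],
                       [gene("g1", 101_001, 102_000)]) == []
    assert cis_targets([lnc("l1", 0, 1_000)],
                       [gene("g1", 5_000, 6_000, chrom="chr2")]) == []


def test_overlapping_gene_has_distance_zero():
    pairs = cis_targets([lnc("l1", 1_000, 5_000)], [gene("g1", 4_000, 8_000)])
    assert pairs[0].distance == 0 and pairs[0].window == 10_000


def test_cis_matches_brute_force_on_random_fixtures():
    rng = np.random.default_rng(11)
    for _ in range(100):
        genes = [gene(f"g{i}", s, s + int(rng.integers(500, 5_000)),
                      chrom=f"chr{rng.integers(1, 3)}")
                 for i, s in enumerate(rng.integers(0, 400_000, size=15))]
        lncs = [lnc(f"l{j}", s, s + int(rng.integers(200, 3_000)),
                    chrom=f"chr{rng.integers(1, 3)}")
                for j, s in enumerate(rng.integers(0, 400_000, size=15))]
        got = {(p.lnc_id, p.gene_id, p.distance, p.window)
               for p in cis_targets(lncs, genes)}
        assert got == brute_force_cis(lncs, genes)


def test_cis_is_invariant_under_genome_reflection():
    rng = np.random.default_rng(12)
    L = 500_000
    genes = [gene(f"g{i}", s, s + 2_000)
             for i, s in enumerate(rng.integers(0, L - 2_000, size=12))]
    lncs = [lnc(f"l{j}", s, s + 1_000)
            for j, s in enumerate(rng.integers(0, L - 1_000, size=12))]
    fwd = {(p.lnc_id, p.gene_id, p.distance, p.window)
           for p in cis_targets(lncs, genes)}
    rgenes = [gene(g.gene_id, L - g.span[1], L - g.span[0]) for g in genes]
    rlncs = [lnc(t.transcript_id, L - t.span[1], L - t.span[0]) for t in lncs]
    rev = {(p.lnc_id, p.gene_id, p.distance, p.window)
           for p in cis_targets(rlncs, rgenes)}
    assert fwd == rev


def test_pearson_closed_forms():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    assert pearson_r(x, x) == pytest.approx(1.0)
    assert pearson_r(x, [-2 * v + 7 for v in x]) == pytest.approx(-1.0)
    # direct formula evaluation, independent of the implementation
    y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    expected = (n * sxy - sx * sy) / (
        ((n * sxx - sx ** 2) ** 0.5) * ((n * syy - sy ** 2) ** 0.5))
    assert pearson_r(x, y) == pytest.approx(expected)


def test_pearson_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="3 samples"):
        pearson_r([1, 2], [3, 4])
    with pytest.raises(ValueError, match="variance"):
        pearson_r([1, 1, 1], [1, 2, 3])


def test_trans_threshold_is_strict():
    # constant column sums keep FPKM affine in the counts, so the perfectly
    # anticorrelated pair has r = -1 exactly
    expr = toy_expression({"l": [1, 2, 3, 4, 5, 6], "g": [6, 5, 4, 3, 2, 1]},
                          {"l": 1000, "g": 1000})
    assert pearson_r(expr.fpkm.loc["l"], expr.fpkm.loc["g"]) == -1.0
    assert trans_targets(expr, ["l"], ["g"], threshold=1.0) == []  # strict
    below = trans_targets(expr, ["l"], ["g"], threshold=0.95)
    assert len(below) == 1 and below[0].r == pytest.approx(-1.0)
    # a duplicated row correlates at exactly 1: included at 0.95, excluded
    # at the (strict) boundary threshold of 1
    expr2 = toy_expression({"l": [1, 2, 3, 4, 5, 6], "dup": [1, 2, 3, 4, 5, 6],
                            "other": [9, 1, 7, 2, 8, 3]},
                           {"l": 1000, "dup": 1000, "other": 1000})
    dup = trans_targets(expr2, ["l"], ["dup"], threshold=0.95)
    assert len(dup) == 1 and dup[0].r == pytest.approx(1.0)
    assert trans_targets(expr2, ["l"], ["dup"], threshold=1.0) == []


def test_trans_needs_three_samples():
    expr = toy_expression({"l": [1, 3], "g": [2, 5]}, {"l": 100, "g": 100},
                          n_per_group=1)
    with pytest.raises(ValueError, match="3 samples"):
        trans_targets(expr, ["l"], ["g"])


def test_trans_skips_zero_variance_rows():
    # constant library sizes keep FPKM rows constant: both rows are skipped
    # (logged) instead of raising
    expr = toy_expression({"l": [5, 5, 5, 5, 5, 5], "g": [10, 10, 10, 10, 10, 10]},
                          {"l": 1000, "g": 1000})
    assert trans_targets(expr, ["l"], ["g"]) == []


def test_trans_matches_per_pair_oracle_on_random_fixtures():
    rng = np.random.default_rng(13)
    for _ in range(50):
        n_l, n_g = 8, 8
        counts = {f"l{i}": rng.integers(1, 500, size=6).tolist()
                  for i in range(n_l)}
        counts |= {f"g{i}": rng.integers(1, 500, size=6).tolist()
                   for i in range(n_g)}
        expr = toy_expression(counts, {k: 1000 for k in counts})
        got = {(p.lnc_id, p.gene_id) for p in trans_targets(
            expr, [f"l{i}" for i in range(n_l)],
            [f"g{i}" for i in range(n_g)], threshold=0.6)}
        want = set()
        for i in range(n_l):
            for j in range(n_g):
                r = stats.pearsonr(expr.fpkm.loc[f"l{i}"],
                                   expr.fpkm.loc[f"g{j}"]).statistic
                if abs(r) > 0.6:
                    want.add((f"l{i}", f"g{j}"))
        assert got == want


def test_trans_invariant_under_row_affine_rescaling():
    # Pearson invariance: rescaling/shifting any expression row positively
    # leaves the predicted pair set unchanged
    rng = np.random.default_rng(14)
    counts = {f"t{i}": rng.integers(1, 300, size=6).tolist() for i in range(10)}
    expr = toy_expression(counts, {k: 1000 for k in counts})
    lids, gids = [f"t{i}" for i in range(5)], [f"t{i}" for i in range(5, 10)]
    base = {(p.lnc_id, p.gene_id) for p in
            trans_targets(expr, lids, gids, threshold=0.5)}
    scaled = toy_expression(counts, {k: 1000 for k in counts})
    fp = expr.fpkm.copy()
    factors = rng.uniform(0.5, 5.0, size=len(fp))
    shifts = rng.uniform(0.0, 3.0, size=len(fp))
    scaled._fpkm = fp.mul(factors, axis=0).add(shifts, axis=0)
    got = {(p.lnc_id, p.gene_id) for p in
           trans_targets(scaled, lids, gids, threshold=0.5)}
    assert got == base


def test_target_pair_invariants():
    with pytest.raises(ValueError, match="window"):
        TargetPair("l", "g", "cis", distance=20_000, window=10_000)
    with pytest.raises(ValueError, match="r in"):
        TargetPair("l", "g", "trans", r=1.5)


def test_target_table_shapes():
    cis = [TargetPair("l1", "gA", "cis", distance=0, window=10_000)]
    trans = [TargetPair("l1", "gB", "trans", r=0.99),
             TargetPair("l1", "gC", "trans", r=-0.97)]
    table = target_table(cis, trans).set_index("lnc_id")
    assert list(table.index) == ["l1"]
    assert (table.loc["l1", "n_cis"], table.loc["l1", "n_trans"]) == (1, 2)
    assert target_table([], []).empty


def test_planted_pairs_recovered(quiet_study):
    truth = quiet_study.truth
    lncs = [tx for tx in quiet_study.transcripts
            if tx.transcript_id in set(truth.true_lnc_ids)]
    cis = cis_targets(lncs, quiet_study.genes)
    assert {(l, g) for l, g, _ in truth.cis_pairs} <= \
        {(p.lnc_id, p.gene_id) for p in cis}
    for lnc_id, gid, dist in truth.cis_pairs:
        match = [p for p in cis if (p.lnc_id, p.gene_id) == (lnc_id, gid)]
        assert match[0].distance == dist
    gene_of = {tx.transcript_id: tx.gene_id for tx in quiet_study.transcripts}
    trans = trans_targets(quiet_study.expr, truth.true_lnc_ids,
                          truth.true_coding_ids, gene_of=gene_of)
    assert {(l, g) for l, g, _ in truth.trans_pairs} <= \
        {(p.lnc_id, p.gene_id) for p in trans}
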