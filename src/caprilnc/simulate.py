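"""Synthetic study generator with planted ground truth.

Emulates the assembled-transcript stage of a goat hypothalamus RNA-seq
experiment: a compact genome with non-overlapping protein-coding genes,
lncRNA loci of three positional classes (intergenic, antisense, intronic),
spliced sequences with planted ORFs, negative-binomial counts for a 3-vs-3
prepubertal/pubertal design with planted differential expression, planted
cis lncRNA-gene neighbours at chosen distances, planted trans-correlated
pairs, group-specific lncRNAs, a term-to-gene map with one planted enriched
term, and a qPCR Ct table. Every output is a deterministic function of the
seed, and every planted answer is recorded in a GroundTruth object so each
downstream stage can be scored.

Default feature scales follow the study conditions this generator emulates:
lncRNA mean length 1180 nt with a 105 nt mean ORF versus mRNA mean length
2869 nt, fewer exons in lncRNAs, three samples per group, and million-read
libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .codonmodel import (
    DEFAULT_MOTIF_LIBRARY,
    encode_peptide,
    sample_coding_codons,
)
from .expression import ExpressionData
from .io import GeneAnnotation, TranscriptModel
from .screen import find_orfs, longest_orf

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SyntheticStudy",
    "SizingError",
    "generate_annotation",
    "generate_sequences",
    "generate_counts",
    "generate_term_map",
    "generate_ct_table",
    "generate_study",
    "write_study",
]

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")
NONSTOP_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                  if a + b + c not in STOPS]


class SizingError(ValueError):
    """A locus could not be placed on the configured chromosome."""


class DesignError(ValueError):
    """The sample design is too small for a two-group comparison."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic study; the seed determines every output."""

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 10_000_000
    n_coding_genes: int = 300
    n_lnc_loci: int = 200
    lnc_class_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    lnc_length_mean: float = 1180.0
    mrna_length_mean: float = 2869.0
    lnc_orf_mean: float = 105.0
    lnc_exon_mean: float = 2.8
    mrna_exon_mean: float = 9.0
    n_samples_per_group: int = 3
    de_fraction: float = 0.10
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    planted_cis_windows: tuple[int, ...] = (2_000, 10_000, 60_000, 100_000)
    planted_trans_pairs: int = 20
    trans_target_r: float = 0.99
    n_group_specific: int = 5          # per group
    library_sizes: tuple[int, ...] | None = None   # default 1e6 per sample
    length_sigma: float = 0.5
    intergenic_margin: int = 1_500
    gap_range: tuple[int, int] = (20_000, 60_000)
    n_terms: int = 40
    term_size_range: tuple[int, int] = (10, 60)
    enrich_query_size: int = 10
    planted_term_extra: int = 5
    group_names: tuple[str, str] = ("prepubertal", "pubertal")  # (control, case)
    lnc_base_fpkm_median: float = 10.0
    mrna_base_fpkm_median: float = 30.0
    expr_sigma: float = 0.8

    def validate(self) -> None:
        if abs(sum(self.lnc_class_fractions) - 1.0) > 1e-9:
            raise ValueError("lnc_class_fractions must sum to 1")
        if any(f < 0 for f in self.lnc_class_fractions):
            raise ValueError("lnc_class_fractions must be non-negative")
        for name in ("lnc_length_mean", "mrna_length_mean", "lnc_orf_mean",
                     "lnc_exon_mean", "mrna_exon_mean", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_samples_per_group < 2:
            raise DesignError("need at least 2 samples per group")
        if not (-1.0 <= self.trans_target_r <= 1.0):
            raise ValueError("trans_target_r must be in [-1, 1]")

    @property
    def samples(self) -> list[str]:
        control, case = self.group_names
        n = self.n_samples_per_group
        return [f"{control}_{i + 1}" for i in range(n)] + \
               [f"{case}_{i + 1}" for i in range(n)]

    @property
    def design(self) -> dict[str, str]:
        control, case = self.group_names
        n = self.n_samples_per_group
        return {s: (control if i < n else case)
                for i, s in enumerate(self.samples)}

    def resolved_library_sizes(self) -> list[int]:
        if self.library_sizes is not None:
            if len(self.library_sizes) != 2 * self.n_samples_per_group:
                raise ValueError("library_sizes must have one entry per sample")
            return list(self.library_sizes)
        return [1_000_000] * (2 * self.n_samples_per_group)


@dataclass
class GroundTruth:
    """Planted answers for every downstream stage."""

    true_lnc_ids: list[str] = field(default_factory=list)
    true_coding_ids: list[str] = field(default_factory=list)
    biotype: dict[str, str] = field(default_factory=dict)          # lnc tid -> class
    host_gene: dict[str, str | None] = field(default_factory=dict)  # lnc tid -> gene
    de: dict[str, str] = field(default_factory=dict)               # tid -> up|down
    cis_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    trans_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    group_specific: dict[str, list[str]] = field(default_factory=dict)
    planted_term: str | None = None
    query_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cis_pairs"] = [list(p) for p in self.cis_pairs]
        d["trans_pairs"] = [list(p) for p in self.trans_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["cis_pairs"] = [tuple(p) for p in d.get("cis_pairs", [])]
        d["trans_pairs"] = [tuple(p) for p in d.get("trans_pairs", [])]
        return cls(**d)


def _rng(config: SynthConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


def _lognormal_length(rng, mean: float, sigma: float, minimum: int) -> int:
    mu = np.log(mean) - sigma**2 / 2
    return max(minimum, int(round(rng.lognormal(mu, sigma))))


def _exon_count(rng, mean: float, spliced_len: int) -> int:
    k = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
    return max(1, min(k, spliced_len // 80 or 1))


def _split_exons(rng, spliced_len: int, k: int) -> list[int]:
    if k == 1:
        return [spliced_len]
    base = 30
    extra = spliced_len - base * k
    w = rng.dirichlet(np.full(k, 2.0))
    lens = base + np.floor(extra * w).astype(int)
    lens[0] += spliced_len - int(lens.sum())
    return lens.tolist()


@dataclass
class _Locus:
    """A transcript structure before genomic placement."""
    spliced_len: int
    exon_lens: list[int]
    intron_lens: list[int]

    @property
    def extent(self) -> int:
        return sum(self.exon_lens) + sum(self.intron_lens)

    def place(self, start: int) -> list[tuple[int, int]]:
        exons = []
        pos = start
        for i, el in enumerate(self.exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if i < len(self.intron_lens):
                pos += self.intron_lens[i]
        return exons


def _make_locus(rng, mean_len: float, sigma: float, exon_mean: float,
                min_len: int, intron_range: tuple[int, int]) -> _Locus:
    L = _lognormal_length(rng, mean_len, sigma, min_len)
    k = _exon_count(rng, exon_mean, L)
    exon_lens = _split_exons(rng, L, k)
    intron_lens = rng.integers(intron_range[0], intron_range[1] + 1,
                               size=k - 1).tolist()
    return _Locus(spliced_len=L, exon_lens=exon_lens, intron_lens=intron_lens)


def _class_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n loci over the three classes."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    remainders = [x - c for x, c in zip(raw, counts)]
    for i in sorted(range(len(raw)), key=lambda i: -remainders[i]):
        if sum(counts) == n:
            break
        counts[i] += 1
    return counts


def generate_annotation(config: SynthConfig):
    """Place coding genes and lncRNA loci; returns (genes, transcripts, truth).

    Coding genes never overlap; lincRNA loci are intergenic (at least 1 bp
    from every gene span, and a configurable margin for the non-planted
    ones); antisense loci overlap a host gene's exons on the opposite strand
    and stay within the host span; intronic loci sit strictly inside one
    intron of a same-strand host. Planted cis lincRNAs sit at the exact
    span-gap distances listed in ``planted_cis_windows``.
    """
    config.validate()
    rng = _rng(config, 1)

    n_linc, n_anti, n_intr = _class_counts(config.n_lnc_loci,
                                           config.lnc_class_fractions)
    n_cis = len(config.planted_cis_windows)
    if n_cis > n_linc:
        raise ValueError("more planted cis windows than lincRNA loci")

    lnc_kw = dict(mean_len=config.lnc_length_mean, sigma=config.length_sigma,
                  exon_mean=config.lnc_exon_mean, min_len=210)
    intronic_loci = [_make_locus(rng, intron_range=(150, 600), **lnc_kw)
                     for _ in range(n_intr)]
    antisense_loci = [_make_locus(rng, intron_range=(100, 500), **lnc_kw)
                      for _ in range(n_anti)]
    linc_loci = [_make_locus(rng, intron_range=(200, 2000), **lnc_kw)
                 for _ in range(n_linc)]

    # coding gene structures; some genes host an intronic lncRNA and get one
    # intron widened to fit it
    if n_intr > config.n_coding_genes:
        raise ValueError("more intronic lncRNAs than coding genes")
    host_of_intronic = (np.linspace(0, config.n_coding_genes - 1, num=n_intr)
                        .astype(int).tolist() if n_intr else [])
    gene_structs: list[_Locus] = []
    intronic_slot: dict[int, tuple[int, int, int]] = {}  # gene idx -> (intron idx, lnc idx, offset)
    for gi in range(config.n_coding_genes):
        loc = _make_locus(rng, mean_len=config.mrna_length_mean,
                          sigma=config.length_sigma,
                          exon_mean=config.mrna_exon_mean, min_len=400,
                          intron_range=(200, 2000))
        if gi in host_of_intronic:
            li = host_of_intronic.index(gi)
            while len(loc.exon_lens) < 2:  # host needs an intron
                loc = _make_locus(rng, mean_len=config.mrna_length_mean,
                                  sigma=config.length_sigma,
                                  exon_mean=max(config.mrna_exon_mean, 2.0),
                                  min_len=400, intron_range=(200, 2000))
            ii = int(rng.integers(0, len(loc.intron_lens)))
            pad_left = int(rng.integers(100, 500))
            pad_right = int(rng.integers(100, 500))
            loc.intron_lens[ii] = intronic_loci[li].extent + pad_left + pad_right
            intronic_slot[gi] = (ii, li, pad_left)
        gene_structs.append(loc)

    # planted cis lincRNAs attach after evenly spaced genes
    cis_gene_idx = (np.linspace(0, config.n_coding_genes - 1, num=n_cis)
                    .astype(int).tolist() if n_cis else [])
    cis_attach = {g: (w_i, config.planted_cis_windows[w_i])
                  for w_i, g in enumerate(cis_gene_idx)}
    if len(cis_attach) != n_cis:
        raise ValueError("not enough coding genes to anchor the planted cis loci")

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genes: list[GeneAnnotation] = []
    transcripts: list[TranscriptModel] = []
    truth = GroundTruth()
    placed_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    cursors = {c: int(rng.integers(1_000, 5_001)) for c in chroms}
    gene_records: list[dict] = []   # placement info for antisense/intronic hosts
    linc_structs_left = list(range(n_cis, n_linc))
    lnc_counter = 0

    def new_lnc_ids():
        nonlocal lnc_counter
        lnc_counter += 1
        return f"XLOC_{lnc_counter:06d}", f"TCONS_{lnc_counter:06d}"

    for gi, loc in enumerate(gene_structs):
        chrom = chroms[gi % len(chroms)]
        start = cursors[chrom]
        if start + loc.extent > config.chrom_length:
            raise SizingError(
                f"chromosome {chrom} too short to place gene GENE_{gi:05d}")
        strand = "+" if rng.random() < 0.5 else "-"
        exons = loc.place(start)
        gid, tid = f"GENE_{gi:05d}", f"MRNA_{gi:05d}"
        genes.append(GeneAnnotation(gene_id=gid, chrom=chrom, strand=strand,
                                    span=(exons[0][0], exons[-1][1]),
                                    biotype="protein_coding", exons=exons))
        transcripts.append(TranscriptModel(
            transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
            exons=exons, attributes={"gene_biotype": "protein_coding"}))
        truth.true_coding_ids.append(tid)
        gene_records.append({"gid": gid, "idx": gi, "chrom": chrom,
                             "strand": strand, "exons": exons,
                             "span": (exons[0][0], exons[-1][1]),
                             "struct": loc})
        placed_spans[chrom].append((exons[0][0], exons[-1][1]))
        cursor = exons[-1][1]

        if gi in cis_attach:  # planted cis lincRNA at an exact gap distance
            li, dist = cis_attach[gi]
            linc = linc_loci[li]
            lstart = cursor + dist
            if lstart + linc.extent > config.chrom_length:
                raise SizingError(
                    f"chromosome {chrom} too short to place planted cis "
                    f"lincRNA after GENE_{gi:05d}")
            lgid, ltid = new_lnc_ids()
            lexons = linc.place(lstart)
            lstrand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(TranscriptModel(
                transcript_id=ltid, gene_id=lgid, chrom=chrom,
                strand=lstrand, exons=lexons))
            truth.true_lnc_ids.append(ltid)
            truth.biotype[ltid] = "lincRNA"
            truth.host_gene[ltid] = None
            truth.cis_pairs.append((ltid, gid, int(dist)))
            placed_spans[chrom].append((lexons[0][0], lexons[-1][1]))
            cursor = lexons[-1][1]

        gap = int(rng.integers(config.gap_range[0], config.gap_range[1] + 1))
        cursors[chrom] = cursor + gap

    # intronic lncRNAs strictly inside their host intron, same strand
    for gi, (ii, li, pad_left) in sorted(intronic_slot.items()):
        rec = gene_records[gi]
        host_exons = rec["exons"]
        intron = (host_exons[ii][1], host_exons[ii + 1][0])
        loc = intronic_loci[li]
        lstart = intron[0] + pad_left
        assert lstart > intron[0] and lstart + loc.extent < intron[1]
        lgid, ltid = new_lnc_ids()
        transcripts.append(TranscriptModel(
            transcript_id=ltid, gene_id=lgid, chrom=rec["chrom"],
            strand=rec["strand"], exons=loc.place(lstart)))
        truth.true_lnc_ids.append(ltid)
        truth.biotype[ltid] = "intronic"
        truth.host_gene[ltid] = rec["gid"]

    # antisense lncRNAs overlap a host exon on the opposite strand, within
    # the host span
    for loc in antisense_loci:
        eligible = [r for r in gene_records
                    if r["span"][1] - r["span"][0] >= loc.extent + 2]
        if not eligible:
            raise SizingError("no coding gene span can host an antisense lncRNA")
        rec = eligible[int(rng.integers(0, len(eligible)))]
        span = rec["span"]
        lstart = rec["exons"][0][0]
        if lstart + loc.extent > span[1]:
            lstart = span[1] - loc.extent  # still overlaps the last host exon
        lgid, ltid = new_lnc_ids()
        lstrand = "-" if rec["strand"] == "+" else "+"
        transcripts.append(TranscriptModel(
            transcript_id=ltid, gene_id=lgid, chrom=rec["chrom"],
            strand=lstrand, exons=loc.place(lstart)))
        truth.true_lnc_ids.append(ltid)
        truth.biotype[ltid] = "antisense"
        truth.host_gene[ltid] = rec["gid"]

    # remaining lincRNAs go into intergenic gaps with a safety margin
    margin = config.intergenic_margin
    for li in linc_structs_left:
        loc = linc_loci[li]
        placed = False
        chrom_order = list(rng.permutation(chroms))
        for chrom in chrom_order:
            spans = sorted(placed_spans[chrom])
            gaps = []
            prev = 0
            for s, e in spans:
                gaps.append((prev, s))
                prev = max(prev, e)
            gaps.append((prev, config.chrom_length))
            fitting = [(a, b) for a, b in gaps
                       if b - a >= loc.extent + 2 * margin]
            if not fitting:
                continue
            a, b = fitting[int(rng.integers(0, len(fitting)))]
            lstart = int(rng.integers(a + margin, b - margin - loc.extent + 1))
            lgid, ltid = new_lnc_ids()
            lstrand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(TranscriptModel(
                transcript_id=ltid, gene_id=lgid, chrom=chrom,
                strand=lstrand, exons=loc.place(lstart)))
            truth.true_lnc_ids.append(ltid)
            truth.biotype[ltid] = "lincRNA"
            truth.host_gene[ltid] = None
            placed_spans[chrom].append((lstart, lstart + loc.extent))
            placed = True
            break
        if not placed:
            raise SizingError(
                f"chromosomes too short to place lincRNA locus {li}")

    return genes, transcripts, truth


# ---------------------------------------------------------------------------
# sequences


def _random_bases(rng, n: int) -> list[str]:
    return BASES[rng.integers(0, 4, size=n)].tolist()


def _plant_orf(rng, seq: list[str], start: int, orf_len: int,
               motif: str | None) -> None:
    n_codons = orf_len // 3
    codons = ["ATG"]
    codons += sample_coding_codons(rng, n_codons - 2)
    codons.append(STOPS[int(rng.integers(0, 3))])
    if motif is not None and n_codons - 2 >= len(motif) + 2:
        enc = encode_peptide(motif)
        mpos = int(rng.integers(1, n_codons - 1 - len(motif)))
        for j in range(len(motif)):
            codons[mpos + j] = enc[3 * j:3 * j + 3]
    seq[start:start + orf_len] = list("".join(codons))


def _coding_sequence(rng, length: int, motif: str) -> str:
    seq = _random_bases(rng, length)
    orf_len = min(max(300, int(round(0.66 * length / 3)) * 3),
                  (length - 6) // 3 * 3)
    orf_len = max(orf_len, 30)
    start = int(rng.integers(0, length - orf_len + 1))
    _plant_orf(rng, seq, start, orf_len, motif)
    return "".join(seq)


def _uniform_nonstop_codons(rng, n: int) -> list[str]:
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n)
    return [NONSTOP_CODONS[i] for i in idx]


def _lnc_sequence(rng, length: int, target_orf: int, _depth: int = 0) -> str:
    """Background sequence whose longest complete ORF is exactly target_orf nt."""
    if _depth > 5:
        raise RuntimeError("lncRNA sequence construction failed to converge")
    seq = _random_bases(rng, length)
    p = int(rng.integers(3, length - target_orf + 1))
    codons = ["ATG"] + _uniform_nonstop_codons(rng, target_orf // 3 - 2) \
        + [STOPS[int(rng.integers(0, 3))]]
    seq[p:p + target_orf] = list("".join(codons))
    planted = (p, p + target_orf)
    for _ in range(300):
        best = longest_orf("".join(seq))
        if best is None or best.length <= target_orf:
            break
        if (best.frame == p % 3 and best.start < p
                and best.end == planted[1]):
            # an upstream in-frame ATG extends the planted ORF; cut it off
            seq[p - 3:p] = list("TAA")
            continue
        candidates = [c for c in range(best.start + 3, best.end - 3, 3)
                      if c + 3 <= planted[0] or c >= planted[1]]
        if not candidates:
            return _lnc_sequence(rng, length, target_orf, _depth + 1)
        c = candidates[int(rng.integers(0, len(candidates)))]
        seq[c:c + 3] = list("TAA")
    else:
        return _lnc_sequence(rng, length, target_orf, _depth + 1)
    return "".join(seq)


def _target_orf_length(rng, config: SynthConfig, length: int) -> int:
    shape = 4.0
    draw = rng.gamma(shape, config.lnc_orf_mean / shape)
    cap = min(int(0.35 * length), length - 3)
    target = int(round(draw / 3)) * 3
    return int(np.clip(target, 30, max(30, cap // 3 * 3)))


def generate_sequences(transcripts: Sequence[TranscriptModel],
                       truth: GroundTruth, config: SynthConfig) -> dict[str, str]:
    """Spliced sequences: planted coding ORFs (with a library motif encoded
    inside) for coding transcripts, background sequence with an incidental
    ORF near ``lnc_orf_mean`` for lncRNAs."""
    rng = _rng(config, 2)
    coding = set(truth.true_coding_ids)
    lnc = set(truth.true_lnc_ids)
    out: dict[str, str] = {}
    for tx in transcripts:
        L = tx.spliced_length
        if tx.transcript_id in coding:
            motif = DEFAULT_MOTIF_LIBRARY[
                int(rng.integers(0, len(DEFAULT_MOTIF_LIBRARY)))]
            out[tx.transcript_id] = _coding_sequence(rng, L, motif)
        elif tx.transcript_id in lnc:
            target = _target_orf_length(rng, config, L)
            out[tx.transcript_id] = _lnc_sequence(rng, L, target)
        else:
            out[tx.transcript_id] = "".join(_random_bases(rng, L))
    return out


# ---------------------------------------------------------------------------
# counts


def generate_counts(transcripts: Sequence[TranscriptModel],
                    truth: GroundTruth, config: SynthConfig) -> ExpressionData:
    """Negative-binomial counts with planted DE, trans-correlated pairs and
    group-specific lncRNAs.

    Per-transcript expected counts scale with transcript length and library
    size. Planted DE transcripts split the configured log2 fold change
    symmetrically between the groups, so the ratio of expected group means is
    exactly ``2**de_log2fc`` (up in the case group, inverted for down).
    Planted trans pairs share a per-sample latent factor constructed so the
    empirical correlation of their expected expression equals
    ``trans_target_r`` exactly; group-specific lncRNAs have expectation zero
    in the off group. Also fills in the DE / group-specific / trans fields of
    ``truth`` in place.
    """
    config.validate()
    rng = _rng(config, 3)
    tids = [tx.transcript_id for tx in transcripts]
    lengths = pd.Series({tx.transcript_id: tx.spliced_length
                         for tx in transcripts})
    coding = [t for t in tids if t in set(truth.true_coding_ids)]
    lnc = [t for t in tids if t in set(truth.true_lnc_ids)]
    gene_of = {tx.transcript_id: tx.gene_id for tx in transcripts}

    samples = config.samples
    design = config.design
    control, case = config.group_names
    lib = np.array(config.resolved_library_sizes(), dtype=float)
    n_s = len(samples)

    base = pd.Series(0.0, index=tids)
    base[coding] = rng.lognormal(np.log(config.mrna_base_fpkm_median),
                                 config.expr_sigma, size=len(coding))
    base[lnc] = rng.lognormal(np.log(config.lnc_base_fpkm_median),
                              config.expr_sigma, size=len(lnc))

    # planted DE over all transcripts
    n_de = int(round(config.de_fraction * len(tids)))
    de_ids = list(rng.choice(tids, size=n_de, replace=False)) if n_de else []
    truth.de = {}
    for i, t in enumerate(de_ids):
        truth.de[t] = "up" if rng.random() < 0.5 else "down"

    # group-specific lncRNAs (zero expectation in the off group)
    available = [t for t in lnc if t not in truth.de]
    n_gs = config.n_group_specific
    if 2 * n_gs > len(available):
        raise ValueError("not enough non-DE lncRNAs for group-specific planting")
    gs = list(rng.choice(available, size=2 * n_gs, replace=False)) if n_gs else []
    truth.group_specific = {case: gs[:n_gs], control: gs[n_gs:]}
    base[gs] = base[gs].clip(lower=5.0)

    # trans-correlated pairs
    taken = set(truth.de) | set(gs)
    lnc_pool = [t for t in lnc if t not in taken]
    gene_pool = [t for t in coding if t not in truth.de]
    if config.planted_trans_pairs > min(len(lnc_pool), len(gene_pool)):
        raise ValueError("not enough free transcripts for planted trans pairs")
    trans_lnc = list(rng.choice(lnc_pool, size=config.planted_trans_pairs,
                                replace=False))
    trans_gene = list(rng.choice(gene_pool, size=config.planted_trans_pairs,
                                 replace=False))
    # planted coexpressed pairs are well-expressed so counting noise cannot
    # mask the planted correlation
    base[trans_lnc + trans_gene] = base[trans_lnc + trans_gene].clip(lower=20.0)
    truth.trans_pairs = []

    # expected FPKM-scale mean per transcript and sample
    mu_fpkm = pd.DataFrame(
        np.tile(base.values[:, None], (1, n_s)), index=tids, columns=samples)
    half = 2 ** (config.de_log2fc / 2.0)
    case_cols = [s for s in samples if design[s] == case]
    control_cols = [s for s in samples if design[s] == control]
    for t, direction in truth.de.items():
        hi, lo = (case_cols, control_cols) if direction == "up" \
            else (control_cols, case_cols)
        mu_fpkm.loc[t, hi] = base[t] * half
        mu_fpkm.loc[t, lo] = base[t] / half
    for t in truth.group_specific[case]:
        mu_fpkm.loc[t, control_cols] = 0.0
    for t in truth.group_specific[control]:
        mu_fpkm.loc[t, case_cols] = 0.0

    r = config.trans_target_r
    for lt, gt in zip(trans_lnc, trans_gene):
        x = rng.normal(size=n_s)
        xc = x - x.mean()
        xu = xc / np.linalg.norm(xc)
        z = rng.normal(size=n_s)
        zc = z - z.mean()
        zp = zc - (zc @ xu) * xu
        if np.linalg.norm(zp) < 1e-12:      # pathological draw; retry once
            zp = rng.normal(size=n_s)
            zp = zp - zp.mean()
            zp = zp - (zp @ xu) * xu
        zu = zp / np.linalg.norm(zp)
        ydir = r * xu + np.sqrt(max(0.0, 1 - r * r)) * zu
        # max-normalised latent profiles keep every sample mean positive and
        # guarantee a fixed relative spread, so counting noise cannot wash
        # out the planted correlation at small dispersion
        mu_fpkm.loc[lt] = base[lt] * (1.0 + 0.8 * xu / np.abs(xu).max())
        mu_fpkm.loc[gt] = base[gt] * (1.0 + 0.8 * ydir / np.abs(ydir).max())
        truth.trans_pairs.append((lt, gene_of[gt], float(r)))

    # FPKM scale -> expected counts; rescale globally so expected library
    # size matches the configured one
    mu = mu_fpkm.mul(lengths / 1000.0, axis=0).mul(lib / 1e6, axis=1)
    total = mu.values.sum(axis=0).mean()
    if total > 0:
        mu *= lib.mean() / total

    disp = config.nb_dispersion
    mu_v = mu.values
    if disp < 1e-6:
        counts = rng.poisson(mu_v)
    else:
        size = 1.0 / disp
        counts = np.zeros_like(mu_v, dtype=np.int64)
        pos = mu_v > 0
        counts[pos] = rng.negative_binomial(
            size, size / (size + mu_v[pos]))
    cdf = pd.DataFrame(counts.astype(int), index=tids, columns=samples)
    return ExpressionData(counts=cdf, lengths=lengths, design=design)


# ---------------------------------------------------------------------------
# term map and Ct tables


def generate_term_map(genes: Sequence[GeneAnnotation], config: SynthConfig,
                      ) -> tuple[dict[str, set[str]], str, list[str]]:
    """Random term -> gene-set map with one planted enriched term.

    Returns (term_map, planted_term_id, query_genes); the planted term
    contains the full query plus a few extra genes, so the query is maximally
    enriched in it.
    """
    rng = _rng(config, 4)
    background = [g.gene_id for g in genes]
    if len(background) < config.enrich_query_size + config.planted_term_extra:
        raise ValueError("background too small for the planted term")
    query = list(rng.choice(background, size=config.enrich_query_size,
                            replace=False))
    extra_pool = [g for g in background if g not in set(query)]
    extra = list(rng.choice(extra_pool, size=config.planted_term_extra,
                            replace=False))
    term_map: dict[str, set[str]] = {}
    planted_id = None
    planted_idx = int(rng.integers(0, config.n_terms))
    lo, hi = config.term_size_range
    for i in range(config.n_terms):
        term_id = f"TERM_{i:04d}"
        if i == planted_idx:
            term_map[term_id] = set(query) | set(extra)
            planted_id = term_id
        else:
            size = min(int(rng.integers(lo, hi + 1)), len(background))
            term_map[term_id] = set(rng.choice(background, size=size,
                                               replace=False))
    return term_map, planted_id, query


def generate_ct_table(truth: GroundTruth, config: SynthConfig,
                      reference_gene: str = "beta-actin") -> pd.DataFrame:
    """qPCR Ct table for up to two planted DE lncRNAs plus the reference gene.

    Ct values are built so the case/calibrator expression ratio matches the
    planted fold change; replicate and per-sample technical noise are small.
    """
    rng = _rng(config, 5)
    control, case = config.group_names
    de_lnc = [t for t in truth.true_lnc_ids if t in truth.de]
    up = [t for t in de_lnc if truth.de[t] == "up"][:1]
    down = [t for t in de_lnc if truth.de[t] == "down"][:1]
    targets = up + down
    rows = []
    for sample, group in config.design.items():
        shift = rng.normal(0.0, 0.3)    # per-sample technical offset
        for rep in range(1, 4):
            rows.append((sample, group, reference_gene, rep,
                         18.0 + shift + rng.normal(0.0, 0.1)))
        for t in targets:
            dct = 5.0 - (config.de_log2fc if truth.de[t] == "up" else
                         -config.de_log2fc) * (group == case)
            for rep in range(1, 4):
                rows.append((sample, group, t, rep,
                             18.0 + shift + dct + rng.normal(0.0, 0.1)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene",
                                       "replicate", "ct"])


# ---------------------------------------------------------------------------
# full study


@dataclass
class SyntheticStudy:
    config: SynthConfig
    genes: list[GeneAnnotation]
    transcripts: list[TranscriptModel]
    sequences: dict[str, str]
    expr: ExpressionData
    term_map: dict[str, set[str]]
    ct_table: pd.DataFrame
    truth: GroundTruth


def generate_study(config: SynthConfig | None = None, **overrides) -> SyntheticStudy:
    """Generate the complete synthetic study for a config (or keyword overrides)."""
    if config is None:
        config = SynthConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    genes, transcripts, truth = generate_annotation(config)
    sequences = generate_sequences(transcripts, truth, config)
    for tx in transcripts:
        tx.sequence = sequences[tx.transcript_id]
    expr = generate_counts(transcripts, truth, config)
    term_map, planted_term, query = generate_term_map(genes, config)
    truth.planted_term = planted_term
    truth.query_genes = query
    ct = generate_ct_table(truth, config)
    return SyntheticStudy(config=config, genes=genes, transcripts=transcripts,
                          sequences=sequences, expr=expr, term_map=term_map,
                          ct_table=ct, truth=truth)


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write the study as GTF + FASTA + TSV + JSON files; returns the paths."""
    from pathlib import Path
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": outdir / "transcripts.gtf",
        "fasta": outdir / "transcripts.fa",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "term_map": outdir / "term_map.tsv",
        "ct": outdir / "ct_values.tsv",
        "truth": outdir / "truth.json",
    }
    cio.write_gtf(study.transcripts, paths["gtf"])
    cio.write_fasta(study.sequences, paths["fasta"])
    cio.write_counts(study.expr, paths["counts"])
    cio.write_design(study.expr.design, paths["design"])
    with open(paths["term_map"], "w") as fh:
        fh.write("term_id\tgene_id\n")
        for term in sorted(study.term_map):
            for gene in sorted(study.term_map[term]):
                fh.write(f"{term}\t{gene}\n")
    study.ct_table.to_csv(paths["ct"], sep="\t", index=False,
                          float_format="%.4f")
    cio.write_json(study.truth.to_dict(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}
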