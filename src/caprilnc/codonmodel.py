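"""A fixed biased codon-usage model shared by the sequence generator and the
triplet (hexamer) coding-potential scorer.

The model weights each non-stop codon by exp(GC_WEIGHT * GC-count), giving
coding sequence a compositional and in-frame hexamer signature that a
log-likelihood-ratio scorer can separate from the i.i.d. uniform background
the noncoding generator uses. The scorer's default coding hexamer table is
derived from this table; the noncoding table is uniform.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
GC_WEIGHT = 0.8
#: smoothing mass mixed into the coding hexamer table so no hexamer has
#: zero probability (in-frame stop-containing hexamers would otherwise)
HEXAMER_SMOOTHING = 0.02

ALL_CODONS = ["".join(c) for c in product(BASES, repeat=3)]
CODING_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]


@lru_cache(maxsize=1)
def codon_probabilities() -> dict[str, float]:
    """Probability of each non-stop codon under the biased coding model."""
    weights = {c: float(np.exp(GC_WEIGHT * (c.count("G") + c.count("C"))))
               for c in CODING_CODONS}
    total = sum(weights.values())
    return {c: w / total for c, w in weights.items()}


@lru_cache(maxsize=1)
def coding_hexamer_logfreq() -> dict[str, float]:
    """log-frequency of each of the 4096 hexamers as adjacent codon pairs."""
    probs = codon_probabilities()
    uniform = 1.0 / 4096
    table = {}
    for c1 in ALL_CODONS:
        p1 = probs.get(c1, 0.0)
        for c2 in ALL_CODONS:
            p = p1 * probs.get(c2, 0.0)
            table[c1 + c2] = float(np.log((1 - HEXAMER_SMOOTHING) * p
                                          + HEXAMER_SMOOTHING * uniform))
    return table


@lru_cache(maxsize=1)
def noncoding_hexamer_logfreq() -> dict[str, float]:
    """Uniform background: every hexamer at 1/4096."""
    lf = float(np.log(1.0 / 4096))
    return {"".join(h): lf for h in product(BASES, repeat=6)}


@lru_cache(maxsize=1)
def preferred_codon_by_aa() -> dict[str, str]:
    """For each amino acid, the highest-weight codon under the model."""
    std = CodonTable.unambiguous_dna_by_name["Standard"]
    probs = codon_probabilities()
    best: dict[str, tuple[float, str]] = {}
    for codon, aa in std.forward_table.items():
        p = probs.get(codon, 0.0)
        if aa not in best or p > best[aa][0]:
            best[aa] = (p, codon)
    return {aa: codon for aa, (_, codon) in best.items()}


def sample_coding_codons(rng: np.random.Generator, n: int) -> list[str]:
    """Draw n codons i.i.d. from the biased coding model."""
    probs = codon_probabilities()
    codons = list(probs)
    p = np.array([probs[c] for c in codons])
    idx = rng.choice(len(codons), size=n, p=p)
    return [codons[i] for i in idx]


#: toy peptide motif library standing in for a protein-domain database;
#: 8-mers are long enough that random noncoding translations essentially
#: never contain one
DEFAULT_MOTIF_LIBRARY = (
    "HEAGAWGH",
    "KWLDRRAE",
    "PFGQLVRD",
    "MSTNAQKL",
    "YWCDERFH",
    "GAVLIPFM",
    "NQHKRDES",
    "WFYMCAPG",
)


def encode_peptide(peptide: str) -> str:
    """Encode a peptide with the model's preferred codons (no stops)."""
    table = preferred_codon_by_aa()
    return "".join(table[aa] for aa in peptide)
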