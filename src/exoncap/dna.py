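"""Small DNA utilities shared across the toolkit.

Sequences are plain upper-case strings over A,C,G,T plus N, IUPAC
ambiguity codes and ``-`` (gap / discarded region).
"""

from __future__ import annotations

import math

COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN-tgcayrswmkvhdbn",
)

#: canonical unambiguous bases, fixed order used by numeric encodings
BASES = "ACGT"

_IUPAC_TO_SET = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_SETS = {code: frozenset(b) for code, b in _IUPAC_TO_SET.items()}
SET_TO_IUPAC = {v: k for k, v in IUPAC_SETS.items()}

#: 4-bit state masks (A=1, C=2, G=4, T=8) for parsimony machinery
STATE_MASK = {code: sum(1 << BASES.index(b) for b in s) for code, s in _IUPAC_TO_SET.items()}
STATE_MASK["-"] = 15
STATE_MASK["?"] = 15


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def iupac_code(bases) -> str:
    """IUPAC code for a set of unambiguous bases (e.g. {'A','G'} -> 'R')."""
    key = frozenset(bases)
    if not key:
        return "N"
    return SET_TO_IUPAC[frozenset("".join(sorted(key)))]


def gc_fraction(seq: str) -> float | None:
    """GC content over unambiguous bases; ``None`` when no A/C/G/T present."""
    n = sum(seq.count(b) for b in BASES)
    if n == 0:
        return None
    return (seq.count("G") + seq.count("C")) / n


def triplet_entropy(window: str) -> float:
    """Shannon entropy (bits) of overlapping 3-mers in a window.

    Low values indicate simple repeats: (AT)n has two distinct triplets
    and an entropy of 1 bit, random DNA sits near log2(min(4^3, w)).
    """
    counts: dict[str, int] = {}
    for i in range(len(window) - 2):
        t = window[i : i + 3]
        counts[t] = counts.get(t, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts.values():
        p = c / total
        h -= p * math.log2(p)
    return h


def low_complexity_fraction(seq: str, window: int = 64, step: int = 16,
                            min_entropy: float = 2.0) -> float:
    """Fraction of sliding windows whose triplet entropy falls below
    ``min_entropy`` — a DUST-like screen for simple repeats."""
    if len(seq) < window:
        return 1.0 if triplet_entropy(seq) < min_entropy else 0.0
    n = low = 0
    for i in range(0, len(seq) - window + 1, step):
        n += 1
        if triplet_entropy(seq[i : i + window]) < min_entropy:
            low += 1
    return low / n


def kmer_set(seq: str, k: int) -> set[str]:
    """All k-mers containing only A/C/G/T."""
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if all(c in "ACGT" for c in km):
            out.add(km)
    return out


def shared_kmer_fraction(seq: str, library_kmers: set[str], k: int) -> float:
    """Fraction of the sequence's k-mers present in a library k-mer set."""
    own = kmer_set(seq, k)
    if not own:
        return 0.0
    return len(own & library_kmers) / len(own)
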