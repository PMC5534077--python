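"""Small sequence utilities shared across the package."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC degeneracy sets (uppercase), used for primer matching only.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC degenerate codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str, max_mismatch: int = 0) -> bool:
    """Match ``seq`` against an IUPAC ``pattern`` of equal length.

    A position matches when the read base is in the pattern's degeneracy
    set.  Returns True when at most ``max_mismatch`` positions fail.
    """
    if len(pattern) != len(seq):
        return False
    mismatches = 0
    for p, b in zip(pattern, seq):
        if b not in IUPAC.get(p, p):
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def hamming(a: str, b: str) -> int:
    """Hamming distance of two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def spawn_seed(rng_or_seed, index: int) -> int:
    """Derive a stable child seed (< 2**31) from a base seed and an index."""
    base = int(rng_or_seed)
    return int((base * 1_000_003 + index * 7_919 + 17) % (2**31 - 1))
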