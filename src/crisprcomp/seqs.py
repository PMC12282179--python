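"""Small DNA-string helpers shared across modules.

Sequences are plain upper-case ``str`` over the alphabet ``ACGTN``
everywhere in this package; Biopython objects appear only at file
boundaries.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = "ACGT"

# byte codes used for vectorised comparison (N gets a code that never matches)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographically smaller of a sequence and its reverse complement.

    Used as a strand-independent key for spacers and repeats.
    """
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def encode(seq: str) -> np.ndarray:
    """Encode DNA as uint8 codes; non-ACGT bases get a never-matching code."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """I.i.d. uniform DNA of the given length."""
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at the given per-base rate.

    A drawn substitution always changes the base (one of the three
    alternatives, uniformly), so `rate` is the expected per-base
    difference from the input.
    """
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alternatives = [b for b in DNA_ALPHABET if b != out[i]]
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def validate_dna(seq: str, allow_n: bool = True) -> None:
    """Raise ``ValueError`` on characters outside ACGT (optionally N)."""
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)!r}")


def hamming_identity(a: str, b: str) -> float:
    """Fraction of agreeing positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal lengths")
    if not a:
        return 1.0
    return sum(x == y for x, y in zip(a, b)) / len(a)
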