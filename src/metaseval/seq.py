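"""Small DNA-string helpers shared across the package.

Sequences are plain Python strings over the alphabet {A, C, G, T};
coordinates are 0-based, half-open, on the forward strand.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: base -> 2-bit code used by the k-mer machinery (A=0, C=1, G=2, T=3)
BASE_CODE = {b: i for i, b in enumerate(BASES)}
CODE_BASE = {i: b for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographically smaller of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random i.i.d. DNA of the given length and GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def point_mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. point substitutions at the given per-base rate.

    Each mutated base is replaced uniformly by one of the three other bases.
    """
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size == 0:
        return seq
    code = np.zeros(256, dtype=np.uint8)
    for b, i in BASE_CODE.items():
        code[ord(b)] = i
    old = code[arr[hit]]
    new = (old + rng.integers(1, 4, size=hit.size)) % 4
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    arr[hit] = lut[new]
    return arr.tobytes().decode()


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
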