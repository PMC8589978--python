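"""Shared low-level helpers: base encoding, RNG coercion, small integer sampling."""

from __future__ import annotations

import numpy as np

# Bases are held internally as uint8 codes 0..3 = A,C,G,T so that the
# complement is simply 3 - code.  Code 4 is reserved for N/unknown.
BASES = "ACGT"
_CODE2ASCII = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ASCII2CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ASCII2CODE[_b] = _i
    _ASCII2CODE[_b + 32] = _i  # lowercase

N_CODE = 4


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string into uint8 codes (A,C,G,T -> 0..3, anything else -> 4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ASCII2CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back into a DNA string."""
    return _CODE2ASCII[codes].tobytes().decode("ascii")


def complement(codes: np.ndarray) -> np.ndarray:
    out = 3 - codes
    out[codes >= 4] = N_CODE
    return out


def revcomp(codes: np.ndarray) -> np.ndarray:
    return complement(codes)[::-1]


def transition(code: int) -> int:
    """The transition partner of a base code (A<->G, C<->T)."""
    return {0: 2, 2: 0, 1: 3, 3: 1}[int(code)]


def is_transversion_pair(a: str, b: str) -> bool:
    """True when the unordered allele pair {a, b} is a purine<->pyrimidine change."""
    purines = {"A", "G"}
    return (a in purines) != (b in purines)


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, None, or an existing Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def distinct_ints(rng: np.random.Generator, n: int, high: int) -> np.ndarray:
    """Draw n distinct integers from [0, high) without building a full permutation."""
    if n > high:
        raise ValueError(f"cannot draw {n} distinct values below {high}")
    got = np.unique(rng.integers(0, high, size=int(n * 1.2) + 16))
    while got.size < n:
        more = rng.integers(0, high, size=n)
        got = np.unique(np.concatenate([got, more]))
    return np.sort(rng.choice(got, size=n, replace=False))
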