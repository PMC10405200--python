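"""Small nucleotide-sequence helpers shared across modules."""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return codes_to_str(codes)


def codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3; other characters map to 4."""
    table = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))
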