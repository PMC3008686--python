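"""Shared helpers: alphabet encoding, reproducible RNG substreams."""

from __future__ import annotations

import zlib

import numpy as np

#: Fixed column order used for every matrix in the package.
ALPHABET = "ACGT"

#: Integer codes; 4 is the ambiguity code N (pass-through in scoring).
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
N_CODE = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (A=0,C=1,G=2,T=3,N=4).

    Raises ValueError on characters outside {A,C,G,T,N} (case-insensitive).
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"invalid nucleotide {bad!r} in sequence")
    return codes


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def substream(seed: int, *tags: object) -> np.random.Generator:
    """Named, reproducible RNG substream derived from one master seed.

    Tags (strings/ints) are hashed into the SeedSequence spawn key so that
    e.g. ``substream(seed, "null-sets", 7)`` is stable across runs and
    independent of call order.
    """
    key = tuple(
        zlib.crc32(str(t).encode("utf-8")) if not isinstance(t, (int, np.integer)) else int(t)
        for t in tags
    )
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(int(seed_or_rng))
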