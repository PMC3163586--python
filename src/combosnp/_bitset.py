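"""Packed-word bitsets over individuals.

Carrier sets are stored as little-endian ``uint64`` word arrays of fixed
width ``ceil(n/64)``; intersection is bitwise AND, cardinality is popcount.
"""

from __future__ import annotations

import numpy as np

WORD_BITS = 64


def n_words(n_bits: int) -> int:
    return (n_bits + WORD_BITS - 1) // WORD_BITS


def pack(mask: np.ndarray) -> np.ndarray:
    """Pack a boolean vector into a uint64 word array (little-endian bits)."""
    mask = np.asarray(mask, dtype=bool)
    nw = n_words(mask.size)
    as_bytes = np.packbits(mask, bitorder="little")
    buf = np.zeros(nw * 8, dtype=np.uint8)
    buf[: as_bytes.size] = as_bytes
    return buf.view(np.uint64)


def unpack(words: np.ndarray, n_bits: int) -> np.ndarray:
    """Inverse of :func:`pack`; returns a boolean vector of length ``n_bits``."""
    bits = np.unpackbits(words.view(np.uint8), bitorder="little")
    return bits[:n_bits].astype(bool)


def popcount(words: np.ndarray) -> int:
    return int(np.bitwise_count(words).sum())


def indices(words: np.ndarray, n_bits: int) -> np.ndarray:
    """0-based positions of set bits."""
    return np.flatnonzero(unpack(words, n_bits))
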