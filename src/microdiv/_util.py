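"""Shared helpers: sequence encoding, interval arithmetic, RNG plumbing."""

from __future__ import annotations

import zlib

import numpy as np

# Canonical base order used throughout for uint8 encodings.
BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        pos = int(np.argmax(arr == 255))
        raise ValueError(f"non-ACGTN character {seq[pos]!r} at position {pos}")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    if not seq:
        return 0.0
    g = seq.count("G") + seq.count("g") + seq.count("C") + seq.count("c")
    return 100.0 * g / len(seq)


def merge_intervals(ivals) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivals = sorted((s, e) for s, e in ivals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivals:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_span(ivals) -> int:
    return sum(e - s for s, e in merge_intervals(ivals))


def spawn_rng(seed, *salt) -> np.random.Generator:
    """Independent generator derived from a base seed plus string/int salt.

    Uses crc32 for the salt so the stream is stable across processes
    (``hash()`` is randomized per interpreter).
    """
    words = [int(seed) & 0x7FFFFFFF]
    words += [zlib.crc32(repr(s).encode()) & 0x7FFFFFFF for s in salt]
    return np.random.default_rng(np.random.SeedSequence(words))
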