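"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (pure-Python scans, boolean-array
interval unions, external edit-distance alignment) and shares no code with
the implementation under test.
"""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_find(text: str, pattern: str, max_mm: int = 0, both_strands: bool = True):
    """Sliding-window Hamming scan; returns sorted (pos, strand, mismatches)."""
    out = []
    pats = [(pattern, "+")]
    if both_strands and rc(pattern) != pattern:
        pats.append((rc(pattern), "-"))
    m = len(pattern)
    for pat, strand in pats:
        for i in range(len(text) - m + 1):
            mm = sum(a != b for a, b in zip(text[i: i + m], pat))
            if mm <= max_mm:
                out.append((i, strand, mm))
    out.sort()
    return out


def global_identity(a: str, b: str) -> float:
    """Identity from an independent global edit-distance alignment."""
    import edlib

    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def union_length_bool(intervals, length: int) -> int:
    """Interval-union length via an explicit boolean coverage array."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())


def read_kmers(seq: str, k: int) -> set[str]:
    """Canonical k-mer set of a sequence (independent re-implementation)."""
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i: i + k]
        out.add(min(km, rc(km)))
    return out
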