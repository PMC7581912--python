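"""Shared low-level sequence machinery.

Reverse complement, seeded mutation, approximate string scanning (used both
for probe hit counting and boundary-marker search), interval arithmetic, and
thin FASTA/FASTQ wrappers around Biopython.

Coordinates are 0-based half-open everywhere in this package.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMP = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random ACGT string of length ``n``."""
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at per-base probability ``rate``.

    Length-preserving: substitutions only, each mutated base is replaced by a
    uniformly chosen *different* base.
    """
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    k = rng.binomial(len(arr), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(arr), size=k, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True, order=True)
class Match:
    """One approximate occurrence of a pattern on a text."""

    pos: int
    strand: str
    mismatches: int


def find_matches(
    text: str,
    pattern: str,
    max_mismatches: int = 0,
    both_strands: bool = True,
) -> list[Match]:
    """All occurrences of ``pattern`` on ``text`` with <= ``max_mismatches``
    substitutions, optionally also as reverse complement ('-' strand).

    Positions always refer to the forward coordinates of ``text``. A
    palindromic pattern is reported once, on the '+' strand.
    """
    m = len(pattern)
    if m == 0 or m > len(text):
        return []
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(t, m)
    searches = [(pattern, "+")]
    if both_strands:
        rc = revcomp(pattern)
        if rc != pattern:
            searches.append((rc, "-"))
    out: list[Match] = []
    for pat, strand in searches:
        pa = np.frombuffer(pat.encode(), dtype=np.uint8)
        mism = (win != pa).sum(axis=1)
        for pos in np.nonzero(mism <= max_mismatches)[0]:
            out.append(Match(int(pos), strand, int(mism[pos])))
    out.sort(key=lambda h: (h.pos, h.strand))
    return out


# ---------------------------------------------------------------------------
# interval arithmetic (0-based half-open)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O
# ---------------------------------------------------------------------------

@dataclass
class SeqRead:
    """A sequencing read (FASTQ record)."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[SeqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(SeqRead(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fastq(path: str | Path, reads: Iterable[SeqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
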