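"""Repeat-aware greedy capture-probe panel design.

Candidate 120-base windows are tiled over the reference haplotypes, windows
touching any repeat-masked base or an ambiguous base are discarded, and each
surviving candidate is scored by its total alignment hit count across the
references (both strands, hits inside repeat masks discarded).  Probes are
then added greedily in descending hit-count order until every reference is
covered with no inter-hit gap of the expected mean fragment length (~4-5 kb,
default threshold 5000) or the candidates are exhausted.

Because homologous loci share conserved blocks, one probe recurs across all
of them, so the greedy order strongly prefers the family-wide conserved
probes -- the mechanism that lets a handful of probes tile an entire gene
cluster.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigError, DesignInfeasibleError, ValidationError
from .sequtils import find_matches, merge_intervals, overlaps, read_fasta, write_fasta

log = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass
class MaskedReference:
    """A reference haplotype plus repeat-mask intervals (0-based half-open,
    normalized to sorted non-overlapping form on construction)."""

    ref_id: str
    sequence: str
    repeat_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, e in self.repeat_intervals:
            if not (0 <= s < e <= len(self.sequence)):
                raise ValidationError(
                    f"repeat interval ({s}, {e}) outside reference {self.ref_id}"
                )
        self.repeat_intervals = merge_intervals(self.repeat_intervals)
        self.sequence = self.sequence.upper()

    def masked(self, interval: tuple[int, int]) -> bool:
        """True if the interval overlaps any repeat by at least one base."""
        return any(overlaps(interval, iv) for iv in self.repeat_intervals)


@dataclass
class DesignConfig:
    """Probe design parameters.

    probe_length: capture probe length (bases).
    stride: candidate window step; defaults to probe_length (non-overlapping
        tiling) when None.
    max_gap: coverage criterion -- every inter-hit midpoint gap must fall
        strictly below this (the expected mean captured-fragment length).
    allow_mismatches: substitution budget when counting design-time hits.
    max_panel: optional cap on panel size.
    """

    probe_length: int = 120
    stride: int | None = None
    max_gap: int = 5000
    allow_mismatches: int = 0
    max_panel: int | None = None

    def __post_init__(self) -> None:
        if self.probe_length <= 0:
            raise ConfigError("probe_length must be positive")
        if self.max_gap <= self.probe_length:
            raise ConfigError("max_gap must exceed probe_length")
        if self.stride is not None and self.stride <= 0:
            raise ConfigError("stride must be positive")
        if self.allow_mismatches < 0:
            raise ConfigError("allow_mismatches must be >= 0")

    @property
    def effective_stride(self) -> int:
        return self.stride if self.stride is not None else self.probe_length


@dataclass(frozen=True)
class ProbeHit:
    """One design-time probe alignment."""

    ref_id: str
    pos: int
    strand: str
    mismatches: int


@dataclass
class Probe:
    probe_id: str
    sequence: str
    hits: list[ProbeHit] = field(default_factory=list)


@dataclass
class GapReport:
    """Per-reference coverage-gap summary (midpoint convention)."""

    gaps: list[tuple[float, float]]
    max_gap: float
    mean_gap: float


@dataclass
class ProbePanel:
    """Greedy-ordered probe selection plus the gap state it achieved."""

    probes: list[Probe] = field(default_factory=list)
    max_gap_per_ref: dict[str, float] = field(default_factory=dict)
    satisfied: bool = True
    violations: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probes)


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(
    refs: Sequence[MaskedReference], cfg: DesignConfig
) -> list[str]:
    """All length-``probe_length`` windows at the configured stride that
    contain only ACGT and overlap no repeat interval, deduplicated by
    sequence (first occurrence keeps its place in the order).

    Windows are tiled from position 0; a terminal window flush with the
    reference end is added only when the end would otherwise sit more than
    max_gap/2 beyond the last tiled window.
    """
    if not refs:
        raise ValidationError("at least one reference is required")
    L = cfg.probe_length
    seen: set[str] = set()
    out: list[str] = []
    for ref in refs:
        n = len(ref.sequence)
        starts = list(range(0, n - L + 1, cfg.effective_stride))
        if starts and n - (starts[-1] + L) > cfg.max_gap / 2:
            starts.append(n - L)
        elif not starts and n >= L:
            starts = [0]
        kept = 0
        for s in starts:
            window = ref.sequence[s: s + L]
            if ref.masked((s, s + L)):
                continue
            if not _ACGT.issuperset(window):
                continue
            kept += 1
            if window not in seen:
                seen.add(window)
                out.append(window)
        if kept == 0:
            log.warning("reference %s contributed no candidate windows", ref.ref_id)
    return out


# ---------------------------------------------------------------------------
# hit counting
# ---------------------------------------------------------------------------

def count_hits(
    candidate: str,
    refs: Sequence[MaskedReference],
    allow_mismatches: int = 0,
) -> list[ProbeHit]:
    """All positions on either strand of every reference where the candidate
    matches with at most ``allow_mismatches`` substitutions; hits overlapping
    a repeat interval are discarded."""
    L = len(candidate)
    hits: list[ProbeHit] = []
    for ref in refs:
        for m in find_matches(ref.sequence, candidate, allow_mismatches, both_strands=True):
            if ref.masked((m.pos, m.pos + L)):
                continue
            hits.append(ProbeHit(ref.ref_id, m.pos, m.strand, m.mismatches))
    return hits


# ---------------------------------------------------------------------------
# gap computation (midpoint convention)
# ---------------------------------------------------------------------------

def _midpoints_per_ref(
    probes: Iterable[Probe], refs: Sequence[MaskedReference], probe_length: int
) -> dict[str, list[float]]:
    mids: dict[str, list[float]] = {r.ref_id: [] for r in refs}
    for p in probes:
        for h in p.hits:
            mids[h.ref_id].append(h.pos + probe_length / 2.0)
    for v in mids.values():
        v.sort()
    return mids


def _gaps_from_midpoints(mids: list[float], ref_len: int) -> list[tuple[float, float]]:
    """Gap intervals between consecutive hit midpoints, including the
    distances from each reference end to the nearest midpoint."""
    if not mids:
        return [(0.0, float(ref_len))]
    bounds = [0.0, *mids, float(ref_len)]
    return [(a, b) for a, b in zip(bounds, bounds[1:])]


def coverage_gaps(
    panel: ProbePanel, refs: Sequence[MaskedReference], probe_length: int = 120
) -> dict[str, GapReport]:
    """Per-reference gap intervals, maximum gap, and mean inter-hit distance
    recomputed directly from the panel's hit coordinates."""
    mids = _midpoints_per_ref(panel.probes, refs, probe_length)
    out: dict[str, GapReport] = {}
    for ref in refs:
        gaps = _gaps_from_midpoints(mids[ref.ref_id], len(ref.sequence))
        sizes = [b - a for a, b in gaps]
        out[ref.ref_id] = GapReport(
            gaps=gaps,
            max_gap=max(sizes),
            mean_gap=sum(sizes) / len(sizes),
        )
    return out


# ---------------------------------------------------------------------------
# greedy selection
# ---------------------------------------------------------------------------

def greedy_select(
    candidates: Sequence[str],
    refs: Sequence[MaskedReference],
    cfg: DesignConfig,
) -> ProbePanel:
    """Select probes in descending hit-count order (ties broken by probe
    sequence, then first hit position) until every reference's largest
    midpoint gap falls strictly below ``cfg.max_gap``.

    A reference shorter than max_gap is already satisfied by zero probes, so
    an empty panel is a valid result.  If the candidates run out first, the
    panel is returned unsatisfied with a per-reference gap-violation report.
    """
    scored: list[tuple[int, str, tuple, str, list[ProbeHit]]] = []
    ref_order = {r.ref_id: i for i, r in enumerate(refs)}
    for cand in candidates:
        hits = count_hits(cand, refs, cfg.allow_mismatches)
        if not hits:
            continue
        first = min((ref_order[h.ref_id], h.pos) for h in hits)
        scored.append((-len(hits), cand, first, cand, hits))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))

    panel = ProbePanel()

    def current_state() -> tuple[bool, dict[str, float]]:
        mids = _midpoints_per_ref(panel.probes, refs, cfg.probe_length)
        max_gaps = {}
        for ref in refs:
            gaps = _gaps_from_midpoints(mids[ref.ref_id], len(ref.sequence))
            max_gaps[ref.ref_id] = max(b - a for a, b in gaps)
        ok = all(g < cfg.max_gap for g in max_gaps.values())
        return ok, max_gaps

    ok, max_gaps = current_state()
    if ok:
        panel.max_gap_per_ref = max_gaps
        return panel
    if not scored:
        raise DesignInfeasibleError("no candidate probes with hits; design infeasible")

    for _neg, _seq, _first, cand, hits in scored:
        if cfg.max_panel is not None and len(panel.probes) >= cfg.max_panel:
            break
        panel.probes.append(Probe(f"P{len(panel.probes) + 1:03d}", cand, hits))
        ok, max_gaps = current_state()
        if ok:
            break

    panel.max_gap_per_ref = max_gaps
    panel.satisfied = ok
    if not ok:
        mids = _midpoints_per_ref(panel.probes, refs, cfg.probe_length)
        for ref in refs:
            gaps = _gaps_from_midpoints(mids[ref.ref_id], len(ref.sequence))
            bad = [g for g in gaps if g[1] - g[0] >= cfg.max_gap]
            if bad:
                panel.violations[ref.ref_id] = bad
        log.warning(
            "greedy selection exhausted candidates with %d unresolved gap(s)",
            sum(len(v) for v in panel.violations.values()),
        )
    return panel


def design_panel(
    refs: Sequence[MaskedReference], cfg: DesignConfig | None = None
) -> ProbePanel:
    """Convenience composition: enumerate candidates then greedily select."""
    cfg = cfg or DesignConfig()
    return greedy_select(enumerate_candidates(refs, cfg), refs, cfg)


# ---------------------------------------------------------------------------
# panel I/O
# ---------------------------------------------------------------------------

def write_panel(panel: ProbePanel, fasta_path: str | Path, bed_path: str | Path) -> None:
    """Emit probe FASTA (selection order) and a BED of hit intervals."""
    write_fasta(fasta_path, [(p.probe_id, p.sequence) for p in panel.probes])
    with open(bed_path, "w") as fh:
        for p in panel.probes:
            for h in p.hits:
                fh.write(
                    f"{h.ref_id}\t{h.pos}\t{h.pos + len(p.sequence)}\t"
                    f"{p.probe_id}\t{h.mismatches}\t{h.strand}\n"
                )


def read_panel(fasta_path: str | Path, bed_path: str | Path | None = None) -> ProbePanel:
    """Round-trip reader for :func:`write_panel` output."""
    seqs = read_fasta(fasta_path)
    probes = {pid: Probe(pid, seq) for pid, seq in seqs.items()}
    if bed_path is not None and Path(bed_path).exists():
        with open(bed_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                ref_id, s, _e, pid, mm, strand = line.rstrip("\n").split("\t")
                probes[pid].hits.append(ProbeHit(ref_id, int(s), strand, int(mm)))
    return ProbePanel(probes=list(probes.values()))


def read_masks_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED repeat masks -> {ref_id: [(start, end), ...]}."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            out.setdefault(cols[0], []).append((int(cols[1]), int(cols[2])))
    return out


def read_repeatmasker_out(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Convert RepeatMasker .out annotation to mask intervals (1-based
    inclusive columns 6-7 -> 0-based half-open)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 7 or not parts[0].isdigit():
                continue
            ref_id, s, e = parts[4], int(parts[5]), int(parts[6])
            out.setdefault(ref_id, []).append((s - 1, e))
    return out
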