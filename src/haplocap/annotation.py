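"""Annotation of assembled haplotigs for homologous gene clusters.

The locus content of a haplotig is recovered from the *alignment pattern* of
the capture probes along it: within a gene family the probes recur in a fixed
per-locus order, so the label sequence of probe hits can be tokenized into
locus occurrences.  Within each locus occurrence, exon/intron/UTR boundaries
are then placed by scanning for 16-base boundary markers -- each marker takes
8 bases from the element on the left of a junction and 8 from the element on
the right -- with mismatch tolerance escalated 0 -> 1 -> 2 -> 3 only when an
exact hit is absent.

Outputs are GenBank feature-table (.tbl) and GFF3, both with 1-based
inclusive coordinates; internally everything is 0-based half-open.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, ValidationError
from .sequtils import Match, find_matches, revcomp

log = logging.getLogger(__name__)

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationConfig:
    """Parameters of the annotation stage.

    marker_length
        Length of a boundary marker (bases). Always twice ``half_length``.
    half_length
        Bases contributed by each flanking element to a marker.
    max_marker_mismatches
        Highest substitution count tolerated when locating a marker; the
        scan escalates one mismatch at a time and stops at the first
        threshold that yields a consistent hit.
    probe_align_mismatches
        Substitution budget when aligning 120-base capture probes to a
        haplotig (assembled sequence carries real allelic variation).
    """

    marker_length: int = 16
    half_length: int = 8
    max_marker_mismatches: int = 3
    probe_align_mismatches: int = 3

    def __post_init__(self) -> None:
        if self.marker_length != 2 * self.half_length:
            raise ConfigError("marker_length must equal 2 * half_length")
        if not (0 <= self.max_marker_mismatches < self.half_length):
            raise ConfigError("max_marker_mismatches must lie in [0, half_length)")
        if self.probe_align_mismatches < 0:
            raise ConfigError("probe_align_mismatches must be >= 0")


@dataclass(frozen=True)
class ProbeHit:
    """One capture-probe occurrence on a haplotig."""

    label: str
    strand: str
    pos: int
    mismatches: int = 0


@dataclass
class ProbeSignature:
    """Ordered capture-probe hits along one haplotig."""

    haplotig_id: str
    hits: list[ProbeHit] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.hits]


@dataclass(frozen=True)
class LocusPattern:
    """Expected probe-label sequence of one locus.

    ``optional`` holds the indices of labels that are absent in some
    occurrences (a probe site destroyed by allelic variation still leaves
    the rest of the pattern recognisable).
    """

    locus_name: str
    labels: tuple[str, ...]
    optional: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("locus pattern must be non-empty")
        if any(i < 0 or i >= len(self.labels) for i in self.optional):
            raise ValidationError("optional index out of range")


@dataclass(frozen=True)
class BoundaryMarker:
    """16-base junction marker: 8 bases from each flanking element.

    ``index`` is the junction's rank within the locus's element chain
    (0 = locus start, i.e. the upstream|first-element junction).
    """

    marker: str
    left_element: str
    right_element: str
    locus_name: str
    index: int
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if len(self.marker) % 2 != 0:
            raise ValidationError("marker length must be even")

    @property
    def left_half(self) -> str:
        return self.marker[: len(self.marker) // 2]

    @property
    def right_half(self) -> str:
        return self.marker[len(self.marker) // 2:]


@dataclass
class FeatureAnnotation:
    """A locus occurrence on a haplotig with its ordered sub-elements.

    ``elements`` is an ordered tuple of (label, (start, end)) pairs that
    tile ``interval`` contiguously on the '+' strand; on the '-' strand the
    intervals are stored in the haplotig's own increasing coordinates with
    labels running in reverse transcriptional order.
    """

    haplotig_id: str
    locus_name: str
    interval: tuple[int, int]
    strand: str = "+"
    elements: tuple[tuple[str, tuple[int, int]], ...] = ()
    allele_name: str | None = None
    allele_level: str | None = None
    complete: bool = True

    @property
    def exon_intervals(self) -> list[tuple[int, int]]:
        return [iv for label, iv in self.elements if label.startswith("exon")]

    def validate(self) -> None:
        s, e = self.interval
        if not (0 <= s < e):
            raise ValidationError(f"bad feature interval {self.interval}")
        prev_end = None
        for label, (es, ee) in self.elements:
            if not (s <= es < ee <= e):
                raise ValidationError(f"element {label} outside feature interval")
            if prev_end is not None and es < prev_end:
                raise ValidationError(f"element {label} overlaps its predecessor")
            prev_end = ee


@dataclass
class JunctionCall:
    """Result of scanning one expected junction within a feature."""

    index: int
    left_element: str
    right_element: str
    pos: int | None          # junction coordinate, feature-relative
    mismatches: int | None   # threshold at which the hit was accepted


# ---------------------------------------------------------------------------
# probe alignment and orientation
# ---------------------------------------------------------------------------

def _panel_items(panel) -> list[tuple[str, str]]:
    """Accept a ProbePanel, a mapping label->sequence, or (label, seq) pairs."""
    if hasattr(panel, "probes"):
        return [(p.probe_id, p.sequence) for p in panel.probes]
    if isinstance(panel, Mapping):
        return list(panel.items())
    return list(panel)


def align_probes(panel, haplotig: str, cfg: AnnotationConfig | None = None) -> ProbeSignature:
    """All occurrences of every panel probe on either strand of a haplotig."""
    cfg = cfg or AnnotationConfig()
    sig = ProbeSignature(haplotig_id="")
    for label, seq in _panel_items(panel):
        for m in find_matches(haplotig, seq, cfg.probe_align_mismatches, both_strands=True):
            sig.hits.append(ProbeHit(label, m.strand, m.pos, m.mismatches))
    sig.hits.sort(key=lambda h: (h.pos, h.label))
    return sig


def orient_haplotig(
    haplotig: str, signature: ProbeSignature, panel, cfg: AnnotationConfig | None = None
) -> tuple[str, ProbeSignature, bool]:
    """Canonicalize orientation: if the majority of probe hits are on the
    reverse strand, reverse-complement the haplotig and recompute the
    signature.  Returns (sequence, signature, flipped)."""
    cfg = cfg or AnnotationConfig()
    fwd = sum(1 for h in signature.hits if h.strand == "+")
    rev = len(signature.hits) - fwd
    if rev > fwd:
        flipped_seq = revcomp(haplotig)
        new_sig = align_probes(panel, flipped_seq, cfg)
        new_sig.haplotig_id = signature.haplotig_id
        return flipped_seq, new_sig, True
    if rev == fwd and rev > 0:
        log.warning("strand tie for %s: keeping input orientation", signature.haplotig_id)
    return haplotig, signature, False


# ---------------------------------------------------------------------------
# locus segmentation by probe-pattern tokenization
# ---------------------------------------------------------------------------

@dataclass
class LocusSegment:
    """A tokenized locus occurrence: a run of probe hits plus the search
    window (midpoints to neighbouring tokens / haplotig ends)."""

    candidates: tuple[str, ...]   # locus names whose pattern matched the run
    window: tuple[int, int]
    hit_slice: tuple[int, int]    # [i, j) into the signature's hit list

    @property
    def locus_name(self) -> str:
        return self.candidates[0]


def _match_pattern(pattern: LocusPattern, labels: Sequence[str], start: int) -> int:
    """Number of signature tokens consumed by ``pattern`` anchored at
    ``start``; 0 if the pattern does not match there.  Optional labels may
    be skipped; all consumed tokens must match in order."""
    p, j = 0, start
    while p < len(pattern.labels):
        if j < len(labels) and labels[j] == pattern.labels[p]:
            j += 1
            p += 1
        elif p in pattern.optional:
            p += 1
        else:
            return 0
    return j - start


def segment_loci(
    signature: ProbeSignature,
    patterns: Sequence[LocusPattern],
    haplotig_len: int,
    probe_length: int | None = None,
) -> tuple[list[LocusSegment], list[tuple[int, int]]]:
    """Greedy left-to-right tokenization of the probe-label sequence by
    longest-matching locus pattern.

    Returns (segments, unannotated hit intervals).  Window boundaries fall
    at the midpoint between adjacent tokens' flanking probe hits; terminal
    windows extend to the haplotig ends.
    """
    labels = signature.labels
    hits = signature.hits
    plen = probe_length if probe_length is not None else (120 if not hits else 120)
    tokens: list[tuple[tuple[str, ...], int, int]] = []
    unmatched: list[int] = []
    i = 0
    while i < len(labels):
        best_len = 0
        best: list[str] = []
        for pat in patterns:
            c = _match_pattern(pat, labels, i)
            if c > best_len:
                best_len, best = c, [pat.locus_name]
            elif c == best_len and c > 0 and pat.locus_name not in best:
                best.append(pat.locus_name)
        if best_len == 0:
            unmatched.append(i)
            i += 1
        else:
            tokens.append((tuple(sorted(best)), i, i + best_len))
            i += best_len

    segments: list[LocusSegment] = []
    for k, (cands, a, b) in enumerate(tokens):
        if k == 0:
            start = 0
        else:
            prev_end = hits[tokens[k - 1][2] - 1].pos + plen
            start = (prev_end + hits[a].pos) // 2
        if k == len(tokens) - 1:
            end = haplotig_len
        else:
            cur_end = hits[b - 1].pos + plen
            end = (cur_end + hits[tokens[k + 1][1]].pos) // 2
        segments.append(LocusSegment(cands, (start, end), (a, b)))

    un_ivs = [(hits[i].pos, hits[i].pos + plen) for i in unmatched]
    return segments, un_ivs


def learn_locus_patterns(
    references: Mapping[str, str],
    features_by_ref: Mapping[str, Sequence[FeatureAnnotation]],
    panel,
    cfg: AnnotationConfig | None = None,
) -> list[LocusPattern]:
    """Derive per-locus probe-label patterns from annotated references.

    For every truth locus occurrence, the labels of probe hits falling fully
    inside the occurrence form one observation; the longest observation is
    the canonical label order and labels missing from some occurrence are
    flagged optional.
    """
    cfg = cfg or AnnotationConfig()
    probe_len = len(_panel_items(panel)[0][1]) if _panel_items(panel) else 0
    occurrences: dict[str, list[tuple[str, ...]]] = defaultdict(list)
    for ref_id, seq in references.items():
        sig = align_probes(panel, seq, cfg)
        for feat in features_by_ref.get(ref_id, []):
            s, e = feat.interval
            labels = tuple(
                h.label for h in sig.hits if s <= h.pos and h.pos + probe_len <= e
            )
            occurrences[feat.locus_name].append(labels)

    patterns = []
    for locus, occs in sorted(occurrences.items()):
        canon = max(occs, key=len)
        if not canon:
            log.warning("locus %s has no probe hits in any reference; no pattern", locus)
            continue
        optional: set[int] = set()
        for occ in occs:
            # greedy subsequence alignment of occ against canon
            j = 0
            used = set()
            for lab in occ:
                while j < len(canon) and canon[j] != lab:
                    j += 1
                if j < len(canon):
                    used.add(j)
                    j += 1
            optional.update(set(range(len(canon))) - used)
        patterns.append(LocusPattern(locus, canon, frozenset(optional)))
    return patterns


# ---------------------------------------------------------------------------
# boundary markers
# ---------------------------------------------------------------------------

def build_boundary_markers(
    references: Mapping[str, str],
    features_by_ref: Mapping[str, Sequence[FeatureAnnotation]],
    cfg: AnnotationConfig | None = None,
) -> list[BoundaryMarker]:
    """Extract 16-base junction markers from annotated references.

    For each locus occurrence the junction chain is
    upstream|e0, e0|e1, ..., e_last|downstream; the marker at a junction
    takes the ``half_length`` bases ending the left element and the
    ``half_length`` bases starting the right one.  Markers whose flanking
    element is shorter than ``half_length``, or that would reach past the
    reference ends, are skipped with a warning.  A marker string observed at
    two different junctions of the same locus is flagged ambiguous.
    """
    cfg = cfg or AnnotationConfig()
    h = cfg.half_length
    seen: dict[tuple[str, str], set[tuple[str, str, int]]] = defaultdict(set)
    for ref_id, seq in references.items():
        for feat in features_by_ref.get(ref_id, []):
            if not feat.elements:
                continue
            chain: list[tuple[str, str, int]] = []  # (left, right, junction coord)
            first_label, (fs, _) = feat.elements[0]
            chain.append((UPSTREAM, first_label, fs))
            for (la, (sa, ea)), (lb, (sb, eb)) in zip(feat.elements, feat.elements[1:]):
                chain.append((la, lb, ea))
            last_label, (_, le) = feat.elements[-1]
            chain.append((last_label, DOWNSTREAM, le))
            lengths = {label: e - s for label, (s, e) in feat.elements}
            for idx, (left, right, pos) in enumerate(chain):
                if left != UPSTREAM and lengths.get(left, h) < h:
                    log.warning("element %s of %s shorter than %d; marker skipped",
                                left, feat.locus_name, h)
                    continue
                if right != DOWNSTREAM and lengths.get(right, h) < h:
                    log.warning("element %s of %s shorter than %d; marker skipped",
                                right, feat.locus_name, h)
                    continue
                if pos - h < 0 or pos + h > len(seq):
                    log.warning("junction %s|%s of %s too close to sequence end; skipped",
                                left, right, feat.locus_name)
                    continue
                marker = seq[pos - h: pos + h]
                seen[(feat.locus_name, marker)].add((left, right, idx))

    out: list[BoundaryMarker] = []
    for (locus, marker), junctions in sorted(seen.items()):
        ambiguous = len(junctions) > 1
        for left, right, idx in sorted(junctions, key=lambda j: j[2]):
            out.append(BoundaryMarker(marker, left, right, locus, idx, ambiguous))
    out.sort(key=lambda m: (m.locus_name, m.index, m.marker))
    return out


def markers_for_locus(markers: Iterable[BoundaryMarker], locus: str) -> list[BoundaryMarker]:
    return [m for m in markers if m.locus_name == locus]


def scan_boundaries(
    feature_seq: str,
    locus_markers: Sequence[BoundaryMarker],
    cfg: AnnotationConfig | None = None,
) -> tuple[list[JunctionCall], bool]:
    """Locate every expected junction of one locus within a feature sequence.

    Junctions are visited in element order.  Each is scanned at mismatch
    threshold 0 and, only if absent, the threshold escalates one at a time up
    to ``max_marker_mismatches``.  A junction position is the marker start
    plus ``half_length``; among several hits at the accepted threshold the
    leftmost position strictly after the previous junction wins.  Returns
    (calls, inconsistent): ``inconsistent`` is True when a junction had hits
    but none compatible with the element order.
    """
    cfg = cfg or AnnotationConfig()
    by_index: dict[int, list[BoundaryMarker]] = defaultdict(list)
    for m in locus_markers:
        by_index[m.index].append(m)
    calls: list[JunctionCall] = []
    inconsistent = False
    prev = -1
    for idx in sorted(by_index):
        variants = by_index[idx]
        left, right = variants[0].left_element, variants[0].right_element
        found_pos: int | None = None
        found_t: int | None = None
        had_any_hit = False
        for t in range(cfg.max_marker_mismatches + 1):
            positions = []
            for v in variants:
                for m in find_matches(feature_seq, v.marker, t, both_strands=False):
                    had_any_hit = True
                    pos = m.pos + cfg.half_length
                    if pos > prev:
                        positions.append(pos)
            if positions:
                found_pos, found_t = min(positions), t
                break
        if found_pos is None and had_any_hit:
            inconsistent = True
        calls.append(JunctionCall(idx, left, right, found_pos, found_t))
        if found_pos is not None:
            prev = found_pos
    return calls, inconsistent


# ---------------------------------------------------------------------------
# full composition
# ---------------------------------------------------------------------------

def _mirror(iv: tuple[int, int], length: int) -> tuple[int, int]:
    return (length - iv[1], length - iv[0])


def _feature_from_calls(
    haplotig_id: str,
    locus: str,
    calls: Sequence[JunctionCall],
    offset: int,
    seq_len: int,
    flipped: bool,
    inconsistent: bool,
) -> FeatureAnnotation | None:
    resolved = [c for c in calls if c.pos is not None]
    if len(resolved) < 2:
        return None
    elements = []
    complete = not inconsistent and len(resolved) == len(calls)
    for a, b in zip(calls, calls[1:]):
        if a.pos is None or b.pos is None:
            complete = False
            continue
        elements.append((a.right_element, (offset + a.pos, offset + b.pos)))
    interval = (offset + resolved[0].pos, offset + resolved[-1].pos)
    strand = "+"
    if flipped:
        interval = _mirror(interval, seq_len)
        elements = [(lab, _mirror(iv, seq_len)) for lab, iv in reversed(elements)]
        strand = "-"
    feat = FeatureAnnotation(
        haplotig_id=haplotig_id,
        locus_name=locus,
        interval=interval,
        strand=strand,
        elements=tuple(elements),
        complete=complete,
    )
    feat.validate()
    return feat


def annotate(
    haplotigs: Mapping[str, str],
    panel,
    patterns: Sequence[LocusPattern],
    markers: Sequence[BoundaryMarker],
    cfg: AnnotationConfig | None = None,
) -> list[FeatureAnnotation]:
    """Annotate haplotigs: align probes, canonicalize orientation, tokenize
    the probe signature into locus occurrences, then place element boundaries
    with the 16-base markers.

    When homologous loci share an identical probe pattern, the ambiguity is
    resolved by the boundary markers themselves: the candidate locus whose
    junction set is best recovered (most junctions, fewest mismatches) wins.
    """
    cfg = cfg or AnnotationConfig()
    items = _panel_items(panel)
    probe_len = len(items[0][1]) if items else 0
    features: list[FeatureAnnotation] = []
    for hid, seq in haplotigs.items():
        sig = align_probes(panel, seq, cfg)
        sig.haplotig_id = hid
        seq_c, sig, flipped = orient_haplotig(seq, sig, panel, cfg)
        segments, _ = segment_loci(sig, patterns, len(seq_c), probe_len)
        for seg in segments:
            ws, we = seg.window
            window_seq = seq_c[ws:we]
            best: tuple | None = None
            for locus in seg.candidates:
                calls, inconsistent = scan_boundaries(
                    window_seq, markers_for_locus(markers, locus), cfg
                )
                n_found = sum(1 for c in calls if c.pos is not None)
                total_mm = sum(c.mismatches or 0 for c in calls if c.pos is not None)
                score = (n_found, -total_mm)
                if best is None or score > best[0]:
                    best = (score, locus, calls, inconsistent)
            if best is None:
                continue
            _, locus, calls, inconsistent = best
            feat = _feature_from_calls(
                hid, locus, calls, ws, len(seq_c), flipped, inconsistent
            )
            if feat is not None:
                features.append(feat)
    features.sort(key=lambda f: (f.haplotig_id, f.interval))
    return features


# ---------------------------------------------------------------------------
# allele naming
# ---------------------------------------------------------------------------

def feature_sequence(feat: FeatureAnnotation, haplotig_seq: str) -> str:
    """Transcription-orientation sequence of a feature."""
    s, e = feat.interval
    seq = haplotig_seq[s:e]
    return revcomp(seq) if feat.strand == "-" else seq


def spliced_exons(feat: FeatureAnnotation, haplotig_seq: str) -> str:
    """Concatenated exon sequence in transcriptional order."""
    exons = [(lab, iv) for lab, iv in feat.elements if lab.startswith("exon")]
    if feat.strand == "-":
        return "".join(revcomp(haplotig_seq[s:e]) for lab, (s, e) in reversed(exons))
    return "".join(haplotig_seq[s:e] for lab, (s, e) in exons)


def name_alleles(
    features: Sequence[FeatureAnnotation],
    library: Mapping[str, str],
    haplotigs: Mapping[str, str],
    markers: Sequence[BoundaryMarker],
    cfg: AnnotationConfig | None = None,
) -> list[FeatureAnnotation]:
    """Assign allele names against a library of full-gene allele sequences.

    Library ids follow ``locus*allele``.  A full-sequence exact match takes
    that name at full level; otherwise an exact match of the spliced exonic
    sequence (library exon structure recovered with the locus's own markers)
    takes the name at cDNA level; otherwise the feature is named ``NEW``.
    """
    cfg = cfg or AnnotationConfig()
    by_locus: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for name, seq in library.items():
        if "*" not in name:
            raise ValidationError(f"library id {name!r} is not locus*allele")
        by_locus[name.split("*", 1)[0]].append((name, seq.upper()))

    spliced_cache: dict[str, str | None] = {}

    def lib_spliced(name: str, seq: str, locus: str) -> str | None:
        if name not in spliced_cache:
            calls, _ = scan_boundaries(seq, markers_for_locus(markers, locus), cfg)
            # a bare allele sequence has no flanking context, so the terminal
            # junctions (locus start/end) fall back to the sequence ends
            if calls and calls[0].pos is None and calls[0].left_element == UPSTREAM:
                calls[0].pos = 0
            if calls and calls[-1].pos is None and calls[-1].right_element == DOWNSTREAM:
                calls[-1].pos = len(seq)
            if any(c.pos is None for c in calls):
                spliced_cache[name] = None
            else:
                pos = {c.index: c.pos for c in calls}
                parts = []
                ordered = sorted(pos)
                for a, b in zip(ordered, ordered[1:]):
                    # element between junction a and a+1 is right_element of a
                    label = next(c.right_element for c in calls if c.index == a)
                    if label.startswith("exon"):
                        parts.append(seq[pos[a]: pos[b]])
                spliced_cache[name] = "".join(parts)
        return spliced_cache[name]

    out = []
    for feat in features:
        entries = by_locus.get(feat.locus_name)
        if not entries:
            log.warning("no library alleles for locus %s; feature left unnamed",
                        feat.locus_name)
            out.append(feat)
            continue
        hap = haplotigs[feat.haplotig_id]
        full = feature_sequence(feat, hap)
        name = level = None
        for lib_name, lib_seq in entries:
            if full == lib_seq:
                name, level = lib_name, "full"
                break
        if name is None:
            cdna = spliced_exons(feat, hap)
            for lib_name, lib_seq in entries:
                if cdna and cdna == lib_spliced(lib_name, lib_seq, feat.locus_name):
                    name, level = lib_name, "cdna"
                    break
        if name is None:
            name, level = "NEW", None
        out.append(replace_allele(feat, name, level))
    return out


def replace_allele(feat: FeatureAnnotation, name: str, level: str | None) -> FeatureAnnotation:
    new = FeatureAnnotation(
        feat.haplotig_id, feat.locus_name, feat.interval, feat.strand,
        feat.elements, name, level, feat.complete,
    )
    return new


# ---------------------------------------------------------------------------
# tbl / GFF3 output (1-based inclusive) with bundled round-trip parsers
# ---------------------------------------------------------------------------

_TBL_KEYS = {"utr5": "5'UTR", "utr3": "3'UTR"}
_GFF_TYPES = {"utr5": "five_prime_UTR", "utr3": "three_prime_UTR"}


def _element_key(label: str, table: Mapping[str, str], default_map=True) -> str:
    if label in table:
        return table[label]
    if label.startswith("exon"):
        return "exon"
    if label.startswith("intron"):
        return "intron"
    return "misc_feature" if default_map else label


def _tbl_coords(iv: tuple[int, int], strand: str) -> tuple[int, int]:
    s, e = iv[0] + 1, iv[1]
    return (e, s) if strand == "-" else (s, e)


def write_tbl(features: Sequence[FeatureAnnotation], path: str | Path) -> None:
    """GenBank feature-table output (1-based inclusive; reverse strand is
    encoded, per convention, by start > end)."""
    by_tig: dict[str, list[FeatureAnnotation]] = defaultdict(list)
    for f in features:
        by_tig[f.haplotig_id].append(f)
    with open(path, "w") as fh:
        for tid in sorted(by_tig):
            fh.write(f">Feature {tid}\n")
            for f in sorted(by_tig[tid], key=lambda f: f.interval):
                s, e = _tbl_coords(f.interval, f.strand)
                fh.write(f"{s}\t{e}\tgene\n")
                fh.write(f"\t\t\tgene\t{f.locus_name}\n")
                if f.allele_name:
                    fh.write(f"\t\t\tallele\t{f.allele_name}\n")
                for label, iv in f.elements:
                    es, ee = _tbl_coords(iv, f.strand)
                    fh.write(f"{es}\t{ee}\t{_element_key(label, _TBL_KEYS)}\n")
                    fh.write(f"\t\t\tnote\t{label}\n")


def read_tbl(path: str | Path) -> list[FeatureAnnotation]:
    """Parse a feature table written by :func:`write_tbl`."""
    features: list[FeatureAnnotation] = []
    tid = None
    cur: dict | None = None
    pending_element: tuple[int, int, str] | None = None

    def close(cur):
        if cur is not None:
            features.append(FeatureAnnotation(
                cur["tid"], cur["locus"], cur["interval"], cur["strand"],
                tuple(cur["elements"]), cur.get("allele"),
            ))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">Feature"):
                close(cur)
                cur = None
                tid = line.split(None, 1)[1]
                continue
            parts = line.split("\t")
            if parts[0]:  # coordinate line
                a, b, key = int(parts[0]), int(parts[1]), parts[2]
                strand = "-" if a > b else "+"
                lo, hi = (b, a) if a > b else (a, b)
                iv = (lo - 1, hi)
                if key == "gene":
                    close(cur)
                    cur = {"tid": tid, "interval": iv, "strand": strand,
                           "locus": None, "elements": []}
                    pending_element = None
                else:
                    pending_element = (iv[0], iv[1], key)
            else:  # qualifier line
                qual, value = parts[3], parts[4]
                if qual == "gene":
                    cur["locus"] = value
                elif qual == "allele":
                    cur["allele"] = value
                elif qual == "note" and pending_element is not None:
                    s, e, _key = pending_element
                    cur["elements"].append((value, (s, e)))
                    pending_element = None
    close(cur)
    for f in features:
        if f.strand == "-":
            f.elements = tuple(sorted(f.elements, key=lambda el: el[1]))
    return features


def write_gff3(features: Sequence[FeatureAnnotation], path: str | Path) -> None:
    """GFF3 output with gene parents and element children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(sorted(features, key=lambda f: (f.haplotig_id, f.interval))):
            gid = f"gene{i:04d}"
            s, e = f.interval[0] + 1, f.interval[1]
            attrs = f"ID={gid};Name={f.locus_name}"
            if f.allele_name:
                attrs += f";allele={f.allele_name}"
            fh.write(f"{f.haplotig_id}\thaplocap\tgene\t{s}\t{e}\t.\t{f.strand}\t.\t{attrs}\n")
            for j, (label, (es, ee)) in enumerate(f.elements):
                gtype = _element_key(label, _GFF_TYPES)
                if gtype == "misc_feature":
                    gtype = "region"
                fh.write(
                    f"{f.haplotig_id}\thaplocap\t{gtype}\t{es + 1}\t{ee}\t.\t{f.strand}\t."
                    f"\tID={gid}.{j};Parent={gid};Name={label}\n"
                )


def read_gff3(path: str | Path) -> list[FeatureAnnotation]:
    """Parse GFF3 written by :func:`write_gff3`."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            seqid, _src, gtype, s, e, _score, strand, _phase, attr = cols
            attrs = dict(kv.split("=", 1) for kv in attr.split(";"))
            iv = (int(s) - 1, int(e))
            if gtype == "gene":
                genes[attrs["ID"]] = {
                    "tid": seqid, "locus": attrs["Name"], "interval": iv,
                    "strand": strand, "allele": attrs.get("allele"),
                    "elements": [],
                }
                order.append(attrs["ID"])
            else:
                genes[attrs["Parent"]]["elements"].append((attrs["Name"], iv))
    out = []
    for gid in order:
        g = genes[gid]
        elements = tuple(sorted(g["elements"], key=lambda el: el[1]))
        out.append(FeatureAnnotation(
            g["tid"], g["locus"], g["interval"], g["strand"], elements, g["allele"],
        ))
    return out


# ---------------------------------------------------------------------------
# pattern / marker TSV interchange
# ---------------------------------------------------------------------------

def write_patterns_tsv(patterns: Sequence[LocusPattern], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tlabels\toptional\n")
        for p in patterns:
            opt = ",".join(str(i) for i in sorted(p.optional)) or "-"
            fh.write(f"{p.locus_name}\t{','.join(p.labels)}\t{opt}\n")


def read_patterns_tsv(path: str | Path) -> list[LocusPattern]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            locus, labels, opt = line.rstrip("\n").split("\t")
            optional = frozenset() if opt == "-" else frozenset(
                int(i) for i in opt.split(","))
            out.append(LocusPattern(locus, tuple(labels.split(",")), optional))
    return out


def write_markers_tsv(markers: Sequence[BoundaryMarker], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tindex\tleft\tright\tmarker\tambiguous\n")
        for m in markers:
            fh.write(f"{m.locus_name}\t{m.index}\t{m.left_element}\t"
                     f"{m.right_element}\t{m.marker}\t{int(m.ambiguous)}\n")


def read_markers_tsv(path: str | Path) -> list[BoundaryMarker]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            locus, idx, left, right, marker, amb = line.rstrip("\n").split("\t")
            out.append(BoundaryMarker(marker, left, right, locus, int(idx), bool(int(amb))))
    return out
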