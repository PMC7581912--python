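"""Assembly evaluation: phased coverage, concordance and LG-style metrics.

A haplotig set is scored against reference haplotypes from standard
alignment files (PAF or SAM, produced by any external aligner):

* coverage  -- percent of the reference covered by the union of alignment
  target intervals (overlaps are never double counted);
* concordance -- percent identity over aligned columns, pooled as
  100 * sum(matches) / sum(aligned columns); gap columns count against it;
* LG(f)     -- the number of haplotigs, taken in decreasing order of aligned
  reference span, whose cumulative target-interval union first reaches a
  fraction f of the reference length (f = 0.75 gives LG75).  Undefined when
  the fraction is never reached.

A trivial exact-substring anchor aligner is bundled so that error-free
synthetic haplotigs can be evaluated without an external aligner.
"""
from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .errors import AlignmentParseError, ConfigError, ValidationError
from .sequtils import merge_intervals, revcomp, union_length


@dataclass(frozen=True)
class AlignmentRecord:
    """One haplotig-to-reference alignment."""

    query_id: str
    query_length: int
    target_id: str
    target_start: int
    target_end: int
    strand: str
    matches: int
    aligned_columns: int

    def __post_init__(self) -> None:
        if self.matches > self.aligned_columns:
            raise ValidationError("matches cannot exceed aligned columns")
        if self.target_start >= self.target_end:
            raise ValidationError("empty target interval")

    @property
    def target_interval(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)


@dataclass(frozen=True)
class EvalConfig:
    """lg_fraction: reference fraction for the LG metric (0.75 -> LG75);
    min_alignment_length: records with a shorter target span are ignored;
    order_by: haplotig ranking for LG ('span' = aligned reference span,
    'length' = raw haplotig length)."""

    lg_fraction: float = 0.75
    min_alignment_length: int = 0
    order_by: str = "span"

    def __post_init__(self) -> None:
        if not (0.0 < self.lg_fraction <= 1.0):
            raise ConfigError("lg_fraction must lie in (0, 1]")
        if self.order_by not in ("span", "length"):
            raise ConfigError("order_by must be 'span' or 'length'")


@dataclass
class RefReport:
    ref_id: str
    ref_length: int
    coverage_percent: float
    concordance_percent: float | None
    lg_value: int | None
    n_haplotigs: int


@dataclass
class EvalReport:
    per_ref: list[RefReport] = field(default_factory=list)
    coverage_percent: float = 0.0
    concordance_percent: float | None = None
    mean_lg: float | None = None
    lg_fraction: float = 0.75

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(r).copy() for r in self.per_ref]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "coverage_percent": self.coverage_percent,
            "concordance_percent": self.concordance_percent,
            "mean_lg": self.mean_lg,
            "lg_fraction": self.lg_fraction,
            "per_ref": [vars(r) for r in self.per_ref],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# alignment parsing
# ---------------------------------------------------------------------------

def parse_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse minimap2-style PAF: matches from column 10, aligned columns
    (matches + mismatches + gap columns) from column 11."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise AlignmentParseError(f"{path}: line {lineno}: expected >= 12 PAF columns")
            try:
                records.append(AlignmentRecord(
                    query_id=cols[0],
                    query_length=int(cols[1]),
                    target_id=cols[5],
                    target_start=int(cols[7]),
                    target_end=int(cols[8]),
                    strand=cols[4],
                    matches=int(cols[9]),
                    aligned_columns=int(cols[10]),
                ))
            except (ValueError, ValidationError) as exc:
                raise AlignmentParseError(f"{path}: line {lineno}: {exc}") from exc
    return records


def parse_sam(path: str | Path) -> list[AlignmentRecord]:
    """Parse SAM; match counts come from =/X CIGAR ops when present, else
    from the NM tag (NM = mismatches + inserted + deleted bases)."""
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            stats = defaultdict(int)
            for op, length in aln.cigartuples:
                stats[op] += length
            m = stats[0]            # M
            eq, x = stats[7], stats[8]   # =, X
            ins, dele = stats[1], stats[2]
            aligned_cols = m + eq + x + ins + dele
            if eq or x:
                matches = eq
            else:
                nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
                matches = m - max(nm - ins - dele, 0)
            records.append(AlignmentRecord(
                query_id=aln.query_name,
                query_length=aln.infer_read_length() or (aln.query_length or 0),
                target_id=aln.reference_name,
                target_start=aln.reference_start,
                target_end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                matches=matches,
                aligned_columns=aligned_cols,
            ))
    return records


def parse_alignments(path: str | Path, fmt: str | None = None) -> list[AlignmentRecord]:
    """Dispatch on declared or file-suffix format ('paf' or 'sam')."""
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt == "paf":
        return parse_paf(path)
    if fmt == "sam":
        return parse_sam(path)
    raise AlignmentParseError(f"unknown alignment format {fmt!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def reference_coverage(records: Sequence[AlignmentRecord], ref_length: int) -> float:
    """100 * |union of target intervals| / ref_length."""
    if ref_length <= 0:
        raise ValidationError("ref_length must be positive")
    return 100.0 * union_length(r.target_interval for r in records) / ref_length


def concordance(records: Sequence[AlignmentRecord]) -> float | None:
    """100 * sum(matches) / sum(aligned columns); None for empty input
    (undefined, reported as missing rather than zero)."""
    if not records:
        return None
    total_cols = sum(r.aligned_columns for r in records)
    if total_cols == 0:
        return None
    return 100.0 * sum(r.matches for r in records) / total_cols


def lg_metric(
    records: Sequence[AlignmentRecord],
    ref_length: int,
    cfg: EvalConfig | None = None,
) -> int | None:
    """Number of haplotigs needed to cover ``lg_fraction`` of the reference.

    Haplotigs are ranked by total aligned reference span (or raw length,
    per config) descending, ties by query_id; their target-interval unions
    accumulate until the threshold is reached."""
    cfg = cfg or EvalConfig()
    if ref_length <= 0:
        raise ValidationError("ref_length must be positive")
    by_query: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for r in records:
        if r.target_end - r.target_start >= cfg.min_alignment_length:
            by_query[r.query_id].append(r)
    if not by_query:
        return None

    def rank_key(q: str) -> tuple:
        recs = by_query[q]
        if cfg.order_by == "span":
            size = union_length(r.target_interval for r in recs)
        else:
            size = max(r.query_length for r in recs)
        return (-size, q)

    threshold = cfg.lg_fraction * ref_length
    covered: list[tuple[int, int]] = []
    for n, q in enumerate(sorted(by_query, key=rank_key), 1):
        covered = merge_intervals(covered + [r.target_interval for r in by_query[q]])
        if sum(e - s for s, e in covered) >= threshold:
            return n
    return None


def evaluate(
    references: Mapping[str, str] | Mapping[str, int],
    records: Sequence[AlignmentRecord],
    cfg: EvalConfig | None = None,
) -> EvalReport:
    """Full report: per-reference coverage/concordance/LG plus pooled values.

    ``references`` maps ref_id to sequence or to length.
    """
    cfg = cfg or EvalConfig()
    lengths = {
        rid: (len(v) if isinstance(v, str) else int(v))
        for rid, v in references.items()
    }
    usable = [r for r in records
              if r.target_end - r.target_start >= cfg.min_alignment_length]
    report = EvalReport(lg_fraction=cfg.lg_fraction)
    union_total = 0
    for rid, L in lengths.items():
        recs = [r for r in usable if r.target_id == rid]
        cov = reference_coverage(recs, L)
        union_total += union_length(r.target_interval for r in recs)
        report.per_ref.append(RefReport(
            ref_id=rid,
            ref_length=L,
            coverage_percent=cov,
            concordance_percent=concordance(recs),
            lg_value=lg_metric(recs, L, cfg),
            n_haplotigs=len({r.query_id for r in recs}),
        ))
    total_len = sum(lengths.values())
    report.coverage_percent = 100.0 * union_total / total_len if total_len else 0.0
    report.concordance_percent = concordance(usable)
    lgs = [r.lg_value for r in report.per_ref if r.lg_value is not None]
    report.mean_lg = sum(lgs) / len(lgs) if lgs else None
    return report


# ---------------------------------------------------------------------------
# bundled exact-anchor aligner (fixture tests only)
# ---------------------------------------------------------------------------

def align_exact(
    haplotigs: Mapping[str, str],
    references: Mapping[str, str],
) -> list[AlignmentRecord]:
    """Align each haplotig to every reference containing it as an exact
    substring (either strand).  Intended for error-free synthetic fixtures;
    real haplotigs need a real aligner."""
    records = []
    for qid, qseq in haplotigs.items():
        for rid, rseq in references.items():
            for strand, probe in (("+", qseq), ("-", revcomp(qseq))):
                start = rseq.find(probe)
                while start != -1:
                    records.append(AlignmentRecord(
                        query_id=qid,
                        query_length=len(qseq),
                        target_id=rid,
                        target_start=start,
                        target_end=start + len(qseq),
                        strand=strand,
                        matches=len(qseq),
                        aligned_columns=len(qseq),
                    ))
                    start = rseq.find(probe, start + 1)
    return records


def write_paf(records: Sequence[AlignmentRecord], path: str | Path,
              ref_lengths: Mapping[str, int] | None = None) -> None:
    """Emit records as minimal PAF (query coords synthesised as full-length)."""
    with open(path, "w") as fh:
        for r in records:
            tlen = (ref_lengths or {}).get(r.target_id, r.target_end)
            fh.write("\t".join(str(x) for x in (
                r.query_id, r.query_length, 0, r.query_length, r.strand,
                r.target_id, tlen, r.target_start, r.target_end,
                r.matches, r.aligned_columns, 255,
            )) + "\n")
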