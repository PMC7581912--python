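"""K-mer read classification and per-locus binning.

On/off-target classification mirrors bbduk-style matching with k=25,
canonical k-mers (reverse complements collapse to one entry) and "any hit
counts" semantics: a read is on-target when it shares at least
``min_shared_kmers`` k-mers with the capture-probe panel.  On-target reads
are then assigned to every locus whose probe set they share k-mers with;
junction-spanning reads legitimately land in several bins.

The published per-gene 25-mer probe sets are not distributed, so the locus
catalog is derived from annotated reference haplotypes instead: every k-mer
occurring in exactly one locus across the references becomes a probe for
that locus.  A file-based catalog (FASTA or two-column TSV) can be supplied
in its place.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import FeatureAnnotation
from .errors import ConfigError, ValidationError
from .sequtils import SeqRead, read_fasta, revcomp, write_fastq

PANEL = "__panel__"


@dataclass(frozen=True)
class BinConfig:
    """k: k-mer length; both_strands: index/lookup canonical k-mers;
    min_shared_kmers: shared k-mers required for an assignment."""

    k: int = 25
    both_strands: bool = True
    min_shared_kmers: int = 1

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigError("k must be positive")
        if self.min_shared_kmers < 1:
            raise ConfigError("min_shared_kmers must be >= 1")


@dataclass
class LocusCatalog:
    """Per-locus k-mer probe sets."""

    loci: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(km) for probes in self.loci.values() for km in probes}
        if len(lengths) > 1:
            raise ValidationError("catalog k-mers must share one length")


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _kmers(seq: str, k: int, canonicalize: bool) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        km = seq[i: i + k]
        yield canonical(km) if canonicalize else km


# ---------------------------------------------------------------------------
# index construction
# ---------------------------------------------------------------------------

def build_index(
    source: Mapping[str, str] | LocusCatalog | Sequence[tuple[str, str]],
    cfg: BinConfig | None = None,
) -> dict[str, set[str]]:
    """K-mer index: canonical k-mer -> set of labels.

    ``source`` is either a mapping/sequence of (label, probe sequence) pairs
    -- every length-k window of every probe is indexed -- or a LocusCatalog,
    whose k-mers are indexed under their locus name.
    """
    cfg = cfg or BinConfig()
    index: dict[str, set[str]] = defaultdict(set)
    if isinstance(source, LocusCatalog):
        for locus, kmers in source.loci.items():
            for km in kmers:
                if len(km) != cfg.k:
                    raise ValidationError(
                        f"catalog k-mer length {len(km)} != k={cfg.k}")
                key = canonical(km) if cfg.both_strands else km
                index[key].add(locus)
        return dict(index)
    items = source.items() if isinstance(source, Mapping) else source
    items = list(items)
    if not items:
        raise ValidationError("probe set must be non-empty")
    for label, seq in items:
        if len(seq) < cfg.k:
            raise ValidationError(
                f"probe {label} shorter than k={cfg.k} ({len(seq)} bases)")
        for km in _kmers(seq.upper(), cfg.k, cfg.both_strands):
            index[km].add(label)
    return dict(index)


def shared_kmer_labels(seq: str, index: Mapping[str, set[str]], cfg: BinConfig) -> dict[str, int]:
    """Count of distinct shared k-mers per label for one sequence."""
    counts: dict[str, set[str]] = defaultdict(set)
    for km in set(_kmers(seq.upper(), cfg.k, cfg.both_strands)):
        labels = index.get(km)
        if labels:
            for lab in labels:
                counts[lab].add(km)
    return {lab: len(kms) for lab, kms in counts.items()}


# ---------------------------------------------------------------------------
# classification and binning
# ---------------------------------------------------------------------------

def classify_on_target(
    reads: Sequence[SeqRead],
    panel_index: Mapping[str, set[str]],
    cfg: BinConfig | None = None,
) -> tuple[list[SeqRead], list[SeqRead]]:
    """Partition reads into (on_target, off_target): a read is on-target iff
    it shares at least ``min_shared_kmers`` indexed k-mers on either strand.
    The partition is exhaustive and disjoint."""
    cfg = cfg or BinConfig()
    on: list[SeqRead] = []
    off: list[SeqRead] = []
    for read in reads:
        shared = 0
        for km in set(_kmers(read.sequence, cfg.k, cfg.both_strands)):
            if km in panel_index:
                shared += 1
                if shared >= cfg.min_shared_kmers:
                    break
        (on if shared >= cfg.min_shared_kmers else off).append(read)
    return on, off


def bin_by_locus(
    on_reads: Sequence[SeqRead],
    catalog_index: Mapping[str, set[str]],
    cfg: BinConfig | None = None,
) -> tuple[dict[str, list[SeqRead]], list[SeqRead]]:
    """Assign each on-target read to every locus with which it shares at
    least ``min_shared_kmers`` catalog k-mers; reads matching no locus go to
    the unbinned pool."""
    cfg = cfg or BinConfig()
    bins: dict[str, list[SeqRead]] = defaultdict(list)
    unbinned: list[SeqRead] = []
    for read in on_reads:
        per_locus = shared_kmer_labels(read.sequence, catalog_index, cfg)
        assigned = [loc for loc, n in per_locus.items() if n >= cfg.min_shared_kmers]
        if assigned:
            for loc in sorted(assigned):
                bins[loc].append(read)
        else:
            unbinned.append(read)
    return dict(bins), unbinned


# ---------------------------------------------------------------------------
# catalog derivation and I/O
# ---------------------------------------------------------------------------

def derive_locus_catalog(
    references: Mapping[str, str],
    features_by_ref: Mapping[str, Sequence[FeatureAnnotation]],
    cfg: BinConfig | None = None,
) -> LocusCatalog:
    """Build a locus catalog from annotated references: canonical k-mers of
    each locus's occurrences, keeping only those unique to a single locus."""
    cfg = cfg or BinConfig()
    by_locus: dict[str, set[str]] = defaultdict(set)
    for ref_id, seq in references.items():
        for feat in features_by_ref.get(ref_id, []):
            s, e = feat.interval
            for km in _kmers(seq[s:e], cfg.k, cfg.both_strands):
                by_locus[feat.locus_name].add(km)
    owner: dict[str, str | None] = {}
    for locus, kmers in by_locus.items():
        for km in kmers:
            owner[km] = None if km in owner else locus
    loci = {
        locus: {km for km in kmers if owner[km] == locus}
        for locus, kmers in by_locus.items()
    }
    return LocusCatalog({loc: kms for loc, kms in loci.items() if kms})


def write_catalog_tsv(catalog: LocusCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tkmer\n")
        for locus in sorted(catalog.loci):
            for km in sorted(catalog.loci[locus]):
                fh.write(f"{locus}\t{km}\n")


def read_catalog_tsv(path: str | Path) -> LocusCatalog:
    loci: dict[str, set[str]] = defaultdict(set)
    with open(path) as fh:
        fh.readline()
        for line in fh:
            locus, km = line.rstrip("\n").split("\t")
            loci[locus].add(km)
    return LocusCatalog(dict(loci))


def read_catalog_fasta(path: str | Path) -> LocusCatalog:
    """FASTA catalog: record ids ``locus:serial`` (or bare locus names)."""
    loci: dict[str, set[str]] = defaultdict(set)
    for name, seq in read_fasta(path).items():
        loci[name.split(":", 1)[0]].add(seq)
    return LocusCatalog(dict(loci))


def write_bins(
    bins: Mapping[str, Sequence[SeqRead]],
    on_reads: Sequence[SeqRead],
    off_reads: Sequence[SeqRead],
    unbinned: Sequence[SeqRead],
    out_dir: str | Path,
) -> dict[str, Path]:
    """One FASTQ per locus plus on/off-target and unbinned FASTQs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, reads in (("on_target", on_reads), ("off_target", off_reads),
                        ("unbinned", unbinned)):
        paths[name] = out / f"{name}.fastq"
        write_fastq(paths[name], reads)
    for locus in sorted(bins):
        paths[locus] = out / f"bin_{locus}.fastq"
        write_fastq(paths[locus], bins[locus])
    return paths
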