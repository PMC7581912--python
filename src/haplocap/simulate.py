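"""Synthetic homologous-haplotype simulator.

Generates toy gene-cluster references that emulate the statistical structure
of the KIR region: a family of loci whose sequences are 85-98% identical,
built from alternating conserved and variable blocks, plus one repeat-rich
intergenic "hotspot" template carrying inverted repeat elements (an
Alu-pair-like recombination substrate).  Diploid haplotypes are ordered
concatenations of mutated template copies separated by intergenic spacers;
reads are drawn from 2-8 kb fragments at a low substitution error rate.

All outputs are deterministic for a fixed seed, and every product carries
full ground truth (feature annotations, repeat intervals, read origins).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import FeatureAnnotation
from .errors import ConfigError, ValidationError
from .sequtils import SeqRead, mutate, random_dna, revcomp, write_fasta, write_fastq

HOTSPOT = "INTERGENIC"

# Gene template geometry: (element label, block kind, length).  Exons are the
# inter-locus variable blocks (probes must avoid them); UTRs and introns are
# conserved across the family.  ~3.1 kb per gene keeps whole haplotypes at
# desk scale while preserving the alternating conserved/variable layout.
GENE_LAYOUT: tuple[tuple[str, str, int], ...] = (
    ("utr5", "conserved", 300),
    ("exon1", "variable", 300),
    ("intron1", "conserved", 700),
    ("exon2", "variable", 400),
    ("intron2", "conserved", 700),
    ("exon3", "variable", 400),
    ("utr3", "conserved", 300),
)

# Hotspot geometry: conserved L1-like filler interleaved with three short
# Alu-like repeats, two of them in opposite orientations.
HOTSPOT_LAYOUT: tuple[tuple[str, str, int], ...] = (
    ("flank5", "conserved", 600),
    ("alu_a", "repeat", 300),
    ("line_a", "conserved", 500),
    ("alu_b_rc", "repeat", 300),
    ("line_b", "conserved", 400),
    ("alu_c", "repeat", 300),
    ("flank3", "conserved", 600),
)


@dataclass(frozen=True)
class Block:
    """One template building block."""

    name: str
    kind: str  # conserved | variable | repeat
    sequence: str


@dataclass(frozen=True)
class LocusTemplate:
    """A locus's block decomposition plus element-level annotation.

    ``elements`` are (label, (start, end)) in template coordinates; for gene
    templates they coincide with the blocks, for the hotspot a single
    "intergenic" element spans the whole template.
    """

    locus_name: str
    blocks: tuple[Block, ...]
    elements: tuple[tuple[str, tuple[int, int]], ...]

    @property
    def sequence(self) -> str:
        return "".join(b.sequence for b in self.blocks)

    @property
    def exon_intervals(self) -> list[tuple[int, int]]:
        return [iv for label, iv in self.elements if label.startswith("exon")]

    def __post_init__(self) -> None:
        total = sum(len(b.sequence) for b in self.blocks)
        for label, (s, e) in self.elements:
            if not (0 <= s < e <= total):
                raise ValidationError(f"element {label} outside template")
        ivs = [iv for _, iv in self.elements]
        if ivs != sorted(ivs) or any(a[1] > b[0] for a, b in zip(ivs, ivs[1:])):
            raise ValidationError("elements must be sorted and non-overlapping")


@dataclass(frozen=True)
class HaplotypeSpec:
    """Ordered locus content of one haplotype (cA/tB-style structure)."""

    name: str
    locus_order: tuple[str, ...]
    hotspot_index: int | None = None

    def __post_init__(self) -> None:
        if not self.locus_order:
            raise ValidationError("locus_order must be non-empty")
        if self.hotspot_index is not None and not (
            0 <= self.hotspot_index < len(self.locus_order)
        ):
            raise ValidationError("hotspot_index out of range")


@dataclass
class SimConfig:
    """Simulation parameters.

    n_loci counts templates including the intergenic hotspot.  identity_range
    is the inter-locus identity window; the per-template substitution rate is
    drawn from it and applied to variable blocks (conserved blocks mutate at
    a tenth of that rate).  allelic_rate is the within-locus (allele-level)
    substitution rate applied when a template is placed on a haplotype.
    """

    n_loci: int = 4
    fragment_len_range: tuple[int, int] = (2000, 8000)
    error_rate: float = 0.001
    depth: float = 30.0
    identity_range: tuple[float, float] = (0.85, 0.98)
    seed: int = 0
    allelic_rate: float = 0.002
    spacer_len_range: tuple[int, int] = (400, 800)

    def validate(self) -> None:
        if self.n_loci < 2:
            raise ConfigError("n_loci must be >= 2 (gene loci plus the hotspot)")
        lo, hi = self.fragment_len_range
        if not (0 < lo < hi):
            raise ConfigError("fragment_len_range must satisfy 0 < min < max")
        if not (0.0 <= self.error_rate < 0.1):
            raise ConfigError("error_rate must lie in [0, 0.1)")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        ilo, ihi = self.identity_range
        if not (0.0 < ilo <= ihi <= 1.0):
            raise ConfigError("identity_range must satisfy 0 < lo <= hi <= 1")


@dataclass
class SimRead(SeqRead):
    """A read plus its ground-truth origin (forward-strand interval)."""

    origin: str = ""
    start: int = 0
    end: int = 0


@dataclass
class SimHaplotype:
    name: str
    sequence: str
    features: list[FeatureAnnotation]
    repeat_intervals: list[tuple[int, int]]


@dataclass
class SimTruth:
    """Full ground truth of a simulated diploid."""

    haplotypes: dict[str, str]
    features: dict[str, list[FeatureAnnotation]]
    repeat_intervals: dict[str, list[tuple[int, int]]]
    templates: list[LocusTemplate]
    reads: list[SimRead] = field(default_factory=list)
    rng_seed: int = 0


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def build_locus_templates(cfg: SimConfig) -> list[LocusTemplate]:
    """Build ``cfg.n_loci`` templates: n_loci - 1 gene templates named
    GENE1.. plus one repeat-rich hotspot template.

    Gene templates share ancestral conserved blocks near-verbatim; variable
    (exon) blocks diverge at a per-template rate drawn from identity_range.
    The hotspot shares the gene family's flanking conserved ancestors and
    carries three Alu-like repeats, one of them reverse-complemented.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_anc = {name: random_dna(rng, length) for name, _k, length in GENE_LAYOUT}
    hot_anc = {
        "flank5": random_dna(rng, 600),
        "line_a": random_dna(rng, 500),
        "line_b": random_dna(rng, 400),
        "flank3": random_dna(rng, 600),
    }
    alu_anc = random_dna(rng, 300)

    templates: list[LocusTemplate] = []
    for i in range(cfg.n_loci - 1):
        identity = rng.uniform(*cfg.identity_range)
        rate = 1.0 - identity
        blocks = []
        for name, kind, _length in GENE_LAYOUT:
            block_rate = rate if kind == "variable" else rate / 10.0
            blocks.append(Block(name, kind, mutate(gene_anc[name], block_rate, rng)))
        elements = []
        pos = 0
        for b in blocks:
            elements.append((b.name, (pos, pos + len(b.sequence))))
            pos += len(b.sequence)
        templates.append(LocusTemplate(f"GENE{i + 1}", tuple(blocks), tuple(elements)))

    identity = rng.uniform(*cfg.identity_range)
    rate = (1.0 - identity) / 10.0
    alu_a = mutate(alu_anc, rate, rng)
    alu_b = revcomp(mutate(alu_anc, 0.05, rng))
    alu_c = mutate(alu_anc, 0.05, rng)
    hot_blocks = (
        Block("flank5", "conserved", mutate(hot_anc["flank5"], rate, rng)),
        Block("alu_a", "repeat", alu_a),
        Block("line_a", "conserved", mutate(hot_anc["line_a"], rate, rng)),
        Block("alu_b_rc", "repeat", alu_b),
        Block("line_b", "conserved", mutate(hot_anc["line_b"], rate, rng)),
        Block("alu_c", "repeat", alu_c),
        Block("flank3", "conserved", mutate(hot_anc["flank3"], rate, rng)),
    )
    total = sum(len(b.sequence) for b in hot_blocks)
    templates.append(LocusTemplate(
        HOTSPOT, hot_blocks, (("intergenic", (0, total)),)
    ))
    return templates


# ---------------------------------------------------------------------------
# haplotype simulation
# ---------------------------------------------------------------------------

def simulate_haplotype(
    spec: HaplotypeSpec,
    templates: Sequence[LocusTemplate],
    seed: int,
    allelic_rate: float = 0.002,
    spacer_len_range: tuple[int, int] = (400, 800),
) -> SimHaplotype:
    """Concatenate allele-mutated template copies with random intergenic
    spacers, returning the sequence plus exact truth annotations."""
    tdict = {t.locus_name: t for t in templates}
    for locus in spec.locus_order:
        if locus not in tdict:
            raise KeyError(f"unknown locus {locus!r} in spec {spec.name}")
    rng = np.random.default_rng(seed)
    lo, hi = spacer_len_range
    parts: list[str] = []
    features: list[FeatureAnnotation] = []
    repeats: list[tuple[int, int]] = []
    pos = 0

    def add_spacer() -> None:
        nonlocal pos
        s = random_dna(rng, int(rng.integers(lo, hi + 1)))
        parts.append(s)
        pos += len(s)

    add_spacer()
    for locus in spec.locus_order:
        t = tdict[locus]
        copy_parts = []
        off = 0
        for b in t.blocks:
            rate = allelic_rate if b.kind == "variable" else allelic_rate / 10.0
            seq = mutate(b.sequence, rate, rng)
            if b.kind == "repeat":
                repeats.append((pos + off, pos + off + len(seq)))
            copy_parts.append(seq)
            off += len(seq)
        copy = "".join(copy_parts)
        elements = tuple(
            (label, (s + pos, e + pos)) for label, (s, e) in t.elements
        )
        feat = FeatureAnnotation(
            haplotig_id=spec.name,
            locus_name=locus,
            interval=(pos, pos + len(copy)),
            strand="+",
            elements=elements,
        )
        feat.validate()
        features.append(feat)
        parts.append(copy)
        pos += len(copy)
        add_spacer()
    return SimHaplotype(spec.name, "".join(parts), features, repeats)


def default_diploid_specs(templates: Sequence[LocusTemplate]) -> tuple[HaplotypeSpec, HaplotypeSpec]:
    """A structurally distinct haplotype pair in the style of the common
    A/B family structures: hapA carries every gene; hapB deletes one
    centromeric gene and duplicates the terminal telomeric gene."""
    genes = [t.locus_name for t in templates if t.locus_name != HOTSPOT]
    mid = (len(genes) + 1) // 2
    cen, tel = genes[:mid], genes[mid:]
    order_a = tuple(cen) + (HOTSPOT,) + tuple(tel)
    cen_b = cen[:-1] if len(cen) > 1 else cen
    tel_b = tel + [tel[-1]] if tel else [cen[-1]]
    order_b = tuple(cen_b) + (HOTSPOT,) + tuple(tel_b)
    return (
        HaplotypeSpec("hapA", order_a, hotspot_index=len(cen)),
        HaplotypeSpec("hapB", order_b, hotspot_index=len(cen_b)),
    )


def simulate_diploid(
    cfg: SimConfig,
    specs: tuple[HaplotypeSpec, HaplotypeSpec] | None = None,
) -> SimTruth:
    """Templates plus a diploid haplotype pair with full truth."""
    cfg.validate()
    templates = build_locus_templates(cfg)
    if specs is None:
        specs = default_diploid_specs(templates)
    rng = np.random.default_rng(cfg.seed + 1)
    truth = SimTruth({}, {}, {}, templates, rng_seed=cfg.seed)
    for spec in specs:
        hap_seed = int(rng.integers(0, 2**31))
        hap = simulate_haplotype(
            spec, templates, hap_seed, cfg.allelic_rate, cfg.spacer_len_range
        )
        truth.haplotypes[hap.name] = hap.sequence
        truth.features[hap.name] = hap.features
        truth.repeat_intervals[hap.name] = hap.repeat_intervals
    return truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(haplotypes: Mapping[str, str], cfg: SimConfig) -> list[SimRead]:
    """Draw reads from 2-8 kb fragments (uniform within fragment_len_range)
    at mean coverage ``cfg.depth`` with i.i.d. substitution errors.

    Reads are emitted in the forward orientation of their origin haplotype,
    so at error rate 0 every read is an exact substring of its origin.
    """
    cfg.validate()
    names = list(haplotypes)
    if not names or any(not haplotypes[n] for n in names):
        raise ValidationError("haplotypes must be non-empty")
    lo, hi = cfg.fragment_len_range
    lengths = np.array([len(haplotypes[n]) for n in names], dtype=float)
    if lo > lengths.min():
        raise ValidationError(
            f"fragment_len_range minimum {lo} exceeds shortest haplotype "
            f"({int(lengths.min())} bases)"
        )
    rng = np.random.default_rng(cfg.seed + 2)
    mean_frag = (lo + hi) / 2.0
    n_reads = int(round(cfg.depth * lengths.sum() / mean_frag))
    weights = lengths / lengths.sum()
    reads: list[SimRead] = []
    for i in range(n_reads):
        hap_idx = int(rng.choice(len(names), p=weights))
        name = names[hap_idx]
        L = len(haplotypes[name])
        frag = int(rng.integers(lo, min(hi, L) + 1))
        start = int(rng.integers(0, L - frag + 1))
        seq = haplotypes[name][start: start + frag]
        seq = mutate(seq, cfg.error_rate, rng)
        reads.append(SimRead(
            read_id=f"read{i:06d}", sequence=seq, quality=None,
            origin=name, start=start, end=start + frag,
        ))
    return reads


# ---------------------------------------------------------------------------
# haplotig fragmentation (assembler bypass for pipeline testing)
# ---------------------------------------------------------------------------

def fragment_haplotigs(haplotype: str, breakpoints: Sequence[int]) -> list[str]:
    """Cut a haplotype at the given sorted internal breakpoints; the pieces
    concatenate back to the input."""
    prev = 0
    for b in breakpoints:
        if not (0 < b < len(haplotype)):
            raise ValidationError(f"breakpoint {b} out of range")
        if b <= prev and prev != 0:
            raise ValidationError("breakpoints must be strictly increasing")
        prev = b
    if list(breakpoints) != sorted(set(breakpoints)):
        raise ValidationError("breakpoints must be sorted and unique")
    cuts = [0, *breakpoints, len(haplotype)]
    return [haplotype[a:b] for a, b in zip(cuts, cuts[1:])]


def intergenic_breakpoints(features: Sequence[FeatureAnnotation]) -> list[int]:
    """Midpoints of the spacers between consecutive locus occurrences --
    deterministic breakpoints that never cut a feature."""
    out = []
    for a, b in zip(features, features[1:]):
        out.append((a.interval[1] + b.interval[0]) // 2)
    return out


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write haplotype FASTA, repeat-mask BED, truth GFF3, reads FASTQ and
    the read-origin sidecar TSV.  Returns the paths written."""
    from .annotation import write_gff3  # deferred: avoids import noise at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["haplotypes"] = out / "haplotypes.fasta"
    write_fasta(paths["haplotypes"], truth.haplotypes.items())
    paths["masks"] = out / "repeats.bed"
    with open(paths["masks"], "w") as fh:
        for name, ivs in truth.repeat_intervals.items():
            for s, e in ivs:
                fh.write(f"{name}\t{s}\t{e}\trepeat\n")
    paths["truth_gff3"] = out / "truth.gff3"
    all_feats = [f for feats in truth.features.values() for f in feats]
    write_gff3(all_feats, paths["truth_gff3"])
    if truth.reads:
        paths["reads"] = out / "reads.fastq"
        write_fastq(paths["reads"], truth.reads)
        paths["read_truth"] = out / "reads_truth.tsv"
        with open(paths["read_truth"], "w") as fh:
            fh.write("read_id\thaplotype\tstart\tend\n")
            for r in truth.reads:
                fh.write(f"{r.read_id}\t{r.origin}\t{r.start}\t{r.end}\n")
    return paths
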