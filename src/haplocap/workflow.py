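"""End-to-end pipeline runner with config, logging and manifests.

Stage order mirrors the capture workflow: simulate (or load) references and
reads, design the probe panel, bin the reads, obtain haplotigs (external
assembler hook or ground-truth fragmentation bypass), annotate them, and
evaluate against the references.  Every stage writes a manifest entry with
its parameters and the SHA-256 of its inputs and outputs, and a re-run with
the same config and seed reproduces byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import annotation as ann
from . import binning, design, evaluation as ev, simulate as sim
from .errors import ConfigError
from .sequtils import read_fasta, write_fasta

log = logging.getLogger(__name__)

DEFAULT_SECTIONS = ("simulate", "design", "bin", "annotate", "evaluate", "paths")


@dataclass
class RunConfig:
    """Aggregated stage configs plus run-level settings."""

    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    design: design.DesignConfig = field(default_factory=design.DesignConfig)
    bin: binning.BinConfig = field(default_factory=binning.BinConfig)
    annotate: ann.AnnotationConfig = field(default_factory=ann.AnnotationConfig)
    evaluate: ev.EvalConfig = field(default_factory=ev.EvalConfig)
    seed: int = 0
    log_level: str = "INFO"
    paths: dict[str, str] = field(default_factory=dict)
    assemble_command: str | None = None


_SECTION_TYPES = {
    "simulate": ("sim", sim.SimConfig),
    "design": ("design", design.DesignConfig),
    "bin": ("bin", binning.BinConfig),
    "annotate": ("annotate", ann.AnnotationConfig),
    "evaluate": ("evaluate", ev.EvalConfig),
}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run config; an empty/absent file yields all defaults
    (probe_length 120, k 25, marker 16 = 8 + 8, 3 mismatches, max_gap 5000,
    lg_fraction 0.75).  Unknown sections or fields raise ConfigError."""
    data: dict[str, Any] = {}
    if path is not None:
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    cfg = RunConfig()
    known_top = set(_SECTION_TYPES) | {"paths", "seed", "log_level", "assemble_command"}
    unknown = set(data) - known_top
    if unknown:
        raise ConfigError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    for section, (attr, cls) in _SECTION_TYPES.items():
        overrides = data.get(section) or {}
        if not isinstance(overrides, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(overrides) - valid
        if bad:
            raise ConfigError(
                f"unknown field(s) in {section!r}: {', '.join(sorted(bad))}")
        coerced = {
            k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
        }
        setattr(cfg, attr, cls(**{**_defaults(cls), **coerced}))
    if "seed" in data:
        cfg.seed = int(data["seed"])
    if "log_level" in data:
        cfg.log_level = str(data["log_level"])
    cfg.paths = dict(data.get("paths") or {})
    cfg.assemble_command = data.get("assemble_command")
    # the run seed propagates to the simulation stage unless it set its own
    if "simulate" not in data or "seed" not in (data.get("simulate") or {}):
        cfg.sim.seed = cfg.seed
    return cfg


def _defaults(cls) -> dict[str, Any]:
    out = {}
    for f in dataclasses.fields(cls):
        if f.default is not dataclasses.MISSING:
            out[f.name] = f.default
        elif f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
            out[f.name] = f.default_factory()  # type: ignore[misc]
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params(obj) -> dict[str, Any]:
    return {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(obj).items()}


def run(cfg: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the pipeline into ``out_dir``; returns the manifest dict.

    Haplotigs come from, in order of precedence: ``paths['haplotigs']``
    (pre-made FASTA), the external ``assemble_command`` hook, or the
    ground-truth fragmentation bypass (haplotypes cut mid-spacer)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    for key, p in cfg.paths.items():
        if not Path(p).exists():
            raise ConfigError(f"configured path {key!r} does not exist: {p}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": cfg.seed, "stages": {}}

    def record(stage: str, params: Mapping[str, Any], files: Mapping[str, Path]) -> None:
        manifest["stages"][stage] = {
            "parameters": dict(params),
            "outputs": {k: {"path": str(v), "sha256": _sha256(Path(v))}
                        for k, v in files.items()},
        }

    # -- simulate ----------------------------------------------------------
    truth = sim.simulate_diploid(cfg.sim)
    truth.reads = sim.simulate_reads(truth.haplotypes, cfg.sim)
    sim_paths = sim.write_truth(truth, out / "simulate")
    record("simulate", _params(cfg.sim), sim_paths)

    # -- design ------------------------------------------------------------
    refs = [
        design.MaskedReference(name, seq, list(truth.repeat_intervals[name]))
        for name, seq in truth.haplotypes.items()
    ]
    panel = design.design_panel(refs, cfg.design)
    ddir = out / "design"
    ddir.mkdir(exist_ok=True)
    design.write_panel(panel, ddir / "panel.fasta", ddir / "panel_hits.bed")
    gaps = design.coverage_gaps(panel, refs, cfg.design.probe_length)
    with open(ddir / "gap_report.tsv", "w") as fh:
        fh.write("ref_id\tmax_gap\tmean_gap\n")
        for rid, rep in gaps.items():
            fh.write(f"{rid}\t{rep.max_gap:.1f}\t{rep.mean_gap:.1f}\n")
    record("design", _params(cfg.design), {
        "panel": ddir / "panel.fasta",
        "hits": ddir / "panel_hits.bed",
        "gap_report": ddir / "gap_report.tsv",
    })

    # -- bin ---------------------------------------------------------------
    panel_index = binning.build_index(
        {p.probe_id: p.sequence for p in panel.probes}, cfg.bin)
    catalog = binning.derive_locus_catalog(truth.haplotypes, truth.features, cfg.bin)
    on, off = binning.classify_on_target(truth.reads, panel_index, cfg.bin)
    catalog_index = binning.build_index(catalog, cfg.bin)
    bins, unbinned = binning.bin_by_locus(on, catalog_index, cfg.bin)
    bdir = out / "bin"
    bin_paths = binning.write_bins(bins, on, off, unbinned, bdir)
    binning.write_catalog_tsv(catalog, bdir / "catalog.tsv")
    bin_paths["catalog"] = bdir / "catalog.tsv"
    record("bin", _params(cfg.bin), bin_paths)

    # -- haplotigs ---------------------------------------------------------
    adir = out / "assemble"
    adir.mkdir(exist_ok=True)
    tig_path = adir / "haplotigs.fasta"
    if "haplotigs" in cfg.paths:
        haplotigs = read_fasta(cfg.paths["haplotigs"])
        write_fasta(tig_path, haplotigs.items())
        source = "provided"
    elif cfg.assemble_command:
        cmd = cfg.assemble_command.format(bins=str(bdir), out=str(tig_path))
        log.info("running external assembler: %s", cmd)
        subprocess.run(shlex.split(cmd), check=True)
        haplotigs = read_fasta(tig_path)
        source = "external"
    else:
        haplotigs = {}
        for name, seq in truth.haplotypes.items():
            bps = sim.intergenic_breakpoints(truth.features[name])
            for i, piece in enumerate(sim.fragment_haplotigs(seq, bps)):
                haplotigs[f"{name}_tig{i:02d}"] = piece
        write_fasta(tig_path, haplotigs.items())
        source = "truth_fragmentation"
    record("assemble", {"source": source}, {"haplotigs": tig_path})

    # -- annotate ----------------------------------------------------------
    patterns = ann.learn_locus_patterns(
        truth.haplotypes, truth.features, panel, cfg.annotate)
    markers = ann.build_boundary_markers(
        truth.haplotypes, truth.features, cfg.annotate)
    features = ann.annotate(haplotigs, panel, patterns, markers, cfg.annotate)
    ndir = out / "annotate"
    ndir.mkdir(exist_ok=True)
    ann.write_patterns_tsv(patterns, ndir / "patterns.tsv")
    ann.write_markers_tsv(markers, ndir / "markers.tsv")
    ann.write_tbl(features, ndir / "features.tbl")
    ann.write_gff3(features, ndir / "features.gff3")
    record("annotate", _params(cfg.annotate), {
        "patterns": ndir / "patterns.tsv",
        "markers": ndir / "markers.tsv",
        "tbl": ndir / "features.tbl",
        "gff3": ndir / "features.gff3",
    })

    # -- evaluate ----------------------------------------------------------
    edir = out / "evaluate"
    edir.mkdir(exist_ok=True)
    if "alignments" in cfg.paths:
        records = ev.parse_alignments(cfg.paths["alignments"])
    else:
        records = ev.align_exact(haplotigs, truth.haplotypes)
        ev.write_paf(records, edir / "alignments.paf",
                     {n: len(s) for n, s in truth.haplotypes.items()})
    report = ev.evaluate(truth.haplotypes, records, cfg.evaluate)
    report.write_tsv(edir / "report.tsv")
    report.write_json(edir / "report.json")
    record("evaluate", _params(cfg.evaluate), {
        "report_tsv": edir / "report.tsv",
        "report_json": edir / "report.json",
    })

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["report"] = {
        "coverage_percent": report.coverage_percent,
        "concordance_percent": report.concordance_percent,
        "mean_lg": report.mean_lg,
    }
    return manifest
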