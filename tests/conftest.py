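"""Session-scoped fixtures: one simulated diploid cluster with its designed
panel, learned patterns and boundary markers, shared across test modules."""
from __future__ import annotations

import pytest

import haplocap as hc
from haplocap import annotation as ann
from haplocap import design as dg
from haplocap import simulate as sim


@pytest.fixture(scope="session")
def sim_cfg() -> hc.SimConfig:
    return hc.SimConfig(n_loci=4, depth=10.0, seed=3)


@pytest.fixture(scope="session")
def truth(sim_cfg) -> hc.SimTruth:
    return hc.simulate_diploid(sim_cfg)


@pytest.fixture(scope="session")
def refs(truth) -> list[dg.MaskedReference]:
    return [
        dg.MaskedReference(name, seq, list(truth.repeat_intervals[name]))
        for name, seq in truth.haplotypes.items()
    ]


@pytest.fixture(scope="session")
def panel(refs) -> dg.ProbePanel:
    return dg.design_panel(refs, dg.DesignConfig())


@pytest.fixture(scope="session")
def patterns(truth, panel) -> list[ann.LocusPattern]:
    return ann.learn_locus_patterns(truth.haplotypes, truth.features, panel)


@pytest.fixture(scope="session")
def markers(truth) -> list[ann.BoundaryMarker]:
    return ann.build_boundary_markers(truth.haplotypes, truth.features)


@pytest.fixture(scope="session")
def haplotigs(truth) -> tuple[dict[str, str], dict[str, int]]:
    """Error-free truth fragments cut mid-spacer, plus each fragment's
    offset on its source haplotype."""
    tigs: dict[str, str] = {}
    offsets: dict[str, int] = {}
    for name, seq in truth.haplotypes.items():
        bps = sim.intergenic_breakpoints(truth.features[name])
        off = 0
        for i, piece in enumerate(sim.fragment_haplotigs(seq, bps)):
            tid = f"{name}_tig{i:02d}"
            tigs[tid] = piece
            offsets[tid] = off
            off += len(piece)
    return tigs, offsets


@pytest.fixture(scope="session")
def reads(truth, sim_cfg) -> list[sim.SimRead]:
    return hc.simulate_reads(truth.haplotypes, sim_cfg)
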