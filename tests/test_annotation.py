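"""Annotation: probe signatures, orientation, pattern tokenization, boundary
markers (construction, mismatch escalation, exhaustive-scan oracle), allele
naming, and tbl/GFF3 round trips."""
from __future__ import annotations

import numpy as np
import pytest

from haplocap import annotation as ann
from haplocap import simulate as sim
from haplocap.sequtils import random_dna, revcomp

from oracles import naive_find

CFG = ann.AnnotationConfig()


# ---------------------------------------------------------------------------
# align_probes / orient_haplotig
# ---------------------------------------------------------------------------

def test_signature_of_constructed_haplotig():
    rng = np.random.default_rng(0)
    pa, pb = random_dna(rng, 120), random_dna(rng, 120)
    tig = pa + random_dna(rng, 1000) + pb
    sig = ann.align_probes({"A": pa, "B": pb}, tig, CFG)
    assert sig.labels == ["A", "B"]
    assert [h.strand for h in sig.hits] == ["+", "+"]


def test_signature_of_reverse_complement_is_mirrored():
    rng = np.random.default_rng(1)
    pa, pb = random_dna(rng, 120), random_dna(rng, 120)
    tig = pa + random_dna(rng, 500) + pb
    sig = ann.align_probes({"A": pa, "B": pb}, revcomp(tig), CFG)
    assert sig.labels == ["B", "A"]
    assert all(h.strand == "-" for h in sig.hits)


def test_signature_matches_naive_scan_oracle():
    """Probe occurrences on a long synthetic haplotig equal a pure-Python
    sliding-window Hamming scan."""
    rng = np.random.default_rng(2)
    tig = random_dna(rng, 50_000)
    probe = tig[10_000:10_120]
    # plant a 2-mismatch copy and a reverse-complement copy
    mutated = list(probe)
    mutated[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[5]]
    mutated[80] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[80]]
    tig = tig[:30_000] + "".join(mutated) + tig[30_120:40_000] + revcomp(probe) + tig[40_120:]
    sig = ann.align_probes({"P": probe}, tig, CFG)
    want = naive_find(tig, probe, CFG.probe_align_mismatches)
    assert [(h.pos, h.strand, h.mismatches) for h in sig.hits] == want


def test_orientation_all_forward_unchanged():
    rng = np.random.default_rng(3)
    p = random_dna(rng, 120)
    tig = p + random_dna(rng, 200) + p
    sig = ann.align_probes({"P": p}, tig, CFG)
    seq2, sig2, flipped = ann.orient_haplotig(tig, sig, {"P": p}, CFG)
    assert seq2 == tig and not flipped


def test_orientation_flips_majority_reverse_and_is_involutive():
    rng = np.random.default_rng(4)
    p = random_dna(rng, 120)
    fwd = p + random_dna(rng, 200) + p
    rev = revcomp(fwd)
    sig = ann.align_probes({"P": p}, rev, CFG)
    seq2, sig2, flipped = ann.orient_haplotig(rev, sig, {"P": p}, CFG)
    assert flipped and seq2 == fwd
    assert all(h.strand == "+" for h in sig2.hits)
    # orienting the already-canonical output changes nothing
    seq3, _sig3, flipped3 = ann.orient_haplotig(seq2, sig2, {"P": p}, CFG)
    assert not flipped3 and seq3 == fwd


# ---------------------------------------------------------------------------
# segment_loci
# ---------------------------------------------------------------------------

def _sig(labels, spacing=1000, probe_len=120):
    hits = [ann.ProbeHit(lab, "+", i * spacing, 0) for i, lab in enumerate(labels)]
    return ann.ProbeSignature("t", hits)


def test_single_full_pattern_spans_haplotig():
    pat = ann.LocusPattern("L", ("a", "b", "c"))
    sig = _sig(["a", "b", "c"])
    segments, unmatched = ann.segment_loci(sig, [pat], 5000, 120)
    assert len(segments) == 1 and unmatched == []
    assert segments[0].window == (0, 5000)
    assert segments[0].candidates == ("L",)


def test_repeated_pattern_with_optional_label_absent_in_middle_copy():
    """Three copies of a locus pattern tokenize into three features even
    when the optional label is missing from the middle copy."""
    pat = ann.LocusPattern("L", ("a", "b", "c"), optional=frozenset({1}))
    sig = _sig(["a", "b", "c", "a", "c", "a", "b", "c"])
    segments, unmatched = ann.segment_loci(sig, [pat], 9000, 120)
    assert [s.candidates for s in segments] == [("L",)] * 3
    assert unmatched == []


def test_unmatched_probe_runs_reported_not_raised():
    pat = ann.LocusPattern("L", ("a", "b"))
    sig = _sig(["x", "a", "b", "y"])
    segments, unmatched = ann.segment_loci(sig, [pat], 5000, 120)
    assert len(segments) == 1
    assert len(unmatched) == 2


def test_longest_pattern_wins_tokenization():
    short = ann.LocusPattern("S", ("a", "b"))
    long_ = ann.LocusPattern("L", ("a", "b", "c"))
    sig = _sig(["a", "b", "c"])
    segments, _ = ann.segment_loci(sig, [short, long_], 5000, 120)
    assert segments[0].candidates == ("L",)


def test_recovered_locus_order_equals_truth_over_seeds(truth, panel, patterns):
    from haplocap import design as dg

    for seed in range(3):  # further seeds exercised by the pipeline suite
        cfg = sim.SimConfig(n_loci=4, seed=seed + 50)
        t = sim.simulate_diploid(cfg)
        refs = [dg.MaskedReference(n, s, list(t.repeat_intervals[n]))
                for n, s in t.haplotypes.items()]
        pan = dg.design_panel(refs)
        pats = ann.learn_locus_patterns(t.haplotypes, t.features, pan)
        markers = ann.build_boundary_markers(t.haplotypes, t.features)
        for name, seq in t.haplotypes.items():
            feats = ann.annotate({name: seq}, pan, pats, markers, CFG)
            got = [f.locus_name for f in feats if f.locus_name != sim.HOTSPOT]
            want = [f.locus_name for f in t.features[name]
                    if f.locus_name != sim.HOTSPOT]
            assert got == want


# ---------------------------------------------------------------------------
# boundary markers
# ---------------------------------------------------------------------------

def _manual_reference():
    """Hand-built annotated reference whose exon2|intron2 junction is the
    KIR2DL4-style worked example ACACGTGG + GTGAGTCC."""
    rng = np.random.default_rng(7)
    utr5, exon1, intron1 = random_dna(rng, 60), random_dna(rng, 50), random_dna(rng, 70)
    exon2 = random_dna(rng, 42) + "ACACGTGG"
    intron2 = "GTGAGTCC" + random_dna(rng, 62)
    exon3, utr3 = random_dna(rng, 50), random_dna(rng, 60)
    parts = [utr5, exon1, intron1, exon2, intron2, exon3, utr3]
    labels = ["utr5", "exon1", "intron1", "exon2", "intron2", "exon3", "utr3"]
    flank_l, flank_r = random_dna(rng, 40), random_dna(rng, 40)
    seq = flank_l + "".join(parts) + flank_r
    elements, pos = [], len(flank_l)
    for lab, part in zip(labels, parts):
        elements.append((lab, (pos, pos + len(part))))
        pos += len(part)
    feat = ann.FeatureAnnotation("ref", "GENEX", (len(flank_l), pos), "+", tuple(elements))
    return seq, feat


def test_marker_construction_worked_example():
    seq, feat = _manual_reference()
    markers = ann.build_boundary_markers({"ref": seq}, {"ref": [feat]}, CFG)
    m = next(m for m in markers if m.left_element == "exon2" and m.right_element == "intron2")
    assert m.marker == "ACACGTGGGTGAGTCC"
    assert m.left_half == "ACACGTGG" and m.right_half == "GTGAGTCC"


def test_all_markers_are_sixteen_bases_of_two_halves(markers):
    for m in markers:
        assert len(m.marker) == 16
        assert m.left_half + m.right_half == m.marker
        assert len(m.left_half) == len(m.right_half) == 8


def test_short_element_marker_skipped():
    rng = np.random.default_rng(8)
    seq = random_dna(rng, 300)
    elements = (("exon1", (50, 55)), ("intron1", (55, 150)))  # exon1 < 8 bases
    feat = ann.FeatureAnnotation("r", "L", (50, 150), "+", elements)
    markers = ann.build_boundary_markers({"r": seq}, {"r": [feat]}, CFG)
    keys = {(m.left_element, m.right_element) for m in markers}
    assert ("exon1", "intron1") not in keys
    assert ("intron1", ann.DOWNSTREAM) in keys


def test_self_annotation_recovers_every_truth_junction(truth, markers):
    """Scanning each reference feature with its own markers reproduces the
    truth junction coordinates exactly."""
    for name, seq in truth.haplotypes.items():
        for feat in truth.features[name]:
            fs, fe = feat.interval
            window = seq[max(fs - 60, 0): fe + 60]
            offset = max(fs - 60, 0)
            calls, inconsistent = ann.scan_boundaries(
                window, ann.markers_for_locus(markers, feat.locus_name), CFG)
            assert not inconsistent
            truth_bounds = [feat.elements[0][1][0]] + [iv[1] for _lab, iv in feat.elements]
            got = [offset + c.pos for c in calls if c.pos is not None]
            assert got == truth_bounds


# ---------------------------------------------------------------------------
# scan_boundaries: mismatch escalation
# ---------------------------------------------------------------------------

def _feature_with_marker():
    rng = np.random.default_rng(9)
    left = random_dna(rng, 400)
    right = random_dna(rng, 400)
    marker = ann.BoundaryMarker("ACACGTGGGTGAGTCC", "exon2", "intron2", "L", 0)
    seq = left + marker.marker + right
    return seq, marker, len(left) + 8  # junction position


def _mutated_site(seq, site_start, k, rng):
    arr = list(seq)
    positions = rng.choice(16, size=k, replace=False)
    for p in positions:
        arr[site_start + p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[site_start + p]]
    return "".join(arr)


@pytest.mark.parametrize("k,found", [(0, True), (1, True), (2, True), (3, True), (4, False)])
def test_junction_recovered_up_to_three_mismatches(k, found):
    seq, marker, junction = _feature_with_marker()
    rng = np.random.default_rng(10 + k)
    mutated = _mutated_site(seq, junction - 8, k, rng)
    calls, _ = ann.scan_boundaries(mutated, [marker], CFG)
    assert len(calls) == 1
    if found:
        assert calls[0].pos == junction and calls[0].mismatches == k
    else:
        assert calls[0].pos is None


def test_escalation_is_minimal():
    """A junction present exactly is reported at threshold 0 even though
    higher thresholds would also find it."""
    seq, marker, junction = _feature_with_marker()
    calls, _ = ann.scan_boundaries(seq, [marker], CFG)
    assert calls[0].mismatches == 0


def test_recovered_junctions_monotone_in_threshold(truth, markers):
    """Junction sets found at threshold t are subsets of those at t+1."""
    name = next(iter(truth.haplotypes))
    feat = truth.features[name][0]
    fs, fe = feat.interval
    window = truth.haplotypes[name][fs - 60: fe + 60]
    rng = np.random.default_rng(11)
    mutated = _mutated_site(window, 200, 2, rng)  # perturb inside the feature
    found_prev: set[int] = set()
    for t in range(4):
        cfg = ann.AnnotationConfig(max_marker_mismatches=t)
        calls, _ = ann.scan_boundaries(
            mutated, ann.markers_for_locus(markers, feat.locus_name), cfg)
        found = {c.index for c in calls if c.pos is not None}
        assert found_prev <= found
        found_prev = found


def test_scan_positions_equal_exhaustive_window_oracle():
    """Accepted junction positions match a brute-force scan enumerating all
    16-base windows and their Hamming distances."""
    seq, marker, junction = _feature_with_marker()
    rng = np.random.default_rng(12)
    mutated = _mutated_site(seq, junction - 8, 2, rng)
    calls, _ = ann.scan_boundaries(mutated, [marker], CFG)
    # oracle: lowest threshold with any hit, leftmost position
    for t in range(4):
        hits = [pos + 8 for pos, _s, _mm in naive_find(mutated, marker.marker, t, both_strands=False)]
        if hits:
            assert calls[0].pos == min(hits) and calls[0].mismatches == t
            break


# ---------------------------------------------------------------------------
# annotate composition
# ---------------------------------------------------------------------------

def test_error_free_haplotigs_annotate_to_exact_truth(truth, panel, patterns, markers, haplotigs):
    tigs, offsets = haplotigs
    feats = ann.annotate(tigs, panel, patterns, markers, CFG)
    got = sorted(
        (f.locus_name, tuple((lab, (s + offsets[f.haplotig_id], e + offsets[f.haplotig_id]))
                             for lab, (s, e) in f.elements))
        for f in feats if f.locus_name != sim.HOTSPOT
    )
    want = sorted(
        (tf.locus_name, tuple(tf.elements))
        for name in truth.haplotypes for tf in truth.features[name]
        if tf.locus_name != sim.HOTSPOT
    )
    assert got == want
    assert all(f.complete for f in feats)


def test_empty_haplotig_set_yields_empty_annotation(panel, patterns, markers):
    assert ann.annotate({}, panel, patterns, markers, CFG) == []


def test_reverse_complement_haplotig_annotates_as_mirror(panel, patterns, markers, haplotigs):
    tigs, _ = haplotigs
    tid = next(t for t in tigs if "tig00" in t)
    fwd = ann.annotate({tid: tigs[tid]}, panel, patterns, markers, CFG)
    rev = ann.annotate({tid: revcomp(tigs[tid])}, panel, patterns, markers, CFG)
    L = len(tigs[tid])
    assert len(fwd) == len(rev) >= 1
    for f, r in zip(fwd, rev):
        assert r.locus_name == f.locus_name
        assert r.strand == ("-" if f.strand == "+" else "+")
        assert r.interval == (L - f.interval[1], L - f.interval[0])
        mirrored = tuple(
            (lab, (L - e, L - s)) for lab, (s, e) in reversed(f.elements)
        )
        assert r.elements == mirrored


# ---------------------------------------------------------------------------
# allele naming
# ---------------------------------------------------------------------------

def _named_fixture(truth, panel, patterns, markers):
    name = next(iter(truth.haplotypes))
    seq = truth.haplotypes[name]
    feats = ann.annotate({name: seq}, panel, patterns, markers, CFG)
    gene_feats = [f for f in feats if f.locus_name != sim.HOTSPOT]
    return name, seq, gene_feats


def test_exact_library_match_gets_that_name(truth, panel, patterns, markers):
    name, seq, feats = _named_fixture(truth, panel, patterns, markers)
    feat = feats[0]
    lib = {f"{feat.locus_name}*001": seq[feat.interval[0]: feat.interval[1]]}
    named = ann.name_alleles([feat], lib, {name: seq}, markers, CFG)
    assert named[0].allele_name == f"{feat.locus_name}*001"
    assert named[0].allele_level == "full"


def test_intronic_substitution_demotes_to_cdna_match(truth, panel, patterns, markers):
    name, seq, feats = _named_fixture(truth, panel, patterns, markers)
    feat = feats[0]
    allele = seq[feat.interval[0]: feat.interval[1]]
    intron = next(iv for lab, iv in feat.elements if lab.startswith("intron"))
    off = intron[0] - feat.interval[0] + 30
    perturbed = allele[:off] + {"A": "C", "C": "G", "G": "T", "T": "A"}[allele[off]] + allele[off + 1:]
    lib = {f"{feat.locus_name}*001": perturbed}
    named = ann.name_alleles([feat], lib, {name: seq}, markers, CFG)
    assert named[0].allele_name == f"{feat.locus_name}*001"
    assert named[0].allele_level == "cdna"


def test_empty_library_names_everything_new(truth, panel, patterns, markers):
    name, seq, feats = _named_fixture(truth, panel, patterns, markers)
    other = {"OTHERLOCUS*001": "ACGT" * 100}
    named = ann.name_alleles(feats, other, {name: seq}, markers, CFG)
    assert all(f.allele_name is None for f in named)  # locus absent -> unnamed
    named2 = ann.name_alleles(
        feats, {f"{feats[0].locus_name}*009": "ACGT" * 100}, {name: seq}, markers, CFG)
    assert named2[0].allele_name == "NEW"


# ---------------------------------------------------------------------------
# tbl / GFF3 output
# ---------------------------------------------------------------------------

def test_tbl_round_trip_and_coordinate_convention(tmp_path, truth, panel, patterns, markers, haplotigs):
    tigs, _ = haplotigs
    feats = ann.annotate(tigs, panel, patterns, markers, CFG)
    path = tmp_path / "features.tbl"
    ann.write_tbl(feats, path)
    back = ann.read_tbl(path)
    key = lambda f: (f.haplotig_id, f.interval)
    for f, g in zip(sorted(feats, key=key), sorted(back, key=key)):
        assert (g.haplotig_id, g.locus_name, g.interval, g.strand) == \
               (f.haplotig_id, f.locus_name, f.interval, f.strand)
        assert g.elements == f.elements
    # a 0-based half-open interval [10, 20) prints as 11..20
    one = ann.FeatureAnnotation("t", "L", (10, 20), "+", (("exon1", (10, 20)),))
    ann.write_tbl([one], path)
    text = path.read_text()
    assert "11\t20\tgene" in text and "11\t20\texon" in text


def test_gff3_round_trip_and_third_party_parse(tmp_path, truth, panel, patterns, markers, haplotigs):
    import gffutils

    tigs, _ = haplotigs
    feats = ann.annotate(tigs, panel, patterns, markers, CFG)
    path = tmp_path / "features.gff3"
    ann.write_gff3(feats, path)
    back = ann.read_gff3(path)
    key = lambda f: (f.haplotig_id, f.interval)
    for f, g in zip(sorted(feats, key=key), sorted(back, key=key)):
        assert (g.haplotig_id, g.locus_name, g.interval, g.strand) == \
               (f.haplotig_id, f.locus_name, f.interval, f.strand)
        assert g.elements == f.elements
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    genes = list(db.features_of_type("gene"))
    assert len(genes) == len(feats)
    for g in genes:
        assert len(list(db.children(g))) >= 1


def test_patterns_and_markers_tsv_round_trip(tmp_path, patterns, markers):
    pp, mp = tmp_path / "patterns.tsv", tmp_path / "markers.tsv"
    ann.write_patterns_tsv(patterns, pp)
    ann.write_markers_tsv(markers, mp)
    assert ann.read_patterns_tsv(pp) == patterns
    assert ann.read_markers_tsv(mp) == markers
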