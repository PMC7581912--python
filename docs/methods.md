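# Methods

## The problem

Gene clusters such as the human KIR locus consist of a dozen or so loci
that arose by tandem duplication: any two genes are 85–98% identical,
conserved stretches alternate with variable (largely exonic) ones, repeat
elements are dense, and haplotypes differ structurally (gene presence,
copy number, order) as well as allelically. Short reads cannot be placed
uniquely, and whole-genome assemblers collapse or drop the region. The
workflow modeled here instead captures 2–8 kb fragments with a small probe
panel that deliberately targets the *conserved* blocks — so one probe pulls
down fragments from every homologous locus — sequences them with accurate
long reads, bins the reads per locus, assembles each bin, and annotates the
resulting haplotigs.

This package implements every computational stage of that workflow plus a
simulator that reproduces the statistical structure the method relies on.
Wet-lab capture, error correction and the assembler itself are external:
the workflow runner exposes an assembler hook and otherwise accepts
pre-made haplotigs (or, for testing, cuts the simulated truth haplotypes
between loci).

## Probe design

Candidates are all `probe_length` (default 120) windows tiled at `stride`
(default: non-overlapping) from position 0 of each repeat-masked reference,
discarding windows that touch a masked base (a single base of overlap
disqualifies) or a non-ACGT base. A terminal, end-flush window is added
only when the reference end would otherwise lie more than `max_gap/2`
beyond the last tiled window; this keeps windows unragged without leaving a
systematically uncovered tail.

Each candidate is scored by its total hit count over all references, both
strands, at `allow_mismatches` substitutions (default 0 — design-time hits
are exact), with hits inside masks discarded. Selection is greedy in
descending hit count (ties: probe sequence lexicographically, then first
hit position), and stops when on every reference the largest gap between
consecutive hit *midpoints* — including the distances from each reference
end to the nearest midpoint — is strictly below `max_gap` (default 5000,
the expected mean captured-fragment length of ~4–5 kb). A reference shorter
than `max_gap` is satisfied by zero probes, so an empty panel is a valid
design. If candidates run out first, the panel is returned flagged
unsatisfied together with the residual gap intervals.

Greedy-by-hit-count is the selection rule of record; on small instances an
exhaustive search gives the optimal panel size as a lower bound in the test
suite, documenting (not "fixing") the greedy gap. The design criterion is a
coverage property, not optimality.

## Read binning

Matching is canonical-k-mer exact matching with k = 25: every length-k
window of every probe is indexed under min(kmer, revcomp(kmer)), and a
sequence matches when it shares at least `min_shared_kmers` (default 1 —
any hit counts) k-mers with the index. On/off-target classification uses
the capture-probe panel; per-locus binning uses a locus catalog and assigns
a read to *every* locus above threshold. Multi-assignment is deliberate:
bins are assembled independently downstream, duplication across bins is
harmless, and junction-spanning reads carry the phasing evidence.

The locus catalog is derived from annotated reference haplotypes: the
canonical k-mers of each locus's occurrences, minus any k-mer seen in more
than one locus. A pre-computed catalog can be supplied as TSV or FASTA
instead.

## Annotation

Stage order: align probes → orient → segment → scan boundaries.

* **Probe signatures.** Every panel probe is aligned to the haplotig on
  both strands with up to `probe_align_mismatches` (default 3 over 120
  bases) substitutions — assembled sequence carries real allelic variation,
  so exact matching would drop sites.
* **Orientation.** If the majority of probe hits are on the reverse strand
  the haplotig is reverse-complemented for processing; reported coordinates
  are mapped back to the input orientation (a feature on a flipped haplotig
  gets strand `-` and mirrored intervals).
* **Segmentation.** The probe-label sequence is tokenized greedily left to
  right by the longest-matching locus pattern. Patterns are learned from
  annotated references: the label sequence of probe hits inside each truth
  occurrence, with labels missing from some occurrence flagged optional
  (a probe site destroyed by variation leaves the rest of the pattern
  recognisable). Token windows extend to the midpoints between adjacent
  tokens' flanking hits, or to the haplotig ends. When homologous loci
  share an identical pattern — the expected situation when the panel
  contains only family-wide conserved probes — the candidate locus is
  resolved by the boundary markers themselves: the locus whose junction set
  is recovered best (most junctions, fewest mismatches) wins. This keeps
  locus identity within the annotation stage rather than requiring the
  k-mer catalog.
* **Boundary markers.** For each junction in a locus's element chain
  (upstream|e₀, e₀|e₁, …, e_last|downstream) the marker is the
  `half_length` (8) bases ending the left element plus the 8 bases starting
  the right one. Markers for elements shorter than 8 bases, or junctions
  too close to the reference ends, are skipped with a warning; a marker
  string occurring at two junctions of the same locus is flagged ambiguous.
  Treating the locus start and end as junctions against flanking context
  makes the first and last elements (the UTRs) carry their own markers.
* **Scanning.** Junctions are visited in element order. Each is searched at
  0 mismatches first, escalating one at a time to `max_marker_mismatches`
  (default 3) only if nothing was found — minimal escalation. The junction
  coordinate is marker start + 8. Among hits at the accepted threshold the
  leftmost position strictly after the previous junction wins; a junction
  with hits but none compatible with the element order flags the feature
  inconsistent, and unresolved junctions leave a partial annotation rather
  than an error.
* **Allele naming.** A feature whose full sequence equals a library entry
  (`locus*allele` ids) takes that name at full resolution; otherwise an
  exact match of spliced exon sequence gives the name at cDNA resolution;
  otherwise `NEW`. Library alleles are themselves spliced by scanning the
  locus markers; a bare allele sequence has no flanking context, so the
  terminal junctions fall back to the sequence ends.

Internally all coordinates are 0-based half-open; .tbl and GFF3 output are
1-based inclusive (reverse strand in .tbl encoded as start > end, per the
feature-table convention). Both writers have bundled parsers and round-trip
losslessly.

## Evaluation

* coverage% = 100 · |union of alignment target intervals| / reference
  length — overlapping haplotig alignments are unioned, never double
  counted.
* concordance% = 100 · Σ matches / Σ aligned columns, pooled over records.
  The denominator includes gap columns, so indels are penalized; this is a
  documented choice, the upstream definition being verbal only.
* LG(f): haplotigs ranked by total aligned reference span (configurable to
  raw length), descending, ties by id; the count at which the cumulative
  interval union first reaches f·L, or undefined if never. Span-ordering
  makes the metric alignment-aware.

Matches are taken from the format's native fields: PAF column 10/11, SAM
=/X CIGAR operations when present, else M minus the substitution part of
NM. A bundled exact-substring aligner serves error-free fixtures only;
real haplotigs need a real aligner (any PAF/SAM producer).

## The simulator

What it emulates — the properties the method exploits:

* a family of gene templates built from alternating conserved and variable
  blocks (~3.1 kb per gene: 5'UTR, 3 exons, 2 introns, 3'UTR). Conserved
  blocks descend from shared ancestors and diverge at a tenth of the
  per-template rate; variable (exon) blocks diverge at the full rate drawn
  uniformly from `identity_range` (default 0.85–0.98). Template sizes are
  scaled down from real 10–16 kb genes to keep default runs at desk scale;
  the geometry, not the absolute size, carries the structure;
* one intergenic "hotspot" template: conserved L1-like filler around three
  Alu-like repeats, two in opposite orientations — the recombination
  substrate. Repeat blocks become the repeat-mask intervals. The hotspot
  has no exons (it is an intergenic element), so gene-level invariants
  (≥2 exons separated by introns) apply to gene templates only;
* diploid haplotypes as ordered locus concatenations with random
  intergenic spacers (400–800 bp), per-copy allelic substitutions
  (`allelic_rate` 0.002 in variable blocks, a tenth elsewhere), and
  structurally distinct default haplotype pairs (one deletes a gene and
  duplicates another — the A/B-family situation);
* reads from fragments uniform in `fragment_len_range` (default 2000–8000),
  i.i.d. substitution errors at `error_rate` (default 0.001 — accurate
  consensus reads; indels are not modeled), mean coverage `depth`.
  Reads are emitted in the forward orientation of their origin so that at
  error rate 0 every read is an exact substring of its origin; strand
  symmetry of the binning stage is exercised separately by
  reverse-complementing reads in tests.

What it does not emulate: PCR dropout in repeat-rich stretches (the
poly-AT gap seen in real data), indel errors, chimeric fragments, coverage
bias, fosmid libraries. Passing tests therefore demonstrate correctness of
the computational stages under the model's assumptions, not robustness to
those artifacts; real data additionally needs error correction and a real
assembler upstream.

Everything is seeded through numpy Generators and byte-identical across
re-runs with the same configuration.

## Numerical and degenerate-input choices

* Gap arithmetic uses float midpoints (pos + probe_length/2); the stopping
  comparison is strict (`< max_gap`).
* Tie-breaks are deterministic everywhere: probe selection (hit count desc,
  sequence, first hit), LG ranking (span desc, query id), marker hits
  (leftmost order-consistent), pattern tokenization (longest match).
* A strand tie in haplotig orientation keeps the input orientation with a
  warning.
* Empty inputs: empty read set → empty partition; empty panel → whole-
  reference gap; empty haplotig set → empty annotation; concordance of an
  empty record set is reported as missing (None), never 0; LG is undefined
  (None) when the fraction is unreachable.
* Palindromic patterns are reported once (forward strand) by the scanner.

## Default parameters

| parameter | default | unit | role |
|---|---|---|---|
| probe_length | 120 | bases | capture probe length |
| stride | probe_length | bases | candidate tiling step |
| max_gap | 5000 | bases | coverage criterion (~ mean captured fragment) |
| k | 25 | bases | binning k-mer |
| min_shared_kmers | 1 | count | any-hit matching |
| marker_length / half_length | 16 / 8 | bases | boundary marker anatomy |
| max_marker_mismatches | 3 | count | boundary scan tolerance ceiling |
| probe_align_mismatches | 3 | count | probe-to-haplotig budget |
| lg_fraction | 0.75 | fraction | LG75 |
| fragment_len_range | 2000–8000 | bases | simulated fragment window |
| error_rate | 0.001 | /base | read substitution rate |
| identity_range | 0.85–0.98 | fraction | inter-locus identity window |

## Known limitations

* Pattern learning assumes consistent probe order across occurrences of a
  locus (true for duplication-derived clusters; rearranged fusion alleles
  would need dedicated patterns).
* Allele naming is exact-match only at both resolutions; nearest-allele
  reporting and fusion breakpoint calling are out of scope.
* The bundled exact aligner cannot score diverged haplotigs; evaluation of
  real assemblies relies on external PAF/SAM.
* The locus catalog requires annotated references; without them binning
  stops at the on/off-target split.
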