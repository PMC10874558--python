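# Methods

## The amplicon model

The edited locus is represented as `left_flank + insert + right_flank`,
with the double-strand break at the flank boundary (1-based inclusive
coordinates throughout). The defaults model a second-round nested PCR
product with 146 bp of retained genomic sequence left of the cut and
186 bp right of it, giving a 332 bp insert-free (background) amplicon.
The donor contributes two insertable fragments: the expression cassette
`F` (5,526 bp, carrying an 85 bp left homology arm that duplicates the
inner edge of the left flank and a zero-length right arm) and the
plasmid backbone `B` (2,174 bp). These lengths are fixed by the single-
insert product sizes (2,506 and 5,858 bp) minus the background; the
category enumerator then predicts all nine one-to-three-piece products
exactly (e.g. `BF` 8,032 bp, `FFF` 16,910 bp).

Assumptions: insertion is modeled as concatenation at the cut (no
junction microhomology modeling); multi-piece chains concatenate
without linkers; PCR length bias is not modeled (the tool reports read
proportions, not molecule proportions).

## Probe design and read classification

Exact 17-mers tolerate indel-dominated noise statistically: one 17-mer
survives 5% per-base error with probability 0.95¹⁷ ≈ 0.42, and a probe
is useless the moment one base inside it is wrong, so sets of probes
tiled across a source are the unit of evidence. Probe parameters:

| probe set | k | spacing | count | purpose |
|---|---|---|---|---|
| BCseq (per barcode) | 11 | 1 | 7 | demultiplexing |
| flank probes | 17 | 20 | 7 left / 9 right | anchoring, denominator |
| component probes | 17 | even | 20 per fragment & orientation | content calling |
| Cas9-plasmid probes | 17 | 100 | source/100 | plasmid-remnant scan |
| U6-plasmid probes | 17 | 40 | source/40 | plasmid-remnant scan |

All component and plasmid probe sets are screened at build time to be
unique against every other reference in the run configuration (both
strands); this removes, for example, cassette probes falling inside the
homology arm, which is shared with the genomic flank and would
otherwise match every read.

A component-orientation is *present* when at least `min_hits = 1` of
its probes match exactly inside the category's restricted range (the
perfect insert span moved 300 bp inward per side; for the single-
backbone category this is positions 447–2020 of a 2,506 bp product).
A single exact 17-mer is decisive evidence because its chance-match
probability is 4⁻¹⁷ per position after uniqueness screening; requiring
more hits was measured to discard ~3% of genuine single-backbone reads
at 5% error, since only ~14 of the 20 backbone probes lie inside the
restricted range.

Candidate categories are those whose length window contains the
anchored amplicon length (read length minus the barcode/primer offset
found by the leftmost left-flank probe hit). A candidate is *consistent*
when the set of components present in its restricted range equals its
composition — scanning all components, not only the candidate's,
resolves overlapping windows (a cassette+backbone read falling in the
triple-backbone window is rejected there because cassette probes are
present). Exactly one consistent candidate yields a call; several yield
`ambiguous` (never double-counted); none routes the read onward: to the
foreign scan if it is longer than the background window (or carries an
insert estimate ≥50 bp inside it), to deletion analysis if shorter.

The ordered orientation chain is reconstructed by scoring every ordered
arrangement × orientation assignment of the composition: each chain
defines fragment slots by cumulative lengths, and the chain maximizing
the number of in-slot probe hits of the matching component-orientation
wins (slot tolerance 150 bp; score ties are reported `ambiguous`). At
5% balanced-indel noise, positional drift over a 10 kb read has a
standard deviation near 20 bp, well inside the tolerance.

## Grouping windows

Windows are ±20% of the expected *product* length with the half-width
rounded to the nearest 100 bp, reproducing the published single-
backbone example (2,506 → 2,006–3,006 bp). An exact (unrounded) rule is
available in configuration. Note the alternative anchoring of the 20%
on the *insert* length does not reproduce that worked example, which is
why the product-length rule is the default.

## Demultiplexing

A read is assigned to the barcode whose BCseqs match most often within
the first 200 bp of the read or of its reverse complement (barcodes sit
at read starts; bounding the search avoids chance internal hits). Ties
or zero hits fall back to bounded edit-distance placement of the 17-nt
barcode+prefix tag (edlib infix, ≤3 edits, winner must lead the
runner-up by ≥1 edit). The fallback exists because a *central* single
edit (positions 7–11 of the tag) lies inside all seven 11-mer windows
and destroys every exact probe; with barcodes generated at pairwise tag
distance ≥5, every single-base corruption still assigns correctly, and
assignment accuracy at 5% read error is ≥99%. Assigned reads are
re-oriented to the forward amplicon strand.

## Repair genotyping

For forward single-donor insertions, the left/right homology arms are
placed in the read by best edit-distance infix alignment within a
junction window (arm length + 200 bp each side of the expected
junction), accepting placements with identity ≥80% (identity = matching
columns / all alignment columns). Distinct copies are found by
iterative masking; copies may be adjacent — a blunt end-joining
junction produces exactly two abutting arm copies — but may overlap an
accepted copy by at most 10% of the arm length, so one noisy alignment
cannot split into two copies. Any evaluable arm with ≥2 copies ⇒ NHEJ;
all evaluable arms at exactly 1 copy ⇒ HDR; otherwise Other (including
the not-evaluable case of zero-length arms on both sides).

## Foreign-insert annotation

The insert is the read subsequence strictly between the inner flank
edges (rightmost matched base of the left flank, leftmost matched base
of the right flank, located by infix alignment). It is annotated by
seed-and-extend local alignment against the reference panel (donor
fragments, editing-plasmid unique regions, mini-genome contigs, LINE-1
consensus; 15-mer seeds on both strands, diagonal banding, bounded
glocal refinement). Segment trimming maximizes an alignment-column
score (match +1, mismatch/gap −2) and anchors both ends on a run of ≥8
consecutive matches, so isolated chance matches beyond a junction
cannot extend a segment (a chance 8-run has probability 4⁻⁸). Reported
segments need ≥50 matched bp and ≥80% identity; genomic hits inside the
exclusion regions (supplied as standard 0-based half-open BED) are
discarded; overlapping candidates from different sources are resolved
by identity, then length — so the highest-identity chromosome wins for
homologous sources. Donor-class segments below 80% of the full fragment
length are labelled degraded (`short-F`/`short-B`); the dedicated
degraded-donor screen additionally applies the read-length gates
(backbone k-mers in reads <2 kb with insert <1,700 bp; cassette k-mers
in reads <5 kb with insert <4,400 bp).

Known identifiability limit: a compound insert led by a near-window-
sized degraded donor piece (e.g. backbone piece + genomic fragment
totalling a single-backbone-window length) satisfies the length+content
rule of the donor category and is grouped there; this is inherent to
length-plus-probe classification, and the foreign scan only sees reads
the donor grouping could not explain.

## Deletion metrics

Insert-free reads (background window, or shorter) are aligned glocally
to the wild-type amplicon; deletion runs separated by ≤10 matched bases
are merged into clusters whose *size* is the total deleted bases — an
edit-distance-optimal alignment interrupts one biological deletion with
coincidental single-base matches, inflating the spanned interval but
never the deleted-base count. The deletion index is `(R − mean depth)/R`
with `R` the anchored read count; "read depth" is interpreted as the
anchored read count because the expected depth of a gap-free pile-up is
flat at `R`, which gives the closed form that a uniform fractional
deletion `f` yields index exactly `f`. D100 counts reads whose largest
deletion cluster overlapping the cut (±50 bp window) exceeds 100 bp.
Gap structure can equally be ingested from coordinate-sorted SAM
records; both paths agree on noise-free input.

## The simulator

`simulate_dataset` draws each read's class from an explicit mixture
(donor chains in `Bf`/`Ff+Br` notation, `background`, `deletion`,
`decoy`, and foreign tokens joinable into compound chains), assembles
`barcode + primer + left flank + insert + right flank`, flips the
strand with probability 0.5, and applies independent per-base errors:
5% total by default, 70% of them indels split evenly between 1-bp
insertions and deletions, the rest substitutions — an indel-dominated
profile typical of nanopore chemistry. HDR is modeled on forward
single-donor insertions (default fraction 0.5, within the 40–60% range
observed for this design) by removing the duplicated arm copies;
NHEJ is plain concatenation, which duplicates the arm. Degraded donor
fragments keep a uniform-length single-ended piece; pieces inside
compound foreign chains are capped at half the fragment length,
matching the observed predominance of sub-half-length degraded inserts.
Foreign length models: genomic segments mostly 60–400 bp with a 3% tail
to 3 kb; LINE-1 fragments are 3′-anchored truncations up to 1,505 bp;
Cas9-plasmid remnants either <500 bp or ~3 kb; U6-plasmid remnants
centred on 300 bp. Cut-spanning deletions (default 101–400 bp; sizes
are clamped for the short amplicon) leave ≥60 bp of each flank so the
read remains anchorable. Reads are byte-deterministic under the seed
(numpy PCG64 generator).

All references are generated random DNA at the printed lengths; the
LINE-1 record is a synthetic stand-in consensus, and the mini-genome is
five contigs of 6–8 kb, one of which embeds a copy of the amplicon
covered by an exclusion region (emulating the locus homolog that must
be filtered). What the simulator does **not** emulate — homopolymer-
biased nanopore errors, chimeric reads, PCR length bias against long
products, microhomology at junctions, real genome repeat structure —
bounds what passing tests show about real data: recovery results
demonstrate correctness of the classification logic under the stated
noise model, not performance on a real flow cell.

## Problem sizes used in the test suite

Mixture recovery uses 10,000 reads at 5% error (shares recovered within
3 binomial SE); oracle equivalence uses 2,000 error-free reads covering
every class; HDR recovery uses 1,500 reads per seeded fraction; D100
recovery uses 10,000 reads on the long deletion-assay amplicon
(2,669 + 2,217 bp flanks) with 1.5% seeded large deletions; the
exhaustive demultiplexer check covers all 544 single-edit variants of
four barcodes. `scripts/acceptance.py` re-runs the exact arithmetic and
the 10,000-read share recovery from scratch under a user seed.

## Limitations

Junction breakpoints are resolved only to probe spacing, not to the
base; HDR calling is restricted to forward single-donor insertions;
compound insertions are not repair-genotyped; the genomic scan is a
desk-scale seed-and-extend against a mini-genome — a full mammalian
genome would route through an external long-read aligner; and absolute
insertion rates inherit the length biases of the upstream PCR, so
cross-category proportions are comparative, not absolute.
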