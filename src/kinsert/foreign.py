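"""Detection of non-canonical insert content at the edited site.

Reads that carry both flanks but no full-length donor pattern can contain
degraded donor pieces, remnants of the circular editing plasmids,
captured endogenous genomic fragments, or LINE-1 retrotransposon
fragments — alone or chained.  The insert is the read subsequence
strictly between the inner flank edges (the rightmost matched base of the
left flank and the leftmost matched base of the right flank); it is
annotated by local alignment against a reference panel with a minimum
matched length of 50 bp for genomic/LINE-1 sources, exclusion regions
removed, and the highest-identity source chromosome winning when several
align.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import KmerIndex, SegmentHit, find_segments, locate_infix
from .errors import ConfigError
from .locus import FragmentLibrary, LocusModel
from .probes import ProbeSet, count_probe_hits, generate_probes, screen_unique

log = logging.getLogger(__name__)

# source classes
SHORT_F = "short-F"
SHORT_B = "short-B"
CAS9 = "Cas9-plasmid"
SGRNA = "sgRNA-plasmid"
GENOMIC = "genomic"
LINE1 = "LINE-1"
UNKNOWN = "unknown"

CAS9_PROBE_STEP = 100
SGRNA_PROBE_STEP = 40

# degraded-donor gates: reads shorter than the read gate are scanned for
# donor k-mers; an inferred insert shorter than the insert gate (which is
# <80% of the full fragment length) is a degraded-donor call.
DEFAULT_GATES = {
    "B": {"read_max": 2000, "insert_max": 1700},
    "F": {"read_max": 5000, "insert_max": 4400},
}


@dataclass(frozen=True)
class InsertSegment:
    qstart: int  # 1-based inclusive, within the extracted insert
    qend: int
    klass: str
    ref_name: str
    rstart: int
    rend: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.qend - self.qstart + 1


@dataclass
class ForeignCall:
    read_id: str
    insert_start: int | None  # read coordinate of the first insert base
    insert_length: int
    segments: tuple[InsertSegment, ...]
    flagged: str = ""  # non-empty when extraction failed

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(s.klass for s in self.segments))

    @property
    def compound(self) -> bool:
        return len(self.segments) >= 2 and len(set(s.klass for s in self.segments)) >= 2


class ReferencePanel:
    """All scan targets for foreign-insert annotation.

    ``plasmids`` maps a class (Cas9-plasmid / sgRNA-plasmid) to the unique
    region of the corresponding editing plasmid; ``genome`` maps contig
    names to sequences; ``line1`` is a single consensus.  Donor components
    come from the fragment library.  Probe sets for the plasmid regions
    use the class-specific tiling steps and are screened to be unique
    against every other reference in the configuration.
    """

    def __init__(
        self,
        library: FragmentLibrary,
        locus: LocusModel,
        cas9_region: str | None = None,
        sgrna_region: str | None = None,
        genome: dict[str, str] | None = None,
        line1: str | None = None,
        probe_k: int = 17,
        seed_k: int = 15,
    ):
        self.library = library
        self.locus = locus
        self.genome = {k: v.upper() for k, v in (genome or {}).items()}
        self.line1 = line1.upper() if line1 else None

        refs: dict[str, str] = {}
        self.ref_class: dict[str, str] = {}
        for comp in library.insertable:
            refs[comp.name] = comp.sequence.upper()
            self.ref_class[comp.name] = comp.name
        if cas9_region:
            refs["cas9"] = cas9_region.upper()
            self.ref_class["cas9"] = CAS9
        if sgrna_region:
            refs["sgrna"] = sgrna_region.upper()
            self.ref_class["sgrna"] = SGRNA
        for contig, seq in self.genome.items():
            name = f"genome:{contig}"
            refs[name] = seq
            self.ref_class[name] = GENOMIC
        if self.line1:
            refs["line1"] = self.line1
            self.ref_class["line1"] = LINE1
        if not refs:
            raise ConfigError("reference panel is empty")
        self.refs = refs
        self.index = KmerIndex(refs, k=seed_k)

        # plasmid probe sets, screened for uniqueness across the run config
        self.plasmid_probes: dict[str, ProbeSet] = {}
        everything = [locus.left_flank, locus.right_flank] + [
            s for n, s in refs.items() if not n.startswith(("cas9", "sgrna"))
        ]
        if cas9_region:
            pset = generate_probes(cas9_region, probe_k, CAS9_PROBE_STEP, "cas9")
            self.plasmid_probes[CAS9] = screen_unique(pset, everything)
        if sgrna_region:
            pset = generate_probes(sgrna_region, probe_k, SGRNA_PROBE_STEP, "sgrna")
            self.plasmid_probes[SGRNA] = screen_unique(pset, everything)

        # donor probe sets for the degraded-donor scan
        self.donor_probes: dict[str, tuple[ProbeSet, ProbeSet]] = {}
        for comp in library.insertable:
            others = [locus.left_flank, locus.right_flank] + [
                c.sequence for c in library.insertable if c.name != comp.name
            ]
            pset = screen_unique(
                generate_probes(comp.sequence, probe_k, 20, comp.name), others
            )
            self.donor_probes[comp.name] = (pset, pset.reverse_complemented())


def extract_insert(
    read: str, locus: LocusModel, max_flank_distance: int | None = None
) -> tuple[str, int | None, int | None, str]:
    """Insert between the inner flank edges of a forward-oriented read.

    Returns ``(insert, left_inner_edge, right_inner_edge, flag)`` with
    1-based read coordinates of the last left-flank base and the first
    right-flank base.  A read whose flank placements overlap or are out of
    order (deletion through the cut) yields an empty insert with a flag.
    """
    read = read.upper()
    if max_flank_distance is None:
        max_flank_distance = max(10, len(locus.left_flank) // 3)
    lhit = locate_infix(locus.left_flank, read, max_flank_distance)
    rhit = locate_infix(locus.right_flank, read, max_flank_distance)
    if lhit is None or rhit is None:
        return "", None, None, "flank not located"
    if rhit.start <= lhit.end:
        return "", lhit.end, rhit.start, "flanks overlap or out of order"
    return read[lhit.end : rhit.start - 1], lhit.end, rhit.start, ""


def scan_plasmid_fragments(
    read_or_insert: str,
    panel: ReferencePanel,
    min_hits: int = 1,
) -> dict[str, int]:
    """Exact probe-hit counts of the editing-plasmid unique regions.

    Classification requires >= ``min_hits`` hits; the sparse tiling (one
    probe per 100 / 40 bp) makes a single exact 17-mer strong evidence.
    Probes are searched in both orientations.
    """
    counts = {}
    for klass, pset in panel.plasmid_probes.items():
        n = count_probe_hits(read_or_insert, pset) + count_probe_hits(
            read_or_insert, pset.reverse_complemented()
        )
        if n >= min_hits:
            counts[klass] = n
    return counts


def detect_degraded_donor(
    read_length: int,
    insert: str,
    panel: ReferencePanel,
    gates: dict | None = None,
    min_hits: int = 1,
) -> list[str]:
    """Degraded-donor classes supported by a read, per the published gates.

    A short-backbone call requires the read below the 2 kb read gate,
    backbone k-mer hits in the insert, and an inferred insert below
    1700 bp (<80% of the full backbone); short-cassette analogously with
    the 5 kb / 4400 bp gates.
    """
    gates = gates or DEFAULT_GATES
    out = []
    for name, (fwd, rev) in panel.donor_probes.items():
        g = gates.get(name)
        if g is None:
            continue
        if read_length >= g["read_max"] or len(insert) >= g["insert_max"]:
            continue
        hits = count_probe_hits(insert, fwd) + count_probe_hits(insert, rev)
        if hits >= min_hits:
            out.append(f"short-{name}")
    return out


def _excluded(panel: ReferencePanel, contig: str, rstart: int, rend: int) -> bool:
    for ex_contig, lo, hi in panel.locus.exclusion_regions:
        # exclusion intervals are 0-based half-open (BED convention)
        if ex_contig == contig and rstart - 1 < hi and rend > lo:
            return True
    return False


def _classify_segment(hit: SegmentHit, panel: ReferencePanel) -> InsertSegment | None:
    klass = panel.ref_class[hit.ref_name]
    ref_name = hit.ref_name
    if klass == GENOMIC:
        contig = hit.ref_name.split(":", 1)[1]
        if _excluded(panel, contig, hit.rstart, hit.rend):
            return None
        ref_name = contig
    elif klass in panel.donor_probes:
        # donor component: degraded iff the matched stretch is below 80%
        # of the full fragment length (the read/insert length gates belong
        # to the dedicated degraded-donor screening pass)
        comp_len = panel.library.get(klass).length
        degraded = hit.qend - hit.qstart + 1 < 0.8 * comp_len
        klass = f"short-{klass}" if degraded else klass
    return InsertSegment(
        hit.qstart, hit.qend, klass, ref_name, hit.rstart, hit.rend, hit.strand, hit.identity
    )


def segment_insert(
    insert: str,
    panel: ReferencePanel,
    read_length: int | None = None,
    min_len: int = 50,
    min_identity: float = 80.0,
    gates: dict | None = None,
) -> list[InsertSegment]:
    """Annotate an insert as an ordered list of source segments.

    Matched stretches shorter than ``min_len`` (50 bp) or below the
    identity floor are discarded, as are genomic hits inside exclusion
    regions.  Overlapping candidates from different sources are resolved
    by identity (longer alignment on ties) inside the segment search.
    """
    if read_length is None:
        read_length = len(insert) + panel.locus.background_length
    hits = find_segments(insert, panel.index, min_len=min_len, min_identity=min_identity)
    segments = []
    for hit in hits:
        seg = _classify_segment(hit, panel)
        if seg is not None:
            segments.append(seg)
    return segments


def align_insert_to_genome(
    insert: str,
    panel: ReferencePanel,
    min_len: int = 50,
    min_identity: float = 80.0,
) -> list[InsertSegment]:
    """Genomic segments of an insert (exclusions applied, best contig wins)."""
    if not panel.genome:
        log.info("no genome reference supplied; genomic scan skipped")
        return []
    return [s for s in segment_insert(insert, panel, min_len=min_len, min_identity=min_identity)
            if s.klass == GENOMIC]


def detect_line1(
    insert: str,
    panel: ReferencePanel,
    min_len: int = 50,
    min_identity: float = 80.0,
) -> list[InsertSegment]:
    """LINE-1 consensus segments of an insert (truncation expected)."""
    if not panel.line1:
        return []
    return [s for s in segment_insert(insert, panel, min_len=min_len, min_identity=min_identity)
            if s.klass == LINE1]


def classify_foreign(
    read: str,
    read_id: str,
    panel: ReferencePanel,
    min_len: int = 50,
    min_identity: float = 80.0,
    gates: dict | None = None,
) -> ForeignCall:
    """Full foreign-content annotation of one (forward-oriented) read."""
    insert, left_edge, right_edge, flag = extract_insert(read, panel.locus)
    if flag:
        return ForeignCall(read_id, left_edge, 0, (), flagged=flag)
    segments = segment_insert(
        insert, panel, read_length=len(read), min_len=min_len,
        min_identity=min_identity, gates=gates,
    )
    return ForeignCall(
        read_id,
        (left_edge + 1) if left_edge is not None else None,
        len(insert),
        tuple(segments),
    )
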