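"""Per-read insertion-pattern calling and proportion computation.

A read is accepted into the analysis when both retained genomic flanks are
found (17-mer probes, step 20) on a consistent strand.  Its anchored
amplicon length selects candidate categories by grouping window; the
orientation probe sets of each candidate's components are then scanned in
a position range shrunk inward from the perfect insert span, and the
ordered fragment chain is reconstructed by scoring every orientation
chain compatible with the candidate composition against the observed
probe-hit positions.  Reads matching no candidate are routed to the
foreign-insert scan; reads matching more than one are reported ambiguous
rather than double-counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations, product
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError
from .locus import (
    FragmentLibrary,
    LocusModel,
    OrientationPattern,
    PatternCategory,
    background_category,
)
from .probes import ProbeSet, evenly_spaced_probes, find_probe_hits, generate_probes, screen_unique
from .seq import revcomp

log = logging.getLogger(__name__)

# category / verdict sentinels
BACKGROUND = "background"
AMBIGUOUS = "ambiguous"
UNCLASSIFIED = "unclassified"

FLANK_PROBE_K = 17
FLANK_PROBE_STEP = 20
PROBES_PER_COMPONENT = 20


@dataclass(frozen=True)
class FlankProbes:
    left: ProbeSet
    right: ProbeSet

    @classmethod
    def from_locus(cls, locus: LocusModel, k: int = FLANK_PROBE_K, step: int = FLANK_PROBE_STEP):
        return cls(
            left=generate_probes(locus.left_flank, k, step, "left_flank"),
            right=generate_probes(locus.right_flank, k, step, "right_flank"),
        )


@dataclass(frozen=True)
class ComponentProbes:
    """Forward and reverse orientation probe sets per insertable component."""

    forward: dict[str, ProbeSet]
    reverse: dict[str, ProbeSet]
    lengths: dict[str, int]

    @classmethod
    def from_library(
        cls,
        library: FragmentLibrary,
        locus: LocusModel,
        n_probes: int = PROBES_PER_COMPONENT,
        k: int = FLANK_PROBE_K,
        screen_against: Sequence[str] = (),
    ) -> "ComponentProbes":
        """Build probe sets, screening out probes shared with the flanks,
        with other components, or with any extra reference (homology arms
        embedded in a donor fragment would otherwise match every read)."""
        fwd, rev, lengths = {}, {}, {}
        comps = library.insertable
        for comp in comps:
            others = [locus.left_flank, locus.right_flank, *screen_against]
            others += [c.sequence for c in comps if c.name != comp.name]
            pset = evenly_spaced_probes(comp.sequence, k, n_probes, comp.name)
            pset = screen_unique(pset, others)
            if not pset.probes:
                raise ConfigError(f"no unique probes left for component {comp.name!r}")
            fwd[comp.name] = pset
            rev[comp.name] = pset.reverse_complemented()
            lengths[comp.name] = comp.length
        return cls(fwd, rev, lengths)

    def probe_set(self, name: str, orient: str) -> ProbeSet:
        return self.forward[name] if orient == "f" else self.reverse[name]


@dataclass
class FlankEvidence:
    has_left: bool
    has_right: bool
    strand: str | None  # '+', '-', or None when undetermined
    anchor: int | None  # 1-based read position where the amplicon starts
    oriented_read: str


@dataclass
class ReadCall:
    read_id: str
    read_length: int
    has_left: bool = False
    has_right: bool = False
    strand: str | None = None
    amplicon_length: int | None = None
    candidates: tuple[str, ...] = ()
    category: str = UNCLASSIFIED
    pattern: OrientationPattern | None = None
    hits: dict = field(default_factory=dict)
    route: str = "none"  # donor | background | foreign | deletion | none

    @property
    def both_flanks(self) -> bool:
        return self.has_left and self.has_right


def check_flanks(
    read: str, flanks: FlankProbes, min_hits: int = 1
) -> FlankEvidence:
    """Detect both flanks, pick the strand, and anchor the amplicon start.

    The strand is chosen as the orientation with more total flank probe
    hits, requiring left-before-right ordering when both flanks are seen.
    The anchor maps read coordinates onto amplicon coordinates using the
    leftmost left-flank probe hit (exact on error-free reads).
    """
    read = read.upper()
    best = None
    for strand, seq in (("+", read), ("-", revcomp(read))):
        lhits = find_probe_hits(seq, flanks.left)
        rhits = find_probe_hits(seq, flanks.right)
        has_left = len(lhits) >= min_hits
        has_right = len(rhits) >= min_hits
        ordered = True
        if has_left and has_right:
            ordered = _median(p for _, p in lhits) < _median(p for _, p in rhits)
        score = (has_left and has_right and ordered, len(lhits) + len(rhits))
        if best is None or score > best[0]:
            best = (score, strand, seq, lhits, rhits, has_left, has_right, ordered)
    _, strand, seq, lhits, rhits, has_left, has_right, ordered = best
    if not (has_left or has_right):
        return FlankEvidence(False, False, None, None, read)
    anchor = None
    if has_left:
        src, pos = min(lhits, key=lambda h: h[1])
        anchor = pos - (src - 1)
    return FlankEvidence(has_left, has_right and ordered, strand, anchor, seq)


def _median(values) -> float:
    vals = sorted(values)
    n = len(vals)
    if n == 0:
        return float("nan")
    mid = n // 2
    return float(vals[mid]) if n % 2 else (vals[mid - 1] + vals[mid]) / 2.0


def probe_search_range(
    category: PatternCategory, locus: LocusModel, margin: int = 300
) -> tuple[int, int]:
    """Probe search bounds for a category, in amplicon coordinates.

    The perfect insert spans ``len(left_flank)+1 .. expected_length -
    len(right_flank)``; both bounds are moved inward by ``margin`` to avoid
    picking up erroneous hits near the junctions.  If the shrunken range is
    empty the full span is used (logged).
    """
    lo = len(locus.left_flank) + 1
    hi = category.expected_length - len(locus.right_flank)
    slo, shi = lo + margin, hi - margin
    if slo >= shi:
        log.warning(
            "margin %d collapses search range for %s; using full span", margin, category.name
        )
        return (lo, hi)
    return (slo, shi)


def _slot_bounds(
    arrangement: Sequence[str], comp_probes: ComponentProbes, locus: LocusModel
) -> list[tuple[int, int]]:
    """Amplicon-coordinate interval of each fragment slot of an ordered
    arrangement."""
    bounds = []
    pos = len(locus.left_flank) + 1
    for name in arrangement:
        length = comp_probes.lengths[name]
        bounds.append((pos, pos + length - 1))
        pos += length
    return bounds


def _reconstruct_chain(
    category: PatternCategory,
    hits: dict[tuple[str, str], list[int]],
    comp_probes: ComponentProbes,
    locus: LocusModel,
    slot_tolerance: int = 150,
) -> OrientationPattern | None:
    """Choose the orientation chain best explaining the probe-hit positions.

    Every distinct ordered arrangement of the composition, with every
    orientation assignment, defines expected slot intervals; the chain
    scoring the most in-slot hits of the matching component-orientation
    wins.  A tie is reported as unresolvable (``None``).
    """
    best_score = -1
    best_chain = None
    tie = False
    for arrangement in sorted(set(permutations(category.composition))):
        slots = _slot_bounds(arrangement, comp_probes, locus)
        for orients in product("fr", repeat=len(arrangement)):
            score = 0
            for (name, orient), (lo, hi) in zip(zip(arrangement, orients), slots):
                for pos in hits.get((name, orient), ()):
                    if lo - slot_tolerance <= pos <= hi + slot_tolerance:
                        score += 1
            if score > best_score:
                best_score, best_chain, tie = score, tuple(zip(arrangement, orients)), False
            elif score == best_score and tuple(zip(arrangement, orients)) != best_chain:
                tie = True
    if best_chain is None or tie or best_score <= 0:
        return None
    return OrientationPattern(best_chain)


def call_pattern(
    read: str,
    read_id: str,
    categories: Sequence[PatternCategory],
    locus: LocusModel,
    comp_probes: ComponentProbes,
    flanks: FlankProbes,
    min_hits: int = 1,
    flank_min_hits: int = 1,
    margin: int = 300,
) -> ReadCall:
    """Classify one read into background / a donor category + chain /
    ambiguous / unclassified, and set its downstream route."""
    call = ReadCall(read_id=read_id, read_length=len(read))
    ev = check_flanks(read, flanks, flank_min_hits)
    call.has_left, call.has_right, call.strand = ev.has_left, ev.has_right, ev.strand
    if not (ev.has_left and ev.has_right) or ev.anchor is None:
        return call
    seq = ev.oriented_read
    amplicon_len = len(seq) - ev.anchor + 1
    call.amplicon_length = amplicon_len

    bg = background_category(locus)
    in_background = bg.window[0] <= amplicon_len <= bg.window[1]
    candidates = [c for c in categories if c.window[0] <= amplicon_len <= c.window[1]]
    call.candidates = tuple(c.name for c in candidates)

    # All probe hits of every component, in amplicon coordinates, collected
    # once; candidate checks then filter by their restricted ranges.
    all_hits: dict[tuple[str, str], list[int]] = {}
    for name in comp_probes.forward:
        for orient in ("f", "r"):
            pset = comp_probes.probe_set(name, orient)
            found = find_probe_hits(seq, pset, ev.anchor)
            if found:
                all_hits[(name, orient)] = sorted(p - ev.anchor + 1 for _, p in found)

    consistent: list[tuple[PatternCategory, dict]] = []
    for cat in candidates:
        lo, hi = probe_search_range(cat, locus, margin)
        present: set[str] = set()
        cat_hits: dict[tuple[str, str], list[int]] = {}
        for (name, orient), positions in all_hits.items():
            in_range = [p for p in positions if lo <= p <= hi]
            if in_range:
                cat_hits[(name, orient)] = in_range
            if len(in_range) >= min_hits:
                present.add(name)
        if present == set(cat.composition):
            consistent.append((cat, cat_hits))

    if len(consistent) == 1:
        cat, cat_hits = consistent[0]
        call.hits = {f"{n}{o}": len(v) for (n, o), v in cat_hits.items()}
        chain = _reconstruct_chain(cat, cat_hits, comp_probes, locus)
        if chain is None or sorted(n for n, _ in chain.chain) != list(cat.composition):
            call.category = AMBIGUOUS
            call.route = "none"
        else:
            call.category = cat.name
            call.pattern = chain
            call.route = "donor"
    elif len(consistent) > 1:
        call.category = AMBIGUOUS
        call.route = "none"
    elif in_background:
        # a read in the background window can still harbour a short
        # foreign insert: >= 50 bp between the inner flank edges counts
        # as an insertion and goes to the foreign scan
        if amplicon_len - locus.background_length >= 50:
            call.category = UNCLASSIFIED
            call.route = "foreign"
        else:
            call.category = BACKGROUND
            call.route = "background"
    else:
        call.category = UNCLASSIFIED
        # insert-bearing but unexplained reads go to the foreign scan;
        # shorter-than-background reads carry deletions through the cut
        call.route = "foreign" if amplicon_len > bg.window[1] else "deletion"
    return call


def call_reads(
    reads: Iterable[tuple[str, str]],
    categories: Sequence[PatternCategory],
    locus: LocusModel,
    comp_probes: ComponentProbes,
    flanks: FlankProbes,
    **kwargs,
) -> list[ReadCall]:
    return [
        call_pattern(seq, rid, categories, locus, comp_probes, flanks, **kwargs)
        for rid, seq in reads
    ]


# report groups used in summaries
GROUPS = ("single_F", "single_B", "complete_donor", "compound")


def _group_of(category: str, composition: tuple[str, ...] | None) -> str | None:
    if composition is None:
        return None
    if composition == ("F",):
        return "single_F"
    if composition == ("B",):
        return "single_B"
    if composition == ("B", "F"):
        return "complete_donor"
    if composition:
        return "compound"
    return None


@dataclass
class ProportionTable:
    """Pattern / category / group proportions over a defined denominator."""

    per_pattern: pd.DataFrame
    per_category: pd.DataFrame
    groups: pd.DataFrame
    denominator: int
    denominator_mode: str
    defined: bool = True


def compute_proportions(
    calls: Sequence[ReadCall], denominator_mode: str = "both_flanks"
) -> ProportionTable:
    """Proportions of called patterns/categories among flank-anchored reads.

    The default denominator is the count of reads carrying both flanks
    (background and unresolved reads included); proportions of called
    categories therefore sum to at most 1.
    """
    if denominator_mode == "both_flanks":
        denom_calls = [c for c in calls if c.both_flanks]
    elif denominator_mode == "all":
        denom_calls = list(calls)
    else:
        raise ConfigError(f"unknown denominator mode: {denominator_mode!r}")
    denom = len(denom_calls)
    defined = denom > 0
    if not defined:
        log.warning("zero denominator (%s); proportions undefined", denominator_mode)

    pattern_counts: dict[str, int] = {}
    category_counts: dict[str, int] = {}
    group_counts = {g: 0 for g in GROUPS}
    for c in denom_calls:
        category_counts[c.category] = category_counts.get(c.category, 0) + 1
        if c.pattern is not None:
            key = str(c.pattern)
            pattern_counts[key] = pattern_counts.get(key, 0) + 1
            group = _group_of(c.category, c.pattern.composition)
            if group:
                group_counts[group] += 1

    def table(counts: dict[str, int], label: str) -> pd.DataFrame:
        df = pd.DataFrame({label: list(counts), "count": list(counts.values())})
        df["proportion"] = df["count"] / denom if defined else float("nan")
        return df.sort_values("count", ascending=False, ignore_index=True)

    return ProportionTable(
        per_pattern=table(pattern_counts, "pattern"),
        per_category=table(category_counts, "category"),
        groups=table(group_counts, "group"),
        denominator=denom,
        denominator_mode=denominator_mode,
        defined=defined,
    )
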