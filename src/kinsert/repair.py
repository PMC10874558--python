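"""NHEJ / HDR classification of correctly oriented donor insertions.

The donor carries copies of the genomic homology arms.  Direct (end
joining) capture of the full fragment leaves the arm present twice in
tandem — once in the retained genomic flank and once at the fragment
edge — whereas homology-directed repair collapses the two copies into
one.  Counting distinct arm copies near the junction therefore genotypes
the repair pathway: any evaluable arm with two copies is NHEJ evidence;
all evaluable arms at a single copy is HDR; anything else is Other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .align import locate_infix
from .calling import ReadCall
from .locus import LocusModel, OrientationPattern

log = logging.getLogger(__name__)

NHEJ = "NHEJ"
HDR = "HDR"
OTHER = "Other"


@dataclass(frozen=True)
class ArmMatch:
    arm: str  # 'left' or 'right'
    start: int  # 1-based inclusive on the read
    end: int
    identity: float
    strand: str = "+"


@dataclass
class RepairCall:
    read_id: str
    verdict: str
    copies: dict[str, int | None]  # per arm; None = not evaluable
    matches: tuple[ArmMatch, ...]
    reason: str = ""


def find_arm_matches(
    read: str,
    arm: str,
    arm_name: str = "left",
    min_identity: float = 80.0,
    window: tuple[int, int] | None = None,
    max_copies: int = 4,
) -> list[ArmMatch]:
    """Distinct copies of an arm within (a window of) a forward-oriented read.

    Copies are found by iterated best-placement alignment with masking:
    the best infix alignment with identity >= ``min_identity`` is
    recorded, its interval masked, and the search repeated.  Distinct
    copies may be adjacent (tandem duplication at a blunt junction) but
    may overlap an accepted copy by at most 10% of the arm length, which
    prevents one noisy alignment from being split into two copies.
    """
    if not arm:
        return []
    read = read.upper()
    lo, hi = (1, len(read)) if window is None else window
    lo = max(1, lo)
    hi = min(len(read), hi)
    if hi - lo + 1 < len(arm) // 2:
        return []
    region = list(read[lo - 1 : hi])
    matches: list[ArmMatch] = []
    max_overlap = max(1, len(arm) // 10)
    for _ in range(max_copies):
        hit = locate_infix(arm, "".join(region))
        if hit is None or hit.identity < min_identity:
            break
        start, end = hit.start + lo - 1, hit.end + lo - 1
        overlap = sum(
            max(0, min(end, m.end) - max(start, m.start) + 1) for m in matches
        )
        if overlap > max_overlap:
            break
        matches.append(ArmMatch(arm_name, start, end, hit.identity))
        for i in range(hit.start - 1, hit.end):
            region[i] = "\0"  # mask; never matches a base
    matches.sort(key=lambda m: m.start)
    return matches


def _junction_windows(
    locus: LocusModel, pattern: OrientationPattern, anchor: int, component_lengths: dict[str, int]
) -> dict[str, tuple[int, int]]:
    """Read-coordinate windows around the expected left/right junctions."""
    insert_len = sum(component_lengths[name] for name, _ in pattern.chain)
    left_junction = anchor + len(locus.left_flank) - 1
    right_junction = left_junction + insert_len + 1
    windows = {}
    for arm_name, arm, junction in (
        ("left", locus.left_arm, left_junction),
        ("right", locus.right_arm, right_junction),
    ):
        pad = len(arm) + 200
        windows[arm_name] = (junction - pad, junction + pad)
    return windows


def classify_repair(
    read: str,
    read_id: str,
    locus: LocusModel,
    pattern: OrientationPattern,
    component_lengths: dict[str, int],
    anchor: int = 1,
    min_identity: float = 80.0,
) -> RepairCall:
    """Genotype the repair pathway of a forward single-donor insertion.

    ``anchor`` is the 1-based read position where the amplicon (left
    flank) starts.  Arms of length zero are not evaluable; with no
    evaluable arm the verdict is Other with a stated reason.
    """
    windows = _junction_windows(locus, pattern, anchor, component_lengths)
    copies: dict[str, int | None] = {}
    all_matches: list[ArmMatch] = []
    for arm_name, arm in (("left", locus.left_arm), ("right", locus.right_arm)):
        if not arm:
            copies[arm_name] = None
            continue
        found = find_arm_matches(
            read, arm, arm_name, min_identity=min_identity, window=windows[arm_name]
        )
        copies[arm_name] = len(found)
        all_matches.extend(found)

    evaluable = {k: v for k, v in copies.items() if v is not None}
    if not evaluable:
        verdict, reason = OTHER, "not evaluable (both arms empty)"
    elif any(v >= 2 for v in evaluable.values()):
        verdict, reason = NHEJ, "duplicated homology arm"
    elif all(v == 1 for v in evaluable.values()):
        verdict, reason = HDR, "single collapsed homology arm"
    else:
        verdict, reason = OTHER, "homology arm missing"
    return RepairCall(read_id, verdict, copies, tuple(all_matches), reason)


def is_forward_single_donor(call: ReadCall, donor_component: str = "F") -> bool:
    """The repair classifier applies only to single forward donor insertions."""
    return (
        call.pattern is not None
        and len(call.pattern.chain) == 1
        and call.pattern.chain[0] == (donor_component, "f")
    )


def summarize_repair(calls: Sequence[RepairCall]):
    """Counts and fractions of NHEJ/HDR/Other among classified reads."""
    import pandas as pd

    counts = {v: 0 for v in (NHEJ, HDR, OTHER)}
    for c in calls:
        counts[c.verdict] += 1
    total = sum(counts.values())
    df = pd.DataFrame(
        {"verdict": list(counts), "count": list(counts.values())}
    )
    df["fraction"] = df["count"] / total if total else float("nan")
    return df
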