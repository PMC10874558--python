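"""Deletion quantification over the wild-type amplicon.

Two summary statistics are computed from gap-aware alignments of
insert-free reads to the wild-type amplicon:

* the deletion index ``(R - mean_depth) / R`` with ``R`` the number of
  anchored reads — the expected depth of a gap-free pile-up is flat at
  ``R``, so the index equals the mean deleted fraction of the interval
  (uniform fractional deletion f yields exactly f);
* D100, the fraction of reads whose largest deletion overlapping the cut
  site exceeds 100 bp.

Gap structure can come from standard alignment records (SAM) or from the
package's internal glocal alignment of reads against the amplicon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import covered_blocks, deletion_gaps, merge_gap_runs
from .errors import ReferenceError_
from .locus import LocusModel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadGaps:
    """Per-read alignment summary on the amplicon reference.

    ``blocks`` are covered reference intervals (1-based inclusive);
    ``gaps`` are merged deletion clusters ``(start, end, deleted)``: the
    reference interval spanned and the total deleted bases within it.
    """

    read_id: str
    blocks: tuple[tuple[int, int], ...]
    gaps: tuple[tuple[int, int, int], ...]


@dataclass
class CoverageProfile:
    reference: str
    depth: np.ndarray  # per-position depth over the amplicon interval
    n_reads: int


@dataclass
class DeletionReport:
    deletion_index: float
    d100: float
    n_reads: int
    per_read: pd.DataFrame  # read_id, max_gap, max_gap_at_cut, counted


def align_read(read: str, locus: LocusModel, merge_within: int = 10) -> ReadGaps:
    """Gap structure of one read from an internal glocal alignment."""
    ref = locus.background_sequence
    return ReadGaps(
        read_id="",
        blocks=tuple(covered_blocks(read, ref)),
        gaps=tuple(deletion_gaps(read, ref, merge_within=merge_within)),
    )


def gaps_from_reads(
    reads: Iterable[tuple[str, str]], locus: LocusModel, merge_within: int = 10
) -> list[ReadGaps]:
    out = []
    for rid, seq in reads:
        rg = align_read(seq, locus, merge_within)
        out.append(ReadGaps(rid, rg.blocks, rg.gaps))
    return out


def gaps_from_sam(path: str, reference: str) -> list[ReadGaps]:
    """Ingest coordinate-level gap structure from a SAM/BAM file."""
    import pysam

    out = []
    with pysam.AlignmentFile(path) as af:
        if reference not in af.references:
            raise ReferenceError_(f"reference {reference!r} not present in {path}")
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_name != reference:
                continue
            blocks = tuple((s + 1, e) for s, e in aln.get_blocks())
            runs = []
            pos = aln.reference_start
            for op, n in aln.cigartuples or ():
                if op in (0, 7, 8):  # M, =, X
                    pos += n
                elif op == 3 or op == 2:  # N or D
                    runs.append((pos + 1, pos + n))
                    pos += n
            out.append(ReadGaps(aln.query_name, blocks, tuple(merge_gap_runs(runs))))
    return out


def coverage_from_alignments(
    alignments: Sequence[ReadGaps], interval_length: int, reference: str = "amplicon"
) -> CoverageProfile:
    """Per-position depth over the amplicon interval (gaps excluded)."""
    depth = np.zeros(interval_length, dtype=np.int64)
    for aln in alignments:
        for lo, hi in aln.blocks:
            lo = max(1, lo)
            hi = min(interval_length, hi)
            if hi >= lo:
                depth[lo - 1 : hi] += 1
    return CoverageProfile(reference, depth, n_reads=len(alignments))


def deletion_index(profile: CoverageProfile) -> float:
    """``(R - mean_depth) / R`` with R the anchored read count."""
    if profile.n_reads < 1:
        log.warning("deletion index undefined: no anchored reads")
        return float("nan")
    return float((profile.n_reads - profile.depth.mean()) / profile.n_reads)


def _max_gap(gaps: Sequence[tuple[int, int, int]], cut: int | None, window: int) -> int:
    sizes = [
        size
        for lo, hi, size in gaps
        if cut is None or (lo <= cut + window and hi >= cut - window)
    ]
    return max(sizes, default=0)


def d100(
    alignments: Sequence[ReadGaps],
    cut_position: int,
    size_threshold: int = 100,
    cut_window: int = 50,
) -> tuple[float, pd.DataFrame]:
    """Fraction of reads whose largest deletion overlapping the cut site
    (within ``cut_window`` bp) exceeds ``size_threshold``."""
    rows = []
    for aln in alignments:
        max_gap = _max_gap(aln.gaps, None, 0)
        max_at_cut = _max_gap(aln.gaps, cut_position, cut_window)
        rows.append(
            {
                "read_id": aln.read_id,
                "max_gap": max_gap,
                "max_gap_at_cut": max_at_cut,
                "counted": max_at_cut > size_threshold,
            }
        )
    table = pd.DataFrame(rows, columns=["read_id", "max_gap", "max_gap_at_cut", "counted"])
    frac = float(table["counted"].mean()) if len(table) else float("nan")
    return frac, table


def deletion_report(
    alignments: Sequence[ReadGaps],
    locus: LocusModel,
    size_threshold: int = 100,
    cut_window: int = 50,
) -> DeletionReport:
    profile = coverage_from_alignments(alignments, locus.background_length)
    frac, table = d100(alignments, locus.cut_position, size_threshold, cut_window)
    return DeletionReport(
        deletion_index=deletion_index(profile),
        d100=frac,
        n_reads=len(alignments),
        per_read=table,
    )


def length_distribution(lengths: Iterable[int], binwidth: int | None = None) -> pd.DataFrame:
    """Binned read-length counts; total equals the read count.

    With ``binwidth`` unset, exact lengths are tabulated.
    """
    lengths = list(lengths)
    if not lengths:
        return pd.DataFrame(columns=["length", "count"])
    if binwidth:
        series = pd.Series([(l // binwidth) * binwidth for l in lengths])
    else:
        series = pd.Series(lengths)
    counts = series.value_counts().sort_index()
    return pd.DataFrame({"length": counts.index, "count": counts.values})
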