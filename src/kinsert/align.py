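"""Alignment helpers built on edlib.

edlib computes edit-distance-optimal alignments with extended CIGARs
(``=``, ``X``, ``I``, ``D``), from which percent identity is taken as
``100 * matches / alignment_columns``.  Three uses are wrapped here:

* infix search (``locate_infix``): best placement of a whole query inside
  a target — flank anchoring and homology-arm matching;
* glocal read-vs-amplicon alignment (``deletion_gaps``): gap structure of
  an insert-free read against the wild-type amplicon;
* seed-and-extend segment search (``find_segments``): local alignments of
  an unknown insert against a panel of references, for foreign-insert
  annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import edlib

from .seq import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def cigar_identity(cigar: str) -> float:
    """Percent identity over all alignment columns of an extended CIGAR."""
    cols = matches = 0
    for n, op in parse_cigar(cigar):
        cols += n
        if op == "=":
            matches += n
    return 100.0 * matches / cols if cols else 0.0


@dataclass(frozen=True)
class InfixHit:
    """Best placement of a full query within a target (1-based inclusive)."""

    start: int
    end: int
    edit_distance: int
    identity: float
    cigar: str


def locate_infix(query: str, target: str, max_distance: int = -1) -> InfixHit | None:
    """Best edit-distance placement of ``query`` inside ``target``.

    Returns ``None`` when no placement within ``max_distance`` exists
    (``-1`` disables the cap).
    """
    if not query or not target:
        return None
    res = edlib.align(query.upper(), target.upper(), mode="HW", task="path", k=max_distance)
    if res["editDistance"] == -1 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return InfixHit(
        start=start + 1,
        end=end + 1,
        edit_distance=res["editDistance"],
        identity=cigar_identity(res["cigar"]),
        cigar=res["cigar"],
    )


def deletion_gaps(
    read: str, reference: str, min_gap: int = 1, merge_within: int = 10
) -> list[tuple[int, int, int]]:
    """Deletion clusters of a glocal read-vs-reference alignment.

    Returns ``(start, end, deleted)`` per cluster: the 1-based inclusive
    reference interval it spans and the total number of deleted bases in
    it.  Deletion runs separated by at most ``merge_within`` reference
    bases are merged, and the deleted total (not the span) measures the
    deletion size: edit-distance-optimal alignments interrupt one
    biological deletion with coincidental single-base matches, which
    inflate the span but never the deleted-base count.
    """
    res = edlib.align(read.upper(), reference.upper(), mode="NW", task="path")
    runs: list[tuple[int, int]] = []
    ref_pos = 0  # bases of reference consumed
    for n, op in parse_cigar(res["cigar"]):
        if op in ("=", "X"):
            ref_pos += n
        elif op == "D":  # in edlib CIGAR, D consumes the *target* (reference)
            runs.append((ref_pos + 1, ref_pos + n))
            ref_pos += n
        # 'I' consumes only the query
    return merge_gap_runs(runs, min_gap=min_gap, merge_within=merge_within)


def merge_gap_runs(
    runs: Sequence[tuple[int, int]], min_gap: int = 1, merge_within: int = 10
) -> list[tuple[int, int, int]]:
    """Merge deletion runs into clusters; see :func:`deletion_gaps`."""
    if not runs:
        return []
    merged: list[list[int]] = [[runs[0][0], runs[0][1], runs[0][1] - runs[0][0] + 1]]
    for lo, hi in runs[1:]:
        if lo - merged[-1][1] - 1 <= merge_within:
            merged[-1][1] = hi
            merged[-1][2] += hi - lo + 1
        else:
            merged.append([lo, hi, hi - lo + 1])
    return [(lo, hi, size) for lo, hi, size in merged if size >= min_gap]


def covered_blocks(read: str, reference: str) -> list[tuple[int, int]]:
    """Reference intervals covered by a glocal alignment (gaps excluded)."""
    res = edlib.align(read.upper(), reference.upper(), mode="NW", task="path")
    blocks: list[tuple[int, int]] = []
    ref_pos = 0
    for n, op in parse_cigar(res["cigar"]):
        if op in ("=", "X"):
            if blocks and blocks[-1][1] == ref_pos:
                blocks[-1] = (blocks[-1][0], ref_pos + n)
            else:
                blocks.append((ref_pos + 1, ref_pos + n))
            ref_pos += n
        elif op == "D":
            ref_pos += n
    return blocks


@dataclass(frozen=True)
class SegmentHit:
    """A local alignment of part of a query against one reference."""

    qstart: int  # 1-based inclusive on the query
    qend: int
    ref_name: str
    rstart: int  # 1-based inclusive on the forward reference strand
    rend: int
    strand: str  # '+' or '-'
    identity: float
    matches: int


class KmerIndex:
    """Exact k-mer index over both strands of a reference panel."""

    def __init__(self, references: dict[str, str], k: int = 15, max_occ: int = 50):
        self.k = k
        self.refs = {name: seq.upper() for name, seq in references.items()}
        self._index: dict[str, list[tuple[str, int, str]]] = {}
        for name, seq in self.refs.items():
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                for i in range(len(s) - k + 1):
                    kmer = s[i : i + k]
                    bucket = self._index.setdefault(kmer, [])
                    if len(bucket) < max_occ:
                        bucket.append((name, i, strand))

    def seeds(self, query: str) -> list[tuple[int, str, int, str]]:
        """(qpos, ref_name, ref_pos_on_search_strand, strand) seed matches."""
        query = query.upper()
        out = []
        for i in range(len(query) - self.k + 1):
            for name, j, strand in self._index.get(query[i : i + self.k], ()):
                out.append((i, name, j, strand))
        return out


def _refine(
    query: str, ref_name: str, ref_seq: str, qlo: int, qhi: int, rlo: int, rhi: int, strand: str, k: int
) -> SegmentHit | None:
    """Glocal alignment of a bounded query window against a bounded
    reference window, trimmed to the outermost matching columns."""
    search_seq = ref_seq if strand == "+" else revcomp(ref_seq)
    pad = 8  # recover segment edges lost to noisy seeds; kept small so
    # junction-degenerate alignments cannot drift far
    qlo, qhi = max(0, qlo - pad), min(len(query), qhi + pad)
    rlo, rhi = max(0, rlo - pad), min(len(search_seq), rhi + pad)
    qseq = query[qlo:qhi].upper()
    rseq = search_seq[rlo:rhi]
    if not qseq or not rseq:
        return None
    # Infix mode lets the query window float within the (padded) reference
    # window; trimming then removes the padded non-matching ends.
    res = edlib.align(qseq, rseq, mode="HW", task="path")
    if res["editDistance"] == -1 or not res["locations"]:
        return None
    r_off = res["locations"][0][0]
    ops = parse_cigar(res["cigar"])
    # Trim to the maximum-scoring stretch of alignment columns (match +1,
    # mismatch/gap -2): chance isolated matches in the padded windows must
    # not extend the segment past its true junction.
    columns: list[tuple[int, int, int]] = []  # (score, q_adv, r_adv)
    for n, op in ops:
        score = 1 if op == "=" else -2
        q_adv = 1 if op in ("=", "X", "I") else 0
        r_adv = 1 if op in ("=", "X", "D") else 0
        columns.extend([(score, q_adv, r_adv)] * n)
    best = cur = 0
    best_bounds = (0, 0)
    cur_start = 0
    for i, (score, _, _) in enumerate(columns):
        cur += score
        if cur <= 0:
            cur, cur_start = 0, i + 1
        elif cur > best:
            best, best_bounds = cur, (cur_start, i + 1)
    if best <= 0:
        return None
    c0, c1 = best_bounds
    # anchor both ends on a run of >= 8 consecutive matches: isolated
    # chance matches beyond a true junction must not extend the segment
    min_anchor = 8
    run = 0
    start_anchor = end_anchor = None
    for i in range(c0, c1):
        run = run + 1 if columns[i][0] == 1 else 0
        if run == min_anchor:
            if start_anchor is None:
                start_anchor = i - min_anchor + 1
            end_anchor = i + 1
        elif run > min_anchor:
            end_anchor = i + 1
    if start_anchor is None:
        return None
    c0, c1 = start_anchor, end_anchor
    q0 = sum(c[1] for c in columns[:c0])
    r0 = sum(c[2] for c in columns[:c0])
    q1 = q0 + sum(c[1] for c in columns[c0:c1])
    r1 = r0 + sum(c[2] for c in columns[c0:c1])
    if q1 <= q0 or r1 <= r0:
        return None
    # identity over the trimmed columns
    seg = columns[c0:c1]
    cols = len(seg)
    matches = sum(1 for c in seg if c[0] == 1)
    identity = 100.0 * matches / cols if cols else 0.0
    # map back to query / forward-reference coordinates
    qstart, qend = qlo + q0 + 1, qlo + q1
    s_start, s_end = rlo + r_off + r0, rlo + r_off + r1 - 1  # 0-based on search strand
    if strand == "+":
        rstart, rend = s_start + 1, s_end + 1
    else:
        L = len(ref_seq)
        rstart, rend = L - s_end, L - s_start
    return SegmentHit(qstart, qend, ref_name, rstart, rend, strand, identity, matches)


def find_segments(
    query: str,
    index: KmerIndex,
    min_len: int = 50,
    min_identity: float = 80.0,
    band: int = 40,
) -> list[SegmentHit]:
    """Seed-and-extend local segment search of ``query`` against a panel.

    Seeds sharing (reference, strand, diagonal band) are clustered into
    candidate segments, refined by bounded glocal alignment, then greedily
    selected by (identity, length) with overlapping query intervals
    suppressed — so for homologous references the highest-identity source
    wins.  Returned segments are in query order.
    """
    if len(query) < index.k:
        return []
    clusters: dict[tuple[str, str, int], list[tuple[int, int]]] = {}
    for qpos, name, rpos, strand in index.seeds(query):
        diag = (qpos - rpos) // band
        # a seed near a band edge belongs to both neighbouring bands
        for d in (diag, diag + 1):
            clusters.setdefault((name, strand, d), []).append((qpos, rpos))
    candidates: list[SegmentHit] = []
    seen: set[tuple] = set()
    for (name, strand, _), seeds in clusters.items():
        qlo = min(q for q, _ in seeds)
        qhi = max(q for q, _ in seeds) + index.k
        rlo = min(r for _, r in seeds)
        rhi = max(r for _, r in seeds) + index.k
        key = (name, strand, qlo, qhi, rlo, rhi)
        if key in seen:
            continue
        seen.add(key)
        hit = _refine(query, name, index.refs[name], qlo, qhi, rlo, rhi, strand, index.k)
        if hit and hit.qend - hit.qstart + 1 >= min_len and hit.identity >= min_identity:
            candidates.append(hit)
    # greedy non-overlapping selection on the query, best identity first
    candidates.sort(key=lambda h: (-h.identity, -(h.qend - h.qstart), h.ref_name))
    chosen: list[SegmentHit] = []
    for hit in candidates:
        span = hit.qend - hit.qstart + 1
        overlap = sum(
            max(0, min(hit.qend, c.qend) - max(hit.qstart, c.qstart) + 1) for c in chosen
        )
        if overlap <= 0.2 * span:
            chosen.append(hit)
    chosen.sort(key=lambda h: h.qstart)
    return chosen
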