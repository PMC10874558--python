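"""k-mer probe sets for exact-match content filtering of noisy long reads.

Short exact k-mers ("grepseqs") tolerate the indel-dominated error of
nanopore reads statistically: an individual 17-mer survives ~5% per-base
error with probability ~0.42, so a set of probes tiled across a source
sequence almost always leaves several intact copies in a read that truly
contains the source.  Exact matching keeps the false-positive rate
negligible (a specific 17-mer occurs by chance with probability 4^-17 per
position).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .errors import ConfigError
from .seq import find_all, revcomp

SearchOrientation = Literal["as-is", "reverse-complement", "both"]


@dataclass(frozen=True)
class Probe:
    sequence: str
    source_name: str
    source_position: int  # 1-based start within the source


@dataclass(frozen=True)
class ProbeSet:
    k: int
    step: int
    probes: tuple[Probe, ...]
    search_orientation: SearchOrientation = "as-is"

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.probes]

    def reverse_complemented(self) -> "ProbeSet":
        """Probe set matching the reverse-complemented source.

        Source positions are remapped so that position 1 refers to the
        start of the reverse-complemented source.
        """
        if not self.probes:
            return self
        src_len = max(p.source_position + self.k - 1 for p in self.probes)
        probes = tuple(
            Probe(
                sequence=revcomp(p.sequence),
                source_name=p.source_name,
                source_position=src_len - (p.source_position + self.k - 1) + 1,
            )
            for p in reversed(self.probes)
        )
        return ProbeSet(self.k, self.step, probes, self.search_orientation)


def generate_probes(
    source: str, k: int, step: int, source_name: str = "source"
) -> ProbeSet:
    """Tile ``source`` with k-mers at starts 1, 1+step, ... (1-based).

    Probes are emitted while the full k-mer fits in the source.
    """
    if k < 1 or step < 1:
        raise ConfigError("k and step must be >= 1")
    if len(source) < k:
        raise ConfigError(f"source shorter than probe length ({len(source)} < {k})")
    source = source.upper()
    probes = tuple(
        Probe(source[start : start + k], source_name, start + 1)
        for start in range(0, len(source) - k + 1, step)
    )
    return ProbeSet(k=k, step=step, probes=probes)


def evenly_spaced_probes(
    source: str, k: int, n: int, source_name: str = "source"
) -> ProbeSet:
    """``n`` k-mers at (approximately) evenly spaced starts across ``source``."""
    if len(source) < k:
        raise ConfigError(f"source shorter than probe length ({len(source)} < {k})")
    source = source.upper()
    starts = np.unique(np.round(np.linspace(0, len(source) - k, n)).astype(int))
    probes = tuple(Probe(source[s : s + k], source_name, int(s) + 1) for s in starts)
    step = int(starts[1] - starts[0]) if len(starts) > 1 else len(source)
    return ProbeSet(k=k, step=step, probes=probes)


def screen_unique(probeset: ProbeSet, other_sequences: Iterable[str]) -> ProbeSet:
    """Drop probes occurring in any other reference (either strand).

    Used to restrict probe sets to sequence unique to their source, e.g.
    dropping donor probes that fall inside a homology arm shared with the
    genomic flank.
    """
    others = [s.upper() for s in other_sequences]
    kept = tuple(
        p
        for p in probeset.probes
        if not any(p.sequence in o or revcomp(p.sequence) in o for o in others)
    )
    return ProbeSet(probeset.k, probeset.step, kept, probeset.search_orientation)


def find_probe_hits(
    seq: str, probeset: ProbeSet, lo: int = 1, hi: int | None = None
) -> list[tuple[int, int]]:
    """Exact probe occurrences as (source_position, seq_position) pairs.

    Positions are 1-based; ``lo``/``hi`` bound the occurrence *start*
    positions in ``seq`` (inclusive).
    """
    if hi is None:
        hi = len(seq)
    hits = []
    for p in probeset.probes:
        for i in find_all(seq, p.sequence, lo - 1, hi):
            hits.append((p.source_position, i + 1))
    return hits


def count_probe_hits(seq: str, probeset: ProbeSet, lo: int = 1, hi: int | None = None) -> int:
    return len(find_probe_hits(seq, probeset, lo, hi))
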