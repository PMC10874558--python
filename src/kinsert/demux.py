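"""Demultiplexing pooled reads by indel-tolerant barcode probes (BCseqs).

Each sample is tagged with an 11-nt barcode followed by the amplification
primer.  The BCseq set of a barcode is every 11-mer, step 1, of the 17-nt
string ``barcode + primer[:6]`` (seven probes).  A read is assigned to the
barcode whose BCseqs occur most often in its first ``search_prefix_bp``
bases (either strand); edits near the barcode edges always leave an intact
11-mer.  Edits in the centre of the barcode can destroy every exact
11-mer, so when probe counting produces no unique winner the assigner
falls back to bounded edit-distance matching of ``barcode + primer prefix``
against the read prefix, which resolves any single-edit corruption as long
as barcodes are mutually well separated.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import edlib
import pandas as pd

from .errors import ConfigError
from .probes import ProbeSet, count_probe_hits, generate_probes
from .seq import revcomp

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

BCSEQ_K = 11
BCSEQ_PRIMER_PREFIX = 6


@dataclass(frozen=True)
class BarcodeSpec:
    """A sample barcode with its derived BCseq probe set."""

    barcode_id: str
    barcode: str
    primer: str
    bcseqs: ProbeSet = field(init=False)

    def __post_init__(self):
        if len(self.primer) < BCSEQ_PRIMER_PREFIX:
            raise ConfigError(
                f"primer of {self.barcode_id!r} shorter than {BCSEQ_PRIMER_PREFIX} nt"
            )
        source = (self.barcode + self.primer[:BCSEQ_PRIMER_PREFIX]).upper()
        object.__setattr__(
            self, "bcseqs", generate_probes(source, BCSEQ_K, 1, self.barcode_id)
        )

    @property
    def tag(self) -> str:
        """The barcode + primer-prefix region the BCseqs tile."""
        return (self.barcode + self.primer[:BCSEQ_PRIMER_PREFIX]).upper()


def _validate_specs(specs: list[BarcodeSpec]) -> None:
    if not specs:
        raise ConfigError("no barcode specs supplied")
    seen: dict[str, str] = {}
    for spec in specs:
        bc = spec.barcode.upper()
        if bc in seen:
            raise ConfigError(
                f"duplicate barcode sequence shared by {seen[bc]!r} and {spec.barcode_id!r}"
            )
        seen[bc] = spec.barcode_id


def assign_read(
    read: str,
    specs: list[BarcodeSpec],
    min_hits: int = 1,
    search_prefix_bp: int = 200,
    max_fallback_distance: int = 3,
) -> tuple[str, str | None]:
    """Assign a read to a barcode; returns ``(barcode_id, strand)``.

    ``strand`` is ``"+"`` if the barcode was found on the read as given,
    ``"-"`` if on its reverse complement, ``None`` if unassigned.  Probe
    counting wins when it produces a unique best spec with >= ``min_hits``
    hits; otherwise the edit-distance fallback assigns the unique spec
    whose tag matches the read prefix within ``max_fallback_distance``
    edits, with a margin of at least one edit over the runner-up.
    """
    _validate_specs(specs)
    read = read.upper()
    prefixes = {"+": read[:search_prefix_bp], "-": revcomp(read)[:search_prefix_bp]}

    best: tuple[int, str, str | None] = (0, UNASSIGNED, None)
    tied = False
    for spec in specs:
        for strand, prefix in prefixes.items():
            hits = count_probe_hits(prefix, spec.bcseqs)
            if hits > best[0]:
                best = (hits, spec.barcode_id, strand)
                tied = False
            elif hits == best[0] and hits > 0 and spec.barcode_id != best[1]:
                tied = True
    if best[0] >= min_hits and not tied:
        return best[1], best[2]

    # Edit-distance fallback for reads whose barcode region lost every
    # intact 11-mer (central single edits) or tied between specs.
    dists: list[tuple[int, str, str]] = []
    for spec in specs:
        for strand, prefix in prefixes.items():
            if not prefix:
                continue
            d = edlib.align(spec.tag, prefix, mode="HW", task="distance")["editDistance"]
            dists.append((d, spec.barcode_id, strand))
    dists.sort(key=lambda t: t[0])
    if dists and dists[0][0] <= max_fallback_distance:
        runner_up = next((d for d, bid, _ in dists if bid != dists[0][1]), None)
        if runner_up is None or runner_up > dists[0][0]:
            return dists[0][1], dists[0][2]
    return UNASSIGNED, None


def _open_maybe_gz(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) triples; malformed trailing records are
    skipped with a logged warning."""
    with _open_maybe_gz(path, "r") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
                log.warning("skipping malformed FASTQ record at %r", header.strip())
                continue
            yield header[1:].split()[0].strip(), seq, qual


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> int:
    n = 0
    with _open_maybe_gz(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def demultiplex(
    fastq_in: str | Path,
    specs: list[BarcodeSpec],
    outdir: str | Path,
    min_hits: int = 1,
    search_prefix_bp: int = 200,
    reorient: bool = True,
    gzip_out: bool = False,
) -> pd.DataFrame:
    """Split a pooled FASTQ into per-barcode files plus ``unassigned``.

    Reads assigned on the reverse strand are re-oriented to the forward
    amplicon strand when ``reorient`` is set.  Returns a summary table
    (barcode, n_reads, fraction) whose counts sum to the parsed input.
    """
    _validate_specs(specs)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_out else ".fastq"
    handles = {}
    counts: dict[str, int] = {}
    for name in [s.barcode_id for s in specs] + [UNASSIGNED]:
        handles[name] = _open_maybe_gz(outdir / f"{name}{suffix}", "w")
        counts[name] = 0
    total = 0
    try:
        for rid, seq, qual in iter_fastq(fastq_in):
            total += 1
            bid, strand = assign_read(seq, specs, min_hits, search_prefix_bp)
            if reorient and strand == "-":
                seq, qual = revcomp(seq), qual[::-1]
            handles[bid].write(f"@{rid}\n{seq}\n+\n{qual}\n")
            counts[bid] += 1
    finally:
        for fh in handles.values():
            fh.close()
    summary = pd.DataFrame(
        {
            "barcode": list(counts),
            "n_reads": list(counts.values()),
        }
    )
    summary["fraction"] = summary["n_reads"] / total if total else 0.0
    log.info("demultiplexed %d reads: %s", total, dict(counts))
    return summary
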