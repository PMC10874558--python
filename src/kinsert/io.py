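"""File ingestion helpers: FASTA, BED, barcode tables."""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .demux import BarcodeSpec
from .errors import ConfigError


def read_fasta(path: str | Path) -> dict[str, str]:
    """Record id -> uppercase sequence (gzip transparent)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ConfigError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def read_bed(path: str | Path) -> tuple[tuple[str, int, int], ...]:
    """BED intervals (0-based half-open) as (contig, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigError(f"malformed BED line: {line!r}")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return tuple(out)


def read_barcode_table(path: str | Path) -> list[BarcodeSpec]:
    """TSV with columns barcode_id, barcode, primer."""
    df = pd.read_csv(path, sep="\t")
    required = {"barcode_id", "barcode", "primer"}
    if not required.issubset(df.columns):
        raise ConfigError(f"barcode table must have columns {sorted(required)}")
    return [
        BarcodeSpec(str(r.barcode_id), str(r.barcode), str(r.primer))
        for r in df.itertuples()
    ]
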