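"""Run configuration: a single structured YAML file naming references,
inputs, and all stage parameters.

Schema (keys with defaults may be omitted)::

    fastq: reads.fastq.gz
    references:
      fasta: references.fasta      # named records
      left_flank: left_flank       # record id of the left retained flank
      right_flank: right_flank
      left_arm_length: 85          # arm = inner edge of the flank
      right_arm_length: 0
      components: {B: B, F: F}     # component name -> record id
      cas9: cas9_unique            # optional scan-only records
      sgrna: sgrna_unique
      line1: line1_synthetic
      genome: genome.fasta         # optional mini-genome FASTA
      exclusions: exclusions.bed   # optional BED of excluded regions
    barcodes: barcodes.tsv
    params:
      max_pieces: 3
      window_fraction: 0.20
      rounding: nearest100
      margin: 300
      min_hits: 1
      flank_min_hits: 1
      min_identity: 80.0
      min_genomic_len: 50
      denominator: both_flanks
    outdir: out/
    seed: 0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .demux import BarcodeSpec
from .errors import ConfigError
from .foreign import ReferencePanel
from .io import read_barcode_table, read_bed, read_fasta
from .locus import FragmentComponent, FragmentLibrary, LocusModel

DEFAULT_PARAMS: dict[str, Any] = {
    "max_pieces": 3,
    "window_fraction": 0.20,
    "rounding": "nearest100",
    "margin": 300,
    "min_hits": 1,
    "flank_min_hits": 1,
    "min_identity": 80.0,
    "min_genomic_len": 50,
    "denominator": "both_flanks",
}


@dataclass
class RunConfig:
    fastq: Path
    locus: LocusModel
    library: FragmentLibrary
    barcodes: list[BarcodeSpec]
    outdir: Path
    seed: int = 0
    params: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    cas9_region: str | None = None
    sgrna_region: str | None = None
    genome: dict[str, str] | None = None
    line1: str | None = None
    raw: dict[str, Any] = field(default_factory=dict)

    def panel(self) -> ReferencePanel:
        return ReferencePanel(
            self.library,
            self.locus,
            cas9_region=self.cas9_region,
            sgrna_region=self.sgrna_region,
            genome=self.genome,
            line1=self.line1,
        )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a run configuration; fails fast on missing items."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    for key in ("fastq", "references", "barcodes", "outdir"):
        if key not in raw:
            raise ConfigError(f"missing configuration key: {key!r}")
    refs_cfg = raw["references"]
    records = read_fasta(resolve(refs_cfg["fasta"]))

    def record(name_key: str, required: bool = True) -> str | None:
        rec_id = refs_cfg.get(name_key)
        if rec_id is None:
            if required:
                raise ConfigError(f"references.{name_key} not configured")
            return None
        if rec_id not in records:
            raise ConfigError(f"record {rec_id!r} ({name_key}) missing from FASTA")
        return records[rec_id]

    left_flank = record("left_flank")
    right_flank = record("right_flank")
    left_arm_len = int(refs_cfg.get("left_arm_length", 0))
    right_arm_len = int(refs_cfg.get("right_arm_length", 0))
    exclusions = ()
    if refs_cfg.get("exclusions"):
        exclusions = read_bed(resolve(refs_cfg["exclusions"]))
    locus = LocusModel(
        left_flank=left_flank,
        right_flank=right_flank,
        left_arm=left_flank[-left_arm_len:] if left_arm_len else "",
        right_arm=right_flank[:right_arm_len] if right_arm_len else "",
        exclusion_regions=exclusions,
    )
    comp_map = refs_cfg.get("components") or {}
    if not comp_map:
        raise ConfigError("references.components must name >= 1 insertable component")
    components = []
    for name, rec_id in comp_map.items():
        if rec_id not in records:
            raise ConfigError(f"component record {rec_id!r} missing from FASTA")
        components.append(FragmentComponent(str(name), records[rec_id]))
    library = FragmentLibrary(components)

    genome = None
    if refs_cfg.get("genome"):
        genome = read_fasta(resolve(refs_cfg["genome"]))

    params = dict(DEFAULT_PARAMS)
    params.update(raw.get("params") or {})

    return RunConfig(
        fastq=resolve(raw["fastq"]),
        locus=locus,
        library=library,
        barcodes=read_barcode_table(resolve(raw["barcodes"])),
        outdir=resolve(raw["outdir"]),
        seed=int(raw.get("seed", 0)),
        params=params,
        cas9_region=record("cas9", required=False),
        sgrna_region=record("sgrna", required=False),
        genome=genome,
        line1=record("line1", required=False),
        raw=raw,
    )


def dump_effective_config(config: RunConfig, path: str | Path) -> None:
    """Archive the effective configuration next to the outputs."""
    payload = dict(config.raw)
    payload["params"] = dict(config.params)
    payload["seed"] = config.seed
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
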