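"""End-to-end orchestration: demux -> pattern calling -> repair ->
foreign scan -> deletion metrics -> aggregate report.

Each stage writes its tables under the run output directory so stages are
independently inspectable; the effective configuration is archived next
to the outputs, making a run reproducible byte-for-byte given the seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import (
    ComponentProbes,
    FlankProbes,
    ReadCall,
    call_pattern,
    check_flanks,
    compute_proportions,
)
from .config import RunConfig, dump_effective_config
from .deletions import deletion_report, gaps_from_reads
from .demux import demultiplex, iter_fastq
from .foreign import classify_foreign
from .locus import enumerate_categories
from .repair import classify_repair, is_forward_single_donor, summarize_repair

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def _calls_table(calls: list[ReadCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "read_length": c.read_length,
                "has_left": c.has_left,
                "has_right": c.has_right,
                "strand": c.strand or "",
                "amplicon_length": c.amplicon_length or 0,
                "candidates": ",".join(c.candidates),
                "category": c.category,
                "pattern": str(c.pattern) if c.pattern else "",
                "hits": ";".join(f"{k}={v}" for k, v in sorted(c.hits.items())),
                "route": c.route,
            }
            for c in calls
        ]
    )


def pattern_references(config: RunConfig, max_pieces: int | None = None) -> dict[str, str]:
    """Alignment-ready reference sequences for every orientation pattern
    (flankL + oriented components + flankR), for external IGV inspection."""
    from .locus import enumerate_orientation_patterns
    from .seq import revcomp

    locus, library = config.locus, config.library
    refs = {"background": locus.background_sequence}
    for n in range(1, (max_pieces or config.params["max_pieces"]) + 1):
        for pattern in enumerate_orientation_patterns(n, library):
            seq = locus.left_flank
            for name, orient in pattern.chain:
                frag = library.get(name).sequence
                seq += frag if orient == "f" else revcomp(frag)
            seq += locus.right_flank
            refs[str(pattern)] = seq
    return refs


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the aggregate report (also written as
    JSON under the output directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_effective_config(config, outdir / "effective_config.yaml")
    params = config.params

    categories = enumerate_categories(
        config.library,
        config.locus,
        max_pieces=params["max_pieces"],
        fraction=params["window_fraction"],
        rounding=params["rounding"],
    )
    pd.DataFrame(
        [
            {
                "category": c.name,
                "composition": "+".join(c.composition),
                "expected_length": c.expected_length,
                "window_lo": c.window[0],
                "window_hi": c.window[1],
            }
            for c in categories
        ]
    ).to_csv(outdir / "categories.tsv", sep="\t", index=False)

    flanks = FlankProbes.from_locus(config.locus)
    screen_extra = [s for s in (config.cas9_region, config.sgrna_region, config.line1) if s]
    comp_probes = ComponentProbes.from_library(
        config.library, config.locus, screen_against=screen_extra
    )
    panel = config.panel()

    demux_dir = outdir / "demux"
    summary = demultiplex(config.fastq, config.barcodes, demux_dir)
    summary.to_csv(outdir / "demux_summary.tsv", sep="\t", index=False)
    log.info("demultiplexed:\n%s", summary)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "demux": summary.to_dict(orient="records"),
        "samples": {},
    }

    for spec in config.barcodes:
        fastq = demux_dir / f"{spec.barcode_id}.fastq"
        reads = list(iter_fastq(fastq))
        sample_dir = outdir / spec.barcode_id
        sample_dir.mkdir(exist_ok=True)

        calls = [
            call_pattern(
                seq,
                rid,
                categories,
                config.locus,
                comp_probes,
                flanks,
                min_hits=params["min_hits"],
                flank_min_hits=params["flank_min_hits"],
                margin=params["margin"],
            )
            for rid, seq, _ in reads
        ]
        _calls_table(calls).to_csv(sample_dir / "calls.tsv", sep="\t", index=False)
        props = compute_proportions(calls, params["denominator"])
        props.per_pattern.to_csv(sample_dir / "proportions_pattern.tsv", sep="\t", index=False)
        props.per_category.to_csv(sample_dir / "proportions_category.tsv", sep="\t", index=False)
        props.groups.to_csv(sample_dir / "proportions_group.tsv", sep="\t", index=False)

        seq_by_id = {rid: seq for rid, seq, _ in reads}
        # repair classification of forward single-donor insertions
        repair_calls = []
        for c in calls:
            if not is_forward_single_donor(c):
                continue
            ev = check_flanks(seq_by_id[c.read_id], flanks, params["flank_min_hits"])
            if ev.anchor is None:
                continue
            repair_calls.append(
                classify_repair(
                    ev.oriented_read,
                    c.read_id,
                    config.locus,
                    c.pattern,
                    comp_probes.lengths,
                    anchor=ev.anchor,
                    min_identity=params["min_identity"],
                )
            )
        repair_summary = summarize_repair(repair_calls)
        repair_summary.to_csv(sample_dir / "repair_summary.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "read_id": r.read_id,
                    "verdict": r.verdict,
                    "left_copies": r.copies.get("left"),
                    "right_copies": r.copies.get("right"),
                    "reason": r.reason,
                }
                for r in repair_calls
            ]
        ).to_csv(sample_dir / "repair_calls.tsv", sep="\t", index=False)

        # foreign-insert annotation of unexplained insert-bearing reads
        foreign_rows = []
        for c in calls:
            if c.route != "foreign":
                continue
            ev = check_flanks(seq_by_id[c.read_id], flanks, params["flank_min_hits"])
            fc = classify_foreign(
                ev.oriented_read,
                c.read_id,
                panel,
                min_len=params["min_genomic_len"],
                min_identity=params["min_identity"],
            )
            for seg in fc.segments:
                foreign_rows.append(
                    {
                        "read_id": fc.read_id,
                        "class": seg.klass,
                        "qstart": seg.qstart,
                        "qend": seg.qend,
                        "ref": seg.ref_name,
                        "rstart": seg.rstart,
                        "rend": seg.rend,
                        "strand": seg.strand,
                        "identity": round(seg.identity, 2),
                        "compound": fc.compound,
                    }
                )
        foreign_df = pd.DataFrame(
            foreign_rows,
            columns=[
                "read_id", "class", "qstart", "qend", "ref",
                "rstart", "rend", "strand", "identity", "compound",
            ],
        )
        foreign_df.to_csv(sample_dir / "foreign_segments.tsv", sep="\t", index=False)

        # deletion metrics over insert-free reads
        del_pool = []
        for c in calls:
            if c.route in ("background", "deletion"):
                ev = check_flanks(seq_by_id[c.read_id], flanks, params["flank_min_hits"])
                if ev.anchor is not None:
                    del_pool.append((c.read_id, ev.oriented_read[ev.anchor - 1 :]))
        gaps = gaps_from_reads(del_pool, config.locus)
        del_report = deletion_report(gaps, config.locus)
        del_report.per_read.to_csv(sample_dir / "deletion_per_read.tsv", sep="\t", index=False)

        lengths = pd.Series([len(seq) for _, seq, _ in reads])
        lengths.to_frame("read_length").to_csv(sample_dir / "read_lengths.tsv", sep="\t", index=False)

        n_called = sum(1 for c in calls if c.pattern is not None)
        log.info(
            "%s: parsed=%d both_flanks=%d called=%d ambiguous=%d",
            spec.barcode_id,
            len(calls),
            props.denominator,
            n_called,
            sum(1 for c in calls if c.category == "ambiguous"),
        )
        report["samples"][spec.barcode_id] = {
            "n_reads": len(calls),
            "denominator": props.denominator,
            "groups": props.groups.to_dict(orient="records"),
            "categories": props.per_category.to_dict(orient="records"),
            "repair": repair_summary.to_dict(orient="records"),
            "foreign_class_counts": foreign_df["class"].value_counts().to_dict(),
            "deletion_index": del_report.deletion_index,
            "d100": del_report.d100,
            "deletion_n_reads": del_report.n_reads,
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
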