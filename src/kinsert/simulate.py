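"""Synthetic barcoded nanopore-like amplicon reads with full ground truth.

The generator emulates every phenomenon the pipeline classifies: reads of
the form ``barcode+primer + left_flank + fragment chain + right_flank``
with forward/reverse fragments, optional truncation, HDR arm collapse vs
NHEJ arm duplication, rare foreign inserts (genomic segments, LINE-1
fragments, circular editing-plasmid remnants, degraded donor pieces),
large deletions through the cut, random strand flips, and an
indel-dominated per-base error model (~5% total, as typical of nanopore
chemistry).  Every read is recorded in a truth table for recovery
testing.

All reference sequences are generated random DNA with realistic printed
lengths (flanks 146/186 bp, backbone 2174 bp, cassette 5526 bp); no real
locus or donor sequence is required.  The LINE-1 record is a synthetic
stand-in consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import edlib
import numpy as np
import pandas as pd

from .calling import ComponentProbes, FlankProbes
from .demux import BarcodeSpec, write_fastq
from .errors import ConfigError
from .foreign import CAS9, GENOMIC, LINE1, SGRNA, ReferencePanel
from .locus import FragmentComponent, FragmentLibrary, LocusModel, OrientationPattern
from .seq import revcomp

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

FOREIGN_TOKENS = ("genomic", "line1", "cas9", "sgrna", "short-F", "short-B")
SPECIAL_TOKENS = ("background", "decoy", "deletion")

QUAL_CHAR = "-"  # constant Q12 placeholder; qualities are never used


def random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass
class RefBundle:
    """A coherent synthetic reference set for one simulated study."""

    locus: LocusModel
    library: FragmentLibrary
    cas9_region: str
    sgrna_region: str
    genome: dict[str, str]
    line1: str
    barcodes: list[BarcodeSpec]
    primer: str
    donor_component: str = "F"

    def panel(self) -> ReferencePanel:
        return ReferencePanel(
            self.library,
            self.locus,
            cas9_region=self.cas9_region,
            sgrna_region=self.sgrna_region,
            genome=self.genome,
            line1=self.line1,
        )

    def flank_probes(self) -> FlankProbes:
        return FlankProbes.from_locus(self.locus)

    def component_probes(self) -> ComponentProbes:
        return ComponentProbes.from_library(
            self.library,
            self.locus,
            screen_against=[self.cas9_region, self.sgrna_region, self.line1],
        )


def _make_barcodes(rng: np.random.Generator, n: int, primer: str, min_distance: int = 5) -> list[BarcodeSpec]:
    """Random 11-nt barcodes with pairwise tag edit distance >= min_distance."""
    specs: list[BarcodeSpec] = []
    attempts = 0
    while len(specs) < n:
        attempts += 1
        if attempts > 1000:
            raise ConfigError("could not generate well-separated barcodes")
        bc = random_dna(rng, 11)
        tag = bc + primer[:6]
        if all(
            edlib.align(tag, s.tag, task="distance")["editDistance"] >= min_distance
            for s in specs
        ):
            specs.append(BarcodeSpec(f"bc{len(specs) + 1:02d}", bc, primer))
    return specs


def synthetic_references(
    seed: int = 0,
    left_flank_len: int = 146,
    right_flank_len: int = 186,
    backbone_len: int = 2174,
    cassette_len: int = 5526,
    left_arm_len: int = 85,
    right_arm_len: int = 0,
    n_barcodes: int = 4,
    cas9_region_len: int = 4000,
    sgrna_region_len: int = 1200,
    line1_len: int = 3000,
) -> RefBundle:
    """Generate a full synthetic reference set.

    The donor cassette ``F`` embeds the homology arms at its ends (the
    left arm is the terminal ``left_arm_len`` bases of the left flank, the
    right arm the leading bases of the right flank), so NHEJ capture
    duplicates the arm and HDR collapses it — exactly the evidence the
    repair classifier reads out.  The mini-genome carries a copy of the
    amplicon on ``chr5`` (covered by an exclusion region, mirroring the
    locus-homology filter) plus neutral contigs that foreign genomic
    segments are sampled from.
    """
    rng = np.random.default_rng(seed)
    left_flank = random_dna(rng, left_flank_len)
    right_flank = random_dna(rng, right_flank_len)
    left_arm = left_flank[-left_arm_len:] if left_arm_len else ""
    right_arm = right_flank[:right_arm_len] if right_arm_len else ""

    core_len = cassette_len - len(left_arm) - len(right_arm)
    if core_len <= 0:
        raise ConfigError("arms longer than the cassette")
    cassette = left_arm + random_dna(rng, core_len) + right_arm
    backbone = random_dna(rng, backbone_len)

    genome = {
        "chr1": random_dna(rng, 8000),
        "chr2": random_dna(rng, 6000),
        "chr3": random_dna(rng, 6000),
        "chr4": random_dna(rng, 6000),
    }
    # chr5 embeds the locus amplicon (homolog of the flanks); excluded.
    amplicon = left_flank + right_flank
    chr5 = random_dna(rng, 1500) + amplicon + random_dna(rng, 1500)
    genome["chr5"] = chr5
    exclusions = (("chr5", 1500, 1500 + len(amplicon)),)

    locus = LocusModel(
        left_flank=left_flank,
        right_flank=right_flank,
        left_arm=left_arm,
        right_arm=right_arm,
        exclusion_regions=exclusions,
    )
    library = FragmentLibrary(
        [
            FragmentComponent("B", backbone),
            FragmentComponent("F", cassette),
        ]
    )
    primer = random_dna(rng, 24)
    return RefBundle(
        locus=locus,
        library=library,
        cas9_region=random_dna(rng, cas9_region_len),
        sgrna_region=random_dna(rng, sgrna_region_len),
        genome=genome,
        line1=random_dna(rng, line1_len),
        barcodes=_make_barcodes(rng, n_barcodes, primer),
        primer=primer,
    )


@dataclass
class SimulationConfig:
    """Generative counterpart of every detector in the pipeline.

    ``weights`` mixes read classes: orientation-pattern chains in the
    compact notation (``"Bf"``, ``"Ff+Br"``), ``"background"``,
    ``"deletion"`` (large deletion through the cut), ``"decoy"`` (random
    DNA with a barcode), and foreign tokens (``"genomic"``, ``"line1"``,
    ``"cas9"``, ``"sgrna"``, ``"short-F"``, ``"short-B"``, joinable with
    ``+`` into compound chains).  Weights must be non-negative and sum
    to 1.
    """

    refs: RefBundle
    weights: dict[str, float]
    n_reads: int = 1000
    seed: int = 0
    error_rate: float = 0.05
    indel_fraction: float = 0.7  # of errors; split evenly insertion/deletion
    hdr_fraction: float = 0.5  # among forward single-donor insertions
    truncation_prob: float = 0.0  # per donor fragment
    truncation_min_frac: float = 0.05
    deletion_size: tuple[int, int] = (101, 400)
    strand_flip_prob: float = 0.5

    def validate(self) -> None:
        if not self.weights:
            raise ConfigError("empty pattern mixture")
        total = sum(self.weights.values())
        if any(w < -1e-9 for w in self.weights.values()) or abs(total - 1.0) > 1e-6:
            raise ConfigError(f"mixture weights must be >= 0 and sum to 1 (got {total})")
        if not (0 <= self.error_rate < 1):
            raise ConfigError("error_rate must be in [0, 1)")
        for token in self.weights:
            _parse_token(token, self.refs.library)


def _parse_token(token: str, library: FragmentLibrary):
    """Classify a mixture token: special, donor chain, or foreign chain."""
    if token in SPECIAL_TOKENS:
        return ("special", token)
    parts = token.split("+")
    if all(p in FOREIGN_TOKENS for p in parts):
        return ("foreign", parts)
    try:
        pattern = OrientationPattern.parse(token)
    except ConfigError:
        raise ConfigError(f"unknown mixture token: {token!r}") from None
    for name, _ in pattern.chain:
        if name not in library:
            raise ConfigError(f"unknown component {name!r} in token {token!r}")
    return ("donor", pattern)


def apply_noise(
    seq: str, error_rate: float, indel_fraction: float, rng: np.random.Generator
) -> str:
    """Independent per-base errors: 1-bp insertions/deletions (the indel
    fraction, split evenly) and substitutions (the remainder)."""
    if error_rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    err = rng.random(n) < error_rate
    kind = rng.random(n)
    ins = err & (kind < indel_fraction / 2)
    dele = err & ~ins & (kind < indel_fraction)
    sub = err & (kind >= indel_fraction)
    if sub.any():
        idx = np.searchsorted(_BASES, arr[sub])
        arr[sub] = _BASES[(idx + rng.integers(1, 4, size=int(sub.sum()))) % 4]
    counts = np.ones(n, dtype=np.int64)
    counts[dele] = 0
    counts[ins] = 2
    out = np.repeat(arr, counts)
    if ins.any():
        starts = np.cumsum(counts) - counts
        out[starts[ins]] = _BASES[rng.integers(0, 4, size=int(ins.sum()))]
    return out.tobytes().decode()


@dataclass
class TruthSegment:
    klass: str
    qstart: int
    qend: int
    ref: str
    rstart: int
    rend: int
    strand: str

    def __str__(self):
        return f"{self.klass}:{self.qstart}-{self.qend}:{self.ref}:{self.rstart}-{self.rend}:{self.strand}"


def _sample_interval(rng: np.random.Generator, length: int, total: int) -> tuple[int, int]:
    """Random 1-based inclusive interval of ``length`` within ``total``."""
    start = int(rng.integers(0, total - length + 1))
    return start + 1, start + length


def _foreign_piece(
    token: str, refs: RefBundle, rng: np.random.Generator, compound: bool = False
) -> tuple[str, str, str, int, int, str]:
    """(sequence, class, ref_name, rstart, rend, strand) for one token.

    Donor pieces inside compound chains are sampled below half the full
    fragment length (degraded tandem pieces are predominantly short).
    """
    strand = "+" if rng.random() < 0.5 else "-"
    if token == "genomic":
        contigs = [c for c in ("chr1", "chr2", "chr3", "chr4") if c in refs.genome]
        contig = contigs[int(rng.integers(0, len(contigs)))]
        src = refs.genome[contig]
        if rng.random() < 0.97:
            length = int(rng.integers(60, 401))
        else:
            length = int(rng.integers(401, 3001))
        rstart, rend = _sample_interval(rng, length, len(src))
        klass, ref_name = GENOMIC, contig
    elif token == "line1":
        src = refs.line1
        length = int(rng.integers(100, min(1506, len(src)) + 1))
        rstart, rend = len(src) - length + 1, len(src)  # 3' fragment: always truncated
        klass, ref_name = LINE1, "line1"
    elif token == "cas9":
        src = refs.cas9_region
        if rng.random() < 0.7:
            length = int(rng.integers(150, 501))
        else:
            length = int(rng.integers(2800, min(3201, len(src) + 1)))
        rstart, rend = _sample_interval(rng, length, len(src))
        klass, ref_name = CAS9, "cas9"
    elif token == "sgrna":
        src = refs.sgrna_region
        length = int(np.clip(rng.normal(300, 80), 60, 800))
        rstart, rend = _sample_interval(rng, length, len(src))
        klass, ref_name = SGRNA, "sgrna"
    elif token in ("short-F", "short-B"):
        comp = refs.library.get(token[-1])
        hi = {"short-B": 1600, "short-F": 4300}[token]
        if compound:
            hi = comp.length // 2
        length = int(rng.integers(200, hi + 1))
        rstart, rend = _sample_interval(rng, length, comp.length)
        src = comp.sequence
        klass, ref_name = token, comp.name
    else:  # pragma: no cover - guarded by validate()
        raise ConfigError(f"unknown foreign token {token!r}")
    piece = src[rstart - 1 : rend]
    if strand == "-":
        piece = revcomp(piece)
    return piece, klass, ref_name, rstart, rend, strand


def make_insert(
    token: str,
    refs: RefBundle,
    rng: np.random.Generator,
    hdr_fraction: float = 0.0,
    truncation_prob: float = 0.0,
    truncation_min_frac: float = 0.05,
) -> dict:
    """Build the insert sequence and truth fields for one mixture token."""
    kind, parsed = _parse_token(token, refs.library)
    locus = refs.locus
    out = {
        "pattern": "",
        "repair": "",
        "truncated": "",
        "segments": [],
        "insert": "",
    }
    if kind == "special":
        return out
    if kind == "foreign":
        qpos = 0
        pieces = []
        for tok in parsed:
            piece, klass, ref_name, rstart, rend, strand = _foreign_piece(
                tok, refs, rng, compound=len(parsed) > 1
            )
            out["segments"].append(
                TruthSegment(klass, qpos + 1, qpos + len(piece), ref_name, rstart, rend, strand)
            )
            pieces.append(piece)
            qpos += len(piece)
        out["insert"] = "".join(pieces)
        return out
    # donor chain
    pattern: OrientationPattern = parsed
    out["pattern"] = str(pattern)
    hdr = False
    if (
        hdr_fraction > 0
        and len(pattern.chain) == 1
        and pattern.chain[0] == (refs.donor_component, "f")
        and rng.random() < hdr_fraction
    ):
        hdr = True
    pieces = []
    trunc_flags = []
    for name, orient in pattern.chain:
        frag = refs.library.get(name).sequence
        if hdr:
            # HDR collapses the duplicated arm copies at both junctions
            frag = frag[len(locus.left_arm) : len(frag) - len(locus.right_arm) or None]
        truncated = False
        if truncation_prob > 0 and rng.random() < truncation_prob:
            truncated = True
            keep = int(len(frag) * rng.uniform(truncation_min_frac, 0.999))
            keep = max(1, keep)
            if rng.random() < 0.5:
                frag = frag[:keep]
            else:
                frag = frag[-keep:]
        trunc_flags.append("1" if truncated else "0")
        pieces.append(frag if orient == "f" else revcomp(frag))
    if len(pattern.chain) == 1 and pattern.chain[0][0] == refs.donor_component:
        out["repair"] = ("HDR" if hdr else "NHEJ") if pattern.chain[0][1] == "f" else ""
    out["truncated"] = ";".join(trunc_flags)
    out["insert"] = "".join(pieces)
    return out


@dataclass
class SimResult:
    reads: list[tuple[str, str, str]]  # (id, seq, qual)
    truth: pd.DataFrame
    config: SimulationConfig


def simulate_dataset(config: SimulationConfig) -> SimResult:
    """Generate reads + truth table; byte-deterministic under the seed."""
    config.validate()
    refs = config.refs
    rng = np.random.default_rng(config.seed)
    tokens = list(config.weights)
    probs = np.clip(np.array([config.weights[t] for t in tokens], dtype=float), 0, None)
    probs = probs / probs.sum()
    choices = rng.choice(len(tokens), size=config.n_reads, p=probs)

    reads = []
    rows = []
    locus = refs.locus
    for i, token_idx in enumerate(choices):
        token = tokens[int(token_idx)]
        rid = f"read{i:06d}"
        spec = refs.barcodes[int(rng.integers(0, len(refs.barcodes)))]
        kind, _ = _parse_token(token, refs.library)
        del_start = del_end = 0
        if token == "decoy":
            amplicon = random_dna(rng, int(rng.integers(300, 3001)))
            insert_info = {"pattern": "", "repair": "", "truncated": "", "segments": [], "insert": ""}
        elif token == "deletion":
            # a cut-spanning deletion that leaves detectable flank remnants
            remnant = 60
            size = int(rng.integers(config.deletion_size[0], config.deletion_size[1] + 1))
            size = min(size, locus.background_length - 2 * remnant - 1)
            cut = locus.cut_position
            lo_min = max(remnant + 1, cut - size + 1)
            lo_max = min(cut, locus.background_length - remnant - size + 1)
            lo = int(rng.integers(lo_min, max(lo_min, lo_max) + 1))
            hi = lo + size - 1
            bg = locus.background_sequence
            amplicon = bg[: lo - 1] + bg[hi:]
            del_start, del_end = lo, hi
            insert_info = {"pattern": "", "repair": "", "truncated": "", "segments": [], "insert": ""}
        else:
            insert_info = make_insert(
                token,
                refs,
                rng,
                hdr_fraction=config.hdr_fraction,
                truncation_prob=config.truncation_prob,
                truncation_min_frac=config.truncation_min_frac,
            )
            amplicon = locus.left_flank + insert_info["insert"] + locus.right_flank

        clean = spec.barcode + spec.primer + amplicon
        strand = "+"
        if rng.random() < config.strand_flip_prob:
            strand = "-"
        noisy = apply_noise(clean, config.error_rate, config.indel_fraction, rng)
        if strand == "-":
            noisy = revcomp(noisy)
        reads.append((rid, noisy, QUAL_CHAR * len(noisy)))
        rows.append(
            {
                "read_id": rid,
                "token": token,
                "kind": kind,
                "barcode": spec.barcode_id,
                "strand": strand,
                "pattern": insert_info["pattern"],
                "repair": insert_info["repair"],
                "truncated": insert_info["truncated"],
                "segments": ";".join(str(s) for s in insert_info["segments"]),
                "del_start": del_start,
                "del_end": del_end,
                "insert_length": len(insert_info["insert"]),
                "amplicon_length": len(amplicon) if token != "decoy" else 0,
                "pre_noise_length": len(clean),
            }
        )
    truth = pd.DataFrame(rows)
    return SimResult(reads=reads, truth=truth, config=config)


def study_mixture(
    single_F: float = 0.4024,
    single_B: float = 0.4447,
    complete_donor: float = 0.1416,
    forward_fraction_F: float = 0.38,
) -> dict[str, float]:
    """The published single-fragment / complete-donor share mixture.

    The two-piece complete-donor weight is spread evenly over its eight
    orientation chains; the remainder is spread evenly over one
    representative chain of each remaining multi-fragment category.
    """
    weights: dict[str, float] = {
        "Ff": single_F * forward_fraction_F,
        "Fr": single_F * (1 - forward_fraction_F),
        "Bf": single_B / 2,
        "Br": single_B / 2,
    }
    bf_chains = ["Bf+Ff", "Bf+Fr", "Br+Ff", "Br+Fr", "Ff+Bf", "Ff+Br", "Fr+Bf", "Fr+Br"]
    for chain in bf_chains:
        weights[chain] = complete_donor / len(bf_chains)
    rest = 1.0 - single_F - single_B - complete_donor
    others = ["Bf+Bf", "Ff+Ff", "Bf+Bf+Ff", "Bf+Ff+Fr", "Bf+Br+Bf", "Ff+Fr+Ff"]
    for chain in others:
        weights[chain] = rest / len(others)
    return weights


def write_simulation(result: SimResult, outdir: str | Path, gzip_fastq: bool = True) -> dict:
    """Write FASTQ, truth TSV and reference FASTA/BED files for a run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fastq = outdir / ("reads.fastq.gz" if gzip_fastq else "reads.fastq")
    write_fastq(fastq, result.reads)
    truth_path = outdir / "truth.tsv"
    result.truth.to_csv(truth_path, sep="\t", index=False)
    refs = result.config.refs
    refs_path = outdir / "references.fasta"
    with open(refs_path, "w") as fh:
        fh.write(f">left_flank\n{refs.locus.left_flank}\n>right_flank\n{refs.locus.right_flank}\n")
        for comp in refs.library:
            fh.write(f">{comp.name}\n{comp.sequence}\n")
        fh.write(f">cas9_unique\n{refs.cas9_region}\n>sgrna_unique\n{refs.sgrna_region}\n")
        fh.write(f">line1_synthetic\n{refs.line1}\n")
    genome_path = outdir / "genome.fasta"
    with open(genome_path, "w") as fh:
        for contig, seq in refs.genome.items():
            fh.write(f">{contig}\n{seq}\n")
    bed_path = outdir / "exclusions.bed"
    with open(bed_path, "w") as fh:
        for contig, lo, hi in refs.locus.exclusion_regions:
            fh.write(f"{contig}\t{lo}\t{hi}\n")
    barcodes_path = outdir / "barcodes.tsv"
    pd.DataFrame(
        [
            {"barcode_id": s.barcode_id, "barcode": s.barcode, "primer": s.primer}
            for s in refs.barcodes
        ]
    ).to_csv(barcodes_path, sep="\t", index=False)
    return {
        "fastq": fastq,
        "truth": truth_path,
        "references": refs_path,
        "genome": genome_path,
        "exclusions": bed_path,
        "barcodes": barcodes_path,
    }
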