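"""Foreign-insert extraction, gating, and segment annotation."""

import numpy as np
import pytest

import kinsert as K
from kinsert.foreign import (
    CAS9,
    GENOMIC,
    LINE1,
    SGRNA,
    classify_foreign,
    detect_degraded_donor,
    detect_line1,
    extract_insert,
    scan_plasmid_fragments,
    segment_insert,
)
from kinsert.seq import revcomp
from kinsert.simulate import SimulationConfig, random_dna, simulate_dataset


def _read(refs, insert=""):
    return refs.locus.left_flank + insert + refs.locus.right_flank


class TestExtractInsert:
    def test_background_read_empty_insert(self, refs, panel):
        insert, left_edge, right_edge, flag = extract_insert(_read(refs), refs.locus)
        assert insert == "" and flag == ""
        assert left_edge == len(refs.locus.left_flank)
        assert right_edge == left_edge + 1

    def test_spike_recovered_exactly(self, refs):
        rng = np.random.default_rng(0)
        spike = random_dna(rng, 300)
        insert, *_ , flag = extract_insert(_read(refs, spike), refs.locus)
        assert insert == spike and flag == ""

    def test_flanks_out_of_order_flagged(self, refs):
        read = refs.locus.right_flank + refs.locus.left_flank
        insert, _, _, flag = extract_insert(read, refs.locus)
        assert insert == "" and flag != ""

    def test_deletion_through_cut_flagged(self, refs):
        bg = refs.locus.background_sequence
        read = bg[:100] + bg[250:]
        insert, _, _, flag = extract_insert(read, refs.locus)
        assert insert == ""


class TestGenomicLengthFilter:
    def test_only_segments_of_fifty_bp_or_more_reported(self, refs, panel):
        """Spikes of {30, 49, 50, 51, 400, 5912} bp: exactly those >= 50
        survive the minimum-length filter."""
        for length in (30, 49, 50, 51, 400, 5912):
            spike = refs.genome["chr1"][1000 : 1000 + length]
            segments = K.align_insert_to_genome(spike, panel)
            if length >= 50:
                assert len(segments) == 1, length
                seg = segments[0]
                assert seg.ref_name == "chr1"
                assert (seg.qstart, seg.qend) == (1, length)
                assert (seg.rstart, seg.rend) == (1001, 1000 + length)
            else:
                assert segments == [], length

    def test_exclusion_region_suppresses_call(self, refs, panel):
        contig, lo, hi = refs.locus.exclusion_regions[0]
        spike = refs.genome[contig][lo + 10 : lo + 310]
        assert K.align_insert_to_genome(spike, panel) == []

    def test_highest_identity_chromosome_wins(self, refs):
        """A segment present verbatim on one contig and with mutations on
        another is attributed to the higher-identity source."""
        rng = np.random.default_rng(1)
        segment = refs.genome["chr2"][2000:2400]
        mutated = list(segment)
        for pos in rng.choice(len(mutated), size=20, replace=False):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        genome = dict(refs.genome)
        genome["chr9"] = random_dna(rng, 1000) + "".join(mutated) + random_dna(rng, 1000)
        panel2 = K.ReferencePanel(
            refs.library, refs.locus, genome=genome, line1=refs.line1
        )
        segments = K.align_insert_to_genome(segment, panel2)
        assert len(segments) == 1
        assert segments[0].ref_name == "chr2"
        assert segments[0].identity == 100.0


class TestDegradedDonorGates:
    def test_short_backbone_called_inside_gates(self, refs, panel):
        piece = refs.library.get("B").sequence[100:1600]  # 1500 bp
        read = _read(refs, piece)
        assert detect_degraded_donor(len(read), piece, panel) == ["short-B"]

    def test_read_length_gate_enforced(self, refs, panel):
        piece = refs.library.get("B").sequence[:1690]  # insert < 1700 but read >= 2000
        read = _read(refs, piece)
        assert len(read) >= 2000
        assert detect_degraded_donor(len(read), piece, panel) == []

    def test_full_length_backbone_not_degraded(self, refs, panel):
        piece = refs.library.get("B").sequence  # 2174 bp >= 80% of itself
        read = _read(refs, piece)
        assert detect_degraded_donor(len(read), piece, panel) == []

    def test_short_cassette_gates(self, refs, panel):
        ok = refs.library.get("F").sequence[500:4800]  # 4300 bp < 4400
        too_long = refs.library.get("F").sequence[:4500]  # >= 4400
        assert detect_degraded_donor(len(_read(refs, ok)), ok, panel) == ["short-F"]
        assert detect_degraded_donor(len(_read(refs, too_long)), too_long, panel) == []


class TestPlasmidScan:
    def test_u6_insert_detected(self, refs, panel):
        piece = refs.sgrna_region[200:500]  # 300 bp, the typical size
        assert SGRNA in scan_plasmid_fragments(piece, panel)

    def test_donor_read_has_no_plasmid_hits(self, refs, panel):
        assert scan_plasmid_fragments(refs.library.get("F").sequence, panel) == {}

    def test_reverse_orientation_detected(self, refs, panel):
        piece = revcomp(refs.cas9_region[500:900])
        assert CAS9 in scan_plasmid_fragments(piece, panel)


class TestCompoundInserts:
    def test_backbone_genomic_line1_chain_ordered(self, refs, panel):
        b = refs.library.get("B").sequence[200:1000]
        g = refs.genome["chr3"][3000:3300]
        l1 = refs.line1[-600:]
        call = classify_foreign(_read(refs, b + g + l1), "r1", panel)
        assert [s.klass for s in call.segments] == ["short-B", GENOMIC, LINE1]
        assert call.compound
        starts = [s.qstart for s in call.segments]
        assert starts == sorted(starts)

    def test_line1_truncated_fragment_length(self, refs, panel):
        frag = refs.line1[-1505:]
        segments = detect_line1(frag, panel)
        assert len(segments) == 1
        seg = segments[0]
        assert seg.klass == LINE1
        assert seg.rend == len(refs.line1)
        assert seg.length == 1505

    def test_unrelated_insert_yields_nothing(self, refs, panel):
        rng = np.random.default_rng(3)
        assert detect_line1(random_dna(rng, 400), panel) == []


class TestFlankingRuleInvariant:
    def test_segments_lie_strictly_between_flank_edges(self, refs, panel, flank_probes):
        """Every reported segment interval falls inside the extracted
        insert, i.e. strictly between the inner flank edges."""
        from kinsert.calling import check_flanks

        weights = {"genomic": 0.4, "line1": 0.2, "cas9": 0.2, "short-B+genomic": 0.2}
        cfg = SimulationConfig(refs=refs, weights=weights, n_reads=80, seed=12, error_rate=0.05)
        result = simulate_dataset(cfg)
        n_with_segments = 0
        for rid, seq, _ in result.reads:
            ev = check_flanks(seq, flank_probes)
            if not (ev.has_left and ev.has_right):
                continue
            call = classify_foreign(ev.oriented_read, rid, panel)
            if call.flagged:
                continue
            for seg in call.segments:
                assert 1 <= seg.qstart <= seg.qend <= call.insert_length
            n_with_segments += bool(call.segments)
        assert n_with_segments > 50  # detection, not vacuity

    def test_class_counts_cover_classified_reads(self, refs, panel):
        """A read may carry several classes; per-class counts sum to at
        least the number of reads with any classification."""
        b = refs.library.get("B").sequence[300:1100]
        g = refs.genome["chr4"][100:400]
        calls = [
            classify_foreign(_read(refs, b + g), "r1", panel),
            classify_foreign(_read(refs, g), "r2", panel),
        ]
        class_counts = {}
        for c in calls:
            for k in c.classes:
                class_counts[k] = class_counts.get(k, 0) + 1
        assert sum(class_counts.values()) >= sum(1 for c in calls if c.segments)


class TestSpikeRecoveryRates:
    def test_rare_foreign_rates_recovered_within_ci(self, refs, panel, flank_probes):
        """Foreign inserts spiked at ~1% (genomic) and ~0.1% (LINE-1)
        are recovered within the binomial 95% CI of the seeded rates."""
        from kinsert.calling import check_flanks

        n = 4000
        p_gen, p_l1 = 0.01, 0.001
        weights = {"Bf": 1 - p_gen - p_l1, "genomic": p_gen, "line1": p_l1}
        cfg = SimulationConfig(refs=refs, weights=weights, n_reads=n, seed=13, error_rate=0.05)
        result = simulate_dataset(cfg)
        truth = result.truth.set_index("read_id")
        counts = {GENOMIC: 0, LINE1: 0}
        total = 0
        for rid, seq, _ in result.reads:
            ev = check_flanks(seq, flank_probes)
            if not (ev.has_left and ev.has_right):
                continue
            total += 1
            if truth.loc[rid, "kind"] != "foreign":
                continue
            call = classify_foreign(ev.oriented_read, rid, panel)
            for k in call.classes:
                if k in counts:
                    counts[k] += 1
        for klass, p in ((GENOMIC, p_gen), (LINE1, p_l1)):
            half = 1.96 * np.sqrt(p * (1 - p) / total)
            assert abs(counts[klass] / total - p) <= half + 1e-9, klass
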