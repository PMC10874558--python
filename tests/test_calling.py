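"""Flank anchoring, probe search ranges, pattern calling, proportions."""

import math

import numpy as np
import pytest

import kinsert as K
from kinsert.calling import AMBIGUOUS, BACKGROUND, check_flanks
from kinsert.seq import revcomp
from kinsert.simulate import SimulationConfig, random_dna, simulate_dataset


def _read(refs, *pieces):
    """Assemble barcode+primer+flankL+pieces+flankR."""
    spec = refs.barcodes[0]
    return (
        spec.barcode
        + spec.primer
        + refs.locus.left_flank
        + "".join(pieces)
        + refs.locus.right_flank
    )


def _frag(refs, name, orient):
    seq = refs.library.get(name).sequence
    return seq if orient == "f" else revcomp(seq)


class TestCheckFlanks:
    def test_clean_amplicon_both_flanks_forward(self, refs, flank_probes):
        ev = check_flanks(_read(refs), flank_probes)
        assert (ev.has_left, ev.has_right, ev.strand) == (True, True, "+")
        # anchor points at the first left-flank base (after barcode+primer)
        spec = refs.barcodes[0]
        assert ev.anchor == len(spec.barcode) + len(spec.primer) + 1

    def test_reverse_complement_detected_and_reoriented(self, refs, flank_probes):
        fwd = _read(refs, _frag(refs, "B", "f"))
        ev = check_flanks(revcomp(fwd), flank_probes)
        assert (ev.has_left, ev.has_right, ev.strand) == (True, True, "-")
        assert ev.oriented_read == fwd.upper()

    def test_random_dna_has_no_flanks(self, refs, flank_probes):
        rng = np.random.default_rng(7)
        ev = check_flanks(random_dna(rng, 2500), flank_probes)
        assert (ev.has_left, ev.has_right, ev.strand) == (False, False, None)


class TestProbeSearchRange:
    def test_single_backbone_printed_range(self, refs, cat_by_name):
        assert K.probe_search_range(cat_by_name["B"], refs.locus, margin=300) == (447, 2020)

    def test_zero_margin_gives_perfect_span(self, refs, cat_by_name):
        assert K.probe_search_range(cat_by_name["B"], refs.locus, margin=0) == (147, 2320)

    def test_oversize_margin_falls_back_to_full_span(self, refs, cat_by_name):
        assert K.probe_search_range(cat_by_name["B"], refs.locus, margin=2000) == (147, 2320)


class TestCallPattern:
    def _call(self, refs, categories, comp_probes, flank_probes, read):
        return K.call_pattern(
            read, "r", categories, refs.locus, comp_probes, flank_probes
        )

    def test_reverse_backbone_called(self, refs, categories, comp_probes, flank_probes):
        call = self._call(refs, categories, comp_probes, flank_probes, _read(refs, _frag(refs, "B", "r")))
        assert call.category == "B"
        assert str(call.pattern) == "Br"

    def test_complete_donor_forward_cassette_reverse_backbone(
        self, refs, categories, comp_probes, flank_probes
    ):
        read = _read(refs, _frag(refs, "F", "f"), _frag(refs, "B", "r"))
        call = self._call(refs, categories, comp_probes, flank_probes, read)
        assert call.category == "BF"
        assert str(call.pattern) == "Ff+Br"

    def test_three_piece_chain_order_recovered(self, refs, categories, comp_probes, flank_probes):
        read = _read(refs, _frag(refs, "F", "f"), _frag(refs, "B", "r"), _frag(refs, "F", "f"))
        call = self._call(refs, categories, comp_probes, flank_probes, read)
        assert str(call.pattern) == "Ff+Br+Ff"

    def test_overlapping_windows_resolved_by_probe_content(
        self, refs, categories, comp_probes, flank_probes
    ):
        """A read whose length sits in both the two-backbone and the
        single-cassette windows is assigned by which probes are present."""
        bb = cat = next(c for c in categories if c.name == "BB")
        f = next(c for c in categories if c.name == "F")
        overlap_lo = max(bb.window[0], f.window[0])
        overlap_hi = min(bb.window[1], f.window[1])
        assert overlap_lo <= overlap_hi, "windows are expected to overlap"
        # a slightly shortened single cassette falling into the overlap
        target_insert = overlap_lo + 50 - refs.locus.background_length
        frag = refs.library.get("F").sequence[:target_insert]
        call = self._call(refs, categories, comp_probes, flank_probes, _read(refs, frag))
        assert overlap_lo <= call.amplicon_length <= overlap_hi
        assert call.category == "F"
        assert str(call.pattern) == "Ff"

    def test_background_read(self, refs, categories, comp_probes, flank_probes):
        call = self._call(refs, categories, comp_probes, flank_probes, _read(refs))
        assert call.category == BACKGROUND
        assert call.route == "background"

    def test_strand_invariance(self, refs, categories, comp_probes, flank_probes):
        cfg = SimulationConfig(
            refs=refs,
            weights={"background": 0.25, "Bf": 0.25, "Ff+Br": 0.25, "Fr": 0.25},
            n_reads=60,
            seed=9,
            error_rate=0.05,
            strand_flip_prob=0.0,
        )
        result = simulate_dataset(cfg)
        for rid, seq, _ in result.reads:
            fwd = K.call_pattern(seq, rid, categories, refs.locus, comp_probes, flank_probes)
            rev = K.call_pattern(
                revcomp(seq), rid, categories, refs.locus, comp_probes, flank_probes
            )
            assert fwd.category == rev.category
            assert str(fwd.pattern) == str(rev.pattern)

    def test_called_pattern_multiset_matches_category(
        self, refs, categories, comp_probes, flank_probes
    ):
        cfg = SimulationConfig(
            refs=refs,
            weights={"Bf": 0.3, "Ff": 0.2, "Ff+Br": 0.3, "Bf+Bf+Ff": 0.2},
            n_reads=80,
            seed=10,
            error_rate=0.05,
        )
        result = simulate_dataset(cfg)
        by_name = {c.name: c for c in categories}
        for rid, seq, _ in result.reads:
            call = K.call_pattern(seq, rid, categories, refs.locus, comp_probes, flank_probes)
            if call.pattern is not None:
                assert call.pattern.composition == by_name[call.category].composition


class TestMixtureRecovery:
    def test_seeded_weights_recovered_within_three_se(
        self, refs, categories, comp_probes, flank_probes
    ):
        """Pattern shares of a noisy simulated mixture are recovered within
        3 binomial standard errors (moderate n for speed)."""
        weights = {"Bf": 0.35, "Ff": 0.30, "Ff+Br": 0.25, "Bf+Bf": 0.10}
        n = 2500
        cfg = SimulationConfig(refs=refs, weights=weights, n_reads=n, seed=21, error_rate=0.05)
        result = simulate_dataset(cfg)
        calls = K.call_reads(
            [(r[0], r[1]) for r in result.reads], categories, refs.locus, comp_probes, flank_probes
        )
        props = K.compute_proportions(calls)
        got = props.per_pattern.set_index("pattern")["proportion"]
        for token, w in weights.items():
            se = math.sqrt(w * (1 - w) / props.denominator)
            assert abs(got.get(token, 0.0) - w) <= 3 * se, token


class TestProportions:
    def test_simple_fraction(self, refs):
        calls = []
        for i in range(100):
            c = K.ReadCall(read_id=f"r{i}", read_length=3000, has_left=True, has_right=True)
            if i < 40:
                c.category = "F"
                c.pattern = K.OrientationPattern.parse("Ff")
            calls.append(c)
        props = K.compute_proportions(calls)
        row = props.per_pattern.set_index("pattern").loc["Ff"]
        assert row["count"] == 40 and row["proportion"] == pytest.approx(0.40)

    def test_zero_denominator_flagged(self):
        calls = [K.ReadCall(read_id="r", read_length=100)]  # no flanks
        props = K.compute_proportions(calls)
        assert not props.defined
        assert math.isnan(props.per_category["proportion"].iloc[0]) if len(props.per_category) else True

    def test_group_aggregation(self, refs):
        def call(pattern, category):
            c = K.ReadCall(read_id="x", read_length=1, has_left=True, has_right=True)
            c.category = category
            c.pattern = K.OrientationPattern.parse(pattern)
            return c

        calls = [
            call("Ff", "F"),
            call("Br", "B"),
            call("Ff+Br", "BF"),
            call("Bf+Bf", "BB"),
        ]
        groups = K.compute_proportions(calls).groups.set_index("group")["count"]
        assert groups["single_F"] == 1
        assert groups["single_B"] == 1
        assert groups["complete_donor"] == 1
        assert groups["compound"] == 1
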