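"""Simulator: determinism, error model, insert construction, truth table."""

import edlib
import numpy as np
import pytest

import kinsert as K
from kinsert.errors import ConfigError
from kinsert.locus import OrientationPattern
from kinsert.seq import revcomp
from kinsert.simulate import (
    SimulationConfig,
    apply_noise,
    make_insert,
    random_dna,
    simulate_dataset,
    study_mixture,
)


class TestApplyNoise:
    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 5000)
        assert apply_noise(seq, 0.0, 0.7, rng) == seq

    def test_edit_distance_tracks_error_rate(self):
        """5% per-base errors on a 10 kb sequence yield an edit distance
        near 500 (verified with an independent edit-distance oracle)."""
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 10000)
        dists = []
        for _ in range(5):
            noisy = apply_noise(seq, 0.05, 0.7, rng)
            dists.append(edlib.align(seq, noisy, task="distance")["editDistance"])
        mean = np.mean(dists)
        # alignment may explain some errors with fewer edits; allow slack
        assert 350 <= mean <= 520

    def test_substitution_only_preserves_length(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 2000)
        noisy = apply_noise(seq, 0.2, 0.0, rng)  # indel fraction 0
        assert len(noisy) == len(seq)
        assert noisy != seq
        # substituted bases always differ from the original base
        assert sum(a != b for a, b in zip(seq, noisy)) > 300

    def test_balanced_indels_keep_expected_length(self):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 20000)
        lengths = [len(apply_noise(seq, 0.05, 0.7, rng)) for _ in range(5)]
        sd = np.sqrt(20000 * 0.05 * 0.7)  # binomial bound on indel counts
        assert abs(np.mean(lengths) - 20000) < 3 * sd


class TestDeterminism:
    def test_same_seed_identical_output(self, refs):
        cfg = dict(refs=refs, weights=study_mixture(), n_reads=50, seed=77, error_rate=0.05)
        a = simulate_dataset(SimulationConfig(**cfg))
        b = simulate_dataset(SimulationConfig(**cfg))
        assert a.reads == b.reads
        assert a.truth.equals(b.truth)

    def test_different_seed_differs(self, refs):
        a = simulate_dataset(SimulationConfig(refs=refs, weights={"Bf": 1.0}, n_reads=10, seed=1))
        b = simulate_dataset(SimulationConfig(refs=refs, weights={"Bf": 1.0}, n_reads=10, seed=2))
        assert a.reads != b.reads


class TestValidation:
    def test_weights_not_summing_to_one_rejected(self, refs):
        with pytest.raises(ConfigError):
            simulate_dataset(SimulationConfig(refs=refs, weights={"Bf": 0.5}, n_reads=5))

    def test_unknown_token_rejected(self, refs):
        with pytest.raises(ConfigError):
            simulate_dataset(SimulationConfig(refs=refs, weights={"Qf": 1.0}, n_reads=5))

    def test_negative_weight_rejected(self, refs):
        with pytest.raises(ConfigError):
            simulate_dataset(
                SimulationConfig(refs=refs, weights={"Bf": 1.5, "Ff": -0.5}, n_reads=5)
            )


class TestReadConstruction:
    def test_background_reads_exact_length(self, refs):
        cfg = SimulationConfig(refs=refs, weights={"background": 1.0}, n_reads=20, seed=4, error_rate=0.0)
        result = simulate_dataset(cfg)
        prefix = len(refs.barcodes[0].barcode) + len(refs.barcodes[0].primer)
        assert all(len(seq) == 332 + prefix for _, seq, _ in result.reads)

    def test_single_backbone_reads_exact_length(self, refs):
        cfg = SimulationConfig(refs=refs, weights={"Bf": 1.0}, n_reads=20, seed=5, error_rate=0.0)
        result = simulate_dataset(cfg)
        prefix = len(refs.barcodes[0].barcode) + len(refs.barcodes[0].primer)
        assert all(len(seq) == 2506 + prefix for _, seq, _ in result.reads)

    def test_forward_cassette_insert_is_full_fragment(self, refs):
        rng = np.random.default_rng(6)
        info = make_insert("Ff", refs, rng, hdr_fraction=0.0)
        assert info["insert"] == refs.library.get("F").sequence
        assert info["repair"] == "NHEJ"

    def test_reverse_backbone_insert_is_reverse_complement(self, refs):
        rng = np.random.default_rng(7)
        info = make_insert("Br", refs, rng)
        assert info["insert"] == revcomp(refs.library.get("B").sequence)

    def test_hdr_insert_drops_arm_copy(self, refs):
        rng = np.random.default_rng(8)
        info = make_insert("Ff", refs, rng, hdr_fraction=1.0)
        arm = refs.locus.left_arm
        assert info["repair"] == "HDR"
        assert info["insert"] == refs.library.get("F").sequence[len(arm):]

    def test_genomic_spike_truth_round_trip(self, refs, panel):
        """Truth source coordinates of a genomic spike are recovered by
        insert extraction + genome alignment."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            info = make_insert("genomic", refs, rng)
            seg = info["segments"][0]
            read = refs.locus.left_flank + info["insert"] + refs.locus.right_flank
            insert, *_ = K.extract_insert(read, refs.locus)
            assert insert == info["insert"]
            found = K.align_insert_to_genome(insert, panel)
            assert len(found) == 1
            assert found[0].ref_name == seg.ref
            assert abs(found[0].rstart - seg.rstart) <= 2
            assert abs(found[0].rend - seg.rend) <= 2
            assert found[0].strand == seg.strand

    def test_truth_rows_match_emitted_reads(self, refs):
        cfg = SimulationConfig(
            refs=refs, weights={"Bf": 0.5, "genomic": 0.5}, n_reads=30, seed=10
        )
        result = simulate_dataset(cfg)
        assert list(result.truth["read_id"]) == [rid for rid, _, _ in result.reads]

    def test_truncation_flags_recorded(self, refs):
        cfg = SimulationConfig(
            refs=refs, weights={"Bf": 1.0}, n_reads=200, seed=11, error_rate=0.0,
            truncation_prob=0.3,
        )
        result = simulate_dataset(cfg)
        flags = result.truth["truncated"]
        assert (flags == "1").sum() > 20
        truth = result.truth.set_index("read_id")
        prefix = len(refs.barcodes[0].barcode) + len(refs.barcodes[0].primer)
        for rid, seq, _ in result.reads:
            if truth.loc[rid, "truncated"] == "1":
                assert len(seq) < 2506 + prefix


class TestStudyMixture:
    def test_weights_sum_to_one_and_match_reported_shares(self):
        weights = study_mixture()
        assert sum(weights.values()) == pytest.approx(1.0)
        single_F = sum(w for token, w in weights.items() if token in ("Ff", "Fr"))
        single_B = sum(w for token, w in weights.items() if token in ("Bf", "Br"))
        complete = sum(
            w
            for token, w in weights.items()
            if sorted(OrientationPattern.parse(token).composition) == ["B", "F"]
            and len(token.split("+")) == 2
        )
        assert single_F == pytest.approx(0.4024)
        assert single_B == pytest.approx(0.4447)
        assert complete == pytest.approx(0.1416)
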