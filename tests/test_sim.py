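"""Synthetic genome/read generation, the aligner stand-in and evaluation."""

import dataclasses
import filecmp

import numpy as np
import pysam
import pytest

import telocus as tlc

SMALL = tlc.SimConfig(
    consensus_length=500, spacer_length=100, total_fragments=600, seed=7
)


def small_cfg(**kwargs):
    return dataclasses.replace(SMALL, **kwargs)


class TestGenome:
    def test_zero_divergence_copies_are_identical(self):
        cfg = small_cfg(within_subfamily_divergence=0.0, identical_pairs=0)
        truth = tlc.make_te_genome(cfg)
        g = truth.genome[cfg.chrom]
        for members in truth.index.subfamily_members.values():
            seqs = {g[l.start : l.end] for l in (truth.index.get(m) for m in members)}
            assert len(seqs) == 1

    def test_divergence_rate_matches_target(self):
        cfg = small_cfg(
            n_subfamilies=1,
            copies_per_subfamily=20,
            consensus_length=1000,
            within_subfamily_divergence=0.1,
            identical_pairs=0,
        )
        truth = tlc.make_te_genome(cfg)
        g = truth.genome[cfg.chrom]
        cons = truth.consensus[0]
        fracs = [
            np.mean([a != b for a, b in zip(g[l.start : l.end], cons)])
            for l in truth.index
        ]
        assert np.mean(fracs) == pytest.approx(0.10, abs=0.02)

    def test_same_seed_reproduces_the_genome(self):
        a = tlc.make_te_genome(small_cfg())
        b = tlc.make_te_genome(small_cfg())
        assert a.genome == b.genome
        np.testing.assert_array_equal(a.truth_tpm, b.truth_tpm)

    def test_duplicate_pair_is_identical_with_silenced_member(self):
        truth = tlc.make_te_genome(small_cfg())
        g = truth.genome[truth.config.chrom]
        first, second = truth.index.loci[0], truth.index.loci[1]
        assert g[first.start : first.end] == g[second.start : second.end]
        assert truth.truth_tpm[1] == 0.0
        assert truth.truth_tpm[0] > 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"within_subfamily_divergence": 0.5},
            {"fragment_size": 60},  # < read_length
            {"consensus_length": 150},  # < fragment_size
            {"silent_fraction": 1.0},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            small_cfg(**kwargs).validate()


class TestFragments:
    def test_silent_loci_emit_no_fragments(self):
        truth = tlc.simulate_fragments(tlc.make_te_genome(small_cfg()))
        silent = set(np.flatnonzero(truth.truth_tpm == 0))
        assert silent
        assert all(f.origin not in silent for f in truth.fragments)

    def test_fragment_share_scales_with_tpm_at_equal_length(self):
        cfg = small_cfg(
            n_subfamilies=1,
            copies_per_subfamily=2,
            identical_pairs=0,
            silent_fraction=0.0,
            total_fragments=10000,
        )
        truth = tlc.make_te_genome(cfg)
        truth.truth_tpm = np.array([2e6 / 3, 1e6 / 3])
        truth = tlc.simulate_fragments(truth, cfg)
        n0 = sum(f.origin == 0 for f in truth.fragments)
        # expected 2/3 of 10,000; allow ~4 sigma of binomial noise
        assert abs(n0 - 10000 * 2 / 3) < 4 * np.sqrt(10000 * (2 / 3) * (1 / 3))

    def test_reads_have_declared_length_and_template_size(self, tmp_path):
        truth = tlc.simulate_fragments(tlc.make_te_genome(small_cfg(total_fragments=50)))
        sam = tlc.synthetic_align(truth, tmp_path / "a.sam")
        with pysam.AlignmentFile(str(sam)) as fh:
            records = list(fh)
        assert records
        assert all(r.query_length == 76 for r in records)
        assert all(abs(r.template_length) == 200 for r in records)

    def test_longread_table_matches_truth_without_noise(self):
        truth = tlc.simulate_fragments(tlc.make_te_genome(small_cfg()))
        np.testing.assert_allclose(truth.longread["tpm"], truth.truth_tpm)

    def test_longread_noise_produces_thinned_counts(self):
        truth = tlc.simulate_fragments(
            tlc.make_te_genome(small_cfg(longread_noise=0.5))
        )
        assert "count" in truth.longread.columns
        assert (truth.longread["count"] <= np.round(truth.truth_tpm)).all()


class TestSyntheticAlign:
    def _matrix(self, cfg, tmp_path):
        truth = tlc.simulate_fragments(tlc.make_te_genome(cfg))
        sam = tlc.synthetic_align(truth, tmp_path / "a.sam")
        matrix = tlc.ingest_alignments(sam, truth.index)
        return truth, matrix

    def test_candidate_set_always_contains_the_origin(self, tmp_path):
        truth, matrix = self._matrix(small_cfg(total_fragments=400), tmp_path)
        origin = {f.name: f.origin for f in truth.fragments}
        name_to_row = {n: a for a, n in enumerate(matrix.fragment_names)}
        for name, o in origin.items():
            loci, _ = matrix.row(name_to_row[name])
            assert o in loci

    def test_zero_divergence_makes_every_fragment_multi_with_equal_scores(self, tmp_path):
        cfg = small_cfg(within_subfamily_divergence=0.0, identical_pairs=0, total_fragments=300)
        _, matrix = self._matrix(cfg, tmp_path)
        assert matrix.n_multi == matrix.n_fragments
        for a in range(matrix.n_fragments):
            loci, q = matrix.row(a)
            assert len(loci) == cfg.copies_per_subfamily
            np.testing.assert_array_equal(q, 1.0)

    def test_high_divergence_makes_most_fragments_unique(self, tmp_path):
        cfg = small_cfg(within_subfamily_divergence=0.2, identical_pairs=0, total_fragments=500)
        _, matrix = self._matrix(cfg, tmp_path)
        assert matrix.n_multi / matrix.n_fragments < 0.5


class TestCoverageScaleRatio:
    def test_reported_long_to_short_base_ratio(self):
        assert tlc.coverage_scale_ratio(2_277_300_856, 95_915_952) == 23

    def test_equal_depth_gives_one(self):
        assert tlc.coverage_scale_ratio(1000, 1000) == 1

    def test_zero_long_read_depth_gives_zero(self):
        assert tlc.coverage_scale_ratio(0, 5) == 0

    def test_zero_short_read_depth_rejected(self):
        with pytest.raises(ValueError):
            tlc.coverage_scale_ratio(10, 0)


class TestConfusion:
    def test_perfect_estimate(self):
        truth = np.array([0.0, 5.0, 2.0, 0.0])
        res = tlc.evaluate_confusion(truth.copy(), truth)
        assert (res.precision, res.recall, res.f1) == (1.0, 1.0, 1.0)
        assert res.n == 4

    def test_hand_tallied_confusion_matrix(self):
        truth = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], float)
        est = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0], float)
        res = tlc.evaluate_confusion(est, truth)
        assert (res.tp, res.fp, res.fn, res.tn) == (2, 1, 1, 6)
        assert res.precision == pytest.approx(2 / 3, abs=1e-4)
        assert res.recall == pytest.approx(2 / 3, abs=1e-4)
        assert res.f1 == pytest.approx(2 / 3, abs=1e-4)

    def test_all_zero_estimate_is_degenerate_not_nan(self):
        res = tlc.evaluate_confusion(np.zeros(4), np.array([1.0, 1.0, 0.0, 0.0]))
        assert res.recall == 0.0 and res.precision == 0.0
        assert res.degenerate

    def test_partition_identity_holds(self):
        rng = np.random.default_rng(5)
        est, truth = rng.poisson(1, 50).astype(float), rng.poisson(1, 50).astype(float)
        res = tlc.evaluate_confusion(est, truth)
        assert res.n == 50

    def test_inclusion_mask_restricts_the_universe(self):
        truth = np.array([1.0, 0.0, 1.0])
        est = np.array([1.0, 1.0, 0.0])
        res = tlc.evaluate_confusion(est, truth, include_mask=[True, True, False])
        assert (res.tp, res.fp, res.fn, res.tn) == (1, 1, 0, 0)

    def test_mismatched_universe_reports_offenders(self):
        with pytest.raises(ValueError, match="ghost"):
            tlc.evaluate_confusion(
                np.array([1.0]),
                np.array([1.0]),
                estimated_ids=["a"],
                truth_ids=["ghost"],
            )


def test_bundle_is_deterministic_per_seed(tmp_path):
    cfg = small_cfg(total_fragments=200)
    p1 = tlc.write_bundle(cfg, tmp_path / "a")
    p2 = tlc.write_bundle(cfg, tmp_path / "b")
    for key in p1:
        assert filecmp.cmp(p1[key], p2[key], shallow=False), key
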