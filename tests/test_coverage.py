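import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from forkspeed import (
    CoverageTrack,
    GenomeGeometry,
    bias_correct,
    cross_replicates,
    read_track,
)


def _track(geometry, counts, phase, rep="r1", mask=None):
    return CoverageTrack(geometry, np.asarray(counts, dtype=float), phase=phase,
                         replicate_id=rep, mask=mask)


class TestReadTrack:
    def test_bedgraph_full_bin(self, tmp_path, mini_geometry):
        path = tmp_path / "cov.bedgraph"
        path.write_text("chr\t30000\t40000\t7\n")
        track = read_track(path, mini_geometry)
        assert track.counts[3] == pytest.approx(7.0)
        assert track.counts.sum() == pytest.approx(7.0)

    def test_interval_straddling_two_bins_splits_by_overlap(
        self, tmp_path, mini_geometry
    ):
        path = tmp_path / "cov.bedgraph"
        # [24000, 34000): 6 kbp in bin 2, 4 kbp in bin 3
        path.write_text("chr\t24000\t34000\t10\n")
        track = read_track(path, mini_geometry)
        assert track.counts[2] == pytest.approx(6.0)
        assert track.counts[3] == pytest.approx(4.0)

    def test_total_count_is_conserved(self, tmp_path, mini_geometry, rng):
        lines = []
        total = 0.0
        for _ in range(50):
            start = rng.uniform(0, mini_geometry.length_bp - 5000)
            end = start + rng.uniform(10, 25_000)
            end = min(end, mini_geometry.length_bp)
            value = rng.uniform(0, 100)
            lines.append(f"chr\t{start:.1f}\t{end:.1f}\t{value:.4f}")
            total += value
        path = tmp_path / "cov.bedgraph"
        path.write_text("\n".join(lines) + "\n")
        track = read_track(path, mini_geometry)
        assert track.counts.sum() == pytest.approx(total, rel=1e-9)

    def test_identical_files_identical_tracks(self, tmp_path, mini_geometry):
        content = "chr\t0\t10000\t3\nchr\t10000\t25000\t6\n"
        p1, p2 = tmp_path / "a.bedgraph", tmp_path / "b.bedgraph"
        p1.write_text(content)
        p2.write_text(content)
        t1 = read_track(p1, mini_geometry)
        t2 = read_track(p2, mini_geometry)
        assert np.array_equal(t1.counts, t2.counts)

    def test_tsv_bin_counts(self, tmp_path, mini_geometry):
        path = tmp_path / "cov.tsv"
        path.write_text("0\t11\n5\t3\n5\t2\n")
        track = read_track(path, mini_geometry)
        assert track.counts[0] == 11 and track.counts[5] == 5

    def test_malformed_line_reports_line_number(self, tmp_path, mini_geometry):
        path = tmp_path / "cov.bedgraph"
        path.write_text("chr\t0\t10000\t3\nchr\tnot-a-number\t5\t1\n")
        with pytest.raises(ValueError, match=":2:"):
            read_track(path, mini_geometry)

    def test_out_of_range_interval_rejected(self, tmp_path, mini_geometry):
        path = tmp_path / "cov.bedgraph"
        path.write_text(f"chr\t0\t{int(mini_geometry.length_bp) + 1}\t1\n")
        with pytest.raises(ValueError, match="outside"):
            read_track(path, mini_geometry)


class TestBiasCorrect:
    def test_identical_tracks_become_uniform(self, mini_geometry, rng):
        counts = rng.integers(100, 1000, mini_geometry.n_bins)
        exp = _track(mini_geometry, counts, "exponential")
        stat = _track(mini_geometry, counts, "stationary")
        corrected = bias_correct(exp, stat)
        freq = corrected.frequencies()
        assert np.allclose(freq, 1.0 / mini_geometry.n_bins)

    def test_shared_bias_cancels_exactly(self, mini_geometry, rng):
        n = mini_geometry.n_bins
        abundance = np.exp(-np.abs(mini_geometry.bin_y_mid()) / 50_000.0)
        bias = rng.lognormal(0, 0.5, n)
        exp = _track(mini_geometry, 1e6 * abundance * bias, "exponential")
        stat = _track(mini_geometry, 1e6 * bias, "stationary")
        corrected = bias_correct(exp, stat)
        assert np.allclose(
            corrected.frequencies(), abundance / abundance.sum(), rtol=1e-9
        )

    def test_zero_stationary_bin_is_masked_not_fatal(self, mini_geometry):
        n = mini_geometry.n_bins
        stat_counts = np.full(n, 100.0)
        stat_counts[4] = 0.0
        exp = _track(mini_geometry, np.full(n, 50.0), "exponential")
        stat = _track(mini_geometry, stat_counts, "stationary")
        corrected = bias_correct(exp, stat)
        assert not corrected.mask[4]
        assert corrected.counts[4] == 0.0
        assert corrected.mask.sum() == n - 1
        assert corrected.frequencies().sum() == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale_e=st.floats(0.1, 10.0), scale_s=st.floats(0.1, 10.0))
    def test_invariant_to_rescaling_either_input(self, scale_e, scale_s):
        g = GenomeGeometry(100_000.0, 30_000.0, 10_000.0)
        base_e = np.arange(1.0, g.n_bins + 1) * 40
        base_s = np.arange(g.n_bins, 0.0, -1) * 30
        ref = bias_correct(
            _track(g, base_e, "exponential"), _track(g, base_s, "stationary")
        )
        scaled = bias_correct(
            _track(g, base_e * scale_e, "exponential"),
            _track(g, base_s * scale_s, "stationary"),
        )
        assert np.allclose(scaled.frequencies(), ref.frequencies(), rtol=1e-9)

    def test_wrong_phases_rejected(self, mini_geometry):
        t = _track(mini_geometry, np.ones(mini_geometry.n_bins), "exponential")
        with pytest.raises(ValueError, match="phases"):
            bias_correct(t, t)

    def test_all_masked_is_degenerate(self, mini_geometry):
        exp = _track(mini_geometry, np.ones(mini_geometry.n_bins), "exponential")
        stat = _track(mini_geometry, np.zeros(mini_geometry.n_bins), "stationary")
        with pytest.raises(ValueError, match="masked"):
            bias_correct(exp, stat)


class TestCrossReplicates:
    def test_three_by_three_gives_nine(self, mini_geometry, rng):
        exps = [
            _track(mini_geometry, rng.integers(50, 150, mini_geometry.n_bins),
                   "exponential", rep=f"e{i}")
            for i in range(3)
        ]
        stats = [
            _track(mini_geometry, rng.integers(50, 150, mini_geometry.n_bins),
                   "stationary", rep=f"s{j}")
            for j in range(3)
        ]
        corrected = cross_replicates(exps, stats)
        assert len(corrected) == 9
        assert sorted(t.replicate_id for t in corrected) == sorted(
            f"e{i}xs{j}" for i in range(3) for j in range(3)
        )

    def test_single_pair_equals_bias_correct(self, mini_geometry, rng):
        exp = _track(mini_geometry, rng.integers(50, 150, mini_geometry.n_bins),
                     "exponential")
        stat = _track(mini_geometry, rng.integers(50, 150, mini_geometry.n_bins),
                      "stationary")
        [via_cross] = cross_replicates([exp], [stat])
        direct = bias_correct(exp, stat)
        assert np.array_equal(via_cross.counts, direct.counts)

    def test_identical_replicates_give_identical_outputs(self, mini_geometry, rng):
        counts_e = rng.integers(50, 150, mini_geometry.n_bins)
        counts_s = rng.integers(50, 150, mini_geometry.n_bins)
        exps = [_track(mini_geometry, counts_e, "exponential", rep=f"e{i}")
                for i in range(2)]
        stats = [_track(mini_geometry, counts_s, "stationary", rep=f"s{j}")
                 for j in range(2)]
        outs = cross_replicates(exps, stats)
        for track in outs[1:]:
            assert np.allclose(track.counts, outs[0].counts)

    def test_geometry_mismatch_rejected(self, mini_geometry):
        other = GenomeGeometry(100_000.0, 0.0, 10_000.0)
        exp = _track(mini_geometry, np.ones(mini_geometry.n_bins), "exponential")
        stat = _track(other, np.ones(other.n_bins), "stationary")
        with pytest.raises(ValueError, match="geometry"):
            cross_replicates([exp], [stat])
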