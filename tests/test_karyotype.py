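"""Depth normalization, disomy calling and segment detection."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cinpipe.karyotype import (
    DepthTrack,
    KaryotypeParams,
    call_karyotype,
    detect_segments,
    disomic_set,
    flag_large_segmental,
    reference_depth,
    telomere_window_depth,
)
from cinpipe.simulate import (
    KaryotypeTruth,
    SimulationConfig,
    child_rng,
    random_karyotype_truth,
    simulate_depth,
)


def uniform_track(chrom_lengths, per_bin, bin_size=1_000):
    counts = {
        c: np.full(math.ceil(L / bin_size), float(per_bin))
        for c, L in chrom_lengths.items()
    }
    # shrink last (short) bin proportionally so per-bp depth is uniform
    for c, L in chrom_lengths.items():
        rem = L % bin_size
        if rem:
            counts[c][-1] = per_bin * rem / bin_size
    return DepthTrack(bin_size=bin_size, chrom_lengths=dict(chrom_lengths), counts=counts)


class TestTelomereWindowDepth:
    def test_uniform_depth_returns_that_depth(self):
        track = uniform_track({"c1": 120_000}, per_bin=500)
        assert telomere_window_depth(track, "c1") == pytest.approx(0.5)

    def test_both_ends_average(self):
        # 10 reads/bp over first 15 kb, 30 reads/bp over last 15 kb -> 20
        L, b = 120_000, 1_000
        counts = np.full(L // b, 0.0)
        counts[:15] = 10 * b
        counts[-15:] = 30 * b
        track = DepthTrack(bin_size=b, chrom_lengths={"c1": L}, counts={"c1": counts})
        assert telomere_window_depth(track, "c1") == pytest.approx(20.0)

    def test_single_end_mode_uses_last_window(self):
        L, b = 120_000, 1_000
        counts = np.full(L // b, 0.0)
        counts[-15:] = 30 * b
        track = DepthTrack(bin_size=b, chrom_lengths={"c1": L}, counts={"c1": counts})
        params = KaryotypeParams(both_ends=False)
        assert telomere_window_depth(track, "c1", params) == pytest.approx(30.0)

    def test_short_chromosome_falls_back_to_whole_mean(self):
        # 20 kb chromosome with 15 kb windows: whole-chromosome mean
        track = uniform_track({"c1": 20_000}, per_bin=800)
        assert telomere_window_depth(track, "c1") == pytest.approx(0.8)

    def test_unknown_chromosome_raises(self):
        track = uniform_track({"c1": 40_000}, per_bin=100)
        with pytest.raises(KeyError):
            telomere_window_depth(track, "nope")


class TestReferenceDepth:
    def test_identical_values_return_that_value(self):
        assert reference_depth([7.0] * 16) == 7.0

    def test_disomes_do_not_inflate_reference(self):
        values = [100.0] * 12 + [150.0] * 4
        assert reference_depth(values) == 100.0

    def test_sort_and_slice_oracle_on_1_to_16(self):
        # ranks 5..8 of 1..16 -> mean of 5,6,7,8 = 6.5
        assert reference_depth(range(1, 17)) == pytest.approx(6.5)

    @given(st.lists(st.floats(0.1, 1e6), min_size=4, max_size=24))
    def test_matches_independent_sort_slice(self, values):
        n = len(values)
        lo, hi = math.ceil(n / 4), math.ceil(n / 2)
        expected = float(np.mean(sorted(values)[lo:hi]))
        assert reference_depth(values) == pytest.approx(expected, rel=1e-12)

    def test_reference_robust_to_quarter_of_chromosomes_doubled(self):
        rng = child_rng(3, "ref")
        base = rng.uniform(90, 110, size=16)
        doubled = base.copy()
        k = math.ceil(16 / 4)
        top = np.argsort(base)[-k:]
        doubled[top] *= 2  # doubling pushes them into the top quartiles
        assert reference_depth(doubled) == pytest.approx(reference_depth(base))

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 4"):
            reference_depth([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero"):
            reference_depth([0.0] * 8)


class TestCallKaryotype:
    def test_flat_track_is_fully_euploid(self, chrom_lengths_16):
        calls = call_karyotype(uniform_track(chrom_lengths_16, 100))
        assert all(not c.disomic for c in calls)
        for c in calls:
            assert c.copy_number == pytest.approx(1.0)

    def test_value_exactly_at_threshold_stays_euploid(self, chrom_lengths_16):
        track = uniform_track(chrom_lengths_16, 100)
        track.counts["chr01"] *= 1.5  # normalized value exactly 1.5
        calls = {c.chrom: c for c in call_karyotype(track)}
        assert calls["chr01"].copy_number == pytest.approx(1.5)
        assert not calls["chr01"].disomic

    def test_value_above_threshold_is_disomic(self, chrom_lengths_16):
        track = uniform_track(chrom_lengths_16, 100)
        track.counts["chr02"] *= 2.0
        assert disomic_set(call_karyotype(track)) == {"chr02"}

    def test_simulated_disomies_recovered(self, chrom_lengths_16):
        cfg = SimulationConfig(seed=31, coverage=100.0)
        truth = KaryotypeTruth(
            chrom_copies={c: 2 if c in ("chr08", "chr10") else 1 for c in chrom_lengths_16}
        )
        track = simulate_depth(chrom_lengths_16, truth, cfg)
        assert disomic_set(call_karyotype(track)) == {"chr08", "chr10"}

    def test_recovery_rate_over_seeds(self, chrom_lengths_16):
        # 0-6 random disomies, lambda=50: exact set recovered >= 99/100
        exact = 0
        for seed in range(100):
            rng = child_rng(seed, "unit-recovery")
            truth = random_karyotype_truth(chrom_lengths_16, int(rng.integers(0, 7)), rng)
            cfg = SimulationConfig(seed=seed, coverage=50.0)
            track = simulate_depth(chrom_lengths_16, truth, cfg, "r")
            if disomic_set(call_karyotype(track)) == truth.disomic_set:
                exact += 1
        assert exact >= 99

    def test_scale_invariance(self, chrom_lengths_16):
        cfg = SimulationConfig(seed=17, coverage=60.0)
        rng = child_rng(17, "scale")
        truth = random_karyotype_truth(chrom_lengths_16, 3, rng)
        track = simulate_depth(chrom_lengths_16, truth, cfg)
        base = call_karyotype(track)
        scaled = call_karyotype(track.scaled(7.0))
        assert [c.disomic for c in base] == [c.disomic for c in scaled]
        for a, b in zip(base, scaled):
            assert a.copy_number == pytest.approx(b.copy_number, rel=1e-12)


class TestSegments:
    def flat_ratio_track(self, chrom_lengths, bin_size=4_000, per_bp=0.05):
        counts = {}
        for c, L in chrom_lengths.items():
            edges = np.append(np.arange(0, L, bin_size), L)
            counts[c] = per_bp * np.diff(edges)
        return DepthTrack(bin_size=bin_size, chrom_lengths=dict(chrom_lengths), counts=counts)

    def test_flat_track_has_no_segments(self, chrom_lengths_16):
        track = self.flat_ratio_track(chrom_lengths_16)
        assert detect_segments(track, 0.05) == []

    def test_run_of_50_amplified_bins_is_one_200kb_segment(self):
        lengths = {"c1": 400_000}
        track = self.flat_ratio_track(lengths)
        track.counts["c1"][10:60] *= 2.0
        segs = detect_segments(track, 0.05)
        assert len(segs) == 1
        s = segs[0]
        assert (s.start, s.end, s.n_bins) == (40_000, 240_000, 50)
        assert s.mean_ratio == pytest.approx(2.0)
        assert not s.spans_chromosome

    def test_two_runs_give_two_sorted_segments(self):
        lengths = {"c1": 400_000}
        track = self.flat_ratio_track(lengths)
        track.counts["c1"][5:15] *= 2.0
        track.counts["c1"][60:80] *= 2.0
        segs = detect_segments(track, 0.05)
        assert [(s.start, s.end) for s in segs] == [(20_000, 60_000), (240_000, 320_000)]

    def test_short_runs_are_dropped(self):
        lengths = {"c1": 400_000}
        track = self.flat_ratio_track(lengths)
        track.counts["c1"][10:13] *= 2.0  # 3 bins < min 5
        assert detect_segments(track, 0.05) == []

    def test_whole_chromosome_disomy_spans_chromosome(self):
        lengths = {"c1": 200_000, "c2": 200_000}
        track = self.flat_ratio_track(lengths)
        track.counts["c1"] *= 2.0
        segs = detect_segments(track, 0.05)
        assert len(segs) == 1 and segs[0].spans_chromosome
        assert (segs[0].start, segs[0].end) == (0, 200_000)

    def test_bin_size_mismatch_raises(self, chrom_lengths_16):
        track = uniform_track(chrom_lengths_16, 100)  # 1 kb bins
        with pytest.raises(ValueError, match="rebin"):
            detect_segments(track, 0.1)

    def test_segment_calls_scale_invariant(self):
        lengths = {"c1": 400_000}
        track = self.flat_ratio_track(lengths)
        track.counts["c1"][10:30] *= 2.0
        a = detect_segments(track, 0.05)
        b = detect_segments(track.scaled(7.0), 0.35)
        assert [(s.chrom, s.start, s.end, s.n_bins) for s in a] == [
            (s.chrom, s.start, s.end, s.n_bins) for s in b
        ]


class TestLargeSegmentFlag:
    def test_no_segments_no_flag(self):
        assert not flag_large_segmental([])

    def test_200kb_partial_segment_flags(self):
        lengths = {"c1": 400_000}
        helper = TestSegments()
        track = helper.flat_ratio_track(lengths)
        track.counts["c1"][10:60] *= 2.0
        segs = detect_segments(track, 0.05)
        assert flag_large_segmental(segs)

    def test_chromosome_spanning_segment_is_a_disomy_not_a_flag(self, chrom_lengths_16):
        # simulate a true whole-chromosome disomy: caller sees it, flag does not
        cfg = SimulationConfig(seed=23, coverage=100.0)
        truth = KaryotypeTruth(
            chrom_copies={c: 2 if c == "chr04" else 1 for c in chrom_lengths_16}
        )
        track = simulate_depth(chrom_lengths_16, truth, cfg)
        assert "chr04" in disomic_set(call_karyotype(track))
        from cinpipe.karyotype import telomere_window_depth as twd

        ref = reference_depth([twd(track, c) for c in track.chrom_names])
        segs = detect_segments(track.rebin(4_000), ref)
        assert any(s.chrom == "chr04" and s.spans_chromosome for s in segs)
        assert not flag_large_segmental([s for s in segs if s.chrom == "chr04"])


class TestBedGraphIO:
    def test_round_trip(self, chrom_lengths_16, tmp_path):
        cfg = SimulationConfig(seed=2, coverage=30.0)
        truth = KaryotypeTruth(chrom_copies={c: 1 for c in chrom_lengths_16})
        track = simulate_depth(chrom_lengths_16, truth, cfg)
        path = tmp_path / "depth.bedgraph"
        track.to_bedgraph(path)
        back = DepthTrack.from_bedgraph(path, dict(chrom_lengths_16))
        assert back.bin_size == track.bin_size
        for c in chrom_lengths_16:
            assert np.array_equal(back.counts[c], track.counts[c])

    def test_rebin_preserves_total(self, chrom_lengths_16):
        cfg = SimulationConfig(seed=6, coverage=40.0)
        truth = KaryotypeTruth(chrom_copies={c: 1 for c in chrom_lengths_16})
        track = simulate_depth(chrom_lengths_16, truth, cfg)
        assert track.rebin(4_000).total_reads == pytest.approx(track.total_reads)
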