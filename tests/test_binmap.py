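"""Tests of sliding-window calling and recombination-bin construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rilmap import binmap, simpop
from rilmap.binmap import UNAVAILABLE
from rilmap.simpop import AA, BB, HET, NA


def brute_force_windows(calls, window_size, min_match):
    """Independent oracle: explicit per-window tallies."""
    calls = np.asarray(calls)
    n_win = len(calls) - window_size + 1
    out = []
    for j in range(max(n_win, 0)):
        w = calls[j : j + window_size]
        call = UNAVAILABLE
        for state in (AA, HET, BB):
            if int((w == state).sum()) >= min_match:
                call = state
        out.append(call)
    return np.array(out, dtype=np.int8)


class TestCallWindows:
    def test_unanimous_window(self):
        calls = np.full(15, AA, dtype=np.int8)
        assert binmap.call_windows(calls).tolist() == [AA]

    def test_nine_of_fifteen_majority(self):
        calls = np.array([AA] * 9 + [BB] * 6, dtype=np.int8)
        assert binmap.call_windows(calls).tolist() == [AA]

    def test_eight_seven_split_is_unavailable(self):
        calls = np.array([AA] * 8 + [BB] * 7, dtype=np.int8)
        assert binmap.call_windows(calls).tolist() == [UNAVAILABLE]

    def test_missing_snps_count_toward_window_but_match_nothing(self):
        calls = np.array([AA] * 8 + [NA] * 7, dtype=np.int8)
        assert binmap.call_windows(calls).tolist() == [UNAVAILABLE]
        calls = np.array([AA] * 9 + [NA] * 6, dtype=np.int8)
        assert binmap.call_windows(calls).tolist() == [AA]

    def test_short_chromosome_yields_zero_windows(self):
        calls = np.full(10, AA, dtype=np.int8)
        assert binmap.call_windows(calls).size == 0

    def test_invalid_min_match_rejected(self):
        with pytest.raises(ValueError):
            binmap.call_windows(np.zeros(20, dtype=np.int8), 15, 7)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from([AA, HET, BB, NA]), min_size=1, max_size=100),
        st.integers(3, 15),
    )
    def test_matches_brute_force_enumeration(self, calls, window_size):
        min_match = window_size // 2 + 1
        got = binmap.call_windows(np.array(calls, dtype=np.int8), window_size, min_match)
        want = brute_force_windows(calls, window_size, min_match)
        np.testing.assert_array_equal(got, want)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([AA, HET, BB, NA]), min_size=15, max_size=80))
    def test_raising_min_match_never_adds_calls(self, calls):
        arr = np.array(calls, dtype=np.int8)
        prev = None
        for mm in range(8, 16):
            n_called = int((binmap.call_windows(arr, 15, mm) != UNAVAILABLE).sum())
            if prev is not None:
                assert n_called <= prev
            prev = n_called


class TestLineBins:
    def test_single_run_single_bin_no_breakpoints(self):
        pos = np.arange(1, 101) * 10_000
        calls = np.full(100, AA, dtype=np.int8)
        t = binmap.build_line_bins(calls, pos)
        assert t.bins == [(10_000, 1_000_000, AA)]
        assert t.breakpoints == []

    def test_two_runs_two_bins_one_breakpoint(self):
        pos = np.arange(1, 101) * 10_000
        calls = np.array([AA] * 50 + [BB] * 50, dtype=np.int8)
        t = binmap.build_line_bins(calls, pos)
        assert [b[2] for b in t.bins] == [AA, BB]
        assert t.breakpoints == [(500_000, 510_000)]

    def test_short_middle_run_filtered_but_edges_kept(self):
        # 240-kb middle run dropped by the 250-kb filter; flanks retained
        pos = np.arange(1, 126) * 10_000
        calls = np.array([AA] * 50 + [BB] * 24 + [AA] * 51, dtype=np.int8)
        t = binmap.build_line_bins(calls, pos)
        assert [b[2] for b in t.bins] == [AA, AA]
        spans = [(e - s + 1) for s, e, _ in t.bins]
        assert all(sp >= 250_000 for sp in spans)
        assert len(t.breakpoints) == 2  # both junctions of the removed run

    def test_exact_250kb_run_retained(self):
        pos = np.concatenate(
            [np.arange(1, 51) * 10_000,
             500_001 + np.arange(25) * 10_000,  # spans exactly 250,000 bp?
             800_001 + np.arange(50) * 10_000]
        )
        calls = np.array([AA] * 50 + [BB] * 25 + [AA] * 50, dtype=np.int8)
        t = binmap.build_line_bins(calls, pos, min_bin_length=240_001)
        # middle run spans 240,001 bp -> retained under this exact threshold
        assert [b[2] for b in t.bins] == [AA, BB, AA]

    def test_missing_snps_are_transparent_in_runs(self):
        pos = np.arange(1, 101) * 10_000
        calls = np.array([AA] * 40 + [NA] * 20 + [AA] * 40, dtype=np.int8)
        t = binmap.build_line_bins(calls, pos)
        assert t.bins == [(10_000, 1_000_000, AA)]

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            binmap.build_line_bins(
                np.zeros(5, dtype=np.int8), np.array([5, 3, 8, 9, 10])
            )


class TestPopulationBinMap:
    def _track(self, breakpoints, bins):
        return binmap.LineBinTrack(bins, breakpoints)

    def test_single_line_single_breakpoint_splits_at_midpoint(self):
        t = self._track([(990_000, 1_010_000)], [(1, 990_000, AA),
                                                 (1_010_000, 2_000_000, BB)])
        pbm = binmap.build_population_binmap({"c1": [t]}, ["L1"], {"c1": 2_000_000})
        assert pbm.bins["start"].tolist() == [1, 1_000_001]
        assert pbm.bins["end"].tolist() == [1_000_000, 2_000_000]
        assert pbm.table[0].tolist() == [AA, BB]

    def test_identical_lines_pool_idempotently(self):
        t = self._track([(990_000, 1_010_000)], [(1, 990_000, AA),
                                                 (1_010_000, 2_000_000, BB)])
        one = binmap.build_population_binmap({"c1": [t]}, ["L1"], {"c1": 2_000_000})
        two = binmap.build_population_binmap({"c1": [t, t]}, ["L1", "L2"],
                                             {"c1": 2_000_000})
        assert one.bins.equals(two.bins)

    def test_distinct_breakpoints_cut_count(self):
        # 2 + 3 + 4 distinct cuts -> 10 population bins
        L = 10_000_000
        tracks = []
        cuts = [[2e6, 4e6], [1e6, 5e6, 7e6], [3e6, 6e6, 8e6, 9e6]]
        for cs in cuts:
            bps = [(int(c - 5_000), int(c + 5_000)) for c in cs]
            tracks.append(self._track(bps, [(1, L, AA)]))
        pbm = binmap.build_population_binmap(
            {"c1": tracks}, ["L1", "L2", "L3"], {"c1": L}
        )
        assert pbm.n_bins == 10

    def test_bins_tile_chromosome_exactly(self, ril_population):
        pbm = ril_population["pbm"]
        for chrom, grp in pbm.bins.groupby("chrom"):
            lengths = (grp["end"] - grp["start"] + 1).sum()
            assert lengths == pbm.chrom_lengths[chrom]
            assert grp["start"].iloc[0] == 1
            assert (grp["start"].to_numpy()[1:] == grp["end"].to_numpy()[:-1] + 1).all()


class TestStats:
    def test_all_aa_population(self):
        t = binmap.LineBinTrack([(1, 1_000_000, AA)], [])
        pbm = binmap.build_population_binmap(
            {"c1": [t, t]}, ["L1", "L2"], {"c1": 1_000_000}
        )
        st_ = binmap.binmap_stats(pbm)
        assert st_.overall_homozygous_fraction == 1.0
        assert (st_.per_line["breakpoints"] == 0).all()
        assert st_.boundaries.empty or (
            st_.boundaries["recombination_frequency"] == 0
        ).all()

    def test_half_half_line_fractions(self):
        t = binmap.LineBinTrack(
            [(1, 1_000_000, AA), (1_000_001, 2_000_000, BB)],
            [(1_000_000, 1_000_001)],
        )
        pbm = binmap.build_population_binmap({"c1": [t]}, ["L1"], {"c1": 2_000_000})
        st_ = binmap.binmap_stats(pbm)
        row = st_.per_line.iloc[0]
        assert row["frac_AA"] == pytest.approx(0.5, abs=0.01)
        assert row["frac_BB"] == pytest.approx(0.5, abs=0.01)
        assert row["breakpoints"] == 1

    def test_fraction_columns_sum_to_one(self, ril_population):
        st_ = binmap.binmap_stats(ril_population["pbm"])
        total = (
            st_.per_line[["frac_AA", "frac_BB", "frac_HET", "frac_NA"]].sum(axis=1)
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-12)


class TestRecovery:
    def test_noise_robustness_single_bin_per_chromosome(self):
        # no true breakpoint + 2% error: a single bin almost always
        rng = np.random.default_rng(3)
        n_lines, n_snps = 300, 1000
        pos = np.sort(rng.choice(np.arange(1, 5_000_000), n_snps, replace=False))
        calls = np.zeros((n_lines, n_snps), dtype=np.int8)
        flip = rng.random(calls.shape) < 0.02
        shift = rng.integers(1, 3, size=calls.shape).astype(np.int8)
        calls = np.where(flip, (calls + shift) % 3, calls)
        wc = binmap.call_windows(calls)
        sc = binmap.project_snp_calls(wc, n_snps)
        single = sum(
            len(binmap.build_line_bins(sc[i], pos).bins) == 1 for i in range(n_lines)
        )
        assert single / n_lines >= 0.99

    def test_breakpoint_recovery_on_noisy_population(self, ril_population):
        # >= 90% of true junctions matched within 150 kb, precision >= 90%
        truth = ril_population["truth"]
        tracks = ril_population["tracks"]
        tol = 150_000
        tp_t = n_t = tp_i = n_i = 0
        for chrom, per_line in tracks.items():
            for li, t in enumerate(per_line):
                true_mid = truth.crossover_midpoints(li, chrom)
                inf_mid = np.array([(a + b) / 2 for a, b in t.breakpoints])
                n_t += len(true_mid)
                n_i += len(inf_mid)
                if len(true_mid) and len(inf_mid):
                    for m in true_mid:
                        tp_t += int(np.min(np.abs(inf_mid - m)) <= tol)
                    for m in inf_mid:
                        tp_i += int(np.min(np.abs(true_mid - m)) <= tol)
        assert tp_t / n_t >= 0.90
        assert tp_i / n_i >= 0.90
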