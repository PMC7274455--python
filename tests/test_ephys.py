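"""Spike-train -> functional-network construction."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpsbm import (
    SpikeRecording,
    GlobalBurst,
    CorrelationMatrix,
    read_spikes,
    detect_channel_bursts,
    detect_global_bursts,
    cross_correlation_matrix,
    threshold_network,
    threshold_sweep,
    mean_firing_rate,
    build_network,
)
from gpsbm.ephys import ChannelBurst

from conftest import burst_oracle, global_burst_oracle, random_spike_train


def write_spike_fixture(tmp_path, rows, channels, duration=10.0, device="d1", div=14):
    path = tmp_path / "rec.tsv"
    lines = ["channel\ttime_s"] + [f"{ch}\t{t}" for ch, t in rows]
    path.write_text("\n".join(lines) + "\n")
    path.with_suffix(".json").write_text(
        json.dumps(
            {"device": device, "div": div, "duration_s": duration,
             "channels": channels}
        )
    )
    return path


class TestReadSpikes:
    def test_parses_counts_and_keeps_silent_channels(self, tmp_path):
        rows = [("a", 0.1), ("a", 0.2), ("a", 0.5), ("b", 1.0), ("b", 2.0), ("b", 3.0)]
        path = write_spike_fixture(tmp_path, rows, ["a", "b", "c"])
        rec = read_spikes(path)
        assert rec.n == 3
        assert [len(s) for s in rec.spikes] == [3, 3, 0]
        assert rec.device_id == "d1" and rec.div == 14

    def test_timestamp_beyond_duration_is_an_error(self, tmp_path):
        path = write_spike_fixture(tmp_path, [("a", 11.0)], ["a"], duration=10.0)
        with pytest.raises(ValueError, match="outside"):
            read_spikes(path)

    def test_unsorted_timestamps_are_an_error(self, tmp_path):
        path = write_spike_fixture(tmp_path, [("a", 2.0), ("a", 1.0)], ["a"])
        with pytest.raises(ValueError, match="sorted"):
            read_spikes(path)

    def test_unknown_channel_row_is_an_error(self, tmp_path):
        path = write_spike_fixture(tmp_path, [("zz", 1.0)], ["a"])
        with pytest.raises(ValueError, match="zz"):
            read_spikes(path)


class TestChannelBursts:
    @pytest.mark.parametrize(
        "spikes, expected",
        [
            # 4 spikes inside 100 ms, a straggler far away
            ([0.00, 0.02, 0.05, 0.09, 0.50], [(0.00, 0.09, 4)]),
            # only 3 spikes: below the count threshold
            ([0.00, 0.04, 0.09], []),
            # overlapping qualifying windows merge into one burst
            ([0.00, 0.02, 0.05, 0.09, 0.12, 0.14], [(0.00, 0.14, 6)]),
        ],
    )
    def test_examples(self, spikes, expected):
        rec = SpikeRecording("d", 1, 10.0, ("ch",), (np.array(spikes),))
        bursts = detect_channel_bursts(rec)["ch"]
        got = [(b.t_start, b.t_end, b.n_spikes) for b in bursts]
        assert got == pytest.approx(expected)
        for b in bursts:
            assert b.duration == pytest.approx(b.t_end - b.t_start)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            s = random_spike_train(rng)
            rec = SpikeRecording("d", 1, 10.0, ("ch",), (s,))
            got = [
                (b.t_start, b.t_end, b.n_spikes)
                for b in detect_channel_bursts(rec)["ch"]
            ]
            assert got == pytest.approx(burst_oracle(s))


class TestGlobalBursts:
    @staticmethod
    def _bursts(starts_by_channel):
        return {
            ch: [ChannelBurst(ch, t, t + 0.05, 4) for t in starts]
            for ch, starts in starts_by_channel.items()
        }

    def test_four_channels_within_window_form_one_burst(self):
        bursts = self._bursts({1: [1.00], 2: [1.10], 3: [1.20], 4: [1.24]})
        out = detect_global_bursts(bursts)
        assert len(out) == 1
        assert out[0].n_channels == 4
        assert out[0].t_start == pytest.approx(1.00)
        assert out[0].t_end == pytest.approx(1.29)

    def test_three_channels_are_not_enough(self):
        bursts = self._bursts({1: [1.00], 2: [1.10], 3: [1.20]})
        assert detect_global_bursts(bursts) == []

    def test_two_separated_clusters_give_two_bursts(self):
        bursts = self._bursts(
            {1: [1.00, 5.00], 2: [1.05, 5.05], 3: [1.10, 5.10], 4: [1.15, 5.15]}
        )
        assert len(detect_global_bursts(bursts)) == 2

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_ch = int(rng.integers(2, 9))
            bursts = {}
            total = 0
            for ch in range(n_ch):
                k = int(rng.integers(0, 4))
                k = min(k, 20 - total)
                total += k
                starts = np.sort(rng.uniform(0, 3.0, size=k))
                bursts[ch] = [
                    ChannelBurst(ch, float(t), float(t + rng.uniform(0, 0.2)), 4)
                    for t in starts
                ]
            got = [
                (g.t_start, g.t_end, g.n_channels, len(g.member_bursts))
                for g in detect_global_bursts(bursts)
            ]
            assert got == pytest.approx(global_burst_oracle(bursts))


class TestCrossCorrelation:
    def test_identical_spike_trains_correlate_perfectly(self):
        s = np.array([0.005, 0.012, 0.035, 0.048])
        rec = SpikeRecording("d", 1, 10.0, ("a", "b"), (s, s.copy()))
        gb = [GlobalBurst(0.0, 0.05, (), 2)]
        C = cross_correlation_matrix(rec, gb)
        assert C.values[0, 1] == pytest.approx(1.0)
        assert C.values[0, 0] == 1.0

    def test_silent_channel_gets_zero_row_and_column(self):
        s = np.array([0.005, 0.012, 0.035, 0.048])
        rec = SpikeRecording(
            "d", 1, 10.0, ("a", "b", "c"), (s, s + 0.001, np.array([]))
        )
        gb = [GlobalBurst(0.0, 0.05, (), 2)]
        C = cross_correlation_matrix(rec, gb)
        assert np.all(C.values[2, :] == 0) and np.all(C.values[:2, 2] == 0)

    def test_handbuilt_binned_counts_give_pearson_r(self):
        # 10 ms bins over [0, 0.04): counts a=[2,0,1,0], b=[1,0,2,0]
        a = np.array([0.001, 0.002, 0.021])
        b = np.array([0.003, 0.022, 0.023])
        rec = SpikeRecording("d", 1, 10.0, ("a", "b"), (a, b))
        gb = [GlobalBurst(0.0, 0.04, (), 2)]
        C = cross_correlation_matrix(rec, gb)
        expected = np.corrcoef([2, 0, 1, 0], [1, 0, 2, 0])[0, 1]
        assert expected == pytest.approx(1.75 / 2.75)
        assert C.values[0, 1] == pytest.approx(expected)

    def test_no_global_bursts_gives_zero_matrix(self):
        rec = SpikeRecording("d", 1, 10.0, ("a",), (np.array([1.0]),))
        C = cross_correlation_matrix(rec, [])
        assert np.all(C.values == 0)


class TestThreshold:
    def test_strict_comparison_and_bounds(self):
        vals = np.array([[1.0, 0.25], [0.25, 1.0]])
        C = CorrelationMatrix(vals, ("a", "b"))
        assert threshold_network(C, 0.20).adjacency[0, 1] == 1
        C_eq = CorrelationMatrix(np.array([[1.0, 0.20], [0.20, 1.0]]), ("a", "b"))
        assert threshold_network(C_eq, 0.20).adjacency[0, 1] == 0
        with pytest.raises(ValueError):
            threshold_network(C, 1.5)

    def test_all_below_threshold_gives_empty_graph(self):
        C = CorrelationMatrix(np.eye(3) + 0.1 - 0.1 * np.eye(3), tuple("abc"))
        g = threshold_network(C, 0.20)
        assert g.adjacency.sum() == 0 and g.density() == 0.0

    def test_sweep_examples_and_monotonicity(self):
        ones = np.ones((4, 4))
        C = CorrelationMatrix(ones, tuple("abcd"))
        sweep = threshold_sweep(C, [0.1, 0.5, 0.9])
        assert all(deg == pytest.approx(3.0) for _, deg in sweep)
        # 3-node derived case: off-diagonals 0.3 (ab), 0.15 (ac), 0.25 (bc)
        vals = np.array([[1, 0.3, 0.15], [0.3, 1, 0.25], [0.15, 0.25, 1.0]])
        C3 = CorrelationMatrix(vals, tuple("abc"))
        [(_, deg)] = threshold_sweep(C3, [0.20])
        assert deg == pytest.approx(4 / 3)
        rng = np.random.default_rng(0)
        r = rng.uniform(-1, 1, size=(6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        degs = [d for _, d in threshold_sweep(CorrelationMatrix(r, tuple("abcdef")),
                                              np.linspace(-0.9, 0.9, 10))]
        assert all(a >= b for a, b in zip(degs, degs[1:]))


def test_mean_firing_rate_is_count_over_duration():
    rec = SpikeRecording(
        "d", 1, 600.0, ("a", "b", "c"),
        (np.linspace(1, 599, 60), np.linspace(1, 599, 30), np.array([])),
    )
    rates = mean_firing_rate(rec)
    assert rates == pytest.approx([0.1, 0.05, 0.0])


def test_time_shift_leaves_bursts_correlations_networks_invariant():
    from gpsbm import simulate_spike_recording

    rec = simulate_spike_recording(
        n_channels=8, duration=60.0, seed=3,
        communities=[0, 0, 0, 0, 1, 1, 1, 1],
    )
    shifted = rec.shifted(1.75)
    cb, cb_s = detect_channel_bursts(rec), detect_channel_bursts(shifted)
    for ch in rec.channels:
        assert len(cb[ch]) == len(cb_s[ch])
        for b, bs in zip(cb[ch], cb_s[ch]):
            assert bs.t_start == pytest.approx(b.t_start + 1.75)
            assert bs.n_spikes == b.n_spikes
    g = build_network(rec, threshold=0.2)
    g_s = build_network(shifted, threshold=0.2)
    np.testing.assert_array_equal(g.adjacency, g_s.adjacency)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_correlation_and_network_structural_invariants(seed):
    from gpsbm import simulate_spike_recording

    rng = np.random.default_rng(seed)
    comms = rng.integers(0, 2, size=6)
    rec = simulate_spike_recording(
        n_channels=6, duration=30.0, seed=seed, communities=comms
    )
    cb = detect_channel_bursts(rec)
    gb = detect_global_bursts(cb)
    C = cross_correlation_matrix(rec, gb)
    assert np.allclose(C.values, C.values.T)
    assert np.all(np.abs(C.values) <= 1 + 1e-12)
    g = threshold_network(C, 0.2)
    assert np.array_equal(g.adjacency, g.adjacency.T)
    assert np.all(np.diag(g.adjacency) == 0)
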