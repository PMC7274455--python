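"""Study orchestration, trend labels, inactive-community detection and the
firing-rate-vs-degree diagnostic."""

import numpy as np
import pytest

import gpsbm
from gpsbm import (
    MCMCConfig,
    KernelParams,
    NetworkPanel,
    SpikeRecording,
    StudyConfig,
    TrendRules,
    classify_community_trend,
    firing_rate_vs_degree,
    inactive_community,
    run_study,
    sample_tsbm,
    simulate_spike_recording,
    write_panel,
)


class TestTrendClassification:
    @pytest.mark.parametrize(
        "curve, label",
        [
            ((0.01, 0.02, 0.01), "inactive"),
            ((0.1, 0.9, 0.1), "transient"),
            ((0.1, 0.3, 0.6, 0.8), "increasing"),
            ((0.7, 0.8, 0.9, 0.85), "persistent"),
            ((0.4, 0.1, 0.45, 0.1), "mixed"),
        ],
    )
    def test_rule_examples(self, curve, label):
        assert classify_community_trend(curve) == label

    @pytest.mark.parametrize(
        "curve",
        [(0.01, 0.02, 0.01), (0.1, 0.9, 0.1), (0.1, 0.3, 0.6, 0.8),
         (0.7, 0.8, 0.9, 0.85)],
    )
    def test_padding_with_duplicate_final_div_is_idempotent(self, curve):
        padded = tuple(curve) + (curve[-1],)
        assert classify_community_trend(padded) == classify_community_trend(curve)

    def test_short_curves_rejected(self):
        with pytest.raises(ValueError):
            classify_community_trend((0.1, 0.2))

    def test_rules_are_configurable(self):
        rules = TrendRules(persistent=0.3)
        assert classify_community_trend((0.4, 0.42, 0.41), rules) == "persistent"


class TestInactiveCommunity:
    @staticmethod
    def _summary(eta_mean, counts):
        from gpsbm.summarize import FitSummary

        k, _, T = eta_mean.shape
        return FitSummary(
            k=k, divs=np.arange(T, dtype=float), devices=["d0"],
            mode_z=np.ones((1, counts.shape[1] if counts.ndim > 1 else 1)),
            occupied_k=int((counts.sum(axis=0) > 0).sum()),
            community_counts=counts,
            eta_mean=eta_mean, eta_ci=np.stack([eta_mean, eta_mean]),
            beta_mean=None, beta_sd=None,
        )

    def test_uniformly_silent_community_is_flagged(self):
        eta = np.full((2, 2, 3), 0.4)
        eta[0, :, :] = eta[:, 0, :] = 0.01
        s = self._summary(eta, np.array([[5, 5]]))
        assert inactive_community(s) == 1

    def test_single_hot_div_disqualifies(self):
        eta = np.full((2, 2, 3), 0.01)
        eta[0, 0, 1] = 0.9
        s = self._summary(eta, np.array([[5, 5]]))
        assert inactive_community(s) == 2

    def test_never_firing_nodes_form_an_inactive_community(self):
        # devices where 8 nodes never connect to anything
        rng = np.random.default_rng(0)
        n, T = 16, 4
        adj = np.zeros((2, T, n, n), dtype=np.uint8)
        live = np.arange(8)
        iu, ju = np.triu_indices(len(live), k=1)
        for di in range(2):
            for ti in range(T):
                e = (rng.random(len(iu)) < 0.7).astype(np.uint8)
                block = np.zeros((8, 8), dtype=np.uint8)
                block[iu, ju] = e
                block += block.T
                adj[di, ti][:8, :8] = block
        panel = NetworkPanel(["a", "b"], [10, 13, 17, 20], list(range(n)), adj)
        trace = gpsbm.fit_tsbm(
            panel, k=2,
            mcmc=MCMCConfig(n_chains=1, n_samples=200, n_warmup=200, seed=0),
        )
        summary = gpsbm.relabel_by_size(trace)
        flagged = inactive_community(summary)
        assert flagged is not None
        silent_modal = np.unique(summary.mode_z[:, 8:])
        assert silent_modal.tolist() == [flagged]


def _study_panel(seed=0):
    """Two conditions: A devices use 2 communities, B devices use 3."""
    z = np.zeros((4, 12), dtype=int)
    z[:2] = np.tile(np.repeat([0, 1], 6), (2, 1))
    z[2:] = np.tile(np.repeat([0, 1, 2], 4), (2, 1))
    # distinct within-community offsets make the communities identifiable
    # across devices (the joint model shares eta, not labels)
    beta = np.full((3, 3), -3.0)
    np.fill_diagonal(beta, (2.5, 1.0, 3.5))
    truth = sample_tsbm(
        k=3, alpha=1.0,
        kernel_in=KernelParams(0.25, 3.0, 0.01),
        kernel_out=KernelParams(0.25, 3.0, 0.01),
        divs=[11, 14, 18, 21], n_nodes=12, n_devices=4, seed=seed,
        beta=beta, z=z,
    )
    return truth


@pytest.fixture(scope="module")
def study_dir(tmp_path_factory):
    root = tmp_path_factory.mktemp("study")
    truth = _study_panel()
    write_panel(truth.panel, root / "panel")
    return root


class TestRunStudy:
    def _config(self, root, out_name):
        return StudyConfig(
            conditions={"simple": ["sim0", "sim1"], "complex": ["sim2", "sim3"]},
            divs=[11, 14, 18, 21],
            panel_manifest=str(root / "panel" / "panel.json"),
            k=4,
            mcmc=MCMCConfig(n_chains=1, n_samples=120, n_warmup=240),
            seed=7,
            out_dir=str(root / out_name),
        )

    def test_condition_with_more_communities_shows_higher_occupancy(
        self, study_dir
    ):
        reports = run_study(self._config(study_dir, "out1"))
        occ_simple = max(reports["simple"].occupied_per_device.values())
        occ_complex = min(reports["complex"].occupied_per_device.values())
        assert occ_complex > occ_simple
        for rep in reports.values():
            assert np.all(rep.density_table.sum(axis=1) == 12)

    def test_rerun_with_same_seed_is_byte_identical(self, study_dir):
        run_study(self._config(study_dir, "out2"))
        run_study(self._config(study_dir, "out3"))
        for name in ("community_counts.csv", "eta_curves.csv",
                     "trend_labels.csv"):
            a = (study_dir / "out2" / name).read_bytes()
            b = (study_dir / "out3" / name).read_bytes()
            assert a == b

    def test_unknown_device_is_reported_by_name(self, study_dir):
        cfg = self._config(study_dir, "out4")
        cfg.conditions = {"simple": ["sim0", "ghost"]}
        with pytest.raises(ValueError, match="ghost"):
            run_study(cfg)


class TestFiringRateVsDegree:
    @staticmethod
    def _random_graph_panel(seed, n=12):
        rng = np.random.default_rng(seed)
        iu, ju = np.triu_indices(n, k=1)
        e = (rng.random(len(iu)) < 0.3).astype(np.uint8)
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[iu, ju] = e
        adj += adj.T
        channels = tuple(f"ch{c:02d}" for c in range(n))
        return adj, channels

    @staticmethod
    def _recording_with_counts(counts, channels, duration=100.0):
        spikes = tuple(
            np.linspace(1.0, duration - 1.0, c) if c else np.array([])
            for c in counts
        )
        return SpikeRecording("d0", 14, duration, channels, spikes)

    def test_constant_degree_reports_not_applicable(self):
        adj, channels = self._random_graph_panel(1)
        adj[:] = 0
        rec = self._recording_with_counts(range(2, 14), channels)
        panel = NetworkPanel(["d0"], [14], list(channels), adj[None, None])
        df, rho, ci = firing_rate_vs_degree([rec], panel)
        assert rho is None and ci == (None, None)
        assert len(df) == 12

    def test_rates_proportional_to_degree_give_perfect_rank_correlation(self):
        adj, channels = self._random_graph_panel(2)
        degrees = adj.sum(axis=1)
        rec = self._recording_with_counts(degrees * 3, channels)
        panel = NetworkPanel(["d0"], [14], list(channels), adj[None, None])
        _, rho, _ = firing_rate_vs_degree([rec], panel)
        assert rho == pytest.approx(1.0)

    def test_independent_edges_give_small_correlation(self):
        rng = np.random.default_rng(0)
        covered = 0
        for seed in range(8):
            adj, channels = self._random_graph_panel(seed + 10)
            rec = self._recording_with_counts(
                rng.integers(5, 50, size=12), channels
            )
            panel = NetworkPanel(["d0"], [14], list(channels), adj[None, None])
            _, rho, (lo, hi) = firing_rate_vs_degree([rec], panel)
            covered += lo <= 0 <= hi
        assert covered >= 6
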