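"""Sampler correctness on conjugate, degenerate and exactly-recoverable cases."""

import numpy as np
import pytest

from gpsbm import (
    NetworkPanel,
    MCMCConfig,
    PriorSpec,
    fit_tsbm,
    fit_static_sbm,
    relabel_by_size,
    sample_static_sbm,
    sample_tsbm,
    KernelParams,
)


def _clique_panel(z, n_divs=3, n_devices=2):
    """Deterministic disjoint-clique panel: edges exactly within blocks."""
    z = np.asarray(z)
    n = len(z)
    adj1 = (z[:, None] == z[None, :]).astype(np.uint8)
    np.fill_diagonal(adj1, 0)
    adj = np.tile(adj1, (n_devices, n_divs, 1, 1))
    return NetworkPanel(
        [f"d{i}" for i in range(n_devices)],
        list(range(1, n_divs + 1)), list(range(n)), adj,
    )


class TestStaticSampler:
    def test_single_block_posterior_matches_beta_bernoulli_conjugacy(self):
        params, nets = sample_static_sbm(
            k=1, alpha=1.0, a=1.0, b=1.0, n_nodes=30, n_devices=1,
            seed=3, eta=np.array([[0.35]]),
        )
        trace = fit_static_sbm(
            nets, k=1, mcmc=MCMCConfig(n_chains=2, n_samples=400, seed=0)
        )
        m = nets[0].adjacency.sum() / 2
        N = 30 * 29 / 2
        closed_form = (1 + m) / (2 + N)
        assert trace.eta_static[:, 0, 0].mean() == pytest.approx(
            closed_form, abs=0.01
        )

    def test_two_cliques_recovered_up_to_permutation(self):
        panel = _clique_panel(np.repeat([0, 1], 6), n_divs=1, n_devices=1)
        trace = fit_static_sbm(
            panel, k=2, mcmc=MCMCConfig(n_chains=2, n_samples=200, seed=1)
        )
        summary = relabel_by_size(trace)
        truth = np.repeat([1, 2], 6)
        got = summary.mode_z[0]
        assert (
            np.array_equal(got, truth) or np.array_equal(got, 3 - truth)
        )

    def test_flat_prior_recovered_without_data(self):
        from scipy import stats

        panel = NetworkPanel([], [1], list(range(4)),
                             np.zeros((0, 1, 4, 4), dtype=np.uint8))
        trace = fit_static_sbm(
            panel, k=2, mcmc=MCMCConfig(n_chains=1, n_samples=500, seed=2)
        )
        draws = trace.eta_static[:, 0, 1]
        assert stats.kstest(draws, "uniform").pvalue > 1e-3


class TestTemporalSampler:
    def test_identical_inputs_give_identical_traces(self):
        truth = sample_tsbm(
            k=2, alpha=1.0,
            kernel_in=KernelParams(0.25, 3.0, 0.01),
            kernel_out=KernelParams(0.25, 3.0, 0.01),
            divs=[1, 4, 8], n_nodes=10, n_devices=2, seed=0,
            beta=np.array([[1.0, -2.0], [-2.0, 1.0]]),
            z=np.repeat([0, 1], 5),
        )
        cfg = MCMCConfig(n_chains=2, n_samples=30, n_warmup=30, seed=9)
        t1 = fit_tsbm(truth.panel, 2, cfg)
        t2 = fit_tsbm(truth.panel, 2, cfg)
        np.testing.assert_array_equal(t1.z, t2.z)
        np.testing.assert_allclose(t1.beta, t2.beta)
        np.testing.assert_allclose(t1.sigma_in, t2.sigma_in)

    def test_disjoint_persistent_cliques_recovered_exactly(self):
        z_true = np.repeat([0, 1, 2], 4)
        panel = _clique_panel(z_true, n_divs=3, n_devices=2)
        trace = fit_tsbm(
            panel, k=3,
            mcmc=MCMCConfig(n_chains=2, n_samples=150, n_warmup=150, seed=0),
        )
        summary = relabel_by_size(trace)
        for di in range(2):
            got = summary.mode_z[di]
            # same partition as truth, whatever the labels
            for c in np.unique(z_true):
                members = got[z_true == c]
                assert len(np.unique(members)) == 1
            assert len(np.unique(got)) == 3

    def test_all_zero_panel_drives_occupied_eta_to_zero(self):
        panel = NetworkPanel(
            ["a", "b"], [1, 5, 9], list(range(10)),
            np.zeros((2, 3, 10, 10), dtype=np.uint8),
        )
        trace = fit_tsbm(
            panel, k=2,
            mcmc=MCMCConfig(n_chains=1, n_samples=300, n_warmup=300, seed=0),
        )
        summary = relabel_by_size(trace)
        occupied = np.flatnonzero(summary.community_counts.sum(axis=0) > 0)
        for i in occupied:
            for j in occupied:
                assert np.all(summary.eta_mean[i, j] < 0.05)

    def test_prior_recovered_without_data(self):
        panel = NetworkPanel([], [1, 4, 7], list(range(4)),
                             np.zeros((0, 3, 4, 4), dtype=np.uint8))
        trace = fit_tsbm(
            panel, k=2,
            mcmc=MCMCConfig(n_chains=2, n_samples=400, n_warmup=200, seed=3),
        )
        b = trace.beta[:, 0, 1]
        assert abs(b.mean()) < 0.15
        assert b.std() == pytest.approx(1.0, abs=0.15)
        # half-normal scale s: E sigma = s * sqrt(2/pi)
        expected = trace.priors.sigma_scale * np.sqrt(2 / np.pi)
        assert trace.sigma_in.mean() == pytest.approx(expected, rel=0.25)

    def test_asymmetric_adjacency_rejected(self):
        adj = np.zeros((1, 1, 3, 3), dtype=np.uint8)
        adj[0, 0, 0, 1] = 1  # deliberately not mirrored
        panel = NetworkPanel.__new__(NetworkPanel)
        panel.devices, panel.divs, panel.channels = ["a"], [1], [0, 1, 2]
        panel.adjacency = adj
        panel.observed = np.ones((1, 1), dtype=bool)
        with pytest.raises(ValueError, match="symmetric"):
            fit_tsbm(panel, 2, MCMCConfig(n_chains=1, n_samples=5))

    def test_random_and_spectral_starts_agree_on_strong_structure(self):
        z_true = np.repeat([0, 1], 6)
        panel = _clique_panel(z_true, n_divs=2, n_devices=1)
        cfg = MCMCConfig(n_chains=1, n_samples=200, n_warmup=400, seed=5)
        s_spec = relabel_by_size(fit_tsbm(panel, 2, cfg, init="spectral"))
        s_rand = relabel_by_size(fit_tsbm(panel, 2, cfg, init="random"))
        np.testing.assert_array_equal(s_spec.mode_z, s_rand.mode_z)
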