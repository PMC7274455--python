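import numpy as np
import pytest

import gpsbm
from gpsbm.mcmc import MCMCConfig, PriorSpec, PosteriorTrace


def burst_oracle(spikes, min_spikes=4, window=0.100):
    """Brute-force channel-burst detection: enumerate every window anchored
    at a spike, collect qualifying first-to-last spans, merge overlapping
    time intervals."""
    s = list(spikes)
    spans = []
    for i in range(len(s)):
        members = [t for t in s if s[i] <= t <= s[i] + window]
        if len(members) >= min_spikes:
            spans.append((members[0], members[-1]))
    merged = []
    for a, b in sorted(spans):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [
        (a, b, sum(1 for t in s if a <= t <= b)) for a, b in merged
    ]


def global_burst_oracle(bursts_by_channel, min_channels=4, window=0.250):
    """Brute-force global-burst grouping: repeatedly anchor on the earliest
    unassigned channel-burst start and test the 250 ms window."""
    flat = []
    for ch, bursts in bursts_by_channel.items():
        for b in bursts:
            flat.append((b.t_start, str(b.channel), b.t_end, b.channel))
    flat.sort()
    unassigned = list(range(len(flat)))
    out = []
    while unassigned:
        anchor = flat[unassigned[0]][0]
        group = [j for j in unassigned if flat[j][0] <= anchor + window]
        channels = {flat[j][3] for j in group}
        if len(channels) >= min_channels:
            starts = [flat[j][0] for j in group]
            ends = [flat[j][2] for j in group]
            out.append((min(starts), max(ends), len(channels), len(group)))
            unassigned = [j for j in unassigned if j not in group]
        else:
            unassigned = unassigned[1:]
    return out


def random_spike_train(rng, max_spikes=50, duration=5.0):
    n = int(rng.integers(0, max_spikes + 1))
    # cluster some spikes so bursts actually occur
    base = rng.uniform(0, duration, size=max(n // 3, 1))
    jitter = rng.uniform(0, 0.15, size=n)
    s = np.sort(rng.choice(base, size=n) + jitter) if n else np.array([])
    return np.unique(s)


def make_temporal_trace(
    z_draws, beta_draws, x_draws, divs,
    sigma_in=0.25, ell_in=3.0, sigma_out=0.25, ell_out=3.0,
    eps=0.01, n_chains=1,
):
    """Hand-built temporal trace for summary/prediction unit tests."""
    z = np.asarray(z_draws, dtype=np.int16)
    beta = np.asarray(beta_draws, dtype=float)
    x = np.asarray(x_draws, dtype=float)
    S, k = beta.shape[0], beta.shape[1]
    chain = np.repeat(np.arange(n_chains), S // n_chains)
    priors = PriorSpec(eps=eps).resolved(np.asarray(divs, dtype=float))
    return PosteriorTrace(
        kind="temporal", k=k, divs=np.asarray(divs, dtype=float),
        devices=[f"dev{i}" for i in range(z.shape[1])],
        config=MCMCConfig(n_chains=n_chains, n_samples=S // n_chains),
        priors=priors,
        z=z, pi=np.full((S, k), 1.0 / k), chain=chain,
        iteration=np.arange(S), loglik=np.zeros(S),
        beta=beta, x=x,
        sigma_in=np.full(S, sigma_in), ell_in=np.full(S, ell_in),
        sigma_out=np.full(S, sigma_out), ell_out=np.full(S, ell_out),
        diagnostics={"converged": True, "max_rhat": 1.0},
    )


@pytest.fixture(scope="session")
def validation_fit():
    """Synthetic validation experiment: simulate the modular two-community
    panel and fit it with two chains (scaled chain length)."""
    truth = gpsbm.sample_validation_panel(seed=2025)
    mcmc = MCMCConfig(n_chains=2, n_samples=500, n_warmup=500, seed=0)
    trace = gpsbm.fit_tsbm(truth.panel, k=2, mcmc=mcmc)
    return truth, trace
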