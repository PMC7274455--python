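"""Forward simulation: temporal and static block-model panels, plus a
bursty synthetic spike-train generator for exercising the network-building
pipeline.

The default temporal configuration reproduces the synthetic validation
scenario used throughout the tests: 4 devices of 20 nodes with two fixed
communities of 10, DIV grid (11, 14, 18, 21, 25, 28, 31), kernel
sigma = 0.25, ell = 3, eps = 0.01 for both community-pair classes, and logit
offsets beta_11 = 0.5, beta_12 = -2, beta_22 = 0.7 — a modular regime with
many edges inside communities and few across.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import KernelParams, TemporalSBMParams, StaticSBMParams, link_eta
from .panel import FunctionalNetwork, NetworkPanel
from .ephys import SpikeRecording

__all__ = [
    "SyntheticTruth",
    "sample_tsbm",
    "sample_static_sbm",
    "validation_config",
    "sample_validation_panel",
    "simulate_spike_recording",
]

VALIDATION_DIVS = (11, 14, 18, 21, 25, 28, 31)


@dataclass
class SyntheticTruth:
    """A simulated panel together with the parameters that generated it."""

    params: TemporalSBMParams
    panel: NetworkPanel
    seed: int

    def __post_init__(self):
        d, T, n = (
            self.panel.n_devices,
            self.panel.n_divs,
            self.panel.n,
        )
        if self.params.z.shape != (d, n) or self.params.x.shape[2] != T:
            raise ValueError("panel dimensions do not match parameters")


def _symmetrize_draws(draw_fn, k, T, rng):
    """Fill a (k, k, T) array by drawing the upper triangle and mirroring."""
    out = np.zeros((k, k, T))
    for i in range(k):
        for j in range(i, k):
            out[i, j] = out[j, i] = draw_fn(i, j, rng)
    return out


def sample_tsbm(
    k: int,
    alpha,
    kernel_in: KernelParams,
    kernel_out: KernelParams,
    divs,
    n_nodes: int,
    n_devices: int,
    seed: int,
    beta=None,
    z=None,
) -> SyntheticTruth:
    """Draw a full temporal block-model panel.

    ``beta`` may fix the (k, k) offset table (otherwise beta_ij ~ N(0, 1) on
    the upper triangle, mirrored); ``z`` may fix the community assignment
    (one (n,) vector applied to every device, or a full (n_devices, n)
    table) — otherwise assignments are drawn from pi ~ Dirichlet(alpha).
    Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    divs = np.asarray(divs, dtype=float)
    T = len(divs)
    if T == 0:
        raise ValueError("divs grid must be non-empty")
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (k,)).copy()
    pi = rng.dirichlet(alpha)
    if z is None:
        z = rng.choice(k, size=(n_devices, n_nodes), p=pi)
    else:
        z = np.asarray(z, dtype=int)
        if z.ndim == 1:
            z = np.tile(z, (n_devices, 1))
        if z.shape != (n_devices, n_nodes):
            raise ValueError("z must be (n,) or (n_devices, n)")
    if beta is None:
        beta = np.zeros((k, k))
        tri = rng.standard_normal(k * (k + 1) // 2)
        iu, ju = np.triu_indices(k)
        beta[iu, ju] = tri
        beta[ju, iu] = beta[iu, ju]
    else:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (k, k) or not np.allclose(beta, beta.T):
            raise ValueError("beta must be a symmetric (k, k) table")
    L_in = kernel_in.cholesky(divs)
    L_out = kernel_out.cholesky(divs)

    def draw_x(i, j, rng):
        L = L_in if i == j else L_out
        return L @ rng.standard_normal(T)

    x = _symmetrize_draws(draw_x, k, T, rng)
    params = TemporalSBMParams(
        k=k, alpha=alpha, pi=pi, z=z,
        kernel_in=kernel_in, kernel_out=kernel_out,
        beta=beta, divs=divs, x=x,
    )
    eta = params.eta
    n = n_nodes
    iu, ju = np.triu_indices(n, k=1)
    adj = np.zeros((n_devices, T, n, n), dtype=np.uint8)
    for di in range(n_devices):
        p_pair = eta[z[di][iu], z[di][ju], :]  # (n_pairs, T)
        draws = (rng.random((len(iu), T)) < p_pair).astype(np.uint8)
        for ti in range(T):
            a = adj[di, ti]
            a[iu, ju] = draws[:, ti]
            a[ju, iu] = draws[:, ti]
    devices = [f"sim{di}" for di in range(n_devices)]
    panel = NetworkPanel(devices, list(divs.astype(int)), list(range(n)), adj)
    return SyntheticTruth(params=params, panel=panel, seed=int(seed))


def sample_static_sbm(
    k: int,
    alpha,
    a: float,
    b: float,
    n_nodes: int,
    n_devices: int,
    seed: int,
    eta=None,
    z=None,
):
    """Draw a static multi-device block model: a single eta ~ Beta(a, b)
    (upper triangle, mirrored) shared across devices, per-device z, and
    symmetric Bernoulli adjacencies. Returns (StaticSBMParams, [FunctionalNetwork])."""
    if a <= 0 or b <= 0:
        raise ValueError("Beta shapes a, b must be positive")
    rng = np.random.default_rng(seed)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (k,)).copy()
    pi = rng.dirichlet(alpha)
    if z is None:
        z = rng.choice(k, size=(n_devices, n_nodes), p=pi)
    else:
        z = np.asarray(z, dtype=int)
        if z.ndim == 1:
            z = np.tile(z, (n_devices, 1))
    if eta is None:
        eta = np.zeros((k, k))
        iu, ju = np.triu_indices(k)
        eta[iu, ju] = rng.beta(a, b, size=len(iu))
        eta[ju, iu] = eta[iu, ju]
    else:
        eta = np.asarray(eta, dtype=float)
    # clip so the container's open-interval invariant holds for fixed eta
    eta_c = np.clip(eta, 1e-12, 1 - 1e-12)
    params = StaticSBMParams(k=k, alpha=alpha, pi=pi, z=z, a=a, b=b, eta=eta_c)
    n = n_nodes
    iu, ju = np.triu_indices(n, k=1)
    networks = []
    for di in range(n_devices):
        p_pair = eta[z[di][iu], z[di][ju]]
        edges = (rng.random(len(iu)) < p_pair).astype(np.uint8)
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[iu, ju] = edges
        adj[ju, iu] = edges
        networks.append(
            FunctionalNetwork(adj, tuple(range(n)), f"dev{di}", 0)
        )
    return params, networks


def validation_config():
    """Generative configuration of the synthetic validation scenario."""
    kernel = KernelParams(sigma=0.25, ell=3.0, eps=0.01)
    beta = np.array([[0.5, -2.0], [-2.0, 0.7]])
    z = np.repeat([0, 1], 10)
    return {
        "k": 2,
        "alpha": np.ones(2),
        "kernel_in": kernel,
        "kernel_out": kernel,
        "beta": beta,
        "z": z,
        "divs": np.array(VALIDATION_DIVS, dtype=float),
        "n_nodes": 20,
        "n_devices": 4,
    }


def sample_validation_panel(seed: int) -> SyntheticTruth:
    """Simulate the synthetic validation panel: 4 devices x 20 nodes, two
    fixed communities of 10, with the configuration in
    :func:`validation_config`."""
    cfg = validation_config()
    return sample_tsbm(seed=seed, **cfg)


def simulate_spike_recording(
    n_channels: int = 20,
    duration: float = 300.0,
    seed: int = 0,
    communities=None,
    background_rate: float = 0.2,
    burst_rate: float = 0.1,
    burst_spikes: int = 6,
    burst_jitter: float = 0.03,
    participation: float = 0.9,
    device_id: str = "sim",
    div: int = 14,
) -> SpikeRecording:
    """Synthetic MEA recording with community-synchronized population bursts.

    Each community fires population events at ``burst_rate`` Hz; during an
    event every member channel (independently, with probability
    ``participation``) emits ``burst_spikes`` spikes jittered within
    ``burst_jitter`` seconds, so channel bursts on members start within a few
    tens of milliseconds of each other. A low background Poisson rate adds
    uncorrelated spikes. Channels in community < 0 stay silent, which is
    handy for emulating inactive electrodes.
    """
    rng = np.random.default_rng(seed)
    if communities is None:
        communities = np.zeros(n_channels, dtype=int)
    communities = np.asarray(communities, dtype=int)
    spikes = [[] for _ in range(n_channels)]
    for c in np.unique(communities):
        members = np.flatnonzero(communities == c)
        if c < 0:
            continue
        n_events = rng.poisson(burst_rate * duration)
        starts = rng.uniform(0, duration - 1.0, size=n_events)
        for t0 in starts:
            for ch in members:
                if rng.random() > participation:
                    continue
                offs = np.sort(rng.uniform(0, burst_jitter, size=burst_spikes))
                spikes[ch].extend(t0 + rng.uniform(0, 0.02) + offs)
    for ch in range(n_channels):
        if communities[ch] >= 0 and background_rate > 0:
            n_bg = rng.poisson(background_rate * duration)
            spikes[ch].extend(rng.uniform(0, duration, size=n_bg))
    cleaned = []
    for ch in range(n_channels):
        s = np.clip(np.asarray(spikes[ch], dtype=float), 0, duration)
        cleaned.append(np.unique(s))
    return SpikeRecording(
        device_id, div, duration,
        tuple(f"ch{c:02d}" for c in range(n_channels)),
        tuple(cleaned),
    )
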