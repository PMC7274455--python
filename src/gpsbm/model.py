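"""Model primitives: kernels, the logistic link, parameter containers and
the Bernoulli network likelihood.

The temporal block model assumes each node u of device d picks a fixed
community z_u^(d) ~ Categorical(pi), pi ~ Dirichlet(alpha). The probability
of an edge between communities i and j evolves smoothly over recording days
t:

    eta_ij(t) = sigmoid(beta_ij + x_ij(t)),   beta_ij ~ N(0, 1),
    x_ij ~ GP(0, kappa_in)  for i = j,
    x_ij ~ GP(0, kappa_out) for i != j,

with squared-exponential kernels kappa(t, t') = sigma^2 exp(-(t-t')^2 /
(2 ell^2)) plus a diagonal nugget eps. Edges are conditionally independent
Bernoulli draws given eta and z. The static multi-device variant replaces
eta_ij(t) by a single Beta(a, b)-distributed eta_ij shared across devices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

from .panel import NetworkPanel

__all__ = [
    "KernelParams",
    "se_kernel",
    "link_eta",
    "TemporalSBMParams",
    "StaticSBMParams",
    "log_likelihood",
]


@dataclass(frozen=True)
class KernelParams:
    """Squared-exponential kernel: output scale ``sigma``, length scale
    ``ell`` (in DIV units, i.e. days) and diagonal nugget ``eps``.

    The nugget sits only on the diagonal of the Gram matrix (t = t'); it
    keeps Cholesky factorizations stable and models day-specific jitter in
    the latent connectivity. ``eps = 0`` gives exact interpolation.
    """

    sigma: float
    ell: float
    eps: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0 or self.ell <= 0:
            raise ValueError("sigma and ell must be positive")
        if self.eps < 0:
            raise ValueError("eps must be non-negative")

    def gram(self, t, t_prime=None) -> np.ndarray:
        """Gram matrix K[a, b] = kappa(t[a], t_prime[b]); the nugget is added
        only where t[a] == t_prime[b] refer to the same diagonal position of
        a square, identical-grid Gram matrix."""
        t = np.asarray(t, dtype=float)
        same = t_prime is None
        tp = t if same else np.asarray(t_prime, dtype=float)
        d2 = (t[:, None] - tp[None, :]) ** 2
        K = self.sigma**2 * np.exp(-d2 / (2.0 * self.ell**2))
        if same:
            K = K + self.eps * np.eye(len(t))
        return K

    def cholesky(self, t, jitter: float = 1e-10) -> np.ndarray:
        K = self.gram(t)
        return np.linalg.cholesky(K + jitter * np.eye(len(K)))


def se_kernel(t: float, t_prime: float, kp: KernelParams) -> float:
    """kappa(t, t') = sigma^2 exp(-(t - t')^2 / (2 ell^2)), plus the nugget
    eps when t = t'."""
    val = kp.sigma**2 * np.exp(-((t - t_prime) ** 2) / (2.0 * kp.ell**2))
    if t == t_prime:
        val += kp.eps
    return float(val)


def link_eta(beta_ij, x):
    """Edge probability sigmoid(beta_ij + x), strictly inside (0, 1)."""
    return expit(np.asarray(beta_ij, dtype=float) + np.asarray(x, dtype=float))


def _check_symmetric(name, a, axes=(0, 1)):
    if not np.allclose(a, np.swapaxes(a, *axes)):
        raise ValueError(f"{name} must be symmetric in the community indices")


@dataclass
class TemporalSBMParams:
    """Full generative parameter set for the temporal block model."""

    k: int
    alpha: np.ndarray          # (k,) Dirichlet concentration
    pi: np.ndarray             # (k,) community weights
    z: np.ndarray              # (n_devices, n) assignments in 0..k-1
    kernel_in: KernelParams
    kernel_out: KernelParams
    beta: np.ndarray           # (k, k) symmetric logit offsets
    divs: np.ndarray           # (T,) DIV grid
    x: np.ndarray              # (k, k, T) latent GP values, symmetric in (i, j)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.z = np.asarray(self.z, dtype=int)
        self.beta = np.asarray(self.beta, dtype=float)
        self.divs = np.asarray(self.divs, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        k, T = self.k, len(self.divs)
        if self.alpha.shape != (k,) or self.pi.shape != (k,):
            raise ValueError("alpha and pi must have length k")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")
        if self.beta.shape != (k, k) or self.x.shape != (k, k, T):
            raise ValueError("beta must be (k, k) and x (k, k, T)")
        _check_symmetric("beta", self.beta)
        _check_symmetric("x", self.x)
        if self.z.ndim != 2 or self.z.min() < 0 or self.z.max() >= k:
            raise ValueError("z must be (n_devices, n) with labels in 0..k-1")

    @property
    def eta(self) -> np.ndarray:
        """(k, k, T) edge probabilities sigmoid(beta + x)."""
        return link_eta(self.beta[:, :, None], self.x)


@dataclass
class StaticSBMParams:
    """Time-free multi-device block model with conjugate Beta(a, b) edge
    probabilities shared across devices."""

    k: int
    alpha: np.ndarray
    pi: np.ndarray
    z: np.ndarray              # (n_devices, n)
    a: float
    b: float
    eta: np.ndarray            # (k, k) symmetric

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.z = np.asarray(self.z, dtype=int)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta shapes a, b must be positive")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")
        _check_symmetric("eta", self.eta)
        if np.any(self.eta <= 0) or np.any(self.eta >= 1):
            raise ValueError("eta entries must lie strictly in (0, 1)")


def log_likelihood(panel: NetworkPanel, params: TemporalSBMParams) -> float:
    """Sum over devices, observed DIVs and unordered node pairs u < v of the
    Bernoulli log-mass of A_uv given eta_{z_u z_v}(t)."""
    d, T, n = panel.n_devices, panel.n_divs, panel.n
    if params.z.shape != (d, n) or params.x.shape[2] != T:
        raise ValueError("parameter dimensions do not match the panel")
    logit = params.beta[:, :, None] + params.x  # (k, k, T)
    log_p = log_expit(logit)
    log_q = log_expit(-logit)
    total = 0.0
    iu, ju = np.triu_indices(n, k=1)
    for di in range(d):
        zi = params.z[di]
        bi, bj = zi[iu], zi[ju]
        for ti in range(T):
            if not panel.observed[di, ti]:
                continue
            a = panel.adjacency[di, ti][iu, ju]
            total += float(
                np.where(a == 1, log_p[bi, bj, ti], log_q[bi, bj, ti]).sum()
            )
    return total
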