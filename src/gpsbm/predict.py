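"""GP interpolation / extrapolation of the connection probabilities and
held-out posterior-predictive likelihood.

For each posterior draw, the latent x_ij at new DIVs follows the standard
Gaussian conditional given that draw's x_ij on the training grid and its
kernel hyperparameters; a latent sample is pushed through the sigmoid link
and aggregated across draws. Held-out networks are scored by the log
posterior-predictive mass: a mixture over draws (log-mean-exp of the
Bernoulli likelihood under each draw's labels and predicted eta).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit, logsumexp
from scipy.linalg import cho_factor, cho_solve

from .model import KernelParams
from .mcmc import PosteriorTrace

__all__ = ["predict_eta", "predictive_loglik"]

_JITTER = 1e-10


def _conditional_draw(x_train, divs, t_new, sigma, ell, eps, rng):
    """Sample x(t_new) | x(divs) for one draw's kernel parameters.

    x_train: (P, T) latent rows; returns (P, len(t_new)).
    """
    kp = KernelParams(sigma, ell, eps)
    K = kp.gram(divs) + _JITTER * np.eye(len(divs))
    Ks = kp.gram(divs, t_new)              # (T, T*), no nugget off the grid
    Kss = kp.gram(t_new)                   # nugget on the new diagonal
    cf = cho_factor(K, lower=True)
    A = cho_solve(cf, Ks)                  # K^-1 Ks, (T, T*)
    mean = x_train @ A                     # (P, T*)
    cov = Kss - Ks.T @ A
    cov = (cov + cov.T) / 2 + _JITTER * np.eye(len(t_new))
    Lc = np.linalg.cholesky(cov)
    noise = rng.standard_normal((x_train.shape[0], len(t_new))) @ Lc.T
    return mean, mean + noise


def _eta_star_draws(trace: PosteriorTrace, t_new, rng, sample_latent=True):
    """(S, k, k, T*) predictive eta draws at t_new."""
    t_new = np.atleast_1d(np.asarray(t_new, dtype=float))
    if trace.kind == "static":
        return np.repeat(trace.eta_static[:, :, :, None], len(t_new), axis=3)
    k, divs = trace.k, np.asarray(trace.divs, dtype=float)
    iu, ju = np.triu_indices(k)
    diag = iu == ju
    S = trace.n_draws
    out = np.empty((S, k, k, len(t_new)))
    x_flat = trace.x[:, iu, ju, :]         # (S, P, T)
    b_flat = trace.beta[:, iu, ju]         # (S, P)
    eps = trace.priors.eps
    for s in range(S):
        xs = np.empty((len(iu), len(t_new)))
        for which, sel in (("in", diag), ("out", ~diag)):
            if not sel.any():
                continue
            sigma = trace.sigma_in[s] if which == "in" else trace.sigma_out[s]
            ell = trace.ell_in[s] if which == "in" else trace.ell_out[s]
            mean, draw = _conditional_draw(
                x_flat[s, sel], divs, t_new, sigma, ell, eps, rng
            )
            xs[sel] = draw if sample_latent else mean
        eta_flat = expit(b_flat[s][:, None] + xs)
        eta = np.empty((k, k, len(t_new)))
        eta[iu, ju] = eta_flat
        eta[ju, iu] = eta_flat
        out[s] = eta
    return out


def predict_eta(
    trace: PosteriorTrace,
    t_new,
    seed: int = 0,
    ci_prob: float = 0.94,
    sample_latent: bool = True,
):
    """Predictive mean and central credible band of eta at new DIVs.

    ``t_new`` may interpolate inside the training grid or extrapolate
    beyond it; far extrapolation (beyond 3 posterior-mean length scales
    from the grid) reverts to the GP prior and triggers a wide-interval
    warning. With ``sample_latent=False`` the conditional mean is used
    instead of a latent sample (no nugget/conditional noise).
    Returns (mean, ci, draws) with shapes (k, k, T*), (2, k, k, T*),
    (S, k, k, T*).
    """
    t_new = np.atleast_1d(np.asarray(t_new, dtype=float))
    divs = np.asarray(trace.divs, dtype=float)
    if trace.kind == "temporal":
        ell_bar = max(float(trace.ell_in.mean()), float(trace.ell_out.mean()))
        dist = np.maximum(divs.min() - t_new, t_new - divs.max()).clip(min=0)
        if np.any(dist > 3 * ell_bar):
            warnings.warn(
                "prediction requested beyond 3 length scales from the "
                "training grid; intervals there revert to the prior and "
                "will be wide",
                UserWarning,
            )
    rng = np.random.default_rng(seed)
    draws = _eta_star_draws(trace, t_new, rng, sample_latent=sample_latent)
    lo, hi = (1 - ci_prob) / 2, 1 - (1 - ci_prob) / 2
    mean = draws.mean(axis=0)
    ci = np.stack(
        [np.quantile(draws, lo, axis=0), np.quantile(draws, hi, axis=0)]
    )
    return mean, ci, draws


def predictive_loglik(
    trace: PosteriorTrace,
    heldout: np.ndarray,
    t_star: float,
    seed: int = 0,
) -> float:
    """Log posterior-predictive mass of held-out networks at DIV ``t_star``.

    ``heldout`` is an (n_devices, n, n) stack of binary adjacencies on the
    training node set, one per device in the trace's device order. Per
    posterior draw, eta at t_star is predicted from that draw's latents and
    the Bernoulli log-likelihood is evaluated under that draw's labels; the
    result is log-mean-exp across draws.
    """
    heldout = np.asarray(heldout)
    if heldout.ndim == 2:
        heldout = heldout[None]
    S = trace.n_draws
    d = heldout.shape[0]
    n = heldout.shape[1]
    if trace.z.shape[1] != d or trace.z.shape[2] != n:
        raise ValueError("held-out networks must match the trace's devices and nodes")
    rng = np.random.default_rng(seed)
    eta_star = _eta_star_draws(trace, [float(t_star)], rng)[:, :, :, 0]
    iu, ju = np.triu_indices(n, k=1)
    lls = np.empty(S)
    for s in range(S):
        eta = np.clip(eta_star[s], 1e-12, 1 - 1e-12)
        total = 0.0
        for di in range(d):
            zi = trace.z[s, di]
            p = eta[zi[iu], zi[ju]]
            a = heldout[di][iu, ju]
            total += float(np.sum(np.where(a == 1, np.log(p), np.log1p(-p))))
        lls[s] = total
    return float(logsumexp(lls) - np.log(S))
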