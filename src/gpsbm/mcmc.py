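"""MCMC inference for the temporal and static multi-device block models.

Sampler design
--------------
The joint posterior mixes discrete per-device community labels z with
continuous GP quantities, so a compound kernel is used:

* **z** — exact categorical Gibbs sweeps. The full conditional of z_u^(d)
  given everything else costs O(k^2 T) per node via community-wise edge
  counts.
* **pi** — conjugate Dirichlet update given the label counts.
* **(beta_ij, x_ij)** — elliptical slice sampling per community pair on the
  whitened vector (beta_ij, v_ij) where x_ij = L v_ij, L the Cholesky
  factor of the kernel Gram matrix. After whitening the prior is exactly
  standard normal, which is the regime elliptical slice sampling is exact
  for, and the non-centered parameterization avoids the funnel at small
  sigma.
* **kernel hyperparameters** — random-walk Metropolis on (log sigma,
  log ell) per kernel class (within / between communities), with step sizes
  adapted toward a 30% acceptance rate during warmup only. eps is fixed.

Priors (deliberately weak): alpha_i = 1; sigma ~ half-normal(1);
ell ~ Gamma with mean a third of the DIV-grid span, truncated below at half
the smallest DIV gap so the latent curves cannot wiggle between adjacent
recordings; beta_ij ~ N(0, 1).

The static model is fully conjugate (Beta-Bernoulli) and uses Gibbs updates
throughout, with a single time-free eta shared across devices and one label
vector per device (shared across that device's DIVs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import log_expit, logsumexp

from .panel import NetworkPanel
from .model import KernelParams

__all__ = [
    "MCMCConfig",
    "PriorSpec",
    "PosteriorTrace",
    "fit_tsbm",
    "fit_static_sbm",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout. ``n_samples`` is the post-warmup target per chain; by
    default the first half of each chain (``n_warmup = n_samples``) is
    discarded, mirroring the run-half-then-keep-half convention."""

    n_chains: int = 2
    n_samples: int = 1000
    n_warmup: int | None = None
    seed: int = 0
    thin: int = 1

    def __post_init__(self):
        if self.n_chains < 1 or self.n_samples < 1 or self.thin < 1:
            raise ValueError("n_chains, n_samples and thin must be positive")
        if self.n_warmup is not None and self.n_warmup < 0:
            raise ValueError("n_warmup must be non-negative")

    @property
    def warmup(self) -> int:
        return self.n_samples if self.n_warmup is None else self.n_warmup


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the weak default priors."""

    alpha: float = 1.0
    sigma_scale: float = 0.5
    ell_shape: float = 2.0
    ell_mean: float | None = None   # default: 1.5 x median DIV gap
    ell_min: float | None = None    # default: smallest DIV gap / 2
    eps: float = 1e-2
    a: float = 1.0                  # static-model Beta shapes
    b: float = 1.0

    def resolved(self, divs: np.ndarray) -> "PriorSpec":
        divs = np.sort(np.asarray(divs, dtype=float))
        gaps = np.diff(divs) if len(divs) > 1 else np.array([1.0])
        # the length-scale prior concentrates near the sampling resolution:
        # a much longer scale makes the latent curve an approximate
        # constant, which is beta's job, not the GP's
        ell_mean = (
            self.ell_mean if self.ell_mean is not None
            else max(1.5 * float(np.median(gaps)), 1e-6)
        )
        ell_min = self.ell_min if self.ell_min is not None else float(gaps.min()) / 2.0
        return replace(self, ell_mean=ell_mean, ell_min=ell_min)


@dataclass
class PosteriorTrace:
    """Posterior draws with chain metadata.

    For temporal fits the draws cover z, beta, the latent x, the kernel
    hyperparameters and pi; for static fits z, eta and pi. ``chain`` and
    ``iteration`` index each stored draw; ``diagnostics`` carries split
    R-hat / effective-sample-size summaries and sampler health flags.
    """

    kind: str                       # "temporal" | "static"
    k: int
    divs: np.ndarray
    devices: list
    config: MCMCConfig
    priors: PriorSpec
    z: np.ndarray                   # (S, n_devices, n)
    pi: np.ndarray                  # (S, k)
    chain: np.ndarray               # (S,)
    iteration: np.ndarray           # (S,)
    loglik: np.ndarray              # (S,)
    beta: np.ndarray | None = None  # (S, k, k)
    x: np.ndarray | None = None     # (S, k, k, T)
    sigma_in: np.ndarray | None = None
    ell_in: np.ndarray | None = None
    sigma_out: np.ndarray | None = None
    ell_out: np.ndarray | None = None
    eta_static: np.ndarray | None = None  # (S, k, k)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.z.shape[0]

    def eta_draws(self) -> np.ndarray:
        """(S, k, k, T) edge-probability draws."""
        from scipy.special import expit

        if self.kind == "temporal":
            return expit(self.beta[:, :, :, None] + self.x)
        return np.repeat(self.eta_static[:, :, :, None], len(self.divs), axis=3)

    def last_draws(self, last_n: int) -> np.ndarray:
        """Indices of the final ``last_n`` draws, taken evenly from the tail
        of each chain (chains are interleaved in storage order)."""
        if last_n > self.n_draws:
            raise ValueError(f"last_n={last_n} exceeds {self.n_draws} draws")
        chains = np.unique(self.chain)
        per = int(math.ceil(last_n / len(chains)))
        idx = []
        for c in chains:
            ci = np.flatnonzero(self.chain == c)
            idx.extend(ci[-per:])
        idx = np.sort(np.asarray(idx))[-last_n:]
        return idx

    def save(self, path):
        arrays = {
            f: getattr(self, f)
            for f in (
                "z", "pi", "chain", "iteration", "loglik", "beta", "x",
                "sigma_in", "ell_in", "sigma_out", "ell_out", "eta_static",
            )
            if getattr(self, f) is not None
        }
        np.savez_compressed(
            path,
            kind=self.kind, k=self.k, divs=self.divs,
            devices=np.asarray(self.devices, dtype=object),
            **arrays,
        )

    @classmethod
    def load(cls, path, config: MCMCConfig | None = None,
             priors: PriorSpec | None = None) -> "PosteriorTrace":
        data = np.load(path, allow_pickle=True)
        fields = {}
        for f in ("z", "pi", "chain", "iteration", "loglik", "beta", "x",
                  "sigma_in", "ell_in", "sigma_out", "ell_out", "eta_static"):
            fields[f] = data[f] if f in data.files else None
        return cls(
            kind=str(data["kind"]), k=int(data["k"]),
            divs=np.asarray(data["divs"], dtype=float),
            devices=list(data["devices"]),
            config=config or MCMCConfig(),
            priors=priors or PriorSpec(),
            **fields,
        )


# ---------------------------------------------------------------------------
# shared helpers


def _validate_panel(panel: NetworkPanel):
    for di in range(panel.n_devices):
        for ti in range(panel.n_divs):
            if not panel.observed[di, ti]:
                continue
            a = panel.adjacency[di, ti]
            if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
                raise ValueError(
                    f"adjacency for device {panel.devices[di]!r} at DIV "
                    f"{panel.divs[ti]} is not symmetric and hollow"
                )
            if not np.isin(np.unique(a), (0, 1)).all():
                raise ValueError("adjacency entries must be binary")


def _one_hot(z: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(z), k))
    out[np.arange(len(z)), z] = 1.0
    return out


def _spectral_init(panel: NetworkPanel, k: int, rng) -> np.ndarray:
    """Per-device spectral clustering of the time-averaged adjacency; a
    cheap, data-driven starting point for the label sweeps.

    Because eta is shared across devices, community labels must mean the
    same thing in every device; each device's clustering is aligned to the
    first device's by maximum node overlap (electrodes are physically the
    same across devices, so overlap is an informative anchor)."""
    from scipy.optimize import linear_sum_assignment
    from sklearn.cluster import KMeans

    d, n = panel.n_devices, panel.n
    z0 = np.zeros((d, n), dtype=int)
    for di in range(d):
        obs = panel.observed[di]
        if not obs.any():
            z0[di] = rng.integers(0, k, size=n)
            continue
        mean_a = panel.adjacency[di, obs].mean(axis=0)
        vals, vecs = np.linalg.eigh(mean_a)
        emb = vecs[:, -min(k, n):]
        km = KMeans(
            n_clusters=min(k, n), n_init=5,
            random_state=int(rng.integers(2**31 - 1)),
        )
        z0[di] = km.fit_predict(emb)
    for di in range(1, d):
        overlap = np.zeros((k, k))
        for i in range(k):
            mask = z0[di] == i
            for j in range(k):
                overlap[i, j] = np.sum(mask & (z0[0] == j))
        rows, cols = linear_sum_assignment(-overlap)
        p = np.arange(k)
        p[rows] = cols
        z0[di] = p[z0[di]]
    return z0


def _empirical_beta(m: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Smoothed empirical logits of the block densities under an initial
    labeling — a data-driven start for the offsets."""
    dens = (m.sum(axis=1) + 0.5) / (N.sum(axis=1) + 1.0)
    return np.log(dens / (1.0 - dens))


def _ess_update(w, loglik_fn, rng):
    """One elliptical-slice-sampling update for w with N(0, I) prior."""
    nu = rng.standard_normal(w.shape)
    log_y = loglik_fn(w) + math.log(rng.random())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    lo, hi = theta - 2.0 * math.pi, theta
    while True:
        w_new = w * math.cos(theta) + nu * math.sin(theta)
        if loglik_fn(w_new) > log_y:
            return w_new
        if theta < 0:
            lo = theta
        else:
            hi = theta
        theta = rng.uniform(lo, hi)


def _pair_counts(panel: NetworkPanel, z: np.ndarray, k: int):
    """Sufficient statistics given z: per community pair (upper triangle,
    flattened) and DIV, the observed edge count m and pair total N."""
    iu, ju = np.triu_indices(k)
    P, T = len(iu), panel.n_divs
    m = np.zeros((P, T))
    N = np.zeros((P, T))
    diag = iu == ju
    for di in range(panel.n_devices):
        Z = _one_hot(z[di], k)
        s = Z.sum(axis=0)
        n_within = s * (s - 1) / 2.0
        n_cross = np.outer(s, s)
        obs = np.flatnonzero(panel.observed[di])
        if len(obs) == 0:
            continue
        M = np.einsum("ui,tuv,vj->tij", Z, panel.adjacency[di, obs].astype(float), Z)
        for a, t in enumerate(obs):
            mk = M[a]
            m[diag, t] += np.diag(mk)[iu[diag]] / 2.0
            m[~diag, t] += mk[iu[~diag], ju[~diag]]
        for t in obs:
            N[diag, t] += n_within[iu[diag]]
            N[~diag, t] += n_cross[iu[~diag], ju[~diag]]
    return m, N


def _pair_loglik(beta, x, m, N):
    g = beta + x
    return float(np.sum(m * log_expit(g) + (N - m) * log_expit(-g)))


def _gp_logpdf(x_rows: np.ndarray, L: np.ndarray) -> float:
    """Sum of N(0, L L^T) log-densities over the rows of x_rows (constants
    dropped except the log-determinant, which depends on the kernel)."""
    w = solve_triangular(L, x_rows.T, lower=True)
    return float(-0.5 * np.sum(w**2) - x_rows.shape[0] * np.log(np.diag(L)).sum())


def _ridge_shift(beta_p, v_p, u, denom, rng):
    """Exact Gibbs move along the likelihood-degenerate direction
    (beta += delta, x -= delta).

    With x = L v and u = L^-1 1, shifting v by -delta*u translates x by the
    constant -delta, so beta + x(t) — and hence the likelihood — is
    unchanged; the standard-normal priors make the conditional of delta
    Gaussian with precision 1 + u.u. Without this move the offset/latent
    split mixes very slowly and beta shrinks toward wherever the chain
    started on the ridge."""
    mean = (-beta_p + u @ v_p) / denom
    delta = mean + rng.standard_normal() / math.sqrt(denom)
    return beta_p + delta, v_p - delta * u, delta


def _log_prior_kernel(sigma, ell, pr: PriorSpec):
    lp = -0.5 * (sigma / pr.sigma_scale) ** 2
    scale = pr.ell_mean / pr.ell_shape
    lp += (pr.ell_shape - 1.0) * math.log(ell) - ell / scale
    return lp


# ---------------------------------------------------------------------------
# temporal sampler


def _run_tsbm_chain(panel, k, n_iter, keep_from, thin, priors, rng, init):
    d, T, n = panel.n_devices, panel.n_divs, panel.n
    A = panel.adjacency.astype(float)
    obs = panel.observed
    divs = np.asarray(panel.divs, dtype=float)
    iu, ju = np.triu_indices(k)
    P = len(iu)
    diag_mask = iu == ju
    in_pairs = np.flatnonzero(diag_mask)
    out_pairs = np.flatnonzero(~diag_mask)

    alpha = np.full(k, priors.alpha)
    # initial state
    if init == "spectral" and d > 0:
        z = _spectral_init(panel, k, rng)
    else:
        z = rng.integers(0, k, size=(d, n))
    pi = rng.dirichlet(alpha)
    beta = rng.standard_normal(P)
    v = rng.standard_normal((P, T))
    sigma = {"in": abs(rng.normal(0, priors.sigma_scale)) + 1e-3,
             "out": abs(rng.normal(0, priors.sigma_scale)) + 1e-3}
    scale = priors.ell_mean / priors.ell_shape
    ell = {"in": max(rng.gamma(priors.ell_shape, scale), priors.ell_min),
           "out": max(rng.gamma(priors.ell_shape, scale), priors.ell_min)}

    def chol(which):
        kp = KernelParams(sigma[which], ell[which], priors.eps)
        return kp.cholesky(divs)

    L = {"in": chol("in"), "out": chol("out")}
    x = np.empty((P, T))
    x[in_pairs] = v[in_pairs] @ L["in"].T
    x[out_pairs] = v[out_pairs] @ L["out"].T

    # burn the latents in against the initial labeling before the first z
    # sweep, so the first sweep sees a data-adapted eta instead of a prior
    # draw (which would scramble a good initialization)
    if d > 0:
        m0, N0 = _pair_counts(panel, z, k)
        beta = _empirical_beta(m0, N0)
        v[:] = 0.0
        x[in_pairs] = v[in_pairs] @ L["in"].T
        x[out_pairs] = v[out_pairs] @ L["out"].T
        for _ in range(20):
            for p in range(P):
                Lp = L["in"] if diag_mask[p] else L["out"]
                mp, Np = m0[p], N0[p]

                def ll_fn(w):
                    return _pair_loglik(w[0], Lp @ w[1:], mp, Np)

                w = np.concatenate(([beta[p]], v[p]))
                w = _ess_update(w, ll_fn, rng)
                beta[p], v[p] = w[0], w[1:]
            for which, pairs in (("in", in_pairs), ("out", out_pairs)):
                if len(pairs) == 0:
                    continue
                u = solve_triangular(L[which], np.ones(T), lower=True)
                denom = 1.0 + u @ u
                for p in pairs:
                    beta[p], v[p], _ = _ridge_shift(
                        beta[p], v[p], u, denom, rng
                    )
        x[in_pairs] = v[in_pairs] @ L["in"].T
        x[out_pairs] = v[out_pairs] @ L["out"].T

    step = {"in": 0.15, "out": 0.15}
    accept = {"in": 0, "out": 0}
    tries = {"in": 0, "out": 0}

    n_keep = (n_iter - keep_from + thin - 1) // thin
    store = {
        "z": np.empty((n_keep, d, n), dtype=np.int16),
        "pi": np.empty((n_keep, k)),
        "beta": np.empty((n_keep, k, k)),
        "x": np.empty((n_keep, k, k, T)),
        "sigma_in": np.empty(n_keep),
        "ell_in": np.empty(n_keep),
        "sigma_out": np.empty(n_keep),
        "ell_out": np.empty(n_keep),
        "iteration": np.empty(n_keep, dtype=int),
        "loglik": np.empty(n_keep),
    }
    pair_of = np.zeros((k, k), dtype=int)
    pair_of[iu, ju] = np.arange(P)
    pair_of[ju, iu] = np.arange(P)

    s_idx = 0
    for it in range(n_iter):
        # eta tables for the label sweep
        g = beta[:, None] + x                     # (P, T)
        log_p_flat = log_expit(g)
        log_q_flat = log_expit(-g)
        log_p = log_p_flat[pair_of]               # (k, k, T)
        log_q = log_q_flat[pair_of]
        log_pi = np.log(pi)

        # --- z: categorical Gibbs sweep
        for di in range(d):
            tobs = np.flatnonzero(obs[di])
            if len(tobs) == 0:
                z[di] = rng.choice(k, size=n, p=pi)
                continue
            Ad = A[di, tobs]                      # (To, n, n)
            lp_t = log_p[:, :, tobs]              # (k, k, To)
            lq_t = log_q[:, :, tobs]
            Z = _one_hot(z[di], k)
            for u in range(n):
                Z[u] = 0.0
                s = Z.sum(axis=0)
                e = Ad[:, u, :] @ Z               # (To, k)
                ll = (
                    np.einsum("tc,ict->i", e, lp_t)
                    + np.einsum("tc,ict->i", s[None, :] - e, lq_t)
                )
                logits = log_pi + ll
                pr = np.exp(logits - logsumexp(logits))
                znew = int(np.searchsorted(np.cumsum(pr), rng.random()))
                znew = min(znew, k - 1)
                z[di, u] = znew
                Z[u, znew] = 1.0

        # --- pi: conjugate Dirichlet
        counts = np.bincount(z.ravel(), minlength=k) if d > 0 else np.zeros(k)
        pi = rng.dirichlet(alpha + counts)

        # --- (beta, v) per pair: elliptical slice sampling, then an exact
        # Gibbs shift along the beta/latent-offset ridge
        m, N = _pair_counts(panel, z, k)
        for p in range(P):
            Lp = L["in"] if diag_mask[p] else L["out"]
            mp, Np = m[p], N[p]

            def ll_fn(w):
                return _pair_loglik(w[0], Lp @ w[1:], mp, Np)

            w = np.concatenate(([beta[p]], v[p]))
            w = _ess_update(w, ll_fn, rng)
            beta[p], v[p] = w[0], w[1:]
        for which, pairs in (("in", in_pairs), ("out", out_pairs)):
            if len(pairs) == 0:
                continue
            u = solve_triangular(L[which], np.ones(T), lower=True)
            denom = 1.0 + u @ u
            for p in pairs:
                beta[p], v[p], _ = _ridge_shift(beta[p], v[p], u, denom, rng)
        x[in_pairs] = v[in_pairs] @ L["in"].T
        x[out_pairs] = v[out_pairs] @ L["out"].T

        # --- kernel hyperparameters: RW Metropolis on the log scale.
        # Several proposals per sweep: each is cheap next to the label sweep
        # and the scale/length posteriors mix slowly otherwise.
        for which, pairs in (("in", in_pairs), ("out", out_pairs)):
            cur_ll = sum(
                _pair_loglik(beta[p], x[p], m[p], N[p]) for p in pairs
            )
            for _ in range(5):
                ls, le = math.log(sigma[which]), math.log(ell[which])
                ls_n = ls + step[which] * rng.standard_normal()
                le_n = le + step[which] * rng.standard_normal()
                sig_n, ell_n = math.exp(ls_n), math.exp(le_n)
                tries[which] += 1
                if ell_n >= priors.ell_min:
                    L_n = KernelParams(sig_n, ell_n, priors.eps).cholesky(divs)
                    x_n = v[pairs] @ L_n.T
                    new_ll = sum(
                        _pair_loglik(beta[p], x_n[a], m[p], N[p])
                        for a, p in enumerate(pairs)
                    )
                    log_acc = (
                        new_ll - cur_ll
                        + _log_prior_kernel(sig_n, ell_n, priors)
                        - _log_prior_kernel(sigma[which], ell[which], priors)
                        + (ls_n - ls) + (le_n - le)   # log-scale Jacobians
                    )
                    if math.log(rng.random()) < log_acc:
                        sigma[which], ell[which] = sig_n, ell_n
                        L[which] = L_n
                        x[pairs] = x_n
                        cur_ll = new_ll
                        accept[which] += 1
                # warmup-only step adaptation toward ~30% acceptance
                if it < keep_from and tries[which] >= 50:
                    rate = accept[which] / tries[which]
                    step[which] *= 1.1 if rate > 0.3 else 1 / 1.1
                    step[which] = min(max(step[which], 0.01), 1.0)
                    accept[which] = 0
                    tries[which] = 0

        # --- interweaved centered kernel update: hold x fixed, sample
        # (sigma, ell) from prior * N(x; 0, K), then re-whiten v. The
        # whitened update above mixes poorly when the latent amplitude is
        # data-determined; the centered form sees it directly.
        for which, pairs in (("in", in_pairs), ("out", out_pairs)):
            if len(pairs) == 0:
                continue
            X_c = x[pairs]
            cur = _gp_logpdf(X_c, L[which])
            for _ in range(5):
                ls, le = math.log(sigma[which]), math.log(ell[which])
                ls_n = ls + step[which] * rng.standard_normal()
                le_n = le + step[which] * rng.standard_normal()
                sig_n, ell_n = math.exp(ls_n), math.exp(le_n)
                if ell_n < priors.ell_min:
                    continue
                L_n = KernelParams(sig_n, ell_n, priors.eps).cholesky(divs)
                new = _gp_logpdf(X_c, L_n)
                log_acc = (
                    new - cur
                    + _log_prior_kernel(sig_n, ell_n, priors)
                    - _log_prior_kernel(sigma[which], ell[which], priors)
                    + (ls_n - ls) + (le_n - le)
                )
                if math.log(rng.random()) < log_acc:
                    sigma[which], ell[which] = sig_n, ell_n
                    L[which] = L_n
                    cur = new
            v[pairs] = solve_triangular(L[which], X_c.T, lower=True).T

        # --- store
        if it >= keep_from and (it - keep_from) % thin == 0:
            store["z"][s_idx] = z
            store["pi"][s_idx] = pi
            bfull = np.zeros((k, k))
            bfull[iu, ju] = beta
            bfull[ju, iu] = beta
            store["beta"][s_idx] = bfull
            xfull = np.zeros((k, k, T))
            xfull[iu, ju] = x
            xfull[ju, iu] = x
            store["x"][s_idx] = xfull
            store["sigma_in"][s_idx] = sigma["in"]
            store["ell_in"][s_idx] = ell["in"]
            store["sigma_out"][s_idx] = sigma["out"]
            store["ell_out"][s_idx] = ell["out"]
            store["iteration"][s_idx] = it
            store["loglik"][s_idx] = sum(
                _pair_loglik(beta[p], x[p], m[p], N[p]) for p in range(P)
            )
            s_idx += 1
    return store


def _compute_diagnostics(per_chain_scalars: dict) -> dict:
    """Split R-hat and bulk ESS on scalar continuous parameters via arviz."""
    import warnings

    import arviz as az

    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, chains in per_chain_scalars.items():
            arr = np.stack(chains)  # (chain, draw)
            if arr.shape[1] < 4:
                continue
            data = az.convert_to_dataset({name: arr})
            out[f"rhat_{name}"] = float(az.rhat(data)[name].values)
            out[f"ess_{name}"] = float(az.ess(data)[name].values)
    rhats = [val for key, val in out.items() if key.startswith("rhat_")]
    out["max_rhat"] = max(rhats) if rhats else float("nan")
    out["converged"] = bool(out["max_rhat"] < 1.05) if rhats else True
    return out


def fit_tsbm(
    panel: NetworkPanel,
    k: int,
    mcmc: MCMCConfig = MCMCConfig(),
    priors: PriorSpec = PriorSpec(),
    init: str = "spectral",
) -> PosteriorTrace:
    """Posterior sampling for the temporal block model.

    Returns a :class:`PosteriorTrace` holding ``n_chains x n_samples`` kept
    draws (after warmup and thinning) of z, beta, x, the kernel
    hyperparameters and pi, with convergence diagnostics attached.
    Identical (panel, k, mcmc, priors, init) inputs give identical traces.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _validate_panel(panel)
    divs = np.asarray(panel.divs, dtype=float)
    priors = priors.resolved(divs)
    n_iter = mcmc.warmup + mcmc.n_samples * mcmc.thin
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    stores = []
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(seeds[c])
        stores.append(
            _run_tsbm_chain(
                panel, k, n_iter, mcmc.warmup, mcmc.thin, priors, rng, init
            )
        )
    cat = {key: np.concatenate([s[key] for s in stores]) for key in stores[0]}
    chain_idx = np.concatenate(
        [np.full(len(s["iteration"]), c) for c, s in enumerate(stores)]
    )
    scalars = {
        name: [s[name] for s in stores]
        for name in ("sigma_in", "ell_in", "sigma_out", "ell_out", "loglik")
    }
    diagnostics = _compute_diagnostics(scalars)
    return PosteriorTrace(
        kind="temporal", k=k, divs=divs, devices=list(panel.devices),
        config=mcmc, priors=priors,
        z=cat["z"], pi=cat["pi"], chain=chain_idx, iteration=cat["iteration"],
        loglik=cat["loglik"], beta=cat["beta"], x=cat["x"],
        sigma_in=cat["sigma_in"], ell_in=cat["ell_in"],
        sigma_out=cat["sigma_out"], ell_out=cat["ell_out"],
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# static sampler


def _run_static_chain(panel, k, n_iter, keep_from, thin, priors, rng, init):
    d, T, n = panel.n_devices, panel.n_divs, panel.n
    A = panel.adjacency.astype(float)
    obs = panel.observed
    iu, ju = np.triu_indices(k)
    alpha = np.full(k, priors.alpha)
    if init == "spectral" and d > 0:
        z = _spectral_init(panel, k, rng)
    else:
        z = rng.integers(0, k, size=(d, n))
    pi = rng.dirichlet(alpha)
    eta = rng.beta(priors.a, priors.b, size=(k, k))
    eta[ju, iu] = eta[iu, ju]
    if d > 0:
        # start eta at the smoothed empirical block densities of the initial
        # labeling so the first z sweep does not undo the initialization
        m0, N0 = _pair_counts(panel, z, k)
        dens = (m0.sum(axis=1) + priors.a) / (N0.sum(axis=1) + priors.a + priors.b)
        eta = np.zeros((k, k))
        eta[iu, ju] = dens
        eta[ju, iu] = dens

    n_keep = (n_iter - keep_from + thin - 1) // thin
    store = {
        "z": np.empty((n_keep, d, n), dtype=np.int16),
        "pi": np.empty((n_keep, k)),
        "eta_static": np.empty((n_keep, k, k)),
        "iteration": np.empty(n_keep, dtype=int),
        "loglik": np.empty(n_keep),
    }
    s_idx = 0
    for it in range(n_iter):
        log_p = np.log(np.clip(eta, 1e-12, None))
        log_q = np.log(np.clip(1.0 - eta, 1e-12, None))
        log_pi = np.log(pi)
        # z sweep: eta is time-free, so per-node counts sum over observed DIVs
        for di in range(d):
            tobs = np.flatnonzero(obs[di])
            if len(tobs) == 0:
                z[di] = rng.choice(k, size=n, p=pi)
                continue
            Ad = A[di, tobs]
            Z = _one_hot(z[di], k)
            for u in range(n):
                Z[u] = 0.0
                s = Z.sum(axis=0)
                e = (Ad[:, u, :] @ Z).sum(axis=0)          # (k,)
                tot = len(tobs) * s
                ll = log_p @ e + log_q @ (tot - e)
                logits = log_pi + ll
                pr = np.exp(logits - logsumexp(logits))
                znew = min(int(np.searchsorted(np.cumsum(pr), rng.random())), k - 1)
                z[di, u] = znew
                Z[u, znew] = 1.0
        counts = np.bincount(z.ravel(), minlength=k) if d > 0 else np.zeros(k)
        pi = rng.dirichlet(alpha + counts)
        # eta: conjugate Beta update per community pair
        m, N = _pair_counts(panel, z, k)
        m_tot, N_tot = m.sum(axis=1), N.sum(axis=1)
        draws = rng.beta(priors.a + m_tot, priors.b + N_tot - m_tot)
        eta = np.zeros((k, k))
        eta[iu, ju] = draws
        eta[ju, iu] = draws
        if it >= keep_from and (it - keep_from) % thin == 0:
            store["z"][s_idx] = z
            store["pi"][s_idx] = pi
            store["eta_static"][s_idx] = eta
            store["iteration"][s_idx] = it
            ll = float(
                np.sum(
                    m_tot * np.log(np.clip(draws, 1e-12, None))
                    + (N_tot - m_tot) * np.log(np.clip(1 - draws, 1e-12, None))
                )
            )
            store["loglik"][s_idx] = ll
            s_idx += 1
    return store


def fit_static_sbm(
    networks,
    k: int,
    mcmc: MCMCConfig = MCMCConfig(),
    priors: PriorSpec = PriorSpec(),
    init: str = "spectral",
) -> PosteriorTrace:
    """Posterior sampling for the static multi-device block model.

    ``networks`` may be a :class:`NetworkPanel` (per-device labels shared
    across that device's DIVs) or a list of FunctionalNetworks (each treated
    as its own device at a single time point). eta is a single symmetric
    (k, k) table with a conjugate Beta(a, b) prior, shared across devices.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(networks, NetworkPanel):
        panel = networks
    else:
        networks = list(networks)
        n = networks[0].n
        adj = np.stack([g.adjacency for g in networks])[:, None]
        panel = NetworkPanel(
            [f"net{i}" for i in range(len(networks))], [0],
            list(networks[0].channels), adj,
        )
    _validate_panel(panel)
    divs = np.asarray(panel.divs, dtype=float)
    priors = priors.resolved(divs)
    n_iter = mcmc.warmup + mcmc.n_samples * mcmc.thin
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    stores = []
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(seeds[c])
        stores.append(
            _run_static_chain(
                panel, k, n_iter, mcmc.warmup, mcmc.thin, priors, rng, init
            )
        )
    cat = {key: np.concatenate([s[key] for s in stores]) for key in stores[0]}
    chain_idx = np.concatenate(
        [np.full(len(s["iteration"]), c) for c, s in enumerate(stores)]
    )
    diagnostics = _compute_diagnostics({"loglik": [s["loglik"] for s in stores]})
    return PosteriorTrace(
        kind="static", k=k, divs=divs, devices=list(panel.devices),
        config=mcmc, priors=priors,
        z=cat["z"], pi=cat["pi"], chain=chain_idx, iteration=cat["iteration"],
        loglik=cat["loglik"], eta_static=cat["eta_static"],
        diagnostics=diagnostics,
    )
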