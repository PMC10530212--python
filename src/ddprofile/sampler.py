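"""Posterior sampling for (replicated) hierarchical models.

The sampler is a many-chain blocked adaptive random-walk Metropolis:

* the canonical parameters form one block, proposed on the link scale
  (log/logit coordinates walk unconstrained; a change-of-variables Jacobian
  keeps the natural-scale target);
* each cloned latent replicate forms its own block;
* all chains move simultaneously — proposals, acceptance tests and density
  evaluations are vectorized across chains, so 64 chains cost little more
  than one;
* during warm-up, a scalar step size per block is tuned to a target
  acceptance rate and per-coordinate proposal scales are re-estimated from
  the recent chain history; both are frozen afterwards.

Many short chains (rather than one long one) give better coverage of the
posterior tails, which matters because the density-ratio step divides two
estimated densities.  Latent draws are used internally and discarded: no
marginal-likelihood evaluation is ever required.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .models import Dataset, HierarchicalModel, replicated_log_joint

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "PosteriorDraws",
    "ConvergenceReport",
    "SamplingError",
    "sample_posterior",
    "check_convergence",
]


class SamplingError(RuntimeError):
    """Raised when the sampler cannot produce usable draws."""


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Proper prior on the canonical parameters.

    ``flat_box``: independent uniforms over finite intervals (flat on the
    *natural* scale — the convention the explicit-transformation profile
    algorithm relies on).  ``mvnormal``: N(mean, cov), typically the
    asymptotic distribution of the MLE.
    """

    kind: str
    bounds: Optional[np.ndarray] = None  # (d, 2) for flat_box
    mean: Optional[np.ndarray] = None
    cov: Optional[np.ndarray] = None

    @classmethod
    def flat_box(cls, bounds: np.ndarray) -> "PriorSpec":
        bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
        if bounds.shape[1] != 2:
            raise ValueError("bounds must be (d, 2)")
        if not np.all(np.isfinite(bounds)):
            raise ValueError("flat_box bounds must be finite (proper prior)")
        if not np.all(bounds[:, 0] < bounds[:, 1]):
            raise ValueError("each bound must satisfy lo < hi")
        return cls(kind="flat_box", bounds=bounds)

    @classmethod
    def mvnormal(cls, mean: np.ndarray, cov: np.ndarray) -> "PriorSpec":
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        if cov.shape != (mean.size, mean.size):
            raise ValueError("cov must be (d, d) matching mean")
        if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        eig = np.linalg.eigvalsh(cov)
        if np.min(eig) <= 0:
            raise ValueError(
                "covariance must be positive definite "
                f"(min eigenvalue {np.min(eig):.3g})"
            )
        return cls(kind="mvnormal", mean=mean, cov=cov)

    @property
    def dim(self) -> int:
        return len(self.bounds) if self.kind == "flat_box" else len(self.mean)

    def log_density(self, theta: np.ndarray) -> np.ndarray:
        """Log prior density, vectorized over rows of theta; -inf outside."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if self.kind == "flat_box":
            inside = np.all(
                (theta >= self.bounds[None, :, 0])
                & (theta <= self.bounds[None, :, 1]),
                axis=1,
            )
            logvol = np.sum(np.log(self.bounds[:, 1] - self.bounds[:, 0]))
            out = np.full(theta.shape[0], -np.inf)
            out[inside] = -logvol
            return out
        dev = theta - self.mean[None, :]
        L = np.linalg.cholesky(self.cov)
        u = np.linalg.solve(L, dev.T)
        q = np.sum(u * u, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        d = self.dim
        return -0.5 * (d * np.log(2 * np.pi) + logdet + q)

    def conditional_lambda(self, psi_index: int, psi_value: float
                           ) -> "PriorSpec":
        """Prior on the nuisance block lambda given psi (a coordinate).

        For a flat box this is the flat box with the psi coordinate dropped;
        for a multivariate normal it is the usual Gaussian conditional.
        """
        keep = [j for j in range(self.dim) if j != psi_index]
        if self.kind == "flat_box":
            return PriorSpec.flat_box(self.bounds[keep])
        S = self.cov
        m = self.mean
        s_pp = S[psi_index, psi_index]
        s_lp = S[np.ix_(keep, [psi_index])][:, 0]
        S_ll = S[np.ix_(keep, keep)]
        cond_mean = m[keep] + s_lp / s_pp * (psi_value - m[psi_index])
        cond_cov = S_ll - np.outer(s_lp, s_lp) / s_pp
        return PriorSpec.mvnormal(cond_mean, cond_cov)


# --------------------------------------------------------------------------
# configuration and results
# --------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """Settings for :func:`sample_posterior`.

    ``draws`` is the number of *kept* iterates per chain after thinning, so
    the stored sample size is ``chains * draws``.
    """

    chains: int = 64
    draws: int = 80
    warmup: int = 1000
    thin: int = 6
    seed: int = 0
    target_accept: float = 0.28
    rhat_threshold: float = 1.1
    init_theta: Optional[np.ndarray] = None
    init_jitter: float = 0.10
    theta_updates_per_iter: int = 2
    latent_block_size: int = 10

    def __post_init__(self):
        if self.chains < 1 or self.draws < 1 or self.warmup < 0 or self.thin < 1:
            raise ValueError("invalid sampler settings")

    def replace(self, **kw) -> "SamplerConfig":
        from dataclasses import replace as _rep
        return _rep(self, **kw)


@dataclass
class PosteriorDraws:
    """Stored posterior draws of the canonical parameters."""

    draws: np.ndarray          # (S, d), natural scale
    chain_id: np.ndarray       # (S,)
    names: tuple[str, ...]
    K: int
    rhat: np.ndarray           # (d,)
    ess: np.ndarray            # (d,)
    seed: int
    accept_rate: float
    warning: bool = False
    config: Optional[SamplerConfig] = None

    @property
    def S(self) -> int:
        return self.draws.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.draws, columns=list(self.names))
        df["chain"] = self.chain_id
        return df

    def by_chain(self) -> np.ndarray:
        """Draws reshaped to (chains, draws_per_chain, d)."""
        C = self.n_chains
        return self.draws.reshape(C, self.S // C, -1)


@dataclass
class ConvergenceReport:
    rhat: np.ndarray
    ess: np.ndarray
    names: tuple[str, ...]
    threshold: float
    passed: bool


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def _rhat_ess(chain_draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank-normalized split-Rhat and bulk ESS via arviz; (chains, draws, d)."""
    import warnings
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = chain_draws.shape[2]
        rhat = np.empty(d)
        ess = np.empty(d)
        for j in range(d):
            rhat[j] = float(az.rhat(chain_draws[:, :, j]))
            ess[j] = float(az.ess(chain_draws[:, :, j]))
    return rhat, ess


def sample_posterior(model: HierarchicalModel, data: Dataset, prior: PriorSpec,
                     K: int, cfg: Optional[SamplerConfig] = None
                     ) -> PosteriorDraws:
    """Draw from the posterior of theta under ``K``-fold replicated data.

    The target is proportional to ``exp(replicated_log_joint) * prior``,
    marginalized over the latent blocks (latents are sampled jointly and
    discarded from the output).
    """
    cfg = cfg or SamplerConfig()
    if prior.dim != model.params.dim:
        raise ValueError("prior dimension does not match model parameters")
    rng = np.random.default_rng(cfg.seed)
    space = model.params
    d = space.dim
    C = cfg.chains
    dataK = data.replicate(K)
    L = model.latent_dim(data)

    # ---- initialization -------------------------------------------------
    if cfg.init_theta is not None:
        theta0 = np.asarray(cfg.init_theta, dtype=float)
    elif prior.kind == "mvnormal":
        theta0 = prior.mean
    else:
        theta0 = _default_init(model, data)
    theta0 = _clip_into_box(theta0, prior)
    z = space.to_link(theta0)[None, :] + cfg.init_jitter * rng.standard_normal((C, d))
    x = (model.init_latents(data, np.zeros((C, d)), rng).reshape(C, 1, L)
         .repeat(K, axis=1).copy() if L > 0 else np.zeros((C, K, 0)))
    if L > 0:
        x += 0.02 * rng.standard_normal(x.shape)

    def logpost(z_arr: np.ndarray, x_arr: np.ndarray) -> np.ndarray:
        th = space.from_link(z_arr)
        lp = replicated_log_joint(model, dataK, th, x_arr if L > 0 else None)
        lp = lp + prior.log_density(th) + space.log_jacobian(z_arr)
        return lp

    lp = logpost(z, x)
    if not np.any(np.isfinite(lp)):
        raise SamplingError("no chain initialized at finite posterior density")
    # revive dead chains at the best live one
    bad = ~np.isfinite(lp)
    if np.any(bad):
        best = int(np.argmax(lp))
        z[bad] = z[best]
        x[bad] = x[best]
        lp[bad] = lp[best]

    # ---- proposal state -------------------------------------------------
    if L > 0:
        bs = max(1, min(cfg.latent_block_size, L))
        sub = [slice(a, min(a + bs, L)) for a in range(0, L, bs)]
    else:
        sub = []
    interweave = L > 0 and hasattr(model, "innovations_to_latents")
    n_blocks = 1 + K * len(sub) + (1 if interweave else 0)
    log_eps = np.zeros(n_blocks)
    log_eps[0] = np.log(0.5 / np.sqrt(d))
    for b in range(1, n_blocks):
        log_eps[b] = np.log(0.5 / np.sqrt(max(len(sub) and bs, 1)))
    if interweave:
        log_eps[-1] = np.log(0.5 / np.sqrt(d))
    chol_theta = np.eye(d)  # dense proposal factor, adapted during warm-up
    sd_x = np.ones(L) if L > 0 else None
    acc_count = np.zeros(n_blocks)
    acc_iters = 0

    hist_len = 100
    hist_z = np.empty((hist_len, C, d))
    hist_x = np.empty((hist_len, C, L)) if L > 0 else None

    kept = np.empty((C, cfg.draws, d))
    kept_i = 0
    post_accepts = 0
    post_proposals = 0

    total_iters = cfg.warmup + cfg.draws * cfg.thin
    for t in range(total_iters):
        warm = t < cfg.warmup
        # -- theta block (possibly several refreshes per iteration) -------
        for _ in range(cfg.theta_updates_per_iter):
            noise = rng.standard_normal((C, d)) @ chol_theta.T
            z_prop = z + np.exp(log_eps[0]) * noise
            lp_prop = logpost(z_prop, x)
            accept = np.log(rng.random(C)) < (lp_prop - lp)
            z[accept] = z_prop[accept]
            lp[accept] = lp_prop[accept]
            if warm:
                acc_count[0] += accept.mean()
            else:
                post_accepts += int(accept.sum())
                post_proposals += C
        # -- latent sub-blocks, per clone ---------------------------------
        for k in range(K if L > 0 else 0):
            for si, sl in enumerate(sub):
                b = 1 + k * len(sub) + si
                w = sl.stop - sl.start
                step = np.exp(log_eps[b]) * sd_x[sl]
                x_prop = x.copy()
                x_prop[:, k, sl] = x[:, k, sl] \
                    + step[None, :] * rng.standard_normal((C, w))
                lp_prop = logpost(z, x_prop)
                accept = np.log(rng.random(C)) < (lp_prop - lp)
                x[accept] = x_prop[accept]
                lp[accept] = lp_prop[accept]
                if warm:
                    acc_count[b] += accept.mean()
        # -- interweaving: move theta with the standardized innovations held
        # fixed, so scale parameters and the latent paths shift together
        # (breaks the variance-path funnel of centered parameterizations)
        if interweave:
            noise = rng.standard_normal((C, d)) @ chol_theta.T
            z_prop = z + np.exp(log_eps[-1]) * noise
            th_prop = space.from_link(z_prop)
            th_cur = space.from_link(z)
            ok = space.in_support(th_prop)
            ok &= np.isfinite(prior.log_density(th_prop))
            x_prop = x.copy()
            # acceptance in (theta, eta) coordinates: the standard-normal
            # innovation density cancels, leaving obs terms + prior + Jacobian
            cur_obs = np.zeros(C)
            new_obs = np.full(C, -np.inf)
            safe = np.where(ok)[0]
            if safe.size:
                for k in range(K):
                    eta_k = model.latents_to_innovations(
                        data, th_cur[safe], x[safe, k, :])
                    x_prop[safe, k, :] = model.innovations_to_latents(
                        data, th_prop[safe], eta_k)
                new_obs[safe] = 0.0
                for k in range(K):
                    cur_obs[safe] += model.obs_loglik(data, th_cur[safe],
                                                      x[safe, k, :])
                    new_obs[safe] += model.obs_loglik(data, th_prop[safe],
                                                      x_prop[safe, k, :])
            log_ratio = (new_obs + prior.log_density(th_prop)
                         + space.log_jacobian(z_prop)) \
                - (cur_obs + prior.log_density(th_cur)
                   + space.log_jacobian(z))
            accept = np.log(rng.random(C)) < log_ratio
            if np.any(accept):
                z[accept] = z_prop[accept]
                x[accept] = x_prop[accept]
                lp[accept] = logpost(z, x)[accept]
            if warm:
                acc_count[-1] += accept.mean()

        if warm:
            acc_iters += 1
            h = t % hist_len
            hist_z[h] = z
            if L > 0:
                hist_x[h] = x[:, :, :].mean(axis=1)
            # adapt every hist_len iterations
            if (t + 1) % hist_len == 0:
                rate = acc_count / acc_iters
                rate[0] /= cfg.theta_updates_per_iter
                log_eps += np.clip(rate - cfg.target_accept, -0.5, 0.5) * 2.0
                acc_count[:] = 0.0
                acc_iters = 0
                pooled = hist_z.reshape(-1, d)
                cov_z = np.atleast_2d(np.cov(pooled.T))
                scale_floor = 1e-8 * max(1.0, float(np.trace(cov_z)) / d)
                try:
                    chol_theta = np.linalg.cholesky(
                        cov_z + scale_floor * np.eye(d))
                except np.linalg.LinAlgError:
                    chol_theta = np.diag(np.maximum(pooled.std(axis=0), 1e-4))
                if L > 0:
                    pooled_x = hist_x.reshape(-1, L)
                    sx = pooled_x.std(axis=0)
                    sd_x = np.maximum(sx, 1e-4)
        else:
            if (t - cfg.warmup + 1) % cfg.thin == 0 and kept_i < cfg.draws:
                kept[:, kept_i, :] = space.from_link(z)
                kept_i += 1

    if post_proposals > 0 and post_accepts == 0:
        raise SamplingError("all proposals rejected after warm-up; "
                            "sampling failed (zero acceptance)")

    draws = kept.reshape(C * cfg.draws, d)
    chain_id = np.repeat(np.arange(C), cfg.draws)
    rhat, ess = _rhat_ess(kept)
    warning = bool(np.any(rhat > cfg.rhat_threshold))
    return PosteriorDraws(
        draws=draws, chain_id=chain_id, names=space.names, K=K,
        rhat=rhat, ess=ess, seed=cfg.seed,
        accept_rate=post_accepts / max(post_proposals, 1),
        warning=warning, config=cfg,
    )


def _default_init(model: HierarchicalModel, data: Dataset) -> np.ndarray:
    """Crude data-driven starting point per built-in model family."""
    name = getattr(model, "name", "")
    f = data.frame
    if name == "beta_iid":
        y = f["y"].to_numpy()
        m, v = float(np.mean(y)), float(np.var(y)) + 1e-6
        c = max(m * (1 - m) / v - 1.0, 0.5)
        return np.array([max(m * c, 0.05), max((1 - m) * c, 0.05)])
    if name == "beta_mean_alpha":
        y = f["y"].to_numpy()
        m, v = float(np.mean(y)), float(np.var(y)) + 1e-6
        c = max(m * (1 - m) / v - 1.0, 0.5)
        return np.array([min(max(m, 0.02), 0.98), max(m * c, 0.05)])
    if name in ("normal_mean", "normal_meanvar"):
        y = f["y"].to_numpy()
        if name == "normal_mean":
            return np.array([float(np.mean(y))])
        return np.array([float(np.mean(y)), float(np.var(y)) + 1e-6])
    if name == "normal_sum":
        y = f["y"].to_numpy()
        m = float(np.mean(y))
        return np.array([m / 2, m / 2])
    if name == "sir_binomial":
        return np.array([1.5, 0.7])
    if name == "bevholt_poisson":
        y = f["count"].to_numpy(dtype=float)
        K_guess = max(float(np.mean(y[len(y) // 2:])), 1.0)
        return np.array([2.0, 1.0 / K_guess, 0.05])
    if name == "bevholt_k":
        y = f["count"].to_numpy(dtype=float)
        K_guess = max(float(np.mean(y[len(y) // 2:])), 1.0)
        return np.array([K_guess, 1.0 / K_guess, 0.05])
    if name == "rand_intercept_binom":
        pc = (f["r_c"].to_numpy() + 0.5) / (f["n_c"].to_numpy() + 1.0)
        pt = (f["r_t"].to_numpy() + 0.5) / (f["n_t"].to_numpy() + 1.0)
        mu0 = np.log(pc / (1 - pc))
        de0 = np.log(pt / (1 - pt)) - mu0
        return np.array([float(np.mean(de0)), float(np.mean(mu0)), 10.0, 4.0])
    if name.startswith("mvnormal_iid"):
        y = f.to_numpy(dtype=float)
        mu = y.mean(axis=0)
        Sig = np.cov(y.T) + 1e-6 * np.eye(y.shape[1])
        return model.theta_from_moments(mu, Sig)
    if name == "gaussian_mean_known_cov":
        return f.to_numpy(dtype=float).mean(axis=0)
    return np.zeros(model.params.dim)


def _clip_into_box(theta: np.ndarray, prior: PriorSpec) -> np.ndarray:
    if prior.kind != "flat_box":
        return theta
    lo, hi = prior.bounds[:, 0], prior.bounds[:, 1]
    width = hi - lo
    return np.clip(theta, lo + 1e-9 * width, hi - 1e-9 * width)


def check_convergence(pd_: PosteriorDraws, threshold: float = 1.1
                      ) -> ConvergenceReport:
    """Per-parameter Rhat/ESS report with a pass/fail flag."""
    if pd_.n_chains < 2:
        raise ValueError("Rhat requires at least 2 chains")
    rhat, ess = _rhat_ess(pd_.by_chain())
    return ConvergenceReport(
        rhat=rhat, ess=ess, names=pd_.names, threshold=threshold,
        passed=bool(np.all(rhat <= threshold)),
    )
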