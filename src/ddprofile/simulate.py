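"""Seeded synthetic-data generators for the five example model classes.

Every generator is bit-reproducible given (seed, settings) and returns a
:class:`~ddprofile.models.Dataset` whose ``meta`` records the true parameter
values (and, for state-space models, the latent path) so that recovery tests
and pipelines never need external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .models import Dataset, _sir_curve

__all__ = [
    "SimConfig",
    "gen_beta",
    "gen_bevholt_poisson",
    "gen_sir",
    "gen_rand_intercept_trials",
    "gen_mvn",
    "generate",
]


@dataclass(frozen=True)
class SimConfig:
    """Declarative simulation request (model name, truth, sizes, seed)."""

    model: str
    params: dict
    sizes: dict = field(default_factory=dict)
    seed: int = 0


def gen_beta(n: int, alpha: float, beta: float, seed: int = 0) -> Dataset:
    """n i.i.d. draws from a beta(alpha, beta) distribution."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("beta shape parameters must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    y = rng.beta(alpha, beta, size=n)
    return Dataset("scalar", pd.DataFrame({"y": y}),
                   meta={"truth": {"alpha": alpha, "beta": beta}, "seed": seed})


def gen_bevholt_poisson(T: int, lambda_: float, beta: float, sigma2: float,
                        n0: float = 10.0, seed: int = 0,
                        observe: bool = True) -> Dataset:
    """Beverton-Holt latent dynamics with Poisson-count observation.

    Latent log-abundance: x_1 ~ N(log n0, sigma2),
    x_{t+1} = log(lambda e^{x_t} / (1 + beta e^{x_t})) + N(0, sigma2).
    Observed counts: y_t ~ Poisson(e^{x_t}) (or exp(x_t) rounded when
    ``observe=False``, the noise-free skeleton check).
    """
    if T < 2:
        raise ValueError("need at least T=2 time points")
    if lambda_ <= 0 or beta <= 0 or sigma2 < 0 or n0 <= 0:
        raise ValueError("invalid Beverton-Holt parameters")
    rng = np.random.default_rng(seed)
    x = np.empty(T)
    sd = np.sqrt(sigma2)
    x[0] = np.log(n0) + sd * rng.standard_normal()
    for t in range(1, T):
        drift = x[t - 1] + np.log(lambda_) - np.log1p(beta * np.exp(x[t - 1]))
        x[t] = drift + sd * rng.standard_normal()
    if observe:
        y = rng.poisson(np.exp(x)).astype(float)
    else:
        y = np.exp(x)
    frame = pd.DataFrame({"t": np.arange(1, T + 1), "count": y})
    meta = {
        "truth": {"lambda": lambda_, "beta": beta, "sigma2": sigma2},
        "n0": n0, "seed": seed, "latent_path": x.tolist(),
    }
    return Dataset("timeseries", frame, meta=meta)


def gen_sir(N: int, beta: float, gamma: float, i0: int, days: int,
            seed: int = 0, obs: str = "binomial", dt: float = 0.1) -> Dataset:
    """Discrete-time SIR epidemic curve with exact or binomial observation.

    ``obs='exact'`` records the deterministic infected counts; ``'binomial'``
    draws y_t ~ Binomial(N, I_t / N).  R0 = beta / gamma is recorded in the
    metadata.
    """
    if i0 < 1 or i0 > N:
        raise ValueError("need 1 <= i0 <= N")
    if beta <= 0 or gamma <= 0:
        raise ValueError("rates must be positive")
    if days < 2:
        raise ValueError("need at least 2 days")
    rng = np.random.default_rng(seed)
    I = _sir_curve(np.array([beta]), np.array([gamma]), N, i0, days, dt)[0]
    if obs == "exact":
        y = I
    elif obs == "binomial":
        p = np.clip(I / N, 0.0, 1.0)
        y = rng.binomial(N, p).astype(float)
    else:
        raise ValueError("obs must be 'exact' or 'binomial'")
    frame = pd.DataFrame({"t": np.arange(1, days + 1), "count": y})
    meta = {
        "truth": {"beta": beta, "gamma": gamma}, "R0": beta / gamma,
        "N": N, "i0": i0, "dt": dt, "seed": seed,
    }
    return Dataset("timeseries", frame, meta=meta)


def gen_rand_intercept_trials(I: int, delta: float, mu: float, tau1: float,
                              tau2: float, n_per_arm: int = 200,
                              seed: int = 0) -> Dataset:
    """I two-arm trials from the random-intercept binomial model."""
    if I < 2:
        raise ValueError("need at least 2 trials")
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("precisions must be positive")
    if n_per_arm < 1:
        raise ValueError("arm size must be positive")
    rng = np.random.default_rng(seed)
    mu_i = rng.normal(mu, 1.0 / np.sqrt(tau2), size=I)
    de_i = rng.normal(delta, 1.0 / np.sqrt(tau1), size=I)
    from scipy.special import expit
    p_c = expit(mu_i)
    p_t = expit(mu_i + de_i)
    r_c = rng.binomial(n_per_arm, p_c)
    r_t = rng.binomial(n_per_arm, p_t)
    frame = pd.DataFrame({
        "trial": np.arange(1, I + 1),
        "n_c": n_per_arm, "r_c": r_c,
        "n_t": n_per_arm, "r_t": r_t,
    })
    meta = {"truth": {"delta": delta, "mu": mu, "tau1": tau1, "tau2": tau2},
            "seed": seed}
    return Dataset("trials", frame, meta=meta)


def gen_mvn(n: int, mean: np.ndarray, cov: np.ndarray, seed: int = 0) -> Dataset:
    """n i.i.d. multivariate normal rows."""
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric")
    eig = np.linalg.eigvalsh(cov)
    if np.min(eig) <= 0:
        raise ValueError("covariance must be positive definite")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    y = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    frame = pd.DataFrame(y, columns=[f"y{j + 1}" for j in range(len(mean))])
    meta = {"truth": {"mean": mean.tolist(), "cov": cov.tolist()},
            "max_eigenvalue": float(np.max(eig)), "seed": seed}
    return Dataset("matrix", frame, meta=meta)


_DISPATCH = {
    "beta_iid": lambda p, s, seed: gen_beta(
        s.get("n", 50), p.get("alpha", 3.0), p.get("beta", 2.0), seed),
    "bevholt_poisson": lambda p, s, seed: gen_bevholt_poisson(
        s.get("T", 30), p.get("lambda", 2.0), p.get("beta", 0.01),
        p.get("sigma2", 0.01), p.get("n0", 10.0), seed),
    "sir_binomial": lambda p, s, seed: gen_sir(
        s.get("N", 763), p.get("beta", 2.0), p.get("gamma", 0.5),
        s.get("i0", 1), s.get("days", 14), seed),
    "rand_intercept_binom": lambda p, s, seed: gen_rand_intercept_trials(
        s.get("I", 22), p.get("delta", -0.25), p.get("mu", -2.0),
        p.get("tau1", 25.0), p.get("tau2", 4.0), s.get("n_per_arm", 200), seed),
    "mvnormal_iid": lambda p, s, seed: gen_mvn(
        s.get("n", 50), np.asarray(p.get("mean", [0.0, 0.0])),
        np.asarray(p.get("cov", [[1.0, 0.0], [0.0, 1.0]])), seed),
}


def generate(cfg: SimConfig) -> Dataset:
    """Dispatch a :class:`SimConfig` to the matching generator."""
    try:
        fn = _DISPATCH[cfg.model]
    except KeyError:
        raise KeyError(f"no generator for model {cfg.model!r}") from None
    return fn(cfg.params, cfg.sizes, cfg.seed)
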