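"""Model abstraction, built-in example models, and functions of parameters.

A :class:`HierarchicalModel` exposes the two log-densities that define a
latent-variable model — ``log f(y | x, theta)`` for the observations and
``log g(x | theta)`` for the latent block — plus, when the integral over x is
analytic, the marginal log-likelihood ``log f(y | theta)``.  All density
methods are vectorized over a leading axis of parameter points so that
many-chain samplers evaluate them in one numpy call.

Data replication (the K in data cloning; K=2 is data doubling) is by
whole-dataset copy, each copy carrying its own independent latent block.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, gammaln

from .params import ParamSpace

__all__ = [
    "Dataset",
    "HierarchicalModel",
    "PsiFunction",
    "register_model",
    "lookup_model",
    "registered_models",
    "builtin_psi",
    "replicated_log_joint",
]


# --------------------------------------------------------------------------
# datasets
# --------------------------------------------------------------------------

@dataclass
class Dataset:
    """Observed data plus a replication level K.

    ``K=1`` is the original data, ``K=2`` the doubled data; larger K serves
    data cloning.  Replication is by whole-dataset copy, never by record
    resampling.
    """

    kind: str  # 'scalar' | 'timeseries' | 'trials' | 'matrix'
    frame: pd.DataFrame
    K: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.frame) < 1:
            raise ValueError("dataset must contain at least one record")
        if self.K < 1:
            raise ValueError("replication level K must be >= 1")

    @property
    def n(self) -> int:
        return len(self.frame)

    def replicate(self, K: int) -> "Dataset":
        if K < 1:
            raise ValueError("replication level K must be >= 1")
        return replace(self, K=K)


def _theta2d(theta: np.ndarray) -> tuple[np.ndarray, bool]:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        return theta[None, :], True
    return theta, False


# --------------------------------------------------------------------------
# model base class
# --------------------------------------------------------------------------

class HierarchicalModel:
    """Base class: subclasses implement the log-densities.

    ``obs_loglik`` and ``latent_loglik`` take parameters of shape (C, d) and a
    latent block of shape (C, L) (one replicate's worth of latents) and return
    (C,).  Non-hierarchical models set ``latent_dim(data) == 0`` and implement
    ``marginal_loglik`` instead.
    """

    name: str = "model"
    params: ParamSpace

    # -- structure ---------------------------------------------------------
    def latent_dim(self, data: Dataset) -> int:
        return 0

    @property
    def has_marginal(self) -> bool:
        return type(self).marginal_loglik is not HierarchicalModel.marginal_loglik

    # -- densities ---------------------------------------------------------
    def obs_loglik(self, data: Dataset, theta: np.ndarray,
                   x: Optional[np.ndarray]) -> np.ndarray:
        raise NotImplementedError

    def latent_loglik(self, data: Dataset, theta: np.ndarray,
                      x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def marginal_loglik(self, data: Dataset, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError(
            f"model {self.name!r} has no analytic marginal likelihood"
        )

    # -- sampler helpers ---------------------------------------------------
    def init_latents(self, data: Dataset, theta: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
        """Heuristic latent starting values, shape (C, L)."""
        C = np.asarray(theta).shape[0]
        L = self.latent_dim(data)
        return 0.1 * rng.standard_normal((C, L))


def replicated_log_joint(model: HierarchicalModel, data: Dataset,
                         theta: np.ndarray,
                         x_all: Optional[np.ndarray] = None) -> np.ndarray:
    """Log joint density of K replicated data copies and their latent blocks.

    Returns sum over k of ``obs_loglik(y, x_k, theta) + latent_loglik(x_k,
    theta)``; for a non-hierarchical model this is ``K * marginal_loglik``.
    Parameter points outside the support map to -inf (so samplers reject them)
    rather than raising.

    ``theta`` may be (d,) with ``x_all`` (K, L), or (C, d) with (C, K, L).
    """
    th, scalar = _theta2d(theta)
    C = th.shape[0]
    out = np.full(C, -np.inf)
    ok = model.params.in_support(th)
    if np.any(ok):
        th_ok = th[ok]
        L = model.latent_dim(data)
        if L == 0:
            out[ok] = data.K * model.marginal_loglik(data, th_ok)
        else:
            if x_all is None:
                raise ValueError("hierarchical model requires latent values x_all")
            xa = np.asarray(x_all, dtype=float)
            if scalar:
                xa = xa[None, ...]
            if xa.shape[1] != data.K or xa.shape[2] != L:
                raise ValueError(
                    f"x_all must have shape (..., K={data.K}, L={L}), got {xa.shape}"
                )
            acc = np.zeros(int(ok.sum()))
            for k in range(data.K):
                xk = xa[ok, k, :]
                acc += model.obs_loglik(data, th_ok, xk)
                acc += model.latent_loglik(data, th_ok, xk)
            out[ok] = acc
    return out[0] if scalar else out


# --------------------------------------------------------------------------
# built-in models
# --------------------------------------------------------------------------

class BetaIID(HierarchicalModel):
    """i.i.d. beta observations; canonical parameters (alpha, beta)."""

    name = "beta_iid"

    def __init__(self):
        self.params = ParamSpace(("alpha", "beta"), ("log", "log"))

    def marginal_loglik(self, data, theta):
        y = data.frame["y"].to_numpy()
        a, b = theta[:, 0], theta[:, 1]
        sly, sl1y = np.sum(np.log(y)), np.sum(np.log1p(-y))
        return (a - 1.0) * sly + (b - 1.0) * sl1y - len(y) * betaln(a, b)


class NormalMean(HierarchicalModel):
    """Normal observations with known variance; the mean is the parameter."""

    name = "normal_mean"

    def __init__(self, sigma2: float = 1.0):
        self.sigma2 = float(sigma2)
        self.params = ParamSpace(("mu",), ("identity",))

    def marginal_loglik(self, data, theta):
        y = data.frame["y"].to_numpy()
        mu = theta[:, 0]
        n = len(y)
        ss = np.sum((y[None, :] - mu[:, None]) ** 2, axis=1)
        return -0.5 * n * np.log(2 * np.pi * self.sigma2) - 0.5 * ss / self.sigma2


class NormalMeanVar(HierarchicalModel):
    """Normal observations with unknown mean and variance (mu, sigma2)."""

    name = "normal_meanvar"

    def __init__(self):
        self.params = ParamSpace(("mu", "sigma2"), ("identity", "log"))

    def marginal_loglik(self, data, theta):
        y = data.frame["y"].to_numpy()
        mu, s2 = theta[:, 0], theta[:, 1]
        n = len(y)
        ss = np.sum((y[None, :] - mu[:, None]) ** 2, axis=1)
        return -0.5 * n * np.log(2 * np.pi * s2) - 0.5 * ss / s2


class NormalSum(HierarchicalModel):
    """y ~ N(a + b, 1): a deliberately non-identifiable two-parameter model
    (only the sum a+b enters the likelihood), used to exercise the
    data-cloning estimability diagnostic."""

    name = "normal_sum"

    def __init__(self):
        self.params = ParamSpace(("a", "b"), ("identity", "identity"))

    def marginal_loglik(self, data, theta):
        y = data.frame["y"].to_numpy()
        m = theta[:, 0] + theta[:, 1]
        n = len(y)
        ss = np.sum((y[None, :] - m[:, None]) ** 2, axis=1)
        return -0.5 * n * np.log(2 * np.pi) - 0.5 * ss


class GaussianMeanKnownCov(HierarchicalModel):
    """Multivariate normal observations with known covariance; the mean vector
    is the canonical parameter.  The log-likelihood is exactly quadratic in
    theta, which makes this the reference case for Laplace-term diagnostics."""

    name = "gaussian_mean_known_cov"

    def __init__(self, Sigma: np.ndarray):
        Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
        self.Sigma = Sigma
        self.Sigma_inv = np.linalg.inv(Sigma)
        self._logdet = np.linalg.slogdet(2 * np.pi * Sigma)[1]
        d = Sigma.shape[0]
        self.params = ParamSpace(
            tuple(f"mu{i + 1}" for i in range(d)), ("identity",) * d
        )

    def marginal_loglik(self, data, theta):
        y = data.frame.to_numpy(dtype=float)  # (n, d)
        n = y.shape[0]
        dev = y[None, :, :] - theta[:, None, :]  # (C, n, d)
        q = np.einsum("cnd,de,cne->c", dev, self.Sigma_inv, dev)
        return -0.5 * n * self._logdet - 0.5 * q


class MvNormalIID(HierarchicalModel):
    """i.i.d. multivariate normal observations with unknown mean and covariance.

    Canonical parameters: d means, then the Cholesky factor of the covariance
    with the diagonal on the log scale (so all supports are boxes and the
    implied covariance is positive definite by construction).  Ordering:
    mu_1..mu_d, logL_11..logL_dd, then strictly-lower-triangle entries
    row-major.
    """

    def __init__(self, d: int = 2):
        if d < 1:
            raise ValueError("dimension must be >= 1")
        self.d = d
        names = [f"mu{i + 1}" for i in range(d)]
        names += [f"logL{i + 1}{i + 1}" for i in range(d)]
        tril = [(i, j) for i in range(d) for j in range(i)]
        names += [f"L{i + 1}{j + 1}" for i, j in tril]
        self._tril = tril
        self.name = f"mvnormal_iid_d{d}" if d != 2 else "mvnormal_iid"
        self.params = ParamSpace(tuple(names), ("identity",) * len(names))

    def chol(self, theta: np.ndarray) -> np.ndarray:
        """Cholesky factor(s) L of the covariance, shape (C, d, d)."""
        th, scalar = _theta2d(theta)
        d = self.d
        C = th.shape[0]
        L = np.zeros((C, d, d))
        for i in range(d):
            L[:, i, i] = np.exp(th[:, d + i])
        for m, (i, j) in enumerate(self._tril):
            L[:, i, j] = th[:, 2 * d + m]
        return L[0] if scalar else L

    def cov(self, theta: np.ndarray) -> np.ndarray:
        L = self.chol(theta)
        return L @ np.swapaxes(L, -1, -2)

    def marginal_loglik(self, data, theta):
        y = data.frame.to_numpy(dtype=float)  # (n, d)
        n, d = y.shape
        L = self.chol(theta)  # (C, d, d)
        th = theta
        mu = th[:, :d]
        dev = y[None, :, :] - mu[:, None, :]  # (C, n, d)
        # batched triangular solve L u = dev^T via np.linalg.solve
        rhs = np.swapaxes(dev, 1, 2)  # (C, d, n)
        u = np.linalg.solve(L, rhs)  # (C, d, n)
        q = np.sum(u * u, axis=(1, 2))
        logdetL = np.sum(np.log(np.abs(np.diagonal(L, axis1=1, axis2=2))), axis=1)
        return -0.5 * n * d * np.log(2 * np.pi) - n * logdetL - 0.5 * q

    def theta_from_moments(self, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
        """Canonical parameter point matching given moments (for fixtures)."""
        L = np.linalg.cholesky(np.asarray(Sigma, dtype=float))
        d = self.d
        th = list(np.asarray(mu, dtype=float))
        th += [np.log(L[i, i]) for i in range(d)]
        th += [L[i, j] for i, j in self._tril]
        return np.array(th)


def _sir_curve(beta: np.ndarray, gamma: np.ndarray, N: float, i0: float,
               days: int, dt: float) -> np.ndarray:
    """Deterministic discrete-time SIR (Euler steps); returns infected counts
    at integer days 1..days, vectorized over (C,) parameter vectors."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    C = beta.shape[0]
    steps_per_day = max(1, int(round(1.0 / dt)))
    S = np.full(C, N - i0)
    I = np.full(C, float(i0))
    out = np.empty((C, days))
    for day in range(days):
        for _ in range(steps_per_day):
            new_inf = dt * beta * S * I / N
            new_rec = dt * gamma * I
            new_inf = np.minimum(new_inf, S)
            S = S - new_inf
            I = np.maximum(I + new_inf - new_rec, 1e-12)
        out[:, day] = I
    return out


class SIRBinomial(HierarchicalModel):
    """Deterministic discrete-time SIR epidemic with binomial observation.

    The latent epidemic curve follows Euler steps of dS/dt = -beta S I / N,
    dI/dt = beta S I / N - gamma I in a closed population of size N; the daily
    infected count is observed as Binomial(N, I_t / N).  Canonical parameters
    are the transmission rate beta and recovery rate gamma (per day); the
    basic reproduction number is R0 = beta / gamma.  Population size N,
    initial infections i0, and the Euler step dt ride along with the dataset.
    """

    name = "sir_binomial"

    def __init__(self):
        self.params = ParamSpace(("beta", "gamma"), ("log", "log"))

    def marginal_loglik(self, data, theta):
        y = data.frame["count"].to_numpy(dtype=float)
        N = float(data.meta.get("N", 763))
        i0 = float(data.meta.get("i0", 1))
        dt = float(data.meta.get("dt", 0.1))
        days = len(y)
        I = _sir_curve(theta[:, 0], theta[:, 1], N, i0, days, dt)
        p = np.clip(I / N, 1e-12, 1 - 1e-12)
        const = np.sum(gammaln(N + 1) - gammaln(y + 1) - gammaln(N - y + 1))
        return const + np.sum(
            y[None, :] * np.log(p) + (N - y)[None, :] * np.log1p(-p), axis=1
        )


class BevholtPoisson(HierarchicalModel):
    """Beverton-Holt population dynamics with Poisson measurement error.

    Latent log-abundance x_t evolves as
    ``x_{t+1} = log(lambda e^{x_t} / (1 + beta e^{x_t})) + eps_t`` with process
    noise variance sigma2 (x_1 ~ N(log n0, sigma2)); the observed count is
    Poisson(e^{x_t}).  Canonical parameters (lambda, beta, sigma2); the
    carrying capacity is (lambda - 1) / beta.
    """

    name = "bevholt_poisson"

    def __init__(self):
        self.params = ParamSpace(("lambda", "beta", "sigma2"),
                                 ("log", "log", "log"))

    def latent_dim(self, data):
        return data.n

    def obs_loglik(self, data, theta, x):
        y = data.frame["count"].to_numpy(dtype=float)
        return np.sum(y[None, :] * x - np.exp(x) - gammaln(y + 1)[None, :], axis=1)

    def _skeleton(self, x, lam, beta):
        # log of the Beverton-Holt map applied to abundance e^x
        return x + np.log(lam) - np.log1p(beta * np.exp(x))

    def latent_loglik(self, data, theta, x):
        lam, beta, s2 = theta[:, :1], theta[:, 1:2], theta[:, 2:3]
        n0 = float(data.meta.get("n0", 10.0))
        mean_next = self._skeleton(x[:, :-1], lam, beta)
        resid1 = x[:, :1] - np.log(n0)
        resid = x[:, 1:] - mean_next
        T = x.shape[1]
        return (
            -0.5 * T * np.log(2 * np.pi * s2[:, 0])
            - 0.5 * (resid1[:, 0] ** 2 + np.sum(resid ** 2, axis=1)) / s2[:, 0]
        )

    def init_latents(self, data, theta, rng):
        y = data.frame["count"].to_numpy(dtype=float)
        x0 = np.log(np.maximum(y, 0.5))
        C = np.asarray(theta).shape[0]
        return x0[None, :] + 0.05 * rng.standard_normal((C, len(y)))

    # non-centered representation: x as standardized process innovations.
    # Enables the sampler's interweaving move, which breaks the coupling
    # between sigma2 and the latent path.
    def latents_to_innovations(self, data, theta, x):
        lam, beta, s2 = theta[:, :1], theta[:, 1:2], theta[:, 2:3]
        sd = np.sqrt(s2)
        n0 = float(data.meta.get("n0", 10.0))
        eta = np.empty_like(x)
        eta[:, :1] = (x[:, :1] - np.log(n0)) / sd
        eta[:, 1:] = (x[:, 1:] - self._skeleton(x[:, :-1], lam, beta)) / sd
        return eta

    def innovations_to_latents(self, data, theta, eta):
        lam, beta, s2 = theta[:, :1], theta[:, 1:2], theta[:, 2:3]
        sd = np.sqrt(s2)[:, 0]
        n0 = float(data.meta.get("n0", 10.0))
        x = np.empty_like(eta)
        x[:, 0] = np.log(n0) + sd * eta[:, 0]
        for t in range(1, eta.shape[1]):
            drift = self._skeleton(x[:, t - 1:t], lam, beta)[:, 0]
            x[:, t] = drift + sd * eta[:, t]
        return x


class RandInterceptBinom(HierarchicalModel):
    """Random-effects binary regression pooling control/treatment trials.

    Trial i observes r_ic ~ Bin(n_ic, p_ic) and r_it ~ Bin(n_it, p_it) with
    logit(p_ic) = mu_i, logit(p_it) = mu_i + delta_i, where the trial effects
    delta_i ~ N(delta, 1/tau1) and intercepts mu_i ~ N(mu, 1/tau2).  Canonical
    parameters (delta, mu, tau1, tau2); delta is the common log-odds-ratio
    treatment effect.  Latents per replicate: (mu_1..mu_I, delta_1..delta_I).
    """

    name = "rand_intercept_binom"

    def __init__(self):
        self.params = ParamSpace(("delta", "mu", "tau1", "tau2"),
                                 ("identity", "identity", "log", "log"))

    def latent_dim(self, data):
        return 2 * data.n

    def obs_loglik(self, data, theta, x):
        f = data.frame
        n_c = f["n_c"].to_numpy(dtype=float)
        r_c = f["r_c"].to_numpy(dtype=float)
        n_t = f["n_t"].to_numpy(dtype=float)
        r_t = f["r_t"].to_numpy(dtype=float)
        I = data.n
        mu_i = x[:, :I]
        de_i = x[:, I:]
        eta_t = mu_i + de_i
        # binomial log-pmf with logit mean: r*eta - n*log(1+e^eta) + const
        const = np.sum(
            gammaln(n_c + 1) - gammaln(r_c + 1) - gammaln(n_c - r_c + 1)
            + gammaln(n_t + 1) - gammaln(r_t + 1) - gammaln(n_t - r_t + 1)
        )
        ll = np.sum(r_c[None, :] * mu_i - n_c[None, :] * np.logaddexp(0, mu_i),
                    axis=1)
        ll += np.sum(r_t[None, :] * eta_t - n_t[None, :] * np.logaddexp(0, eta_t),
                     axis=1)
        return const + ll

    def latent_loglik(self, data, theta, x):
        delta, mu = theta[:, :1], theta[:, 1:2]
        tau1, tau2 = theta[:, 2:3], theta[:, 3:4]
        I = data.n
        mu_i = x[:, :I]
        de_i = x[:, I:]
        ll = 0.5 * I * np.log(tau1[:, 0] / (2 * np.pi)) \
            - 0.5 * tau1[:, 0] * np.sum((de_i - delta) ** 2, axis=1)
        ll += 0.5 * I * np.log(tau2[:, 0] / (2 * np.pi)) \
            - 0.5 * tau2[:, 0] * np.sum((mu_i - mu) ** 2, axis=1)
        return ll

    def init_latents(self, data, theta, rng):
        f = data.frame
        pc = (f["r_c"].to_numpy() + 0.5) / (f["n_c"].to_numpy() + 1.0)
        pt = (f["r_t"].to_numpy() + 0.5) / (f["n_t"].to_numpy() + 1.0)
        mu0 = np.log(pc / (1 - pc))
        de0 = np.log(pt / (1 - pt)) - mu0
        x0 = np.concatenate([mu0, de0])
        C = np.asarray(theta).shape[0]
        return x0[None, :] + 0.05 * rng.standard_normal((C, 2 * data.n))

    def latents_to_innovations(self, data, theta, x):
        delta, mu = theta[:, :1], theta[:, 1:2]
        tau1, tau2 = theta[:, 2:3], theta[:, 3:4]
        I = data.n
        return np.concatenate(
            [(x[:, :I] - mu) * np.sqrt(tau2),
             (x[:, I:] - delta) * np.sqrt(tau1)], axis=1)

    def innovations_to_latents(self, data, theta, eta):
        delta, mu = theta[:, :1], theta[:, 1:2]
        tau1, tau2 = theta[:, 2:3], theta[:, 3:4]
        I = data.n
        return np.concatenate(
            [mu + eta[:, :I] / np.sqrt(tau2),
             delta + eta[:, I:] / np.sqrt(tau1)], axis=1)


class BetaMeanAlpha(HierarchicalModel):
    """Beta model re-parameterized as (mean psi1, alpha): beta = alpha(1-psi1)/psi1.

    Makes the beta mean a *component* of the canonical parameter vector so the
    flat-prior (explicit-transformation) profile algorithm applies to it.
    """

    name = "beta_mean_alpha"

    def __init__(self):
        self.params = ParamSpace(("psi1", "alpha"), ("logit", "log"))
        self._beta = BetaIID()

    def to_natural(self, theta: np.ndarray) -> np.ndarray:
        th, scalar = _theta2d(theta)
        psi, a = th[:, 0], th[:, 1]
        b = a * (1.0 - psi) / psi
        out = np.stack([a, b], axis=1)
        return out[0] if scalar else out

    def marginal_loglik(self, data, theta):
        return self._beta.marginal_loglik(data, self.to_natural(theta))


class BevholtK(HierarchicalModel):
    """Beverton-Holt state-space model re-parameterized as
    (carrying capacity K, beta, sigma2) with lambda = 1 + K * beta."""

    name = "bevholt_k"

    def __init__(self):
        self.params = ParamSpace(("K", "beta", "sigma2"), ("log", "log", "log"))
        self._bh = BevholtPoisson()

    def to_natural(self, theta: np.ndarray) -> np.ndarray:
        th, scalar = _theta2d(theta)
        K, b, s2 = th[:, 0], th[:, 1], th[:, 2]
        out = np.stack([1.0 + K * b, b, s2], axis=1)
        return out[0] if scalar else out

    def latent_dim(self, data):
        return data.n

    def obs_loglik(self, data, theta, x):
        return self._bh.obs_loglik(data, theta, x)

    def latent_loglik(self, data, theta, x):
        return self._bh.latent_loglik(data, self.to_natural(theta), x)

    def init_latents(self, data, theta, rng):
        return self._bh.init_latents(data, theta, rng)

    def latents_to_innovations(self, data, theta, x):
        return self._bh.latents_to_innovations(data, self.to_natural(theta), x)

    def innovations_to_latents(self, data, theta, eta):
        return self._bh.innovations_to_latents(data, self.to_natural(theta),
                                               eta)


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

_REGISTRY: dict[str, HierarchicalModel] = {}


def register_model(name: str, model: HierarchicalModel) -> None:
    if name in _REGISTRY:
        raise ValueError(f"model name {name!r} already registered")
    _REGISTRY[name] = model


def lookup_model(name: str) -> HierarchicalModel:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"no model named {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def registered_models() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


for _m in (BetaIID(), MvNormalIID(2), SIRBinomial(), BevholtPoisson(),
           RandInterceptBinom(), NormalMean(), NormalMeanVar(), NormalSum(),
           BetaMeanAlpha(), BevholtK()):
    register_model(_m.name, _m)


# --------------------------------------------------------------------------
# functions of parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PsiFunction:
    """A real-valued function psi = f(theta) of the canonical parameters."""

    name: str
    f: Callable[[np.ndarray], np.ndarray]
    component_index: Optional[int] = None

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        th, scalar = _theta2d(theta)
        with np.errstate(all="ignore"):  # out-of-support probes map to nan/inf
            v = np.asarray(self.f(th), dtype=float)
        return float(v[0]) if scalar else v


def _beta_mean(th):
    a, b = th[:, 0], th[:, 1]
    return a / (a + b)


def _beta_var(th):
    a, b = th[:, 0], th[:, 1]
    s = a + b
    return a * b / (s ** 2 * (s + 1.0))


def _beta_skew(th):
    a, b = th[:, 0], th[:, 1]
    s = a + b
    return 2.0 * (b - a) * np.sqrt(s + 1.0) / ((s + 2.0) * np.sqrt(a * b))


def _mvn_max_eig(th):
    model = lookup_model("mvnormal_iid")
    Sig = model.cov(th)
    return np.linalg.eigvalsh(Sig)[..., -1]


_PSI_BUILTINS = {
    "beta_mean": PsiFunction("beta_mean", _beta_mean),
    "beta_var": PsiFunction("beta_var", _beta_var),
    "beta_skew": PsiFunction("beta_skew", _beta_skew),
    "sir_R0": PsiFunction("sir_R0", lambda th: th[:, 0] / th[:, 1]),
    "bh_growth": PsiFunction("bh_growth", lambda th: th[:, 0], component_index=0),
    "bh_carrying_capacity": PsiFunction(
        "bh_carrying_capacity", lambda th: (th[:, 0] - 1.0) / th[:, 1]
    ),
    "mvn_max_eigenvalue": PsiFunction("mvn_max_eigenvalue", _mvn_max_eig),
    "ri_delta": PsiFunction("ri_delta", lambda th: th[:, 0], component_index=0),
}


def builtin_psi(name: str) -> PsiFunction:
    """Look up a built-in function-of-parameters by name."""
    try:
        return _PSI_BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"no built-in psi named {name!r}; have {sorted(_PSI_BUILTINS)}"
        ) from None


def component_psi(model: HierarchicalModel, component: str) -> PsiFunction:
    """psi that is literally one coordinate of the model's parameter vector."""
    j = model.params.index(component)
    return PsiFunction(component, lambda th, j=j: th[:, j], component_index=j)
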