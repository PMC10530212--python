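"""Ground-truth machinery for models with an analytic marginal likelihood.

* :func:`oracle_profile` — the log-profile likelihood by equality-constrained
  numerical optimization (the classical route, feasible whenever the
  likelihood can be evaluated);
* :func:`quad_profile` — the profile of the quadratic (Taylor) surrogate
  built from the MLE and observed Fisher information; cheap, but *not*
  invariant to the model's parameterization;
* :func:`laplace_terms` — the three factors in the Laplace decomposition of
  the ratio of the doubled-data to single-data posteriors of psi.  With a
  flat prior on the nuisance block, the prior-ratio factor equals one and
  the Hessian-determinant factor is constant in psi, so the ratio reduces to
  the profile likelihood — the identity the data-doubling method rests on.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .curves import ProfileCurve
from .models import Dataset, HierarchicalModel, PsiFunction
from .params import ParamSpace
from .sampler import PriorSpec

__all__ = [
    "QuadApprox",
    "LaplaceTerms",
    "fisher_information",
    "oracle_profile",
    "laplace_terms",
    "quad_lambda_hat",
    "quad_profile",
]


def _marginal_scalar(model: HierarchicalModel, data: Dataset,
                     theta: np.ndarray) -> float:
    th = np.asarray(theta, dtype=float)[None, :]
    if not bool(model.params.in_support(th)[0]):
        return -np.inf
    return float(model.marginal_loglik(data, th)[0])


def fisher_information(model: HierarchicalModel, data: Dataset,
                       theta_hat: np.ndarray, rel_step: float = 1e-4
                       ) -> np.ndarray:
    """Observed information: minus the finite-difference Hessian of the
    marginal log-likelihood at theta_hat (central differences, natural scale)."""
    th = np.asarray(theta_hat, dtype=float)
    d = th.size
    h = rel_step * np.maximum(1.0, np.abs(th))
    H = np.empty((d, d))
    f0 = _marginal_scalar(model, data, th)
    for i in range(d):
        for j in range(i, d):
            if i == j:
                tp, tm = th.copy(), th.copy()
                tp[i] += h[i]
                tm[i] -= h[i]
                H[i, i] = (_marginal_scalar(model, data, tp) - 2 * f0
                           + _marginal_scalar(model, data, tm)) / h[i] ** 2
            else:
                tpp, tpm, tmp, tmm = (th.copy() for _ in range(4))
                tpp[[i, j]] += [h[i], h[j]]
                tpm[i] += h[i]; tpm[j] -= h[j]
                tmp[i] -= h[i]; tmp[j] += h[j]
                tmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (
                    _marginal_scalar(model, data, tpp)
                    - _marginal_scalar(model, data, tpm)
                    - _marginal_scalar(model, data, tmp)
                    + _marginal_scalar(model, data, tmm)
                ) / (4 * h[i] * h[j])
    return -0.5 * (H + H.T)


@dataclass
class QuadApprox:
    """Quadratic surrogate of the log-likelihood: MLE plus information matrix.

    ``blocks(psi_index)`` partitions the information and its inverse into the
    (psi, lambda) coordinates when psi is a coordinate of theta.
    """

    theta_hat: np.ndarray
    info: np.ndarray

    def __post_init__(self):
        self.theta_hat = np.asarray(self.theta_hat, dtype=float)
        self.info = np.atleast_2d(np.asarray(self.info, dtype=float))
        if not np.allclose(self.info, self.info.T, rtol=1e-6, atol=1e-8):
            raise ValueError("information matrix must be symmetric")
        if np.min(np.linalg.eigvalsh(self.info)) <= 0:
            raise ValueError("information matrix must be positive definite")

    @property
    def dim(self) -> int:
        return self.theta_hat.size

    def loglik(self, theta: np.ndarray) -> float:
        dev = np.asarray(theta, dtype=float) - self.theta_hat
        return float(-0.5 * dev @ self.info @ dev)

    def blocks(self, psi_index: int) -> dict:
        keep = [j for j in range(self.dim) if j != psi_index]
        i = self.info
        inv = np.linalg.inv(i)
        return {
            "i_pp": float(i[psi_index, psi_index]),
            "i_pl": i[psi_index, keep],
            "i_ll": i[np.ix_(keep, keep)],
            "inv_pp": float(inv[psi_index, psi_index]),
            "inv_pl": inv[psi_index, keep],
            "inv_ll": inv[np.ix_(keep, keep)],
            "lambda_hat": self.theta_hat[keep],
            "psi_hat": float(self.theta_hat[psi_index]),
        }


# --------------------------------------------------------------------------
# constrained-optimization profiles
# --------------------------------------------------------------------------

def _constrained_max(objective, psi, psi_value, space: ParamSpace,
                     z_start: np.ndarray, rng: np.random.Generator,
                     n_restarts: int, psi_scale: float):
    """Maximize objective(theta) s.t. psi(theta)=psi_value, on the link scale.

    Returns (best_value, best_theta) or (None, None) if every restart fails.
    Profiles of ill-conditioned likelihoods are sensitive to starting values,
    hence the jittered restarts.
    """
    def neg(z):
        v = objective(space.from_link(z))
        return 1e12 if not np.isfinite(v) else -v

    def cons_f(z):
        return psi(space.from_link(z)[None, :])[0] - psi_value

    best_v, best_th = None, None
    for r in range(n_restarts):
        z0 = z_start if r == 0 else z_start + 0.3 * r * rng.standard_normal(
            z_start.size)
        try:
            res = minimize(neg, z0, method="SLSQP",
                           constraints=[{"type": "eq", "fun": cons_f}],
                           options={"maxiter": 300, "ftol": 1e-12})
        except (ValueError, OverflowError):
            continue
        if abs(cons_f(res.x)) > 1e-6 * max(1.0, abs(psi_scale)):
            continue
        v = -neg(res.x)
        if np.isfinite(v) and (best_v is None or v > best_v):
            best_v, best_th = v, space.from_link(res.x)
    return best_v, best_th


def oracle_profile(model: HierarchicalModel, data: Dataset, psi: PsiFunction,
                   grid: np.ndarray, theta0: Optional[np.ndarray] = None,
                   n_restarts: int = 5, seed: int = 0) -> ProfileCurve:
    """Log-profile likelihood by constrained optimization of the analytic
    marginal log-likelihood; max-normalized on the grid.

    Grid points where the constraint is infeasible (or every restart fails)
    are dropped with a warning; they are listed in the curve metadata.
    """
    if not model.has_marginal:
        raise ValueError(f"model {model.name!r} has no analytic marginal "
                         "likelihood; the oracle needs one")
    grid = np.asarray(grid, dtype=float)
    space = model.params
    rng = np.random.default_rng(seed)
    if theta0 is None:
        from .sampler import _default_init
        theta0 = _default_init(model, data)
    # polish the start to the unconstrained MLE for good warm starts
    zhat = minimize(lambda z: -_finite(model, data, space, z),
                    space.to_link(np.asarray(theta0, dtype=float)),
                    method="Nelder-Mead",
                    options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10}).x
    psi_hat = psi(space.from_link(zhat)[None, :])[0]
    psi_scale = max(np.ptp(grid), abs(psi_hat), 1.0)

    order = np.argsort(np.abs(grid - psi_hat))
    values = np.full(grid.size, np.nan)
    starts = {None: zhat}
    solved_z = {}
    objective = lambda th: _marginal_scalar(model, data, th)
    # sweep outward from the peak, warm-starting from the nearest solved point
    for idx in order:
        near = min(solved_z, key=lambda j: abs(grid[j] - grid[idx]),
                   default=None)
        z0 = solved_z.get(near, zhat)
        v, th = _constrained_max(objective, psi, grid[idx], space, z0, rng,
                                 n_restarts, psi_scale)
        if v is None:
            warnings.warn(f"profile point psi={grid[idx]:.6g} dropped: "
                          "constrained optimization failed")
            continue
        values[idx] = v
        solved_z[idx] = space.to_link(th)
    ok = np.isfinite(values)
    if not np.any(ok):
        raise RuntimeError("constrained optimization failed at every grid point")
    return ProfileCurve(
        psi_grid=grid[ok], logpl=values[ok], method="oracle",
        meta={"psi": psi.name, "dropped": grid[~ok].tolist(),
              "theta_hat_link": zhat.tolist()},
    )


def _finite(model, data, space, z):
    v = _marginal_scalar(model, data, space.from_link(z))
    return -1e12 if not np.isfinite(v) else v


def quad_lambda_hat(qa: QuadApprox, psi_index: int, psi_value: float
                    ) -> np.ndarray:
    """Constrained maximizer of the quadratic surrogate in lambda at fixed
    psi (a coordinate): lambda_hat - i_ll^{-1} i_lp (psi - psi_hat)."""
    b = qa.blocks(psi_index)
    i_ll, i_lp = b["i_ll"], b["i_pl"]  # i_lp = i_pl^T (symmetric)
    try:
        shift = np.linalg.solve(i_ll, i_lp)
    except np.linalg.LinAlgError:
        raise ValueError("nuisance information block is singular") from None
    return b["lambda_hat"] - shift * (psi_value - b["psi_hat"])


def quad_profile(qa: QuadApprox, psi: PsiFunction, grid: np.ndarray,
                 space: Optional[ParamSpace] = None, n_restarts: int = 5,
                 seed: int = 0) -> ProfileCurve:
    """Profile of the quadratic surrogate -(theta-that)' i (theta-that)/2
    under the constraint f(theta)=psi.  Exactly quadratic in psi when psi is
    a coordinate; generally not under other parameterizations (the surrogate
    is not parameterization-invariant)."""
    grid = np.asarray(grid, dtype=float)
    if space is None:
        space = ParamSpace(tuple(f"t{i}" for i in range(qa.dim)),
                           ("identity",) * qa.dim)
    rng = np.random.default_rng(seed)
    zhat = space.to_link(qa.theta_hat)
    psi_hat = psi(qa.theta_hat[None, :])[0]
    psi_scale = max(np.ptp(grid), abs(psi_hat), 1.0)
    values = np.full(grid.size, np.nan)
    order = np.argsort(np.abs(grid - psi_hat))
    solved_z = {}
    for idx in order:
        near = min(solved_z, key=lambda j: abs(grid[j] - grid[idx]),
                   default=None)
        z0 = solved_z.get(near, zhat)
        v, th = _constrained_max(qa.loglik, psi, grid[idx], space, z0, rng,
                                 n_restarts, psi_scale)
        if v is None:
            warnings.warn(f"quadratic profile point psi={grid[idx]:.6g} "
                          "dropped: constrained optimization failed")
            continue
        values[idx] = v
        solved_z[idx] = space.to_link(th)
    ok = np.isfinite(values)
    if not np.any(ok):
        raise RuntimeError("constrained optimization failed at every grid point")
    return ProfileCurve(psi_grid=grid[ok], logpl=values[ok], method="quadratic",
                        meta={"psi": psi.name, "dropped": grid[~ok].tolist()})


# --------------------------------------------------------------------------
# Laplace-term diagnostics
# --------------------------------------------------------------------------

@dataclass
class LaplaceTerms:
    """The three factors of the doubled-to-single posterior ratio at one psi.

    ``term1`` is exp(2 l(psi, lam2) - l(psi, lam1)) — the profile-likelihood
    factor (``log_term1`` is provided against overflow).  ``term2`` is the
    square-root Hessian-determinant ratio; ``term3`` the prior-density ratio
    at the two constrained maximizers.  ``hess_single``/``hess_doubled`` are
    the negative lambda-Hessians of the single- and doubled-data
    log-posteriors.
    """

    psi: float
    term1: float
    term2: float
    term3: float
    log_term1: float
    lambda_hat_psi: np.ndarray
    lambda_hat_psi2: np.ndarray
    hess_single: np.ndarray
    hess_doubled: np.ndarray
    warnings: list = field(default_factory=list)


def _hessian_fd(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    x0 = np.asarray(x0, dtype=float)
    p = x0.size
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.empty((p, p))
    f0 = f(x0)
    for i in range(p):
        for j in range(i, p):
            if i == j:
                xp, xm = x0.copy(), x0.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]; xpm[j] -= h[j]
                xmp[i] -= h[i]; xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) \
                    / (4 * h[i] * h[j])
    return 0.5 * (H + H.T)


def laplace_terms(model: HierarchicalModel, data: Dataset, prior: PriorSpec,
                  psi_index: int, psi_value: float, n_restarts: int = 5,
                  seed: int = 0, rel_step: float = 1e-4) -> LaplaceTerms:
    """Compute the three Laplace factors at one psi value.

    Requires an explicit (psi, lambda) split: psi must be a coordinate of the
    model's canonical parameters (re-register a re-parameterized model if it
    is not).  The constrained maximizers of ``l + log prior`` and ``2 l + log
    prior`` over lambda are found numerically; Hessians are central finite
    differences on the natural scale.
    """
    if not model.has_marginal:
        raise ValueError("laplace_terms requires an analytic marginal "
                         "log-likelihood")
    space = model.params
    d = space.dim
    keep = [j for j in range(d) if j != psi_index]
    lam_space = ParamSpace(tuple(space.names[j] for j in keep),
                           tuple(space.links[j] for j in keep),
                           tuple(space.bounds[j] for j in keep))
    cond_prior = prior.conditional_lambda(psi_index, psi_value)
    rng = np.random.default_rng(seed)

    def theta_of(lam):
        th = np.empty(d)
        th[psi_index] = psi_value
        th[keep] = lam
        return th

    def logpost(lam, m):
        lp = cond_prior.log_density(lam[None, :])[0]
        if not np.isfinite(lp):
            return -np.inf
        return m * _marginal_scalar(model, data, theta_of(lam)) + lp

    def maximize(m):
        from .sampler import _default_init
        lam0 = _default_init(model, data)[keep]
        if prior.kind == "mvnormal":
            lam0 = cond_prior.mean
        best = None
        for r in range(n_restarts):
            z0 = lam_space.to_link(np.asarray(lam0, dtype=float))
            if r > 0:
                z0 = z0 + 0.2 * r * rng.standard_normal(z0.size)
            neg = lambda z: -_neg_inf_guard(logpost(lam_space.from_link(z), m))
            res = minimize(neg, z0, method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": 1e-10,
                                    "fatol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("constrained maximization over lambda failed")
        return lam_space.from_link(best.x)

    lam1 = maximize(1)
    lam2 = maximize(2)
    warns = []

    l1 = _marginal_scalar(model, data, theta_of(lam1))
    l2 = _marginal_scalar(model, data, theta_of(lam2))
    log_term1 = 2.0 * l2 - l1
    with np.errstate(over="ignore"):
        term1 = float(np.exp(log_term1))

    def h_single(lam):
        return _neg_inf_guard(logpost(lam, 1))

    def h_doubled(lam):
        return _neg_inf_guard(logpost(lam, 2))

    H1 = -_hessian_fd(h_single, lam1, rel_step)
    H2 = -_hessian_fd(h_doubled, lam2, rel_step)
    for nm, H in (("single", H1), ("doubled", H2)):
        if np.min(np.linalg.eigvalsh(H)) <= 0:
            warns.append(f"negative-Hessian check failed for the {nm}-data "
                         "log-posterior (optimum may be degenerate)")
    s1, ld1 = np.linalg.slogdet(H1)
    s2, ld2 = np.linalg.slogdet(H2)
    term2 = float(np.exp(0.5 * (ld2 - ld1))) if s1 > 0 and s2 > 0 else np.nan
    term3 = float(np.exp(cond_prior.log_density(lam2[None, :])[0]
                         - cond_prior.log_density(lam1[None, :])[0]))
    return LaplaceTerms(
        psi=float(psi_value), term1=term1, term2=term2, term3=term3,
        log_term1=float(log_term1), lambda_hat_psi=lam1, lambda_hat_psi2=lam2,
        hess_single=H1, hess_doubled=H2, warnings=warns,
    )


def _neg_inf_guard(v: float) -> float:
    return -1e15 if not np.isfinite(v) else v
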