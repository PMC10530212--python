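"""Log density-ratio estimation by classification.

Two posterior samples of psi — one under the doubled data, one under the
original data — are pooled and labelled (1 = doubled, 0 = single).  A
logistic regression of the label on a smooth function of psi estimates
P(doubled | psi); its log-odds equals the log ratio of the two posterior
densities plus a constant.  With a matched prior, that log-ratio *is* the
log-profile likelihood up to the constant, which normalization removes.

Smoothers for the log-odds:

* ``quartic`` (default) — degree-4 polynomial, the simple choice that works
  well in practice;
* ``spline`` — cubic B-spline basis;
* ``concave_spline`` — the same basis fitted by constrained maximum
  likelihood with non-positive second differences of the log-odds (profile
  log-likelihoods of regular models are concave near the peak);
* ``kde_diff`` — difference of two Gaussian kernel log-density estimates
  (no classification step; a cross-check, never the default).

Fits are trusted only on ``eval_range`` — the intersection of per-class
central quantile ranges — because flexible smoothers are fragile in the
tails; evaluation outside it is refused rather than extrapolated.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import LinearConstraint, minimize
from scipy.stats import gaussian_kde

from .curves import ProfileCurve

__all__ = [
    "PsiLabelledSample",
    "LogOddsFit",
    "build_labelled",
    "fit_logodds",
    "logprofile_from_fit",
    "SMOOTHERS",
]

SMOOTHERS = ("quartic", "spline", "concave_spline", "kde_diff")


@dataclass
class PsiLabelledSample:
    """Pooled psi draws with 0/1 source labels (1 = doubled-data draw)."""

    values: np.ndarray
    labels: np.ndarray

    @property
    def S1(self) -> int:
        return int(self.labels.sum())

    @property
    def S2(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def build_labelled(psi_doubled: np.ndarray, psi_single: np.ndarray
                   ) -> PsiLabelledSample:
    """Pool doubled- and single-data psi draws into a labelled sample.

    Group sizes need not be equal; the logistic intercept absorbs the
    log-ratio of counts and is discarded anyway.
    """
    d = np.asarray(psi_doubled, dtype=float).ravel()
    s = np.asarray(psi_single, dtype=float).ravel()
    if d.size == 0 or s.size == 0:
        raise ValueError("both psi samples must be non-empty")
    for name, arr in (("doubled", d), ("single", s)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite psi value in the {name}-data sample")
    values = np.concatenate([d, s])
    labels = np.concatenate([np.ones(d.size), np.zeros(s.size)])
    return PsiLabelledSample(values=values, labels=labels)


@dataclass
class LogOddsFit:
    """Fitted log-odds of 'doubled' vs psi, intercept separated out.

    Calling the fit evaluates the log-odds *minus the intercept* (the
    additive constant is irrelevant after max-normalization; the convention
    here anchors the intercept at the midpoint of ``eval_range``).
    """

    smoother: str
    raw: Callable[[np.ndarray], np.ndarray]
    intercept: float
    eval_range: tuple[float, float]
    S1: int
    S2: int

    def __call__(self, psi: np.ndarray) -> np.ndarray:
        return self.raw(np.asarray(psi, dtype=float)) - self.intercept


def _quantile_range(v: np.ndarray, q: float) -> tuple[float, float]:
    return float(np.quantile(v, q)), float(np.quantile(v, 1.0 - q))


def _spline_design(z: np.ndarray, knots: np.ndarray, degree: int = 3
                   ) -> np.ndarray:
    t = np.r_[[knots[0]] * degree, knots, [knots[-1]] * degree]
    n_basis = len(t) - degree - 1
    return BSpline.design_matrix(
        np.clip(z, knots[0], knots[-1]), t, degree
    ).toarray()[:, :n_basis], t, degree


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000,
                             tol=1e-8, fit_intercept=True)
    clf.fit(X, y)
    return np.r_[clf.intercept_, clf.coef_[0]]


def fit_logodds(sample: PsiLabelledSample, smoother: str = "quartic",
                trim_q: float = 0.005, min_per_class: int = 50,
                n_knots: int = 8) -> LogOddsFit:
    """Fit the log-odds of the doubled-data label as a smooth function of psi."""
    if smoother not in SMOOTHERS:
        raise ValueError(f"smoother must be one of {SMOOTHERS}")
    v, lab = sample.values, sample.labels
    S1, S2 = sample.S1, sample.S2
    if S1 < min_per_class or S2 < min_per_class:
        raise ValueError(
            f"need at least {min_per_class} draws per class (have {S1}, {S2})"
        )
    scale = float(np.std(v))
    if scale < 1e-10 * max(1.0, float(np.abs(v).mean())):
        raise ValueError("psi does not vary over the posterior; "
                         "the profile for a constant is undefined")
    lo1, hi1 = _quantile_range(v[lab == 1], trim_q)
    lo0, hi0 = _quantile_range(v[lab == 0], trim_q)
    lo, hi = max(lo1, lo0), min(hi1, hi0)
    if not lo < hi:
        raise ValueError(
            "the two psi samples barely overlap (complete separation); "
            "draw more posterior samples or widen the prior"
        )
    center, sd = float(np.mean(v)), scale

    if smoother == "kde_diff":
        k1 = gaussian_kde(v[lab == 1])
        k0 = gaussian_kde(v[lab == 0])

        def raw(psi, k1=k1, k0=k0):
            return k1.logpdf(psi) - k0.logpdf(psi)

    elif smoother == "quartic":
        z = (v - center) / sd
        X = np.column_stack([z, z ** 2, z ** 3, z ** 4])
        coefs = _fit_logistic(X, lab)

        def raw(psi, c=coefs, center=center, sd=sd):
            z = (np.atleast_1d(psi) - center) / sd
            Z = np.column_stack([np.ones_like(z), z, z ** 2, z ** 3, z ** 4])
            return Z @ c

    else:  # spline bases
        z = (v - center) / sd
        zlo, zhi = (lo - center) / sd, (hi - center) / sd
        interior = np.linspace(zlo, zhi, n_knots)
        X, t, degree = _spline_design(z, interior)
        if smoother == "spline":
            coefs = _fit_logistic(X[:, 1:], lab)  # drop one column: intercept
            coefs = np.r_[coefs[0], coefs[1:]]

            def raw(psi, c=coefs, t=t, degree=degree, center=center, sd=sd,
                    zlo=zlo, zhi=zhi):
                z = np.clip((np.atleast_1d(psi) - center) / sd, zlo, zhi)
                n_basis = len(t) - degree - 1
                B = BSpline.design_matrix(z, t, degree).toarray()[:, :n_basis]
                return c[0] + B[:, 1:] @ c[1:]

        else:  # concave_spline: constrained logistic MLE
            coefs = _concave_logistic(X, lab, t, degree, zlo, zhi)

            def raw(psi, c=coefs, t=t, degree=degree, center=center, sd=sd,
                    zlo=zlo, zhi=zhi):
                z = np.clip((np.atleast_1d(psi) - center) / sd, zlo, zhi)
                n_basis = len(t) - degree - 1
                B = BSpline.design_matrix(z, t, degree).toarray()[:, :n_basis]
                return B @ c

    mid = 0.5 * (lo + hi)
    f_mid = float(np.atleast_1d(raw(np.array([mid])))[0])
    fit = LogOddsFit(smoother=smoother, raw=lambda p, raw=raw:
                     np.atleast_1d(raw(p)), intercept=f_mid,
                     eval_range=(lo, hi), S1=S1, S2=S2)
    # complete-separation guard: an unbounded fitted log-odds means the
    # classifier can tell the groups apart almost perfectly
    probe = fit(np.linspace(lo, hi, 41))
    if np.max(np.abs(probe)) > 50:
        raise ValueError(
            "fitted log-odds is extreme (near-complete separation); "
            "draw more posterior samples or widen the prior"
        )
    return fit


def _concave_logistic(X: np.ndarray, y: np.ndarray, t: np.ndarray,
                      degree: int, zlo: float, zhi: float) -> np.ndarray:
    """Logistic MLE over spline coefficients subject to concave log-odds.

    Concavity is imposed as non-positive second differences of the fitted
    log-odds on a fine grid spanning the trusted range.
    """
    n_basis = X.shape[1]
    # second derivative of a cubic spline is piecewise linear, so imposing
    # g'' <= 0 at every breakpoint makes the fit concave on the whole range
    breaks = np.unique(np.clip(t, zlo, zhi))
    D2 = np.empty((len(breaks), n_basis))
    for i in range(n_basis):
        e = np.zeros(n_basis)
        e[i] = 1.0
        D2[:, i] = BSpline(t, e, degree).derivative(2)(breaks)

    def nll(c):
        eta = X @ c
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    def grad(c):
        eta = X @ c
        p = 1.0 / (1.0 + np.exp(-eta))
        return X.T @ (p - y)

    # start from an unconstrained ridge-stabilized fit projected to feasibility
    from sklearn.linear_model import LogisticRegression
    clf = LogisticRegression(C=100.0, solver="lbfgs",
                             max_iter=1000, fit_intercept=False)
    clf.fit(X, y)
    c0 = clf.coef_[0]
    cons = LinearConstraint(D2, -np.inf, 0.0)
    res = minimize(nll, c0, jac=grad, method="trust-constr",
                   constraints=[cons],
                   options={"maxiter": 300, "gtol": 1e-8, "verbose": 0})
    return res.x


def logprofile_from_fit(fit: LogOddsFit, grid: np.ndarray) -> ProfileCurve:
    """Evaluate the intercept-free log-odds on a grid as a normalized curve.

    Grid points outside the fit's trusted range are refused (no
    extrapolation — the smoothers are unreliable in the tails).
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = fit.eval_range
    if np.any(grid < lo) or np.any(grid > hi):
        raise ValueError(
            f"grid extends beyond the trusted range ({lo:.6g}, {hi:.6g}); "
            "no extrapolation is performed"
        )
    vals = fit(grid)
    return ProfileCurve(
        psi_grid=grid, logpl=vals, method="density_ratio",
        meta={"smoother": fit.smoother, "eval_range": fit.eval_range,
              "S1": fit.S1, "S2": fit.S2},
    )
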