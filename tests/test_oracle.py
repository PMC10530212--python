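"""Constrained-optimization oracle, quadratic surrogate, Laplace terms."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from ddprofile.models import (Dataset, GaussianMeanKnownCov, builtin_psi,
                              component_psi, lookup_model)
from ddprofile.oracle import (QuadApprox, fisher_information, laplace_terms,
                              oracle_profile, quad_lambda_hat, quad_profile)
from ddprofile.params import ParamSpace
from ddprofile.sampler import PriorSpec


@pytest.fixture(scope="module")
def gaussian_setup():
    """Bivariate Gaussian mean model with known covariance: the
    log-likelihood is exactly quadratic in theta."""
    Sigma = np.array([[1.0, 0.3], [0.3, 0.8]])
    model = GaussianMeanKnownCov(Sigma)
    rng = np.random.default_rng(3)
    y = rng.multivariate_normal([0.2, -0.1], Sigma, size=25)
    data = Dataset("matrix", pd.DataFrame(y, columns=["y1", "y2"]))
    theta_hat = y.mean(axis=0)
    info = fisher_information(model, data, theta_hat)
    return model, data, theta_hat, info


class TestOracleProfile:
    def test_normal_mean_profile_is_the_loglik(self, normal_data):
        m = lookup_model("normal_mean")
        grid = np.linspace(-0.6, 1.2, 31)
        c = oracle_profile(m, normal_data, component_psi(m, "mu"), grid)
        truth = -10 * (grid - 0.3) ** 2 / 2
        truth -= truth.max()
        assert np.max(np.abs(c.logpl - truth)) < 1e-6

    def test_beta_mean_peak_at_mle_image(self, beta_data_50):
        m = lookup_model("beta_iid")
        ybar = beta_data_50.frame["y"].mean()
        grid = np.linspace(ybar - 0.12, ybar + 0.12, 25)
        c = oracle_profile(m, beta_data_50, builtin_psi("beta_mean"), grid)
        # the beta-mean MLE profile peaks at the MLE image (= near ybar)
        assert abs(c.psi_hat - ybar) < 0.015
        assert c.logpl.max() == 0.0

    def test_profile_dominates_feasible_slices(self, beta_data_50):
        # brute-force probe: no feasible theta with f(theta)=psi may beat
        # the profiled value
        m = lookup_model("beta_iid")
        psi = builtin_psi("beta_skew")
        grid = np.linspace(-0.8, 0.3, 12)
        c = oracle_profile(m, beta_data_50, psi, grid)
        th2d = lambda a, b: np.array([[a, b]])
        mll = lambda a, b: float(m.marginal_loglik(beta_data_50, th2d(a, b))[0])
        peak = mll_peak(m, beta_data_50)  # normalizing constant of the curve
        rng = np.random.default_rng(0)
        probes = 0
        violations = 0
        for g, v in zip(c.psi_grid, c.logpl):
            for _ in range(9):
                a = np.exp(rng.uniform(-1.5, 2.5))
                # solve skew(a, b) = g for b by 1-D root finding
                f = lambda lb: psi(th2d(a, np.exp(lb)))[0] - g
                lo, hi = -6.0, 6.0
                if f(lo) * f(hi) > 0:
                    continue
                from scipy.optimize import brentq
                b = np.exp(brentq(f, lo, hi, xtol=1e-12))
                probes += 1
                # the profile dominates every feasible likelihood slice
                violations += (mll(a, b) - peak) > v + 1e-6
        assert probes >= 30
        assert violations == 0

    def test_monotone_away_from_peak(self, beta_data_50):
        m = lookup_model("beta_iid")
        grid = np.linspace(0.45, 0.75, 31)
        c = oracle_profile(m, beta_data_50, builtin_psi("beta_mean"), grid)
        i = int(np.argmax(c.logpl))
        assert np.all(np.diff(c.logpl[: i + 1]) >= -1e-8)
        assert np.all(np.diff(c.logpl[i:]) <= 1e-8)

    def test_model_without_marginal_rejected(self, beta_data_50):
        m = lookup_model("bevholt_poisson")
        with pytest.raises(ValueError, match="marginal"):
            oracle_profile(m, beta_data_50, builtin_psi("bh_growth"),
                           np.array([1.5, 2.0]))


_PEAK_CACHE = {}


def mll_peak(model, data):
    key = id(data)
    if key not in _PEAK_CACHE:
        space = model.params
        res = minimize(
            lambda z: -float(model.marginal_loglik(
                data, space.from_link(z)[None, :])[0]),
            space.to_link(np.array([2.0, 2.0])), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12})
        _PEAK_CACHE[key] = -res.fun
    return _PEAK_CACHE[key]


class TestQuadApprox:
    @pytest.mark.parametrize("d", [2, 3, 5])
    def test_lambda_hat_matches_numerical_maximizer(self, d):
        rng = np.random.default_rng(d)
        for _ in range(33):
            A = rng.standard_normal((d, d))
            info = A @ A.T + d * np.eye(d)
            that = rng.standard_normal(d)
            qa = QuadApprox(that, info)
            psi_value = that[0] + rng.uniform(-2, 2)
            lh = quad_lambda_hat(qa, 0, psi_value)
            obj = lambda lam: -qa.loglik(np.r_[psi_value, lam])
            jac = lambda lam: (info @ (np.r_[psi_value, lam] - that))[1:]
            num = minimize(obj, that[1:], jac=jac, method="BFGS",
                           options={"gtol": 1e-13}).x
            assert np.max(np.abs(lh - num)) < 1e-8

    def test_lambda_hat_at_psi_hat_is_lambda_hat(self):
        qa = QuadApprox(np.array([1.0, 2.0, 3.0]), np.diag([2.0, 1.0, 4.0]))
        assert np.allclose(quad_lambda_hat(qa, 0, 1.0), [2.0, 3.0])
        # orthogonal parameters: lambda_hat for every psi
        assert np.allclose(quad_lambda_hat(qa, 0, 7.0), [2.0, 3.0])

    def test_coordinate_profile_closed_form(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((3, 3))
        info = A @ A.T + 3 * np.eye(3)
        qa = QuadApprox(np.zeros(3), info)
        space = ParamSpace(("t0", "t1", "t2"), ("identity",) * 3)
        psi = _coord_psi(0)
        grid = np.linspace(-1, 1, 21)
        c = quad_profile(qa, psi, grid, space)
        inv_pp = np.linalg.inv(info)[0, 0]
        closed = -grid ** 2 / (2 * inv_pp)
        closed -= closed.max()
        assert np.max(np.abs(c.logpl - closed)) < 1e-8

    def test_singlepoint_grid(self):
        qa = QuadApprox(np.zeros(2), np.eye(2))
        c = quad_profile(qa, _coord_psi(0), np.array([0.0]))
        assert c.logpl[0] == 0.0

    def test_parameterization_dependence_of_quadratic_profile(self,
                                                              beta_data_50):
        """Under (psi1, alpha) coordinates the surrogate profile of the beta
        mean is exactly quadratic; under (alpha, beta) it is not."""
        mB = lookup_model("beta_iid")
        mR = lookup_model("beta_mean_alpha")
        # MLEs in both parameterizations
        ybar = beta_data_50.frame["y"].mean()
        zB = minimize(lambda z: -float(mB.marginal_loglik(
            beta_data_50, mB.params.from_link(z)[None, :])[0]),
            mB.params.to_link(np.array([3.0, 2.0])), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12}).x
        thB = mB.params.from_link(zB)
        thR = np.array([thB[0] / (thB[0] + thB[1]), thB[0]])
        qaB = QuadApprox(thB, fisher_information(mB, beta_data_50, thB))
        qaR = QuadApprox(thR, fisher_information(mR, beta_data_50, thR))
        grid = np.linspace(thR[0] - 0.08, thR[0] + 0.08, 21)
        cR = quad_profile(qaR, _coord_psi(0), grid, mR.params)
        cB = quad_profile(qaB, builtin_psi("beta_mean"), grid, mB.params)
        h = grid[1] - grid[0]
        third_R = np.diff(cR.logpl, 3)
        third_B = np.diff(cB.logpl, 3)
        scale = np.max(np.abs(cB.logpl))
        assert np.max(np.abs(third_R)) < 1e-6 * max(scale, 1.0)
        assert np.max(np.abs(third_B)) > 10 * np.max(np.abs(third_R))


def _coord_psi(j):
    from ddprofile.models import PsiFunction
    return PsiFunction(f"t{j}", lambda th, j=j: th[:, j], component_index=j)


class TestLaplaceTerms:
    def test_flat_prior_term3_exactly_one(self):
        m = lookup_model("normal_meanvar")
        rng = np.random.default_rng(3)
        y = rng.normal(0.5, 1.2, 40)
        dn = Dataset("scalar", pd.DataFrame({"y": y}))
        prior = PriorSpec.flat_box(m.params.default_box())
        for psi_value in np.linspace(0.1, 0.9, 5):
            lt = laplace_terms(m, dn, prior, 0, psi_value)
            assert lt.term3 == 1.0
            # identical estimating equations: the two maximizers coincide
            assert np.allclose(lt.lambda_hat_psi, lt.lambda_hat_psi2,
                               rtol=1e-4)

    def test_flat_prior_term2_constant_in_psi(self):
        m = lookup_model("normal_meanvar")
        rng = np.random.default_rng(3)
        y = rng.normal(0.5, 1.2, 40)
        dn = Dataset("scalar", pd.DataFrame({"y": y}))
        prior = PriorSpec.flat_box(m.params.default_box())
        t2 = [laplace_terms(m, dn, prior, 0, v).term2
              for v in np.linspace(0.2, 0.8, 7)]
        # determinant ratio is the psi-independent constant 2^{(d-1)/2}
        assert np.std(t2) / np.mean(t2) < 1e-3
        assert np.mean(t2) == pytest.approx(np.sqrt(2.0), rel=1e-3)

    def test_quadratic_model_hessian_scale_three_halves(self, gaussian_setup):
        model, data, theta_hat, info = gaussian_setup
        prior = PriorSpec.mvnormal(theta_hat, np.linalg.inv(info))
        i_ll = info[1, 1]
        lt = laplace_terms(model, data, prior, 0, theta_hat[0] + 0.2)
        assert lt.hess_single[0, 0] == pytest.approx(2 * i_ll, rel=1e-5)
        assert lt.hess_doubled[0, 0] == pytest.approx(3 * i_ll, rel=1e-5)
        ratio = lt.hess_doubled[0, 0] / lt.hess_single[0, 0]
        assert ratio == pytest.approx(1.5, abs=1e-6)
        # and the two constrained maximizers coincide
        assert np.allclose(lt.lambda_hat_psi, lt.lambda_hat_psi2, atol=1e-6)

    def test_quadratic_model_terms_constant_and_term1_is_profile(
            self, gaussian_setup):
        model, data, theta_hat, info = gaussian_setup
        prior = PriorSpec.mvnormal(theta_hat, np.linalg.inv(info))
        grid = theta_hat[0] + np.linspace(-0.5, 0.5, 21)
        t2, t3, logt1 = [], [], []
        for v in grid:
            lt = laplace_terms(model, data, prior, 0, v)
            t2.append(lt.term2)
            t3.append(lt.term3)
            logt1.append(lt.log_term1)
        # regression slope of term2/term3 on psi ~ 0
        for series in (t2, t3):
            slope = np.polyfit(grid, series, 1)[0]
            assert abs(slope) <= 1e-5 * np.mean(series)
        # log term1 differs from the oracle profile by a constant
        c = oracle_profile(model, data, _coord_psi(0), grid,
                           theta0=theta_hat)
        diff = np.asarray(logt1) - c.logpl
        assert np.ptp(diff) <= 1e-5
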