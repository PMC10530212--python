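"""Model registry, log-joint replication semantics, and psi functions."""
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from ddprofile.models import (Dataset, MvNormalIID, builtin_psi,
                              component_psi, lookup_model, register_model,
                              replicated_log_joint)
from ddprofile.params import ParamSpace


class TestRegistry:
    def test_builtins_present_with_expected_dimensions(self):
        assert lookup_model("beta_iid").params.dim == 2
        assert lookup_model("bevholt_poisson").params.names == (
            "lambda", "beta", "sigma2")
        assert lookup_model("rand_intercept_binom").params.dim == 4
        assert lookup_model("sir_binomial").params.names == ("beta", "gamma")

    def test_duplicate_registration_rejected(self):
        with pytest.raises(ValueError, match="already registered"):
            register_model("beta_iid", lookup_model("beta_iid"))

    def test_unknown_model_is_keyerror(self):
        with pytest.raises(KeyError, match="no_such_model"):
            lookup_model("no_such_model")


class TestReplicatedLogJoint:
    def test_beta_pointwise_value(self):
        # f(0.5; 3, 2) = 0.5^2 * 0.5 / B(3,2) = 1.5
        ds = Dataset("scalar", pd.DataFrame({"y": [0.5]}))
        v = replicated_log_joint(lookup_model("beta_iid"), ds,
                                 np.array([3.0, 2.0]))
        assert v == pytest.approx(np.log(1.5), abs=1e-12)

    @pytest.mark.parametrize("K", [1, 2, 5])
    def test_nonhierarchical_replication_is_exact_multiple(self, K,
                                                           beta_data_50):
        m = lookup_model("beta_iid")
        th = np.array([2.5, 1.7])
        v1 = replicated_log_joint(m, beta_data_50.replicate(1), th)
        vK = replicated_log_joint(m, beta_data_50.replicate(K), th)
        assert vK == pytest.approx(K * v1, rel=1e-15)

    def test_out_of_support_returns_neg_inf_not_exception(self, beta_data_50):
        m = lookup_model("beta_iid")
        assert replicated_log_joint(m, beta_data_50,
                                    np.array([-1.0, 2.0])) == -np.inf

    def test_cloned_latents_are_independent_blocks(self):
        from ddprofile.simulate import gen_bevholt_poisson
        ds = gen_bevholt_poisson(10, 2.0, 0.01, 0.01, seed=0).replicate(2)
        m = lookup_model("bevholt_poisson")
        th = np.array([2.0, 0.01, 0.01])
        rng = np.random.default_rng(1)
        x1 = np.log(10) + 0.3 * rng.standard_normal(10)
        x2 = np.log(10) + 0.3 * rng.standard_normal(10)
        v_indep = replicated_log_joint(m, ds, th, np.stack([x1, x2]))
        v_tied = replicated_log_joint(m, ds, th, np.stack([x1, x1]))
        assert v_indep != pytest.approx(v_tied)
        # and the sum decomposes over blocks
        d1 = ds.replicate(1)
        va = replicated_log_joint(m, d1, th, x1[None, :])
        vb = replicated_log_joint(m, d1, th, x2[None, :])
        assert v_indep == pytest.approx(va + vb, rel=1e-12)

    def test_hierarchical_model_requires_latents(self):
        from ddprofile.simulate import gen_bevholt_poisson
        ds = gen_bevholt_poisson(5, 2.0, 0.01, 0.01, seed=0)
        with pytest.raises(ValueError, match="latent"):
            replicated_log_joint(lookup_model("bevholt_poisson"), ds,
                                 np.array([2.0, 0.01, 0.01]))


class TestPsiFunctions:
    @pytest.mark.parametrize("name,theta,expected", [
        ("beta_mean", [3.0, 2.0], 0.6),
        ("beta_var", [3.0, 2.0], 0.04),
        ("beta_skew", [3.0, 2.0], -2.0 / 7.0),
        ("sir_R0", [2.0, 1.0], 2.0),
        ("bh_carrying_capacity", [2.0, 0.01, 0.05], 100.0),
        ("bh_growth", [2.0, 0.01, 0.05], 2.0),
    ])
    def test_builtin_formula_values(self, name, theta, expected):
        psi = builtin_psi(name)
        assert psi(np.asarray(theta)) == pytest.approx(expected, rel=1e-12)

    def test_unknown_psi_is_keyerror(self):
        with pytest.raises(KeyError, match="no built-in psi"):
            builtin_psi("not_a_psi")

    def test_component_psi_unknown_component(self):
        with pytest.raises(KeyError, match="gamma"):
            component_psi(lookup_model("beta_iid"), "gamma")

    @pytest.mark.parametrize("d", [2, 3])
    def test_max_eigenvalue_invariant_under_relabelling(self, d):
        # permuting coordinates is an orthogonal change of basis; the top
        # eigenvalue of the covariance must not move
        rng = np.random.default_rng(d)
        A = rng.standard_normal((d, d))
        Sigma = A @ A.T + d * np.eye(d)
        mu = rng.standard_normal(d)
        model = MvNormalIID(d)
        psi = builtin_psi("mvn_max_eigenvalue") if d == 2 else None
        perm = np.eye(d)[::-1]
        Sigma_p = perm @ Sigma @ perm.T
        th = model.theta_from_moments(mu, Sigma)
        th_p = model.theta_from_moments(perm @ mu, Sigma_p)
        if d == 2:
            v, vp = psi(th), psi(th_p)
        else:
            v = np.linalg.eigvalsh(model.cov(th)).max()
            vp = np.linalg.eigvalsh(model.cov(th_p)).max()
        assert v == pytest.approx(vp, rel=1e-12)
        assert v == pytest.approx(np.linalg.eigvalsh(Sigma).max(), rel=1e-8)


class TestDensityNormalization:
    @pytest.mark.parametrize("name,theta,lo,hi", [
        ("beta_iid", [3.0, 2.0], 0.0, 1.0),
        ("normal_meanvar", [0.4, 1.3], -15.0, 15.0),
        ("normal_mean", [0.2], -15.0, 15.0),
    ])
    def test_marginal_density_integrates_to_one(self, name, theta, lo, hi):
        m = lookup_model(name)
        th = np.asarray(theta, dtype=float)

        def dens(y):
            ds = Dataset("scalar", pd.DataFrame({"y": [y]}))
            return np.exp(replicated_log_joint(m, ds, th))

        total, _ = quad(dens, lo, hi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestParamSpaceProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(-15.0, 15.0), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_link_round_trip_on_random_points(self, z):
        ps = ParamSpace(("a", "p", "m"), ("log", "logit", "identity"))
        z = np.asarray(z)
        th = ps.from_link(z)
        assert bool(ps.in_support(th))
        assert np.allclose(ps.to_link(th), z, atol=1e-8)

    @given(st.integers(1, 40), st.integers(1, 40))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_labelled_sample_counts_always_match(self, n1, n2):
        from ddprofile.ratio import build_labelled
        rng = np.random.default_rng(0)
        s = build_labelled(rng.normal(size=n1), rng.normal(size=n2))
        assert s.S1 == n1 and s.S2 == n2
        assert len(s.values) == n1 + n2


class TestParamSpace:
    def test_link_round_trip_and_jacobian(self):
        ps = ParamSpace(("a", "p", "m"), ("log", "logit", "identity"))
        th = np.array([2.5, 0.3, -1.2])
        z = ps.to_link(th)
        assert np.allclose(ps.from_link(z), th, rtol=1e-12)
        # numeric Jacobian check
        eps = 1e-6
        lj = 0.0
        for j in range(3):
            zp = z.copy()
            zp[j] += eps
            lj += np.log((ps.from_link(zp)[j] - th[j]) / eps)
        assert ps.log_jacobian(z) == pytest.approx(lj, abs=1e-4)

    def test_default_box_is_wide_and_inside_support(self):
        ps = ParamSpace(("a", "p"), ("log", "logit"))
        box = ps.default_box()
        assert box[0, 0] > 0 and box[0, 1] > 1e8
        assert 0 < box[1, 0] < 1e-8 and 1 - 1e-8 < box[1, 1] < 1

    def test_invalid_space_rejected(self):
        with pytest.raises(ValueError):
            ParamSpace(("a",), ("log", "log"))
        with pytest.raises(ValueError, match="empty support"):
            ParamSpace(("a",), ("identity",), bounds=((2.0, 1.0),))
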