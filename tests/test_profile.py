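"""Data-doubling profile pipelines on the conjugate normal-mean model.

The exact profile there is the log-likelihood itself, -n (psi - ybar)^2 / 2,
so both algorithms can be checked against a closed form cheaply.  The more
expensive hierarchical and beta-model comparisons live in the acceptance
suite.
"""
import numpy as np
import pytest

from ddprofile.cloning import fit_mle_dc
from ddprofile.curves import ProfileCurve, curve_summary
from ddprofile.models import builtin_psi, component_psi, lookup_model
from ddprofile.profile import (mle_by_componentwise_dd, profile_component_flat,
                               profile_function_normalprior)
from ddprofile.sampler import PriorSpec, SamplerConfig

from conftest import central_slice


def _truth_dev(curve, frac=0.9):
    sl = central_slice(len(curve.psi_grid), frac)
    g = curve.psi_grid[sl]
    t = -10 * (g - 0.3) ** 2 / 2
    t -= t.max()
    v = curve.logpl[sl]
    v -= v.max()
    return np.max(np.abs(v - t))


class TestAlgorithmsOnNormalMean:
    def test_flat_componentwise_matches_closed_form(self, normal_data,
                                                    big_cfg):
        c = profile_component_flat(lookup_model("normal_mean"), normal_data,
                                   "mu", bounds=np.array([[-20.0, 20.0]]),
                                   cfg=big_cfg)
        assert c.method == "algorithm1"
        assert _truth_dev(c) <= 0.2

    def test_normalprior_matches_closed_form(self, normal_data, big_cfg,
                                             fast_cfg):
        m = lookup_model("normal_mean")
        mle = fit_mle_dc(m, normal_data, (1, 2, 4, 8),
                         PriorSpec.flat_box([[-20, 20]]), fast_cfg)
        c = profile_function_normalprior(m, normal_data,
                                         component_psi(m, "mu"), mle,
                                         cfg=big_cfg.replace(seed=21))
        assert c.method == "algorithm2"
        assert _truth_dev(c) <= 0.2

    def test_unknown_component_rejected(self, normal_data, fast_cfg):
        with pytest.raises(KeyError, match="sigma"):
            profile_component_flat(lookup_model("normal_mean"), normal_data,
                                   "sigma", cfg=fast_cfg)

    def test_nan_psi_is_reported_with_draw(self, normal_data, fast_cfg):
        from ddprofile.models import PsiFunction
        m = lookup_model("normal_mean")
        mle = fit_mle_dc(m, normal_data, (1, 2), PriorSpec.flat_box([[-20, 20]]),
                         fast_cfg)
        bad = PsiFunction("bad", lambda th: np.full(th.shape[0], np.nan))
        with pytest.raises(ValueError, match="non-finite"):
            profile_function_normalprior(m, normal_data, bad, mle,
                                         cfg=fast_cfg)


class TestComponentwiseMLE:
    def test_normal_mean_recovers_ybar(self, normal_data, big_cfg):
        theta = mle_by_componentwise_dd(lookup_model("normal_mean"),
                                        normal_data,
                                        bounds=np.array([[-20.0, 20.0]]),
                                        cfg=big_cfg)
        assert theta.shape == (1,)
        assert abs(theta[0] - 0.3) < 0.05  # grid resolution + MC error

    def test_single_component_equals_profile_argmax(self, normal_data,
                                                    big_cfg):
        m = lookup_model("normal_mean")
        theta = mle_by_componentwise_dd(m, normal_data,
                                        bounds=np.array([[-20.0, 20.0]]),
                                        cfg=big_cfg)
        c = profile_component_flat(m, normal_data, "mu",
                                   bounds=np.array([[-20.0, 20.0]]),
                                   cfg=big_cfg)
        assert theta[0] == pytest.approx(c.psi_hat, abs=1e-12)


class TestAlgorithmAgreementRandomIntercept:
    def test_flat_and_normalprior_delta_profiles_agree(self):
        """Both doubling routes profile the common log-odds-ratio delta of
        the random-intercept trials model to the same curve."""
        from conftest import max_curve_dev
        from ddprofile.simulate import gen_rand_intercept_trials
        ds = gen_rand_intercept_trials(12, -0.25, -2.0, 25.0, 4.0, 200,
                                       seed=3)
        m = lookup_model("rand_intercept_binom")
        bounds = np.array([[-5.0, 5.0], [-8.0, 4.0], [0.1, 400.0],
                           [0.1, 400.0]])
        cfg = SamplerConfig(chains=48, draws=120, warmup=2000, thin=6,
                            seed=41)
        c1 = profile_component_flat(m, ds, "delta", bounds=bounds, cfg=cfg)
        mle = fit_mle_dc(m, ds, (1, 2, 4), PriorSpec.flat_box(bounds),
                         cfg.replace(seed=43))
        c2 = profile_function_normalprior(m, ds, builtin_psi("ri_delta"),
                                          mle, cfg=cfg.replace(seed=47))
        assert max_curve_dev(c1, c2, 0.9) <= 0.5


class TestCurveSummary:
    def test_peak_and_interval(self):
        c = ProfileCurve(np.array([0.0, 1.0, 2.0]), np.array([-2.0, 0.0, -2.0]))
        psi_hat, (lo, hi), boundary = curve_summary(c, 1.92)
        assert psi_hat == 1.0
        assert 0.0 < lo < 1.0 < hi < 2.0
        assert not boundary

    def test_monotone_curve_flags_boundary(self):
        c = ProfileCurve(np.linspace(0, 1, 11), np.linspace(-5, 0, 11))
        _, _, boundary = curve_summary(c)
        assert boundary

    def test_negative_drop_rejected(self):
        c = ProfileCurve(np.array([0.0, 1.0]), np.array([0.0, -1.0]))
        with pytest.raises(ValueError, match="positive"):
            curve_summary(c, -1.0)

    def test_unnormalized_curve_rejected(self):
        c = ProfileCurve(np.array([0.0, 1.0]), np.array([0.0, -1.0]))
        c.logpl = c.logpl - 3.0  # break the invariant after construction
        with pytest.raises(ValueError, match="normalized"):
            curve_summary(c)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            ProfileCurve(np.array([1.0, 0.0]), np.array([0.0, 0.0]))
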