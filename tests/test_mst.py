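"""Monomer-dimer MST model: closed-form alpha, curve model, joint density
and posterior recovery on synthetic dilution series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import brentq

from survbind import mst, synthetic
from survbind.sampling import SamplerConfig, run_ensemble


def alpha_bisection(c, kd):
    """Numeric root of the mass-action quadratic 2c(1-a)^2/a = Kd on (0, 1]."""
    if kd == 0:
        return 1.0
    f = lambda a: 2 * c * (1 - a) ** 2 / a - kd
    return brentq(f, 1e-15, 1.0, xtol=1e-15, rtol=8.9e-16)


class TestDegreeOfAssociation:
    def test_fully_dimeric_limit(self):
        for c in (1.0, 97.0, 1e6):
            assert mst.degree_of_association(c, 0.0) == pytest.approx(1.0)

    def test_half_association_at_c_equals_kd(self):
        assert mst.degree_of_association(123.4, 123.4) == pytest.approx(0.5, abs=1e-12)

    def test_matches_bisection_oracle(self, rng):
        c = 10 ** rng.uniform(0, 6, 200)
        kd = 10 ** rng.uniform(0, 6, 200)
        a = mst.degree_of_association(c, kd)
        for ci, ki, ai in zip(c, kd, a):
            assert ai == pytest.approx(alpha_bisection(ci, ki), rel=1e-9)

    def test_mass_action_relation(self, rng):
        c = 10 ** rng.uniform(0, 6, 10_000)
        kd = 10 ** rng.uniform(0, 6, 10_000)
        a = mst.degree_of_association(c, kd)
        assert np.all(np.abs(2 * c * (1 - a) ** 2 / a - kd) <= 1e-9 * kd)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(1, 1e6), st.floats(1, 1e6), st.floats(1.01, 3))
    def test_monotone_in_c_and_kd(self, c, kd, factor):
        a = mst.degree_of_association(c, kd)
        assert mst.degree_of_association(c * factor, kd) > a
        assert mst.degree_of_association(c, kd * factor) < a

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            mst.degree_of_association(0.0, 10.0)


class TestProgressMean:
    def test_preheating_constant_one(self):
        assert mst.progress_mean(-2.0, 0.01, 2.0, 0.4, 0.7, 0.3) == 1.0

    def test_continuous_at_laser_on(self, rng):
        for _ in range(20):
            args = (rng.uniform(-1, 1), rng.uniform(0.1, 5), rng.uniform(0.1, 5),
                    rng.uniform(0, 1), rng.uniform(0, 1))
            assert mst.progress_mean(0.0, *args) == pytest.approx(1.0, abs=1e-12)
            assert mst.progress_mean(-1e-9, *args) == 1.0

    def test_decays_to_final_level_without_drift(self):
        a_total = 0.3
        val = mst.progress_mean(1e4, 0.0, 1.0, 0.2, 0.6, a_total)
        assert val == pytest.approx(1.0 - a_total, abs=1e-12)


class TestMSTModel:
    def _toy_experiment(self):
        times = np.array([-5.0, -2.0, 0.5, 2.0, 10.0])
        y1 = np.array([1.0, 1.01, 0.9, 0.8, 0.75])
        y2 = np.array([0.99, 1.0, 0.85, 0.7, 0.6])
        return [
            mst.MSTCapillary(1, 100.0, times, y1),
            mst.MSTCapillary(2, 10_000.0, times, y2),
        ]

    def test_log_density_matches_term_by_term_oracle(self):
        """Independent summation with scipy.stats frozen distributions."""
        caps = self._toy_experiment()
        model = mst.build_mst_model(caps)
        theta = np.array([500.0, 0.2, 0.6, 0.02,
                          0.7, 0.4,      # R per capillary
                          0.01, -0.005,  # nu0
                          1.2, 0.8,      # nu1
                          0.3, 0.2])     # nu2
        kd, u, b, eps = theta[:4]
        r, nu0, nu1, nu2 = theta[4:6], theta[6:8], theta[8:10], theta[10:12]
        expected = (
            stats.uniform(1, 1e6 - 1).logpdf(kd)
            + stats.beta(1, 1).logpdf(u)
            + stats.beta(1, 1).logpdf(b)
            + stats.lognorm(s=1).logpdf(eps)
        )
        for j, cap in enumerate(caps):
            expected += stats.beta(2, 1).logpdf(r[j])
            expected += stats.uniform(-1, 2).logpdf(nu0[j])
            expected += stats.lognorm(s=1).logpdf(nu1[j])
            expected += stats.lognorm(s=1).logpdf(nu2[j])
            alpha = mst.degree_of_association(cap.c_total, kd)
            a_total = u + (b - u) * alpha
            for t, yobs in zip(cap.times, cap.fluorescence):
                mu = mst.progress_mean(t, nu0[j], nu1[j], nu2[j], r[j], a_total)
                expected += stats.norm(mu, eps).logpdf(yobs)
        assert model.log_density(theta) == pytest.approx(expected, rel=1e-10)

    def test_out_of_support_density_is_minus_inf(self):
        model = mst.build_mst_model(self._toy_experiment())
        theta = model.initial_point()
        theta[1] = 1.2  # U outside [0, 1]
        assert model.log_density(theta) == -np.inf

    def test_duplicating_capillaries_doubles_data_loglike(self):
        caps = self._toy_experiment()
        m1 = mst.build_mst_model(caps)
        m2 = mst.build_mst_model(
            caps
            + [
                mst.MSTCapillary(3, caps[0].c_total, caps[0].times, caps[0].fluorescence),
                mst.MSTCapillary(4, caps[1].c_total, caps[1].times, caps[1].fluorescence),
            ]
        )
        theta1 = np.array([500.0, 0.2, 0.6, 0.02, 0.7, 0.4, 0.01, -0.005,
                           1.2, 0.8, 0.3, 0.2])
        theta2 = np.concatenate([
            theta1[:4],
            np.tile(theta1[4:6], 2), np.tile(theta1[6:8], 2),
            np.tile(theta1[8:10], 2), np.tile(theta1[10:12], 2),
        ])
        ll1 = m1.log_likelihood(theta1[None, :])[0]
        ll2 = m2.log_likelihood(theta2[None, :])[0]
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_capillary_without_postheating_rejected(self):
        times = np.array([-5.0, -3.0, -1.0])
        y = np.ones(3)
        caps = [
            mst.MSTCapillary(1, 100.0, times, y),
            mst.MSTCapillary(2, 1000.0, np.array([-5.0, 1.0, 2.0]), np.ones(3)),
        ]
        with pytest.raises(ValueError, match="post-heating"):
            mst.build_mst_model(caps)

    def test_single_capillary_rejected(self):
        c = self._toy_experiment()[0]
        with pytest.raises(ValueError):
            mst.build_mst_model([c])


@pytest.fixture(scope="module")
def mst_posterior():
    """One shared recovery fit (truth Kd = 2000 nM, default design)."""
    import warnings

    caps, gt = synthetic.gen_mst(seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = mst.fit_mst(caps, SamplerConfig(steps=600, burn=1500, seed=3))
    return post, gt


class TestFitMST:
    def test_posterior_mean_within_30_percent(self, mst_posterior):
        post, gt = mst_posterior
        kd_true = gt.params["Kd"]
        assert abs(post.mean("Kd") - kd_true) / kd_true < 0.30

    def test_convergence_diagnostics_reported(self, mst_posterior):
        post, _ = mst_posterior
        for p in ("Kd", "U", "B", "epsilon"):
            assert np.isfinite(post.rhat[p])
        assert post.rhat["Kd"] < 1.05

    def test_posterior_predictive_tracks_truth(self, mst_posterior):
        post, gt = mst_posterior
        tr = synthetic.MSTParameters(**gt.params)
        caps0, _ = synthetic.gen_mst(
            truth=synthetic.MSTParameters(**{**gt.params, "epsilon": 0.0}), seed=0
        )
        model = mst.build_mst_model(caps0)
        theta = np.array([post.mean(p) for p in model.param_names])[None, :]
        rms = np.sqrt(np.mean((model._means(theta)[0] - model.y) ** 2))
        assert rms < 3 * tr.epsilon

    def test_seed_reproducible(self):
        import warnings

        caps, _ = synthetic.gen_mst(
            concentrations=np.array([200.0, 2000.0, 20000.0]), seed=1
        )
        cfg = SamplerConfig(steps=50, burn=50, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = mst.fit_mst(caps, cfg).draws
            d2 = mst.fit_mst(caps, cfg).draws
        assert d1.equals(d2)

    def test_prior_only_sampling_recovers_flat_beta_mean(self):
        caps, _ = synthetic.gen_mst(
            concentrations=np.array([100.0, 1000.0]), dt=2.0, seed=0
        )
        model = mst.build_mst_model(caps)
        post = run_ensemble(
            model, SamplerConfig(steps=1500, burn=1500, seed=8, prior_only=True)
        )
        assert post.mean("U") == pytest.approx(0.5, abs=0.05)
        assert post.mean("B") == pytest.approx(0.5, abs=0.05)


class TestSummarizeKd:
    def test_degenerate_posterior_zero_width(self):
        import pandas as pd

        from survbind.sampling import PosteriorSamples

        df = pd.DataFrame({"chain": [0, 0, 1, 1], "draw": [0, 1, 0, 1],
                           "Kd": [1500.0] * 4})
        post = PosteriorSamples(draws=df, rhat={"Kd": 1.0})
        s = mst.summarize_kd(post)
        assert s["mean"] == 1500.0
        assert s["ci95"] == (1500.0, 1500.0)

    def test_unit_rescaling(self, mst_posterior):
        post, _ = mst_posterior
        nm = mst.summarize_kd(post, unit="nM")
        um = mst.summarize_kd(post, unit="uM")
        assert um["mean"] == pytest.approx(nm["mean"] * 1e-3)

    def test_empty_posterior_rejected(self):
        import pandas as pd

        from survbind.sampling import PosteriorSamples

        post = PosteriorSamples(draws=pd.DataFrame(), rhat={})
        with pytest.raises(ValueError):
            mst.summarize_kd(post)
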