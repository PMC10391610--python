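"""1:1 Langmuir BLI model: phase means, empirical-Bayes delta0 prior, joint
density oracle and posterior recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survbind import bli, synthetic
from survbind.sampling import PosteriorSamples, SamplerConfig, run_ensemble


class TestPhaseMeans:
    def test_association_zero_at_start(self):
        assert bli.association_mean(0.0, 1e-8, 1e-8, 1e5, 1e-3, 1.0) == 0.0

    def test_association_half_saturation_plateau(self):
        val = bli.association_mean(1e9, 1e-8, 1e-8, 1e5, 1e-3, 1.0)
        assert val == pytest.approx(0.5, rel=1e-9)

    def test_association_time_constant(self):
        c, kd, kon, koff, a = 2e-8, 1e-8, 1e5, 1e-3, 1.0
        tau = 1.0 / (kon * c + koff)
        plateau = a * c / (kd + c)
        assert bli.association_mean(tau, c, kd, kon, koff, a) == pytest.approx(
            plateau * (1 - np.exp(-1)), rel=1e-12
        )

    def test_association_monotone_and_bounded(self):
        t = np.linspace(0, 5000, 500)
        c, kd, kon, koff, a = 3.3e-8, 1e-8, 1e5, 1e-3, 1.0
        y = bli.association_mean(t, c, kd, kon, koff, a)
        assert np.all(np.diff(y) > 0)
        assert np.all(y <= a * c / (kd + c) + 1e-12)

    def test_dissociation_start_and_half_life(self):
        koff = 2e-3
        assert bli.dissociation_mean(0.0, 0.8, koff) == 0.8
        assert bli.dissociation_mean(np.log(2) / koff, 0.8, koff) == pytest.approx(0.4)

    def test_dissociation_zero_rate_limit(self):
        t = np.linspace(0, 100, 11)
        assert np.allclose(bli.dissociation_mean(t, 0.6, 1e-15), 0.6)


def _trace(y_dissoc_head, conc=1e-8):
    t_a = np.arange(0.0, 10.0)
    y_a = np.linspace(0, 0.5, 10)
    n = len(y_dissoc_head)
    t_d = np.concatenate([np.linspace(0, 1, n), [5.0, 10.0]])
    y_d = np.concatenate([y_dissoc_head, [0.3, 0.2]])
    return bli.BLITrace("t", conc, t_a, y_a, t_d, y_d)


class TestDelta0Prior:
    def test_two_point_window(self):
        prior = bli.delta0_prior_params(_trace([0.4, 0.6]))
        assert prior.mu == pytest.approx(0.5)
        assert prior.sigma == pytest.approx(0.01)  # population SD 0.1, over 10

    def test_four_point_window(self):
        prior = bli.delta0_prior_params(_trace([1.0, 1.0, 1.0, 3.0]))
        assert prior.mu == pytest.approx(1.5)
        assert prior.sigma == pytest.approx(np.sqrt(0.75) / 10.0)

    def test_constant_window_floored(self):
        prior = bli.delta0_prior_params(_trace([0.5, 0.5, 0.5]))
        assert prior.mu == pytest.approx(0.5)
        assert prior.sigma == pytest.approx(0.5e-3)  # 1e-3 of mu

    def test_insufficient_window_rejected(self):
        tr = bli.BLITrace(
            "t", 1e-8, np.arange(3.0), np.zeros(3),
            np.array([0.5, 5.0, 10.0]), np.array([0.5, 0.3, 0.2]),
        )
        with pytest.raises(ValueError, match="dissociation samples"):
            bli.delta0_prior_params(tr)


class TestBLIModel:
    def _toy_traces(self):
        t = np.array([0.0, 1.0, 2.0, 5.0, 10.0])
        return [
            bli.BLITrace("a", 1e-8, t, np.array([0.0, 0.1, 0.18, 0.3, 0.4]),
                         t, np.array([0.42, 0.41, 0.40, 0.35, 0.30])),
            bli.BLITrace("b", 3e-8, t, np.array([0.0, 0.2, 0.3, 0.5, 0.6]),
                         t, np.array([0.62, 0.60, 0.59, 0.50, 0.45])),
        ]

    def test_log_density_matches_term_by_term_oracle(self):
        traces = self._toy_traces()
        model = bli.build_bli_model(traces)
        theta = np.array([2e-8, 5e-3, 1.2, 0.03, 0.40, 0.58])
        kd, koff, a, eps = theta[:4]
        kon = koff / kd
        expected = (
            stats.uniform(1e-15, 1e-3 - 1e-15).logpdf(kd)
            + stats.uniform(1e-20, 10 - 1e-20).logpdf(koff)
            + stats.uniform(1e-6, 10 - 1e-6).logpdf(a)
            + stats.uniform(1e-6, 1 - 1e-6).logpdf(eps)
        )
        for j, tr in enumerate(traces):
            pr = bli.delta0_prior_params(tr)
            lo = (pr.lower - pr.mu) / pr.sigma
            expected += stats.truncnorm(lo, np.inf, pr.mu, pr.sigma).logpdf(
                theta[4 + j]
            )
            for t, y in zip(tr.t_assoc, tr.y_assoc):
                mu = bli.association_mean(t, tr.conc, kd, kon, koff, a)
                expected += stats.norm(mu, eps).logpdf(y)
            for t, y in zip(tr.t_dissoc, tr.y_dissoc):
                mu = bli.dissociation_mean(t, theta[4 + j], koff)
                expected += stats.norm(mu, eps).logpdf(y)
        assert model.log_density(theta) == pytest.approx(expected, rel=1e-9)

    def test_out_of_support_rejected(self):
        model = bli.build_bli_model(self._toy_traces())
        theta = np.array([2e-8, 5e-3, 1.2, 1.5, 0.4, 0.58])  # eps > 1
        assert model.log_density(theta) == -np.inf

    def test_trace_missing_phase_rejected(self):
        t = np.arange(5.0)
        tr = bli.BLITrace("x", 1e-8, t, np.zeros(5), np.array([]), np.array([]))
        with pytest.raises(ValueError, match="both phases"):
            bli.build_bli_model([tr])


@pytest.fixture(scope="module")
def bli_posterior():
    """Shared recovery fit at the 4-concentration study design."""
    import warnings

    traces, gt = synthetic.gen_bli(seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = bli.fit_bli(traces, SamplerConfig(steps=500, burn=1000, seed=5))
    return post, gt


class TestFitBLI:
    def test_recovery_within_25_percent(self, bli_posterior):
        post, gt = bli_posterior
        assert abs(post.mean("KD_app") - gt.params["KD_app"]) / gt.params["KD_app"] < 0.25
        assert abs(post.mean("k_off") - gt.params["k_off"]) / gt.params["k_off"] < 0.25

    def test_truth_inside_95_interval(self, bli_posterior):
        post, gt = bli_posterior
        lo, hi = post.interval("KD_app", 0.95)
        assert lo <= gt.params["KD_app"] <= hi

    def test_prior_only_kd_mean_near_uniform_mean(self):
        traces, _ = synthetic.gen_bli(
            concs_nM=(11.1, 100.0), assoc_span=30, dissoc_span=60,
            rate_hz=2.0, seed=0,
        )
        model = bli.build_bli_model(traces)
        post = run_ensemble(
            model, SamplerConfig(steps=2000, burn=2000, seed=2, prior_only=True)
        )
        prior_mean = (1e-3 + 1e-15) / 2
        assert post.mean("KD_app") == pytest.approx(prior_mean, rel=0.10)

    def test_seed_reproducible(self):
        import warnings

        traces, _ = synthetic.gen_bli(
            assoc_span=60, dissoc_span=120, rate_hz=2.0, seed=1
        )
        cfg = SamplerConfig(steps=50, burn=50, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert bli.fit_bli(traces, cfg).draws.equals(bli.fit_bli(traces, cfg).draws)


class TestSummarizeBLI:
    def test_kon_is_derived_ratio(self, bli_posterior):
        post, _ = bli_posterior
        s = bli.summarize_bli(post)
        ratio = post.values("k_off") / post.values("KD_app")
        assert s["k_on"]["mean"] == pytest.approx(float(ratio.mean()))

    def test_unit_conversion(self, bli_posterior):
        post, _ = bli_posterior
        s_m = bli.summarize_bli(post, conc_unit="M")
        s_nm = bli.summarize_bli(post, conc_unit="nM")
        assert s_nm["KD_app"]["mean"] == pytest.approx(s_m["KD_app"]["mean"] * 1e9)
        assert s_nm["k_off_per_s"]["mean"] == s_m["k_off_per_s"]["mean"]
        assert s_nm["k_on"]["mean"] == pytest.approx(s_m["k_on"]["mean"] * 1e-9)

    def test_degenerate_draws_zero_width(self):
        df = pd.DataFrame(
            {"chain": [0, 0], "draw": [0, 1], "KD_app": [1e-8] * 2,
             "k_off": [1e-3] * 2, "A": [1.0] * 2, "epsilon": [0.01] * 2}
        )
        s = bli.summarize_bli(PosteriorSamples(draws=df, rhat={}))
        assert s["KD_app"]["ci95"] == (1e-8, 1e-8)
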