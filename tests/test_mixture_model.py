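import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipbit2 import mixture_model as mm
from chipbit2.mixture_model import MixtureParams
from chipbit2.synthetic_data import simulate_windows
from chipbit2.windowing import Window

from oracles import plain_posterior


def params(**kwargs):
    defaults = dict(mu1=8.0, sigma1_sq=4.0, sigma0_sq=1.0, lambda_=1e-3)
    defaults.update(kwargs)
    return MixtureParams(**defaults)


def make_window(s, r, d=None):
    return Window(0, 0, "chr1", 0, 50, s=s, r=r, d=d)


class TestSignalLikelihood:
    def test_density_at_bound_mode(self):
        p = params(sigma1_sq=4.0)
        assert mm.signal_likelihood(8.0, 1.0, 1, p) == pytest.approx(
            1.0 / math.sqrt(2 * math.pi * 4.0)
        )

    def test_density_at_background_mode(self):
        p = params(sigma0_sq=2.5)
        assert mm.signal_likelihood(3.0, 3.0, 0, p) == pytest.approx(
            1.0 / math.sqrt(2 * math.pi * 2.5)
        )

    def test_enrichment_likelihood_ratio(self):
        # s four background-sds above r and exactly at the bound mean
        p = params(mu1=5.0, sigma1_sq=1.0, sigma0_sq=1.0)
        ratio = mm.signal_likelihood(5.0, 1.0, 1, p) / mm.signal_likelihood(
            5.0, 1.0, 0, p
        )
        assert ratio == pytest.approx(math.exp(8.0))


class TestDistanceLikelihood:
    def test_exponential_density_at_tss(self):
        p = params(lambda_=1e-3)
        assert mm.distance_likelihood(0, 1, "promoter", p) == pytest.approx(1e-3)

    def test_exponential_decay_ratio(self):
        p = params(lambda_=1e-3)
        ratio = mm.distance_likelihood(1000, 1, "promoter", p) / mm.distance_likelihood(
            0, 1, "promoter", p
        )
        assert ratio == pytest.approx(math.exp(-1.0))

    def test_background_is_uniform_over_promoter(self):
        p = params(d_P=20_000.0)
        assert mm.distance_likelihood(-7_000, 0, "promoter", p) == pytest.approx(
            1.0 / 20_000.0
        )

    def test_enhancer_components_are_identical(self):
        p = params(d_E=2_000.0)
        for d in (-900, 0, 333):
            assert mm.distance_likelihood(d, 1, "enhancer", p) == mm.distance_likelihood(
                d, 0, "enhancer", p
            )

    def test_wg_mode_drops_distance_term(self):
        p = params()
        assert mm.distance_likelihood(None, 1, "wg", p) == 1.0
        assert mm.distance_likelihood(None, 0, "wg", p) == 1.0

    def test_out_of_range_distance_is_contract_violation(self):
        p = params(d_P=20_000.0)
        with pytest.raises(ValueError, match="d_P"):
            mm.distance_likelihood(10_001, 1, "promoter", p)


class TestPosterior:
    def test_symmetric_likelihoods_give_half(self):
        p = params(mu1=5.0, sigma1_sq=1.0, sigma0_sq=1.0)
        # s equidistant between mu1 and r: both densities equal
        assert mm.posterior(make_window(s=4.0, r=3.0), p, "wg") == pytest.approx(0.5)

    def test_strong_enrichment_saturates(self):
        p = params(mu1=10.0, sigma1_sq=2.0, sigma0_sq=1.0)
        assert mm.posterior(make_window(s=60.0, r=1.0), p, "wg") > 0.999

    @pytest.mark.parametrize("mode", ["promoter", "enhancer", "wg"])
    def test_matches_plain_arithmetic_oracle(self, mode):
        """Log-space posterior equals the direct Bayes computation to 1e-12."""
        rng = np.random.default_rng(2024)
        p_base = dict(d_P=20_000.0, d_E=2_000.0)
        for _ in range(1_000):
            p = MixtureParams(
                mu1=rng.uniform(1, 15),
                sigma1_sq=rng.uniform(0.5, 9),
                sigma0_sq=rng.uniform(0.5, 9),
                lambda_=rng.uniform(1e-4, 1e-2),
                **p_base,
            )
            s = rng.uniform(0, 20)
            r = rng.uniform(0, 10)
            if mode == "promoter":
                d = int(rng.uniform(-10_000, 10_000))
            elif mode == "enhancer":
                d = int(rng.uniform(-1_000, 1_000))
            else:
                d = None
            expected = plain_posterior(
                s, r, d, mode, p.mu1, p.sigma1_sq, p.sigma0_sq, p.lambda_, p.d_P, p.d_E
            )
            got = mm.posterior(make_window(s=s, r=r, d=d), p, mode)
            assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("mode", ["enhancer", "wg"])
    def test_distance_perturbation_cancels(self, mode):
        """Outside promoter mode the posterior is a function of (s, r) only."""
        p = params()
        rng = np.random.default_rng(5)
        for _ in range(50):
            s, r = rng.uniform(0, 12), rng.uniform(0, 6)
            d_values = [None, 0, -777, 999] if mode == "wg" else [0, -777, 999]
            posts = {
                mm.posterior(make_window(s=s, r=r, d=d), p, mode) for d in d_values
            }
            assert len(posts) == 1  # bit-identical

    @given(st.floats(min_value=0.0, max_value=30.0), st.floats(min_value=0.01, max_value=5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_s_when_variances_match(self, s, delta):
        """With sigma1 = sigma0 and mu1 > r the posterior never decreases in s."""
        p = params(mu1=10.0, sigma1_sq=2.0, sigma0_sq=2.0)
        low = mm.posterior(make_window(s=s, r=1.0), p, "wg")
        high = mm.posterior(make_window(s=s + delta, r=1.0), p, "wg")
        assert high >= low - 1e-15


class TestEstimateSigma0:
    def test_two_point_sample_variance(self):
        assert mm.estimate_sigma0([1.0, 3.0]) == pytest.approx(2.0)

    def test_constant_input_hits_floor(self):
        assert mm.estimate_sigma0([2.0] * 50) == pytest.approx(1e-6)

    def test_matches_two_pass_textbook_variance(self):
        rng = np.random.default_rng(8)
        r = rng.gamma(5, 1, size=200).tolist()
        mean = sum(r) / len(r)
        expected = sum((x - mean) ** 2 for x in r) / (len(r) - 1)
        assert mm.estimate_sigma0(r) == pytest.approx(expected)

    def test_needs_two_windows(self):
        with pytest.raises(ValueError):
            mm.estimate_sigma0([1.0])


class TestInitParams:
    def test_degenerate_input_takes_fallback(self):
        windows = [make_window(s=1.0, r=2.0 + i * 0.01) for i in range(20)]
        p = mm.init_params(windows, "wg", sigma0_sq=1.0)
        assert math.isfinite(p.mu1) and p.sigma1_sq > 0

    def test_enriched_windows_push_mu1_up(self):
        rng = np.random.default_rng(1)
        windows = [make_window(s=float(rng.normal(2, 0.3)), r=2.0) for _ in range(90)]
        windows += [make_window(s=float(rng.normal(9, 1)), r=2.0) for _ in range(10)]
        p = mm.init_params(windows, "wg", sigma0_sq=0.09)
        assert p.mu1 > 2.0


class TestEmFit:
    def test_separable_clusters_converge_fast(self):
        rng = np.random.default_rng(9)
        windows = [
            make_window(s=float(rng.normal(20, 0.5)), r=1.0) for _ in range(30)
        ] + [make_window(s=float(rng.normal(1, 0.5)), r=1.0) for _ in range(270)]
        truth = [1] * 30 + [0] * 270
        p0 = MixtureParams(mu1=20.0, sigma1_sq=0.25, sigma0_sq=0.25)
        fitted, trace, out = mm.em_fit(windows, "wg", params0=p0)
        assert trace.converged
        assert trace.n_iterations <= 2
        assert [w.b for w in out] == truth

    def test_recovers_generating_parameters(self):
        """EM on model-drawn promoter windows recovers mu1 and lambda."""
        windows, labels = simulate_windows(seed=123)
        fitted, trace, out = mm.em_fit(windows, "promoter")
        assert trace.converged
        assert trace.iterations[-1].max_rel_change < 0.05
        assert abs(fitted.mu1 - 8.0) / 8.0 < 0.10
        assert abs(fitted.lambda_ - 5e-4) / 5e-4 < 0.20
        # posterior labels should track the generating labels closely
        agree = np.mean([w.b == lab for w, lab in zip(out, labels)])
        assert agree > 0.95

    def test_convergence_flag_honors_tolerance(self):
        windows, _ = simulate_windows(n_windows=2_000, seed=77)
        _, trace, _ = mm.em_fit(windows, "promoter", tol=0.05)
        if trace.converged:
            assert trace.iterations[-1].max_rel_change < 0.05

    def test_initial_bound_set_recalls_planted_windows(self):
        windows, labels = simulate_windows(seed=5)
        p0 = mm.init_params(windows, "promoter")
        s = np.array([w.s for w in windows])
        r = np.array([w.r for w in windows])
        seed_set = s > r + math.sqrt(p0.sigma0_sq)
        recall = seed_set[labels == 1].mean()
        assert recall >= 0.5

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            mm.em_fit([make_window(1.0, 1.0)] * 5, "wg")
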