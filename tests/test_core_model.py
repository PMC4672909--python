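"""Unit and property tests for the causal-inference observer core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avcausal.core_model import (
    LikelihoodSpec,
    ObserverParams,
    PriorSpec,
    SensorySample,
    StimulusCondition,
    conditional_estimate,
    decide_and_estimate,
    effective_likelihood,
    evidence_common,
    evidence_independent,
    fused_estimate,
    posterior_common_cause,
    predict_response_distribution,
    product_prior,
    sample_sensory,
)

from oracles import fused_quadrature, single_cue_quadrature

FLAT = PriorSpec(kind="flat", support_halfwidth=45.0)


class TestEffectiveLikelihood:
    @pytest.mark.parametrize(
        "s, spec, mu, sigma",
        [
            (13.0, LikelihoodSpec(2.0, -0.1, 0.0), 11.7, 2.0),
            (0.0, LikelihoodSpec(9.0, 0.37, 1.0), 0.0, 9.0),
            (-13.0, LikelihoodSpec(2.0, 0.08, 0.5), -14.04, 3.0),
        ],
    )
    def test_gain_bias_and_eccentric_sd(self, s, spec, mu, sigma):
        got_mu, got_sigma = effective_likelihood(s, spec)
        assert got_mu == pytest.approx(mu)
        assert got_sigma == pytest.approx(sigma)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            LikelihoodSpec(sigma0=-1.0)
        with pytest.raises(ValueError):
            LikelihoodSpec(sigma0=1.0, delta_sigma=-0.1)


class TestSampling:
    def test_sample_moments_match_effective_likelihood(self, rng):
        vis = LikelihoodSpec(2.0, -0.1, 0.0)
        cond = StimulusCondition(s_V=13.0)
        xs = np.array(
            [sample_sensory(cond, vis, LikelihoodSpec(8.0), rng).x_V for _ in range(20000)]
        )
        se_mean = 2.0 / math.sqrt(len(xs))
        assert abs(xs.mean() - 11.7) < 3 * se_mean
        se_sd = 2.0 / math.sqrt(2 * (len(xs) - 1))
        assert abs(xs.std(ddof=1) - 2.0) < 3 * se_sd

    def test_absent_modality_stays_absent(self, rng):
        s = sample_sensory(StimulusCondition(s_V=0.0), LikelihoodSpec(2.0), LikelihoodSpec(8.0), rng)
        assert s.x_A is None and s.x_V is not None


class TestConditionalEstimate:
    def test_equal_precision_gaussian_prior_splits_the_difference(self):
        prior = PriorSpec(kind="gaussian", mean=0.0, sigma=2.0)
        assert conditional_estimate(4.0, 2.0, prior) == pytest.approx(2.0)

    def test_flat_prior_returns_measurement(self):
        assert conditional_estimate(4.0, 2.0, FLAT) == pytest.approx(4.0, abs=1e-9)

    def test_mirrored_pair_symmetry_forces_zero(self):
        prior = PriorSpec(kind="mirrored_pair", mean=10.0, sigma=5.0)
        assert conditional_estimate(0.0, 3.0, prior) == pytest.approx(0.0, abs=1e-12)

    def test_mirrored_pair_matches_quadrature(self):
        prior = PriorSpec(kind="mirrored_pair", mean=10.0, sigma=5.0)
        expected, _ = single_cue_quadrature(6.0, 3.0, prior)
        assert conditional_estimate(6.0, 3.0, prior) == pytest.approx(expected, rel=1e-6)


class TestFusedEstimate:
    def test_flat_prior_precision_weighted_average(self):
        # (2/1 + 10/9) / (1/1 + 1/9) = 2.8
        x = SensorySample(x_A=10.0, x_V=2.0)
        assert fused_estimate(x, 1.0, 3.0, [FLAT]) == pytest.approx(2.8, rel=1e-9)

    def test_gaussian_prior_acts_as_third_cue(self):
        prior = PriorSpec(kind="gaussian", mean=5.0, sigma=1.0)
        x = SensorySample(x_A=0.0, x_V=0.0)
        assert fused_estimate(x, 1.0, 1.0, [prior]) == pytest.approx(5.0 / 3.0, rel=1e-9)

    def test_symmetric_inputs_give_zero(self):
        prior = PriorSpec(kind="mirrored_pair", mean=8.0, sigma=4.0)
        x = SensorySample(x_A=0.0, x_V=0.0)
        assert fused_estimate(x, 2.0, 6.0, [prior]) == pytest.approx(0.0, abs=1e-12)

    def test_missing_modality_rejected(self):
        with pytest.raises(ValueError):
            fused_estimate(SensorySample(x_V=1.0), 1.0, 1.0, [FLAT])


class TestEvidences:
    def test_common_cause_flat_prior_closed_form(self):
        x = SensorySample(x_A=0.0, x_V=0.0)
        expected = (1.0 / 90.0) * 1.0 / (2.0 * math.sqrt(math.pi))
        assert evidence_common(x, 1.0, 1.0, [FLAT]) == pytest.approx(expected, rel=1e-9)

    def test_independent_flat_prior_is_inverse_support_squared(self):
        x = SensorySample(x_A=3.0, x_V=-5.0)
        assert evidence_independent(x, 1.0, 1.0, FLAT, FLAT) == pytest.approx(
            (1.0 / 90.0) ** 2, rel=1e-6
        )

    def test_mirror_symmetry_of_independent_evidence(self):
        prior = PriorSpec(kind="mirrored_pair", mean=10.0, sigma=5.0)
        a = evidence_independent(SensorySample(x_A=7.0, x_V=-2.0), 2.0, 6.0, prior, FLAT)
        b = evidence_independent(SensorySample(x_A=-7.0, x_V=2.0), 2.0, 6.0, prior, FLAT)
        assert a == pytest.approx(b, rel=1e-12)

    def test_broader_likelihoods_dilute_common_evidence(self):
        x = SensorySample(x_A=0.0, x_V=0.0)
        assert evidence_common(x, 10.0, 10.0, [FLAT]) < evidence_common(x, 1.0, 1.0, [FLAT])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        x_A=st.floats(-20, 20),
        x_V=st.floats(-20, 20),
        sigma_A=st.floats(2.0, 12.0),
        sigma_V=st.floats(0.5, 5.0),
        kind=st.sampled_from(["flat", "gaussian", "mirrored_pair"]),
        pmean=st.floats(0.0, 12.0),
        psigma=st.floats(2.0, 20.0),
    )
    def test_evidences_match_quadrature(self, x_A, x_V, sigma_A, sigma_V, kind, pmean, psigma):
        prior = (
            FLAT
            if kind == "flat"
            else PriorSpec(kind=kind, mean=pmean, sigma=psigma)
        )
        x = SensorySample(x_A=x_A, x_V=x_V)
        _, ev1 = fused_quadrature(x_A, x_V, sigma_A, sigma_V, prior)
        assert evidence_common(x, sigma_V, sigma_A, [prior]) == pytest.approx(ev1, rel=1e-6)
        _, evA = single_cue_quadrature(x_A, sigma_A, prior)
        _, evV = single_cue_quadrature(x_V, sigma_V, prior)
        assert evidence_independent(x, sigma_V, sigma_A, prior, prior) == pytest.approx(
            evA * evV, rel=1e-6
        )


class TestCausalPosterior:
    def test_degenerate_binding_priors(self):
        x = SensorySample(x_A=5.0, x_V=-5.0)
        p1 = ObserverParams(p_common=1.0, sigma_V=2.0, sigma_A=8.0)
        p0 = ObserverParams(p_common=0.0, sigma_V=2.0, sigma_A=8.0)
        assert posterior_common_cause(x, p1).p_common == 1.0
        assert posterior_common_cause(x, p0).p_common == 0.0

    def test_coincident_cues_strongly_favor_common_cause(self):
        x = SensorySample(x_A=0.0, x_V=0.0)
        op = ObserverParams(p_common=0.5, sigma_V=1.0, sigma_A=1.0)
        post = posterior_common_cause(x, op)
        assert post.p_common == pytest.approx(0.9621, abs=2e-4)
        assert post.p_common + post.p_independent == pytest.approx(1.0, abs=0.0)

    def test_posterior_decreases_with_cue_conflict(self):
        op = ObserverParams(p_common=0.5, sigma_V=2.0, sigma_A=6.0)
        mid = 4.0
        probs = [
            posterior_common_cause(
                SensorySample(x_A=mid + d / 2.0, x_V=mid - d / 2.0), op
            ).p_common
            for d in (0.0, 2.0, 5.0, 10.0, 20.0)
        ]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        d=st.floats(0.0, 25.0),
        total=st.floats(-20.0, 20.0),
        sigma_P=st.floats(5.0, 30.0),
    )
    def test_conflict_monotonicity_with_central_gaussian_prior(self, d, total, sigma_P):
        op = ObserverParams(p_common=0.6, sigma_V=2.0, sigma_A=7.0, sigma_P=sigma_P)
        narrower = posterior_common_cause(
            SensorySample(x_A=total / 2 + d / 2, x_V=total / 2 - d / 2), op
        ).p_common
        wider = posterior_common_cause(
            SensorySample(x_A=total / 2 + d / 2 + 2.0, x_V=total / 2 - d / 2 - 2.0), op
        ).p_common
        assert wider <= narrower + 1e-12


class _ForcedXi:
    """Stub random source returning a fixed uniform draw."""

    def __init__(self, value):
        self.value = value

    def uniform(self):
        return self.value


class TestDecideAndEstimate:
    def setup_method(self):
        self.op = ObserverParams(p_common=0.5, sigma_V=2.0, sigma_A=6.0)

    def test_xi_one_always_segregates(self):
        est = decide_and_estimate(SensorySample(x_A=0.0, x_V=0.0), self.op, _ForcedXi(1.0))
        assert not est.inferred_common

    def test_xi_zero_always_fuses(self):
        est = decide_and_estimate(SensorySample(x_A=6.0, x_V=1.0), self.op, _ForcedXi(0.0))
        assert est.inferred_common
        assert est.s_hat_A == est.s_hat_V

    def test_unisensory_bypasses_causal_inference(self, rng):
        est = decide_and_estimate(SensorySample(x_A=4.0), self.op, rng)
        assert est.s_hat_V is None and est.s_hat_A is not None

    def test_probability_matching_fraction(self, rng):
        x = SensorySample(x_A=6.0, x_V=1.0)
        p = posterior_common_cause(x, self.op).p_common
        n = 20000
        fused = sum(decide_and_estimate(x, self.op, rng).inferred_common for _ in range(n))
        se = math.sqrt(p * (1 - p) / n)
        assert abs(fused / n - p) < 3 * se


class TestPredictResponseDistribution:
    def test_probabilities_normalized(self, m8_params, rng):
        dist = predict_response_distribution(
            StimulusCondition(s_A=6.5, s_V=-6.5), m8_params, n_sim=2000, rng=rng
        )
        assert dist.probs.shape == (90, 90)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unbiased_unisensory_mean_is_near_truth(self, rng):
        op = ObserverParams(p_common=0.5, sigma_V=2.0, sigma_A=8.0)
        dist = predict_response_distribution(
            StimulusCondition(s_V=6.5), op, n_sim=40000, rng=rng
        )
        _, mean_v = dist.mean()
        assert abs(mean_v - 6.5) < 3 * 2.0 / math.sqrt(40000) + 0.3  # binning coarseness

    def test_compressive_gain_shifts_the_mean(self, rng):
        op = ObserverParams(p_common=0.5, sigma_V=2.0, sigma_A=8.0, dx_V=-0.1)
        dist = predict_response_distribution(
            StimulusCondition(s_V=13.0), op, n_sim=40000, rng=rng
        )
        _, mean_v = dist.mean()
        assert abs(mean_v - 11.7) < 3 * 2.0 / math.sqrt(40000) + 0.3

    def test_fusion_improves_precision_when_binding_is_certain(self):
        op = ObserverParams(p_common=1.0, sigma_V=2.0, sigma_A=8.0)
        rngs = [np.random.default_rng(5) for _ in range(3)]
        uni_v = predict_response_distribution(StimulusCondition(s_V=0.0), op, 20000, rngs[0], smoothing=0.0)
        uni_a = predict_response_distribution(StimulusCondition(s_A=0.0), op, 20000, rngs[1], smoothing=0.0)
        bi = predict_response_distribution(StimulusCondition(s_A=0.0, s_V=0.0), op, 20000, rngs[2], smoothing=0.0)

        def sd(p, centers):
            m = p @ centers
            return math.sqrt(p @ (centers - m) ** 2)

        c = uni_v.bin_centers
        sd_v = sd(uni_v.probs, c)
        sd_a = sd(uni_a.probs, c)
        sd_bi = sd(bi.probs.sum(axis=0), c)
        assert sd_bi <= min(sd_v, sd_a) + 0.05

    def test_very_wide_gaussian_prior_converges_to_flat_estimates(self):
        """As sigma_P grows the *location estimates* lose the prior's pull and
        match the flat-prior observer.  (The causal-structure posterior does
        not converge — evidence ratios scale with the prior's density height
        — so the comparison forces fusion to isolate the estimation pathway.)
        """
        flat = ObserverParams(p_common=1.0, sigma_V=2.0, sigma_A=8.0)
        wide = ObserverParams(p_common=1.0, sigma_V=2.0, sigma_A=8.0, sigma_P=5e4)
        # conditions keep the measurements far from the flat support edge,
        # where truncation (a real difference between the priors) kicks in
        for cond in (StimulusCondition(s_V=13.0), StimulusCondition(s_A=0.0),
                     StimulusCondition(s_A=13.0, s_V=-13.0)):
            d_flat = predict_response_distribution(cond, flat, 4096, np.random.default_rng(9))
            d_wide = predict_response_distribution(cond, wide, 4096, np.random.default_rng(9))
            assert np.abs(d_flat.probs - d_wide.probs).max() < 1e-3

    def test_hybrid_with_zeroed_biases_reproduces_baseline_model(self):
        baseline = ObserverParams(p_common=0.55, sigma_V=2.2, sigma_A=8.5, sigma_P=25.0)
        hybrid = ObserverParams(
            p_common=0.55, sigma_V=2.2, sigma_A=8.5,
            dx_V=0.0, dx_A=0.0, dsigma_V=0.0, sigma_P=25.0, x_P=0.0,
        )
        for cond in (StimulusCondition(s_A=13.0, s_V=6.5), StimulusCondition(s_V=-6.5)):
            a = predict_response_distribution(cond, baseline, 4096, np.random.default_rng(3))
            b = predict_response_distribution(cond, hybrid, 4096, np.random.default_rng(3))
            assert np.array_equal(a.probs, b.probs)


class TestPriorAlgebra:
    def test_product_of_gaussians_is_precision_weighted(self):
        g1 = PriorSpec(kind="gaussian", mean=0.0, sigma=2.0)
        g2 = PriorSpec(kind="gaussian", mean=6.0, sigma=2.0)
        prod = product_prior([g1, g2])
        w, m, t = prod.components()
        assert m[0] == pytest.approx(3.0)
        assert t[0] == pytest.approx(math.sqrt(2.0))

    def test_flat_factors_drop_out(self):
        g = PriorSpec(kind="gaussian", mean=1.0, sigma=3.0)
        prod = product_prior([FLAT, g])
        assert prod.kind == "gaussian"

    def test_density_integrates_to_one(self):
        s = np.linspace(-200, 200, 400001)
        for prior in (
            FLAT,
            PriorSpec(kind="gaussian", mean=3.0, sigma=10.0),
            PriorSpec(kind="mirrored_pair", mean=10.0, sigma=5.0),
            product_prior(
                [
                    PriorSpec(kind="gaussian", mean=0.0, sigma=12.0),
                    PriorSpec(kind="mirrored_pair", mean=10.0, sigma=5.0),
                ]
            ),
        ):
            # 5e-5 slack: the flat prior's edge discontinuity costs the
            # trapezoid rule ~ step / (2 * support) per edge
            assert np.trapezoid(prior.density(s), s) == pytest.approx(1.0, abs=5e-5)

    def test_condition_requires_a_stimulus(self):
        with pytest.raises(ValueError):
            StimulusCondition()
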