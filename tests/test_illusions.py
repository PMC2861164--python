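"""Forward illusion predictions and the summed-likelihood alternative."""

import numpy as np
import pytest

from pursuitbayes import (
    NoiseParams,
    ObserverParams,
    PriorParams,
    gain_ratio,
    predict_aubert_fleischl,
    predict_filehne,
    predict_psychometric,
    predict_trajectory,
    summed_model_predictions,
)


class TestSymmetricObserverNulls:
    """Identical channels shrink identically, so every illusion vanishes."""

    def test_aubert_fleischl_ratio_is_one(self, symmetric_observer):
        pred = predict_aubert_fleischl(8.0, symmetric_observer)
        assert pred.gain_ratio == pytest.approx(1.0, abs=1e-3)

    def test_filehne_is_zero(self, symmetric_observer):
        assert predict_filehne(8.0, symmetric_observer).predicted == pytest.approx(
            0.0, abs=1e-9)

    def test_trajectory_deviation_is_zero(self, symmetric_observer):
        pred = predict_trajectory(8.0, 4.0, symmetric_observer)
        assert pred.predicted == pytest.approx(0.0, abs=1e-7)

    def test_gain_ratio_is_one(self, symmetric_observer):
        assert gain_ratio(8.0, symmetric_observer) == pytest.approx(1.0, abs=1e-12)


class TestAsymmetricObserverSignatures:
    """A noisier T channel produces the whole illusion family at once."""

    def test_all_four_signatures_simultaneously(self, asymmetric_observer):
        af = predict_aubert_fleischl(8.0, asymmetric_observer)
        fi = predict_filehne(8.0, asymmetric_observer)
        tr = predict_trajectory(8.0, 4.0, asymmetric_observer)
        gr = gain_ratio(8.0, asymmetric_observer)
        assert af.gain_ratio < 1.0
        assert fi.predicted < 0.0
        assert tr.predicted > 0.0
        assert gr < 1.0

    def test_af_match_confirmed_by_mc_oracle(self, asymmetric_observer):
        """At the matched speed the MC choice probability is 1/2."""
        from pursuitbayes import IntervalSpec, p_choose_comparison
        af = predict_aubert_fleischl(8.0, asymmetric_observer)
        p = p_choose_comparison(IntervalSpec("E", 8.0),
                                IntervalSpec("F", af.predicted),
                                asymmetric_observer, method="monte_carlo",
                                n_samples=400_000, seed=17)
        assert p == pytest.approx(0.5, abs=0.005)

    def test_af_ratio_consistent_with_ef_pse(self, asymmetric_observer):
        """Root-found match equals the PSE of the model's E-F psychometric.

        The extraction grid straddles the match point, as a matching
        experiment's method-of-constant-stimuli grid would.  The model EF
        curve is slightly asymmetric in comparison speed (its mean and
        variance both vary with the comparison), so the fitted-Gaussian
        PSE approaches the exact p = 0.5 crossing as the grid narrows;
        +-35% around the match keeps the discrepancy inside 1%.
        """
        af = predict_aubert_fleischl(8.0, asymmetric_observer)
        grid = np.linspace(0.65 * af.predicted, 1.35 * af.predicted, 9)
        curve = predict_psychometric("EF", 8.0, grid, asymmetric_observer)
        fit = curve.fit()
        assert af.predicted == pytest.approx(fit.pse, rel=0.01)

    def test_filehne_odd_in_pursuit_speed(self, asymmetric_observer):
        f = predict_filehne(6.0, asymmetric_observer).predicted
        # the scene with reversed pursuit has mirrored inputs
        from pursuitbayes.illusions import _mean_h
        f_rev = _mean_h(6.0, -6.0, asymmetric_observer)
        assert f_rev == pytest.approx(-f, abs=1e-9)

    def test_af_ratio_monotone_in_t_baseline_noise(self, asymmetric_observer):
        """More T noise -> stronger underestimation of pursued speed."""
        ratios = []
        for c_T in (0.6, 0.8, 1.0):
            obs = ObserverParams(
                asymmetric_observer.noise_R,
                NoiseParams(asymmetric_observer.noise_T.a,
                            asymmetric_observer.noise_T.b, c_T),
                asymmetric_observer.prior)
            ratios.append(predict_aubert_fleischl(8.0, obs).gain_ratio)
        assert ratios[0] > ratios[1] > ratios[2]

    def test_gain_ratio_decreasing_in_a_T(self, asymmetric_observer):
        ratios = []
        for a_T in (0.2, 0.35, 0.5):
            obs = ObserverParams(
                asymmetric_observer.noise_R,
                NoiseParams(a_T, 0.6, asymmetric_observer.noise_T.c),
                asymmetric_observer.prior)
            ratios.append(gain_ratio(8.0, obs))
        assert ratios[0] > ratios[1] > ratios[2]

    def test_gain_ratio_closed_form_constant_noise(self, constant_noise_observer):
        """With constant noise sigma_T = 2 sigma_R the ratio is exact.

        E[w(|m|) m] has no closed form in general, but with a = 0 the
        shrinkage weight is constant, so the ratio of expected estimates is
        (sigma_p^2 + sigma_R^2) / (sigma_p^2 + sigma_T^2) exactly.
        """
        obs = constant_noise_observer  # sigma_R = 1, sigma_T = 2, sigma_p = 2
        # ratio of weights: w_T / w_R = (4/(4+4)) / (4/(4+1)) = 5/8
        assert gain_ratio(8.0, obs) == pytest.approx(5.0 / 8.0, abs=1e-4)

    def test_trajectory_deviation_vanishes_with_flat_prior(self, asymmetric_observer):
        obs = ObserverParams(asymmetric_observer.noise_R,
                             asymmetric_observer.noise_T,
                             PriorParams(1e6))
        pred = predict_trajectory(8.0, 4.0, obs)
        assert pred.predicted == pytest.approx(0.0, abs=1e-3)

    def test_af_error_when_no_root_in_bracket(self, asymmetric_observer):
        with pytest.raises(RuntimeError, match="bracket"):
            predict_aubert_fleischl(8.0, asymmetric_observer, bracket_hi=0.01)


class TestSummedLikelihoodAlternative:
    """One likelihood on the summed measurement predicts no illusions."""

    @pytest.mark.parametrize("sigma_p", [0.5, 2.0, 10.0])
    def test_filehne_exactly_zero_for_any_parameters(self, asymmetric_observer,
                                                     sigma_p):
        obs = ObserverParams(asymmetric_observer.noise_R,
                             asymmetric_observer.noise_T, PriorParams(sigma_p))
        pred = summed_model_predictions("filehne", obs)
        assert pred.predicted == pytest.approx(0.0, abs=1e-12)

    def test_trajectory_exactly_vertical(self, asymmetric_observer):
        pred = summed_model_predictions("trajectory", asymmetric_observer)
        assert pred.predicted == pytest.approx(0.0, abs=1e-10)

    def test_perceived_speed_still_shrunk(self, asymmetric_observer):
        pred = summed_model_predictions("aubert_fleischl", asymmetric_observer,
                                        pursuit_speed=8.0)
        assert 0.0 < pred.predicted < 8.0

    def test_unknown_scenario_rejected(self, asymmetric_observer):
        with pytest.raises(ValueError, match="scenario"):
            summed_model_predictions("slalom", asymmetric_observer)
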