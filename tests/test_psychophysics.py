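"""2IFC response probabilities, psychometric prediction and extraction."""

import numpy as np
import pandas as pd
import pytest

from pursuitbayes import (
    IntervalSpec,
    PsychometricPoint,
    fit_cumulative_gaussian,
    interval_to_inputs,
    p_choose_comparison,
    predict_psychometric,
    predicted_probabilities,
)
from pursuitbayes.psychophysics import PsychometricCurve


class TestIntervalToInputs:
    @pytest.mark.parametrize(
        "kind, speed, r, t",
        [("F", 8.0, 8.0, 0.0), ("E", 8.0, 0.0, 8.0), ("F", 0.0, 0.0, 0.0)],
    )
    def test_mapping(self, kind, speed, r, t):
        sv = interval_to_inputs(IntervalSpec(kind, speed))
        assert (sv.r, sv.t) == (r, t)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            IntervalSpec("X", 5.0)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            IntervalSpec("F", -1.0)


class TestPChooseComparison:
    def test_identical_intervals_give_half(self, asymmetric_observer):
        for kind in ("F", "E"):
            iv = IntervalSpec(kind, 6.0)
            assert p_choose_comparison(iv, iv, asymmetric_observer) == pytest.approx(
                0.5, abs=1e-9)

    def test_much_faster_comparison_dominates(self, asymmetric_observer):
        p = p_choose_comparison(IntervalSpec("F", 2.0), IntervalSpec("F", 20.0),
                                asymmetric_observer)
        assert p > 0.99

    def test_aubert_fleischl_signature_vs_mc_oracle(self, asymmetric_observer):
        """A fixated stimulus of equal speed beats the pursued standard."""
        std = IntervalSpec("E", 8.0)
        cmp_ = IntervalSpec("F", 8.0)
        p_quad = p_choose_comparison(std, cmp_, asymmetric_observer)
        p_mc = p_choose_comparison(std, cmp_, asymmetric_observer,
                                   method="monte_carlo", n_samples=10**6, seed=42)
        assert p_quad > 0.5
        assert p_mc > 0.5
        assert p_quad == pytest.approx(p_mc, abs=0.005)

    def test_temporal_order_invariance(self, asymmetric_observer):
        """p(E-F) at a speed pair equals 1 - p(F-E) with roles swapped."""
        p_ef = p_choose_comparison(IntervalSpec("E", 8.0), IntervalSpec("F", 5.0),
                                   asymmetric_observer)
        p_fe = p_choose_comparison(IntervalSpec("F", 5.0), IntervalSpec("E", 8.0),
                                   asymmetric_observer)
        assert p_ef == pytest.approx(1.0 - p_fe, abs=1e-9)

    def test_lapse_compresses_toward_half(self, asymmetric_observer):
        from pursuitbayes import ObserverParams
        lapsy = ObserverParams(asymmetric_observer.noise_R,
                               asymmetric_observer.noise_T,
                               asymmetric_observer.prior, lapse=0.1)
        std, cmp_ = IntervalSpec("F", 2.0), IntervalSpec("F", 3.5)
        p0 = p_choose_comparison(std, cmp_, asymmetric_observer)
        p1 = p_choose_comparison(std, cmp_, lapsy)
        assert p1 == pytest.approx(0.05 + 0.9 * p0, abs=1e-9)

    def test_degenerate_settings_rejected(self, asymmetric_observer):
        iv = IntervalSpec("F", 2.0)
        with pytest.raises(ValueError):
            p_choose_comparison(iv, iv, asymmetric_observer, n_nodes=0)
        with pytest.raises(ValueError):
            p_choose_comparison(iv, iv, asymmetric_observer,
                                method="monte_carlo", n_samples=0)

    def test_quadrature_matches_mc_across_conditions(self, asymmetric_observer):
        rng_seed = 99
        worst = 0.0
        for s in (1.0, 4.0, 8.0):
            for tt in ("FF", "EE", "EF", "FE"):
                for c in (0.7 * s, 1.2 * s):
                    pq = p_choose_comparison(IntervalSpec(tt[0], s),
                                             IntervalSpec(tt[1], c),
                                             asymmetric_observer)
                    pm = p_choose_comparison(IntervalSpec(tt[0], s),
                                             IntervalSpec(tt[1], c),
                                             asymmetric_observer,
                                             method="monte_carlo",
                                             n_samples=200_000, seed=rng_seed)
                    worst = max(worst, abs(pq - pm))
        assert worst < 0.01  # 200k MC samples; the acceptance run uses 10^6


class TestPredictPsychometric:
    def test_symmetric_observer_ef_pse_at_standard(self, symmetric_observer):
        grid = np.linspace(4.0, 12.0, 9)
        curve = predict_psychometric("EF", 8.0, grid, symmetric_observer)
        fit = curve.fit()
        assert fit.pse == pytest.approx(8.0, abs=0.05)

    def test_ff_curve_monotone_nondecreasing(self, asymmetric_observer):
        grid = np.linspace(2.0, 14.0, 13)
        curve = predict_psychometric("FF", 8.0, grid, asymmetric_observer)
        assert np.all(np.diff(curve.proportions) >= -1e-12)

    def test_pursuit_thresholds_exceed_fixation(self, asymmetric_observer):
        """Pursued stimuli are harder to discriminate at every standard."""
        for s in (1.0, 2.0, 4.0, 8.0):
            grid = np.linspace(0.5 * s, 1.5 * s, 9)
            thr = {}
            for tt in ("FF", "EE"):
                thr[tt] = predict_psychometric(tt, s, grid,
                                               asymmetric_observer).fit().threshold
            assert thr["EE"] > thr["FF"]

    def test_empty_grid_rejected(self, asymmetric_observer):
        with pytest.raises(ValueError):
            predict_psychometric("FF", 8.0, [], asymmetric_observer)

    def test_batch_engine_matches_single_calls(self, asymmetric_observer):
        cells = pd.DataFrame({
            "trial_type": ["FF", "EE", "EF", "FE"],
            "standard_speed": [2.0, 4.0, 8.0, 8.0],
            "comparison_speed": [2.5, 3.5, 6.0, 9.0],
        })
        batch = predicted_probabilities(cells, asymmetric_observer)
        for i, row in cells.iterrows():
            single = p_choose_comparison(
                IntervalSpec(row.trial_type[0], row.standard_speed),
                IntervalSpec(row.trial_type[1], row.comparison_speed),
                asymmetric_observer)
            # the shared binning grid spans the whole batch, so batch and
            # single-cell evaluations differ at the grid-resolution scale
            assert batch[i] == pytest.approx(single, abs=1e-3)


class TestFitCumulativeGaussian:
    @staticmethod
    def _points_on_gaussian(mu, sd, n_per_point, rng):
        from scipy.stats import norm
        x = np.linspace(mu - 2.5 * sd, mu + 2.5 * sd, 9)
        p = norm.cdf((x - mu) / sd)
        k = rng.binomial(n_per_point, p)
        return [PsychometricPoint(xi, n_per_point, ki) for xi, ki in zip(x, k)]

    def test_recovers_generating_parameters(self, rng):
        pts = self._points_on_gaussian(10.0, 2.0, 400, rng)
        fit = fit_cumulative_gaussian(pts)
        assert fit.pse == pytest.approx(10.0, abs=0.3)
        assert fit.threshold == pytest.approx(2.0, rel=0.15)
        assert fit.identifiable

    def test_mirrored_proportions_leave_pse_invariant(self):
        x = np.array([6.0, 8.0, 10.0, 12.0, 14.0])
        k = np.array([2, 10, 20, 30, 38])
        pts = [PsychometricPoint(xi, 40, ki) for xi, ki in zip(x, k)]
        mirrored = [PsychometricPoint(xi, 40, ki)
                    for xi, ki in zip(x, (40 - k)[::-1])]
        f1 = fit_cumulative_gaussian(pts)
        f2 = fit_cumulative_gaussian(mirrored)
        assert f1.pse == pytest.approx(f2.pse, abs=1e-3)

    def test_all_zero_responses_flagged_nonidentifiable(self):
        pts = [PsychometricPoint(x, 20, 0) for x in (1.0, 2.0, 3.0, 4.0)]
        fit = fit_cumulative_gaussian(pts)
        assert not fit.identifiable
        assert np.isfinite(fit.pse) and np.isfinite(fit.threshold)

    def test_needs_three_distinct_levels(self):
        pts = [PsychometricPoint(1.0, 20, 5), PsychometricPoint(2.0, 20, 15)]
        with pytest.raises(ValueError):
            fit_cumulative_gaussian(pts)

    def test_matches_statsmodels_probit(self, rng):
        """Independent oracle: probit GLM gives the same ML estimates."""
        sm = pytest.importorskip("statsmodels.api")
        pts = self._points_on_gaussian(5.0, 1.5, 200, rng)
        fit = fit_cumulative_gaussian(pts)
        x = np.array([p.comparison_speed for p in pts])
        resp = np.column_stack([[p.n_chose_comparison for p in pts],
                                [p.n_trials - p.n_chose_comparison for p in pts]])
        glm = sm.GLM(resp, sm.add_constant(x),
                     family=sm.families.Binomial(sm.families.links.Probit())).fit()
        b0, b1 = glm.params
        assert fit.pse == pytest.approx(-b0 / b1, rel=1e-3)
        assert fit.threshold == pytest.approx(1.0 / b1, rel=1e-3)

    def test_curve_keeps_points_sorted(self):
        pts = [PsychometricPoint(3.0, 10, 5), PsychometricPoint(1.0, 10, 1),
               PsychometricPoint(2.0, 10, 3)]
        curve = PsychometricCurve("FF", 2.0, pts)
        assert list(curve.comparison_speeds) == [1.0, 2.0, 3.0]
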