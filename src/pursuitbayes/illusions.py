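"""Forward predictions of pursuit-based velocity illusions.

A fitted (or specified) observer predicts a consistent family of effects:

* Aubert-Fleischl: a pursued stimulus appears slower than the same stimulus
  viewed under fixation, so the fixated match speed is below the pursued
  standard.
* Filehne: during pursuit over a stationary background, the background's
  relative motion is equal and opposite to the eye movement; unequal
  shrinkage of the two channels leaves a nonzero perceived velocity against
  the pursuit.
* Trajectory misperception: a vertically moving object seen during
  horizontal pursuit acquires an illusory horizontal component, tilting its
  perceived direction away from vertical.
* Gain ratio: the internal signal for eye velocity relative to that for
  image motion; below 1 when the target channel is the noisier one.

The module also implements the single-likelihood alternative in which the
two measurements are summed *before* estimation.  Because the summed
measurement of a Filehne or trajectory scene is centered on the truth and
the prior is centered on zero, that model predicts no Filehne illusion and
no direction error for any parameter values — the structural argument for
placing separate Bayes estimators before the signals are combined.

Sign conventions: pursuit is in the positive direction; the Filehne
prediction is negative when the background appears to move against pursuit,
and the trajectory deviation is reported in degrees from vertical, positive
when the perceived path tilts against the pursuit direction (the illusory
side, consistent with the Filehne sign).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .observer import NoiseParams, ObserverParams, noise_sd
from .psychophysics import (
    DEFAULT_MODE,
    IntervalSpec,
    _channel_estimate_atoms,
    _std_normal_nodes,
    p_choose_comparison,
)

__all__ = [
    "IllusionPrediction",
    "expected_estimate",
    "gain_ratio",
    "predict_aubert_fleischl",
    "predict_filehne",
    "predict_trajectory",
    "summed_model_predictions",
]

SCENARIOS = ("aubert_fleischl", "filehne", "trajectory")


@dataclass(frozen=True)
class IllusionPrediction:
    """One scenario's prediction: inputs, perceived quantity, gain ratio."""

    scenario: str
    inputs: dict
    predicted: float
    units: str
    gain_ratio: float | None = None


def expected_estimate(true_v: float, noise: NoiseParams, sigma_p: float,
                      n_nodes: int = 201, mode: str = DEFAULT_MODE) -> float:
    """E over measurement noise of one channel's shrunk estimate.

    In "true" mode the weight is conditioned on the stimulus speed, so the
    expectation is simply w(v) * v.  In "measured" mode the weight tracks
    the measured speed and the expectation of the nonlinearly shrunk
    estimate is computed by quadrature (quantile-mapped, split at the
    m = 0 kink), atom by atom — the mean of the shrunk measurement, not
    the shrinkage of the mean.
    """
    if mode == "true":
        sd = noise_sd(noise, true_v)
        s2 = sigma_p * sigma_p
        return float(s2 / (s2 + sd * sd) * true_v)
    if mode == "measured":
        e, w = _channel_estimate_atoms(true_v, noise, sigma_p, n_nodes)
        return float(np.sum(w[0] * e[0]))
    raise ValueError(f"unknown mode {mode!r}")


def _mean_h(r: float, t: float, obs: ObserverParams, n_nodes: int = 201,
            mode: str = DEFAULT_MODE) -> float:
    """Mean perceived head-centered velocity for scene inputs (r, t)."""
    return (expected_estimate(r, obs.noise_R, obs.sigma_p_R, n_nodes, mode)
            + expected_estimate(t, obs.noise_T, obs.sigma_p_T, n_nodes, mode))


def gain_ratio(speed: float, obs: ObserverParams, n_nodes: int = 201,
               mode: str = DEFAULT_MODE) -> float:
    """E[T' | t = speed] / E[R' | r = speed]: eye-velocity signal gain.

    Equals 1 for a symmetric observer; below 1 when the target channel is
    noisier (eye speed underestimated relative to image speed).
    """
    if speed <= 0:
        raise ValueError("speed must be > 0")
    num = expected_estimate(speed, obs.noise_T, obs.sigma_p_T, n_nodes, mode)
    den = expected_estimate(speed, obs.noise_R, obs.sigma_p_R, n_nodes, mode)
    return num / den


def predict_aubert_fleischl(standard_speed: float, obs: ObserverParams,
                            n_nodes: int = 61, bracket_hi: float = 3.0,
                            mode: str = DEFAULT_MODE) -> IllusionPrediction:
    """Fixated match speed for a pursued standard, via the decision rule.

    Root-finds the fixated comparison speed at which the observer is
    indifferent (P(choose comparison) = 0.5) against the pursued standard.
    The match ratio below 1 quantifies how much fixated motion must be
    slowed to appear as fast as the pursued stimulus.
    """
    if standard_speed <= 0:
        raise ValueError("standard_speed must be > 0")
    standard = IntervalSpec("E", standard_speed)

    def g(c: float) -> float:
        return p_choose_comparison(standard, IntervalSpec("F", c), obs,
                                   n_nodes=n_nodes, mode=mode) - 0.5

    lo, hi = 1e-6, bracket_hi * standard_speed
    g_lo, g_hi = g(lo), g(hi)
    if g_lo * g_hi > 0:
        raise RuntimeError(
            "no perceived-speed match in bracket "
            f"[{lo}, {hi}]: g(lo)={g_lo:.4f}, g(hi)={g_hi:.4f}"
        )
    match = brentq(g, lo, hi, xtol=1e-8)
    return IllusionPrediction(
        scenario="aubert_fleischl",
        inputs={"standard_speed": standard_speed},
        predicted=float(match),
        units="deg/s (fixated match speed)",
        gain_ratio=float(match / standard_speed),
    )


def predict_filehne(pursuit_speed: float, obs: ObserverParams,
                    n_nodes: int = 201,
                    mode: str = DEFAULT_MODE) -> IllusionPrediction:
    """Mean perceived velocity of a stationary background during pursuit.

    The scene inputs are r = -pursuit_speed (the background sweeps across
    the retina against the eye movement) and t = +pursuit_speed.  Negative
    output = background seen moving against the pursuit.
    """
    if pursuit_speed <= 0:
        raise ValueError("pursuit_speed must be > 0")
    h = _mean_h(-pursuit_speed, pursuit_speed, obs, n_nodes, mode)
    t_gain = expected_estimate(pursuit_speed, obs.noise_T, obs.sigma_p_T,
                               n_nodes, mode) / pursuit_speed
    r_gain = expected_estimate(pursuit_speed, obs.noise_R, obs.sigma_p_R,
                               n_nodes, mode) / pursuit_speed
    return IllusionPrediction(
        scenario="filehne",
        inputs={"pursuit_speed": pursuit_speed},
        predicted=float(h),
        units="deg/s (perceived background velocity)",
        gain_ratio=float(t_gain / r_gain),
    )


def predict_trajectory(pursuit_speed: float, object_vertical_speed: float,
                       obs: ObserverParams, n_nodes: int = 201,
                       mode: str = DEFAULT_MODE) -> IllusionPrediction:
    """Perceived direction error for a vertically moving object during pursuit.

    Horizontal axis: r = -pursuit_speed, t = +pursuit_speed (as in the
    Filehne scene).  Vertical axis: r = object speed, t = 0.  Each axis is
    estimated independently; the deviation from vertical (degrees) is
    positive when the perceived trajectory tilts against the pursuit.
    """
    if pursuit_speed <= 0 or object_vertical_speed <= 0:
        raise ValueError("speeds must be > 0")
    h_x = _mean_h(-pursuit_speed, pursuit_speed, obs, n_nodes, mode)
    h_y = _mean_h(object_vertical_speed, 0.0, obs, n_nodes, mode)
    deviation = math.degrees(math.atan2(-h_x, h_y))
    return IllusionPrediction(
        scenario="trajectory",
        inputs={"pursuit_speed": pursuit_speed,
                "object_vertical_speed": object_vertical_speed},
        predicted=float(deviation),
        units="deg from vertical (positive = against pursuit)",
        gain_ratio=float(gain_ratio(pursuit_speed, obs, n_nodes, mode)),
    )


# ---------------------------------------------------------------------------
# Summed-likelihood alternative
# ---------------------------------------------------------------------------

def _summed_expected_estimate(r: float, t: float, obs: ObserverParams,
                              n_nodes: int = 201) -> float:
    """Mean estimate under the single-likelihood model.

    The alternative sums the unbiased measurements first, H_m = R_m + T_m
    ~ N(r + t, sigma_R(r)^2 + sigma_T(t)^2), forms one likelihood centered
    on H_m, and shrinks toward a single zero prior.
    """
    z, w = _std_normal_nodes(n_nodes)
    var = noise_sd(obs.noise_R, r) ** 2 + noise_sd(obs.noise_T, t) ** 2
    sd = math.sqrt(var)
    h_m = (r + t) + sd * z
    s2 = obs.prior.sigma_p ** 2
    shrink = s2 / (s2 + var)
    return float(np.sum(w * shrink * h_m))


def summed_model_predictions(scenario: str, obs: ObserverParams,
                             pursuit_speed: float = 8.0,
                             object_vertical_speed: float = 4.0,
                             n_nodes: int = 201) -> IllusionPrediction:
    """Predictions of the single-likelihood alternative model.

    In a Filehne scene the summed measurement is centered on zero, and so
    (with a zero prior) is the posterior: no illusion, for any parameters.
    In the trajectory scene the horizontal component is likewise zero on
    average, so the perceived direction is exactly vertical.  Perceived
    speed is still shrunk below veridical — the zero prior compresses
    magnitude but can never displace direction.
    """
    if scenario == "filehne":
        h = _summed_expected_estimate(-pursuit_speed, pursuit_speed, obs, n_nodes)
        return IllusionPrediction(
            scenario="filehne", inputs={"pursuit_speed": pursuit_speed},
            predicted=float(h), units="deg/s (perceived background velocity)",
            gain_ratio=1.0,
        )
    if scenario == "trajectory":
        h_x = _summed_expected_estimate(-pursuit_speed, pursuit_speed, obs,
                                        n_nodes)
        h_y = _summed_expected_estimate(object_vertical_speed, 0.0, obs, n_nodes)
        deviation = math.degrees(math.atan2(-h_x, h_y))
        return IllusionPrediction(
            scenario="trajectory",
            inputs={"pursuit_speed": pursuit_speed,
                    "object_vertical_speed": object_vertical_speed},
            predicted=float(deviation),
            units="deg from vertical (positive = against pursuit)",
            gain_ratio=1.0,
        )
    if scenario == "aubert_fleischl":
        # pursued stimulus: r = 0, t = v; fixated: r = v, t = 0
        perceived_e = _summed_expected_estimate(0.0, pursuit_speed, obs, n_nodes)
        perceived_f = _summed_expected_estimate(pursuit_speed, 0.0, obs, n_nodes)
        return IllusionPrediction(
            scenario="aubert_fleischl", inputs={"standard_speed": pursuit_speed},
            predicted=float(perceived_e),
            units="deg/s (perceived pursued-stimulus speed)",
            gain_ratio=float(perceived_e / perceived_f),
        )
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
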