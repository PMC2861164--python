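"""Generative observer model: speed-dependent measurement noise and Bayes estimation.

The observer measures two velocity signals on a single (horizontal) axis:

* ``R`` — relative motion of the stimulus with respect to the pursuit target
  (eye-movement independent image motion), and
* ``T`` — motion of the pursuit target with respect to the head.

Each measurement is unbiased but corrupted by Gaussian internal noise whose
standard deviation grows with speed, ``sigma(v) = a * |v|**b + c``.  Each
noisy measurement is then combined with a zero-centered Gaussian prior over
velocity ("objects tend to be at rest"), producing a shrunk estimate.  The
sum of the two estimates is the perceived head-centered velocity ``H'``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "NoiseParams",
    "PriorParams",
    "ObserverParams",
    "SceneVelocities",
    "noise_sd",
    "draw_measurement",
    "bayes_estimate",
    "head_centered_estimate",
]


@dataclass(frozen=True)
class NoiseParams:
    """Internal-noise law ``sigma(v) = a * |v|**b + c`` for one channel.

    Parameters
    ----------
    a : float
        Noise scale, units (deg/s)^(1-b).  Non-negative.
    b : float
        Speed exponent, dimensionless, in [0, 3].
    c : float
        Baseline noise SD at zero speed (deg/s).  Must be positive so that
        a stationary input still carries measurement noise.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b) and np.isfinite(self.c)):
            raise ValueError("noise parameters must be finite")
        if self.a < 0:
            raise ValueError(f"a must be >= 0, got {self.a}")
        if not (0.0 <= self.b <= 3.0):
            raise ValueError(f"b must be in [0, 3], got {self.b}")
        if self.c <= 0:
            raise ValueError(f"c must be > 0, got {self.c}")

    def sd(self, v):
        """Noise SD at signed velocity ``v`` (vectorized)."""
        return noise_sd(self, v)


@dataclass(frozen=True)
class PriorParams:
    """Zero-centered Gaussian prior over velocity with SD ``sigma_p`` (deg/s)."""

    sigma_p: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma_p) and self.sigma_p > 0):
            raise ValueError(f"sigma_p must be finite and > 0, got {self.sigma_p}")


@dataclass(frozen=True)
class ObserverParams:
    """Full generative model: two noise channels, one shared zero prior, lapse.

    The default configuration has seven free parameters
    ``(a_R, b_R, c_R, a_T, b_T, c_T, sigma_p)``; the lapse rate defaults to
    zero and is exposed only for robustness studies.
    """

    noise_R: NoiseParams
    noise_T: NoiseParams
    prior: PriorParams
    lapse: float = 0.0
    prior_T: PriorParams | None = None  # None = prior shared by both channels

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError(f"lapse must be in [0, 0.1], got {self.lapse}")

    @property
    def sigma_p_R(self) -> float:
        return self.prior.sigma_p

    @property
    def sigma_p_T(self) -> float:
        return (self.prior_T or self.prior).sigma_p

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "a_R": self.noise_R.a,
            "b_R": self.noise_R.b,
            "c_R": self.noise_R.c,
            "a_T": self.noise_T.a,
            "b_T": self.noise_T.b,
            "c_T": self.noise_T.c,
            "sigma_p": self.prior.sigma_p,
            "lapse": self.lapse,
            **({"sigma_p_T": self.prior_T.sigma_p} if self.prior_T else {}),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverParams":
        return cls(
            noise_R=NoiseParams(d["a_R"], d["b_R"], d["c_R"]),
            noise_T=NoiseParams(d["a_T"], d["b_T"], d["c_T"]),
            prior=PriorParams(d["sigma_p"]),
            lapse=d.get("lapse", 0.0),
            prior_T=PriorParams(d["sigma_p_T"]) if "sigma_p_T" in d else None,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ObserverParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SceneVelocities:
    """True scene inputs for one stimulus interval.

    ``r`` is the signed relative motion of the stimulus with respect to the
    pursuit target and ``t`` the signed pursuit-target motion, both in deg/s
    with positive = rightward.
    """

    r: float
    t: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r) and np.isfinite(self.t)):
            raise ValueError("scene velocities must be finite")


def noise_sd(params: NoiseParams, v):
    """Measurement-noise SD ``a * |v|**b + c`` at signed velocity ``v``.

    Accepts scalars or arrays; the noise law depends only on speed (|v|).
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity must be finite")
    out = params.a * np.abs(v) ** params.b + params.c
    return float(out) if out.ndim == 0 else out


def draw_measurement(v, params: NoiseParams, rng: np.random.Generator, size=None):
    """Draw unbiased noisy measurement(s) of signed velocity ``v``.

    Samples from N(v, sigma(v)^2) using the supplied seeded generator; the
    noise SD is evaluated at the true stimulus velocity.
    """
    sd = noise_sd(params, v)
    return rng.normal(loc=v, scale=sd, size=size)


def _shrinkage_weight(sigma_like, sigma_p):
    s2 = sigma_p * sigma_p
    return s2 / (s2 + np.asarray(sigma_like, dtype=float) ** 2)


def bayes_estimate(m, noise: NoiseParams, prior: PriorParams, mode: str = "measured",
                   true_speed=None):
    """Posterior-peak velocity estimate from measurement ``m`` under a zero prior.

    Under the Gaussian approximation the posterior of a Gaussian likelihood
    N(m; v, sigma^2) times a zero-centered Gaussian prior N(v; 0, sigma_p^2)
    peaks at ``w * m`` with ``w = sigma_p^2 / (sigma_p^2 + sigma^2)`` (MAP and
    posterior mean coincide).  The likelihood width is not observable from the
    true stimulus, so by default it is evaluated at the measured speed |m|.

    Parameters
    ----------
    m : float or array
        Noisy measurement(s), deg/s.
    mode : {"measured", "true", "map"}
        "measured" (default): closed form with sigma = sigma(|m|).
        "true": closed form with sigma = sigma(|true_speed|) (requires
        ``true_speed``); matches the pipeline's default stimulus-conditioned
        mode.
        "map": numerically maximizes N(m; v, sigma(|v|)^2) * N(v; 0,
        sigma_p^2) over v, the exact non-Gaussian MAP (scalar m only).
    """
    if mode == "measured":
        m_arr = np.asarray(m, dtype=float)
        w = _shrinkage_weight(noise_sd(noise, m_arr), prior.sigma_p)
        out = w * m_arr
        return float(out) if out.ndim == 0 else out
    if mode == "true":
        if true_speed is None:
            raise ValueError("mode='true' requires true_speed")
        w = _shrinkage_weight(noise_sd(noise, true_speed), prior.sigma_p)
        out = w * np.asarray(m, dtype=float)
        return float(out) if out.ndim == 0 else out
    if mode == "map":
        return _map_estimate(float(m), noise, prior)
    raise ValueError(f"unknown estimator mode {mode!r}")


def _map_estimate(m: float, noise: NoiseParams, prior: PriorParams) -> float:
    """Numerical MAP with speed-dependent likelihood width evaluated at v."""
    if m == 0.0:
        return 0.0

    def neg_log_post(v: float) -> float:
        sd = noise.a * abs(v) ** noise.b + noise.c
        return (
            math.log(sd)
            + 0.5 * ((m - v) / sd) ** 2
            + 0.5 * (v / prior.sigma_p) ** 2
        )

    lo, hi = (0.0, m) if m > 0 else (m, 0.0)
    res = minimize_scalar(neg_log_post, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def head_centered_estimate(r_m, t_m, obs: ObserverParams, mode: str = "measured",
                           true_scene: SceneVelocities | None = None):
    """Perceived head-centered velocity H' = R' + T' from the two measurements."""
    kw_r = {}
    kw_t = {}
    if mode == "true":
        if true_scene is None:
            raise ValueError("mode='true' requires true_scene")
        kw_r["true_speed"] = true_scene.r
        kw_t["true_speed"] = true_scene.t
    r_est = bayes_estimate(r_m, obs.noise_R, obs.prior, mode=mode, **kw_r)
    t_est = bayes_estimate(t_m, obs.noise_T, obs.prior, mode=mode, **kw_t)
    return r_est + t_est
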