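"""Joint maximum-likelihood fitting of the observer model to choice data.

The seven free parameters (a_R, b_R, c_R, a_T, b_T, c_T, sigma_p) are fit
simultaneously to all of an observer's psychometric functions by maximizing
the binomial likelihood of the raw per-cell choice counts — not the
extracted thresholds and PSEs.  Scale parameters are optimized on a log
scale; the exponents b_R, b_T stay linear.  Multi-start optimization
(Latin-hypercube starts plus one heuristic start read off the data) guards
against local minima, and nonparametric bootstrap over trials within each
psychometric point yields 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .observer import NoiseParams, ObserverParams, PriorParams, noise_sd
from .psychophysics import (
    PsychometricPoint,
    fit_cumulative_gaussian,
    predicted_probabilities,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "IdentifiabilityError",
    "trials_to_cells",
    "negative_log_likelihood",
    "fit_observer",
    "bootstrap_cis",
    "count_free_parameters",
    "run_parameter_recovery",
]

_P_CLIP = 1e-9

DISCRIMINATION_TYPES = {"FF", "EE"}
PERCEIVED_SPEED_TYPES = {"EF", "FE"}


class IdentifiabilityError(ValueError):
    """Raised when the trial table cannot constrain the model."""


@dataclass(frozen=True)
class FitConfig:
    """Bounds, transforms and optimizer settings for the joint fit.

    Bounds are in natural units; scale parameters (a, c, sigma_p) are
    log-transformed internally, the exponents b stay linear.  ``n_starts``
    Latin-hypercube starting points are drawn inside the bounds, plus one
    heuristic start derived from per-curve cumulative-Gaussian summaries.
    """

    n_starts: int = 20
    n_nodes: int = 61
    mode: str = "true"
    share_prior: bool = True
    fit_lapse: bool = False
    a_bounds: tuple[float, float] = (1e-4, 3.0)
    b_bounds: tuple[float, float] = (0.0, 3.0)
    c_bounds: tuple[float, float] = (0.02, 10.0)
    sigma_p_bounds: tuple[float, float] = (0.1, 50.0)
    lapse_bounds: tuple[float, float] = (0.0, 0.1)
    gtol: float = 1e-6
    maxiter: int = 400
    bootstrap_B: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.bootstrap_B < 0:
            raise ValueError("bootstrap_B must be >= 0")
        if self.c_bounds[0] <= 0 or self.sigma_p_bounds[0] <= 0:
            raise ValueError("c and sigma_p lower bounds must be > 0")
        if self.a_bounds[0] < 0:
            raise ValueError("a lower bound must be >= 0")


@dataclass
class FitResult:
    """Outcome of a joint fit: parameters, likelihood, and diagnostics."""

    params: ObserverParams
    nll: float
    converged: bool
    start_table: pd.DataFrame
    ci: dict | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "nll": self.nll,
            "converged": self.converged,
            "n_starts": len(self.start_table),
            "ci": self.ci,
        }


def count_free_parameters(share_prior: bool = True, fit_lapse: bool = False) -> int:
    """Number of free parameters in the model configuration.

    The measurement stage always contributes six (a, b, c per channel); the
    estimation stage contributes one shared prior SD, or two if unshared;
    an optional lapse adds one more.
    """
    n = 6 + (1 if share_prior else 2)
    if fit_lapse:
        n += 1
    return n


def trials_to_cells(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a trial table into per-cell binomial counts (n, k)."""
    required = {"trial_type", "standard_speed", "comparison_speed", "response"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    g = trials.groupby(["trial_type", "standard_speed", "comparison_speed"],
                       sort=True)
    cells = g["response"].agg(n="size", k="sum").reset_index()
    cells["k"] = cells["k"].astype(float)
    return cells


def negative_log_likelihood(trials: pd.DataFrame, params: ObserverParams,
                            n_nodes: int = 61, mode: str = "true") -> float:
    """Binomial negative log-likelihood (nats) of the trial table.

    Probabilities come from the response-probability engine (closed form in
    "true" mode, quadrature in "measured" mode) and are clipped to
    [1e-9, 1 - 1e-9] before taking logs.  ``trials`` may be a raw trial
    table or a pre-aggregated cell table with columns n, k.
    """
    cells = trials if {"n", "k"} <= set(trials.columns) else trials_to_cells(trials)
    p = predicted_probabilities(cells, params, n_nodes=n_nodes, mode=mode)
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    n = cells["n"].to_numpy(dtype=float)
    k = cells["k"].to_numpy(dtype=float)
    return float(-np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# Parameter vector <-> ObserverParams
# ---------------------------------------------------------------------------

def _theta_names(config: FitConfig) -> list[str]:
    names = ["log_a_R", "b_R", "log_c_R", "log_a_T", "b_T", "log_c_T",
             "log_sigma_p"]
    if not config.share_prior:
        names.append("log_sigma_p_T")
    if config.fit_lapse:
        names.append("lapse")
    return names


def _theta_bounds(config: FitConfig) -> list[tuple[float, float]]:
    la = tuple(np.log(config.a_bounds))
    lc = tuple(np.log(config.c_bounds))
    lp = tuple(np.log(config.sigma_p_bounds))
    bounds = [la, config.b_bounds, lc, la, config.b_bounds, lc, lp]
    if not config.share_prior:
        bounds.append(lp)
    if config.fit_lapse:
        bounds.append(config.lapse_bounds)
    return bounds


def _theta_to_params(theta: np.ndarray, config: FitConfig) -> ObserverParams:
    i = 7
    prior_T = None
    if not config.share_prior:
        prior_T = PriorParams(float(np.exp(theta[i])))
        i += 1
    lapse = float(theta[i]) if config.fit_lapse else 0.0
    return ObserverParams(
        noise_R=NoiseParams(float(np.exp(theta[0])), float(theta[1]),
                            float(np.exp(theta[2]))),
        noise_T=NoiseParams(float(np.exp(theta[3])), float(theta[4]),
                            float(np.exp(theta[5]))),
        prior=PriorParams(float(np.exp(theta[6]))),
        lapse=lapse,
        prior_T=prior_T,
    )


def _params_to_theta(params: ObserverParams, config: FitConfig) -> np.ndarray:
    theta = [np.log(params.noise_R.a), params.noise_R.b, np.log(params.noise_R.c),
             np.log(params.noise_T.a), params.noise_T.b, np.log(params.noise_T.c),
             np.log(params.prior.sigma_p)]
    if not config.share_prior:
        theta.append(np.log(params.sigma_p_T))
    if config.fit_lapse:
        theta.append(params.lapse)
    return np.array(theta)


def _clip_to_bounds(theta: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(theta, lo, hi)


# ---------------------------------------------------------------------------
# Heuristic start from per-curve summaries
# ---------------------------------------------------------------------------

def _heuristic_start(cells: pd.DataFrame, config: FitConfig) -> np.ndarray:
    """Initial guess read off cumulative-Gaussian summaries of the curves.

    Discrimination thresholds approximate sqrt(2) times the effective noise
    of the repeated channel, giving a crude (a, c) line per channel with
    b = 1; the perceived-speed PSE ratio then pins sigma_p through the
    ratio of the two shrinkage weights.
    """
    summaries = []
    for (tt, std), sub in cells.groupby(["trial_type", "standard_speed"]):
        pts = [PsychometricPoint(r.comparison_speed, r.n, r.k)
               for r in sub.itertuples()]
        try:
            f = fit_cumulative_gaussian(pts)
        except ValueError:
            continue
        summaries.append((tt, float(std), f.pse, f.threshold))
    df = pd.DataFrame(summaries, columns=["trial_type", "standard", "pse", "thr"])

    def noise_line(tt: str) -> tuple[float, float]:
        sub = df[df.trial_type == tt]
        if len(sub) == 0:
            return 0.1, 0.5
        sigma = sub.thr.to_numpy() / np.sqrt(2.0)  # 2IFC: two noisy intervals
        if len(sub) >= 2:
            A = np.vstack([sub.standard.to_numpy(), np.ones(len(sub))]).T
            coef, *_ = np.linalg.lstsq(A, sigma, rcond=None)
            a, c = float(coef[0]), float(coef[1])
        else:
            a, c = 0.1, float(sigma[0])
        return a, c

    a_R, c_R = noise_line("FF")
    a_T, c_T = noise_line("EE")
    a_R = float(np.clip(a_R, *config.a_bounds))
    a_T = float(np.clip(a_T, *config.a_bounds))
    c_R = float(np.clip(c_R, *config.c_bounds))
    c_T = float(np.clip(c_T, *config.c_bounds))

    sigma_p = 4.0
    ps = df[df.trial_type.isin(PERCEIVED_SPEED_TYPES)]
    if len(ps) > 0:
        row = ps.iloc[-1]
        v = row.standard
        # EF: match ratio g = PSE/standard ~ w_T(v) / w_R(v)
        g = row.pse / v if row.trial_type == "EF" else v / max(row.pse, 1e-6)
        g = float(np.clip(g, 0.05, 0.999))
        s_R = a_R * v + c_R
        s_T = a_T * v + c_T
        num = g * s_T ** 2 - s_R ** 2
        if num > 0:
            sigma_p = float(np.sqrt(num / (1.0 - g)))
    sigma_p = float(np.clip(sigma_p, *config.sigma_p_bounds))

    start = ObserverParams(NoiseParams(max(a_R, config.a_bounds[0]), 1.0, c_R),
                           NoiseParams(max(a_T, config.a_bounds[0]), 1.0, c_T),
                           PriorParams(sigma_p),
                           prior_T=None if config.share_prior
                           else PriorParams(sigma_p))
    return _params_to_theta(start, config)


# ---------------------------------------------------------------------------
# Joint fit
# ---------------------------------------------------------------------------

def fit_observer(trials: pd.DataFrame, config: FitConfig | None = None) -> FitResult:
    """Fit the observer model jointly to all psychometric functions.

    Requires at least one discrimination condition (FF or EE) and one
    perceived-speed condition (EF or FE); without both, the prior width and
    the noise asymmetry are not separately identifiable and an
    ``IdentifiabilityError`` is raised.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = FitConfig()
    cells = trials_to_cells(trials)
    types = set(cells["trial_type"].unique())
    if not (types & DISCRIMINATION_TYPES and types & PERCEIVED_SPEED_TYPES):
        raise IdentifiabilityError(
            "trial table must contain at least one discrimination condition "
            f"(FF/EE) and one perceived-speed condition (EF/FE); got {sorted(types)}"
        )

    bounds = _theta_bounds(config)
    names = _theta_names(config)

    def objective(theta: np.ndarray) -> float:
        try:
            params = _theta_to_params(theta, config)
            val = negative_log_likelihood(cells, params, n_nodes=config.n_nodes,
                                          mode=config.mode)
        except (ValueError, FloatingPointError, OverflowError):
            return np.inf
        return val if np.isfinite(val) else np.inf

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=len(bounds), seed=config.seed)
    lhs = lo + sampler.random(config.n_starts) * (hi - lo)
    starts = [_clip_to_bounds(_heuristic_start(cells, config), bounds)]
    starts += list(lhs[: max(config.n_starts - 1, 0)])

    rows = []
    best = None
    for i, x0 in enumerate(starts):
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"gtol": config.gtol, "maxiter": config.maxiter})
        rows.append({"start": i, "nll": float(res.fun),
                     "converged": bool(res.success),
                     **dict(zip(names, res.x))})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    start_table = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} starts failed to produce a finite likelihood; "
            f"start table:\n{start_table}"
        )
    params = _theta_to_params(best.x, config)
    return FitResult(params=params, nll=float(best.fun),
                     converged=bool(best.success), start_table=start_table)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_cis(trials: pd.DataFrame, config: FitConfig | None = None,
                  fit: FitResult | None = None,
                  refit_starts: int = 1) -> dict:
    """Percentile 95% bootstrap intervals for parameters and curve summaries.

    Trials are resampled with replacement within each psychometric point
    (each (trial type, standard, comparison) cell keeps its n).  Per-curve
    PSE/threshold intervals come from cumulative-Gaussian refits of each
    resample; per-parameter intervals from warm-started refits of the full
    model.  Seeded by ``config.seed`` and reproducible.
    """
    if config is None:
        config = FitConfig()
    B = config.bootstrap_B
    if B == 0:
        warnings.warn("bootstrap_B = 0: returning empty intervals")
        return {"params": {}, "curves": {}}
    if fit is None:
        fit = fit_observer(trials, config)

    cells = trials_to_cells(trials)
    rng = np.random.default_rng(config.seed + 1)
    warm = _params_to_theta(fit.params, config)
    bounds = _theta_bounds(config)
    names = _theta_names(config)

    param_draws = []
    curve_draws: dict[tuple[str, float], list[tuple[float, float]]] = {}
    n_arr = cells["n"].to_numpy(dtype=float)
    p_hat = cells["k"].to_numpy(dtype=float) / n_arr

    for _ in range(B):
        k_boot = rng.binomial(n_arr.astype(int), p_hat).astype(float)
        boot = cells.copy()
        boot["k"] = k_boot

        for (tt, std), sub in boot.groupby(["trial_type", "standard_speed"]):
            pts = [PsychometricPoint(r.comparison_speed, r.n, r.k)
                   for r in sub.itertuples()]
            try:
                f = fit_cumulative_gaussian(pts)
                curve_draws.setdefault((tt, float(std)), []).append(
                    (f.pse, f.threshold))
            except ValueError:
                continue

        def objective(theta):
            try:
                return negative_log_likelihood(
                    boot, _theta_to_params(theta, config),
                    n_nodes=config.n_nodes, mode=config.mode)
            except (ValueError, FloatingPointError):
                return np.inf

        res = minimize(objective, warm, method="L-BFGS-B", bounds=bounds,
                       options={"gtol": config.gtol, "maxiter": config.maxiter})
        param_draws.append(res.x)

    draws = np.array(param_draws)
    param_ci = {}
    natural = {"log_a_R": "a_R", "log_c_R": "c_R", "log_a_T": "a_T",
               "log_c_T": "c_T", "log_sigma_p": "sigma_p",
               "log_sigma_p_T": "sigma_p_T"}
    for j, name in enumerate(names):
        col = draws[:, j]
        if name in natural:
            col = np.exp(col)
            name = natural[name]
        lo_q, hi_q = np.percentile(col, [2.5, 97.5])
        param_ci[name] = (float(lo_q), float(hi_q))

    curve_ci = {}
    for key, vals in curve_draws.items():
        arr = np.array(vals)
        pse_lo, pse_hi = np.percentile(arr[:, 0], [2.5, 97.5])
        thr_lo, thr_hi = np.percentile(arr[:, 1], [2.5, 97.5])
        curve_ci[key] = {"pse": (float(pse_lo), float(pse_hi)),
                         "threshold": (float(thr_lo), float(thr_hi))}
    return {"params": param_ci, "curves": curve_ci}


# ---------------------------------------------------------------------------
# Parameter-recovery harness
# ---------------------------------------------------------------------------

def run_parameter_recovery(truth: ObserverParams, design, n_replicates: int,
                           config: FitConfig | None = None,
                           seed: int = 0,
                           speed_grid=None) -> pd.DataFrame:
    """Simulate-and-refit experiment: one row of recovery metrics per replicate.

    Each replicate simulates a fresh trial table from ``truth`` under
    ``design``, fits the model, and records the relative error of sigma_p
    and the worst pointwise relative error of the fitted noise-SD curves
    sigma_R(v), sigma_T(v) over ``speed_grid`` (default: the design's
    standard speeds).
    """
    from .synthetic import simulate_observer  # local import to avoid cycle

    if config is None:
        config = FitConfig(n_starts=10)
    if speed_grid is None:
        speed_grid = sorted({s for speeds in design.standards.values()
                             for s in speeds})
    speed_grid = np.asarray(speed_grid, dtype=float)

    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_replicates) % (2 ** 31)
    for rep, rep_seed in enumerate(child_seeds):
        trials = simulate_observer(design, truth, seed=int(rep_seed),
                                   mode=config.mode)
        cfg = FitConfig(**{**config.__dict__, "seed": int(rep_seed)})
        result = fit_observer(trials, cfg)
        est = result.params
        sp_err = abs(est.prior.sigma_p - truth.prior.sigma_p) / truth.prior.sigma_p
        err_R = (np.abs(noise_sd(est.noise_R, speed_grid)
                        - noise_sd(truth.noise_R, speed_grid))
                 / noise_sd(truth.noise_R, speed_grid))
        err_T = (np.abs(noise_sd(est.noise_T, speed_grid)
                        - noise_sd(truth.noise_T, speed_grid))
                 / noise_sd(truth.noise_T, speed_grid))
        rows.append({"replicate": rep, "seed": int(rep_seed),
                     "nll": result.nll,
                     "sigma_p_hat": est.prior.sigma_p,
                     "sigma_p_rel_err": float(sp_err),
                     "sigma_R_max_rel_err": float(err_R.max()),
                     "sigma_T_max_rel_err": float(err_T.max()),
                     **{f"sigma_R_rel_err_v{v:g}": float(e)
                        for v, e in zip(speed_grid, err_R)},
                     **{f"sigma_T_rel_err_v{v:g}": float(e)
                        for v, e in zip(speed_grid, err_T)},
                     **{f"hat_{k}": v for k, v in est.to_dict().items()}})
    return pd.DataFrame(rows)
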