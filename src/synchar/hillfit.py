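"""Bayesian calibration of Hill dose-response models by parallel tempering.

Input sensors (chemically inducible promoters) follow the activatory Hill
equation

    f(x) = y_min + (y_max - y_min) * x^n / (k^n + x^n)

and NOT gates (repressor-based inverters) the inhibitory form

    f(x) = y_min + (y_max - y_min) * k^n / (k^n + x^n)

with theta = (y_max, y_min, n, k). y_min/y_max bound the output dynamic range
in RPU, k locates the transition region (inducer units for sensors, input RPU
for gates) and the Hill coefficient n sets its steepness.

Because both outputs and parameters span orders of magnitude, all differences
are taken in the natural-log domain. The likelihood factorizes over the
median dose-response points,

    p(D|theta) ∝ prod_i exp(-(log f(x_i) - log y_i)^2),

and the prior places flat-top log-domain bands on y_max (in
[y^_max, 2 y^_max]) and y_min (in [0.5 y^_min, y^_min]), where y^_max/y^_min
are the largest/smallest observed medians, with squared-distance decay
outside the band; n and k carry flat (improper) priors. The maximum a
posteriori configuration theta-hat is located by parallel tempering: several
independent walkers each run a ladder of Metropolis chains at increasing
temperatures, with state swaps proposed between adjacent rungs, and theta-hat
is the best configuration among every posterior evaluation performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

Mode = Literal["sensor", "gate"]

#: hard sampling bounds for the otherwise-flat priors on n and k; far wider
#: than any biologically plausible Hill coefficient or transition point
N_BOUNDS = (1e-2, 1e2)
K_BOUNDS = (1e-6, 1e6)


@dataclass(frozen=True)
class HillParams:
    """theta = (y_max, y_min, n, k); all strictly positive."""

    y_max: float
    y_min: float
    n: float
    k: float

    def __post_init__(self) -> None:
        for name in ("y_max", "y_min", "n", "k"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"HillParams.{name} must be finite and > 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.y_max, self.y_min, self.n, self.k], dtype=float)

    @staticmethod
    def from_array(a: np.ndarray) -> "HillParams":
        return HillParams(*(float(v) for v in a))


@dataclass
class DoseResponseDataset:
    """Calibration data D = {(x_i, y_i)}: inducer level (sensors) or input RPU
    (gates) against median output RPU."""

    x: np.ndarray
    y: np.ndarray
    mode: Mode = "sensor"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 4:
            raise ValueError("need at least 4 points to calibrate a 4-parameter model")
        if np.any(self.x < 0):
            raise ValueError("inputs x must be non-negative")
        if np.any(self.y <= 0):
            raise ValueError("outputs y must be strictly positive")
        if self.mode not in ("sensor", "gate"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def y_max_hat(self) -> float:
        return float(self.y.max())

    @property
    def y_min_hat(self) -> float:
        return float(self.y.min())


@dataclass
class CalibrationResult:
    theta_hat: HillParams
    log_posterior: float
    n_evaluations: int
    seed: int
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# model, prior, likelihood
# ---------------------------------------------------------------------------


def hill_activatory(x, theta: HillParams):
    """Activatory Hill response; non-decreasing from y_min (x=0) to y_max."""
    x = np.asarray(x, dtype=float)
    xn = np.power(x, theta.n)
    return theta.y_min + (theta.y_max - theta.y_min) * xn / (theta.k**theta.n + xn)


def hill_inhibitory(x, theta: HillParams):
    """Inhibitory Hill response; non-increasing from y_max (x=0) to y_min."""
    x = np.asarray(x, dtype=float)
    kn = theta.k**theta.n
    return theta.y_min + (theta.y_max - theta.y_min) * kn / (kn + np.power(x, theta.n))


def hill_response(x, theta: HillParams, mode: Mode):
    return hill_activatory(x, theta) if mode == "sensor" else hill_inhibitory(x, theta)


def band_distance(x: float, x_low: float, x_high: float) -> float:
    """phi(x, x_l, x_h): 0 inside [x_l, x_h], distance to the nearest edge outside."""
    if x_low <= x <= x_high:
        return 0.0
    return min(abs(x - x_high), abs(x - x_low))


def log_prior(theta: HillParams, y_max_hat: float, y_min_hat: float) -> float:
    """Log prior density (up to a constant) for theta given the observed
    extremes. y_max is most plausible in [y^_max, 2 y^_max] and y_min in
    [0.5 y^_min, y^_min]; n and k are flat."""
    if not (y_max_hat >= y_min_hat > 0):
        raise ValueError("need y_max_hat >= y_min_hat > 0")
    pen_max = band_distance(
        math.log(theta.y_max), math.log(y_max_hat), math.log(2 * y_max_hat)
    )
    pen_min = band_distance(
        math.log(theta.y_min), math.log(0.5 * y_min_hat), math.log(y_min_hat)
    )
    return -(pen_max**2) - (pen_min**2)


def log_likelihood(theta: HillParams, data: DoseResponseDataset) -> float:
    """Factorized log-domain likelihood: -sum_i (log f(x_i) - log y_i)^2."""
    f = hill_response(data.x, theta, data.mode)
    resid = np.log(f) - np.log(data.y)
    return float(-np.sum(resid**2))


def log_posterior(theta: HillParams, data: DoseResponseDataset) -> float:
    return log_prior(theta, data.y_max_hat, data.y_min_hat) + log_likelihood(theta, data)


def initial_theta(data: DoseResponseDataset, mode: Mode | None = None) -> HillParams:
    """theta_0 = (y^_max, y^_max, n_0, k_0) with n_0 = 2 and k_0 = 1 for
    sensors or k_0 = 0.01 for gates."""
    mode = mode or data.mode
    k0 = 1.0 if mode == "sensor" else 0.01
    return HillParams(data.y_max_hat, data.y_max_hat, 2.0, k0)


# ---------------------------------------------------------------------------
# vectorized posterior over batches of log-parameters
# ---------------------------------------------------------------------------


def _log_posterior_batch(log_theta: np.ndarray, data: DoseResponseDataset) -> np.ndarray:
    """Log posterior for an (..., 4) array of log-domain parameter vectors.

    Configurations with n or k outside the sampling bounds get -inf.
    """
    ly_max, ly_min, ln, lk = np.moveaxis(log_theta, -1, 0)
    n = np.exp(ln)
    k = np.exp(lk)
    y_max = np.exp(ly_max)
    y_min = np.exp(ly_min)

    lo_n, hi_n = N_BOUNDS
    lo_k, hi_k = K_BOUNDS
    valid = (n > lo_n) & (n < hi_n) & (k > lo_k) & (k < hi_k)

    # the Hill fraction x^n/(k^n+x^n) is a logistic in n*(log x - log k);
    # evaluating it through expit avoids overflow of k^n / x^n
    with np.errstate(divide="ignore"):
        lx = np.log(data.x)  # x = 0 maps to -inf, handled exactly by expit
    t = n[..., None] * (lk[..., None] - lx)
    frac = expit(-t) if data.mode == "sensor" else expit(t)
    f = y_min[..., None] + (y_max - y_min)[..., None] * frac
    ll = -np.sum((np.log(np.maximum(f, 1e-300)) - np.log(data.y)) ** 2, axis=-1)

    lgm = math.log(data.y_max_hat)
    lg2m = math.log(2 * data.y_max_hat)
    lghalf = math.log(0.5 * data.y_min_hat)
    lgmin = math.log(data.y_min_hat)
    pen_max = np.where(
        (ly_max >= lgm) & (ly_max <= lg2m),
        0.0,
        np.minimum(np.abs(ly_max - lg2m), np.abs(ly_max - lgm)),
    )
    pen_min = np.where(
        (ly_min >= lghalf) & (ly_min <= lgmin),
        0.0,
        np.minimum(np.abs(ly_min - lgmin), np.abs(ly_min - lghalf)),
    )
    lp = ll - pen_max**2 - pen_min**2
    return np.where(valid, lp, -np.inf)


# ---------------------------------------------------------------------------
# parallel tempering
# ---------------------------------------------------------------------------


def swap_log_acceptance(
    beta_cold: float, beta_hot: float, lp_cold: float, lp_hot: float
) -> float:
    """Log acceptance probability for exchanging states between two rungs.

    The tempered target at inverse temperature beta is pi(theta)^beta; the
    exchange ratio is exp((beta_cold - beta_hot) * (lp_hot - lp_cold)),
    which preserves detailed balance at both rungs.
    """
    return min(0.0, (beta_cold - beta_hot) * (lp_hot - lp_cold))


def temperature_ladder(chains: int, t_max: float = 50.0) -> np.ndarray:
    """Geometric ladder of temperatures from 1 to ``t_max``."""
    if chains == 1:
        return np.array([1.0])
    return np.geomspace(1.0, t_max, chains)


def parallel_tempering(
    data: DoseResponseDataset,
    theta0: HillParams,
    walkers: int = 10,
    chains: int = 10,
    steps: int = 10_000,
    seed: int = 0,
    t_max: float = 50.0,
    cold_step: float = 0.05,
    extra_candidates: Sequence[HillParams] = (),
) -> CalibrationResult:
    """Locate the MAP estimate by parallel-tempering MCMC.

    Each of ``walkers`` independent walkers runs ``chains`` Metropolis chains
    on a geometric temperature ladder between T=1 and ``t_max``. Proposals are
    isotropic Gaussian steps on (log y_max, log y_min, log n, log k) with
    standard deviation ``cold_step * sqrt(T)``; after every Metropolis sweep a
    state swap is proposed between each pair of adjacent rungs. theta-hat is
    the configuration with the highest log posterior among *all* evaluations
    (accepted or not, any temperature); ``extra_candidates`` are evaluated up
    front and eligible for theta-hat as well. Fully reproducible given
    ``seed``.
    """
    if min(walkers, chains, steps) < 1:
        raise ValueError("walkers, chains and steps must all be >= 1")
    rng = np.random.default_rng(seed)
    temps = temperature_ladder(chains, t_max)
    betas = 1.0 / temps  # (C,)
    step_sizes = cold_step * np.sqrt(temps)  # (C,)

    state = np.tile(np.log(theta0.as_array()), (walkers, chains, 1))  # (W, C, 4)
    lp = _log_posterior_batch(state, data)  # (W, C)
    n_eval = state.shape[0] * state.shape[1]

    best_lp = float(lp.max())
    best_theta = state.reshape(-1, 4)[int(lp.argmax())].copy()
    for cand in extra_candidates:
        l = np.log(cand.as_array())
        clp = float(_log_posterior_batch(l[None, :], data)[0])
        n_eval += 1
        if clp > best_lp:
            best_lp, best_theta = clp, l.copy()

    n_accept_cold = 0
    n_swap_accept = 0
    n_swap_prop = 0
    stagnant = 0
    max_stagnant = 0

    for _ in range(steps):
        prop = state + rng.normal(size=state.shape) * step_sizes[None, :, None]
        lp_prop = _log_posterior_batch(prop, data)
        n_eval += walkers * chains
        # track the global optimum over every evaluated configuration
        m = int(lp_prop.argmax())
        if lp_prop.ravel()[m] > best_lp:
            best_lp = float(lp_prop.ravel()[m])
            best_theta = prop.reshape(-1, 4)[m].copy()
        log_u = np.log(rng.random(size=lp.shape))
        accept = log_u < betas[None, :] * (lp_prop - lp)
        state = np.where(accept[..., None], prop, state)
        lp = np.where(accept, lp_prop, lp)

        cold_acc = int(accept[:, 0].sum())
        n_accept_cold += cold_acc
        if cold_acc == 0:
            stagnant += 1
            max_stagnant = max(max_stagnant, stagnant)
        else:
            stagnant = 0

        # adjacent-rung swap sweep (vectorized over walkers)
        for c in range(chains - 1):
            log_alpha = (betas[c] - betas[c + 1]) * (lp[:, c + 1] - lp[:, c])
            do_swap = np.log(rng.random(size=walkers)) < log_alpha
            n_swap_prop += walkers
            n_swap_accept += int(do_swap.sum())
            if do_swap.any():
                tmp = state[do_swap, c].copy()
                state[do_swap, c] = state[do_swap, c + 1]
                state[do_swap, c + 1] = tmp
                lp[do_swap, c], lp[do_swap, c + 1] = (
                    lp[do_swap, c + 1],
                    lp[do_swap, c].copy(),
                )

    diagnostics = {
        "cold_acceptance_rate": n_accept_cold / (walkers * steps),
        "swap_acceptance_rate": n_swap_accept / max(n_swap_prop, 1),
        "max_consecutive_cold_rejections": max_stagnant,
        "stagnation_warning": max_stagnant >= 1000,
        "temperatures": temps.tolist(),
    }
    theta_hat = HillParams.from_array(np.exp(best_theta))
    if theta_hat.y_max < theta_hat.y_min:
        diagnostics["y_order_warning"] = (
            "theta_hat has y_max < y_min; the ordering is not enforced during sampling"
        )
    return CalibrationResult(theta_hat, best_lp, n_eval, seed, diagnostics)


def calibrate(
    data: DoseResponseDataset,
    mode: Mode | None = None,
    seed: int = 0,
    walkers: int = 10,
    chains: int = 10,
    steps: int = 10_000,
    **kwargs,
) -> CalibrationResult:
    """Fit the mode-appropriate Hill model to one dose-response dataset.

    Sensors use the activatory form with k_0 = 1 (inducer units); gates use
    the inhibitory form with k_0 = 0.01 RPU. Calibration is independent per
    dataset.
    """
    if mode is not None and mode != data.mode:
        data = DoseResponseDataset(data.x, data.y, mode)
    theta0 = initial_theta(data)
    return parallel_tempering(
        data, theta0, walkers=walkers, chains=chains, steps=steps, seed=seed, **kwargs
    )
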