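"""Parametric failure-time families and their residual-lifetime laws.

Under the stationarity assumption, the density of a residual lifetime
(forward recurrence time) sampled on a prevalence day is

    f_res(t) = S_U(t) / mu,

where ``S_U`` is the underlying (unbiased) failure-time survival function and
``mu = E(T)`` its mean.  This module provides the supported parametric
families, their induced residual density and residual survival

    S_res(t) = int_t^inf S_U(x) dx / mu,

the censored-data residual log-likelihood

    l(theta) = sum_i  d_i * log f_res(v_i; theta)
             + (1 - d_i) * log S_res(v_i; theta),

and maximum-likelihood fitting of that likelihood.

All residual-survival expressions are closed forms built from incomplete
gamma/beta functions and the normal CDF, so the likelihood is cheap and
smooth inside the optimizer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "SUPPORTED_FAMILIES",
    "PARAM_NAMES",
    "FamilySpec",
    "FittedParametricModel",
    "ParameterDomainError",
    "InfiniteMeanError",
    "DegenerateDataError",
    "underlying_survival",
    "underlying_mean",
    "residual_density",
    "residual_survival",
    "residual_loglik",
    "fit_parametric",
]

logger = logging.getLogger(__name__)

SUPPORTED_FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal", "gamma")

#: Natural parameterization of each family, in order.
PARAM_NAMES = {
    "exponential": ("mean",),
    "weibull": ("shape", "scale"),
    "loglogistic": ("shape", "scale"),
    "lognormal": ("meanlog", "sdlog"),
    "gamma": ("shape", "scale"),
}

# Log-logistic shapes at or below 1 have infinite mean; fits are kept
# strictly above this bound so Eq. f_res = S_U/mu stays well defined.
LOGLOGISTIC_SHAPE_FLOOR = 1.0 + 1e-6


class ParameterDomainError(ValueError):
    """A parameter lies outside the family's domain."""


class InfiniteMeanError(ValueError):
    """The parameter point has an infinite mean, so no residual law exists."""


class DegenerateDataError(ValueError):
    """The data cannot identify the requested estimator (e.g. no events)."""


@dataclass(frozen=True)
class FamilySpec:
    """A named parametric family at a specific parameter point.

    Parameters use each family's natural parameterization: (shape, scale)
    for weibull / loglogistic / gamma, (meanlog, sdlog) for lognormal and
    (mean,) for exponential.  Positivity of scale-type parameters is checked
    at construction; finiteness of the mean is checked by the operations
    that need it (`underlying_mean` and everything residual), so that
    infinite-mean points remain constructible for pure sampling purposes.
    """

    family_id: str
    theta: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family_id not in SUPPORTED_FAMILIES:
            raise ParameterDomainError(
                f"unknown family {self.family_id!r}; supported: {SUPPORTED_FAMILIES}"
            )
        theta = tuple(float(x) for x in self.theta)
        object.__setattr__(self, "theta", theta)
        names = PARAM_NAMES[self.family_id]
        if len(theta) != len(names):
            raise ParameterDomainError(
                f"{self.family_id} expects parameters {names}, got {len(theta)} values"
            )
        for name, value in zip(names, theta):
            if not math.isfinite(value):
                raise ParameterDomainError(f"{self.family_id} {name} must be finite")
            if name != "meanlog" and value <= 0.0:
                raise ParameterDomainError(
                    f"{self.family_id} {name} must be strictly positive, got {value}"
                )

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES[self.family_id], self.theta))

    def frozen(self) -> stats.rv_continuous:
        """The scipy frozen distribution of the underlying failure time."""
        p = self.params
        if self.family_id == "exponential":
            return stats.expon(scale=p["mean"])
        if self.family_id == "weibull":
            return stats.weibull_min(p["shape"], scale=p["scale"])
        if self.family_id == "loglogistic":
            return stats.fisk(p["shape"], scale=p["scale"])
        if self.family_id == "lognormal":
            return stats.lognorm(p["sdlog"], scale=math.exp(p["meanlog"]))
        return stats.gamma(p["shape"], scale=p["scale"])


@dataclass(frozen=True)
class FittedParametricModel:
    """MLE of a parametric family under the residual-lifetime likelihood."""

    spec: FamilySpec
    loglik: float
    converged: bool
    n_obs: int
    n_events: int

    def residual_survival(self, t):
        return residual_survival(self.spec, t)

    def underlying_survival(self, t):
        return underlying_survival(self.spec, t)


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t


def underlying_survival(spec: FamilySpec, t):
    """S_U(t; theta): survival function of the underlying failure time."""
    t = _check_times(t)
    p = spec.params
    if spec.family_id == "exponential":
        out = np.exp(-t / p["mean"])
    elif spec.family_id == "weibull":
        with np.errstate(over="ignore"):
            out = np.exp(-((t / p["scale"]) ** p["shape"]))
    elif spec.family_id == "loglogistic":
        with np.errstate(over="ignore"):
            out = 1.0 / (1.0 + (t / p["scale"]) ** p["shape"])
    elif spec.family_id == "lognormal":
        with np.errstate(divide="ignore"):
            z = (p["meanlog"] - np.log(t)) / p["sdlog"]
        out = special.ndtr(z)
    else:  # gamma
        out = special.gammaincc(p["shape"], t / p["scale"])
    return out if out.ndim else float(out)


def underlying_mean(spec: FamilySpec) -> float:
    """mu(theta) = E(T) = int_0^inf S_U(x) dx; errors on infinite-mean points."""
    p = spec.params
    if spec.family_id == "exponential":
        return p["mean"]
    if spec.family_id == "weibull":
        return p["scale"] * math.gamma(1.0 + 1.0 / p["shape"])
    if spec.family_id == "loglogistic":
        b = p["shape"]
        if b <= 1.0:
            raise InfiniteMeanError(
                f"loglogistic shape={b} has infinite mean (requires shape > 1)"
            )
        return p["scale"] * (math.pi / b) / math.sin(math.pi / b)
    if spec.family_id == "lognormal":
        return math.exp(p["meanlog"] + 0.5 * p["sdlog"] ** 2)
    return p["shape"] * p["scale"]


def residual_density(spec: FamilySpec, t):
    """f_res(t) = S_U(t)/mu: the stationary residual-lifetime density.

    Non-increasing in t because S_U is; f_res(0) = 1/mu.
    """
    mu = underlying_mean(spec)
    s = underlying_survival(spec, t)
    return s / mu


def residual_survival(spec: FamilySpec, t):
    """S_res(t) = int_t^inf S_U(x) dx / mu, via partial-expectation closed forms.

    Each expression is E[(T - t)^+] / mu written with regularized incomplete
    gamma/beta functions, so no quadrature enters the likelihood.
    """
    t = _check_times(t)
    p = spec.params
    mu = underlying_mean(spec)
    if spec.family_id == "exponential":
        out = np.exp(-t / p["mean"])
    elif spec.family_id == "weibull":
        k = p["shape"]
        with np.errstate(over="ignore", divide="ignore"):
            logx = k * np.log(t / p["scale"])
            out = special.gammaincc(1.0 / k, np.exp(np.minimum(logx, 700.0)))
            # (t/scale)^k underflows for large shapes; there
            # P(a, x) ~ x^a / Gamma(a+1) with x^a = t/scale exactly
            tiny = np.atleast_1d(logx) < -600.0
            if tiny.any():
                t1 = np.atleast_1d(t)
                small = 1.0 - (t1[tiny] / p["scale"]) / math.gamma(1.0 + 1.0 / k)
                out = np.atleast_1d(out)
                out[tiny] = small
                out = out.reshape(np.shape(t))
    elif spec.family_id == "loglogistic":
        b = p["shape"]
        with np.errstate(over="ignore"):
            x = (t / p["scale"]) ** b
            z = np.where(np.isinf(x), 1.0, x / (1.0 + x))
        out = special.betaincc(1.0 / b, 1.0 - 1.0 / b, z)
    elif spec.family_id == "lognormal":
        m, s = p["meanlog"], p["sdlog"]
        with np.errstate(divide="ignore"):
            logt = np.log(t)
        out = special.ndtr((m + s * s - logt) / s) - (t / mu) * special.ndtr(
            (m - logt) / s
        )
    else:  # gamma
        a, s = p["shape"], p["scale"]
        out = special.gammaincc(a + 1.0, t / s) - (t / mu) * special.gammaincc(
            a, t / s
        )
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def residual_loglik(spec: FamilySpec, v, delta) -> float:
    """Censored residual-lifetime log-likelihood.

    ``v`` are residual times, ``delta`` the event indicators.  Returns -inf
    when an observation falls where its density/survival term vanishes.
    """
    v = _check_times(np.atleast_1d(v))
    delta = np.atleast_1d(np.asarray(delta))
    if v.size == 0:
        raise ValueError("data must be non-empty")
    if v.shape != delta.shape:
        raise ValueError("time and event arrays must have equal length")
    ev = delta.astype(bool)
    with np.errstate(divide="ignore"):
        total = 0.0
        if ev.any():
            total += float(np.sum(np.log(residual_density(spec, v[ev]))))
        if (~ev).any():
            total += float(np.sum(np.log(residual_survival(spec, v[~ev]))))
    return total


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _moment_inits(family_id: str, v: np.ndarray) -> list[np.ndarray]:
    """Three deterministic moment-style starting points per family.

    Residual data are length-biased toward small values relative to the
    underlying law, so starts bracket the sample scale from below and above.
    """
    m = float(np.mean(v))
    m = max(m, 1e-8)
    sd = float(np.std(v)) or m
    if family_id == "exponential":
        return [np.array([x]) for x in (m, 2.0 * m, 0.5 * m)]
    if family_id == "weibull":
        # anchor at the Weibull method-of-moments point (CV power
        # approximation) with modest flanks
        k0 = float(np.clip((sd / m) ** -1.086, 0.3, 10.0))
        s0 = m / math.gamma(1.0 + 1.0 / k0)
        return [
            np.array([k0, s0]),
            np.array([1.5 * k0, s0]),
            np.array([k0 / 1.5, 1.5 * s0]),
        ]
    if family_id == "loglogistic":
        return [
            np.array([1.5, m]),
            np.array([3.0, 2.0 * m]),
            np.array([1.1, 0.5 * m]),
        ]
    if family_id == "lognormal":
        lm = math.log(m)
        return [
            np.array([lm, 1.0]),
            np.array([lm + 0.5, 0.5]),
            np.array([lm - 0.5, 1.5]),
        ]
    # gamma
    shape0 = max((m / sd) ** 2, 0.2)
    return [
        np.array([1.0, m]),
        np.array([shape0, m / shape0]),
        np.array([0.5, 2.0 * m]),
    ]


def _to_internal(family_id: str, theta: np.ndarray) -> np.ndarray:
    """Map natural parameters to the unconstrained optimization scale."""
    x = np.array(theta, dtype=float)
    if family_id == "lognormal":
        return np.array([x[0], math.log(x[1])])
    if family_id == "loglogistic":
        return np.array([math.log(max(x[0] - LOGLOGISTIC_SHAPE_FLOOR, 1e-6)),
                         math.log(x[1])])
    return np.log(x)


def _from_internal(family_id: str, x: np.ndarray) -> np.ndarray:
    x = np.clip(x, -700.0, 700.0)  # keep exp() finite; FamilySpec rejects the rest
    if family_id == "lognormal":
        return np.array([x[0], math.exp(x[1])])
    if family_id == "loglogistic":
        return np.array([LOGLOGISTIC_SHAPE_FLOOR + math.exp(x[0]), math.exp(x[1])])
    return np.exp(x)


def fit_parametric(
    family_id: str,
    v,
    delta,
    init: Sequence[float] | None = None,
) -> FittedParametricModel:
    """Fit a family to censored residual lifetimes by maximum likelihood.

    Optimization runs on log-transformed positive parameters (raw meanlog)
    with L-BFGS-B from three deterministic moment-style starts (plus
    ``init`` if given); the best local maximizer is returned.  All-censored
    data raise :class:`DegenerateDataError`; non-convergence of every start
    is reported through ``converged=False``, never silently.
    """
    if family_id not in SUPPORTED_FAMILIES:
        raise ParameterDomainError(
            f"unknown family {family_id!r}; supported: {SUPPORTED_FAMILIES}"
        )
    v = _check_times(np.atleast_1d(v))
    delta = np.atleast_1d(np.asarray(delta))
    n = v.size
    n_events = int(np.sum(delta))
    if n_events == 0:
        raise DegenerateDataError(
            "cannot fit a residual-lifetime MLE with zero events"
        )

    def neg_loglik(x: np.ndarray) -> float:
        theta = _from_internal(family_id, x)
        try:
            spec = FamilySpec(family_id, tuple(theta))
            ll = residual_loglik(spec, v, delta)
        except (ParameterDomainError, InfiniteMeanError, OverflowError):
            return 1e12
        if not math.isfinite(ll):
            return 1e12
        return -ll

    starts = [np.asarray(init, dtype=float)] if init is not None else []
    starts += _moment_inits(family_id, v)

    best = None
    any_converged = False
    for theta0 in starts:
        try:
            x0 = _to_internal(family_id, theta0)
        except (ValueError, OverflowError):
            continue
        res = optimize.minimize(
            neg_loglik, x0, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)
    if best is None or not math.isfinite(best.fun) or best.fun >= 1e12:
        raise DegenerateDataError(
            f"{family_id} likelihood could not be evaluated at any starting point"
        )
    theta_hat = tuple(_from_internal(family_id, best.x))
    spec = FamilySpec(family_id, theta_hat)
    if not any_converged:
        logger.warning("fit_parametric(%s): no start converged cleanly", family_id)
    return FittedParametricModel(
        spec=spec,
        loglik=-float(best.fun),
        converged=any_converged,
        n_obs=n,
        n_events=n_events,
    )
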