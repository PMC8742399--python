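"""Stacked survival estimation for right-censored residual lifetimes.

A stack is a convex combination of submodel residual-survival estimators,

    S_res_stack(t) = sum_k alpha_k * S_res_k(t),    alpha on the simplex,

with weights chosen to minimize a cross-validated Brier score in which each
subject-time contribution is inversely weighted by the Kaplan-Meier estimate
of the censoring survival (IPCW).  The same weights combine the submodels'
plug-in underlying-survival estimates into the stacked underlying survival.

Submodels are the parametric residual-lifetime MLEs of
:mod:`reslife.families` and the corrected NPMLE of :mod:`reslife.npmle`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter

from . import families, npmle
from .families import DegenerateDataError, FittedParametricModel
from .npmle import NPMLEFit

__all__ = [
    "DEFAULT_MODELS",
    "EvaluationGrid",
    "CensoringSurvival",
    "WeightVector",
    "StackedFit",
    "default_grid",
    "censoring_km",
    "ipcw_brier",
    "cv_predictions",
    "optimize_weights",
    "stack_fit",
    "stack_survival",
    "bootstrap_bands",
]

logger = logging.getLogger(__name__)

DEFAULT_MODELS = ("weibull", "loglogistic", "lognormal", "gamma", "npmle")
DEFAULT_GRID_SIZE = 9
DEFAULT_FOLDS = 5


class WeightDegeneracyError(RuntimeError):
    """The censoring survival vanishes where an IPCW weight is required."""


@dataclass(frozen=True)
class EvaluationGrid:
    """Strictly increasing positive evaluation times for the Brier score."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size == 0:
            raise ValueError("grid needs at least one point")
        if pts[0] <= 0 or np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing and positive")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.size


def default_grid(v, size: int = DEFAULT_GRID_SIZE) -> EvaluationGrid:
    """Equally spaced interior points t_r = r * V_max / (size + 1).

    With the default ``size=9`` this covers the observed residual-lifetime
    support while excluding both 0 and the frontier V_max, where the
    censoring-survival estimate can vanish.
    """
    vmax = float(np.max(np.asarray(v, dtype=float)))
    if vmax <= 0:
        raise ValueError("all residual times are zero")
    r = np.arange(1, size + 1, dtype=float)
    return EvaluationGrid(r * vmax / (size + 1))


class CensoringSurvival:
    """Right-continuous step estimate of G(t) = P(C > t), with left limits."""

    def __init__(self, times: np.ndarray, values: np.ndarray):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("step times must strictly increase")
        if np.any(values < -1e-12) or np.any(values > 1 + 1e-12) or np.any(
            np.diff(values) > 1e-12
        ):
            raise ValueError("G must be non-increasing within [0,1]")
        self.times = times  # jump locations, > 0
        self.values = values  # G(t) for t in [times[j], times[j+1])

    def __call__(self, t):
        """G(t), right-continuous."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.values[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def left(self, t):
        """G(t-): the value just before t (1 at and below the first jump)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(idx < 0, 1.0, self.values[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)


def censoring_km(v, delta) -> CensoringSurvival:
    """Kaplan-Meier estimator of the residual censoring-time survival.

    Censorings (delta = 0) are the events of interest; failures (delta = 1)
    censor the censoring time.  G_hat(0) = 1 by construction.
    """
    v = np.asarray(v, dtype=float)
    delta = np.asarray(delta).astype(int)
    if v.size == 0:
        raise ValueError("data must be non-empty")
    km = KaplanMeierFitter()
    km.fit(v, event_observed=1 - delta)
    sf = km.survival_function_
    times = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)
    pos = times > 0
    return CensoringSurvival(times[pos], vals[pos])


@dataclass(frozen=True)
class WeightVector:
    """Simplex weights over the ordered submodel list."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
            raise ValueError("weights must lie in [0,1]")
        if abs(a.sum() - 1.0) > 1e-8:
            raise ValueError(f"weights must sum to 1, got {a.sum()}")
        object.__setattr__(self, "alpha", a)

    def __len__(self) -> int:
        return self.alpha.size


def _ipcw_weights(v, delta, grid: EvaluationGrid, G: CensoringSurvival) -> np.ndarray:
    """Graf-style IPCW weight matrix w[i, r] for the Brier score.

    Subjects failing by t_r weigh 1/G(V_i-); subjects still at risk weigh
    1/G(t_r); subjects censored by t_r contribute nothing.
    """
    v = np.asarray(v, dtype=float)
    delta = np.asarray(delta).astype(bool)
    t = grid.points
    at_risk = v[:, None] > t[None, :]
    failed = (~at_risk) & delta[:, None]
    w = np.zeros((v.size, t.size))
    g_t = np.asarray(G(t), dtype=float)
    if np.any((g_t <= 0) & at_risk.any(axis=0)):
        bad = t[(g_t <= 0) & at_risk.any(axis=0)][0]
        raise WeightDegeneracyError(
            f"censoring survival is 0 at grid point t={bad}; IPCW undefined"
        )
    w[at_risk] = np.broadcast_to(1.0 / g_t, at_risk.shape)[at_risk]
    g_vm = np.asarray(G.left(v), dtype=float)
    if np.any((g_vm <= 0) & failed.any(axis=1)):
        bad = v[(g_vm <= 0) & failed.any(axis=1)][0]
        raise WeightDegeneracyError(
            f"censoring survival is 0 just before event time {bad}; IPCW undefined"
        )
    w[failed] = np.broadcast_to(
        np.where(g_vm > 0, 1.0 / g_vm, 0.0)[:, None], failed.shape
    )[failed]
    return w


def ipcw_brier(pred, v, delta, grid: EvaluationGrid, G: CensoringSurvival) -> float:
    """IPCW Brier score of a [subject x grid point] prediction matrix."""
    pred = np.asarray(pred, dtype=float)
    v = np.asarray(v, dtype=float)
    if pred.shape != (v.size, len(grid)):
        raise ValueError("prediction matrix must be subjects x grid points")
    if np.any(pred < -1e-12) or np.any(pred > 1 + 1e-12):
        raise ValueError("predictions must lie in [0,1]")
    w = _ipcw_weights(v, delta, grid, G)
    z = (v[:, None] > grid.points[None, :]).astype(float)
    return float(np.sum(w * (z - pred) ** 2))


# ---------------------------------------------------------------------------
# Submodel fitting / prediction dispatch
# ---------------------------------------------------------------------------

def _fit_submodel(label: str, v, delta):
    if label == "npmle":
        return npmle.fit_npmle(v, delta)
    return families.fit_parametric(label, v, delta)


def _predict(model, t, scale: str):
    if scale not in ("residual", "underlying"):
        raise ValueError("scale must be 'residual' or 'underlying'")
    if isinstance(model, NPMLEFit):
        return (model.residual_survival(t) if scale == "residual"
                else model.underlying_survival(t))
    if isinstance(model, FittedParametricModel):
        return (model.residual_survival(t) if scale == "residual"
                else model.underlying_survival(t))
    raise TypeError(f"unknown submodel type {type(model)!r}")


def _stratified_folds(delta: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic fold labels, stratified by event indicator."""
    rng = np.random.default_rng(seed)
    n = delta.size
    fold = np.empty(n, dtype=int)
    for group in (True, False):
        idx = np.nonzero(delta.astype(bool) == group)[0]
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def cv_predictions(
    v,
    delta,
    models: Sequence[str] = DEFAULT_MODELS,
    grid: EvaluationGrid | None = None,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> np.ndarray:
    """Held-out residual-survival predictions, shape (n, m, s).

    Subject i's predictions come from submodels refit with i's fold held
    out; folds are stratified by the event indicator so every training set
    contains events.  A submodel that fails on a training fold falls back
    to its full-data fit (logged).
    """
    v = np.asarray(v, dtype=float)
    delta = np.asarray(delta).astype(int)
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    n_folds = min(n_folds, v.size)
    if grid is None:
        grid = default_grid(v)
    fold = _stratified_folds(delta, n_folds, seed)
    full_fits = {m: _fit_submodel(m, v, delta) for m in models}
    pred = np.empty((v.size, len(models), len(grid)))
    for f in range(n_folds):
        test = fold == f
        train = ~test
        if not test.any():
            continue
        for k, label in enumerate(models):
            try:
                fit = _fit_submodel(label, v[train], delta[train])
            except (DegenerateDataError, ValueError) as exc:
                logger.warning(
                    "cv_predictions: %s failed on fold %d (%s); using full-data fit",
                    label, f, exc)
                fit = full_fits[label]
            pred[test, k, :] = _predict(fit, grid.points, "residual")
    return np.clip(pred, 0.0, 1.0)


def optimize_weights(pred, v, delta, grid: EvaluationGrid,
                     G: CensoringSurvival) -> WeightVector:
    """Minimize the IPCW Brier score over the probability simplex.

    The objective is the quadratic a' Q a - 2 b' a (plus a constant) with
    Q = P' W P.  The exact minimizer is found by enumerating the 2^m - 1
    candidate supports: on each support the equality-constrained
    least-squares solution is obtained from the KKT system, feasible
    candidates are scored, and the best is returned.  Deterministic, with
    near-singular supports solved by the minimum-norm least-squares rule.
    """
    pred = np.asarray(pred, dtype=float)
    v = np.asarray(v, dtype=float)
    n, m, s = pred.shape
    if m == 1:
        return WeightVector(np.array([1.0]))
    if m > 12:
        raise ValueError("support enumeration is intended for small stacks")
    w = _ipcw_weights(v, delta, grid, G)  # (n, s)
    z = (v[:, None] > grid.points[None, :]).astype(float)
    P = pred.transpose(0, 2, 1).reshape(n * s, m)
    wf = w.reshape(n * s)
    zf = z.reshape(n * s)
    Q = P.T @ (wf[:, None] * P)
    b = P.T @ (wf * zf)
    const = float(np.sum(wf * zf * zf))

    def obj(a):
        return float(a @ Q @ a - 2.0 * b @ a + const)

    best_alpha = None
    best_obj = np.inf
    for mask in range(1, 2**m):
        support = [k for k in range(m) if mask >> k & 1]
        msz = len(support)
        kkt = np.zeros((msz + 1, msz + 1))
        kkt[:msz, :msz] = 2.0 * Q[np.ix_(support, support)]
        kkt[:msz, msz] = 1.0
        kkt[msz, :msz] = 1.0
        rhs = np.concatenate([2.0 * b[support], [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        a_sup = sol[:msz]
        if np.any(a_sup < -1e-10) or abs(a_sup.sum() - 1.0) > 1e-6:
            continue
        alpha = np.zeros(m)
        alpha[support] = np.clip(a_sup, 0.0, None)
        alpha /= alpha.sum()
        val = obj(alpha)
        if val < best_obj - 1e-12:
            best_obj = val
            best_alpha = alpha
    if best_alpha is None:  # pathological Q: fall back to the best vertex
        logger.warning("optimize_weights: no feasible support solution; "
                       "returning the best vertex")
        best_alpha = min((np.eye(m)[k] for k in range(m)), key=obj)
    return WeightVector(best_alpha)


@dataclass(frozen=True)
class StackedFit:
    """An ordered submodel list with optimized simplex weights."""

    labels: tuple[str, ...]
    submodels: tuple
    weights: WeightVector
    grid: EvaluationGrid
    objective_value: float
    seed: int = 0
    n_folds: int = DEFAULT_FOLDS
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.submodels):
            raise ValueError("one weight per submodel required")

    def survival(self, t, scale: str = "underlying"):
        return stack_survival(self, t, scale)

    def weight_table(self) -> dict[str, float]:
        return dict(zip(self.labels, self.weights.alpha.tolist()))


def stack_survival(fit: StackedFit, t, scale: str = "underlying"):
    """Convex combination of submodel survival curves on either scale."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape if t.ndim else ())
    for a, model in zip(fit.weights.alpha, fit.submodels):
        out = out + a * np.asarray(_predict(model, t, scale))
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(out) else float(out)


def stack_fit(
    v,
    delta,
    models: Sequence[str] = DEFAULT_MODELS,
    n_folds: int = DEFAULT_FOLDS,
    grid: EvaluationGrid | None = None,
    seed: int = 0,
) -> StackedFit:
    """End-to-end stacking pipeline on one dataset.

    Fits every submodel on the full data, computes stratified K-fold
    held-out predictions on the evaluation grid, estimates the censoring
    survival by Kaplan-Meier, and optimizes the IPCW-Brier weights.
    """
    v = np.asarray(v, dtype=float)
    delta = np.asarray(delta).astype(int)
    if len(models) < 1:
        raise ValueError("need at least one submodel")
    if len(set(models)) != len(models):
        raise ValueError("duplicate submodel labels")
    if grid is None:
        grid = default_grid(v)
    full_fits = tuple(_fit_submodel(mlabel, v, delta) for mlabel in models)
    pred = cv_predictions(v, delta, models, grid=grid, n_folds=n_folds, seed=seed)
    G = censoring_km(v, delta)
    weights = optimize_weights(pred, v, delta, grid, G)
    stacked_pred = np.einsum("k,nks->ns", weights.alpha, pred)
    objective = ipcw_brier(np.clip(stacked_pred, 0, 1), v, delta, grid, G)
    return StackedFit(
        labels=tuple(models),
        submodels=full_fits,
        weights=weights,
        grid=grid,
        objective_value=objective,
        seed=seed,
        n_folds=n_folds,
    )


def bootstrap_bands(
    v,
    delta,
    models: Sequence[str] = DEFAULT_MODELS,
    B: int = 500,
    time_grid=None,
    seed: int = 0,
    scale: str = "underlying",
    n_folds: int = DEFAULT_FOLDS,
    level: float = 0.95,
    max_retries: int = 100,
):
    """Percentile pointwise confidence bands for the stacked survival curve.

    Resamples (V_i, delta_i) pairs with replacement B times, reruns the full
    pipeline (submodel fits, CV, weight optimization) per resample, and
    returns the pointwise lower/upper quantile curves on ``time_grid``.
    Resamples with zero events are redrawn (bounded retries, logged).
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    v = np.asarray(v, dtype=float)
    delta = np.asarray(delta).astype(int)
    if time_grid is None:
        time_grid = np.linspace(0.0, float(v.max()), 101)
    time_grid = np.asarray(time_grid, dtype=float)
    rng = np.random.default_rng(seed)
    curves = np.empty((B, time_grid.size))
    for b in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, v.size, size=v.size)
            if delta[idx].sum() > 0:
                break
            logger.info("bootstrap_bands: resample %d had no events; redrawn", b)
        else:
            raise DegenerateDataError("could not draw a resample containing events")
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fit = stack_fit(v[idx], delta[idx], models=models, n_folds=n_folds,
                        seed=sub_seed)
        curves[b] = fit.survival(time_grid, scale=scale)
    lo = (1.0 - level) / 2.0
    lower = np.quantile(curves, lo, axis=0)
    upper = np.quantile(curves, 1.0 - lo, axis=0)
    return time_grid, lower, upper
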