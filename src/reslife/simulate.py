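"""Prevalent-cohort residual-lifetime simulation and the DISSE metric.

The generator emulates screening a stationary population: onsets O are
Uniform(0, 50) calendar times, failures T come from a stated underlying
distribution, and a subject enters the prevalent cohort only if still alive
on prevalence day R = 50 (T > 50 - O, i.e. left truncation).  The observed
residual lifetime is V = T - (50 - O), optionally right-censored either
administratively (a common end-of-study date chosen to censor an exact
in-sample proportion) or randomly (exponential loss to follow-up calibrated
to a target proportion).

Estimator quality is measured by the discrete integrated squared survival
error (DISSE) on a uniform mesh over [0, 50] with gauge 0.1,

    DISSE = sum_j (t_j - t_{j-1}) * (S_hat(t_j) - S_0(t_j))^2,

a Riemann approximation of the integrated squared error between the
estimated and true underlying survival curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as _optimize

from . import families, npmle, stacking
from .families import FamilySpec

__all__ = [
    "PREVALENCE_DAY",
    "MixtureSpec",
    "SimulationConfig",
    "SimulationResult",
    "SimulationError",
    "default_mixture",
    "make_mesh",
    "true_underlying_survival",
    "sample_failures",
    "sample_mixture_failure",
    "sample_prevalent_residuals",
    "apply_administrative_censoring",
    "calibrate_censoring_rate",
    "apply_random_censoring",
    "disse",
    "run_simulation_study",
]

logger = logging.getLogger(__name__)

#: Prevalence (screening) day; onsets are Uniform(0, PREVALENCE_DAY).
PREVALENCE_DAY = 50.0
MESH_UPPER = 50.0
MESH_GAUGE = 0.1
CALIBRATION_PILOT_N = 100_000


class SimulationError(RuntimeError):
    """The study as a whole failed (e.g. too many failed runs)."""


@dataclass(frozen=True)
class MixtureSpec:
    """Finite mixture of parametric failure-time laws.

    The default is the four-component, equally weighted mixture of
    Weibull(4, 2), Log-Logistic(1, 2), Log-Normal(-5, 1) and Gamma(25, 1)
    used to produce an underlying survival curve with kinks that no single
    standard family matches.  Sampling needs no finite mean, so the
    infinite-mean log-logistic component is legitimate here.
    """

    components: tuple[FamilySpec, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size != len(self.components):
            raise ValueError("one weight per component required")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be non-negative and sum to 1")

    def survival(self, t):
        w = np.asarray(self.weights, dtype=float)
        out = sum(
            wk * np.asarray(families.underlying_survival(c, t))
            for wk, c in zip(w, self.components)
        )
        return out if np.ndim(out) else float(out)


def default_mixture() -> MixtureSpec:
    return MixtureSpec(
        components=(
            FamilySpec("weibull", (4.0, 2.0)),
            FamilySpec("loglogistic", (1.0, 2.0)),
            FamilySpec("lognormal", (-5.0, 1.0)),
            FamilySpec("gamma", (25.0, 1.0)),
        ),
        weights=(0.25, 0.25, 0.25, 0.25),
    )


def make_mesh(upper: float = MESH_UPPER, gauge: float = MESH_GAUGE) -> np.ndarray:
    """Uniform mesh 0 = t_1 < ... < t_k = upper with the stated gauge."""
    k = int(round(upper / gauge))
    return np.linspace(0.0, upper, k + 1)


def true_underlying_survival(generator, t):
    """S_0 on the mesh for either a single family or a mixture generator."""
    if isinstance(generator, MixtureSpec):
        return generator.survival(t)
    return families.underlying_survival(generator, t)


def sample_failures(generator, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw underlying failure times from a family or mixture generator."""
    if isinstance(generator, MixtureSpec):
        return sample_mixture_failure(generator, size, rng)
    return np.asarray(generator.frozen().rvs(size=size, random_state=rng), dtype=float)


def sample_mixture_failure(spec: MixtureSpec, size: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Component chosen by a multinomial draw, then one draw from it."""
    comp = rng.choice(len(spec.components), size=size, p=np.asarray(spec.weights))
    out = np.empty(size)
    for k, c in enumerate(spec.components):
        mask = comp == k
        if mask.any():
            out[mask] = c.frozen().rvs(size=int(mask.sum()), random_state=rng)
    return out


def sample_prevalent_residuals(generator, n: int, seed: int,
                               max_draws: int = 20_000_000) -> np.ndarray:
    """Rejection-sample n uncensored residual lifetimes V = T - (R - O) > 0.

    Onsets are Uniform(0, R); (O, T) pairs are kept only when the subject
    survives to prevalence day (T > R - O).  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    total_drawn = 0
    total_accepted = 0
    while total_accepted < n:
        batch = max(4 * (n - total_accepted), 1024)
        if total_drawn > 0 and total_accepted > 0:
            rate = total_accepted / total_drawn
            batch = int(min(max(batch, 1.5 * (n - total_accepted) / rate), 2_000_000))
        onset = rng.uniform(0.0, PREVALENCE_DAY, size=batch)
        failure = sample_failures(generator, batch, rng)
        residual = failure - (PREVALENCE_DAY - onset)
        keep = residual > 0
        accepted.append(residual[keep])
        total_drawn += batch
        total_accepted += int(keep.sum())
        if total_drawn >= max_draws and total_accepted < n:
            raise SimulationError(
                f"acceptance probability ~{total_accepted / total_drawn:.2e} "
                "too low; generator incompatible with the prevalence design"
            )
    return np.concatenate(accepted)[:n]


def apply_administrative_censoring(residuals, p: float):
    """Censor at the empirical (1-p) quantile so exactly ceil(p*n) are censored.

    The end-of-study date C* is the (n - ceil(p*n))-th order statistic;
    residuals beyond it become censored observations at C*.  Returns
    (v, delta) arrays.
    """
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    if not 0.0 < p < 1.0:
        raise ValueError("administrative censoring proportion must be in (0,1)")
    k = int(np.ceil(p * n))
    order = np.sort(residuals)
    c_star = order[n - k - 1]
    delta = (residuals <= c_star).astype(int)
    v = np.minimum(residuals, c_star)
    return v, delta


def calibrate_censoring_rate(pilot_residuals, target: float) -> float:
    """Exponential censoring rate hitting the target censored fraction.

    Solves mean_i(1 - exp(-rate * v_i)) = target over the pilot residual
    sample by deterministic root bracketing; the left side is the exact
    expected censored fraction under C ~ Exp(rate) independent of V.
    """
    pilot = np.asarray(pilot_residuals, dtype=float)
    if not 0.0 < target < 1.0:
        raise ValueError("target censoring proportion must be in (0,1)")

    def expected_fraction(rate: float) -> float:
        return float(np.mean(-np.expm1(-rate * pilot)))

    lo, hi = 1e-12, 1.0
    for _ in range(200):
        if expected_fraction(hi) >= target:
            break
        hi *= 2.0
    else:
        raise SimulationError(
            f"could not bracket the censoring rate (reached rate={hi})"
        )
    rate = _optimize.brentq(lambda r: expected_fraction(r) - target, lo, hi,
                            xtol=1e-12, rtol=1e-12)
    achieved = expected_fraction(rate)
    if abs(achieved - target) > 0.01:
        raise SimulationError(
            f"censoring-rate calibration off target: {achieved:.4f} vs {target}"
        )
    return float(rate)


def apply_random_censoring(residuals, target: float, seed: int,
                           rate: float | None = None):
    """Pair each residual with an independent Exp(rate) censoring time.

    If ``rate`` is not supplied it is calibrated on the residuals themselves;
    study drivers calibrate once on a large pilot sample and pass it in.
    Returns (v, delta, realized_fraction).
    """
    residuals = np.asarray(residuals, dtype=float)
    if rate is None:
        rate = calibrate_censoring_rate(residuals, target)
    rng = np.random.default_rng(seed)
    c = rng.exponential(scale=1.0 / rate, size=residuals.size)
    delta = (residuals <= c).astype(int)
    v = np.minimum(residuals, c)
    return v, delta, float(1.0 - delta.mean())


def disse(estimate, truth, mesh) -> float:
    """Discrete integrated squared survival error on a common mesh."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    mesh = np.asarray(mesh, dtype=float)
    if estimate.shape != mesh.shape or truth.shape != mesh.shape:
        raise ValueError("estimate, truth and mesh must share a shape")
    d = estimate - truth
    return float(np.sum(np.diff(mesh) * d[1:] ** 2))


# ---------------------------------------------------------------------------
# Study driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """One Monte-Carlo study: generator, censoring design, and estimators.

    ``censoring`` is ("administrative", p), ("random", target) or None.
    ``stacks`` maps a stack name to the tuple of submodel labels it holds.
    """

    generator: object
    n: int = 125
    censoring: tuple[str, float] | None = ("administrative", 0.1)
    n_runs: int = 100
    seed: int = 0
    models: tuple[str, ...] = stacking.DEFAULT_MODELS
    stacks: dict = field(default_factory=lambda: {"all": stacking.DEFAULT_MODELS})
    n_folds: int = stacking.DEFAULT_FOLDS
    max_failure_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")
        if self.censoring is not None:
            kind, level = self.censoring
            if kind not in ("administrative", "random"):
                raise ValueError(f"unknown censoring kind {kind!r}")
            if not 0.0 < level < 1.0:
                raise ValueError("censoring level must be in (0,1)")
        for name, members in self.stacks.items():
            unknown = set(members) - set(self.models)
            if unknown:
                raise ValueError(f"stack {name!r} uses unfitted models {unknown}")


@dataclass(frozen=True)
class SimulationResult:
    config: SimulationConfig
    runs: pd.DataFrame
    mean_disse: pd.Series
    mean_weights: dict
    n_failed: int
    censoring_rate: float | None


def _underlying_curve(model, mesh: np.ndarray) -> np.ndarray:
    if isinstance(model, npmle.NPMLEFit):
        return np.asarray(model.underlying_survival(mesh))
    return np.asarray(families.underlying_survival(model.spec, mesh))


def run_simulation_study(config: SimulationConfig) -> SimulationResult:
    """Run the full Monte-Carlo study defined by ``config``.

    Per run: generate prevalent residual data, censor them, fit every
    submodel individually and every configured stack, and score each
    estimator's underlying-survival curve by DISSE against the generator's
    truth on the 0.1-gauge mesh.  Fully deterministic given ``config.seed``;
    failed runs are logged and excluded, and more than
    ``max_failure_fraction`` of failures aborts the study.
    """
    mesh = make_mesh()
    truth = np.asarray(true_underlying_survival(config.generator, mesh))
    master = np.random.default_rng(config.seed)
    run_seeds = master.integers(0, 2**31 - 1, size=3 * config.n_runs)

    rate = None
    realized = []
    if config.censoring is not None and config.censoring[0] == "random":
        pilot_seed = int(master.integers(0, 2**31 - 1))
        pilot = sample_prevalent_residuals(config.generator, CALIBRATION_PILOT_N,
                                           pilot_seed)
        rate = calibrate_censoring_rate(pilot, config.censoring[1])

    records = []
    weight_records: dict[str, list[dict]] = {name: [] for name in config.stacks}
    n_failed = 0
    for r in range(config.n_runs):
        s_data, s_cens, s_fold = (int(x) for x in run_seeds[3 * r: 3 * r + 3])
        try:
            residuals = sample_prevalent_residuals(config.generator, config.n, s_data)
            if config.censoring is None:
                v, delta = residuals, np.ones(config.n, dtype=int)
            elif config.censoring[0] == "administrative":
                v, delta = apply_administrative_censoring(residuals,
                                                          config.censoring[1])
            else:
                v, delta, frac = apply_random_censoring(
                    residuals, config.censoring[1], s_cens, rate=rate)
                realized.append(frac)

            fits = {m: stacking._fit_submodel(m, v, delta) for m in config.models}
            rec = {"run": r, "seed": s_data,
                   "censored_fraction": float(1.0 - delta.mean())}
            curves = {}
            for m in config.models:
                curves[m] = _underlying_curve(fits[m], mesh)
                rec[f"disse_{m}"] = disse(curves[m], truth, mesh)

            grid = stacking.default_grid(v)
            pred = stacking.cv_predictions(v, delta, config.models, grid=grid,
                                           n_folds=config.n_folds, seed=s_fold)
            G = stacking.censoring_km(v, delta)
            for name, members in config.stacks.items():
                cols = [config.models.index(m) for m in members]
                w = stacking.optimize_weights(pred[:, cols, :], v, delta, grid, G)
                stacked = sum(a * curves[m] for a, m in zip(w.alpha, members))
                rec[f"disse_stack_{name}"] = disse(stacked, truth, mesh)
                weight_records[name].append(dict(zip(members, w.alpha.tolist())))
        except Exception as exc:  # noqa: BLE001 - per-run isolation by design
            n_failed += 1
            logger.warning("simulation run %d failed: %s", r, exc)
            continue
        records.append(rec)

    if n_failed > config.max_failure_fraction * config.n_runs:
        raise SimulationError(
            f"{n_failed}/{config.n_runs} runs failed; study aborted"
        )
    runs = pd.DataFrame.from_records(records)
    disse_cols = [c for c in runs.columns if c.startswith("disse_")]
    mean_disse = runs[disse_cols].mean().rename(lambda c: c[len("disse_"):])
    mean_weights = {
        name: pd.DataFrame.from_records(w).mean().to_dict()
        for name, w in weight_records.items() if w
    }
    return SimulationResult(
        config=config,
        runs=runs,
        mean_disse=mean_disse,
        mean_weights=mean_weights,
        n_failed=n_failed,
        censoring_rate=float(np.mean(realized)) if realized else None,
    )
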