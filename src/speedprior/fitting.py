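"""Fast PSE-variance model fitting and slow-speed prior reconstruction.

The fitting method uses only two summary statistics per condition instead of
every trial: the mean PSE across staircases and its across-staircase variance.
At the PSE the posterior means of the two gratings are equal,

    f(v1, c1) + a(v1) sigma^2(v1, c1) = f(v2, c2) + a(v2) sigma^2(v2, c2),

which predicts the mean PSE, while the across-staircase variance of the PSE is
approximately proportional to the summed likelihood variances of the two
gratings and inversely proportional to the number of trials per staircase,

    var_PSE = alpha * (sigma_1^2 + sigma_2^2) / N,

with a proportionality constant alpha ~= 6.6 calibrated against trial-level
maximum-likelihood fitting.  Stacking mean-PSE residuals (deg/s) with
log-variance residuals constrains all 10 free parameters: 4 prior slopes a(v),
4 likelihood-width knots g(v), and the 2 contrast-gain parameters (q, c50).
Because a(v) and sigma(v, c) enter the mean equation only as a product, and g
and h share an overall scale, the identifiable quantities are the products
a * sigma^2 (and the shape, not the absolute scale, of g and h).

The trial-level maximum-likelihood method (Bernoulli likelihood of every 2-AFC
response under the closed-form choice probability) is also implemented, as the
slower reference the fast method is validated against.  The prior density is
reconstructed from fitted slopes by numerical integration,
``p(v) = exp(integral a(v) dv)``, fixed to 1 at the lowest grid speed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq, least_squares, minimize
from scipy.special import ndtr

from .experiment import Condition, PSE_TABLE_COLUMNS
from .models import (
    DEFAULT_KNOT_SPEEDS,
    ContrastResponse,
    LikelihoodModel,
    ObserverSpec,
    PriorModel,
    RatioParams,
    ratio_output,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "predict_pse",
    "predict_pse_var",
    "predict_table",
    "fit_model",
    "fit_combined",
    "fit_full_likelihood",
    "reconstruct_prior",
    "goodness_of_fit",
]

_BRACKET = (1e-3, 200.0)  # deg/s search interval for the predicted PSE


@dataclass(frozen=True)
class FitConfig:
    """Settings for the least-squares and maximum-likelihood fits."""

    variant: str = "bayesian"  # "bayesian" | "combined"
    slope_bounds: Tuple[float, float] = (-3.0, 1.0)
    g_bounds: Tuple[float, float] = (1e-3, 20.0)
    q_bounds: Tuple[float, float] = (0.5, 8.0)
    c50_bounds: Tuple[float, float] = (0.005, 0.9)
    n_multistart: int = 20
    master_seed: int = 0
    variance_weight: float = 1.0
    alpha: float = 6.6  # PSE-variance proportionality constant
    n_trials: int = 35  # trials per staircase (N in the variance relation)
    knot_speeds: Tuple[float, ...] = DEFAULT_KNOT_SPEEDS
    ratio: Optional[RatioParams] = None  # fixed front end for variant="combined"
    spatial_frequency: float = 2.0
    # nested (outer) search over shared ratio parameters in fit_combined
    outer_s_bounds: Tuple[float, float] = (0.1, 2.0)
    outer_k_bounds: Tuple[float, float] = (0.1, 2.0)
    outer_tau_scale_bounds: Tuple[float, float] = (1.0, 10.0)
    outer_coarse_n: int = 3
    outer_refine_iters: int = 30
    inner_multistart_search: int = 3

    def __post_init__(self):
        if self.variant not in ("bayesian", "combined"):
            raise ValueError("variant must be 'bayesian' or 'combined'")
        for name in ("slope_bounds", "g_bounds", "q_bounds", "c50_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be well-ordered")
        if self.n_multistart < 1:
            raise ValueError("n_multistart must be at least 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if self.variance_weight < 0:
            raise ValueError("variance_weight must be non-negative")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a fit: the fitted observer plus goodness-of-fit diagnostics.

    ``sse`` and ``r2`` are computed on the contrast-dependent bias (CDB =
    predicted PSE / reference speed), the dimensionless quantity the model is
    judged on.  ``cost`` is the optimizer's objective at the optimum (stacked
    squared residuals for the fast method, negative log-likelihood for the
    trial-level method).
    """

    observer: ObserverSpec
    variant: str
    sse: float
    r2: float
    residual_table: Optional[pd.DataFrame]
    converged: bool
    best_start: int
    cost: float
    loglik: Optional[float] = None

    @property
    def params(self) -> ObserverSpec:
        return self.observer


# ---------------------------------------------------------------------------
# Forward predictions
# ---------------------------------------------------------------------------


def _effective_observer(observer: ObserverSpec, variant: str) -> ObserverSpec:
    if variant == "combined":
        if observer.ratio is None:
            raise ValueError("variant='combined' requires an observer with ratio params")
        return observer
    return observer.with_ratio(None)


def _mean_percept(observer: ObserverSpec, v, c):
    """Posterior mean, vectorized; observer.ratio already reflects the variant."""
    v = np.asarray(v, dtype=float)
    if observer.ratio is None:
        f = v
    else:
        f = ratio_output(observer.ratio, v, c, observer.spatial_frequency)
    sigma = observer.likelihood.sigma(v, c)
    return f + observer.prior.slope_at(v) * sigma**2


def _predict_pse_batch_full(observer: ObserverSpec, v1, c1, c2):
    """Solve the PSE equality for many conditions at once by bisection.

    Returns ``(pse, violation)``: NaN entries in ``pse`` mark conditions where
    the perceived-speed equation has no root in the bracket (non-identifiable
    conditions); ``violation`` is the corresponding bracket residual, used by
    the fitter to steer back into the invertible region.
    """
    v1 = np.atleast_1d(np.asarray(v1, dtype=float))
    c1 = np.broadcast_to(np.asarray(c1, dtype=float), v1.shape)
    c2 = np.broadcast_to(np.asarray(c2, dtype=float), v1.shape)
    target = _mean_percept(observer, v1, c1)
    lo = np.full_like(v1, _BRACKET[0])
    hi = np.full_like(v1, _BRACKET[1])
    f_lo = _mean_percept(observer, lo, c2) - target
    f_hi = _mean_percept(observer, hi, c2) - target
    ok = (f_lo < 0) & (f_hi > 0)
    violation = np.maximum(f_lo, 0.0) + np.maximum(-f_hi, 0.0)
    for _ in range(70):  # ~2e-19 relative bracket after 70 halvings
        mid = 0.5 * (lo + hi)
        f_mid = _mean_percept(observer, mid, c2) - target
        take_hi = f_mid > 0
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid)
    out = 0.5 * (lo + hi)
    return np.where(ok, out, np.nan), violation


def _predict_pse_batch(observer: ObserverSpec, v1, c1, c2) -> np.ndarray:
    return _predict_pse_batch_full(observer, v1, c1, c2)[0]


def predict_pse(
    observer: ObserverSpec, condition: Condition, variant: str = "bayesian"
) -> float:
    """Test speed at which the two gratings' perceived speeds match.

    Solved numerically (Brent's method) for the test speed whose posterior
    mean equals the reference grating's.  Raises if the perceived-speed
    residual does not change sign over the search bracket, which flags a
    non-identifiable condition.
    """
    obs = _effective_observer(observer, variant)
    target = _mean_percept(obs, condition.v_ref, condition.c_ref)

    def resid(v2: float) -> float:
        return _mean_percept(obs, v2, condition.c_test) - target

    lo, hi = _BRACKET
    if not resid(lo) < 0 < resid(hi):
        raise ValueError(
            f"condition {condition.condition_id}: no PSE in ({lo}, {hi}); "
            "perceived speed is not invertible here"
        )
    return float(brentq(resid, lo, hi, xtol=1e-12, rtol=1e-14))


def predict_pse_var(
    observer: ObserverSpec,
    condition: Condition,
    config: FitConfig,
    pse: Optional[float] = None,
) -> float:
    """Predicted across-staircase PSE variance: alpha * (sigma1^2 + sigma2^2) / N.

    sigma1 is evaluated at the reference grating, sigma2 at the *predicted*
    PSE and the test contrast.
    """
    if pse is None:
        pse = predict_pse(observer, condition, config.variant)
    s1 = observer.likelihood.sigma(condition.v_ref, condition.c_ref)
    s2 = observer.likelihood.sigma(pse, condition.c_test)
    return float(config.alpha * (s1**2 + s2**2) / config.n_trials)


def predict_table(
    observer: ObserverSpec, conditions: Sequence[Condition], config: FitConfig
) -> pd.DataFrame:
    """Model-predicted PSE table for a set of conditions (noise-free)."""
    rows = []
    for cond in conditions:
        pse = predict_pse(observer, cond, config.variant)
        rows.append(
            {
                "condition_id": cond.condition_id,
                "v_ref": cond.v_ref,
                "c_ref": cond.c_ref,
                "c_test": cond.c_test,
                "n_staircases": 0,
                "mean_pse": pse,
                "sem2_pse": predict_pse_var(observer, cond, config, pse=pse),
            }
        )
    return pd.DataFrame(rows, columns=PSE_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# Parameter vector plumbing
# ---------------------------------------------------------------------------


def _observer_from_vector(x: np.ndarray, config: FitConfig, ratio) -> ObserverSpec:
    n = len(config.knot_speeds)
    return ObserverSpec(
        prior=PriorModel(knot_slopes=tuple(x[:n]), knot_speeds=config.knot_speeds),
        likelihood=LikelihoodModel(
            knot_g=tuple(x[n : 2 * n]),
            knot_speeds=config.knot_speeds,
            contrast=ContrastResponse(q=x[2 * n], c50=x[2 * n + 1]),
        ),
        ratio=ratio,
        spatial_frequency=config.spatial_frequency,
    )


def _vector_from_observer(observer: ObserverSpec) -> np.ndarray:
    return np.concatenate(
        [
            observer.prior.knot_slopes,
            observer.likelihood.knot_g,
            [observer.likelihood.contrast.q, observer.likelihood.contrast.c50],
        ]
    )


def _bounds(config: FitConfig) -> Tuple[np.ndarray, np.ndarray]:
    n = len(config.knot_speeds)
    lo = np.array(
        [config.slope_bounds[0]] * n
        + [config.g_bounds[0]] * n
        + [config.q_bounds[0], config.c50_bounds[0]]
    )
    hi = np.array(
        [config.slope_bounds[1]] * n
        + [config.g_bounds[1]] * n
        + [config.q_bounds[1], config.c50_bounds[1]]
    )
    return lo, hi


def _starts(config: FitConfig, n_starts: int) -> List[np.ndarray]:
    """Neutral initial point plus seeded +-50% multiplicative jitters."""
    n = len(config.knot_speeds)
    neutral = np.array([-0.1] * n + [1.0] * n + [2.0, 0.1])
    lo, hi = _bounds(config)
    rng = np.random.default_rng(config.master_seed)
    starts = [neutral.copy()]
    while len(starts) < n_starts:
        jitter = 1.0 + rng.uniform(-0.5, 0.5, size=neutral.size)
        starts.append(np.clip(neutral * jitter, lo, hi))
    return starts


# ---------------------------------------------------------------------------
# Fast PSE-variance fit
# ---------------------------------------------------------------------------


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(PSE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"PSE table is missing columns: {sorted(missing)}")
    if len(table) < 10:
        raise ValueError(
            "need at least 10 conditions for the 10-parameter model to be identifiable"
        )
    return table.reset_index(drop=True)


def _conditions_from_table(table: pd.DataFrame) -> List[Condition]:
    return [
        Condition(
            v_ref=float(r.v_ref),
            c_ref=float(r.c_ref),
            c_test=float(r.c_test),
            condition_id=str(r.condition_id),
        )
        for r in table.itertuples()
    ]


def _cdb_goodness(obs_mean, pred_mean, v_ref) -> Tuple[float, float]:
    cdb_obs = np.asarray(obs_mean) / np.asarray(v_ref)
    cdb_pred = np.asarray(pred_mean) / np.asarray(v_ref)
    sse = float(np.sum((cdb_obs - cdb_pred) ** 2))
    tss = float(np.sum((cdb_obs - cdb_obs.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else (1.0 if sse == 0 else -np.inf)
    return sse, r2


def fit_model(
    table: pd.DataFrame, config: Optional[FitConfig] = None, _n_starts: Optional[int] = None
) -> FitResult:
    """Least-squares fit of the 10-parameter observer to a per-condition PSE table.

    Minimizes stacked residuals of (observed - predicted) mean PSE in deg/s
    and (log observed - log predicted) PSE variance, over the prior slopes,
    likelihood-width knots and contrast-gain parameters, within box bounds,
    with seeded multistart.  Deterministic for a fixed ``master_seed``.
    """
    config = config if config is not None else FitConfig()
    ratio = None
    if config.variant == "combined":
        if config.ratio is None:
            raise ValueError("variant='combined' requires config.ratio (fixed front end)")
        ratio = config.ratio
    table = _check_table(table)
    v1 = table["v_ref"].to_numpy(float)
    c1 = table["c_ref"].to_numpy(float)
    c2 = table["c_test"].to_numpy(float)
    obs_mean = table["mean_pse"].to_numpy(float)
    obs_var = table["sem2_pse"].to_numpy(float)
    if np.any(obs_var <= 0):
        raise ValueError("sem2_pse must be positive for the log-variance residuals")
    log_obs_var = np.log(obs_var)
    w = config.variance_weight
    scale = config.alpha / config.n_trials

    def residuals(x: np.ndarray) -> np.ndarray:
        observer = _observer_from_vector(x, config, ratio)
        pse, violation = _predict_pse_batch_full(observer, v1, c1, c2)
        bad = ~np.isfinite(pse)
        pse_safe = np.where(bad, v1, pse)
        s1sq = observer.likelihood.sigma(v1, c1) ** 2
        s2sq = observer.likelihood.sigma(pse_safe, c2) ** 2
        var_pred = scale * (s1sq + s2sq)
        r_mean = obs_mean - pse_safe
        r_var = w * (log_obs_var - np.log(var_pred))
        # non-invertible conditions: penalty grows with the bracket violation,
        # giving the optimizer a slope back into the feasible region
        r_mean = np.where(bad, 1e2 * (1.0 + violation), r_mean)
        return np.concatenate([r_mean, r_var])

    lo, hi = _bounds(config)
    n_starts = _n_starts if _n_starts is not None else config.n_multistart
    best = None
    best_idx = -1
    for i, x0 in enumerate(_starts(config, n_starts)):
        sol = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
        if best is None or sol.cost < best.cost:
            best, best_idx = sol, i
    observer = _observer_from_vector(best.x, config, ratio)
    pse_pred = _predict_pse_batch(observer, v1, c1, c2)
    var_pred = np.array(
        [
            predict_pse_var(observer, cond, config, pse=p)
            for cond, p in zip(_conditions_from_table(table), pse_pred)
        ]
    )
    sse, r2 = _cdb_goodness(obs_mean, pse_pred, v1)
    residual_table = pd.DataFrame(
        {
            "condition_id": table["condition_id"],
            "v_ref": v1,
            "c_ref": c1,
            "c_test": c2,
            "obs_mean_pse": obs_mean,
            "pred_mean_pse": pse_pred,
            "obs_var_pse": obs_var,
            "pred_var_pse": var_pred,
        }
    )
    return FitResult(
        observer=observer,
        variant=config.variant,
        sse=sse,
        r2=r2,
        residual_table=residual_table,
        converged=bool(best.success),
        best_start=best_idx,
        cost=float(best.cost),
    )


# ---------------------------------------------------------------------------
# Nested combined-model fit
# ---------------------------------------------------------------------------


def _ratio_from_outer(theta: np.ndarray) -> RatioParams:
    s, k, tau_scale = theta
    base = RatioParams.literature()
    return RatioParams(
        tau1=base.tau1 * tau_scale, tau2=base.tau2 * tau_scale, k=k, s_p=s, s_m=s
    )


def fit_combined(
    tables: Union[pd.DataFrame, Sequence[pd.DataFrame]],
    config: Optional[FitConfig] = None,
    ratio_candidates: Optional[Sequence[Optional[RatioParams]]] = None,
) -> Union[FitResult, List[FitResult]]:
    """Nested fit of the ratio front end plus Bayesian observer.

    The outer search adjusts the shared ratio parameters -- a common
    semi-saturation ``s = s_p = s_m``, the gain ``k`` and a common scale factor
    on the literature time constants -- and the inner problem refits the same
    10 Bayesian parameters per candidate, so the combined model keeps 10 free
    parameters per subject.  When several tables are given the ratio
    parameters are shared across them.  The outer search evaluates a coarse
    grid (always including the published optimum s=0.5, k=0.55, scale=4.9 as a
    start) and then refines locally with Nelder-Mead.

    ``ratio_candidates`` short-circuits the search: each entry is either a
    fixed ``RatioParams`` or ``None`` for a degenerate (absent) front end, in
    which case the fit is exactly `fit_model`.
    """
    config = config if config is not None else FitConfig()
    single = isinstance(tables, pd.DataFrame)
    table_list = [tables] if single else list(tables)

    def inner(ratio: Optional[RatioParams], n_starts: Optional[int]) -> List[FitResult]:
        if ratio is None:
            cfg = replace(config, variant="bayesian", ratio=None)
        else:
            cfg = replace(config, variant="combined", ratio=ratio)
        return [fit_model(t, cfg, _n_starts=n_starts) for t in table_list]

    if ratio_candidates is not None:
        best_fits, best_cost = None, np.inf
        for cand in ratio_candidates:
            fits = inner(cand, None)
            cost = sum(f.cost for f in fits)
            if cost < best_cost:
                best_fits, best_cost = fits, cost
        return best_fits[0] if single else best_fits

    s_lo, s_hi = config.outer_s_bounds
    k_lo, k_hi = config.outer_k_bounds
    t_lo, t_hi = config.outer_tau_scale_bounds
    n = config.outer_coarse_n
    grid = [
        np.array([s, k, ts])
        for s in np.geomspace(s_lo, s_hi, n)
        for k in np.geomspace(k_lo, k_hi, n)
        for ts in np.geomspace(t_lo, t_hi, n)
    ]
    grid.append(np.array([0.5, 0.55, 4.9]))  # published optimum as a start

    cache: Dict[Tuple[float, float, float], float] = {}

    def outer_cost(theta: np.ndarray) -> float:
        theta = np.clip(theta, [s_lo, k_lo, t_lo], [s_hi, k_hi, t_hi])
        key = tuple(np.round(theta, 10))
        if key not in cache:
            fits = inner(_ratio_from_outer(theta), config.inner_multistart_search)
            cache[key] = sum(f.cost for f in fits)
        return cache[key]

    best_theta = min(grid, key=outer_cost)
    refine = minimize(
        outer_cost,
        best_theta,
        method="Nelder-Mead",
        options={"maxfev": config.outer_refine_iters, "xatol": 1e-3, "fatol": 1e-8},
    )
    theta = np.clip(refine.x, [s_lo, k_lo, t_lo], [s_hi, k_hi, t_hi])
    if outer_cost(best_theta) < outer_cost(theta):
        theta = best_theta
    fits = inner(_ratio_from_outer(theta), None)
    return fits[0] if single else fits


# ---------------------------------------------------------------------------
# Trial-level maximum likelihood (reference method)
# ---------------------------------------------------------------------------


def _trials_to_arrays(trials) -> Tuple[np.ndarray, ...]:
    if isinstance(trials, pd.DataFrame):
        frame = trials
    else:
        frame = pd.DataFrame(
            {
                "v_ref": [t.v_ref for t in trials],
                "c_ref": [t.c_ref for t in trials],
                "v_test": [t.v_test for t in trials],
                "c_test": [t.c_test for t in trials],
                "response_test_faster": [t.response_test_faster for t in trials],
            }
        )
    return (
        frame["v_ref"].to_numpy(float),
        frame["c_ref"].to_numpy(float),
        frame["v_test"].to_numpy(float),
        frame["c_test"].to_numpy(float),
        frame["response_test_faster"].to_numpy(bool),
    )


def trial_log_likelihood(observer: ObserverSpec, trials, variant: str = "bayesian") -> float:
    """Bernoulli log-likelihood of 2-AFC responses under the observer model."""
    v1, c1, v2, c2, resp = _trials_to_arrays(trials)
    obs = _effective_observer(observer, variant)
    e1 = _mean_percept(obs, v1, c1)
    e2 = _mean_percept(obs, v2, c2)
    var1 = obs.likelihood.sigma(v1, c1) ** 2
    var2 = obs.likelihood.sigma(v2, c2) ** 2
    p = ndtr((e2 - e1) / np.sqrt(var1 + var2))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(np.where(resp, np.log(p), np.log1p(-p))))


def fit_full_likelihood(trials, config: Optional[FitConfig] = None) -> FitResult:
    """Maximum-likelihood fit of the observer to the entire trial log.

    Maximizes the Bernoulli likelihood of every response under the closed-form
    choice probability, over the same 10 parameters as the fast method.  This
    is the slower reference method; the fast PSE-variance fit is validated
    against it.  Deterministic for a fixed ``master_seed``.
    """
    config = config if config is not None else FitConfig()
    ratio = None
    if config.variant == "combined":
        if config.ratio is None:
            raise ValueError("variant='combined' requires config.ratio (fixed front end)")
        ratio = config.ratio
    v1, c1, v2, c2, resp = _trials_to_arrays(trials)

    def nll(x: np.ndarray) -> float:
        observer = _observer_from_vector(x, config, ratio)
        e1 = _mean_percept(observer, v1, c1)
        e2 = _mean_percept(observer, v2, c2)
        var1 = observer.likelihood.sigma(v1, c1) ** 2
        var2 = observer.likelihood.sigma(v2, c2) ** 2
        p = ndtr((e2 - e1) / np.sqrt(var1 + var2))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(np.where(resp, np.log(p), np.log1p(-p))))

    lo, hi = _bounds(config)
    best, best_idx = None, -1
    for i, x0 in enumerate(_starts(config, config.n_multistart)):
        sol = minimize(
            nll, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)), options={"maxiter": 500}
        )
        if best is None or sol.fun < best.fun:
            best, best_idx = sol, i
    observer = _observer_from_vector(best.x, config, ratio)
    return FitResult(
        observer=observer,
        variant=config.variant,
        sse=float("nan"),
        r2=float("nan"),
        residual_table=None,
        converged=bool(best.success),
        best_start=best_idx,
        cost=float(best.fun),
        loglik=-float(best.fun),
    )


# ---------------------------------------------------------------------------
# Prior reconstruction and goodness of fit
# ---------------------------------------------------------------------------


def reconstruct_prior(prior: PriorModel, grid) -> np.ndarray:
    """Unnormalized prior density on a speed grid: exp of the integrated slope.

    Cumulative trapezoidal integration of the interpolated log-slope from the
    lowest grid speed; the density there is fixed to 1, absorbing the
    log-linear intercept into the integration constant.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive and strictly increasing")
    slopes = np.interp(grid, prior.knot_speeds, prior.knot_slopes)
    log_density = cumulative_trapezoid(slopes, grid, initial=0.0)
    return np.exp(log_density)


def goodness_of_fit(fit: FitResult, table: pd.DataFrame) -> Dict[str, float]:
    """SSE and R^2 of a fitted model on a PSE table, in CDB space.

    Residuals are (predicted - observed) PSE/v_ref ratios per condition; R^2
    is relative to the spread of the observed ratios about their mean.
    """
    table = _check_table(table)
    if fit.residual_table is not None:
        fitted_ids = set(fit.residual_table["condition_id"])
        if fitted_ids != set(table["condition_id"]):
            raise ValueError("fit and table cover different conditions")
    preds = [
        predict_pse(fit.observer, cond, fit.variant)
        for cond in _conditions_from_table(table)
    ]
    sse, r2 = _cdb_goodness(
        table["mean_pse"].to_numpy(float), preds, table["v_ref"].to_numpy(float)
    )
    return {"sse": sse, "r2": r2}
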