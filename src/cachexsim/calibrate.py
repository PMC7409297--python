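"""Three-stage parameterization pipeline.

Stage 1 extends the supplier body-weight growth curve with a logistic fit so
the homeostatic adult mass is represented in the data.  Stage 2 fits the four
healthy feedback parameters (p0, p1, nu0, nu1) by simulated annealing on the
pooled muscle+stem RMSE, with an outer one-at-a-time loop over the fixed
parameters (d0, m).  Stage 3 fits tumor growth (mu, mu1), the cachexia
perturbations (eps, dS, dM, m2) and the treatment efficacies (A1..A4) by
exhaustive grid search minimizing the RMSE, evaluating every grid point in a
single stacked vectorized ODE solve.

All stochastic steps are driven by an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .model_core import (
    CachexiaParams,
    ConversionConvention,
    HealthyParams,
    LogisticParams,
    TissueState,
    TreatmentParams,
    TumorParams,
    logistic_weight,
)

__all__ = [
    "ObservationSeries",
    "FitResult",
    "SAConfig",
    "rmse",
    "fit_logistic",
    "extend_dataset",
    "fit_healthy",
    "fit_tumor",
    "fit_cachexia",
    "fit_treatment",
    "DEFAULT_GRIDS",
]

# Generous default search ranges (overridable); the full 4-D cachexia
# product is astronomically large, so callers normally pass a coarser grid.
DEFAULT_GRIDS = {
    "mu": np.arange(0.05, 1.0 + 1e-12, 0.002),
    "mu1": np.arange(10.0, 300.0 + 1e-12, 0.5),
    "eps": np.arange(0.0, 0.5 + 1e-12, 0.002),
    "dS": np.arange(0.0, 0.2 + 1e-12, 0.002),
    "dM": np.arange(0.0, 0.3 + 1e-12, 0.002),
    "m2": np.arange(50.0, 1000.0 + 1e-12, 2.0),
    "A1": np.arange(0.0, 1.0 + 1e-12, 0.01),
    "A2": np.arange(0.0, 1.0 + 1e-12, 0.01),
    "A3": np.arange(0.0, 1.0 + 1e-12, 0.01),
    "A4": np.arange(0.0, 1.0 + 1e-12, 0.01),
}


@dataclass
class ObservationSeries:
    """A measured time series: days, values, and what was observed.

    ``kind`` is one of body_weight (g), lean_mass (g), muscle_mass (g),
    stem_mass (g), tumor_volume (mm^3).
    """

    days: np.ndarray
    values: np.ndarray
    kind: str = "lean_mass"

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.size != self.values.size:
            raise ValueError("days and values must have equal length")
        if self.days.size and np.any(np.diff(self.days) < 0):
            raise ValueError("days must be non-decreasing")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")

    def __len__(self):
        return self.days.size

    @classmethod
    def from_csv(cls, path, kind: str = "lean_mass") -> "ObservationSeries":
        df = pd.read_csv(path)
        return cls(df["day"].to_numpy(), df["value"].to_numpy(), kind)

    def to_csv(self, path) -> None:
        pd.DataFrame({"day": self.days, "value": self.values}).to_csv(path, index=False)


@dataclass
class FitResult:
    """Fitted parameters, their RMSE, and enough diagnostics to re-run.

    ``surface``/``axes`` hold the full objective surface for grid fits;
    ``diagnostics`` records the seed, iteration counts, objective trace and
    boundary flags; ``fixed`` the parameters held constant during the fit.
    """

    params: object
    rmse: float
    diagnostics: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    surface: Optional[np.ndarray] = None
    axes: Optional[dict] = None

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("RMSE >= 0 violated")

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict() if hasattr(self.params, "to_dict") else self.params,
            "rmse": self.rmse,
            "diagnostics": _jsonable(self.diagnostics),
            "fixed": _jsonable(self.fixed),
        }
        if self.surface is not None:
            d["surface"] = self.surface.tolist()
            d["axes"] = {k: np.asarray(v).tolist() for k, v in (self.axes or {}).items()}
        return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# --------------------------------------------------------------------------
# RMSE
# --------------------------------------------------------------------------


def rmse(predicted, observed) -> float:
    """Root-mean-squared error between aligned series.

    Accepts arrays or equal-length lists of arrays; lists are pooled into a
    single residual vector (used by the healthy fit, which pools muscle and
    satellite mass residuals).
    """
    def _is_series_list(x):
        return isinstance(x, (list, tuple)) and len(x) > 0 and np.ndim(x[0]) >= 1

    if _is_series_list(predicted) or _is_series_list(observed):
        if not (_is_series_list(predicted) and _is_series_list(observed)) or len(predicted) != len(observed):
            raise ValueError("length mismatch between predicted and observed series lists")
        res = np.concatenate(
            [np.atleast_1d(np.asarray(p, float) - np.asarray(o, float)) for p, o in zip(predicted, observed)]
        )
    else:
        p = np.asarray(predicted, dtype=float)
        o = np.asarray(observed, dtype=float)
        if p.shape != o.shape:
            raise ValueError(f"length mismatch: predicted {p.shape} vs observed {o.shape}")
        res = p - o
    return float(np.sqrt(np.mean(res**2)))


# --------------------------------------------------------------------------
# Stage 1: logistic body-weight extension
# --------------------------------------------------------------------------


def fit_logistic(weights: ObservationSeries) -> FitResult:
    """Nonlinear least squares of the closed-form logistic to body weights.

    W(0) is fixed to the day-0 observation when one is present.  A constant
    series leaves alpha unidentifiable; in that case K is reported as the
    constant and alpha is flagged unconstrained rather than guessed.
    """
    if len(weights) < 3:
        raise ValueError("need at least 3 observations to fit the logistic curve")
    days = weights.days
    vals = weights.values
    if np.any(vals <= 0):
        raise ValueError("weights must be positive")

    if np.ptp(vals) < 1e-12 * max(1.0, vals.max()):
        lp = LogisticParams(alpha=1e-9, K=float(vals[0]), W0=float(vals[0]))
        return FitResult(
            params=lp,
            rmse=0.0,
            diagnostics={"alpha_unconstrained": True, "n_obs": len(weights)},
        )

    has_day0 = np.isclose(days[0], 0.0)
    W0_fixed = float(vals[0]) if has_day0 else None
    a0 = 0.05
    K0 = float(vals.max()) * 1.05

    try:
        if W0_fixed is not None:
            popt, _ = curve_fit(
                lambda t, a, K: logistic_weight(t, LogisticParams(a, K, W0_fixed)),
                days, vals, p0=[a0, K0], maxfev=20000,
                bounds=([1e-8, vals.max() * 0.5], [5.0, vals.max() * 10]),
            )
            lp = LogisticParams(float(popt[0]), float(popt[1]), W0_fixed)
        else:
            popt, _ = curve_fit(
                lambda t, a, K, W0: logistic_weight(t, LogisticParams(a, K, W0)),
                days, vals, p0=[a0, K0, float(vals[0])], maxfev=20000,
                bounds=([1e-8, vals.max() * 0.5, 1e-6], [5.0, vals.max() * 10, vals.max() * 10]),
            )
            lp = LogisticParams(float(popt[0]), float(popt[1]), float(popt[2]))
    except RuntimeError as err:
        raise RuntimeError(f"logistic fit did not converge: {err}") from err

    err = rmse(logistic_weight(days, lp), vals)
    return FitResult(
        params=lp,
        rmse=err,
        diagnostics={"W0_fixed": W0_fixed is not None, "n_obs": len(weights)},
    )


def extend_dataset(
    lp: LogisticParams,
    last_observed_day: float,
    horizon: float = 300.0,
    start: float = 90.0,
    step: float = 10.0,
) -> ObservationSeries:
    """Logistic-curve samples extending the observed record.

    Default schedule: every 10 days from day 90 through the horizon
    (day 300), keeping only days beyond the last observation.
    """
    days = np.arange(start, horizon + 1e-9, step)
    days = days[days > last_observed_day]
    return ObservationSeries(days, logistic_weight(days, lp), kind="body_weight")


# --------------------------------------------------------------------------
# Stage 2: simulated annealing for the healthy feedback parameters
# --------------------------------------------------------------------------


@dataclass
class SAConfig:
    """Simulated-annealing schedule: geometric cooling, reflective bounds."""

    seed: int = 0
    n_temps: int = 200
    n_props: int = 50
    cooling: float = 0.95
    t0: float = 1.0
    step_frac: float = 0.08
    bounds: dict = field(
        default_factory=lambda: {
            "p0": (0.30, 0.4999),
            "p1": (0.001, 0.699),
            "nu0": (0.001, 1.0),
            "nu1": (0.01, 10.0),
        }
    )
    x0: Optional[dict] = None


def _feasible(x: dict) -> bool:
    s = x["p0"] + x["p1"]
    return (0.5 < s <= 1.0) and (x["p0"] < 0.5)


def _healthy_objective_factory(
    muscle: ObservationSeries,
    stem: ObservationSeries,
    d0: float,
    m: float,
    conv: ConversionConvention,
    rtol: float,
    atol: float,
):
    if len(muscle) == 0 or len(stem) == 0:
        raise ValueError("empty observation series")
    if not np.array_equal(muscle.days, stem.days):
        raise ValueError("muscle and stem series must share the same days")
    days = muscle.days
    S0 = stem.values[0] / conv.xi
    M0 = muscle.values[0] / conv.xi
    t_eval = days - days[0]
    obs = [muscle.values, stem.values]

    def objective(x: dict) -> float:
        hp = HealthyParams(x["p0"], x["p1"], x["nu0"], x["nu1"], d0, m)

        def rhs(t, y):
            f = 1.0 / (1.0 + y[1] / hp.m)
            p = hp.p0 + hp.p1 * f
            nu = hp.nu0 + hp.nu1 * f
            return [(2 * p - 1) * nu * y[0], 2 * (1 - p) * nu * y[0] - hp.d0 * y[1]]

        sol = solve_ivp(
            rhs, (0.0, t_eval[-1] if t_eval[-1] > 0 else 1.0), [S0, M0],
            method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval,
        )
        if not sol.success or sol.y.shape[1] != t_eval.size:
            return np.inf
        pred_m = conv.xi * sol.y[1]
        pred_s = conv.xi * sol.y[0]
        return rmse([pred_m, pred_s], obs)

    return objective


def _anneal(objective, cfg: SAConfig) -> tuple:
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.bounds)
    lo = np.array([cfg.bounds[n][0] for n in names])
    hi = np.array([cfg.bounds[n][1] for n in names])
    scale = cfg.step_frac * (hi - lo)

    if cfg.x0 is not None:
        x = np.array([cfg.x0[n] for n in names], dtype=float)
    else:
        x = 0.5 * (lo + hi)
    xd = dict(zip(names, x))
    if not _feasible(xd):
        # nudge toward a feasible self-renewal sum
        xd["p1"] = min(cfg.bounds["p1"][1], 0.55 - xd["p0"] + 0.05)
        x = np.array([xd[n] for n in names])
    if not _feasible(dict(zip(names, x))):
        raise RuntimeError("no feasible starting point within the bounds")

    fx = objective(dict(zip(names, x)))
    best_x, best_f = x.copy(), fx
    temp = cfg.t0
    trace = []
    n_accept = 0
    n_infeasible = 0
    for _ in range(cfg.n_temps):
        # proposal scale anneals with the square root of temperature so the
        # walk refines near the end of the schedule
        step = scale * max(np.sqrt(temp / cfg.t0), 1e-4)
        for _ in range(cfg.n_props):
            prop = x + rng.normal(size=x.size) * step
            # reflective bounds
            prop = np.where(prop < lo, 2 * lo - prop, prop)
            prop = np.where(prop > hi, 2 * hi - prop, prop)
            prop = np.clip(prop, lo, hi)
            pd_ = dict(zip(names, prop))
            if not _feasible(pd_):
                n_infeasible += 1
                continue
            fp = objective(pd_)
            if fp < fx or rng.random() < np.exp(-(fp - fx) / max(temp, 1e-300)):
                x, fx = prop, fp
                n_accept += 1
                if fx < best_f:
                    best_x, best_f = x.copy(), fx
        trace.append(best_f)
        temp *= cfg.cooling
    if not np.isfinite(best_f):
        raise RuntimeError("simulated annealing found no feasible finite-objective point")
    return dict(zip(names, best_x)), best_f, {
        "trace": trace,
        "n_accept": n_accept,
        "n_infeasible": n_infeasible,
    }


def fit_healthy(
    muscle: ObservationSeries,
    stem: ObservationSeries,
    d0: float = 0.05,
    m: float = 1000.0,
    sa: Optional[SAConfig] = None,
    d0_grid: Optional[Sequence[float]] = None,
    m_grid: Optional[Sequence[float]] = None,
    conv: ConversionConvention = ConversionConvention(),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Simulated-annealing fit of (p0, p1, nu0, nu1) to muscle+stem mass data.

    The pooled RMSE over both series (in grams) is minimized subject to
    0 < p0+p1 <= 1 and p0 < 1/2 < p0+p1; initial conditions come from the
    series' day-0 values.  An outer one-at-a-time loop re-runs the annealer
    over a small grid of the fixed parameters (d0, m) and keeps the global
    best.  Deterministic for a given ``sa.seed``.
    """
    sa = sa or SAConfig()
    d0_grid = list(d0_grid) if d0_grid is not None else [d0]
    m_grid = list(m_grid) if m_grid is not None else [m]

    best = None
    outer = []
    for i, (d0_i, m_i) in enumerate(itertools.product(d0_grid, m_grid)):
        objective = _healthy_objective_factory(muscle, stem, d0_i, m_i, conv, rtol, atol)
        cfg_i = SAConfig(**{**sa.__dict__, "seed": sa.seed + i})
        x, f, diag = _anneal(objective, cfg_i)
        outer.append({"d0": d0_i, "m": m_i, "rmse": f, "seed": cfg_i.seed})
        if best is None or f < best[1]:
            best = (x, f, diag, d0_i, m_i, cfg_i.seed)

    x, f, diag, d0_b, m_b, seed_b = best
    hp = HealthyParams(x["p0"], x["p1"], x["nu0"], x["nu1"], d0_b, m_b)
    return FitResult(
        params=hp,
        rmse=f,
        diagnostics={
            "method": "simulated_annealing",
            "seed": seed_b,
            "base_seed": sa.seed,
            "n_temps": sa.n_temps,
            "n_props": sa.n_props,
            "cooling": sa.cooling,
            "objective_trace": diag["trace"],
            "n_accept": diag["n_accept"],
            "n_infeasible": diag["n_infeasible"],
            "outer_loop": outer,
        },
        fixed={"d0": d0_b, "m": m_b},
    )


# --------------------------------------------------------------------------
# Stage 3: grid-search fits (vectorized batch ODE solves)
# --------------------------------------------------------------------------


def _batch_solve(rhs_vec, y0_stack: np.ndarray, t_eval: np.ndarray, rtol: float, atol: float):
    """Integrate N independent systems at once.

    ``y0_stack`` has shape (k, N); ``rhs_vec(t, y)`` must accept and return
    (k, N).  Returns array of shape (len(t_eval), k, N).
    """
    k, N = y0_stack.shape

    def flat_rhs(t, y):
        return rhs_vec(t, y.reshape(k, N)).reshape(-1)

    t0 = 0.0
    t1 = float(t_eval[-1]) if t_eval[-1] > 0 else 1.0
    sol = solve_ivp(
        flat_rhs, (t0, t1), y0_stack.reshape(-1),
        method="RK45", rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success or sol.y.shape[1] != t_eval.size:
        raise RuntimeError(f"batch ODE solve failed: {sol.message}")
    return sol.y.T.reshape(len(t_eval), k, N)


def _grid_product(grid: dict, order: Sequence[str]):
    axes = {n: np.atleast_1d(np.asarray(grid[n], dtype=float)) for n in order}
    for n, a in axes.items():
        if a.size == 0:
            raise ValueError(f"empty grid for parameter {n!r}")
    mesh = np.meshgrid(*[axes[n] for n in order], indexing="ij")
    flat = {n: m.reshape(-1) for n, m in zip(order, mesh)}
    shape = tuple(axes[n].size for n in order)
    return axes, flat, shape


def _boundary_flags(axes: dict, best_idx: dict) -> list:
    flags = []
    for n, a in axes.items():
        if a.size > 1 and best_idx[n] in (0, a.size - 1):
            flags.append(n)
    return flags


def _finish_grid_fit(order, axes, shape, errs, make_params, fixed, extra_diag=None):
    surface = errs.reshape(shape)
    flat_best = int(np.argmin(errs))
    idx = np.unravel_index(flat_best, shape)
    best_idx = dict(zip(order, (int(i) for i in idx)))
    best_vals = {n: float(axes[n][best_idx[n]]) for n in order}
    diagnostics = {
        "method": "grid_search",
        "grid_shape": list(shape),
        "n_points": int(errs.size),
        "argmin_index": [int(i) for i in idx],
        "on_boundary": _boundary_flags(axes, best_idx),
        **(extra_diag or {}),
    }
    return FitResult(
        params=make_params(best_vals),
        rmse=float(errs[flat_best]),
        diagnostics=diagnostics,
        fixed=fixed,
        surface=surface,
        axes=axes,
    )


def fit_tumor(
    data: ObservationSeries,
    grid: Optional[dict] = None,
    T0: float = 0.5,
    eta: float = 20.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Exhaustive grid search of (mu, mu1) against tumor-volume data.

    T(0) = 0.5 mm^3 (the implant) and eta = 20 are fixed.  All grid points
    are integrated simultaneously as one stacked ODE system; the full RMSE
    surface is returned alongside the argmin.
    """
    if len(data) == 0:
        raise ValueError("empty observation series")
    grid = grid or {"mu": DEFAULT_GRIDS["mu"], "mu1": DEFAULT_GRIDS["mu1"]}
    order = ["mu", "mu1"]
    axes, flat, shape = _grid_product(grid, order)
    mu, mu1 = flat["mu"], flat["mu1"]
    tth = mu1 / mu
    t_eval = np.unique(np.concatenate([[0.0], data.days]))

    def rhs_vec(t, y):
        T = np.maximum(y[0], 0.0)
        r = T / tth
        with np.errstate(divide="ignore"):
            x = eta * np.log(np.where(r > 0, r, 1.0))
        sp = np.where(x > 0, x + np.log1p(np.exp(-np.abs(x))), np.log1p(np.exp(np.minimum(x, 0.0))))
        return (mu * T * np.exp(-sp / eta))[None, :]

    y = _batch_solve(rhs_vec, np.full((1, mu.size), T0), t_eval, rtol, atol)
    sel = np.searchsorted(t_eval, data.days)
    pred = y[sel, 0, :]  # (n_days, N)
    errs = np.sqrt(np.mean((pred - data.values[:, None]) ** 2, axis=0))
    return _finish_grid_fit(
        order, axes, shape, errs,
        lambda v: TumorParams(v["mu"], v["mu1"], eta),
        fixed={"T0": T0, "eta": eta},
    )


def _cachexia_rhs_vec_factory(hp: HealthyParams, tp: TumorParams, eps, dS, dM, m2, A=None):
    A1 = A2 = A3 = A4 = 1.0
    if A is not None:
        A1, A2, A3, A4 = A

    def rhs_vec(t, y):
        S, M, T = y[0], y[1], np.maximum(y[2], 0.0)
        f = 1.0 / (1.0 + M / hp.m)
        p = hp.p0 + hp.p1 * f
        nu = hp.nu0 + hp.nu1 * f
        tf = T / (m2 + T)
        sup = 1.0 - A1 * eps * tf
        dS_dt = (2 * p - 1) * nu * sup * S - A2 * dS * tf * S
        dM_dt = 2 * (1 - p) * nu * sup * S - (A4 * hp.d0 + A3 * dM * tf) * M
        r = T / tp.threshold
        with np.errstate(divide="ignore"):
            x = tp.eta * np.log(np.where(r > 0, r, 1.0))
        sp = np.where(x > 0, x + np.log1p(np.exp(-np.abs(x))), np.log1p(np.exp(np.minimum(x, 0.0))))
        dT_dt = tp.mu * T * np.exp(-sp / tp.eta)
        return np.stack([dS_dt, dM_dt, dT_dt])

    return rhs_vec


def fit_cachexia(
    data: ObservationSeries,
    grid: Optional[dict] = None,
    hp: Optional[HealthyParams] = None,
    tp: Optional[TumorParams] = None,
    ics: Optional[TissueState] = None,
    conv: ConversionConvention = ConversionConvention(),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Grid search of (eps, dS, dM, m2) against lean-mass data in grams.

    The observable is the model-predicted lean mass xi*(S+M).  Initial
    conditions must come from the cohort's day-0 weight (see
    :func:`cachexsim.model_core.initial_conditions_from_weight`) with
    T(0)=0.5 mm^3.  The full objective surface is kept so the documented
    eps~0 flat direction can be inspected.
    """
    if len(data) == 0:
        raise ValueError("empty observation series")
    if hp is None or tp is None or ics is None:
        raise ValueError("fit_cachexia needs healthy params, tumor params and initial conditions")
    grid = grid or {n: DEFAULT_GRIDS[n] for n in ("eps", "dS", "dM", "m2")}
    order = ["eps", "dS", "dM", "m2"]
    axes, flat, shape = _grid_product(grid, order)
    N = flat["eps"].size
    rhs_vec = _cachexia_rhs_vec_factory(hp, tp, flat["eps"], flat["dS"], flat["dM"], flat["m2"])
    y0 = np.tile(np.array([[ics.S], [ics.M], [ics.T]]), (1, N))
    t_eval = np.unique(np.concatenate([[0.0], data.days]))
    y = _batch_solve(rhs_vec, y0, t_eval, rtol, atol)
    sel = np.searchsorted(t_eval, data.days)
    pred = conv.xi * (y[sel, 0, :] + y[sel, 1, :])
    errs = np.sqrt(np.mean((pred - data.values[:, None]) ** 2, axis=0))
    return _finish_grid_fit(
        order, axes, shape, errs,
        lambda v: CachexiaParams(v["eps"], v["dS"], v["dM"], v["m2"]),
        fixed={"healthy": hp.to_dict(), "tumor": tp.to_dict(), "ics": [ics.S, ics.M, ics.T]},
    )


def fit_treatment(
    data: ObservationSeries,
    t_start: float,
    grid: Optional[dict] = None,
    hp: Optional[HealthyParams] = None,
    cp: Optional[CachexiaParams] = None,
    tp: Optional[TumorParams] = None,
    ics: Optional[TissueState] = None,
    conv: ConversionConvention = ConversionConvention(),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Grid search of (A1, A2, A3, A4) against treated-cohort lean mass.

    The pre-treatment phase [0, t_start) follows the cachexia system (one
    shared solve); every efficacy combination is then integrated from the
    common switch state to the last observation day.
    """
    if len(data) == 0:
        raise ValueError("empty observation series")
    if hp is None or cp is None or tp is None or ics is None:
        raise ValueError("fit_treatment needs healthy, cachexia, tumor params and ICs")
    grid = grid or {n: DEFAULT_GRIDS[n] for n in ("A1", "A2", "A3", "A4")}
    for n in ("A1", "A2", "A3", "A4"):
        a = np.atleast_1d(np.asarray(grid[n], float))
        if np.any((a < 0) | (a > 1)):
            raise ValueError(f"{n} grid must lie within [0, 1]")
    order = ["A1", "A2", "A3", "A4"]
    axes, flat, shape = _grid_product(grid, order)
    N = flat["A1"].size

    pre_days = data.days[data.days <= t_start]
    post_days = data.days[data.days > t_start]

    # shared cachexia solve up to the switch
    rhs_pre = _cachexia_rhs_vec_factory(
        hp, tp, np.array([cp.eps]), np.array([cp.dS]), np.array([cp.dM]), np.array([cp.m2])
    )
    t_pre = np.unique(np.concatenate([[0.0], pre_days, [t_start]]))
    y_pre = _batch_solve(rhs_pre, np.array([[ics.S], [ics.M], [ics.T]]), t_pre, rtol, atol)
    y_switch = y_pre[-1, :, 0]

    preds = []
    if pre_days.size:
        sel = np.searchsorted(t_pre, pre_days)
        preds.append(np.tile(conv.xi * (y_pre[sel, 0, 0] + y_pre[sel, 1, 0])[:, None], (1, N)))
    if post_days.size:
        rhs_post = _cachexia_rhs_vec_factory(
            hp, tp, cp.eps, cp.dS, cp.dM, cp.m2,
            A=(flat["A1"], flat["A2"], flat["A3"], flat["A4"]),
        )
        t_post = np.unique(np.concatenate([[t_start], post_days])) - t_start
        y0 = np.tile(y_switch[:, None], (1, N))
        y_post = _batch_solve(rhs_post, y0, t_post, rtol, atol)
        sel = np.searchsorted(t_post, post_days - t_start)
        preds.append(conv.xi * (y_post[sel, 0, :] + y_post[sel, 1, :]))

    pred = np.concatenate(preds, axis=0)
    obs = np.concatenate([data.values[data.days <= t_start], data.values[data.days > t_start]])
    errs = np.sqrt(np.mean((pred - obs[:, None]) ** 2, axis=0))
    return _finish_grid_fit(
        order, axes, shape, errs,
        lambda v: TreatmentParams(v["A1"], v["A2"], v["A3"], v["A4"], t_start),
        fixed={
            "healthy": hp.to_dict(), "cachexia": cp.to_dict(), "tumor": tp.to_dict(),
            "ics": [ics.S, ics.M, ics.T], "t_start": t_start,
        },
    )
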