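"""Synthetic mouse cohorts with the statistical structure the pipeline assumes.

The generators emulate the three kinds of input the calibration pipeline
consumes, none of which are available machine-readably:

* healthy growth cohorts — logistic body-weight curves (the supplier growth
  data convention: weekly weighings to day 84, then every 10 days to 300),
* cachectic cohorts — lean mass, gross body weight, and tumor volume from
  the tumor-bearing ODE system, with initial conditions built from the
  cohort's day-0 weight at the day-49 reference stem ratio,
* treated cohorts — the same observables under ActRIIB blockade starting at
  a given day.

Measurement noise is multiplicative Gaussian on the *reported* quantities
(scales measure proportionally), truncated at four standard deviations to
preserve positivity; CV defaults to 2%.  At CV=0 every generator is
deterministic, and the weight reconstruction

    weight = lean/lean_fraction + xi*T

is the exact inverse of the lean-mass deconstruction used in fitting, so
round trips are lossless and parameter-recovery tests can be exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .calibrate import ObservationSeries
from .model_core import (
    CachexiaParams,
    ConversionConvention,
    HealthyParams,
    LogisticParams,
    TissueState,
    TreatmentParams,
    TumorParams,
    initial_conditions_from_weight,
    logistic_weight,
)
from .simulate import ExperimentSpec, day49_stem_ratio, integrate, simulate_treatment

__all__ = [
    "CohortSpec",
    "Cohort",
    "default_healthy_schedule",
    "default_disease_schedule",
    "generate_healthy_cohort",
    "generate_cachexia_cohort",
    "generate_treatment_cohort",
]


def default_healthy_schedule() -> np.ndarray:
    """Weekly weighings days 0-84, then every 10 days to day 300."""
    return np.concatenate([np.arange(0.0, 85.0, 7.0), np.arange(90.0, 301.0, 10.0)])


def default_disease_schedule() -> np.ndarray:
    """Daily weighings for 30 days post-implantation."""
    return np.arange(0.0, 31.0, 1.0)


@dataclass
class CohortSpec:
    """How to generate one cohort: size, schedule, noise, seed.

    ``days=None`` selects the generator's default cadence (healthy: weekly
    to day 84 then every 10 days to 300; disease: daily to day 30).
    """

    n: int = 10
    days: Optional[np.ndarray] = None
    cv: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.days is not None:
            self.days = np.asarray(self.days, dtype=float)
            if self.days.size == 0:
                raise ValueError("measurement schedule must be non-empty")
        if self.n < 1:
            raise ValueError(f"n >= 1 violated (n={self.n})")
        if self.cv < 0:
            raise ValueError(f"CV >= 0 violated (cv={self.cv})")


@dataclass
class Cohort:
    """Generated cohort: long-format animal table plus the noiseless truth.

    ``animals`` has columns (animal_id, day, value, observable); ``truth``
    maps observable name -> noiseless ObservationSeries; ``manifest``
    records the generating spec, parameters and seed.
    """

    animals: pd.DataFrame
    truth: dict
    manifest: dict

    def mean(self, observable: str) -> ObservationSeries:
        sub = self.animals[self.animals["observable"] == observable]
        if sub.empty:
            raise KeyError(f"no observable {observable!r} in cohort")
        g = sub.groupby("day")["value"].mean()
        return ObservationSeries(g.index.to_numpy(), g.to_numpy(), observable)

    def to_csv(self, path) -> None:
        self.animals.to_csv(path, index=False)


def _noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    z = rng.standard_normal(shape)
    z = np.clip(z, -4.0, 4.0)  # truncate to keep reported values positive
    return 1.0 + cv * z


def _long_table(days: np.ndarray, per_animal: dict) -> pd.DataFrame:
    frames = []
    for obs, mat in per_animal.items():
        n = mat.shape[0]
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": np.repeat(np.arange(n), days.size),
                    "day": np.tile(days, n),
                    "value": mat.reshape(-1),
                    "observable": obs,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_healthy_cohort(
    spec: CohortSpec,
    lp: Optional[LogisticParams] = None,
) -> Cohort:
    """Body-weight series per animal from the closed-form logistic curve.

    Defaults reproduce the reference growth conditions (alpha=0.0756/day,
    K=28.3 g, W0=11.26 g at age 3 weeks) on the healthy weighing schedule.
    """
    from .model_core import logistic_defaults

    lp = lp or logistic_defaults()
    days = spec.days if spec.days is not None else default_healthy_schedule()
    days = np.asarray(days, dtype=float)
    rng = np.random.default_rng(spec.seed)
    w = logistic_weight(days, lp)
    weights = w[None, :] * _noise(rng, (spec.n, days.size), spec.cv)
    animals = _long_table(days, {"body_weight": weights})
    truth = {"body_weight": ObservationSeries(days, w, "body_weight")}
    manifest = {
        "generator": "healthy",
        "logistic": lp.to_dict(),
        "n": spec.n,
        "cv": spec.cv,
        "seed": spec.seed,
        "days": days.tolist(),
    }
    return Cohort(animals, truth, manifest)


def _disease_truth(
    traj, conv: ConversionConvention
) -> dict:
    lean = conv.xi * (traj.S + traj.M)
    weight = lean / conv.lean_fraction + conv.xi * traj.T
    return {
        "lean_mass": ObservationSeries(traj.times, lean, "lean_mass"),
        "body_weight": ObservationSeries(traj.times, weight, "body_weight"),
        "tumor_volume": ObservationSeries(traj.times, traj.T, "tumor_volume"),
    }


def _emit_disease_cohort(spec: CohortSpec, traj, conv, manifest) -> Cohort:
    truth = _disease_truth(traj, conv)
    days = traj.times
    rng = np.random.default_rng(spec.seed)
    w_noisy = truth["body_weight"].values[None, :] * _noise(rng, (spec.n, days.size), spec.cv)
    t_noisy = truth["tumor_volume"].values[None, :] * _noise(rng, (spec.n, days.size), spec.cv)
    # lean mass is derived from the reported weight by the fitting
    # deconstruction: 40% of (weight minus model-predicted tumor mass)
    lean_noisy = conv.lean_fraction * (w_noisy - conv.xi * truth["tumor_volume"].values[None, :])
    animals = _long_table(
        days, {"body_weight": w_noisy, "lean_mass": lean_noisy, "tumor_volume": t_noisy}
    )
    return Cohort(animals, truth, manifest)


def generate_cachexia_cohort(
    spec: CohortSpec,
    hp: HealthyParams,
    cp: CachexiaParams,
    tp: TumorParams,
    day0_weight: float = 25.26,
    T0: float = 0.5,
    psi_ref: Optional[float] = None,
    conv: ConversionConvention = ConversionConvention(),
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Cohort:
    """Untreated tumor-bearing cohort from the cachexia ODE system.

    Initial conditions come from the cohort's day-0 weight split at the
    day-49 reference stem ratio (computed from the healthy growth solve
    unless ``psi_ref`` is given); the tumor starts at the 0.5 mm^3 implant.
    """
    days = spec.days if spec.days is not None else default_disease_schedule()
    psi = psi_ref if psi_ref is not None else day49_stem_ratio(hp)
    S0, M0 = initial_conditions_from_weight(day0_weight, psi, conv)
    ics = TissueState(S0, M0, T0)
    run = ExperimentSpec(
        model="cachexia", healthy=hp, cachexia=cp, tumor=tp, initial_state=ics,
        t_stop=float(days[-1]) if days[-1] > 0 else 1.0,
        t_step=_step_for(days), rtol=rtol, atol=atol,
    )
    traj = integrate(run)
    traj = _sample_at(traj, days)
    manifest = {
        "generator": "cachexia",
        "healthy": hp.to_dict(), "cachexia": cp.to_dict(), "tumor": tp.to_dict(),
        "day0_weight": day0_weight, "psi_ref": psi, "T0": T0,
        "n": spec.n, "cv": spec.cv, "seed": spec.seed, "days": np.asarray(days).tolist(),
    }
    return _emit_disease_cohort(spec, traj, conv, manifest)


def generate_treatment_cohort(
    spec: CohortSpec,
    hp: HealthyParams,
    cp: CachexiaParams,
    tp: TumorParams,
    tx: TreatmentParams,
    day0_weight: float = 25.26,
    T0: float = 0.5,
    psi_ref: Optional[float] = None,
    conv: ConversionConvention = ConversionConvention(),
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Cohort:
    """Treated cohort: cachexia dynamics until ``tx.t_start``, blockade after."""
    days = spec.days if spec.days is not None else default_disease_schedule()
    psi = psi_ref if psi_ref is not None else day49_stem_ratio(hp)
    S0, M0 = initial_conditions_from_weight(day0_weight, psi, conv)
    ics = TissueState(S0, M0, T0)
    run = ExperimentSpec(
        model="cachexia", healthy=hp, cachexia=cp, tumor=tp, initial_state=ics,
        t_stop=float(days[-1]) if days[-1] > 0 else 1.0,
        t_step=_step_for(days), rtol=rtol, atol=atol,
    )
    traj = simulate_treatment(run, tx)
    traj = _sample_at(traj, days)
    manifest = {
        "generator": "treatment",
        "healthy": hp.to_dict(), "cachexia": cp.to_dict(), "tumor": tp.to_dict(),
        "treatment": tx.to_dict(),
        "day0_weight": day0_weight, "psi_ref": psi, "T0": T0,
        "n": spec.n, "cv": spec.cv, "seed": spec.seed, "days": np.asarray(days).tolist(),
    }
    return _emit_disease_cohort(spec, traj, conv, manifest)


def _step_for(days: np.ndarray) -> float:
    diffs = np.diff(np.unique(days))
    step = float(diffs.min()) if diffs.size else 1.0
    return max(step, 1e-3)


def _sample_at(traj, days: np.ndarray):
    from .model_core import Trajectory

    idx = []
    for d in days:
        i = int(np.argmin(np.abs(traj.times - d)))
        if not np.isclose(traj.times[i], d, atol=1e-9):
            raise RuntimeError(f"schedule day {d} not on the solver reporting grid")
        idx.append(i)
    idx = np.asarray(idx)
    T = traj.T[idx] if traj.T is not None else None
    return Trajectory(traj.times[idx], traj.S[idx], traj.M[idx], T, traj.meta)
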