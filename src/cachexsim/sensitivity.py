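"""Local one-at-a-time sensitivity analysis.

Each parameter rho is perturbed by a fraction f (default +/-5%) and the
relative change

    phi = 100 * (y(rho*(1+f)) - y(rho)) / y(rho)   [%]

is reported for the satellite and muscle observables.  Two evaluation
contexts are provided: the healthy closed-form steady state (Sss, Mss), and
the day-20 state of the cachexia or treatment solve (during active muscle
loss, since the cachectic animal never reaches a steady state).

Structural NA entries — parameters the closed-form observable simply does
not contain, e.g. Mss versus nu0 — are derived symbolically from the steady
state expressions, not hard-coded.  Perturbations that push p0 across the
1/2 boundary are evaluated anyway (the closed form blows up there) and
flagged ``unphysical`` instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    CachexiaParams,
    HealthyParams,
    TissueState,
    TreatmentParams,
    TumorParams,
)
from .simulate import ExperimentSpec, integrate, simulate_treatment

__all__ = [
    "SensitivityReport",
    "relative_sensitivity",
    "healthy_sensitivity_table",
    "cachexia_sensitivity_table",
    "treatment_sensitivity_table",
]


@dataclass
class SensitivityReport:
    """Rows of relative-change results for one evaluation context.

    Each row: parameter name, base value, signed fraction, percent change in
    the satellite (``S_pct``) and muscle (``M_pct``) observables (None where
    the observable does not depend on the parameter), and an
    ``unphysical_regime`` flag for perturbations that leave the
    p0 < 1/2 < p0+p1 region.
    """

    context: str
    rows: list = field(default_factory=list)

    def add(self, param, base, fraction, S_pct, M_pct, unphysical=False):
        self.rows.append(
            {
                "param": param,
                "base": base,
                "fraction": fraction,
                "S_pct": S_pct,
                "M_pct": M_pct,
                "unphysical_regime": unphysical,
            }
        )

    def cell(self, param: str, observable: str, fraction: float) -> Optional[float]:
        """Look up one phi value (observable 'S' or 'M', signed fraction)."""
        for r in self.rows:
            if r["param"] == param and np.isclose(r["fraction"], fraction):
                return r[f"{observable}_pct"]
        raise KeyError(f"no row for param={param!r}, fraction={fraction}")

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per parameter, decrease/increase columns."""
        params = list(dict.fromkeys(r["param"] for r in self.rows))
        recs = []
        for p in params:
            rec = {"param": p, "base": next(r["base"] for r in self.rows if r["param"] == p)}
            for r in self.rows:
                if r["param"] != p:
                    continue
                tag = "decrease" if r["fraction"] < 0 else "increase"
                rec[f"S_{tag}_pct"] = r["S_pct"]
                rec[f"M_{tag}_pct"] = r["M_pct"]
                if r["unphysical_regime"]:
                    rec["unphysical_regime"] = True
            rec.setdefault("unphysical_regime", False)
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump({"context": self.context, "rows": self.rows}, fh, indent=1)


# --------------------------------------------------------------------------
# Generic operation
# --------------------------------------------------------------------------


def relative_sensitivity(observable, params, name: str, fraction: float) -> float:
    """phi = 100*(y(rho*(1+fraction)) - y(rho))/y(rho) for one parameter.

    ``observable`` is a callable of the parameter object; ``fraction`` is
    signed (-0.05 for a 5% decrease).
    """
    base = observable(params)
    if base == 0:
        raise ZeroDivisionError(f"base observable is zero; phi undefined for {name}")
    perturbed = observable(params.replace(**{name: getattr(params, name) * (1.0 + fraction)}))
    return 100.0 * (perturbed - base) / base


# --------------------------------------------------------------------------
# Healthy steady-state context (closed form)
# --------------------------------------------------------------------------

# Raw steady-state formulas, evaluated without the p0 < 1/2 precondition so
# that boundary-crossing perturbations reproduce the documented extreme
# (unphysical) values instead of erroring.


def _raw_mss(hp: HealthyParams) -> float:
    return hp.m * (2 * (hp.p0 + hp.p1) - 1) / (1 - 2 * hp.p0)


def _raw_sss(hp: HealthyParams) -> float:
    return (
        2 * hp.m * hp.d0 * hp.p1 * (2 * (hp.p0 + hp.p1) - 1)
        / ((1 - 2 * hp.p0) * (2 * hp.p1 * hp.nu0 + (1 - 2 * hp.p0) * hp.nu1))
    )


def _steady_state_dependencies() -> dict:
    """Which parameters each closed-form observable actually contains."""
    import sympy as sp

    p0, p1, nu0, nu1, d0, m = sp.symbols("p0 p1 nu0 nu1 d0 m", positive=True)
    mss = m * (2 * (p0 + p1) - 1) / (1 - 2 * p0)
    sss = (
        2 * m * d0 * p1 * (2 * (p0 + p1) - 1)
        / ((1 - 2 * p0) * (2 * p1 * nu0 + (1 - 2 * p0) * nu1))
    )
    names = {p0: "p0", p1: "p1", nu0: "nu0", nu1: "nu1", d0: "d0", m: "m"}
    return {
        "S": {names[s] for s in sss.free_symbols},
        "M": {names[s] for s in mss.free_symbols},
    }


_SS_DEPS: Optional[dict] = None


def _ss_deps() -> dict:
    global _SS_DEPS
    if _SS_DEPS is None:
        _SS_DEPS = _steady_state_dependencies()
    return _SS_DEPS


def healthy_sensitivity_table(
    hp: HealthyParams,
    fraction: float = 0.05,
    params: Sequence[str] = ("m", "p0", "p1", "nu0", "nu1", "d0"),
) -> SensitivityReport:
    """Steady-state sensitivities of (Sss, Mss) for each healthy parameter.

    NA (None) is recorded where the closed form does not contain the
    parameter; perturbations that violate p0 < 1/2 < p0+p1 are evaluated on
    the raw formulas and flagged unphysical.
    """
    hp.require_steady_state()
    deps = _ss_deps()
    base_s, base_m = _raw_sss(hp), _raw_mss(hp)
    report = SensitivityReport(context="steady-state")
    for name in params:
        for f in (-fraction, +fraction):
            pert = hp.replace(**{name: getattr(hp, name) * (1.0 + f)})
            unphys = not (pert.p0 < 0.5 < pert.p0 + pert.p1)
            s_pct = (
                100.0 * (_raw_sss(pert) - base_s) / base_s if name in deps["S"] else None
            )
            m_pct = (
                100.0 * (_raw_mss(pert) - base_m) / base_m if name in deps["M"] else None
            )
            report.add(name, getattr(hp, name), f, s_pct, m_pct, unphys)
    return report


# --------------------------------------------------------------------------
# Day-20 dynamic context (cachexia / treatment solves)
# --------------------------------------------------------------------------


def _solve_day(spec: ExperimentSpec, tx: Optional[TreatmentParams], day: float):
    if tx is None:
        traj = integrate(spec)
    else:
        traj = simulate_treatment(spec, tx)
    i = int(np.argmin(np.abs(traj.times - day)))
    if not np.isclose(traj.times[i], day):
        raise RuntimeError(f"evaluation day {day} not on the reporting grid")
    return float(traj.S[i]), float(traj.M[i])


def cachexia_sensitivity_table(
    hp: HealthyParams,
    cp: CachexiaParams,
    tp: TumorParams,
    ics: TissueState,
    day: float = 20.0,
    fraction: float = 0.05,
    params: Sequence[str] = ("m2", "eps", "dS", "dM"),
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SensitivityReport:
    """Day-20 sensitivities of S and M to the cachexia parameters.

    Each perturbation re-solves the tumor-bearing system from the cohort
    initial conditions (T(0)=0.5 mm^3 by convention) to the evaluation day.
    """

    def solve(cp_i):
        spec = ExperimentSpec(
            model="cachexia", healthy=hp, cachexia=cp_i, tumor=tp,
            initial_state=ics, t_stop=day, t_step=day / 40, rtol=rtol, atol=atol,
        )
        return _solve_day(spec, None, day)

    base_s, base_m = solve(cp)
    report = SensitivityReport(context=f"day-{day:g}")
    for name in params:
        for f in (-fraction, +fraction):
            s, m = solve(cp.replace(**{name: getattr(cp, name) * (1.0 + f)}))
            report.add(
                name, getattr(cp, name), f,
                100.0 * (s - base_s) / base_s,
                100.0 * (m - base_m) / base_m,
            )
    return report


def treatment_sensitivity_table(
    hp: HealthyParams,
    cp: CachexiaParams,
    tp: TumorParams,
    tx: TreatmentParams,
    ics: TissueState,
    day: float = 20.0,
    fraction: float = 0.05,
    params: Sequence[str] = ("A3", "A4"),
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SensitivityReport:
    """Day-20 sensitivities of S and M to the treatment efficacies.

    Defaults to A3 and A4 only (A1 and A2 are fitted to zero, where a
    multiplicative perturbation has no effect).  The solve switches from
    cachexia to treatment dynamics at ``tx.t_start``.
    """

    def solve(tx_i):
        spec = ExperimentSpec(
            model="cachexia", healthy=hp, cachexia=cp, tumor=tp,
            initial_state=ics, t_stop=day, t_step=day / 40, rtol=rtol, atol=atol,
        )
        return _solve_day(spec, tx_i, day)

    base_s, base_m = solve(tx)
    report = SensitivityReport(context=f"day-{day:g} treatment")
    for name in params:
        base_val = getattr(tx, name)
        for f in (-fraction, +fraction):
            s, m = solve(tx.replace(**{name: base_val * (1.0 + f)}))
            report.add(
                name, base_val, f,
                100.0 * (s - base_s) / base_s,
                100.0 * (m - base_m) / base_m,
            )
    return report
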