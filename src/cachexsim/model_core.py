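"""Core model: parameter types, ODE right-hand sides, and closed forms.

The model describes skeletal-muscle tissue as a two-compartment stem-cell
lineage: satellite cells ``S`` (muscle stem cells) and differentiated muscle
cells ``M``, both measured as tissue volume in mm^3.  Negative feedback from
the muscle compartment onto both the satellite self-renewal probability

    p(M) = p0 + p1 / (1 + M/m)

and the satellite division rate

    nu(M) = nu0 + nu1 / (1 + M/m)

maintains homeostasis.  A growing tumor (exponential-linear growth law)
perturbs the healthy system by suppressing satellite proliferation and adding
tumor-driven death rates to both compartments; ActRIIB-blockade treatment
scales those tumor-derived perturbations down by efficacy factors A1..A4.

Everything downstream (integration, calibration, sensitivity) builds on the
rate functions and closed-form steady states defined here.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "HealthyParams",
    "TumorParams",
    "CachexiaParams",
    "TreatmentParams",
    "TissueState",
    "Trajectory",
    "ConversionConvention",
    "LogisticParams",
    "feedback_probability",
    "feedback_division_rate",
    "healthy_rates",
    "tumor_rate",
    "suppression_factor",
    "cachexia_rates",
    "treatment_rates",
    "steady_state",
    "steady_state_stem_ratio",
    "transition_threshold",
    "effective_muscle_death",
    "initial_conditions_from_weight",
    "weight_to_lean_compartments",
    "logistic_weight",
    "load_params",
    "save_params",
    "table1_healthy_params",
    "table1_reference_state",
    "table2_bundle",
    "logistic_defaults",
]


# --------------------------------------------------------------------------
# Parameter and state types
#
# Validation is eager (on construction) with error messages naming the
# violated inequality: the feedback model is extremely sensitive near
# p = 1/2, so a silently out-of-range parameter set produces confusing
# dynamics rather than an obvious crash.
# --------------------------------------------------------------------------


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


class _ParamBase:
    """Serialization shared by all parameter dataclasses."""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict):
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in fields})

    def replace(self, **changes):
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class HealthyParams(_ParamBase):
    """The six constants of the healthy feedback model.

    p0, p1 : homeostatic / perturbation self-renewal probabilities
    nu0, nu1 : homeostatic / perturbation division rates (1/day)
    d0 : natural muscle-cell death rate (1/day)
    m : feedback half-saturation volume (mm^3)
    """

    p0: float
    p1: float
    nu0: float
    nu1: float
    d0: float
    m: float

    def __post_init__(self):
        _require(self.p0 >= 0, f"p0 >= 0 violated (p0={self.p0})")
        _require(self.p1 >= 0, f"p1 >= 0 violated (p1={self.p1})")
        _require(self.nu0 >= 0, f"nu0 >= 0 violated (nu0={self.nu0})")
        _require(self.nu1 >= 0, f"nu1 >= 0 violated (nu1={self.nu1})")
        _require(self.d0 >= 0, f"d0 >= 0 violated (d0={self.d0})")
        _require(self.m > 0, f"m > 0 violated (m={self.m})")
        _require(
            0 < self.p0 + self.p1 <= 1,
            f"0 < p0+p1 <= 1 violated (p0+p1={self.p0 + self.p1})",
        )

    def require_steady_state(self) -> None:
        """Steady-state formulas need p0 < 1/2 < p0+p1 to be positive."""
        _require(self.p0 < 0.5, f"p0 < 1/2 violated (p0={self.p0})")
        _require(
            self.p0 + self.p1 > 0.5,
            f"p0+p1 > 1/2 violated (p0+p1={self.p0 + self.p1})",
        )


@dataclass(frozen=True)
class TumorParams(_ParamBase):
    """Exponential-linear tumor growth constants.

    mu : exponential-phase growth rate (1/day)
    mu1 : linear-phase growth rate (mm^3/day)
    eta : transition sharpness (dimensionless; 20 captures the data's
        abrupt switch between phases)
    """

    mu: float
    mu1: float
    eta: float = 20.0

    def __post_init__(self):
        _require(self.mu > 0, f"mu > 0 violated (mu={self.mu})")
        _require(self.mu1 > 0, f"mu1 > 0 violated (mu1={self.mu1})")
        _require(self.eta >= 1, f"eta >= 1 violated (eta={self.eta})")

    @property
    def threshold(self) -> float:
        """Transition volume Tth = mu1/mu (mm^3), always recomputed."""
        return self.mu1 / self.mu


@dataclass(frozen=True)
class CachexiaParams(_ParamBase):
    """Tumor-induced perturbations to the healthy system.

    eps : maximum suppression of satellite proliferation (0..1)
    dS, dM : tumor-induced satellite / muscle death rates (1/day)
    m2 : tumor half-saturation volume of all three effects (mm^3)
    """

    eps: float
    dS: float
    dM: float
    m2: float

    def __post_init__(self):
        _require(0 <= self.eps <= 1, f"0 <= eps <= 1 violated (eps={self.eps})")
        _require(self.dS >= 0, f"dS >= 0 violated (dS={self.dS})")
        _require(self.dM >= 0, f"dM >= 0 violated (dM={self.dM})")
        _require(self.m2 > 0, f"m2 > 0 violated (m2={self.m2})")


@dataclass(frozen=True)
class TreatmentParams(_ParamBase):
    """ActRIIB-blockade efficacy multipliers.

    A1 scales eps, A2 scales dS, A3 scales dM, and A4 scales the natural
    muscle death rate d0.  Ai = 1 means no effect on that mechanism,
    Ai = 0 a complete block.  ``t_start`` is the treatment start day
    measured from tumor implantation.
    """

    A1: float
    A2: float
    A3: float
    A4: float
    t_start: float = 0.0

    def __post_init__(self):
        for name in ("A1", "A2", "A3", "A4"):
            v = getattr(self, name)
            _require(0 <= v <= 1, f"0 <= {name} <= 1 violated ({name}={v})")
        _require(self.t_start >= 0, f"t_start >= 0 violated (t_start={self.t_start})")


@dataclass(frozen=True)
class TissueState:
    """Instantaneous compartment volumes in mm^3 (tumor optional)."""

    S: float
    M: float
    T: Optional[float] = None

    def __post_init__(self):
        _require(self.S >= 0, f"S >= 0 violated (S={self.S})")
        _require(self.M >= 0, f"M >= 0 violated (M={self.M})")
        if self.T is not None:
            _require(self.T >= 0, f"T >= 0 violated (T={self.T})")


@dataclass(frozen=True)
class ConversionConvention:
    """Body weight (g) <-> compartment volume (mm^3) deconstruction.

    Body weight is taken to be ``lean_fraction`` skeletal lean mass, split
    ``muscle_share`` muscle / ``stem_share`` satellite, and converted to
    volume with the density-like factor xi (default 0.002 g/mm^3, i.e. a
    1000 mm^3 tumor weighs 2 g).
    """

    xi: float = 0.002
    lean_fraction: float = 0.40
    muscle_share: float = 0.95
    stem_share: float = 0.05

    def __post_init__(self):
        _require(self.xi > 0, f"xi > 0 violated (xi={self.xi})")
        _require(
            0 < self.lean_fraction <= 1,
            f"0 < lean_fraction <= 1 violated ({self.lean_fraction})",
        )
        _require(
            abs(self.muscle_share + self.stem_share - 1.0) < 1e-12,
            "muscle_share + stem_share = 1 violated "
            f"({self.muscle_share}+{self.stem_share})",
        )


@dataclass(frozen=True)
class LogisticParams(_ParamBase):
    """Logistic body-weight growth: dW/dt = alpha W (1 - W/K)."""

    alpha: float
    K: float
    W0: float

    def __post_init__(self):
        _require(self.alpha > 0, f"alpha > 0 violated (alpha={self.alpha})")
        _require(self.K > 0, f"K > 0 violated (K={self.K})")
        _require(0 < self.W0 <= self.K, f"0 < W0 <= K violated (W0={self.W0}, K={self.K})")


@dataclass
class Trajectory:
    """Time-indexed (S, M[, T]) series with model/parameter metadata.

    Times are strictly increasing days.  The healthy model carries no tumor
    column (``T is None``).  ``meta`` records the model identifier, the
    parameter snapshot and the time-origin convention (healthy day 0 = age
    3 weeks; cachexia/treatment day 0 = implantation day = healthy day 49).
    """

    times: np.ndarray
    S: np.ndarray
    M: np.ndarray
    T: Optional[np.ndarray] = None
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.T is not None:
            self.T = np.asarray(self.T, dtype=float)
        _require(np.all(np.diff(self.times) > 0), "times strictly increasing violated")
        n = self.times.size
        _require(self.S.size == n and self.M.size == n, "one state per time violated")
        if self.T is not None:
            _require(self.T.size == n, "one state per time violated (T)")

    def state_at(self, i: int) -> TissueState:
        T = None if self.T is None else float(self.T[i])
        return TissueState(float(self.S[i]), float(self.M[i]), T)

    def lean_mass_g(self, conv: ConversionConvention = ConversionConvention()) -> np.ndarray:
        """Model-predicted lean mass xi*(S+M) in grams."""
        return conv.xi * (self.S + self.M)

    def to_frame(self, conv: ConversionConvention = ConversionConvention()):
        import pandas as pd

        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(self.M > 0, self.S / np.where(self.M > 0, self.M, 1.0), np.nan)
        return pd.DataFrame(
            {
                "day": self.times,
                "S_mm3": self.S,
                "M_mm3": self.M,
                "T_mm3": self.T if self.T is not None else np.full_like(self.times, np.nan),
                "lean_mass_g": self.lean_mass_g(conv),
                "stem_ratio": ratio,
            }
        )

    def to_csv(self, path, conv: ConversionConvention = ConversionConvention()) -> None:
        self.to_frame(conv).to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "meta": self.meta,
            "times": self.times.tolist(),
            "S": self.S.tolist(),
            "M": self.M.tolist(),
            "T": None if self.T is None else self.T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# --------------------------------------------------------------------------
# Rate functions (healthy -> tumor -> cachexia -> treatment)
# --------------------------------------------------------------------------


def feedback_probability(M, hp: HealthyParams):
    """Self-renewal probability p(M) = p0 + p1/(1 + M/m).

    Decreases from p0+p1 at M=0 toward p0 as the muscle compartment grows;
    the homeostatic muscle size is where p crosses 1/2.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError(f"M >= 0 violated (M={M})")
    out = hp.p0 + hp.p1 / (1.0 + M / hp.m)
    return float(out) if out.ndim == 0 else out


def feedback_division_rate(M, hp: HealthyParams):
    """Satellite division rate nu(M) = nu0 + nu1/(1 + M/m) per day."""
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError(f"M >= 0 violated (M={M})")
    out = hp.nu0 + hp.nu1 / (1.0 + M / hp.m)
    return float(out) if out.ndim == 0 else out


def healthy_rates(state: TissueState, hp: HealthyParams) -> tuple:
    """(dS/dt, dM/dt) of the healthy feedback model, mm^3/day.

    dS/dt = (2p-1) nu S        (net self-renewal)
    dM/dt = 2(1-p) nu S - d0 M (differentiation influx minus turnover)
    """
    if state.T is not None:
        raise ValueError("healthy model state carries no tumor compartment")
    p = feedback_probability(state.M, hp)
    nu = feedback_division_rate(state.M, hp)
    dS = (2.0 * p - 1.0) * nu * state.S
    dM = 2.0 * (1.0 - p) * nu * state.S - hp.d0 * state.M
    return dS, dM


def tumor_rate(T, tp: TumorParams):
    """Exponential-linear growth dT/dt = mu T (1 + (T/Tth)^eta)^(-1/eta).

    Reduces to mu*T for T << Tth and saturates at mu1 for T >> Tth.
    Evaluated in log space so that (T/Tth)^eta cannot overflow for large
    tumors at eta = 20.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError(f"T >= 0 violated (T={T})")
    r = T / tp.threshold
    out = np.zeros_like(T, dtype=float)
    pos = r > 0
    with np.errstate(divide="ignore"):
        x = tp.eta * np.log(np.where(pos, r, 1.0))
    # log(1 + r^eta) computed as a stable softplus
    log1p_pow = np.where(x > 0, x + np.log1p(np.exp(-np.abs(x))), np.log1p(np.exp(np.minimum(x, 0.0))))
    out = np.where(pos, tp.mu * T * np.exp(-log1p_pow / tp.eta), 0.0)
    return float(out) if out.ndim == 0 else out


def suppression_factor(T, cp: CachexiaParams):
    """Proliferation suppression 1 - eps*T/(m2+T), in [1-eps, 1]."""
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError(f"T >= 0 violated (T={T})")
    out = 1.0 - cp.eps * T / (cp.m2 + T)
    return float(out) if out.ndim == 0 else out


def cachexia_rates(
    state: TissueState, hp: HealthyParams, cp: CachexiaParams, tp: TumorParams
) -> tuple:
    """(dS/dt, dM/dt, dT/dt) of the tumor-bearing system.

    The tumor suppresses satellite proliferation through the factor
    ``1 - eps T/(m2+T)`` and adds saturating death terms dS*T/(m2+T)*S and
    dM*T/(m2+T)*M; the self-renewal probability p is assumed unmodified by
    the tumor.  With eps = dS = dM = 0 this reduces exactly to the healthy
    system plus independent tumor growth.
    """
    T = state.T if state.T is not None else 0.0
    p = feedback_probability(state.M, hp)
    nu = feedback_division_rate(state.M, hp)
    tf = T / (cp.m2 + T)
    sup = 1.0 - cp.eps * tf
    dS = (2.0 * p - 1.0) * nu * sup * state.S - cp.dS * tf * state.S
    dM = 2.0 * (1.0 - p) * nu * sup * state.S - (hp.d0 + cp.dM * tf) * state.M
    dT = tumor_rate(T, tp)
    return dS, dM, dT


def treatment_rates(
    state: TissueState,
    hp: HealthyParams,
    cp: CachexiaParams,
    tp: TumorParams,
    tx: TreatmentParams,
) -> tuple:
    """(dS/dt, dM/dt, dT/dt) under ActRIIB blockade.

    Treatment scales the tumor-derived effects: eps -> A1*eps,
    dS -> A2*dS, dM -> A3*dM, and the natural death rate d0 -> A4*d0.
    Tumor growth itself is unaffected.  A1=A2=A3=A4=1 reproduces
    :func:`cachexia_rates` bit for bit.
    """
    T = state.T if state.T is not None else 0.0
    p = feedback_probability(state.M, hp)
    nu = feedback_division_rate(state.M, hp)
    tf = T / (cp.m2 + T)
    sup = 1.0 - tx.A1 * cp.eps * tf
    dS = (2.0 * p - 1.0) * nu * sup * state.S - tx.A2 * cp.dS * tf * state.S
    dM = 2.0 * (1.0 - p) * nu * sup * state.S - (tx.A4 * hp.d0 + tx.A3 * cp.dM * tf) * state.M
    dT = tumor_rate(T, tp)
    return dS, dM, dT


# Array-form right-hand sides used by the integrators.  ``y`` may be a
# (k,) state vector or a (k, n) stack of n systems sharing parameters.


def healthy_rhs(t, y, hp: HealthyParams):
    S, M = y[0], y[1]
    f = 1.0 / (1.0 + M / hp.m)
    p = hp.p0 + hp.p1 * f
    nu = hp.nu0 + hp.nu1 * f
    return np.stack([(2.0 * p - 1.0) * nu * S, 2.0 * (1.0 - p) * nu * S - hp.d0 * M])


def cachexia_rhs(t, y, hp: HealthyParams, cp: CachexiaParams, tp: TumorParams):
    S, M, T = y[0], y[1], y[2]
    f = 1.0 / (1.0 + M / hp.m)
    p = hp.p0 + hp.p1 * f
    nu = hp.nu0 + hp.nu1 * f
    tf = T / (cp.m2 + T)
    sup = 1.0 - cp.eps * tf
    dS = (2.0 * p - 1.0) * nu * sup * S - cp.dS * tf * S
    dM = 2.0 * (1.0 - p) * nu * sup * S - (hp.d0 + cp.dM * tf) * M
    return np.stack([dS, dM, tumor_rate(np.maximum(T, 0.0), tp)])


def treatment_rhs(
    t, y, hp: HealthyParams, cp: CachexiaParams, tp: TumorParams, tx: TreatmentParams
):
    S, M, T = y[0], y[1], y[2]
    f = 1.0 / (1.0 + M / hp.m)
    p = hp.p0 + hp.p1 * f
    nu = hp.nu0 + hp.nu1 * f
    tf = T / (cp.m2 + T)
    sup = 1.0 - tx.A1 * cp.eps * tf
    dS = (2.0 * p - 1.0) * nu * sup * S - tx.A2 * cp.dS * tf * S
    dM = 2.0 * (1.0 - p) * nu * sup * S - (tx.A4 * hp.d0 + tx.A3 * cp.dM * tf) * M
    return np.stack([dS, dM, tumor_rate(np.maximum(T, 0.0), tp)])


# --------------------------------------------------------------------------
# Closed forms
# --------------------------------------------------------------------------


def steady_state(hp: HealthyParams) -> tuple:
    """Closed-form homeostatic steady state (Sss, Mss) in mm^3.

    Mss = m (2(p0+p1)-1) / (1-2p0)
    Sss = 2 m d0 p1 (2(p0+p1)-1) / [(1-2p0)(2 p1 nu0 + (1-2p0) nu1)]

    Requires p0 < 1/2 < p0+p1 (otherwise the formulas go nonpositive and
    the tissue has no positive equilibrium).
    """
    hp.require_steady_state()
    one_minus_2p0 = 1.0 - 2.0 * hp.p0
    growth = 2.0 * (hp.p0 + hp.p1) - 1.0
    Mss = hp.m * growth / one_minus_2p0
    Sss = (
        2.0 * hp.m * hp.d0 * hp.p1 * growth
        / (one_minus_2p0 * (2.0 * hp.p1 * hp.nu0 + one_minus_2p0 * hp.nu1))
    )
    return Sss, Mss


def steady_state_stem_ratio(hp: HealthyParams) -> float:
    """Homeostatic stem ratio psi_ss = Sss/Mss = 2 d0 p1 / (2 p1 nu0 + (1-2p0) nu1).

    Bounded above by d0/nu0, the turnover-to-proliferation ratio.
    """
    hp.require_steady_state()
    return 2.0 * hp.d0 * hp.p1 / (2.0 * hp.p1 * hp.nu0 + (1.0 - 2.0 * hp.p0) * hp.nu1)


def transition_threshold(tp: TumorParams) -> float:
    """Tumor volume Tth = mu1/mu (mm^3) where growth switches phase."""
    return tp.threshold


def effective_muscle_death(
    hp: HealthyParams, cp: CachexiaParams, tx: TreatmentParams
) -> float:
    """Large-tumor limiting muscle death rate under treatment: A4*d0 + A3*dM."""
    return tx.A4 * hp.d0 + tx.A3 * cp.dM


# --------------------------------------------------------------------------
# Mass/volume conversion conventions
# --------------------------------------------------------------------------


def initial_conditions_from_weight(
    W: float, psi_ref: float, conv: ConversionConvention = ConversionConvention()
) -> tuple:
    """(S0, M0) in mm^3 from a body weight, keeping a reference stem ratio.

    The lean volume lean_fraction*W/xi is split so that S0/M0 equals
    ``psi_ref`` (for cohort initial conditions psi_ref is the day-49 stem
    ratio of the healthy growth solve, keeping the feedback state
    age-appropriate):

        M0 = lean_fraction*W / ((1+psi_ref)*xi),  S0 = psi_ref*M0
    """
    _require(W >= 0, f"W >= 0 violated (W={W})")
    _require(psi_ref > 0, f"psi_ref > 0 violated (psi_ref={psi_ref})")
    M0 = conv.lean_fraction * W / ((1.0 + psi_ref) * conv.xi)
    return psi_ref * M0, M0


def weight_to_lean_compartments(
    W: float,
    conv: ConversionConvention = ConversionConvention(),
    tumor_mass: float = 0.0,
) -> tuple:
    """Deconstruct a body weight into (stem g, muscle g, stem mm^3, muscle mm^3).

    Lean mass is ``lean_fraction`` of the weight after subtracting the tumor
    mass, split 95% muscle / 5% satellite by default.
    """
    _require(tumor_mass >= 0, f"tumor_mass >= 0 violated ({tumor_mass})")
    _require(W >= tumor_mass, f"W >= tumor_mass violated (W={W}, tumor_mass={tumor_mass})")
    lean = conv.lean_fraction * (W - tumor_mass)
    muscle_g = conv.muscle_share * lean
    stem_g = conv.stem_share * lean
    return stem_g, muscle_g, stem_g / conv.xi, muscle_g / conv.xi


def logistic_weight(t, lp: LogisticParams):
    """Closed-form logistic body weight W(t) in grams."""
    t = np.asarray(t, dtype=float)
    out = lp.K / (1.0 + (lp.K / lp.W0 - 1.0) * np.exp(-lp.alpha * t))
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Parameter I/O and shipped fixtures
# --------------------------------------------------------------------------

_CLASS_BY_KIND = {
    "healthy": HealthyParams,
    "tumor": TumorParams,
    "cachexia": CachexiaParams,
    "treatment": TreatmentParams,
    "logistic": LogisticParams,
}


def save_params(params, path) -> None:
    """Write a parameter dataclass to JSON or YAML (by file extension)."""
    d = params.to_dict()
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith((".yaml", ".yml")):
            yaml.safe_dump(d, fh)
        else:
            json.dump(d, fh, indent=1)


def load_params(path, kind: str):
    """Load a parameter set of the given kind from JSON or YAML."""
    if kind not in _CLASS_BY_KIND:
        raise ValueError(f"unknown parameter kind {kind!r}")
    path = str(path)
    with open(path) as fh:
        d = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) else json.load(fh)
    return _CLASS_BY_KIND[kind].from_dict(d)


def _fixture(name: str) -> dict:
    with resources.files("cachexsim.data").joinpath(name).open() as fh:
        return json.load(fh)


def table1_healthy_params() -> HealthyParams:
    """Fitted healthy feedback parameters shipped with the package."""
    return HealthyParams.from_dict(_fixture("table1.json")["healthy_params"])


def table1_reference_state() -> TissueState:
    """The printed 10-week (day-49) reference state (S, M) in mm^3."""
    ic = _fixture("table1.json")["printed_initial_conditions"]
    return TissueState(ic["S_mm3"], ic["M_mm3"])


def table2_bundle() -> dict:
    """Tumor/cachexia/treatment fits and group ICs shipped with the package.

    Returns a dict with keys ``tumor`` (TumorParams), ``cachexia``
    (CachexiaParams), ``treatment_group_a``/``treatment_group_b``
    (TreatmentParams), ``group_a_ics``/``group_b_ics`` (TissueState with
    T(0)=0.5 mm^3), ``day0_weights`` and ``T0``.
    """
    raw = _fixture("table2.json")
    t0 = raw["tumor_params"]["T0_mm3"]
    return {
        "tumor": TumorParams.from_dict(raw["tumor_params"]),
        "cachexia": CachexiaParams.from_dict(raw["cachexia_params"]),
        "treatment_group_a": TreatmentParams.from_dict(raw["treatment_group_a"]),
        "treatment_group_b": TreatmentParams.from_dict(raw["treatment_group_b"]),
        "group_a_ics": TissueState(
            raw["group_a_initial_conditions"]["S_mm3"],
            raw["group_a_initial_conditions"]["M_mm3"],
            t0,
        ),
        "group_b_ics": TissueState(
            raw["group_b_initial_conditions"]["S_mm3"],
            raw["group_b_initial_conditions"]["M_mm3"],
            t0,
        ),
        "day0_weights": {
            "group_a": raw["group_a_initial_conditions"]["day0_weight_g"],
            "group_b": raw["group_b_initial_conditions"]["day0_weight_g"],
        },
        "T0": t0,
    }


def logistic_defaults() -> LogisticParams:
    """Fitted logistic growth parameters of the healthy body-weight curve."""
    return LogisticParams.from_dict(_fixture("logistic.json")["logistic_params"])
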