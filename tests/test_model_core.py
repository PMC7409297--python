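"""Unit and property tests for the rate functions, closed forms, and conversions."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cachexsim as cx
from cachexsim.model_core import logistic_weight

from conftest import random_valid_healthy

MSS = 1000.0 * 0.224 / 0.042  # closed-form muscle steady state, fitted params


# ---------------------------------------------------------------------------
# feedback functions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "M, expected",
    [
        (0.0, 0.612),          # limit M->0 gives p0+p1
        (1e12, 0.479),         # limit M->inf gives p0
        (MSS, 0.5),            # steady state forces p = 1/2
    ],
)
def test_feedback_probability(hp, M, expected):
    assert cx.feedback_probability(M, hp) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize(
    "M, expected",
    [
        (0.0, 5.678),          # nu0 + nu1
        (1000.0, 2.8825),      # half-saturation at M = m
        (MSS, 0.9697842),      # hand evaluation at the muscle steady state
    ],
)
def test_feedback_division_rate(hp, M, expected):
    assert cx.feedback_division_rate(M, hp) == pytest.approx(expected, rel=1e-5)


@pytest.mark.parametrize("fn", [cx.feedback_probability, cx.feedback_division_rate])
def test_feedback_rejects_negative_muscle(hp, fn):
    with pytest.raises(ValueError):
        fn(-1.0, hp)


# ---------------------------------------------------------------------------
# healthy rates
# ---------------------------------------------------------------------------


def test_healthy_rates_empty_stem_pool(hp):
    dS, dM = cx.healthy_rates(cx.TissueState(0.0, 4000.0), hp)
    assert dS == 0.0
    assert dM == pytest.approx(-hp.d0 * 4000.0)


def test_healthy_rates_vanish_at_steady_state(hp):
    Sss, Mss = cx.steady_state(hp)
    dS, dM = cx.healthy_rates(cx.TissueState(Sss, Mss), hp)
    assert abs(dS) < 1e-9 * Mss and abs(dM) < 1e-9 * Mss


def test_healthy_rates_hand_arithmetic_at_zero_muscle(hp):
    # at M=0: p=0.612, nu=5.678, so dS/dt = (2*0.612-1)*5.678*100
    dS, dM = cx.healthy_rates(cx.TissueState(100.0, 0.0), hp)
    assert dS == pytest.approx((2 * 0.612 - 1) * 5.678 * 100, rel=1e-12)
    assert dM == pytest.approx(2 * (1 - 0.612) * 5.678 * 100, rel=1e-12)


def test_healthy_rates_reject_tumor_state(hp):
    with pytest.raises(ValueError):
        cx.healthy_rates(cx.TissueState(1.0, 1.0, 1.0), hp)


# ---------------------------------------------------------------------------
# tumor growth law
# ---------------------------------------------------------------------------


def test_tumor_rate_limits(bundle):
    tp = bundle["tumor"]
    assert cx.tumor_rate(0.0, tp) == 0.0
    # linear-phase limit equals mu1
    assert cx.tumor_rate(1e9, tp) == pytest.approx(116.0, rel=1e-6)
    # at the transition threshold the blend gives mu1 * 2^(-1/eta)
    assert cx.tumor_rate(tp.threshold, tp) == pytest.approx(116.0 * 2 ** (-1 / 20), rel=1e-12)
    with pytest.raises(ValueError):
        cx.tumor_rate(-1.0, tp)


def test_tumor_rate_monotone_and_bounded(bundle):
    tp = bundle["tumor"]
    T = np.logspace(-2, 7, 400)
    r = cx.tumor_rate(T, tp)
    # strictly increasing until the rate saturates at mu1 (where successive
    # values agree to float rounding), never decreasing beyond rounding
    assert np.all(np.diff(r) > -1e-9)
    pre = r < 0.999 * tp.mu1
    assert np.all(np.diff(r[pre]) > 0)
    assert np.all(r <= tp.mu1 * (1 + 1e-9))


def test_tumor_solution_close_to_piecewise_exponential_linear(bundle):
    # eta=20 blend should track the sharp piecewise law within 2%
    from scipy.integrate import solve_ivp

    tp = bundle["tumor"]
    tth = tp.threshold
    sol = solve_ivp(
        lambda t, y: [cx.tumor_rate(max(y[0], 0.0), tp)],
        (0, 25), [0.5], rtol=1e-10, atol=1e-12, t_eval=np.linspace(1, 25, 49),
    )
    t_switch = np.log(tth / 0.5) / tp.mu
    piecewise = np.where(
        sol.t <= t_switch,
        0.5 * np.exp(tp.mu * sol.t),
        tth + tp.mu1 * (sol.t - t_switch),
    )
    assert np.max(np.abs(sol.y[0] - piecewise) / piecewise) < 0.02


# ---------------------------------------------------------------------------
# suppression and disease/treatment rates
# ---------------------------------------------------------------------------


def test_suppression_factor(bundle):
    cp = bundle["cachexia"]
    assert cx.suppression_factor(0.0, cp) == 1.0
    assert cx.suppression_factor(cp.m2, cp) == pytest.approx(1 - cp.eps / 2)
    assert cx.suppression_factor(1e15, cp) == pytest.approx(1 - cp.eps)


def test_cachexia_reduces_to_healthy_without_tumor(hp, bundle):
    state = cx.TissueState(200.0, 4500.0, 0.0)
    dS, dM, dT = cx.cachexia_rates(state, hp, bundle["cachexia"], bundle["tumor"])
    hS, hM = cx.healthy_rates(cx.TissueState(200.0, 4500.0), hp)
    assert (dS, dM, dT) == (hS, hM, 0.0)


def test_cachexia_reduces_to_healthy_with_null_perturbation(hp, bundle):
    cp0 = cx.CachexiaParams(eps=0.0, dS=0.0, dM=0.0, m2=338.0)
    state = cx.TissueState(100.0, 2000.0, 750.0)
    dS, dM, dT = cx.cachexia_rates(state, hp, cp0, bundle["tumor"])
    hS, hM = cx.healthy_rates(cx.TissueState(100.0, 2000.0), hp)
    assert dS == hS and dM == hM
    assert dT == cx.tumor_rate(750.0, bundle["tumor"])


def test_cachexia_rates_term_by_term_oracle(hp, bundle):
    # independent term-by-term evaluation at the Group A starting state
    S, M, T = 252.75, 4799.25, 0.5
    cp, tp = bundle["cachexia"], bundle["tumor"]
    f = 1 / (1 + M / 1000.0)
    p = 0.479 + 0.133 * f
    nu = 0.087 + 5.591 * f
    tf = T / (338.0 + T)
    sup = 1 - 0.004 * tf
    exp_dS = (2 * p - 1) * nu * sup * S - 0.030 * tf * S
    exp_dM = 2 * (1 - p) * nu * sup * S - (0.05 + 0.104 * tf) * M
    exp_dT = 0.446 * T * (1 + (0.446 * T / 116.0) ** 20) ** (-1 / 20)
    dS, dM, dT = cx.cachexia_rates(cx.TissueState(S, M, T), hp, cp, tp)
    assert dS == pytest.approx(exp_dS, rel=1e-12)
    assert dM == pytest.approx(exp_dM, rel=1e-12)
    assert dT == pytest.approx(exp_dT, rel=1e-10)


def test_treatment_identity_and_full_blockade(hp, bundle):
    cp, tp = bundle["cachexia"], bundle["tumor"]
    state = cx.TissueState(150.0, 3000.0, 5000.0)
    ones = cx.TreatmentParams(1, 1, 1, 1)
    assert cx.treatment_rates(state, hp, cp, tp, ones) == cx.cachexia_rates(state, hp, cp, tp)
    # full blockade of tumor-derived terms recovers healthy dynamics
    block = cx.TreatmentParams(0, 0, 0, 1)
    dS, dM, dT = cx.treatment_rates(state, hp, cp, tp, block)
    hS, hM = cx.healthy_rates(cx.TissueState(150.0, 3000.0), hp)
    assert dS == pytest.approx(hS, rel=1e-12) and dM == pytest.approx(hM, rel=1e-12)


def test_effective_muscle_death(hp, bundle):
    cp = bundle["cachexia"]
    assert cx.effective_muscle_death(hp, cp, bundle["treatment_group_a"]) == pytest.approx(0.08, abs=5e-3)
    assert cx.effective_muscle_death(hp, cp, bundle["treatment_group_b"]) == pytest.approx(0.11, abs=5e-3)
    none = cx.TreatmentParams(1, 1, 1, 1)
    assert cx.effective_muscle_death(hp, cp, none) == pytest.approx(0.154, rel=1e-12)


def test_treatment_params_validated():
    with pytest.raises(ValueError, match="A3"):
        cx.TreatmentParams(0, 0, 1.5, 1)


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------


def test_steady_state_values(hp):
    Sss, Mss = cx.steady_state(hp)
    assert Mss == pytest.approx(5333.33, abs=0.01)
    assert Sss == pytest.approx(274.97, abs=0.01)


def test_steady_state_linear_in_m(hp):
    S1, M1 = cx.steady_state(hp)
    S2, M2 = cx.steady_state(hp.replace(m=2 * hp.m))
    assert S2 == pytest.approx(2 * S1) and M2 == pytest.approx(2 * M1)


def test_steady_state_precondition_named_error():
    bad = cx.HealthyParams(p0=0.6, p1=0.2, nu0=0.1, nu1=1.0, d0=0.05, m=1000.0)
    with pytest.raises(ValueError, match="p0 < 1/2"):
        cx.steady_state(bad)


def test_stem_ratio_value_and_limits(hp):
    assert cx.steady_state_stem_ratio(hp) == pytest.approx(0.0516, abs=5e-5)
    assert cx.steady_state_stem_ratio(hp) <= hp.d0 / hp.nu0
    near = hp.replace(p0=0.4999999)
    assert cx.steady_state_stem_ratio(near) == pytest.approx(hp.d0 / hp.nu0, rel=1e-4)


def test_transition_threshold(bundle):
    tth = cx.transition_threshold(bundle["tumor"])
    assert round(tth, -1) == 260 or abs(tth - 260) < 0.5  # 3 significant figures
    assert cx.transition_threshold(cx.TumorParams(1.0, 1.0)) == 1.0
    doubled = cx.TumorParams(0.446, 2 * 116.0)
    assert cx.transition_threshold(doubled) == pytest.approx(2 * tth)


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------


def test_initial_conditions_from_weight(psi49):
    S0, M0 = cx.initial_conditions_from_weight(25.26, psi49)
    assert M0 == pytest.approx(4799.25, abs=0.01)
    assert S0 == pytest.approx(252.75, abs=0.01)
    S0b, M0b = cx.initial_conditions_from_weight(25.10, psi49)
    assert M0b == pytest.approx(4768.85, abs=0.01)
    assert S0b == pytest.approx(251.15, abs=0.01)
    assert cx.initial_conditions_from_weight(0.0, psi49) == (0.0, 0.0)


def test_weight_to_lean_compartments(conv):
    stem_g, muscle_g, stem_v, muscle_v = cx.weight_to_lean_compartments(11.26, conv)
    assert muscle_g == pytest.approx(4.2788)
    assert stem_g == pytest.approx(0.2252)
    assert muscle_v == pytest.approx(2139.4)
    assert stem_v == pytest.approx(112.6)
    assert stem_g / muscle_g == pytest.approx(1 / 19)
    # tumor-only control deconstructs to zero lean tissue
    assert cx.weight_to_lean_compartments(2.0, conv, tumor_mass=2.0)[:2] == (0.0, 0.0)
    with pytest.raises(ValueError):
        cx.weight_to_lean_compartments(2.0, conv, tumor_mass=3.0)


def test_conversion_convention_validated():
    with pytest.raises(ValueError):
        cx.ConversionConvention(xi=0.0)
    with pytest.raises(ValueError):
        cx.ConversionConvention(muscle_share=0.9, stem_share=0.05)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_steady_state_oracle_and_ratio_identity(seed):
    """Random valid parameters: rates vanish at the closed form, and the
    ratio formula equals Sss/Mss to 1e-12 relative, below the d0/nu0 bound."""
    rng = np.random.default_rng(seed)
    hp = random_valid_healthy(rng)
    Sss, Mss = cx.steady_state(hp)
    assert Sss > 0 and Mss > 0
    dS, dM = cx.healthy_rates(cx.TissueState(Sss, Mss), hp)
    assert abs(dS) < 1e-9 * Mss and abs(dM) < 1e-9 * Mss
    psi = cx.steady_state_stem_ratio(hp)
    assert psi == pytest.approx(Sss / Mss, rel=1e-12)
    assert psi <= hp.d0 / hp.nu0 * (1 + 1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_reduction_chain_bit_for_bit(seed):
    """treatment(A=1) == cachexia == healthy+tumor (eps=dS=dM=0), exactly."""
    rng = np.random.default_rng(seed)
    hp = random_valid_healthy(rng)
    tp = cx.TumorParams(rng.uniform(0.1, 1.0), rng.uniform(10, 200))
    cp = cx.CachexiaParams(rng.uniform(0, 0.5), rng.uniform(0, 0.2), rng.uniform(0, 0.3), rng.uniform(50, 1000))
    state = cx.TissueState(rng.uniform(0, 500), rng.uniform(0, 8000), rng.uniform(0, 3000))
    ones = cx.TreatmentParams(1.0, 1.0, 1.0, 1.0)
    assert cx.treatment_rates(state, hp, cp, tp, ones) == cx.cachexia_rates(state, hp, cp, tp)
    cp0 = cp.replace(eps=0.0, dS=0.0, dM=0.0)
    dS, dM, dT = cx.cachexia_rates(state, hp, cp0, tp)
    hS, hM = cx.healthy_rates(cx.TissueState(state.S, state.M), hp)
    assert (dS, dM) == (hS, hM)
    assert dT == cx.tumor_rate(state.T, tp)


# ---------------------------------------------------------------------------
# serialization and fixtures
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("ext", ["json", "yaml"])
def test_params_round_trip(tmp_path, hp, ext):
    path = tmp_path / f"hp.{ext}"
    cx.save_params(hp, path)
    assert cx.load_params(path, "healthy") == hp


def test_fixtures_reproduce_printed_values(hp, bundle):
    assert (hp.p0, hp.p1, hp.nu0, hp.nu1, hp.d0, hp.m) == (0.479, 0.133, 0.087, 5.591, 0.05, 1000.0)
    tp = bundle["tumor"]
    assert (tp.mu, tp.mu1, tp.eta) == (0.446, 116.0, 20.0)
    cp = bundle["cachexia"]
    assert (cp.eps, cp.dS, cp.dM, cp.m2) == (0.004, 0.030, 0.104, 338.0)
    ga, gb = bundle["treatment_group_a"], bundle["treatment_group_b"]
    assert (ga.A1, ga.A2, ga.A3, ga.A4, ga.t_start) == (0.0, 0.0, 0.51, 0.54, 5.0)
    assert (gb.A1, gb.A2, gb.A3, gb.A4, gb.t_start) == (0.0, 0.0, 0.62, 1.0, 14.0)
    assert (bundle["group_a_ics"].S, bundle["group_a_ics"].M) == (252.75, 4799.25)
    assert (bundle["group_b_ics"].S, bundle["group_b_ics"].M) == (251.15, 4768.85)
    ref = cx.table1_reference_state()
    assert (ref.S, ref.M) == (268.01, 5088.92)
    lp = cx.logistic_defaults()
    assert (lp.alpha, lp.K, lp.W0) == (0.0756, 28.3, 11.26)


def test_logistic_weight_closed_form():
    lp = cx.logistic_defaults()
    assert logistic_weight(0.0, lp) == pytest.approx(11.26)
    assert logistic_weight(1e4, lp) == pytest.approx(28.3)


def test_trajectory_invariants():
    with pytest.raises(ValueError, match="strictly increasing"):
        cx.Trajectory(np.array([0.0, 0.0]), np.ones(2), np.ones(2))
    with pytest.raises(ValueError, match="one state per time"):
        cx.Trajectory(np.array([0.0, 1.0]), np.ones(3), np.ones(2))


def test_trajectory_csv_columns(tmp_path, hp):
    traj = cx.healthy_growth_solve(hp, t_stop=5.0, t_step=1.0)
    out = tmp_path / "traj.csv"
    traj.to_csv(out)
    import pandas as pd

    df = pd.read_csv(out)
    assert list(df.columns) == ["day", "S_mm3", "M_mm3", "T_mm3", "lean_mass_g", "stem_ratio"]
    assert json.loads(json.dumps(traj.meta))  # meta is JSON-serializable
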