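"""Model core: Hill gate, vector field, integration, steady state."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifndyn import (
    IntegrationError,
    ModelParameters,
    StateVector,
    Trajectory,
    derivatives,
    hill_activation,
    percent_positive,
    simulate,
    steady_state,
)

from .reference import f1_closed_form, rk4_trajectory

GRID = np.arange(0.0, 27.0)


# ---------------------------------------------------------------- hill gate


@pytest.mark.parametrize(
    "ifn,T,H,expected",
    [
        (0.0, 440.0, 4.0, 0.0),
        (440.0, 440.0, 4.0, 0.5),
        (20.0, 20.0, 1.0, 0.5),
        (17.3, 17.3, 2.7, 0.5),
        (880.0, 440.0, 4.0, 16.0 / 17.0),
    ],
)
def test_hill_values(ifn, T, H, expected):
    assert hill_activation(ifn, T, H) == pytest.approx(expected, rel=1e-12)


def test_hill_domain_errors():
    with pytest.raises(ValueError):
        hill_activation(-1.0, 440.0, 4.0)
    with pytest.raises(ValueError):
        hill_activation(1.0, 0.0, 4.0)
    with pytest.raises(ValueError):
        hill_activation(1.0, 440.0, 0.5)


def test_hill_extreme_ratios_saturate_without_overflow():
    assert hill_activation(1e30, 1.0, 8.0) == pytest.approx(1.0)
    assert 0.0 < hill_activation(1e-30, 1e5, 8.0) < 1e-250


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    T=st.floats(0.1, 1e4),
    H=st.floats(1.0, 8.0),
    x=st.floats(1e-6, 1e6),
    step=st.floats(1e-3, 10.0),
)
def test_hill_strictly_increasing_and_bounded(T, H, x, step):
    lo, hi = hill_activation(x, T, H), hill_activation(x * (1 + step), T, H)
    assert 0.0 <= lo <= hi <= 1.0
    # strict monotonicity away from floating-point saturation of the gate
    if lo > 1e-9 and hi < 1.0 - 1e-9:
        assert lo < hi


# ------------------------------------------------------------- vector field


def test_derivatives_from_rest(low_dose):
    d = derivatives((0.0, 0.0, 0.0), low_dose)
    assert d == pytest.approx((low_dose.kon * low_dose.fr, 0.0, 0.0))


def test_derivatives_at_saturation_boundary(low_dose):
    p = low_dose
    ifn = 100.0
    d = derivatives((p.fr, p.sr, ifn), p)
    # at the pool boundaries both fraction derivatives are pure turn-off
    assert d[0] == pytest.approx(-p.koff * p.fr)
    assert d[1] == pytest.approx(-p.koff * p.sr)
    assert d[2] == pytest.approx(p.kf * (p.fr + p.sr) - p.df * ifn)


def test_derivatives_hand_value():
    p = ModelParameters(kon=0.4, koff=0.2, kf=6600.0, df=0.04, T=440.0, H=4.0)
    d = derivatives((0.005, 0.1, 440.0), p)
    assert d == pytest.approx((0.001, 0.06, 675.4), rel=1e-12)


def test_derivatives_rejects_out_of_bounds_state(low_dose):
    with pytest.raises(ValueError):
        derivatives((0.5, 0.0, 0.0), low_dose)  # f1 > fr


# -------------------------------------------------------------- integration


def test_simulate_single_time_point(low_dose):
    traj = simulate(low_dose, [0.0])
    assert len(traj.times) == 1 and traj.f1[0] == traj.f2[0] == traj.ifn[0] == 0.0


def test_simulate_grid_validation(low_dose):
    with pytest.raises(ValueError):
        simulate(low_dose, [1.0, 2.0])  # must start at 0
    with pytest.raises(ValueError):
        simulate(low_dose, [0.0, 2.0, 1.0])


def test_no_secretion_means_no_second_wave(low_dose):
    p = low_dose.replace(kf=0.0)
    traj = simulate(p, GRID)
    assert np.all(traj.ifn == 0.0)
    assert np.all(traj.f2 == 0.0)
    exact = np.array([f1_closed_form(p, t) for t in GRID])
    assert np.max(np.abs(traj.f1 - exact)) < 1e-8


def test_simulate_approaches_steady_state(low_dose):
    ss = steady_state(low_dose)
    traj = simulate(low_dose, np.arange(0.0, 401.0))
    assert traj.f1[-1] == pytest.approx(ss.f1, rel=1e-4)
    assert traj.f2[-1] == pytest.approx(ss.f2, rel=1e-4)
    assert traj.ifn[-1] == pytest.approx(ss.ifn, rel=1e-3)


def test_tolerance_refinement_stability(low_dose):
    a = simulate(low_dose, GRID, rtol=1e-8, atol=1e-10)
    b = simulate(low_dose, GRID, rtol=1e-9, atol=1e-11)
    for x, y in ((a.f1, b.f1), (a.f2, b.f2), (a.ifn, b.ifn)):
        assert np.max(np.abs(x - y)) <= 1e-6 * max(1e-12, np.max(np.abs(y)))


def test_adaptive_matches_rk4_reference(low_dose):
    traj = simulate(low_dose, GRID)
    f1r, f2r, ifnr = rk4_trajectory(low_dose, GRID)
    for got, ref in ((traj.f1, f1r), (traj.f2, f2r), (traj.ifn, ifnr)):
        ref = np.asarray(ref)
        assert np.max(np.abs(got - ref)) <= 1e-5 * np.max(np.abs(ref))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    kon=st.floats(0.01, 10.0),
    koff=st.floats(0.01, 10.0),
    kf=st.floats(0.0, 1e5),
    df=st.floats(1e-3, 1.0),
    T=st.floats(1.0, 1e4),
    H=st.floats(1.0, 8.0),
)
def test_forward_invariance(kon, koff, kf, df, T, H):
    p = ModelParameters(kon=kon, koff=koff, kf=kf, df=df, T=T, H=H)
    traj = simulate(p, GRID)
    assert np.all((traj.f1 >= 0) & (traj.f1 <= p.fr))
    assert np.all((traj.f2 >= 0) & (traj.f2 <= p.sr))
    assert np.all(traj.ifn >= 0)


def test_monotone_comparative_statics(low_dose):
    # raising the activation threshold can only slow the second wave
    f2_by_T = [simulate(low_dose.replace(T=T), GRID).f2 for T in (100.0, 440.0, 2000.0)]
    for hi, lo in zip(f2_by_T, f2_by_T[1:]):
        assert np.all(lo[1:] <= hi[1:] + 1e-12)
    # raising the activation rate can only speed the first wave
    f1_by_kon = [simulate(low_dose.replace(kon=k), GRID).f1 for k in (0.1, 0.4, 1.5)]
    for lo, hi in zip(f1_by_kon, f1_by_kon[1:]):
        assert np.all(hi[1:] >= lo[1:] - 1e-12)


def test_hill_step_limit_acts_as_threshold(low_dose):
    # with a near-step gate, second responders stay off until ifn crosses T
    p = low_dose.replace(T=300.0, H=64.0)
    traj = simulate(p, np.arange(0.0, 26.01, 0.25))
    below = traj.ifn < 0.8 * p.T
    above = traj.ifn > 1.2 * p.T
    assert below.any() and above.any()
    assert np.all(traj.f2[below] < 1e-3)
    gate_above = [hill_activation(v, p.T, p.H) for v in traj.ifn[above]]
    assert min(gate_above) > 0.999


# ------------------------------------------------------------- steady state


def test_steady_state_no_secretion(low_dose):
    ss = steady_state(low_dose.replace(kf=0.0))
    assert ss.f1 == pytest.approx(low_dose.kon * low_dose.fr / (low_dose.kon + low_dose.koff))
    assert ss.f2 == 0.0 and ss.ifn == 0.0


def test_steady_state_fixed_point(low_dose):
    ss = steady_state(low_dose)
    p = low_dose
    assert ss.f1 == pytest.approx(1.0 / 150.0, rel=1e-12)
    a = p.kon * hill_activation(ss.ifn, p.T, p.H)
    assert ss.f2 == pytest.approx(p.sr * a / (a + p.koff), rel=1e-10)
    assert ss.ifn == pytest.approx(p.kf * (ss.f1 + ss.f2) / p.df, rel=1e-10)
    # saturated gate puts the fixed point near sr*kon/(kon+koff), ifn near 5.61e4
    assert ss.ifn == pytest.approx(5.61e4, rel=1e-3)


def test_steady_state_requires_decay(low_dose):
    with pytest.raises(ValueError):
        steady_state(low_dose.replace(df=0.0))


# ------------------------------------------------- observables and containers


def test_percent_positive_values(low_dose):
    zero = Trajectory(GRID, np.zeros_like(GRID), np.zeros_like(GRID), np.zeros_like(GRID))
    assert np.all(percent_positive(zero) == 0.0)
    sat = Trajectory([0.0], [low_dose.fr], [low_dose.sr], [0.0])
    assert percent_positive(sat)[0] == pytest.approx(51.0)
    ss = steady_state(low_dose)
    assert 100.0 * (ss.f1 + ss.f2) == pytest.approx(34.0, abs=0.01)


def test_trajectory_invariants():
    with pytest.raises(ValueError):
        Trajectory([0.0, 1.0], [0.0], [0.0], [0.0])
    with pytest.raises(ValueError):
        Trajectory([0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [0.0, 0.0])


@pytest.mark.parametrize(
    "bad",
    [
        {"fr": 0.0},
        {"fr": 0.6, "sr": 0.6},
        {"kon": 0.0},
        {"koff": -0.1},
        {"kf": -1.0},
        {"df": -0.1},
        {"T": 0.0},
        {"H": 0.5},
    ],
)
def test_parameter_validation(bad):
    base = dict(kon=0.4, koff=0.2, kf=6600.0, df=0.04, T=440.0, H=4.0)
    with pytest.raises(ValueError):
        ModelParameters(**{**base, **bad})


def test_parameter_serialization_round_trip(low_dose):
    assert ModelParameters.from_json(low_dose.to_json()) == low_dose
    assert ModelParameters.from_yaml(low_dose.to_yaml()) == low_dose
    with pytest.raises(ValueError):
        ModelParameters.from_dict({**low_dose.to_dict(), "bogus": 1.0})


def test_trajectory_csv_round_trip(tmp_path, low_dose):
    import pandas as pd

    traj = simulate(low_dose, GRID)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["time_h", "f1", "f2", "ifn_pg_ml", "percent_positive"]
    assert np.allclose(df["percent_positive"], 100.0 * (df["f1"] + df["f2"]))


def test_integration_failure_raises():
    # a forced blow-up via an absurd initial state is rejected before integration
    p = ModelParameters(kon=0.4, koff=0.2, kf=6600.0, df=0.04, T=440.0, H=4.0)
    with pytest.raises(ValueError):
        simulate(p, GRID, initial=StateVector(0.5, 0.0, 0.0))
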