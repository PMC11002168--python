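"""Three-state ODE model of the population-level type-I interferon response.

Upon TLR stimulation of a cell population (e.g. plasmacytoid dendritic
cells), a small fixed fraction ``fr`` of *first responders* activates
directly and starts secreting IFNα.  The secreted interferon feeds back in
a paracrine fashion: once the supernatant concentration crosses a threshold
``T``, a larger pool of up to ``sr`` *second responders* activates too.
The remaining cells never respond.

States
------
f1 : activated first-responder fraction of the whole population
f2 : activated second-responder fraction
ifn : supernatant IFNα concentration (pg/mL)

Dynamics
--------
::

    df1/dt  = kon (fr - f1) - koff f1
    df2/dt  = kon h(ifn) (sr - f2) - koff f2
    difn/dt = kf (f1 + f2) - df ifn

with the Hill gate ``h(x) = x^H / (T^H + x^H)``.  Activation of second
responders is thus IFN-dependent, with half-maximal rate at ``ifn == T``
and steepness set by the Hill coefficient ``H``.  Both responder types turn
off at the same rate ``koff``; each activated cell secretes at rate ``kf``
and interferon is consumed/degraded with first-order rate ``df``.

Time is in hours, concentrations in pg/mL, fractions dimensionless.  The
measured "percent IFNα-positive cells" is ``100 * (f1 + f2)``.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import odeint
from scipy.optimize import brentq

__all__ = [
    "PARAM_NAMES",
    "ModelParameters",
    "StateVector",
    "Trajectory",
    "IntegrationError",
    "hill_activation",
    "derivatives",
    "simulate",
    "steady_state",
    "percent_positive",
    "DEFAULT_T_GRID",
]

#: canonical parameter order used everywhere (serialisation, fitting vectors)
PARAM_NAMES = ("fr", "sr", "kon", "koff", "kf", "df", "T", "H")

#: hourly reporting grid over the 26 h observation window
DEFAULT_T_GRID = np.arange(0.0, 27.0)


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails or produces out-of-bound states."""


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """Parameter set of the first/second-responder IFNα model.

    Parameters
    ----------
    kon : float
        Activation rate (1/h, > 0).  Encodes stimulus identity and dose;
        the model has no explicit stimulus variable.
    koff : float
        Turn-off rate of activated cells (1/h, > 0), shared by both
        responder types.
    kf : float
        IFNα secretion rate per unit activated-cell fraction (pg/mL/h, >= 0).
    df : float
        IFNα consumption/degradation rate (1/h, >= 0).
    T : float
        IFNα threshold for second-responder activation (pg/mL, > 0).
    H : float
        Hill coefficient of the paracrine activation gate (>= 1).  Treated
        as a positive real so fitting may explore non-integer values.
    fr : float, default 0.01
        Fraction of the population that are first responders, in (0, 1).
    sr : float, default 0.5
        Maximum fraction of potential second responders, in (0, 1).

    ``fr + sr`` may not exceed 1 (responder pools cannot exceed the
    population); violation is a construction error.
    """

    kon: float
    koff: float
    kf: float
    df: float
    T: float
    H: float
    fr: float = 0.01
    sr: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.fr < 1.0):
            raise ValueError(f"fr must lie in (0, 1), got {self.fr}")
        if not (0.0 < self.sr < 1.0):
            raise ValueError(f"sr must lie in (0, 1), got {self.sr}")
        if self.fr + self.sr > 1.0:
            raise ValueError(
                f"fr + sr = {self.fr + self.sr} exceeds 1: responder pools "
                "cannot exceed the population"
            )
        if not self.kon > 0.0:
            raise ValueError(f"kon must be > 0, got {self.kon}")
        if not self.koff > 0.0:
            raise ValueError(f"koff must be > 0, got {self.koff}")
        if self.kf < 0.0:
            raise ValueError(f"kf must be >= 0, got {self.kf}")
        if self.df < 0.0:
            raise ValueError(f"df must be >= 0, got {self.df}")
        if not self.T > 0.0:
            raise ValueError(f"T must be > 0, got {self.T}")
        if self.H < 1.0:
            raise ValueError(f"H must be >= 1, got {self.H}")

    # -- convenience ------------------------------------------------------

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        extra = set(d) - set(PARAM_NAMES)
        if extra:
            raise ValueError(f"unknown parameter names: {sorted(extra)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls.from_dict(json.loads(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelParameters":
        return cls.from_dict(yaml.safe_load(text))


@dataclasses.dataclass(frozen=True)
class StateVector:
    """Model state at one time point: (f1, f2, ifn)."""

    f1: float
    f2: float
    ifn: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.ifn], dtype=float)

    def validate(self, params: ModelParameters) -> None:
        """Assert 0 <= f1 <= fr, 0 <= f2 <= sr, ifn >= 0."""
        if not (0.0 <= self.f1 <= params.fr):
            raise ValueError(f"f1={self.f1} outside [0, fr={params.fr}]")
        if not (0.0 <= self.f2 <= params.sr):
            raise ValueError(f"f2={self.f2} outside [0, sr={params.sr}]")
        if self.ifn < 0.0:
            raise ValueError(f"ifn={self.ifn} negative")


REST_STATE = StateVector(0.0, 0.0, 0.0)


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Simulation output on a reporting grid.

    Attributes
    ----------
    times : ndarray, hours, strictly increasing
    f1, f2, ifn : ndarray, state components per time point
    """

    times: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    ifn: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "f1", "f2", "ifn"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        if any(len(getattr(self, k)) != n for k in ("f1", "f2", "ifn")):
            raise ValueError("state series must match the time grid length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def percent_positive(self) -> np.ndarray:
        """Percent IFNα-positive cells, 100·(f1+f2), per time point."""
        return 100.0 * (self.f1 + self.f2)

    def state_at(self, index: int) -> StateVector:
        return StateVector(float(self.f1[index]), float(self.f2[index]), float(self.ifn[index]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "f1": self.f1,
                "f2": self.f2,
                "ifn_pg_ml": self.ifn,
                "percent_positive": self.percent_positive,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def hill_activation(ifn, T: float, H: float):
    """Hill gate ``ifn^H / (T^H + ifn^H)`` of second-responder activation.

    Continuous and strictly increasing in ``ifn``, exactly 0 at ``ifn == 0``
    (avoiding 0**H/0 pitfalls for non-integer ``H``), 1/2 at ``ifn == T``,
    approaching 1 from below.  Accepts scalars or arrays.
    """
    if not T > 0.0:
        raise ValueError(f"T must be > 0, got {T}")
    if H < 1.0:
        raise ValueError(f"H must be >= 1, got {H}")
    x = np.asarray(ifn, dtype=float)
    if np.any(x < 0.0):
        raise ValueError("ifn concentration must be non-negative")
    # computed as 1 / (1 + (T/ifn)^H) for ifn > 0: overflow-safe for large
    # ifn/T ratios and exact 0 at ifn == 0
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0.0, T / np.where(x > 0.0, x, 1.0), np.inf)
        out = 1.0 / (1.0 + ratio**H)
    out = np.where(x > 0.0, out, 0.0)
    if np.isscalar(ifn) or np.ndim(ifn) == 0:
        return float(out)
    return out


def _rhs(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    f1, f2, ifn = y
    h = hill_activation(max(ifn, 0.0), params.T, params.H)
    return np.array(
        [
            params.kon * (params.fr - f1) - params.koff * f1,
            params.kon * h * (params.sr - f2) - params.koff * f2,
            params.kf * (f1 + f2) - params.df * ifn,
        ]
    )


def derivatives(state, params: ModelParameters) -> tuple:
    """Right-hand side (df1/dt, df2/dt, difn/dt) at ``state``.

    At the boundary f1 == fr the f1-derivative equals -koff*fr < 0, so the
    first-responder fraction can never overshoot its pool; analogously for
    f2 == sr.  Together with ifn >= 0 this makes the admissible box forward
    invariant.
    """
    if isinstance(state, StateVector):
        state.validate(params)
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
        StateVector(*y).validate(params)
    d = _rhs(y, params)
    return (float(d[0]), float(d[1]), float(d[2]))


def simulate(
    params: ModelParameters,
    t_grid: Sequence[float] = DEFAULT_T_GRID,
    initial: StateVector | Iterable[float] = REST_STATE,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model on ``t_grid`` from ``initial`` (default: rest).

    Uses adaptive LSODA integration (the system is non-stiff at all fitted
    parameter regimes but couples fast secretion to slow decay, which LSODA
    handles gracefully at low cost).  Every reported state is checked
    against the invariant box 0 <= f1 <= fr, 0 <= f2 <= sr, ifn >= 0:
    violations beyond integration tolerance raise :class:`IntegrationError`,
    while sub-tolerance excursions are clipped back onto the box.

    Raises
    ------
    IntegrationError
        If the integrator reports failure (e.g. step-size underflow);
        never returns silent NaNs.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if t[0] != 0.0:
        raise ValueError("t_grid must start at 0 (stimulus addition)")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")

    if isinstance(initial, StateVector):
        y0 = initial.as_array()
    else:
        y0 = np.asarray(list(initial), dtype=float)
    StateVector(*y0).validate(params)

    if len(t) == 1:
        return Trajectory(t, [y0[0]], [y0[1]], [y0[2]])

    # plain-float closure: the RHS runs a few hundred times per solve and
    # ~1e5 solves per recovery study, so avoid array/dataclass overhead
    fr, sr = params.fr, params.sr
    kon, koff, kf, dfr = params.kon, params.koff, params.kf, params.df
    TH, H = params.T**params.H, params.H

    def rhs(y, _t):
        f1, f2, ifn = y
        if ifn > 0.0:
            num = ifn**H
            h = num / (TH + num)
        else:
            h = 0.0
        return (
            kon * (fr - f1) - koff * f1,
            kon * h * (sr - f2) - koff * f2,
            kf * (f1 + f2) - dfr * ifn,
        )

    out, info = odeint(
        rhs,
        y0,
        t,
        rtol=rtol,
        atol=atol,
        full_output=True,
        printmessg=False,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(f"ODE integration failed: {info['message']}")
    if not np.all(np.isfinite(out)):
        raise IntegrationError("ODE integration produced non-finite states")

    f1, f2, ifn = out[:, 0], out[:, 1], out[:, 2]
    # invariant box with slack proportional to integration tolerance
    slack_f = 1e3 * (atol + rtol)
    slack_c = 1e3 * (atol + rtol * max(1.0, float(np.max(np.abs(ifn)))))
    if (
        np.any(f1 < -slack_f)
        or np.any(f1 > params.fr + slack_f)
        or np.any(f2 < -slack_f)
        or np.any(f2 > params.sr + slack_f)
        or np.any(ifn < -slack_c)
    ):
        raise IntegrationError("integrated state left the invariant box")
    return Trajectory(
        t,
        np.clip(f1, 0.0, params.fr),
        np.clip(f2, 0.0, params.sr),
        np.clip(ifn, 0.0, None),
    )


def steady_state(params: ModelParameters) -> StateVector:
    """Fixed point of the model, solved semi-analytically.

    The f1 equation is linear, giving f1* = kon*fr/(kon+koff) in closed
    form.  The (f2, ifn) pair satisfies::

        f2*  = sr * a / (a + koff),   a = kon * h(ifn*)
        ifn* = kf * (f1* + f2*) / df

    solved by bracketed scalar root finding on ifn* in
    [kf*f1*/df, kf*(f1*+sr)/df].  Requires koff > 0 and df > 0.
    """
    if not params.df > 0.0:
        raise ValueError("steady_state requires df > 0")
    f1s = params.kon * params.fr / (params.kon + params.koff)
    if params.kf == 0.0:
        return StateVector(f1s, 0.0, 0.0)

    def f2_of(ifn: float) -> float:
        a = params.kon * hill_activation(ifn, params.T, params.H)
        return params.sr * a / (a + params.koff)

    def g(ifn: float) -> float:
        return ifn - params.kf * (f1s + f2_of(ifn)) / params.df

    lo = params.kf * f1s / params.df
    hi = params.kf * (f1s + params.sr) / params.df
    # g(lo) <= 0 and g(hi) >= 0 for any valid parameters
    assert g(lo) <= 0.0 and g(hi) >= 0.0, "fixed-point bracket failed"
    ifns = brentq(g, lo, hi, xtol=1e-14, rtol=1e-15)
    f2s = f2_of(ifns)
    # fixed-point residuals must vanish to ~1e-10 relative
    scale = max(ifns, 1.0)
    assert abs(g(ifns)) <= 1e-9 * scale
    return StateVector(f1s, f2s, float(ifns))


def percent_positive(traj: Trajectory) -> np.ndarray:
    """Percent IFNα-positive cells over time: 100·(f1+f2)."""
    return traj.percent_positive
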