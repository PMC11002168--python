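"""Multi-condition least-squares fitting with shared/fixed/free parameter roles.

The experimental question behind this module is parsimony: which minimal
set of parameters has to change between stimulus conditions (e.g. CpG-C
dosages) to explain both the percent-positive and the secreted-IFNα time
courses?  A :class:`FitSpec` declares, per model parameter, whether it is

* ``Fixed(value)`` — held constant,
* ``Shared(group)`` — optimised, one value common to all conditions of the
  group,
* ``Free()`` — optimised independently per condition.

Fitting minimises the joint sum of squared residuals over all conditions
and both observables.  Positive parameters spanning decades are optimised
in log-space within bounds, with seeded multistart (trust-region
reflective least squares per start) to guard against local minima.

Left-censored ELISA points (below the limit of quantification) enter
one-sidedly: zero residual while the model is below the LOQ, else the
excess over the LOQ.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .model import PARAM_NAMES, IntegrationError, ModelParameters, simulate
from .observations import ObservationSet

__all__ = [
    "Fixed",
    "Shared",
    "Free",
    "FitSpec",
    "FitResult",
    "FitConfigurationError",
    "DEFAULT_BOUNDS",
    "objective",
    "residual_vector",
    "fit",
    "parsimony_compare",
    "ParsimonyReport",
    "profile_parameter",
    "ProfileResult",
]


class FitConfigurationError(ValueError):
    """Inconsistent fit specification (roles, labels, degrees of freedom)."""


@dataclasses.dataclass(frozen=True)
class Fixed:
    value: float


@dataclasses.dataclass(frozen=True)
class Shared:
    group: str = "all"


@dataclasses.dataclass(frozen=True)
class Free:
    pass


Role = Union[Fixed, Shared, Free]
RoleLike = Union[Role, Mapping[str, Role]]

#: generous log-scale envelopes around all fitted values reported for this model
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "kon": (1e-3, 1e2),
    "koff": (1e-3, 1e2),
    "T": (1e-1, 1e5),
    "H": (1.0, 8.0),
    "kf": (1.0, 1e6),
    "df": (1e-4, 10.0),
    "fr": (1e-4, 0.4),
    "sr": (1e-2, 0.95),
}

#: fractions of first responders / potential second responders are held at
#: the model's population assumption unless a spec overrides them
DEFAULT_ROLES: dict[str, Role] = {"fr": Fixed(0.01), "sr": Fixed(0.5)}


@dataclasses.dataclass(frozen=True)
class FitSpec:
    """Declarative description of one fitting problem.

    ``roles`` maps parameter names to a role, or to a per-condition mapping
    of roles.  ``fr`` and ``sr`` default to ``Fixed(0.01)`` / ``Fixed(0.5)``.
    """

    roles: Mapping[str, RoleLike]
    bounds: Mapping[str, tuple[float, float]] = dataclasses.field(default_factory=dict)
    n_starts: int = 16
    seed: int = 0
    weighting: str = "max_observed"  # or "unit"
    max_nfev: int = 120

    def bound(self, name: str) -> tuple[float, float]:
        lo, hi = self.bounds.get(name, DEFAULT_BOUNDS[name])
        if not (0 < lo < hi):
            raise FitConfigurationError(f"invalid bounds for {name}: ({lo}, {hi})")
        return float(lo), float(hi)

    def role_for(self, name: str, condition: str) -> Role:
        rolelike = {**DEFAULT_ROLES, **self.roles}.get(name)
        if rolelike is None:
            raise FitConfigurationError(f"no role declared for parameter {name!r}")
        if isinstance(rolelike, (Fixed, Shared, Free)):
            return rolelike
        try:
            return rolelike[condition]
        except KeyError:
            raise FitConfigurationError(
                f"role map for {name!r} lacks condition {condition!r}"
            ) from None

    def free_condition_specific(self, conditions: Sequence[str]) -> set[str]:
        """Parameter names with a condition-specific (Free) role anywhere."""
        return {
            name
            for name in PARAM_NAMES
            for c in conditions
            if isinstance(self.role_for(name, c), Free)
        }


class _Plan:
    """Resolved mapping between the optimisation vector and per-condition parameters."""

    def __init__(self, spec: FitSpec, conditions: Sequence[str]):
        if len(set(conditions)) != len(conditions):
            raise FitConfigurationError("duplicate condition labels")
        self.conditions = list(conditions)
        self.labels: list[str] = []
        lows: list[float] = []
        highs: list[float] = []
        # per condition: name -> ("fixed", value) or ("var", index)
        self.assignments: dict[str, dict[str, tuple]] = {c: {} for c in conditions}
        var_index: dict[tuple, int] = {}
        for name in PARAM_NAMES:
            for cond in conditions:
                role = spec.role_for(name, cond)
                if isinstance(role, Fixed):
                    self.assignments[cond][name] = ("fixed", float(role.value))
                    continue
                if isinstance(role, Shared):
                    key = (name, "shared", role.group)
                    label = name if role.group == "all" else f"{name}[group={role.group}]"
                else:
                    key = (name, "cond", cond)
                    label = f"{name}[{cond}]"
                if key not in var_index:
                    var_index[key] = len(self.labels)
                    self.labels.append(label)
                    lo, hi = spec.bound(name)
                    lows.append(lo)
                    highs.append(hi)
                self.assignments[cond][name] = ("var", var_index[key])
        self.lower = np.array(lows)
        self.upper = np.array(highs)

    @property
    def n_vars(self) -> int:
        return len(self.labels)

    def resolve(self, theta: np.ndarray) -> dict[str, ModelParameters]:
        out = {}
        for cond in self.conditions:
            values = {}
            for name, (kind, payload) in self.assignments[cond].items():
                values[name] = payload if kind == "fixed" else float(theta[payload])
            out[cond] = ModelParameters(**values)
        return out


def _weighting_scales(observations: Sequence[ObservationSet], weighting: str) -> tuple[float, float]:
    if weighting == "unit":
        return 1.0, 1.0
    if weighting != "max_observed":
        raise FitConfigurationError(f"unknown weighting scheme {weighting!r}")
    pct_max = max((float(np.max(o.pct_pos)) for o in observations), default=0.0)
    conc_vals = [o.ifn_conc[~o.below_loq] for o in observations]
    conc_vals = [v for v in conc_vals if len(v)]
    conc_max = max((float(np.max(v)) for v in conc_vals), default=0.0)
    return (pct_max or 1.0), (conc_max or observations[0].loq)


def _obs_grid(obs: ObservationSet) -> tuple[np.ndarray, slice]:
    """Simulation grid covering the observation times (prepending t=0 if absent)."""
    if obs.times[0] == 0.0:
        return obs.times, slice(0, len(obs.times))
    return np.concatenate([[0.0], obs.times]), slice(1, len(obs.times) + 1)


def residual_vector(
    params_by_condition: Mapping[str, ModelParameters],
    observations: Sequence[ObservationSet],
    weighting: str = "max_observed",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Weighted residuals over all conditions, percent-positive then IFNα per condition."""
    missing = [o.condition for o in observations if o.condition not in params_by_condition]
    if missing:
        raise FitConfigurationError(f"no parameters for conditions: {missing}")
    pct_scale, conc_scale = _weighting_scales(observations, weighting)
    parts = []
    for obs in observations:
        grid, view = _obs_grid(obs)
        traj = simulate(params_by_condition[obs.condition], grid, rtol=rtol, atol=atol)
        model_pct = traj.percent_positive[view]
        model_ifn = traj.ifn[view]
        parts.append((model_pct - obs.pct_pos) / pct_scale)
        uncensored = (model_ifn - obs.ifn_conc) / conc_scale
        censored = np.where(model_ifn <= obs.loq, 0.0, (model_ifn - obs.loq) / conc_scale)
        parts.append(np.where(obs.below_loq, censored, uncensored))
    return np.concatenate(parts)


def objective(
    params_by_condition: Mapping[str, ModelParameters] | ModelParameters,
    observations: Sequence[ObservationSet],
    weighting: str = "max_observed",
) -> float:
    """Sum of weighted squared residuals; 0 iff the model passes through
    every uncensored point exactly (and stays below LOQ at censored ones)."""
    if isinstance(params_by_condition, ModelParameters):
        params_by_condition = {o.condition: params_by_condition for o in observations}
    r = residual_vector(params_by_condition, observations, weighting)
    return float(np.dot(r, r))


@dataclasses.dataclass
class FitResult:
    params_by_condition: dict[str, ModelParameters]
    objective: float
    residuals: dict[str, dict[str, np.ndarray]]
    fitted_vars: dict[str, float]
    spec: FitSpec
    conditions: list[str]
    diagnostics: dict

    @property
    def n_free(self) -> int:
        return len(self.fitted_vars)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def to_dict(self) -> dict:
        return {
            "conditions": self.conditions,
            "objective": self.objective,
            "fitted_vars": {k: float(v) for k, v in self.fitted_vars.items()},
            "params_by_condition": {c: p.to_dict() for c, p in self.params_by_condition.items()},
            "residuals": {
                c: {k: list(map(float, v)) for k, v in obs.items()}
                for c, obs in self.residuals.items()
            },
            "diagnostics": self.diagnostics,
            "weighting": self.spec.weighting,
            "seed": self.spec.seed,
            "n_starts": self.spec.n_starts,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _split_residuals(
    r: np.ndarray, observations: Sequence[ObservationSet]
) -> dict[str, dict[str, np.ndarray]]:
    out = {}
    pos = 0
    for obs in observations:
        n = len(obs.times)
        out[obs.condition] = {
            "pct_pos": r[pos : pos + n].copy(),
            "ifn": r[pos + n : pos + 2 * n].copy(),
        }
        pos += 2 * n
    return out


def fit(
    observations: Sequence[ObservationSet],
    spec: FitSpec,
    extra_starts: Sequence[Mapping[str, float]] = (),
) -> FitResult:
    """Best local least-squares minimum over ``spec.n_starts`` seeded starts.

    Start 0 sits at the log-midpoint of the bounds, optional
    ``extra_starts`` (label -> natural value, e.g. a coarser fit's optimum)
    follow, and the remainder is drawn log-uniformly within bounds from the
    spec's seed.  Deterministic given seed and spec; ties between
    equal-objective restarts resolve to the lowest start index.
    """
    if not observations:
        raise FitConfigurationError("no observations given")
    conditions = [o.condition for o in observations]
    plan = _Plan(spec, conditions)
    pct_scale, conc_scale = _weighting_scales(observations, spec.weighting)

    # during optimisation the ODE is integrated at a looser tolerance; the
    # finite-difference step (1e-4 in log space) is chosen large enough
    # that jacobian differences dominate the integration error, which is
    # what keeps trust-region steps pointed down the valley
    fit_rtol, fit_atol = 1e-6, 1e-9

    def resid(theta_log: np.ndarray) -> np.ndarray:
        try:
            pbc = plan.resolve(np.exp(theta_log))
            return residual_vector(pbc, observations, spec.weighting, rtol=fit_rtol, atol=fit_atol)
        except (ValueError, IntegrationError):
            return np.full(m, 1e6)

    m = sum(2 * len(o.times) for o in observations)
    n_points = sum(o.n_uncensored for o in observations)

    if plan.n_vars == 0:
        pbc = plan.resolve(np.empty(0))
        r = residual_vector(pbc, observations, spec.weighting)
        return FitResult(
            params_by_condition=pbc,
            objective=float(np.dot(r, r)),
            residuals=_split_residuals(r, observations),
            fitted_vars={},
            spec=spec,
            conditions=conditions,
            diagnostics={"converged": True, "n_starts": 0, "best_start": None, "nfev": 0},
        )

    if n_points < plan.n_vars:
        raise FitConfigurationError(
            f"under-determined fit: {plan.n_vars} free parameters but only "
            f"{n_points} uncensored data points"
        )

    log_lo, log_hi = np.log(plan.lower), np.log(plan.upper)
    rng = np.random.default_rng(spec.seed)
    starts = [0.5 * (log_lo + log_hi)]
    for guess in extra_starts:
        x0 = starts[0].copy()
        for i, label in enumerate(plan.labels):
            if label in guess:
                x0[i] = np.log(guess[label])
        starts.append(np.clip(x0, log_lo, log_hi))
    while len(starts) < spec.n_starts:
        x0 = rng.uniform(log_lo, log_hi)
        # redundant with the sampler's support, but enforced per contract
        if np.any(x0 < log_lo) or np.any(x0 > log_hi):
            continue
        starts.append(x0)
    starts = starts[: max(spec.n_starts, 1)]

    best = None
    start_costs = []
    nfev_total = 0
    any_converged = False
    for i, x0 in enumerate(starts):
        sol = least_squares(
            resid,
            x0,
            bounds=(log_lo, log_hi),
            method="trf",
            jac="2-point",
            x_scale="jac",
            diff_step=1e-4,
            max_nfev=spec.max_nfev,
        )
        nfev_total += sol.nfev
        cost = float(np.dot(sol.fun, sol.fun))
        start_costs.append(cost)
        if sol.status > 0:
            any_converged = True
        if best is None or cost < best[0]:
            best = (cost, i, sol)

    cost, best_index, sol = best
    theta = np.exp(sol.x)
    pbc = plan.resolve(theta)
    r = residual_vector(pbc, observations, spec.weighting)
    obj = float(np.dot(r, r))
    return FitResult(
        params_by_condition=pbc,
        objective=obj,
        residuals=_split_residuals(r, observations),
        fitted_vars={label: float(theta[i]) for i, label in enumerate(plan.labels)},
        spec=spec,
        conditions=conditions,
        diagnostics={
            "converged": any_converged,
            "n_starts": len(starts),
            "best_start": best_index,
            "start_costs": start_costs,
            "nfev": nfev_total,
            "scales": {"pct_pos": pct_scale, "ifn": conc_scale},
        },
    )


@dataclasses.dataclass
class ParsimonyReport:
    """Objective vs. number of condition-specific parameters over a nested family."""

    entries: list[dict]
    selected_index: int
    factor: float

    @property
    def selected(self) -> dict:
        return self.entries[self.selected_index]


def parsimony_compare(fits: Sequence[FitResult], factor: float = 1.05) -> ParsimonyReport:
    """Rank a nested family of fits and flag the most parsimonious adequate one.

    The family must be nested on condition-specific parameter sets (each
    member frees a superset of the previous).  The selected member is the
    smallest whose objective is within ``factor`` of the fully-free member's.
    """
    if not fits:
        raise FitConfigurationError("empty fit family")
    keyed = [(f.spec.free_condition_specific(f.conditions), f) for f in fits]
    keyed.sort(key=lambda kv: (len(kv[0]), sorted(kv[0])))
    for (a, _), (b, _) in zip(keyed, keyed[1:]):
        if not a.issubset(b):
            raise FitConfigurationError(
                f"fit family is not nested: {sorted(a)} is not a subset of {sorted(b)}"
            )
    reference = keyed[-1][1].objective
    entries = [
        {
            "condition_specific": sorted(names),
            "n_condition_specific": len(names),
            "n_free_vars": f.n_free,
            "objective": f.objective,
        }
        for names, f in keyed
    ]
    selected = len(entries) - 1
    for i, entry in enumerate(entries):
        if entry["objective"] <= factor * reference or (reference == 0 and entry["objective"] == 0):
            selected = i
            break
    return ParsimonyReport(entries=entries, selected_index=selected, factor=factor)


@dataclasses.dataclass
class ProfileResult:
    parameter: str
    grid: np.ndarray
    objectives: np.ndarray
    fits: list[FitResult]

    @property
    def argmin(self) -> int:
        return int(np.argmin(self.objectives))


def profile_parameter(
    observations: Sequence[ObservationSet],
    spec: FitSpec,
    parameter: str,
    grid: Sequence[float],
    condition: Optional[str] = None,
) -> ProfileResult:
    """Objective profile of one free parameter: re-optimise the rest per grid value.

    For a condition-specific parameter, ``condition`` selects which
    condition's copy is pinned (all copies if omitted).  Profiling a
    ``Fixed`` parameter is an error.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise FitConfigurationError("empty profile grid")
    conditions = [o.condition for o in observations]
    roles_of = [spec.role_for(parameter, c) for c in conditions]
    if all(isinstance(r, Fixed) for r in roles_of):
        raise FitConfigurationError(f"parameter {parameter!r} is fixed; cannot profile")

    objectives = []
    fits = []
    for value in grid:
        if condition is None:
            new_role: RoleLike = Fixed(float(value))
        else:
            new_role = {
                c: (Fixed(float(value)) if c == condition else spec.role_for(parameter, c))
                for c in conditions
            }
        pinned = dataclasses.replace(spec, roles={**dict(spec.roles), parameter: new_role})
        res = fit(observations, pinned)
        objectives.append(res.objective)
        fits.append(res)
    return ProfileResult(
        parameter=parameter, grid=grid, objectives=np.asarray(objectives), fits=fits
    )
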