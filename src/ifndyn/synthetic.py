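"""Synthetic flow-cytometry / ELISA readouts of the IFNα response model.

Emulates the statistical structure of the measured time courses so that
fitting and pipeline stages are testable without any external data:

* ODE-model truth per condition (the fitted parameter regimes of the four
  stimulus conditions ship as :data:`FITTED_REGIMES`),
* binomial cell-counting noise on percent-positive (flow cytometry of a
  finite well, default 25,000 cells),
* multiplicative lognormal noise with unit median on ELISA concentrations
  (immunoassays have roughly constant CV),
* left-censoring at the ELISA limit of quantification — censored points
  are reported at the LOQ with a flag.

Replicates are averaged into one :class:`~ifndyn.observations.ObservationSet`
per condition with SEM attached, the form in which the assay data is
reported; a point is flagged below-LOQ iff every replicate fell below.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import DEFAULT_T_GRID, ModelParameters, simulate
from .observations import ObservationSet

__all__ = [
    "NoiseModel",
    "SyntheticDataset",
    "FITTED_REGIMES",
    "sample_percent_positive",
    "apply_elisa_noise_and_loq",
    "generate_dataset",
]

#: Fitted parameter regimes of the four TLR stimulation conditions.
#: CpG-C dosages share kon, H, kf, df (kf drops at the highest dose);
#: only the activation threshold T and turn-off rate koff change with dose.
#: R848 differs in activation/turn-off kinetics at a 50 ug/mL-like threshold.
FITTED_REGIMES: dict[str, ModelParameters] = {
    "CpG-C 0.5 ug/mL": ModelParameters(kon=0.4, koff=0.2, kf=6600.0, df=0.04, T=440.0, H=4.0),
    "CpG-C 5 ug/mL": ModelParameters(kon=0.4, koff=0.33, kf=6600.0, df=0.04, T=230.0, H=4.0),
    "CpG-C 50 ug/mL": ModelParameters(kon=0.4, koff=2.0, kf=2000.0, df=0.04, T=20.0, H=4.0),
    "R848 4 ug/mL": ModelParameters(kon=1.5, koff=1.0, kf=6600.0, df=0.04, T=20.0, H=4.0),
}


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description of one experiment.

    ``n_cells_per_well=None`` switches off counting noise (infinite-well
    limit); ``elisa_cv=0`` switches off concentration noise.  LOQ censoring
    always applies.  ``donor_cv_kon`` is an optional lognormal donor effect
    on the activation rate (disabled by default; donor-level heterogeneity
    is not part of the measurement model proper).
    """

    n_cells_per_well: Optional[int] = 25_000
    elisa_cv: float = 0.05
    loq_ifn: float = 12.5
    loq_tnf: float = 7.8  # retained for interface completeness; no TNFα model exists
    replicate_count: int = 3
    seed: int = 0
    donor_cv_kon: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells_per_well is not None and self.n_cells_per_well < 1:
            raise ValueError("n_cells_per_well must be >= 1")
        if self.elisa_cv < 0:
            raise ValueError("elisa_cv must be >= 0")
        if self.loq_ifn <= 0 or self.loq_tnf <= 0:
            raise ValueError("LOQ values must be positive")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if self.donor_cv_kon < 0:
            raise ValueError("donor_cv_kon must be >= 0")


@dataclasses.dataclass
class SyntheticDataset:
    observations: list[ObservationSet]
    truth: dict[str, ModelParameters]
    noise: NoiseModel
    seed: int


def sample_percent_positive(true_fraction, n_cells: int, rng: np.random.Generator):
    """Observed percent positive from counting ``n_cells`` flow events.

    Draws k ~ Binomial(n_cells, true_fraction) and returns 100·k/n_cells.
    Vectorised over ``true_fraction``.
    """
    frac = np.asarray(true_fraction, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("true_fraction must lie in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    k = rng.binomial(n_cells, frac)
    out = 100.0 * k / n_cells
    if np.ndim(true_fraction) == 0:
        return float(out)
    return out


def _lognormal_sigma(cv: float) -> float:
    # CV of a lognormal with sigma: sqrt(exp(sigma^2) - 1)
    return float(np.sqrt(np.log1p(cv**2)))


def apply_elisa_noise_and_loq(true_conc, cv: float, loq: float, rng: np.random.Generator):
    """Noisy ELISA readout with left-censoring.

    Multiplies by a unit-median lognormal factor with coefficient of
    variation ``cv``; values below ``loq`` are reported at ``loq`` with the
    below-LOQ flag set.  Returns ``(reported, flagged)``.
    """
    conc = np.asarray(true_conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("true_conc must be non-negative")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv > 0:
        factor = np.exp(_lognormal_sigma(cv) * rng.standard_normal(conc.shape))
    else:
        factor = 1.0
    noisy = conc * factor
    flagged = noisy < loq
    reported = np.where(flagged, loq, noisy)
    if np.ndim(true_conc) == 0:
        return float(reported), bool(flagged)
    return reported, flagged


def generate_dataset(
    truth: Mapping[str, ModelParameters],
    t_grid: Sequence[float] = DEFAULT_T_GRID,
    noise: NoiseModel = NoiseModel(),
    seed: Optional[int] = None,
) -> SyntheticDataset:
    """Simulate → sample → censor, replicated, for every condition.

    One ObservationSet per condition holding the across-replicate mean of
    percent-positive and reported concentration, SEM per point where the
    replicate count allows, and the all-replicates-censored flag.
    Regenerating with the same seed reproduces the dataset bit-exactly.
    """
    seed = noise.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    nrep = noise.replicate_count
    observations = []
    for condition, params in truth.items():
        traj = simulate(params, t_grid)
        pct_reps = np.empty((nrep, len(traj.times)))
        conc_reps = np.empty((nrep, len(traj.times)))
        flag_reps = np.empty((nrep, len(traj.times)), dtype=bool)
        for r in range(nrep):
            if noise.donor_cv_kon > 0:
                kon_r = params.kon * float(
                    np.exp(_lognormal_sigma(noise.donor_cv_kon) * rng.standard_normal())
                )
                traj_r = simulate(params.replace(kon=kon_r), t_grid)
            else:
                traj_r = traj
            frac = traj_r.f1 + traj_r.f2
            if noise.n_cells_per_well is None:
                pct_reps[r] = 100.0 * frac
            else:
                pct_reps[r] = sample_percent_positive(frac, noise.n_cells_per_well, rng)
            conc_reps[r], flag_reps[r] = apply_elisa_noise_and_loq(
                traj_r.ifn, noise.elisa_cv, noise.loq_ifn, rng
            )
        all_censored = flag_reps.all(axis=0)
        observations.append(
            ObservationSet(
                condition=condition,
                times=np.asarray(t_grid, dtype=float),
                pct_pos=pct_reps.mean(axis=0),
                ifn_conc=conc_reps.mean(axis=0),
                below_loq=all_censored,
                pct_pos_sem=(
                    pct_reps.std(axis=0, ddof=1) / np.sqrt(nrep) if nrep >= 2 else None
                ),
                ifn_sem=(
                    conc_reps.std(axis=0, ddof=1) / np.sqrt(nrep) if nrep >= 2 else None
                ),
                loq=noise.loq_ifn,
            )
        )
    return SyntheticDataset(
        observations=observations, truth=dict(truth), noise=noise, seed=seed
    )
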