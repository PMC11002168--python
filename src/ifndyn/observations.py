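"""Measured (or synthetic) time courses of one experimental condition.

An :class:`ObservationSet` holds what the assays report per condition:
percent IFNα-positive cells (flow cytometry) and supernatant IFNα
concentration (ELISA), each with an optional per-point spread (SEM), plus a
per-point flag marking concentrations below the ELISA limit of
quantification (LOQ).  Censored points are reported *at* the LOQ with the
flag set — never dropped, never zero.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ObservationSet", "read_observations_csv", "write_observations_csv", "DEFAULT_LOQ_IFN"]

#: ELISA limit of quantification for IFNα, pg/mL
DEFAULT_LOQ_IFN = 12.5

_CSV_COLUMNS = ["condition", "time_h", "pct_pos", "pct_pos_sem", "ifn_pg_ml", "ifn_sem", "below_loq"]


@dataclasses.dataclass
class ObservationSet:
    condition: str
    times: np.ndarray
    pct_pos: np.ndarray
    ifn_conc: np.ndarray
    below_loq: Optional[np.ndarray] = None
    pct_pos_sem: Optional[np.ndarray] = None
    ifn_sem: Optional[np.ndarray] = None
    loq: float = DEFAULT_LOQ_IFN

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pct_pos = np.asarray(self.pct_pos, dtype=float)
        self.ifn_conc = np.asarray(self.ifn_conc, dtype=float)
        n = len(self.times)
        if self.below_loq is None:
            self.below_loq = np.zeros(n, dtype=bool)
        else:
            self.below_loq = np.asarray(self.below_loq, dtype=bool)
        for name in ("pct_pos_sem", "ifn_sem"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if not (len(self.pct_pos) == len(self.ifn_conc) == len(self.below_loq) == n):
            raise ValueError("all observation series must share one length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any((self.pct_pos < 0) | (self.pct_pos > 100)):
            raise ValueError("pct_pos must lie in [0, 100]")
        if np.any(self.ifn_conc[~self.below_loq] < 0):
            raise ValueError("uncensored ifn_conc must be non-negative")
        if not self.loq > 0:
            raise ValueError("loq must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_uncensored(self) -> int:
        """Number of informative data points (all pct + uncensored conc)."""
        return len(self.times) + int(np.sum(~self.below_loq))

    def to_frame(self) -> pd.DataFrame:
        def col(v):
            return v if v is not None else np.full(len(self.times), np.nan)

        return pd.DataFrame(
            {
                "condition": self.condition,
                "time_h": self.times,
                "pct_pos": self.pct_pos,
                "pct_pos_sem": col(self.pct_pos_sem),
                "ifn_pg_ml": self.ifn_conc,
                "ifn_sem": col(self.ifn_sem),
                "below_loq": self.below_loq.astype(int),
            }
        )


def write_observations_csv(observations: Sequence[ObservationSet], path) -> None:
    pd.concat([o.to_frame() for o in observations], ignore_index=True).to_csv(path, index=False)


def read_observations_csv(path, loq: float = DEFAULT_LOQ_IFN) -> list[ObservationSet]:
    """Read the per-condition long-format CSV written by :func:`write_observations_csv`."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns: {sorted(missing)}")
    out = []
    for condition, grp in df.groupby("condition", sort=False):
        grp = grp.sort_values("time_h")

        def opt(col):
            v = grp[col].to_numpy(dtype=float)
            return None if np.all(np.isnan(v)) else v

        out.append(
            ObservationSet(
                condition=str(condition),
                times=grp["time_h"].to_numpy(dtype=float),
                pct_pos=grp["pct_pos"].to_numpy(dtype=float),
                ifn_conc=grp["ifn_pg_ml"].to_numpy(dtype=float),
                below_loq=grp["below_loq"].to_numpy(dtype=bool),
                pct_pos_sem=opt("pct_pos_sem"),
                ifn_sem=opt("ifn_sem"),
                loq=loq,
            )
        )
    return out
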