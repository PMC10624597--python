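"""Map model trajectories onto the experimental readouts.

The readouts mirror the assays: membrane hERG1 (flow cytometry /
immunofluorescence), open channels (whole-cell current), hERG1/beta1
complex (co-immunoprecipitation), fully glycosylated channel pool and
glycosylated fraction (western blot bands), *herg1* mRNA (RQ-PCR) and
endosomal channel (Rab5 co-localization).  Time-course readouts are
reported as fold change over their value at seeding time (t = 0), the
scale on which the assays are published; the glycosylated fraction is a
ratio already and is never normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .reaction_engine import Trajectory

__all__ = [
    "FOLD_READOUTS",
    "ObservableSet",
    "CurrentContext",
    "compute_observables",
    "current_from_open",
    "open_from_current",
]

#: baselines below this count (molecules/cell) are solver noise
BASELINE_FLOOR = 1e-6

#: Readouts reported as fold change over t = 0.
FOLD_READOUTS = (
    "membrane_total",
    "open_channels",
    "complex",
    "glyco_total",
    "mrna",
    "endosomal",
)


@dataclass
class ObservableSet:
    """Per-time-point observable series for one trajectory."""

    times_min: np.ndarray
    series: dict[str, np.ndarray]
    normalized: bool

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, values in self.series.items():
            for t, v in zip(self.times_min, values):
                rows.append(
                    {
                        "time_min": t,
                        "observable": name,
                        "value": v,
                        "normalized": self.normalized and name != "glyco_fraction",
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _sum_species(traj: Trajectory, names: Sequence[str]) -> np.ndarray:
    total = np.zeros(len(traj.times))
    for n in names:
        if n not in traj.species_names:
            raise KeyError(f"trajectory has no species {n!r}")
        total = total + traj.species(n)
    return total


def _glyco_fraction(traj: Trajectory) -> np.ndarray:
    glyco = _sum_species(traj, ("G", "Sc", "So", "X", "E"))
    total = glyco + traj.species("R")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, glyco / np.where(total > 0, total, 1.0), 0.0)


#: readout name -> raw series from a trajectory (molecules/cell)
READOUT_DEFS = {
    "membrane_total": lambda tr: _sum_species(tr, ("Sc", "So", "X")),
    "open_channels": lambda tr: _sum_species(tr, ("So",)),
    "complex": lambda tr: _sum_species(tr, ("X",)),
    "glyco_total": lambda tr: _sum_species(tr, ("G", "Sc", "So", "X", "E")),
    "glyco_fraction": _glyco_fraction,
    "mrna": lambda tr: _sum_species(tr, ("M",)),
    "endosomal": lambda tr: _sum_species(tr, ("E",)),
}


def compute_observables(
    traj: Trajectory,
    normalize: bool = True,
    readouts: Sequence[str] | None = None,
    zero_baseline: str = "error",
) -> ObservableSet:
    """Observable series of a trajectory, optionally as fold over t = 0.

    ``readouts`` restricts the set (default: everything the trajectory's
    species support is computed; unknown names raise ``KeyError``).  A
    normalized series with a zero baseline raises ``ValueError`` by
    default; ``zero_baseline="raw"`` keeps such a series unnormalized
    instead (it is identically zero in the common intervention cases).
    """
    wanted = list(readouts) if readouts is not None else list(READOUT_DEFS)
    series: dict[str, np.ndarray] = {}
    for name in wanted:
        if name not in READOUT_DEFS:
            raise KeyError(f"unknown readout {name!r}")
        series[name] = READOUT_DEFS[name](traj)
    if normalize:
        for name in wanted:
            if name not in FOLD_READOUTS:
                continue
            base = series[name][0]
            # counts below solver resolution are noise, not a baseline
            if base <= BASELINE_FLOOR:
                if zero_baseline == "raw":
                    continue
                raise ValueError(
                    f"cannot normalize {name!r}: value at t = 0 is {base:g}"
                )
            series[name] = series[name] / base
    return ObservableSet(traj.times_min.copy(), series, normalize)


@dataclass(frozen=True)
class CurrentContext:
    """Electrical context of the whole-cell current relation I = gamma N_o (V_m - E_K).

    Defaults: 12 pS single-channel conductance (literature-typical for
    hERG), the -120 mV hyperpolarizing tail step, and E_K = -80 mV.
    Fold-change analyses are independent of gamma.
    """

    gamma: float = 12e-12  # S
    V_m: float = -0.120  # V
    E_K: float = -0.080  # V

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def current_from_open(n_open: float | np.ndarray, ctx: CurrentContext = CurrentContext()):
    """Whole-cell current (A) carried by ``n_open`` open channels."""
    return ctx.gamma * np.asarray(n_open, dtype=float) * (ctx.V_m - ctx.E_K)


def open_from_current(current: float | np.ndarray, ctx: CurrentContext = CurrentContext()):
    """Open-channel count from a whole-cell current; exact inverse of
    :func:`current_from_open`."""
    drive = ctx.V_m - ctx.E_K
    if drive == 0:
        raise ZeroDivisionError("V_m equals E_K: zero driving force, not invertible")
    return np.asarray(current, dtype=float) / (ctx.gamma * drive)
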