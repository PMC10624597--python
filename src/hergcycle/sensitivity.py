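"""Random-perturbation ensembles around a best fit and observable envelopes.

The sensitivity convention of the study: draw parameter sets by
independently perturbing every floating parameter uniformly within
+/-10% of its best-fit value (linear scale), simulate each set, and
band every fold-change observable with the pointwise minimum and
maximum across the ensemble around the central best-fit curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .observables import FOLD_READOUTS, compute_observables
from .reaction_engine import (
    EquilibrationError,
    IntegrationError,
    ParameterSet,
    ReactionNetwork,
    CANONICAL_GRID_MIN,
    minutes_to_seconds,
    simulate,
)

__all__ = ["EnsembleSpec", "Envelope", "perturbation_ensemble", "envelope"]


@dataclass(frozen=True)
class EnsembleSpec:
    """Ensemble settings: size, perturbation fraction, seed, parameter scope."""

    n_sets: int = 100
    fraction: float = 0.10
    seed: int = 0
    parameters: tuple[str, ...] | None = None  # default: every floating parameter

    def __post_init__(self):
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.fraction < 0:
            raise ValueError("fraction must be >= 0")


@dataclass
class Envelope:
    """Pointwise bounds (min/max or percentiles) around the central curve."""

    times_min: np.ndarray
    lower: dict[str, np.ndarray]
    central: dict[str, np.ndarray]
    upper: dict[str, np.ndarray]
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.central:
            for i, t in enumerate(self.times_min):
                rows.append(
                    {
                        "time_min": t,
                        "observable": name,
                        "lower": self.lower[name][i],
                        "central": self.central[name][i],
                        "upper": self.upper[name][i],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def perturbation_ensemble(best: ParameterSet, spec: EnsembleSpec = EnsembleSpec()) -> list[ParameterSet]:
    """``n_sets`` copies of ``best`` with floating parameters scaled by U(1-f, 1+f).

    Fixed parameters are untouched; deterministic per seed.
    """
    names = list(spec.parameters) if spec.parameters is not None else best.floating_names
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_sets):
        factors = rng.uniform(1.0 - spec.fraction, 1.0 + spec.fraction, size=len(names))
        out.append(best.with_values({n: best[n] * f for n, f in zip(names, factors)}))
    return out


def envelope(
    network: ReactionNetwork,
    ensemble: Sequence[ParameterSet],
    init_policy: Callable[[ReactionNetwork, ParameterSet], np.ndarray] | None = None,
    grid_min: Sequence[float] = CANONICAL_GRID_MIN,
    central: ParameterSet | None = None,
    readouts: Sequence[str] = FOLD_READOUTS,
    percentiles: tuple[float, float] | None = None,
    max_failure_fraction: float = 0.10,
) -> Envelope:
    """Simulate every ensemble member and band the fold observables.

    Bounds are pointwise min/max by default (``percentiles`` switches to
    central percentile bands).  Members that fail to simulate are
    dropped and counted; more than ``max_failure_fraction`` failures is
    an error.  ``central`` defaults to the first ensemble member.
    """
    if init_policy is None:
        from .herg1_model import seeding_policy as init_policy
    if not ensemble:
        raise ValueError("empty ensemble")
    t_sec = minutes_to_seconds(grid_min)
    t_min = np.asarray(grid_min, dtype=float)

    def run(p: ParameterSet) -> dict[str, np.ndarray] | None:
        try:
            init = init_policy(network, p)
            obs = compute_observables(simulate(network, p, init, t_sec), normalize=True)
        except (IntegrationError, EquilibrationError, ValueError):
            return None
        return {r: obs[r] for r in readouts}

    central_obs = run(central if central is not None else ensemble[0])
    if central_obs is None:
        raise IntegrationError("central parameter set failed to simulate")
    stacks: dict[str, list[np.ndarray]] = {r: [] for r in readouts}
    n_failed = 0
    for p in ensemble:
        obs = run(p)
        if obs is None:
            n_failed += 1
            continue
        for r in readouts:
            stacks[r].append(obs[r])
    if n_failed > max_failure_fraction * len(ensemble):
        raise IntegrationError(
            f"{n_failed}/{len(ensemble)} ensemble members failed to simulate"
        )
    lower, upper = {}, {}
    for r in readouts:
        arr = np.vstack(stacks[r])
        if percentiles is None:
            lower[r], upper[r] = arr.min(axis=0), arr.max(axis=0)
        else:
            lower[r] = np.percentile(arr, percentiles[0], axis=0)
            upper[r] = np.percentile(arr, percentiles[1], axis=0)
        # the band is around the central curve by construction for min/max;
        # percentile bands may exclude it, so widen to keep lower<=central<=upper
        lower[r] = np.minimum(lower[r], central_obs[r])
        upper[r] = np.maximum(upper[r], central_obs[r])
    return Envelope(t_min, lower, central_obs, upper, n_failed)
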