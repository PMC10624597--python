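"""Weighted least-squares cost and stochastic Monte-Carlo parameter search.

The search mirrors the study's procedure: starting from an educated
guess, each iteration perturbs a random pair of floating parameters
multiplicatively (log-space steps, since the constants span ten orders
of magnitude), recomputes the weighted sum of squared deviations between
the model's fold-change observables and the replicate means, and accepts
the move only if the score strictly decreases.  Iteration stops when
the relative decrease of the best score over a patience window falls
below a tolerance, or at the iteration cap.  Everything is driven by a
single seed, so a fit is exactly reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .observables import compute_observables
from .reaction_engine import (
    IntegrationError,
    EquilibrationError,
    ParameterSet,
    ReactionNetwork,
    minutes_to_seconds,
    simulate,
)
from .synthetic_data import TimeCourseDataset

__all__ = ["FitOptions", "FitResult", "cost", "mc_fit", "multi_start_fit"]

InitPolicy = Callable[[ReactionNetwork, ParameterSet], np.ndarray]


@dataclass(frozen=True)
class FitOptions:
    """Search settings.

    ``perturb_fraction`` is the multiplicative half-width of one move
    (each chosen parameter is multiplied by exp(U(-d, d)) with
    d = ln(1 + perturb_fraction)); ``rel_tol``/``patience`` define the
    stopping rule (relative decrease of the best score per patience
    window); ``bounds`` optionally boxes named parameters.
    """

    perturb_fraction: float = 0.10
    rel_tol: float = 1e-4
    patience: int = 500
    max_iterations: int = 10_000
    seed: int = 0
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    weights: Mapping[str, float] | None = None

    def __post_init__(self):
        if not 0.0 < self.perturb_fraction < 1.0:
            raise ValueError("perturb_fraction must be in (0, 1)")
        if self.weights is not None and all(w == 0 for w in self.weights.values()):
            raise ValueError("weights must not be all zero")


@dataclass
class FitResult:
    """Outcome of one Monte-Carlo fit."""

    best_params: ParameterSet
    best_score: float
    score_history: list[float]  # accepted scores, non-increasing
    n_evaluations: int
    n_iterations: int
    converged: bool
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "best_params": self.best_params.to_dict(),
            "best_score": self.best_score,
            "score_history": list(self.score_history),
            "n_evaluations": self.n_evaluations,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            ParameterSet.from_dict(d["best_params"]),
            d["best_score"],
            d["score_history"],
            d["n_evaluations"],
            d["n_iterations"],
            d["converged"],
            d["seed"],
        )


def _dataset_targets(dataset: TimeCourseDataset):
    """Replicate means pivoted to (readout -> (times_min, mean values))."""
    means = dataset.replicate_means()
    out = {}
    for readout, sub in means.groupby("readout"):
        sub = sub.sort_values("time_min")
        out[str(readout)] = (
            sub["time_min"].to_numpy(dtype=float),
            sub["value"].to_numpy(dtype=float),
        )
    return out


def cost(
    params: ParameterSet,
    network: ReactionNetwork,
    dataset: TimeCourseDataset,
    weights: Mapping[str, float] | None = None,
    init_policy: InitPolicy | None = None,
    _targets=None,
) -> float:
    """Weighted sum of squared deviations, model fold vs replicate means.

    Any failure to build the initial state, integrate, or normalize the
    observables returns +inf (documented sentinel), so the search simply
    rejects the offending parameter vector.
    """
    if init_policy is None:
        from .herg1_model import seeding_policy as init_policy  # default study protocol
    targets = _targets if _targets is not None else _dataset_targets(dataset)
    if weights is not None and all(w == 0 for w in weights.values()):
        raise ValueError("weights must not be all zero")
    grid_min = dataset.times_min
    from .observables import READOUT_DEFS

    for readout in targets:
        if readout not in READOUT_DEFS:
            raise KeyError(f"dataset readout {readout!r} has no model observable")
    try:
        init = init_policy(network, params)
        traj = simulate(network, params, init, minutes_to_seconds(grid_min))
        obs = compute_observables(traj, normalize=True, readouts=list(targets))
    except (IntegrationError, EquilibrationError, ValueError, FloatingPointError):
        return math.inf
    total = 0.0
    for readout, (t, data_mean) in targets.items():
        w = 1.0 if weights is None else float(weights.get(readout, 0.0))
        if w == 0.0:
            continue
        model = np.interp(t, grid_min, obs[readout])
        total += w * float(np.sum((model - data_mean) ** 2))
    if not np.isfinite(total):
        return math.inf
    return total


def _clip_bounds(name: str, value: float, bounds) -> float:
    lo, hi = bounds.get(name, (0.0, math.inf))
    return min(max(value, lo), hi)


def mc_fit(
    start: ParameterSet,
    network: ReactionNetwork,
    dataset: TimeCourseDataset,
    options: FitOptions = FitOptions(),
    init_policy: InitPolicy | None = None,
    log: Callable[[str], None] | None = None,
) -> FitResult:
    """Greedy accept-if-lower random pairwise-perturbation search.

    Fixed parameters (floating mask false) are never touched; accepted
    parameters stay strictly positive.  Deterministic given the seed.
    """
    floating = start.floating_names
    if len(floating) < 2:
        raise ValueError("need at least 2 floating parameters")
    if init_policy is None:
        from .herg1_model import seeding_policy as init_policy
    targets = _dataset_targets(dataset)

    def score_of(p: ParameterSet) -> float:
        return cost(p, network, dataset, options.weights, init_policy, _targets=targets)

    rng = np.random.default_rng(options.seed)
    current = start.copy()
    best_score = score_of(current)
    if not math.isfinite(best_score):
        raise ValueError("start parameters do not yield a finite score")
    history = [best_score]
    n_eval = 1
    delta = math.log1p(options.perturb_fraction)
    converged = False
    window_best = best_score
    iteration = 0
    while iteration < options.max_iterations:
        iteration += 1
        i, j = rng.choice(len(floating), size=2, replace=False)
        trial_vals = {}
        for idx in (i, j):
            name = floating[idx]
            factor = math.exp(rng.uniform(-delta, delta))
            trial_vals[name] = _clip_bounds(name, current[name] * factor, options.bounds)
        trial = current.with_values(trial_vals)
        s = score_of(trial)
        n_eval += 1
        if s < best_score:
            current = trial
            best_score = s
            history.append(s)
            if log is not None:
                log(
                    f"iter {iteration}: score {s:.6g} "
                    f"(pair {floating[i]}, {floating[j]})"
                )
        if iteration % options.patience == 0:
            if window_best > 0 and (window_best - best_score) / window_best < options.rel_tol:
                converged = True
                break
            window_best = best_score
    return FitResult(
        best_params=current,
        best_score=best_score,
        score_history=history,
        n_evaluations=n_eval,
        n_iterations=iteration,
        converged=converged,
        seed=options.seed,
    )


def multi_start_fit(
    starts: Sequence[ParameterSet],
    network: ReactionNetwork,
    dataset: TimeCourseDataset,
    options: FitOptions = FitOptions(),
    init_policy: InitPolicy | None = None,
) -> FitResult:
    """Run :func:`mc_fit` from every start; return the lowest final score.

    Ties break to the lowest start index.  Start k runs with seed
    ``options.seed + k`` so the runs are independent but reproducible.
    """
    if not starts:
        raise ValueError("need at least one start")
    best = None
    for k, start in enumerate(starts):
        opts = FitOptions(
            perturb_fraction=options.perturb_fraction,
            rel_tol=options.rel_tol,
            patience=options.patience,
            max_iterations=options.max_iterations,
            seed=options.seed + k,
            bounds=options.bounds,
            weights=options.weights,
        )
        try:
            res = mc_fit(start, network, dataset, opts, init_policy)
        except ValueError:
            continue  # infeasible start: skip, like a rejected manual guess
        if best is None or res.best_score < best.best_score:
            best = res
    if best is None:
        raise ValueError("no start produced a finite score")
    return best
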