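"""End-to-end study workflows.

Two reusable procedures:

- the anchor-reproduction pipeline: generate the synthetic replicate
  dataset from the printed kinetic anchors, run the Monte-Carlo fit of
  the reconstructed network starting from a documented educated guess,
  simulate the fitted model densely, and extract the kinetic summary
  statistics (peak folds and times, mRNA fold at 120 min, the
  half-decay time of the membrane elevation);
- the parameter-recovery harness: refit designated rate constants on
  noiseless model-generated data in a testbed regime where each of them
  is rate-limiting, and report relative errors.

The educated guess mirrors the study's procedure (manual exploration of
parameter space before the stochastic fine fit).  Starting from the
published best-fit values verbatim, the greedy pairwise search locks
into a pulseless compromise: those values encode second-to-minute
relaxation times (mRNA lifetime ~10 s, inhibitor relaxation ~8 s) that
cannot express the 90-minute pulse this reconstruction must produce.
The guess therefore sets the handful of timescale-defining constants to
the hour scale read directly off the assays: mRNA turnover slow enough
for a saturating fold over 5 h, Golgi export and membrane delivery in
the minutes-to-tens-of-minutes range, and an inhibitor that builds up
over hours so the activator pulse lasts about 90 min, with its basal
activation/inactivation balance set by the basal complex count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fitting import FitOptions, FitResult, mc_fit
from .herg1_model import (
    default_network,
    seeding_policy,
    published_parameters,
)
from .observables import compute_observables
from .reaction_engine import ParameterSet, minutes_to_seconds, simulate
from .synthetic_data import (
    AnchorProfile,
    TimeCourseDataset,
    default_anchor_profile,
    generate_anchor_dataset,
    generate_model_dataset,
)

__all__ = [
    "EDUCATED_GUESS_OVERRIDES",
    "RECOVERY_TESTBED_OVERRIDES",
    "RECOVERY_PARAMETERS",
    "educated_guess",
    "AnchorFitSummary",
    "anchor_fit_pipeline",
    "recovery_harness",
]

#: Timescale-derived start point for the stochastic fit (see module
#: docstring).  Values are absolute rate constants replacing the
#: published ones.
EDUCATED_GUESS_OVERRIDES = {
    "k_dm": 8e-5,  # mRNA lifetime ~3.5 h
    "k_g": 5e-3,  # ER -> Golgi ~3 min
    "k_tg": 5e-4,  # Golgi -> membrane ~30 min
    "k_ie_plus": 1e-4,  # inhibitor relaxes over ~3 h: pulse lasts ~90 min
    "k_i": 1.2e-11,  # basal activator balance at the basal complex count
}

#: Rate constants exercised by the recovery harness.
RECOVERY_PARAMETERS = ("k_on", "k_off", "k_a", "k_e", "k_tg")

#: Synthetic truth for the recovery harness: a regime in which each of
#: the five recovery constants is individually rate-limiting for the
#: fold observables (complex lifetime on the assay timescale so binding
#: and unbinding separate; delivery trafficking-limited; endocytosis
#: comparable to the constitutive membrane turnover; sub-saturated
#: complex so the binding constants move the readouts).
RECOVERY_TESTBED_OVERRIDES = {
    **EDUCATED_GUESS_OVERRIDES,
    "k_dm": 1e-3,
    "k_tg": 2e-4,
    "k_i": 2e-10,
    "g_dose": 1e-8,
    "k_n": 0.05,
    "k_e": 1e-5,
    "k_tg_plus": 1e-7,
    "k_g_plus": 1e-6,
    "k_on": 1.5e-10,
    "k_off": 5e-4,
}


def educated_guess(cell_line: str = "HEK-hERG1") -> ParameterSet:
    """Published parameters with the timescale-derived overrides applied."""
    return published_parameters(cell_line).with_values(EDUCATED_GUESS_OVERRIDES)


@dataclass
class AnchorFitSummary:
    """Outcome of the end-to-end anchor-reproduction pipeline."""

    dataset: TimeCourseDataset
    fit: FitResult
    times_min: np.ndarray  # dense grid
    observables: dict[str, np.ndarray]  # fold series on the dense grid
    peak_fold: dict[str, float]
    peak_time_min: dict[str, float]
    mrna_fold_at_120: float
    half_decay_time_min: float | None  # first crossing after the peak; None if none


def _pulse_metrics(times_min: np.ndarray, series: np.ndarray):
    peak_idx = int(np.argmax(series))
    peak = float(series[peak_idx])
    elevation = series - 1.0
    half = 0.5 * elevation[peak_idx]
    after = np.nonzero(elevation[peak_idx:] < half)[0]
    t_half = float(times_min[peak_idx + after[0]]) if after.size else None
    return peak, float(times_min[peak_idx]), t_half


def summarize_fitted_model(
    params: ParameterSet,
    dataset: TimeCourseDataset,
    fit: FitResult,
    grid_step_min: float = 1.0,
    t_end_min: float = 300.0,
) -> AnchorFitSummary:
    """Dense simulation of a fitted parameter set plus kinetic summaries."""
    net = default_network()
    times_min = np.arange(0.0, t_end_min + 0.5 * grid_step_min, grid_step_min)
    init = seeding_policy(net, params)
    traj = simulate(net, params, init, minutes_to_seconds(times_min))
    obs = compute_observables(traj, normalize=True)
    peak_fold, peak_time = {}, {}
    for name in ("membrane_total", "open_channels", "complex", "glyco_total"):
        peak_fold[name], peak_time[name], _ = _pulse_metrics(times_min, obs[name])
    _, _, t_half = _pulse_metrics(times_min, obs["membrane_total"])
    mrna_120 = float(np.interp(120.0, times_min, obs["mrna"]))
    return AnchorFitSummary(
        dataset=dataset,
        fit=fit,
        times_min=times_min,
        observables=dict(obs.series),
        peak_fold=peak_fold,
        peak_time_min=peak_time,
        mrna_fold_at_120=mrna_120,
        half_decay_time_min=t_half,
    )


def anchor_fit_pipeline(
    cell_line: str = "HEK-hERG1",
    seed: int = 1,
    max_iterations: int = 25_000,
    profile: AnchorProfile | None = None,
    n_restarts: int = 2,
) -> AnchorFitSummary:
    """Synthetic anchors -> Monte-Carlo fit -> dense simulation -> summary.

    The dataset seed and fit seed both derive from ``seed``.  A greedy
    stochastic search can occasionally stall in a pulseless local
    optimum; when the fitted membrane time course has no interior
    maximum the search restarts with a reseeded random stream (at most
    ``n_restarts`` times), keeping the best pulsed result.
    """
    net = default_network()
    prof = profile if profile is not None else default_anchor_profile(cell_line)
    dataset = generate_anchor_dataset(prof, seed=seed, cell_line=cell_line)
    start = educated_guess(cell_line)
    # the anchor cost landscape has long flat stretches; spend the whole
    # iteration budget rather than stopping on a patience window
    opts = dict(rel_tol=1e-9, patience=max_iterations, max_iterations=max_iterations)
    best = None
    for attempt in range(1 + n_restarts):
        fit = mc_fit(start, net, dataset,
                     FitOptions(seed=seed + 7919 * attempt, **opts))
        summary = summarize_fitted_model(fit.best_params, dataset, fit)

        def rank(s: AnchorFitSummary):
            # pulsed solutions first, then by score
            return (s.half_decay_time_min is not None, -s.fit.best_score)

        if best is None or rank(summary) > rank(best):
            best = summary
        if best.half_decay_time_min is not None:
            break
    return best


def recovery_harness(
    parameters: Sequence[str] = RECOVERY_PARAMETERS,
    seed: int = 0,
    max_iterations: int = 6000,
    start_offsets: dict[str, float] | None = None,
    cell_line: str = "HEK-hERG1",
):
    """Refit designated constants on noiseless testbed data.

    Returns ``{name: (truth, recovered, relative error)}``.  Start
    values are offset from truth by the given factors (default:
    alternating 2x and 0.5x), all other parameters clamped at truth.
    """
    net = default_network()
    truth = published_parameters(cell_line).with_values(RECOVERY_TESTBED_OVERRIDES)
    policy = seeding_policy
    dataset = generate_model_dataset(
        net, truth, noise_cv=0.0, n_rep=1, seed=seed,
        init=policy(net, truth), cell_line=cell_line,
    )
    if start_offsets is None:
        start_offsets = {
            name: (2.0 if i % 2 == 0 else 0.5) for i, name in enumerate(parameters)
        }
    mask = {k: (k in parameters) for k in truth.values}
    start = ParameterSet(
        {k: v * start_offsets.get(k, 1.0) for k, v in truth.values.items()},
        truth.units, mask,
    )
    res = mc_fit(start, net, dataset,
                 FitOptions(max_iterations=max_iterations, seed=seed,
                            rel_tol=1e-8, patience=2000))
    out = {}
    for name in parameters:
        rec = res.best_params[name]
        out[name] = (truth[name], rec, abs(rec - truth[name]) / truth[name])
    return out
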