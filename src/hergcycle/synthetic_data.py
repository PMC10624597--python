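"""Synthetic replicate time courses with the kinetic structure of the assays.

No raw data ship with the study, so the generator emulates the printed
kinetic anchors instead: pulse-shaped readouts that rise from a resting
baseline of 1, peak about fourfold at 90 min after seeding on
fibronectin, and relax towards a late plateau; a saturating mRNA fold
that passes twofold near 120 min; and an endosomal readout that empties
while the membrane pool peaks and refills afterwards.  Replicates are
i.i.d. with multiplicative Gaussian noise truncated at zero,
s.e.m.-scale by default (CV 0.10, n = 3).

The pulse mean curve is a gamma-type pulse
``p(t) = (t/t_p)^h exp(h (1 - t/t_p))`` (0 at t = 0, 1 at the peak time
``t_p``) blended with a baseline that drifts from 1 to the late plateau,
so the curve starts exactly at 1 and attains exactly the peak fold at
``t_p``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .herg1_model import normalize_cell_line, seeding_policy
from .observables import FOLD_READOUTS, compute_observables
from .reaction_engine import CANONICAL_GRID_MIN, ParameterSet, ReactionNetwork, minutes_to_seconds, simulate

__all__ = [
    "ReadoutAnchor",
    "AnchorProfile",
    "TimeCourseDataset",
    "default_anchor_profile",
    "generate_anchor_dataset",
    "generate_model_dataset",
]


@dataclass(frozen=True)
class ReadoutAnchor:
    """Anchors of one readout's mean curve (fold-change units)."""

    peak: float
    peak_time_min: float
    plateau: float
    kind: str = "pulse"  # "pulse" or "saturating"
    h: float = 3.0  # pulse sharpness
    #: for "saturating": time at which the curve must pass this fold
    anchor_fold: float | None = None
    anchor_time_min: float | None = None

    def mean_curve(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        if self.kind == "saturating":
            # 1 + (peak-1)(1 - e^(-t/tau)); tau from the crossing anchor
            if self.anchor_fold is not None:
                frac = (self.anchor_fold - 1.0) / (self.peak - 1.0)
                if not 0 < frac < 1:
                    raise ValueError("saturating anchor fold outside (baseline, peak)")
                tau = -self.anchor_time_min / np.log1p(-frac)
            else:
                tau = self.peak_time_min
            return 1.0 + (self.peak - 1.0) * (1.0 - np.exp(-t / tau))
        if self.kind != "pulse":
            raise ValueError(f"unknown readout kind {self.kind!r}")
        tp, h = self.peak_time_min, self.h
        with np.errstate(divide="ignore", invalid="ignore"):
            pulse = np.where(t > 0, (t / tp) ** h * np.exp(h * (1.0 - t / tp)), 0.0)
        baseline = self.plateau + (1.0 - self.plateau) * np.exp(-h * t / tp)
        b_tp = self.plateau + (1.0 - self.plateau) * np.exp(-h)
        return baseline + (self.peak - b_tp) * pulse


@dataclass(frozen=True)
class AnchorProfile:
    """Per-readout anchors plus the replicate noise model."""

    readouts: Mapping[str, ReadoutAnchor]
    noise_cv: float = 0.10
    n_rep: int = 3

    def __post_init__(self):
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for name, a in self.readouts.items():
            if a.kind == "pulse" and not (a.peak >= a.plateau >= 0 or a.peak <= 1.0):
                raise ValueError(f"readout {name!r}: require peak >= plateau >= 0")


def default_anchor_profile(cell_line: str = "HEK-hERG1") -> AnchorProfile:
    """The study-condition anchors for one cell line.

    HEK: all pulse readouts peak fourfold at 90 min; the current-derived
    readout relaxes to 1.8-fold, membrane/complex/glycosylated pools to
    1.3-fold; mRNA saturates to 2.3-fold passing twofold at 120 min; the
    endosomal pool dips to 0.4 at 90 min and refills.  The cancer lines
    reuse the same shapes with a faster post-peak relaxation (sharper
    pulse, lower late plateau).
    """
    cell = normalize_cell_line(cell_line)
    h = 3.0 if cell == "HEK-hERG1" else 4.0
    plateau = {"HEK-hERG1": 1.3}.get(cell, 1.15)
    open_plateau = {"HEK-hERG1": 1.8}.get(cell, 1.4)
    readouts = {
        "membrane_total": ReadoutAnchor(4.0, 90.0, plateau, "pulse", h),
        "open_channels": ReadoutAnchor(4.0, 90.0, open_plateau, "pulse", h),
        "complex": ReadoutAnchor(4.0, 90.0, plateau, "pulse", h),
        "glyco_total": ReadoutAnchor(4.0, 90.0, plateau, "pulse", h),
        "mrna": ReadoutAnchor(
            2.3, 300.0, 2.3, "saturating", anchor_fold=2.0, anchor_time_min=120.0
        ),
        "endosomal": ReadoutAnchor(0.4, 90.0, 1.0, "pulse", h),
    }
    return AnchorProfile(readouts)


@dataclass
class TimeCourseDataset:
    """Replicate fold-change measurements for one cell line.

    ``frame`` columns: cell_line, readout, time_min, replicate, value.
    ``provenance`` records how the dataset was made (mode, seed,
    profile) so a dataset is reproducible from its own metadata.
    """

    cell_line: str
    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def readouts(self) -> list[str]:
        return sorted(self.frame["readout"].unique())

    @property
    def times_min(self) -> np.ndarray:
        return np.sort(self.frame["time_min"].unique())

    def replicate_means(self) -> pd.DataFrame:
        """Mean over replicates: columns readout, time_min, value."""
        return (
            self.frame.groupby(["readout", "time_min"], as_index=False)["value"]
            .mean()
            .sort_values(["readout", "time_min"], ignore_index=True)
        )

    def content_hash(self) -> str:
        payload = self.frame.sort_values(
            ["readout", "time_min", "replicate"], ignore_index=True
        )[["readout", "time_min", "replicate", "value"]]
        return hashlib.sha256(
            payload.to_csv(index=False, float_format="%.12g").encode()
        ).hexdigest()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
        meta = str(path) + ".json"
        with open(meta, "w") as fh:
            json.dump(self.provenance, fh, indent=1, default=str)

    @classmethod
    def from_csv(cls, path) -> "TimeCourseDataset":
        frame = pd.read_csv(path)
        try:
            with open(str(path) + ".json") as fh:
                prov = json.load(fh)
        except FileNotFoundError:
            prov = {}
        return cls(str(frame["cell_line"].iloc[0]), frame, prov)


def _profile_dict(profile: AnchorProfile) -> dict:
    return {
        "noise_cv": profile.noise_cv,
        "n_rep": profile.n_rep,
        "readouts": {k: vars(a) for k, a in profile.readouts.items()},
    }


def _with_noise(
    rng: np.random.Generator, mean: np.ndarray, cv: float, n_rep: int
) -> np.ndarray:
    """(n_rep, T) replicate draws: mean * (1 + N(0, cv)), truncated at 0."""
    noise = rng.normal(0.0, cv, size=(n_rep, mean.size)) if cv > 0 else np.zeros((n_rep, mean.size))
    return np.maximum(mean[None, :] * (1.0 + noise), 0.0)


def generate_anchor_dataset(
    profile: AnchorProfile,
    grid_min: Sequence[float] = CANONICAL_GRID_MIN,
    seed: int = 0,
    cell_line: str = "HEK-hERG1",
) -> TimeCourseDataset:
    """Draw a replicate dataset from the anchor mean curves."""
    t = np.asarray(grid_min, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    cell = normalize_cell_line(cell_line)
    for readout in sorted(profile.readouts):
        mean = profile.readouts[readout].mean_curve(t)
        values = _with_noise(rng, mean, profile.noise_cv, profile.n_rep)
        for rep in range(profile.n_rep):
            for ti, v in zip(t, values[rep]):
                rows.append((cell, readout, ti, rep, v))
    frame = pd.DataFrame(
        rows, columns=["cell_line", "readout", "time_min", "replicate", "value"]
    )
    return TimeCourseDataset(
        cell,
        frame,
        {"mode": "anchor", "seed": int(seed), "profile": _profile_dict(profile)},
    )


def generate_model_dataset(
    network: ReactionNetwork,
    params: ParameterSet,
    noise_cv: float = 0.10,
    n_rep: int = 3,
    seed: int = 0,
    grid_min: Sequence[float] = CANONICAL_GRID_MIN,
    init: np.ndarray | None = None,
    cell_line: str = "HEK-hERG1",
    readouts: Sequence[str] = FOLD_READOUTS,
) -> TimeCourseDataset:
    """Simulate the model and dress its fold observables in replicate noise.

    With ``noise_cv = 0`` the dataset mean equals the model observables
    exactly, which makes it the self-consistency oracle for the fitting
    cost.  ``init`` defaults to the seeded (FN-release) initial state.
    """
    if init is None:
        init = seeding_policy(network, params)
    traj = simulate(network, params, init, minutes_to_seconds(grid_min))
    obs = compute_observables(traj, normalize=True, readouts=list(readouts))
    rng = np.random.default_rng(seed)
    t = np.asarray(grid_min, dtype=float)
    rows = []
    cell = normalize_cell_line(cell_line)
    for readout in sorted(readouts):
        values = _with_noise(rng, obs[readout], noise_cv, n_rep)
        for rep in range(n_rep):
            for ti, v in zip(t, values[rep]):
                rows.append((cell, readout, ti, rep, v))
    frame = pd.DataFrame(
        rows, columns=["cell_line", "readout", "time_min", "replicate", "value"]
    )
    return TimeCourseDataset(
        cell,
        frame,
        {"mode": "model", "seed": int(seed), "noise_cv": noise_cv, "n_rep": n_rep},
    )
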