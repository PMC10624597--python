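"""The concrete hERG1/beta1-integrin network instance.

Sixteen species, twenty-four mass-action reactions: fibronectin (FN)
engagement activates beta1 integrins, which catalyze *herg1*
transcription; the channel is translated in the ER, glycosylated in the
Golgi, translocated to the surface, opens/closes, complexes with active
integrins (closed state only), and is internalized to endosomes from
which it either recycles or is degraded.  A balanced-inactivation module
(fast activator A, slow inhibitor I, both driven catalytically by the
hERG1/beta1 complex) produces the transient boost of translation and
trafficking; a separate internalization module (N) is inhibited by the
activator, so endocytosis dips while the pulse lasts.

The parameter-to-reaction mapping is a reconstruction: the network ships
as an editable JSON document so corrections are data edits, not code
edits.  Three reconstruction constants close gaps in the published
table: ``g_dose`` (gene-dosage unit carrier of the transcription law),
``N0`` (internalization-module pool size) and ``phi0`` (basal FN-site
availability fraction that makes the no-FN resting state nonzero).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .reaction_engine import (
    ParameterSet,
    Reaction,
    ReactionNetwork,
    pre_equilibrate,
)

__all__ = [
    "CELL_LINES",
    "RECONSTRUCTION_CONSTANTS",
    "INTERVENTIONS",
    "InterventionPreset",
    "default_network",
    "published_parameters",
    "load_parameter_table",
    "normalize_cell_line",
    "initial_state",
    "seeding_policy",
    "apply_intervention",
]

CELL_LINES = ("HEK-hERG1", "PANC-1", "HCT116")

#: Constants absent from the published table, added by this reconstruction.
#: name -> (value, units, rationale)
RECONSTRUCTION_CONSTANTS = {
    "g_dose": (1.0, "#/cell", "gene-dosage unit carrier for the transcription law"),
    "N0": (1.0e3, "#molecules", "internalization-module pool size"),
    "phi0": (0.25, "dimensionless", "basal FN-site availability fraction"),
    "k_dd": (1e-4, "s^-1", "direct degradation of the free closed surface channel"),
}


def normalize_cell_line(name: str) -> str:
    """Resolve common aliases ('HEK', unicode dashes, case) to a canonical name."""
    key = name.replace("–", "-").replace("—", "-").strip().lower()
    aliases = {
        "hek": "HEK-hERG1",
        "hek-herg1": "HEK-hERG1",
        "panc-1": "PANC-1",
        "panc1": "PANC-1",
        "hct116": "HCT116",
    }
    if key not in aliases:
        raise ValueError(f"unknown cell line {name!r}; expected one of {CELL_LINES}")
    return aliases[key]


def default_network(
    activator_inactivation: str = "cooperative",
    include_direct_degradation: bool = True,
) -> ReactionNetwork:
    """The bundled 16-species hERG1/beta1-integrin network.

    ``activator_inactivation`` selects the law of the activator
    inactivation step: ``"cooperative"`` (As * Is^2, matching the
    third-order units of its rate constant) or ``"ternary"``
    (As * Is * X).  ``include_direct_degradation`` keeps the first-order
    loss of the free closed surface channel (constant ``k_dd``); it can
    be dropped, but without any activator-independent membrane sink the
    basal steady state is unreachable on laboratory timescales.
    """
    with resources.files("hergcycle.data").joinpath("herg1_integrin_v1.json").open() as fh:
        import json

        net = ReactionNetwork.from_json_dict(json.load(fh))
    if activator_inactivation == "ternary":
        reactions = [
            Reaction(r.id, r.reactants, r.products, {"Is": 1.0, "X": 1.0},
                     r.rate_constant, r.scale_constants)
            if r.id == "r19_activator_inactivation" else r
            for r in net.reactions
        ]
        net = ReactionNetwork(net.species, reactions)
    elif activator_inactivation != "cooperative":
        raise ValueError(f"unknown activator_inactivation {activator_inactivation!r}")
    if not include_direct_degradation:
        net = ReactionNetwork(
            net.species,
            [r for r in net.reactions if r.id != "r25_direct_degradation"],
        )
    return net


def load_parameter_table() -> dict[str, dict[str, tuple[float, str, bool]]]:
    """Published best-fit table: cell line -> {name: (value, units, floating)}."""
    table: dict[str, dict[str, tuple[float, str, bool]]] = {c: {} for c in CELL_LINES}
    with resources.files("hergcycle.data").joinpath("params_table2.csv").open() as fh:
        for row in csv.DictReader(fh):
            for cell in CELL_LINES:
                table[cell][row["name"]] = (
                    float(row[cell]),
                    row["units"],
                    row["floating"] == "True",
                )
    return table


def published_parameters(cell_line: str) -> ParameterSet:
    """Best-fit parameter set for one cell line, plus reconstruction constants.

    Floating/fixed flags follow the published table: the open/close
    constants and the pool sizes are fixed, everything else floats.
    Reconstruction constants are always fixed.
    """
    cell = normalize_cell_line(cell_line)
    rows = load_parameter_table()[cell]
    values = {k: v for k, (v, _, _) in rows.items()}
    units = {k: u for k, (_, u, _) in rows.items()}
    mask = {k: f for k, (_, _, f) in rows.items()}
    for name, (v, u, _) in RECONSTRUCTION_CONSTANTS.items():
        values[name] = v
        units[name] = u
        mask[name] = False
    return ParameterSet(values, units, mask)


def _basal_start(network: ReactionNetwork, params: ParameterSet) -> np.ndarray:
    """Initial guess before basal equilibration: pools loaded, pathway empty.

    Only the basal fraction phi0 of the FN-site pool is available before
    seeding; the endosomal pool starts at its nominal size E0 and
    relaxes to the basal steady state.
    """
    x0 = np.zeros(network.n_species)
    ix = network.species_index
    x0[ix("B")] = params["B0"]
    x0[ix("F")] = params["phi0"] * params["F0"]
    x0[ix("A")] = params["A0"]
    x0[ix("I")] = params["I0"]
    x0[ix("N")] = params["N0"]
    x0[ix("E")] = params["E0"]
    return x0


def initial_state(
    params: ParameterSet,
    seeding: bool,
    network: ReactionNetwork | None = None,
    t_max: float = 1e7,
    tol: float = 1e-8,
) -> np.ndarray:
    """State at time zero.

    ``seeding=False``: the basal (BSA, no-FN) stationary state, obtained
    by pre-equilibration with only the fraction ``phi0`` of FN sites
    available.  ``seeding=True``: the same state with the withheld FN
    pool released instantaneously at t = 0 (all other species
    continuous), modeling the seeding protocol as an availability step.
    """
    net = network if network is not None else default_network()
    basal = pre_equilibrate(net, params, _basal_start(net, params), t_max=t_max, tol=tol)
    if seeding:
        basal = basal.copy()
        basal[net.species_index("F")] += (1.0 - params["phi0"]) * params["F0"]
    return basal


def seeding_policy(network: ReactionNetwork, params: ParameterSet) -> np.ndarray:
    """Init-policy hook used by the fitting and sensitivity modules.

    Always equilibrates the basal state from the unengaged start (pools
    loaded, signaling off): the basal fixed point is branch-dependent
    in the balanced-inactivation module, and the unengaged start is the
    physical definition of the resting culture.
    """
    return initial_state(params, seeding=True, network=network)


@dataclass(frozen=True)
class InterventionPreset:
    """A virtual perturbation: parameter overrides plus observable flags.

    ``overrides`` maps constant names to either ``("set", value)`` or
    ``("scale", factor)``.  ``blocked_observables`` names readouts whose
    interpretation is invalid under the preset (channel trapped open
    under the pore blocker).
    """

    name: str
    overrides: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    blocked_observables: tuple[str, ...] = ()


_ACTIVATOR_SILENCED = {
    "k_a": ("set", 0.0),
    "k_c_plus": ("set", 0.0),
    "k_g_plus": ("set", 0.0),
    "k_tg_plus": ("set", 0.0),
}

INTERVENTIONS = {
    "none": InterventionPreset("none"),
    # bivalent antibody blocking hERG1/beta1 complex formation
    "scDb": InterventionPreset("scDb", {"k_on": ("set", 0.0)}),
    # pertussis toxin: Gi-pathway block silences the activator branch
    "PTX": InterventionPreset("PTX", _ACTIVATOR_SILENCED),
    # GEF knockdown acts on the same coarse-grained activator branch
    "girdin_siRNA": InterventionPreset("girdin_siRNA", _ACTIVATOR_SILENCED),
    # pore blocker traps the channel open (integrin-incompetent state)
    "E4031": InterventionPreset(
        "E4031", {"k_o_minus": ("set", 0.0)}, blocked_observables=("open_channels",)
    ),
}


def apply_intervention(
    params: ParameterSet, preset: InterventionPreset | str
) -> ParameterSet:
    """Return a copy of ``params`` with the preset's overrides applied."""
    if isinstance(preset, str):
        try:
            preset = INTERVENTIONS[preset]
        except KeyError:
            raise ValueError(
                f"unknown intervention {preset!r}; expected one of {sorted(INTERVENTIONS)}"
            ) from None
    overrides = {}
    for name, (mode, v) in preset.overrides.items():
        if mode == "set":
            overrides[name] = v
        elif mode == "scale":
            overrides[name] = params[name] * v
        else:
            raise ValueError(f"unknown override mode {mode!r}")
    return params.with_values(overrides)
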