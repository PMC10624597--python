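"""Generic mass-action reaction-network engine.

Represents a biochemical network declaratively (species, reactions with
stoichiometry and catalytic modifiers), builds the mean-field ODE system
d x/dt = S f(x), integrates it with a stiff-capable solver, finds basal
steady states by long integration, and detects moiety conservation laws
as an integer basis of the left null space of the stoichiometric matrix.

Copy numbers are treated as continuous nonnegative reals (deterministic
mean-field interpretation); time is seconds internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy
from scipy.integrate import odeint

from ._kernels import jac_kernel, rhs_kernel, rk4_kernel

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "ParameterSet",
    "Trajectory",
    "ConservationLaw",
    "NetworkValidationError",
    "UnknownParameterError",
    "IntegrationError",
    "EquilibrationError",
    "build_rhs",
    "simulate",
    "simulate_rk4",
    "pre_equilibrate",
    "conserved_moieties",
    "validate_units",
    "minutes_to_seconds",
    "CANONICAL_GRID_MIN",
]

#: Canonical reporting grid (minutes): union of the assay time points.
CANONICAL_GRID_MIN = (0.0, 5.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0, 240.0, 300.0)

#: Kinetic order implied by a rate-constant unit string.
ORDER_BY_UNITS = {
    "s^-1": 1,
    "(#/cell)^-1 s^-1": 2,
    "(#/cell)^-2 s^-1": 3,
}


class NetworkValidationError(ValueError):
    """The network definition violates a structural invariant."""


class UnknownParameterError(KeyError):
    """A reaction references a rate constant absent from the parameter set."""


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced an inadmissible state."""


class EquilibrationError(RuntimeError):
    """Pre-equilibration did not reach the requested residual tolerance."""


def minutes_to_seconds(grid_min: Sequence[float]) -> np.ndarray:
    return np.asarray(grid_min, dtype=float) * 60.0


@dataclass(frozen=True)
class Species:
    """A molecular species/state, counted in molecules per cell."""

    name: str
    role: str = ""
    initial_default: float = 0.0

    def __post_init__(self):
        if self.initial_default < 0:
            raise NetworkValidationError(f"species {self.name!r}: negative initial count")


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.

    ``reactants``/``products`` map species names to nonnegative integer
    stoichiometries.  ``modifiers`` map species names to kinetic orders:
    catalysts that enter the rate law but are not consumed, so they do
    not contribute to the stoichiometric matrix.  ``scale_constants``
    name additional parameters that multiply the rate constant (unit
    carriers such as a gene-dosage factor).
    """

    id: str
    reactants: Mapping[str, int] = field(default_factory=dict)
    products: Mapping[str, int] = field(default_factory=dict)
    modifiers: Mapping[str, float] = field(default_factory=dict)
    rate_constant: str = ""
    scale_constants: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.reactants and not self.products:
            raise NetworkValidationError(f"reaction {self.id!r}: empty on both sides")
        for side in (self.reactants, self.products):
            for name, st in side.items():
                if int(st) != st or st < 0:
                    raise NetworkValidationError(
                        f"reaction {self.id!r}: stoichiometry of {name!r} must be a "
                        f"nonnegative integer, got {st}"
                    )
        if not self.rate_constant:
            raise NetworkValidationError(f"reaction {self.id!r}: missing rate constant name")

    @property
    def kinetic_order(self) -> float:
        """Total order of the rate law: reactant stoichiometries + modifier orders."""
        return float(sum(self.reactants.values()) + sum(self.modifiers.values()))


class ParameterSet:
    """Named nonnegative constants with units and a floating/fixed mask."""

    def __init__(
        self,
        values: Mapping[str, float],
        units: Mapping[str, str] | None = None,
        floating_mask: Mapping[str, bool] | None = None,
    ):
        self.values = {k: float(v) for k, v in values.items()}
        for k, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {k!r} must be finite and >= 0, got {v}")
        self.units = dict(units or {})
        self.floating_mask = {k: bool((floating_mask or {}).get(k, False)) for k in self.values}

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise UnknownParameterError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ParameterSet)
            and self.values == other.values
            and self.units == other.units
            and self.floating_mask == other.floating_mask
        )

    @property
    def floating_names(self) -> list[str]:
        return [k for k, v in self.floating_mask.items() if v]

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.values, self.units, self.floating_mask)

    def with_values(self, overrides: Mapping[str, float]) -> "ParameterSet":
        new = dict(self.values)
        for k, v in overrides.items():
            if k not in new:
                raise UnknownParameterError(k)
            new[k] = float(v)
        return ParameterSet(new, self.units, self.floating_mask)

    def to_dict(self) -> dict:
        return {
            "values": dict(self.values),
            "units": dict(self.units),
            "floating_mask": dict(self.floating_mask),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        return cls(d["values"], d.get("units"), d.get("floating_mask"))


@dataclass
class ConservationLaw:
    """Integer moiety weights lying in the left null space of S."""

    coefficients: dict[str, int]
    value: float | None = None

    def evaluate(self, state: np.ndarray, species_names: Sequence[str]) -> float:
        idx = {n: i for i, n in enumerate(species_names)}
        return float(sum(c * state[idx[n]] for n, c in self.coefficients.items()))


@dataclass
class Trajectory:
    """Time-indexed state matrix (molecules/cell per species)."""

    times: np.ndarray  # seconds, strictly increasing from 0
    states: np.ndarray  # shape (len(times), n_species)
    species_names: tuple[str, ...]

    @property
    def times_min(self) -> np.ndarray:
        return self.times / 60.0

    def species(self, name: str) -> np.ndarray:
        return self.states[:, self.species_names.index(name)]

    def at(self, t_seconds: float | np.ndarray) -> np.ndarray:
        """Linear interpolation between stored points (the sampling contract)."""
        t = np.atleast_1d(np.asarray(t_seconds, dtype=float))
        out = np.empty((t.size, self.states.shape[1]))
        for i in range(self.states.shape[1]):
            out[:, i] = np.interp(t, self.times, self.states[:, i])
        return out if np.ndim(t_seconds) else out[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            np.column_stack([self.times, self.states]),
            columns=["time_s", *self.species_names],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ReactionNetwork:
    """Declarative species + reactions list; single source of truth for the ODEs."""

    species: list[Species]
    reactions: list[Reaction]

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise NetworkValidationError("duplicate species names")
        known = set(names)
        for r in self.reactions:
            for n in (*r.reactants, *r.products, *r.modifiers):
                if n not in known:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} references unknown species {n!r}"
                    )
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise NetworkValidationError("duplicate reaction ids")

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def stoichiometric_matrix(self) -> np.ndarray:
        """S[i, j] = net production of species i by reaction j (modifiers excluded)."""
        idx = {n: i for i, n in enumerate(self.species_names)}
        S = np.zeros((self.n_species, len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for n, st in r.reactants.items():
                S[idx[n], j] -= st
            for n, st in r.products.items():
                S[idx[n], j] += st
        return S

    def default_initial_state(self) -> np.ndarray:
        return np.array([s.initial_default for s in self.species], dtype=float)

    # --- declarative round-trip -------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "species": [
                {"name": s.name, "role": s.role, "initial": s.initial_default}
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id,
                    "reactants": dict(r.reactants),
                    "products": dict(r.products),
                    "modifiers": dict(r.modifiers),
                    "rate_constant": r.rate_constant,
                    **({"scale_constants": list(r.scale_constants)} if r.scale_constants else {}),
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "ReactionNetwork":
        species = [
            Species(s["name"], s.get("role", ""), float(s.get("initial", 0.0)))
            for s in d["species"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                reactants={k: int(v) for k, v in r.get("reactants", {}).items()},
                products={k: int(v) for k, v in r.get("products", {}).items()},
                modifiers={k: float(v) for k, v in r.get("modifiers", {}).items()},
                rate_constant=r["rate_constant"],
                scale_constants=tuple(r.get("scale_constants", [])),
            )
            for r in d["reactions"]
        ]
        return cls(species, reactions)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ReactionNetwork":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


# --- compilation to flat arrays -------------------------------------------------


class _CompiledStructure:
    """Network topology flattened to index arrays (parameter-independent)."""

    def __init__(self, network: ReactionNetwork):
        idx = {n: i for i, n in enumerate(network.species_names)}
        t_ptr, t_sp, t_ord = [0], [], []
        s_ptr, s_sp, s_coef = [0], [], []
        for r in network.reactions:
            for n, st in sorted(r.reactants.items()):
                t_sp.append(idx[n])
                t_ord.append(float(st))
            for n, o in sorted(r.modifiers.items()):
                t_sp.append(idx[n])
                t_ord.append(float(o))
            t_ptr.append(len(t_sp))
            net = {}
            for n, st in r.reactants.items():
                net[n] = net.get(n, 0) - st
            for n, st in r.products.items():
                net[n] = net.get(n, 0) + st
            for n, c in sorted(net.items()):
                if c != 0:
                    s_sp.append(idx[n])
                    s_coef.append(float(c))
            s_ptr.append(len(s_sp))
        self.term_ptr = np.asarray(t_ptr, dtype=np.int64)
        self.term_species = np.asarray(t_sp, dtype=np.int64)
        self.term_order = np.asarray(t_ord, dtype=np.float64)
        self.stoich_ptr = np.asarray(s_ptr, dtype=np.int64)
        self.stoich_species = np.asarray(s_sp, dtype=np.int64)
        self.stoich_coef = np.asarray(s_coef, dtype=np.float64)
        self.n_species = network.n_species
        self.rate_names = [(r.rate_constant, r.scale_constants) for r in network.reactions]


def _structure(network: ReactionNetwork) -> _CompiledStructure:
    st = getattr(network, "_compiled_structure", None)
    if st is None:
        st = _CompiledStructure(network)
        object.__setattr__(network, "_compiled_structure", st)
    return st


def _rate_vector(struct: _CompiledStructure, params: ParameterSet) -> np.ndarray:
    k = np.empty(len(struct.rate_names))
    for j, (name, scales) in enumerate(struct.rate_names):
        v = params[name]
        for s in scales:
            v *= params[s]
        k[j] = v
    return k


class CompiledModel:
    """A network bound to a concrete rate-constant vector."""

    def __init__(self, network: ReactionNetwork, params: ParameterSet):
        self.network = network
        self.struct = _structure(network)
        self.k = _rate_vector(self.struct, params)
        n = self.struct.n_species
        self._dy = np.empty(n)
        self._J = np.empty((n, n))

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        s = self.struct
        return rhs_kernel(y, self.k, s.term_ptr, s.term_species, s.term_order,
                          s.stoich_ptr, s.stoich_species, s.stoich_coef, self._dy)

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        s = self.struct
        return jac_kernel(y, self.k, s.term_ptr, s.term_species, s.term_order,
                          s.stoich_ptr, s.stoich_species, s.stoich_coef, self._J)


def build_rhs(
    network: ReactionNetwork,
    params: ParameterSet,
    strict_units: bool = False,
) -> Callable[[np.ndarray, float], np.ndarray]:
    """Return the derivative function f(state, time) -> d state/dt.

    Each reaction j contributes flux_j = k_j * prod(reactants**stoich)
    * prod(modifiers**order); the derivative is S @ flux.  With
    ``strict_units`` any unit/order inconsistency raises instead of
    being merely reported by :func:`validate_units`.
    """
    for r in network.reactions:
        params[r.rate_constant]  # raises UnknownParameterError if unresolved
        for s in r.scale_constants:
            params[s]
    if strict_units:
        findings = validate_units(network, params)
        if findings:
            raise NetworkValidationError("; ".join(findings))
    model = CompiledModel(network, params)

    def rhs(state: np.ndarray, time: float = 0.0) -> np.ndarray:
        return model.rhs(time, np.asarray(state, dtype=float)).copy()

    return rhs


# --- simulation -----------------------------------------------------------------


def simulate(
    network: ReactionNetwork,
    params: ParameterSet,
    init: np.ndarray,
    t_grid: Sequence[float],
    rtol: float = 1e-6,
    atol: float = 1e-3,
    mxstep: int = 100_000,
) -> Trajectory:
    """Integrate the network ODEs on ``t_grid`` (seconds, starting at 0).

    Uses LSODA (automatic stiff/non-stiff switching with an analytic
    Jacobian); required because the rate constants span many orders of
    magnitude.  States more negative than the solver error weight are an
    error; smaller excursions are clipped to zero.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 1 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")
    y0 = np.asarray(init, dtype=float)
    if y0.shape != (network.n_species,) or not np.all(np.isfinite(y0)) or np.any(y0 < 0):
        raise ValueError("init must be finite, nonnegative, one value per species")
    if t.size == 1:
        return Trajectory(t.copy(), y0[None, :].copy(), network.species_names)

    model = CompiledModel(network, params)
    states, info = odeint(
        model.rhs,
        y0,
        t,
        Dfun=model.jac,
        rtol=rtol,
        atol=atol,
        tfirst=True,
        full_output=True,
        mxstep=mxstep,
    )
    if info["message"] != "Integration successful.":
        t_fail = float(info.get("tcur", [np.nan])[-1])
        raise IntegrationError(f"LSODA failed near t = {t_fail:.6g} s: {info['message']}")
    # solver error weight: atol + rtol * |y|, the admissible negative excursion
    eps = atol + rtol * np.abs(states)
    if np.any(states < -eps):
        i, j = np.unravel_index(np.argmin(states + eps), states.shape)
        raise IntegrationError(
            f"state {network.species_names[j]!r} reached {states[i, j]:.6g} "
            f"(beyond solver tolerance) at t = {t[i]:.6g} s"
        )
    states = np.where(states < 0.0, 0.0, states)
    return Trajectory(t.copy(), states, network.species_names)


def simulate_rk4(
    network: ReactionNetwork,
    params: ParameterSet,
    init: np.ndarray,
    t_end: float,
    dt: float,
    n_samples: int = 61,
) -> Trajectory:
    """Fixed-step explicit RK4 reference integrator (oracle use only).

    Feasible only on short horizons; exists so the stiff production
    solver can be cross-checked against an independent scheme.
    """
    struct = _structure(network)
    k = _rate_vector(struct, params)
    n_steps = int(round(t_end / dt))
    sample_every = max(1, n_steps // (n_samples - 1))
    n_steps = sample_every * (n_samples - 1)
    samples = np.empty((n_samples, network.n_species))
    rk4_kernel(
        np.asarray(init, dtype=float), k,
        struct.term_ptr, struct.term_species, struct.term_order,
        struct.stoich_ptr, struct.stoich_species, struct.stoich_coef,
        float(dt), n_steps, sample_every, samples,
    )
    times = np.arange(n_samples) * (sample_every * dt)
    return Trajectory(times, samples, network.species_names)


def pre_equilibrate(
    network: ReactionNetwork,
    params: ParameterSet,
    init: np.ndarray | None = None,
    overrides: Mapping[str, float] | None = None,
    t_max: float = 1e7,
    tol: float = 1e-8,
    rtol: float = 1e-6,
    atol: float = 1e-3,
) -> np.ndarray:
    """Relax to a stationary state by long integration.

    Returns x* with ||RHS(x*)|| / max(||x*||, 1) < tol (units 1/s) — the
    first checkpoint state meeting the tolerance, integrating as far as
    ``t_max``.  ``overrides`` lets a basal condition (e.g., withheld
    ligand) replace selected constants during equilibration.  Only the
    endpoint matters here, so the integration tolerances are looser
    than the trajectory defaults; the residual check is the accuracy
    guarantee.
    """
    p = params.with_values(overrides) if overrides else params
    y = network.default_initial_state() if init is None else np.asarray(init, dtype=float)
    model = CompiledModel(network, p)

    def residual(x):
        return float(np.linalg.norm(model.rhs(0.0, x))) / max(float(np.linalg.norm(x)), 1.0)

    if residual(y) < tol:
        return y.copy()
    checkpoints = [t for t in (1e4, 1e5, 1e6, 1e7, 1e8) if t < t_max * 0.999]
    checkpoints.append(t_max)
    try:
        states = simulate(network, p, y, [0.0, *checkpoints],
                          rtol=rtol, atol=atol).states[1:]
    except IntegrationError:
        # LSODA occasionally stalls on long spans near huge steady
        # states; scipy's BDF is the robust fallback
        from scipy.integrate import solve_ivp

        states = []
        t_prev = 0.0
        for t_stage in checkpoints:
            sol = solve_ivp(model.rhs, (0.0, t_stage - t_prev), y, method="BDF",
                            jac=model.jac, rtol=rtol, atol=atol)
            if not sol.success:
                raise EquilibrationError(
                    f"equilibration stage to t = {t_stage:.3g} s failed: {sol.message}"
                ) from None
            y = np.maximum(sol.y[:, -1], 0.0)
            states.append(y)
            t_prev = t_stage
    for x in states:
        if residual(x) < tol:
            return np.maximum(x, 0.0)
    raise EquilibrationError(
        f"residual {residual(states[-1]):.3g} /s above tol {tol:.3g} after "
        f"t = {t_max:.3g} s (unbounded accumulation?)"
    )


# --- structural analysis --------------------------------------------------------


def conserved_moieties(network: ReactionNetwork) -> list[ConservationLaw]:
    """Integer basis of the left null space of the stoichiometric matrix.

    Computed by exact rational elimination (sympy) and scaled to
    primitive integer vectors; modifiers do not contribute.  Returns an
    empty list for full-row-rank networks.
    """
    S = sympy.Matrix(network.stoichiometric_matrix().astype(int))
    basis = S.T.nullspace()
    names = network.species_names
    laws = []
    for vec in basis:
        denoms = [sympy.fraction(sympy.nsimplify(v))[1] for v in vec]
        scale = sympy.lcm([d for d in denoms] or [1])
        ints = [int(v * scale) for v in vec]
        g = int(sympy.gcd([abs(i) for i in ints if i != 0] or [1]))
        ints = [i // g for i in ints]
        if sum(i for i in ints if i != 0) < 0:
            ints = [-i for i in ints]
        laws.append(ConservationLaw({names[i]: c for i, c in enumerate(ints) if c != 0}))
    laws.sort(key=lambda l: sorted(l.coefficients))
    return laws


def validate_units(network: ReactionNetwork, params: ParameterSet) -> list[str]:
    """Check declared kinetic orders against rate-constant units.

    Returns one finding string per inconsistency (empty list if all
    consistent).  A reaction whose rate constant has no recognized unit
    string is also reported.  Reactions with scale constants are
    annotated, since the scale may be the intended unit carrier.
    """
    findings = []
    for r in network.reactions:
        units = params.units.get(r.rate_constant)
        if units is None:
            findings.append(f"reaction {r.id!r}: constant {r.rate_constant!r} has no units")
            continue
        implied = ORDER_BY_UNITS.get(units)
        if implied is None:
            findings.append(
                f"reaction {r.id!r}: constant {r.rate_constant!r} has unrecognized "
                f"units {units!r}"
            )
            continue
        declared = r.kinetic_order
        if declared != implied:
            note = ""
            if r.scale_constants:
                note = (
                    f" (scale constant(s) {', '.join(r.scale_constants)} may carry "
                    "the missing concentration unit)"
                )
            findings.append(
                f"reaction {r.id!r}: constant {r.rate_constant!r} units {units!r} imply "
                f"order {implied} but the declared rate law has order {declared:g}{note}"
            )
    return findings
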