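"""Mechanistic models of the MEK-ERK (de)phosphorylation module.

The default mechanism is distributive: the kinase (active MEK, ``M``) binds
ERK twice to phosphorylate its two sites successively, and the phosphatase
(``P``) likewise removes the two phosphates in two binding events.  A
processive variant (one binding event per double (de)phosphorylation) is
provided for model comparison.

Active MEK is produced by a time-dependent upstream input ``u(t)`` (a pulse
of intensity ``k1`` for ``t < T_pulse`` followed by a sustained background
``k10``) and degraded at rate ``k2``.  Concentrations are in arbitrary
intensity-equivalent units; times are in minutes.
"""

from __future__ import annotations

import math
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
from scipy.integrate import odeint

from .kernels import ode_rhs, ode_jac, rk45_states

__all__ = [
    "Reaction",
    "ModelSpec",
    "ParamVector",
    "Trajectory",
    "SolverError",
    "build_distributive_model",
    "build_processive_model",
    "upstream_input",
    "initial_state",
    "solve_ode",
    "observables",
]

#: Name of the pseudo rate parameter marking the upstream input reaction.
INPUT = "__input__"


class SolverError(RuntimeError):
    """ODE integration failure; carries the offending parameter vector."""

    def __init__(self, message: str, theta: "ParamVector | None" = None):
        super().__init__(message)
        self.theta = theta


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``rate_param`` is the name of the rate constant, or :data:`INPUT` for
    the zeroth-order upstream-input reaction whose rate is ``u(t)``.
    """

    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_param: str


@dataclass(frozen=True)
class ModelSpec:
    """Reaction network specification (species, stoichiometry, propensities)."""

    name: str
    species_names: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    rate_param_names: tuple[str, ...]  # cycle (mass-action) rate constants
    param_names: tuple[str, ...]  # full free-parameter ordering
    # species summed into each observable (total ppMEK, total ppERK)
    ppmek_species: tuple[str, ...] = ()
    pperk_species: tuple[str, ...] = ()

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @cached_property
    def stoich(self) -> np.ndarray:
        """Integer stoichiometry matrix, species x reactions."""
        idx = {s: i for i, s in enumerate(self.species_names)}
        S = np.zeros((self.n_species, self.n_reactions), dtype=np.int64)
        for r, rxn in enumerate(self.reactions):
            for sp in rxn.reactants:
                S[idx[sp], r] -= 1
            for sp in rxn.products:
                S[idx[sp], r] += 1
        return S

    @cached_property
    def observable_matrix(self) -> np.ndarray:
        """2 x n_species projection onto (ppMEK_total, ppERK_total)."""
        idx = {s: i for i, s in enumerate(self.species_names)}
        L = np.zeros((2, self.n_species))
        for sp in self.ppmek_species:
            L[0, idx[sp]] = 1.0
        for sp in self.pperk_species:
            L[1, idx[sp]] = 1.0
        return L

    @cached_property
    def _solver_arrays(self):
        """Cached (S_float, r1, r2, input_idx) for the compiled kernels."""
        r1, r2, input_idx = self.reactant_indices()
        return self.stoich.astype(np.float64), r1, r2, input_idx

    def reactant_indices(self) -> tuple[np.ndarray, np.ndarray, int]:
        """Per-reaction reactant slots (-1 = absent) and input-reaction index."""
        idx = {s: i for i, s in enumerate(self.species_names)}
        r1 = np.full(self.n_reactions, -1, dtype=np.int64)
        r2 = np.full(self.n_reactions, -1, dtype=np.int64)
        input_idx = -1
        for r, rxn in enumerate(self.reactions):
            if rxn.rate_param == INPUT:
                input_idx = r
                continue
            if len(rxn.reactants) > 2:
                raise ValueError(f"reaction {rxn.name}: > bimolecular not supported")
            if len(rxn.reactants) >= 1:
                r1[r] = idx[rxn.reactants[0]]
            if len(rxn.reactants) == 2:
                r2[r] = idx[rxn.reactants[1]]
        return r1, r2, input_idx

    def rate_array(self, theta: "ParamVector") -> np.ndarray:
        """Per-reaction rate constants (input reaction slot set to 0)."""
        rates = np.zeros(self.n_reactions)
        for r, rxn in enumerate(self.reactions):
            if rxn.rate_param != INPUT:
                rates[r] = theta[rxn.rate_param]
        return rates

    def to_config(self) -> dict:
        """Round-trippable plain-dict description of the network."""
        return {
            "name": self.name,
            "species": list(self.species_names),
            "parameters": list(self.param_names),
            "rate_parameters": list(self.rate_param_names),
            "ppmek_species": list(self.ppmek_species),
            "pperk_species": list(self.pperk_species),
            "reactions": [
                {
                    "name": r.name,
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "rate_param": r.rate_param,
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "ModelSpec":
        return cls(
            name=cfg["name"],
            species_names=tuple(cfg["species"]),
            reactions=tuple(
                Reaction(
                    name=r["name"],
                    reactants=tuple(r["reactants"]),
                    products=tuple(r["products"]),
                    rate_param=r["rate_param"],
                )
                for r in cfg["reactions"]
            ),
            rate_param_names=tuple(cfg["rate_parameters"]),
            param_names=tuple(cfg["parameters"]),
            ppmek_species=tuple(cfg["ppmek_species"]),
            pperk_species=tuple(cfg["pperk_species"]),
        )


# parameters shared by both mechanisms: upstream input + initial conditions
_UPSTREAM_PARAMS = ("k1", "k2", "k10", "T_pulse")
_IC_PARAMS = ("E_tot", "P_tot", "M0", "Epp0")
# structural parameters that must be strictly positive; rate-like entries may
# be zero (a zero rate simply disables the reaction, e.g. decoupled subsystems)
_STRICTLY_POSITIVE = frozenset({"T_pulse", "E_tot", "P_tot"})


class ParamVector(Mapping[str, float]):
    """One cell's parameter values, keyed by a model's parameter names.

    Rate-like entries must be nonnegative (zero disables a reaction);
    ``T_pulse``, ``E_tot`` and ``P_tot`` must be strictly positive, and
    ``Epp0`` may not exceed ``E_tot``.
    """

    __slots__ = ("_names", "_values")

    def __init__(self, model: ModelSpec | Sequence[str], values: Mapping[str, float]):
        names = model.param_names if isinstance(model, ModelSpec) else tuple(model)
        missing = [n for n in names if n not in values]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        self._names = names
        self._values = {n: float(values[n]) for n in names}
        self._validate()

    def _validate(self) -> None:
        for n, v in self._values.items():
            if not math.isfinite(v):
                raise ValueError(f"parameter {n} is not finite: {v}")
            if n in _STRICTLY_POSITIVE:
                if v <= 0:
                    raise ValueError(f"parameter {n} must be > 0, got {v}")
            elif v < 0:
                raise ValueError(f"parameter {n} must be >= 0, got {v}")
        if "Epp0" in self._values and "E_tot" in self._values:
            if self._values["Epp0"] > self._values["E_tot"]:
                raise ValueError(
                    f"Epp0 ({self._values['Epp0']}) exceeds E_tot "
                    f"({self._values['E_tot']})"
                )

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._names)

    def __len__(self) -> int:
        return len(self._names)

    def as_array(self) -> np.ndarray:
        return np.array([self._values[n] for n in self._names])

    def replace(self, **updates: float) -> "ParamVector":
        vals = dict(self._values)
        vals.update(updates)
        return ParamVector(self._names, vals)

    def __repr__(self) -> str:  # pragma: no cover
        body = ", ".join(f"{n}={v:.4g}" for n, v in self._values.items())
        return f"ParamVector({body})"


@dataclass
class Trajectory:
    """Deterministic solution: times (min), per-time states and observables."""

    model: ModelSpec
    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    observables: np.ndarray = field(init=False)  # (n_times, 2)

    def __post_init__(self) -> None:
        self.observables = self.states @ self.model.observable_matrix.T

    @property
    def ppmek(self) -> np.ndarray:
        return self.observables[:, 0]

    @property
    def pperk(self) -> np.ndarray:
        return self.observables[:, 1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(self.model.species_names))
        df.insert(0, "time_min", self.times)
        df["ppMEK_total"] = self.ppmek
        df["ppERK_total"] = self.pperk
        return df


def build_distributive_model() -> ModelSpec:
    """Two-step (distributive) kinase and phosphatase mechanism.

    9 species, 14 reactions, 12 cycle rate constants; 20 free parameters in
    total once the 4 upstream-input and 4 initial-condition parameters are
    included.
    """
    rxns = [
        Reaction("input", (), ("M",), INPUT),
        Reaction("degradation", ("M",), (), "k2"),
    ]
    # kinase step 1: M + E <-> C1 -> M + Ep
    rxns += [
        Reaction("bind1", ("M", "E"), ("C1",), "a1"),
        Reaction("unbind1", ("C1",), ("M", "E"), "d1"),
        Reaction("cat1", ("C1",), ("M", "Ep"), "c1"),
    ]
    # kinase step 2: M + Ep <-> C2 -> M + Epp
    rxns += [
        Reaction("bind2", ("M", "Ep"), ("C2",), "a2"),
        Reaction("unbind2", ("C2",), ("M", "Ep"), "d2"),
        Reaction("cat2", ("C2",), ("M", "Epp"), "c2"),
    ]
    # phosphatase step 1: P + Epp <-> C3 -> P + Ep
    rxns += [
        Reaction("bind3", ("P", "Epp"), ("C3",), "a3"),
        Reaction("unbind3", ("C3",), ("P", "Epp"), "d3"),
        Reaction("cat3", ("C3",), ("P", "Ep"), "c3"),
    ]
    # phosphatase step 2: P + Ep <-> C4 -> P + E
    rxns += [
        Reaction("bind4", ("P", "Ep"), ("C4",), "a4"),
        Reaction("unbind4", ("C4",), ("P", "Ep"), "d4"),
        Reaction("cat4", ("C4",), ("P", "E"), "c4"),
    ]
    rates = ("a1", "d1", "c1", "a2", "d2", "c2", "a3", "d3", "c3", "a4", "d4", "c4")
    return ModelSpec(
        name="distributive",
        species_names=("M", "E", "Ep", "Epp", "P", "C1", "C2", "C3", "C4"),
        reactions=tuple(rxns),
        rate_param_names=rates,
        param_names=rates + _UPSTREAM_PARAMS + _IC_PARAMS,
        ppmek_species=("M", "C1", "C2"),
        pperk_species=("Epp", "C3"),
    )


def build_processive_model() -> ModelSpec:
    """Single-binding-event (processive) variant used for model comparison."""
    rxns = [
        Reaction("input", (), ("M",), INPUT),
        Reaction("degradation", ("M",), (), "k2"),
        Reaction("bind1", ("M", "E"), ("C1",), "a1"),
        Reaction("unbind1", ("C1",), ("M", "E"), "d1"),
        Reaction("cat1", ("C1",), ("M", "Epp"), "c1"),
        Reaction("bind3", ("P", "Epp"), ("C3",), "a3"),
        Reaction("unbind3", ("C3",), ("P", "Epp"), "d3"),
        Reaction("cat3", ("C3",), ("P", "E"), "c3"),
    ]
    rates = ("a1", "d1", "c1", "a3", "d3", "c3")
    return ModelSpec(
        name="processive",
        species_names=("M", "E", "Epp", "P", "C1", "C3"),
        reactions=tuple(rxns),
        rate_param_names=rates,
        param_names=rates + _UPSTREAM_PARAMS + _IC_PARAMS,
        ppmek_species=("M", "C1"),
        pperk_species=("Epp", "C3"),
    )


def upstream_input(
    t: float,
    k1: float,
    k10: float,
    T_pulse: float,
    shape: str = "step",
) -> float:
    """Upstream MEK-activation rate u(t).

    ``shape='step'`` (default): u = k1 on [0, T_pulse), k10 afterwards
    (half-open at T_pulse).  ``shape='smooth'``: exponential relaxation
    from k1 to k10 with timescale T_pulse.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if shape == "step":
        return k1 if t < T_pulse else k10
    if shape == "smooth":
        return k10 + (k1 - k10) * math.exp(-t / T_pulse)
    raise ValueError(f"unknown input shape {shape!r}")


def initial_state(model: ModelSpec, theta: ParamVector) -> np.ndarray:
    """State vector at t=0: M=M0, Epp=Epp0, E=E_tot-Epp0, P=P_tot, rest 0."""
    if theta["Epp0"] > theta["E_tot"]:
        raise ValueError("Epp0 exceeds E_tot")
    x0 = np.zeros(model.n_species)
    idx = {s: i for i, s in enumerate(model.species_names)}
    x0[idx["M"]] = theta["M0"]
    x0[idx["Epp"]] = theta["Epp0"]
    x0[idx["E"]] = theta["E_tot"] - theta["Epp0"]
    x0[idx["P"]] = theta["P_tot"]
    return x0


def observables(model: ModelSpec, state: np.ndarray) -> tuple[float, float]:
    """(ppMEK_total, ppERK_total): free plus complex-bound active forms."""
    out = model.observable_matrix @ np.asarray(state, dtype=float)
    return float(out[0]), float(out[1])


def _segments(times: np.ndarray, T_pulse: float) -> list[tuple[float, float]]:
    """Integration segments split at the input discontinuity."""
    t_end = float(times[-1])
    if T_pulse >= t_end:
        return [(0.0, t_end)]
    return [(0.0, float(T_pulse)), (float(T_pulse), t_end)]


def solve_ode(
    model: ModelSpec,
    theta: ParamVector,
    times: Sequence[float] | np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    input_shape: str = "step",
) -> Trajectory:
    """Deterministic macroscopic trajectory on the requested time grid.

    Integrates with LSODA (stiff-capable), splitting at the pulse end so the
    step input's discontinuity never sits inside a solver step.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be ascending and start at 0")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be > 0")

    states = _integrate_states(model, theta, times, rtol, atol, input_shape)
    return Trajectory(model=model, times=times, states=states)


def _integrate_states(
    model: ModelSpec,
    theta: ParamVector,
    times: np.ndarray,
    rtol: float,
    atol: float,
    input_shape: str = "step",
    method: str = "auto",
) -> np.ndarray:
    S, r1, r2, input_idx = model._solver_arrays
    rates = model.rate_array(theta)
    if input_shape == "step" and method in ("auto", "rk45"):
        ok, out = rk45_states(
            initial_state(model, theta), times, S, rates, r1, r2, input_idx,
            theta["k1"], theta["k10"], theta["T_pulse"], rtol, atol,
        )
        if ok and np.all(np.isfinite(out)):
            return out
        if method == "rk45":
            raise SolverError("RK45 integration failed", theta)
        # fall through to the stiff-capable LSODA path
    k1, k10, T = theta["k1"], theta["k10"], theta["T_pulse"]
    x0 = initial_state(model, theta)

    if input_shape == "smooth":
        # single segment; pass smooth-input parameters through
        return _odeint_segment(
            x0, times, S, rates, r1, r2, input_idx, k1, k10, T, True, rtol, atol, theta
        )
    if input_shape != "step":
        raise ValueError(f"unknown input shape {input_shape!r}")

    out = np.empty((times.size, model.n_species))
    pos = 0
    x = x0
    t_end = float(times[-1])
    for seg_start, seg_end in _segments(times, theta["T_pulse"]):
        in_pulse = seg_start < T
        u = k1 if in_pulse else k10
        mask = (times >= seg_start) & (times <= seg_end)
        if seg_end < t_end:  # exclude boundary from first segment output here?
            mask = (times >= seg_start) & (times < seg_end)
        seg_times = times[mask]
        grid = np.concatenate(([seg_start], seg_times, [seg_end]))
        # de-duplicate while keeping positions of requested outputs
        uniq, inv = np.unique(grid, return_inverse=True)
        ys = _odeint_segment(
            x, uniq, S, rates, r1, r2, input_idx, u, u, np.inf, False, rtol, atol, theta
        )
        if seg_times.size:
            out[pos : pos + seg_times.size] = ys[inv[1 : 1 + seg_times.size]]
            pos += seg_times.size
        x = ys[-1]
    assert pos == times.size
    return out


def _odeint_segment(
    x0: np.ndarray,
    grid: np.ndarray,
    S: np.ndarray,
    rates: np.ndarray,
    r1: np.ndarray,
    r2: np.ndarray,
    input_idx: int,
    k1: float,
    k10: float,
    T: float,
    smooth: bool,
    rtol: float,
    atol: float,
    theta: ParamVector,
) -> np.ndarray:
    t0 = grid[0]
    # odeint wants the grid to start at the initial time
    ys, info = odeint(
        ode_rhs,
        x0,
        grid,
        args=(S, rates, r1, r2, input_idx, k1, k10, T, smooth, t0),
        Dfun=ode_jac,
        rtol=rtol,
        atol=atol,
        full_output=True,
        mxstep=50_000,
    )
    if info["message"] != "Integration successful.":
        raise SolverError(f"ODE integration failed: {info['message']}", theta)
    if not np.all(np.isfinite(ys)):
        raise SolverError("ODE integration produced non-finite values", theta)
    return ys
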