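"""Mass-action kinetic models of protein translation.

Two models of the translation machinery are defined here:

* a **linear** three-species catalytic cycle
  ``40S -> mRNA:40S -> AUG -> 40S`` (rates ``k1, k2, k3``), in which the
  free small ribosomal subunit binds the mRNA initiation site, scans to
  the start codon, and is released after elongation/termination while a
  protein is produced; and

* a **non-linear** six-species model that additionally tracks the
  recycling of the large ribosomal subunit (60S) and of a lumped
  initiation factor (eIF4F)::

      R1: 40S + eIF4F -> mRNA:40S        (rate k1, second order)
      R2: mRNA:40S    -> AUG + eIF4F     (rate k2)
      R3: AUG + 60S   -> 80S             (rate k3, second order)
      R4: 80S         -> 40S + 60S       (rate k4, + one protein)

Both are closed systems (no synthesis or degradation of mRNA, microRNA
or ribosomal components), so the vector fields carry exact linear
conservation laws which the integrator monitors at every output sample.

Concentrations and rate constants are in relative, unitless model units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence
from xml.etree import ElementTree as ET

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DomainError",
    "IntegrationError",
    "UnsupportedModelError",
    "LinearParams",
    "NonlinearParams",
    "LinearState",
    "NonlinearState",
    "Derivative",
    "Trajectory",
    "LINEAR_SPECIES",
    "NONLINEAR_SPECIES",
    "linear_rhs",
    "nonlinear_rhs",
    "integrate",
    "export_sbml",
    "import_sbml",
]

# ---------------------------------------------------------------------------
# configuration defaults (shared across modules)
# ---------------------------------------------------------------------------

#: Default multiplicative separation factor implementing the ">>" / "<<"
#: convention: "much bigger" means bigger by at least one order of magnitude.
SEPARATION_FACTOR = 10.0

#: Default integration tolerances.
RTOL = 1e-8
ATOL = 1e-10

#: Relative conservation-residual budget for accepted trajectories.
CONSERVATION_RTOL = 1e-6

#: Concentrations produced by the integrator may undershoot zero by at most
#: this amount before the trajectory is rejected.
NEGATIVITY_FLOOR = -1e-9

LINEAR_SPECIES = ("c40S", "c_mRNA40S", "cAUG")
NONLINEAR_SPECIES = ("c40S", "c60S", "c_eIF4F", "c_mRNA40S", "cAUG", "c80S")


class DomainError(ValueError):
    """Invalid state or parameter values (negative concentrations/rates)."""


class IntegrationError(RuntimeError):
    """Numerical integration failed or violated its accuracy contract."""


class UnsupportedModelError(ValueError):
    """SBML import encountered a model outside the supported mass-action forms."""


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0 and math.isfinite(value)):
            raise DomainError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class LinearParams:
    """Rate constants and conserved 40S pool of the linear cycle model.

    ``k1``: initiation-complex assembly; ``k2``: late, cap-independent
    initiation steps (start-codon scanning, 60S joining); ``k3``: combined
    elongation/termination with release of the subunit.  All first order,
    units 1/time.  ``total_40S`` is the conserved total amount of the small
    ribosomal subunit.
    """

    k1: float
    k2: float
    k3: float
    total_40S: float = 100.0

    def __post_init__(self) -> None:
        _require_positive(k1=self.k1, k2=self.k2, k3=self.k3, total_40S=self.total_40S)

    @property
    def rates(self) -> tuple[float, float, float]:
        return (self.k1, self.k2, self.k3)

    def free_init(self) -> np.ndarray:
        """Default initial condition: the whole 40S pool free, no complexes."""
        return np.array([self.total_40S, 0.0, 0.0])

    def elongation_separation(self) -> float:
        """How much faster elongation (k3) is than the initiation steps."""
        return self.k3 / max(self.k1, self.k2)

    def replace(self, **changes: float) -> "LinearParams":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class NonlinearParams:
    """Rate constants and conserved pools of the recycling (non-linear) model.

    ``k1`` and ``k3`` are second-order (1/(conc·time)); ``k2`` and ``k4``
    first-order (1/time).  The three totals are the conserved pools of the
    small subunit, large subunit and initiation factor respectively.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    total_40S: float = 100.0
    total_60S: float = 25.0
    total_eIF4F: float = 6.0

    def __post_init__(self) -> None:
        _require_positive(
            k1=self.k1,
            k2=self.k2,
            k3=self.k3,
            k4=self.k4,
            total_40S=self.total_40S,
            total_60S=self.total_60S,
            total_eIF4F=self.total_eIF4F,
        )

    def free_init(self) -> np.ndarray:
        """Default initial condition: all pools free, all complexes empty."""
        return np.array(
            [self.total_40S, self.total_60S, self.total_eIF4F, 0.0, 0.0, 0.0]
        )

    def totals(self) -> tuple[float, float, float]:
        return (self.total_40S, self.total_60S, self.total_eIF4F)

    def ordering_report(self, factor: float = SEPARATION_FACTOR) -> dict[str, bool]:
        """Check the standing assumptions on the parameter ordering.

        The model analysis assumes a particular hierarchy: the 40S pool is
        abundant relative to the initiation factor, the 60S pool sits in
        between, elongation (R3) is fast on the scale of the initiation
        steps, and ribosome recycling (k4) is the slowest first-order rate.
        ``factor`` implements the "much bigger" convention (default one
        order of magnitude).
        """
        return {
            "40S_abundant_vs_eIF4F": self.total_40S >= factor * self.total_eIF4F,
            "60S_between_pools": self.total_eIF4F < self.total_60S < self.total_40S,
            "elongation_fast": self.k3 * self.total_60S
            >= factor * max(self.k2, self.k4),
            "recycling_slowest": self.k4 <= min(self.k2, self.k1 * self.total_eIF4F),
        }

    def ordering_satisfied(self, factor: float = SEPARATION_FACTOR) -> bool:
        return all(self.ordering_report(factor).values())

    def replace(self, **changes: float) -> "NonlinearParams":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


# ---------------------------------------------------------------------------
# state records
# ---------------------------------------------------------------------------


def _check_nonnegative(values: np.ndarray, names: Sequence[str]) -> None:
    for name, value in zip(names, values):
        if value < 0:
            raise DomainError(f"concentration {name} is negative: {value!r}")


@dataclass(frozen=True)
class LinearState:
    c40S: float
    c_mRNA40S: float
    cAUG: float

    def to_array(self) -> np.ndarray:
        return np.array([self.c40S, self.c_mRNA40S, self.cAUG])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "LinearState":
        return cls(*map(float, arr))

    def conservation_residual(self, p: LinearParams) -> float:
        return abs(self.c40S + self.c_mRNA40S + self.cAUG - p.total_40S)


@dataclass(frozen=True)
class NonlinearState:
    c40S: float
    c60S: float
    c_eIF4F: float
    c_mRNA40S: float
    cAUG: float
    c80S: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.c40S, self.c60S, self.c_eIF4F, self.c_mRNA40S, self.cAUG, self.c80S]
        )

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "NonlinearState":
        return cls(*map(float, arr))

    def conservation_residuals(self, p: NonlinearParams) -> tuple[float, float, float]:
        """Absolute residuals of the three conservation laws.

        (1) 40S + mRNA:40S + AUG + 80S = [40S]0 — every form of the small
        subunit; (2) eIF4F + mRNA:40S = [eIF4F]0 — the factor is bound only
        in the initiation complex; (3) 60S + 80S = [60S]0.
        """
        r40 = self.c40S + self.c_mRNA40S + self.cAUG + self.c80S - p.total_40S
        reif = self.c_eIF4F + self.c_mRNA40S - p.total_eIF4F
        r60 = self.c60S + self.c80S - p.total_60S
        return (abs(r40), abs(reif), abs(r60))


class Derivative(NamedTuple):
    """Time derivative of a state together with the per-reaction fluxes."""

    dstate: np.ndarray
    fluxes: np.ndarray


# ---------------------------------------------------------------------------
# vector fields
# ---------------------------------------------------------------------------


def _linear_fluxes(y: np.ndarray, p: LinearParams) -> np.ndarray:
    return np.array([p.k1 * y[0], p.k2 * y[1], p.k3 * y[2]])


def _linear_rhs_raw(y: np.ndarray, p: LinearParams) -> np.ndarray:
    w1, w2, w3 = _linear_fluxes(y, p)
    return np.array([w3 - w1, w1 - w2, w2 - w3])


def linear_rhs(state: "LinearState | np.ndarray", p: LinearParams) -> Derivative:
    """Mass-action vector field of the linear cycle.

    The cycle is closed, so the derivative components sum to zero exactly.
    """
    y = state.to_array() if isinstance(state, LinearState) else np.asarray(state, float)
    _check_nonnegative(y, LINEAR_SPECIES)
    return Derivative(_linear_rhs_raw(y, p), _linear_fluxes(y, p))


def _nonlinear_fluxes(y: np.ndarray, p: NonlinearParams) -> np.ndarray:
    c40S, c60S, c_eIF4F, c_mRNA40S, cAUG, c80S = y
    return np.array(
        [
            p.k1 * c40S * c_eIF4F,
            p.k2 * c_mRNA40S,
            p.k3 * cAUG * c60S,
            p.k4 * c80S,
        ]
    )


def _nonlinear_rhs_raw(y: np.ndarray, p: NonlinearParams) -> np.ndarray:
    w1, w2, w3, w4 = _nonlinear_fluxes(y, p)
    return np.array(
        [
            w4 - w1,  # 40S
            w4 - w3,  # 60S
            w2 - w1,  # eIF4F
            w1 - w2,  # mRNA:40S
            w2 - w3,  # AUG
            w3 - w4,  # 80S
        ]
    )


def nonlinear_rhs(state: "NonlinearState | np.ndarray", p: NonlinearParams) -> Derivative:
    """Mass-action vector field of the recycling model.

    All three conserved linear combinations have identically zero
    derivative: d(eIF4F)+d(mRNA:40S) = 0, d(60S)+d(80S) = 0 and
    d(40S)+d(mRNA:40S)+d(AUG)+d(80S) = 0.
    """
    y = (
        state.to_array()
        if isinstance(state, NonlinearState)
        else np.asarray(state, float)
    )
    _check_nonnegative(y, NONLINEAR_SPECIES)
    return Derivative(_nonlinear_rhs_raw(y, p), _nonlinear_fluxes(y, p))


def protein_rate(
    y: np.ndarray, p: "LinearParams | NonlinearParams", definition: str = "recycling"
) -> np.ndarray:
    """Instantaneous protein synthesis rate Prsynth(t).

    For the linear model this is the elongation flux ``k3*[AUG]``.  For the
    non-linear model the default is the flux of the reaction that completes
    a protein and releases the subunits, ``k4*[80S]`` ("recycling"); the
    alternative convention ``k3*[AUG]*[60S]`` ("assembly") is available via
    ``definition``.  At steady state all conventions coincide.
    """
    y = np.atleast_2d(np.asarray(y, float))
    if isinstance(p, LinearParams):
        out = p.k3 * y[:, 2]
    elif definition == "recycling":
        out = p.k4 * y[:, 5]
    elif definition == "assembly":
        out = p.k3 * y[:, 4] * y[:, 1]
    else:  # pragma: no cover - guarded by CLI/config validation
        raise ValueError(f"unknown Prsynth definition {definition!r}")
    return out


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time grid, species concentrations, reaction fluxes and Prsynth(t)."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    fluxes: np.ndarray  # shape (n_times, n_reactions)
    protein_rate: np.ndarray
    species: tuple[str, ...]
    params: "LinearParams | NonlinearParams"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.states) == len(self.fluxes) == len(self.protein_rate) == n):
            raise ValueError("inconsistent trajectory array lengths")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def conservation_residuals(self) -> np.ndarray:
        """Max relative residual of each conservation law over the grid."""
        p = self.params
        s = self.states
        if isinstance(p, LinearParams):
            res = np.abs(s.sum(axis=1) - p.total_40S)[:, None] / p.total_40S
        else:
            r40 = s[:, 0] + s[:, 3] + s[:, 4] + s[:, 5] - p.total_40S
            reif = s[:, 2] + s[:, 3] - p.total_eIF4F
            r60 = s[:, 1] + s[:, 5] - p.total_60S
            res = np.abs(
                np.stack(
                    [r40 / p.total_40S, reif / p.total_eIF4F, r60 / p.total_60S],
                    axis=1,
                )
            )
        return res.max(axis=0)

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times}
        for j, name in enumerate(self.species):
            data[name] = self.states[:, j]
        for j in range(self.fluxes.shape[1]):
            data[f"w{j + 1}"] = self.fluxes[:, j]
        data["prsynth"] = self.protein_rate
        return pd.DataFrame(data)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            frame.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def _time_grid(t_end: float, rates: Sequence[float], n_points: int) -> np.ndarray:
    fastest = max(rates)
    t0 = min(1e-3 / fastest, t_end / 1e6)
    grid = np.geomspace(t0, t_end, n_points)
    return np.concatenate([[0.0], grid])


def integrate(
    p: "LinearParams | NonlinearParams",
    init: "np.ndarray | LinearState | NonlinearState | None" = None,
    t_end: float = 100.0,
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
    n_points: int = 400,
    method: str | None = None,
    protein_rate_definition: str = "recycling",
    check_conservation: bool = True,
) -> Trajectory:
    """Integrate a model on a log-friendly grid with conservation checks.

    ``init`` defaults to the all-free initial condition (pools at their
    totals, complexes at zero).  A stiff implicit method is selected
    automatically when the elongation rate scale dominates the other rates
    by more than two orders of magnitude; otherwise LSODA is used (which
    itself switches to BDF on stiffness).
    """
    if t_end <= 0:
        raise DomainError(f"t_end must be positive, got {t_end}")
    linear = isinstance(p, LinearParams)
    if init is None:
        y0 = p.free_init()
    elif isinstance(init, (LinearState, NonlinearState)):
        y0 = init.to_array()
    else:
        y0 = np.asarray(init, dtype=float)
    _check_nonnegative(y0, LINEAR_SPECIES if linear else NONLINEAR_SPECIES)

    if linear:
        rates = [p.k1, p.k2, p.k3]
        rhs = lambda t, y: _linear_rhs_raw(y, p)  # noqa: E731
        fluxes_of = lambda y: _linear_fluxes(y, p)  # noqa: E731
        species = LINEAR_SPECIES
        elong_scale = p.k3
        other_scale = max(p.k1, p.k2)
    else:
        rates = [
            p.k1 * p.total_eIF4F,
            p.k2,
            p.k3 * p.total_60S,
            p.k4,
            p.k1 * p.total_40S,
        ]
        rhs = lambda t, y: _nonlinear_rhs_raw(y, p)  # noqa: E731
        fluxes_of = lambda y: _nonlinear_fluxes(y, p)  # noqa: E731
        species = NONLINEAR_SPECIES
        elong_scale = p.k3 * p.total_40S
        other_scale = max(p.k1 * p.total_40S, p.k2, p.k4)

    if method is None:
        method = "Radau" if elong_scale > 100.0 * other_scale else "LSODA"

    t_eval = _time_grid(t_end, rates, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed near t={sol.t[-1] if len(sol.t) else 0.0:g} "
            f"(method {method}): {sol.message}"
        )
    states = sol.y.T.copy()
    low = states.min()
    if low < NEGATIVITY_FLOOR:
        raise IntegrationError(
            f"integrator produced a concentration of {low:.3e}, below the "
            f"positivity floor {NEGATIVITY_FLOOR:g}"
        )
    np.clip(states, 0.0, None, out=states)

    traj = Trajectory(
        times=sol.t,
        states=states,
        fluxes=np.array([fluxes_of(y) for y in states]),
        protein_rate=protein_rate(states, p, protein_rate_definition),
        species=species,
        params=p,
        meta={"method": method, "rtol": rtol, "atol": atol, "t_end": t_end},
    )
    if check_conservation:
        worst = traj.conservation_residuals().max()
        if worst > CONSERVATION_RTOL:
            raise IntegrationError(
                f"conservation residual {worst:.3e} exceeds {CONSERVATION_RTOL:g}"
            )
    return traj


# ---------------------------------------------------------------------------
# SBML Level 3 export / import (mass-action kinetic laws only)
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_LINEAR_REACTIONS = (
    ("R1", ("c40S",), ("c_mRNA40S",), "k1"),
    ("R2", ("c_mRNA40S",), ("cAUG",), "k2"),
    ("R3", ("cAUG",), ("c40S",), "k3"),
)
_NONLINEAR_REACTIONS = (
    ("R1", ("c40S", "c_eIF4F"), ("c_mRNA40S",), "k1"),
    ("R2", ("c_mRNA40S",), ("cAUG", "c_eIF4F"), "k2"),
    ("R3", ("cAUG", "c60S"), ("c80S",), "k3"),
    ("R4", ("c80S",), ("c40S", "c60S"), "k4"),
)


def export_sbml(
    p: "LinearParams | NonlinearParams", init: "np.ndarray | None" = None
) -> str:
    """Serialize a model as an SBML Level 3 document (mass-action laws).

    Every reaction carries an explicit ``k * reactant1 [* reactant2]``
    kinetic law; species carry initial concentrations.  The document is
    self-contained: :func:`import_sbml` reconstructs the parameter record
    and initial state exactly.
    """
    linear = isinstance(p, LinearParams)
    species = LINEAR_SPECIES if linear else NONLINEAR_SPECIES
    reactions = _LINEAR_REACTIONS if linear else _NONLINEAR_REACTIONS
    y0 = p.free_init() if init is None else np.asarray(init, float)
    if len(y0) != len(species):
        raise DomainError("initial condition has the wrong number of species")

    ET.register_namespace("", _SBML_NS)
    root = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(
        root,
        f"{{{_SBML_NS}}}model",
        {"id": "linear_translation" if linear else "nonlinear_translation"},
    )
    lcomp = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(
        lcomp,
        f"{{{_SBML_NS}}}compartment",
        {"id": "cytoplasm", "size": "1", "constant": "true", "spatialDimensions": "3"},
    )
    lspec = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for name, value in zip(species, y0):
        ET.SubElement(
            lspec,
            f"{{{_SBML_NS}}}species",
            {
                "id": name,
                "compartment": "cytoplasm",
                "initialConcentration": repr(float(value)),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )
    lpar = ET.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")
    rate_names = ("k1", "k2", "k3") if linear else ("k1", "k2", "k3", "k4")
    for name in rate_names:
        ET.SubElement(
            lpar,
            f"{{{_SBML_NS}}}parameter",
            {"id": name, "value": repr(float(getattr(p, name))), "constant": "true"},
        )
    lrxn = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for rid, reactants, products, k in reactions:
        rxn = ET.SubElement(
            lrxn, f"{{{_SBML_NS}}}reaction", {"id": rid, "reversible": "false"}
        )
        lref = ET.SubElement(rxn, f"{{{_SBML_NS}}}listOfReactants")
        for s in reactants:
            ET.SubElement(
                lref,
                f"{{{_SBML_NS}}}speciesReference",
                {"species": s, "stoichiometry": "1", "constant": "true"},
            )
        lprod = ET.SubElement(rxn, f"{{{_SBML_NS}}}listOfProducts")
        for s in products:
            ET.SubElement(
                lprod,
                f"{{{_SBML_NS}}}speciesReference",
                {"species": s, "stoichiometry": "1", "constant": "true"},
            )
        klaw = ET.SubElement(rxn, f"{{{_SBML_NS}}}kineticLaw")
        mathml = ET.SubElement(klaw, f"{{{_MATHML_NS}}}math")
        apply = ET.SubElement(mathml, f"{{{_MATHML_NS}}}apply")
        ET.SubElement(apply, f"{{{_MATHML_NS}}}times")
        for ci_name in (k, *reactants):
            ci = ET.SubElement(apply, f"{{{_MATHML_NS}}}ci")
            ci.text = ci_name
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def import_sbml(doc: str) -> "tuple[LinearParams | NonlinearParams, np.ndarray]":
    """Parse an SBML document produced by :func:`export_sbml`.

    Raises :class:`UnsupportedModelError` for unknown species, non-mass-action
    kinetic laws, or a reaction topology that matches neither model.
    """
    try:
        root = ET.fromstring(doc)
    except ET.ParseError as exc:
        raise UnsupportedModelError(f"not parseable as SBML: {exc}") from exc
    model = root.find(f"{{{_SBML_NS}}}model")
    if model is None:
        raise UnsupportedModelError("document has no <model> element")

    values: dict[str, float] = {}
    for par in model.iter(f"{{{_SBML_NS}}}parameter"):
        values[par.get("id", "")] = float(par.get("value", "nan"))

    init_map: dict[str, float] = {}
    for sp in model.iter(f"{{{_SBML_NS}}}species"):
        init_map[sp.get("id", "")] = float(sp.get("initialConcentration", "nan"))

    if set(init_map) == set(LINEAR_SPECIES):
        species, reactions, linear = LINEAR_SPECIES, _LINEAR_REACTIONS, True
    elif set(init_map) == set(NONLINEAR_SPECIES):
        species, reactions, linear = NONLINEAR_SPECIES, _NONLINEAR_REACTIONS, False
    else:
        raise UnsupportedModelError(f"unknown species set: {sorted(init_map)}")

    seen = {}
    for rxn in model.iter(f"{{{_SBML_NS}}}reaction"):
        rid = rxn.get("id", "")
        reactants = tuple(
            ref.get("species")
            for ref in rxn.findall(
                f"{{{_SBML_NS}}}listOfReactants/{{{_SBML_NS}}}speciesReference"
            )
        )
        products = tuple(
            ref.get("species")
            for ref in rxn.findall(
                f"{{{_SBML_NS}}}listOfProducts/{{{_SBML_NS}}}speciesReference"
            )
        )
        apply = rxn.find(
            f"{{{_SBML_NS}}}kineticLaw/{{{_MATHML_NS}}}math/{{{_MATHML_NS}}}apply"
        )
        if apply is None or apply.find(f"{{{_MATHML_NS}}}times") is None:
            raise UnsupportedModelError(f"reaction {rid}: kinetic law is not a product")
        cis = [ci.text for ci in apply.findall(f"{{{_MATHML_NS}}}ci")]
        if not cis or set(cis[1:]) != set(reactants):
            raise UnsupportedModelError(
                f"reaction {rid}: kinetic law is not mass action over its reactants"
            )
        seen[rid] = (reactants, products, cis[0])

    for rid, reactants, products, k in reactions:
        if rid not in seen:
            raise UnsupportedModelError(f"missing reaction {rid}")
        got_r, got_p, got_k = seen[rid]
        if set(got_r) != set(reactants) or set(got_p) != set(products) or got_k != k:
            raise UnsupportedModelError(f"reaction {rid} does not match the model")

    y0 = np.array([init_map[s] for s in species])
    if linear:
        params = LinearParams(
            k1=values["k1"], k2=values["k2"], k3=values["k3"], total_40S=float(y0.sum())
        )
    else:
        params = NonlinearParams(
            k1=values["k1"],
            k2=values["k2"],
            k3=values["k3"],
            k4=values["k4"],
            total_40S=float(y0[0] + y0[3] + y0[4] + y0[5]),
            total_60S=float(y0[1] + y0[5]),
            total_eIF4F=float(y0[2] + y0[3]),
        )
    return params, y0
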