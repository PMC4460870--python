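"""Constraint-based metabolic models and the linear-programming primitive.

A :class:`StoichiometricModel` is the minimal substrate for flux balance
analysis: metabolites (rows of the stoichiometry matrix S), bounded reactions
(columns), and a designated biomass reaction.  :func:`solve_lp` maximises or
minimises a single reaction flux subject to the steady-state constraint
``S @ v = 0`` and the flux bounds — the one LP primitive every other module
builds on.

Models are read from COBRA-style JSON or SBML Level 3 with the FBC package.
Flux units follow the COBRA convention, mmol * gDW^-1 * h^-1, and uptake of an
exchanged substrate is a negative lower bound on its exchange reaction
(glucose uptake 10 => lb = -10).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "FluxSolution",
    "ModelValidationError",
    "read_model",
    "write_model_json",
    "solve_lp",
    "STEADY_STATE_TOL",
    "BOUND_TOL",
]

logger = logging.getLogger(__name__)

#: assertion tolerance on |S @ v| for an optimal solution
STEADY_STATE_TOL = 1e-6
#: assertion tolerance on bound violation for an optimal solution
BOUND_TOL = 1e-9

_DEFAULT_UB = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model violates its structural invariants."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    """A bounded reaction column.

    ``stoichiometry`` maps metabolite id to its coefficient; negative means
    consumed, positive produced.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = _DEFAULT_UB

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.lower_bound, self.upper_bound)


@dataclass
class StoichiometricModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_id: str
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id!r}")

    def has_metabolite(self, mid: str) -> bool:
        return mid in {m.id for m in self.metabolites}

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            biomass_id=self.biomass_id,
            id=self.id,
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError("duplicate metabolite ids")
        if any(not m for m in met_ids):
            raise ModelValidationError("empty metabolite id")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id!r} has empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} > upper bound {r.upper_bound}"
                )
            dangling = set(r.stoichiometry) - known
            if dangling:
                raise ModelValidationError(
                    f"reaction {r.id!r} references undeclared metabolite(s) {sorted(dangling)}"
                )
        if self.biomass_id not in set(rxn_ids):
            raise ModelValidationError(f"biomass reaction {self.biomass_id!r} not in model")

    # -- matrix form -----------------------------------------------------
    def stoichiometry_matrix(self) -> sparse.csr_matrix:
        """S as a sparse matrix, metabolites x reactions, in declaration order."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                rows.append(met_index[mid])
                cols.append(j)
                vals.append(float(coef))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds(self) -> list[tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]


@dataclass(frozen=True)
class FluxSolution:
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    status: str = "optimal"  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

_LINPROG_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_lp(model: StoichiometricModel, objective_id: str, sense: str = "max") -> FluxSolution:
    """Optimise one reaction flux subject to S @ v = 0 and the flux bounds.

    Only the objective value is contractual: flux vectors of degenerate optima
    may differ between runs or solvers, the optimum itself may not.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    rxn_ids = model.reaction_ids
    try:
        j_obj = rxn_ids.index(objective_id)
    except ValueError:
        raise KeyError(f"objective reaction {objective_id!r} not in model") from None

    n = len(model.reactions)
    c = np.zeros(n)
    c[j_obj] = -1.0 if sense == "max" else 1.0
    S = model.stoichiometry_matrix()
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=model.bounds(),
        method="highs",
    )
    status = _LINPROG_STATUS.get(res.status, "infeasible")
    if status != "optimal":
        logger.info("LP %s %s(%s): status=%s", model.id, sense, objective_id, status)
        return FluxSolution(objective_value=None, fluxes={}, status=status)
    fluxes = {rid: float(v) for rid, v in zip(rxn_ids, res.x)}
    obj = fluxes[objective_id]
    return FluxSolution(objective_value=obj, fluxes=fluxes, status="optimal")


# ---------------------------------------------------------------------------
# I/O: COBRA-style JSON
# ---------------------------------------------------------------------------


def _model_from_json_dict(doc: dict, model_id: str = "model") -> StoichiometricModel:
    mets = [
        Metabolite(
            id=m["id"], name=m.get("name", ""), compartment=m.get("compartment", "")
        )
        for m in doc.get("metabolites", [])
    ]
    rxns = []
    biomass_id = doc.get("biomass_id")
    for r in doc.get("reactions", []):
        rxns.append(
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", _DEFAULT_UB)),
            )
        )
        if biomass_id is None and float(r.get("objective_coefficient", 0.0)) != 0.0:
            biomass_id = r["id"]
    if biomass_id is None:
        raise ModelValidationError(
            "no biomass reaction: set 'biomass_id' or a non-zero 'objective_coefficient'"
        )
    return StoichiometricModel(
        metabolites=mets, reactions=rxns, biomass_id=biomass_id, id=doc.get("id", model_id)
    )


def _read_json(path: str) -> StoichiometricModel:
    with open(path) as fh:
        doc = json.load(fh)
    return _model_from_json_dict(doc)


def write_model_json(model: StoichiometricModel, path: str) -> None:
    """Write the COBRA-style JSON dialect (reactions/metabolites/bounds keys)."""
    doc = {
        "id": model.id,
        "biomass_id": model.biomass_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "objective_coefficient": 1.0 if r.id == model.biomass_id else 0.0,
            }
            for r in model.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# I/O: SBML Level 3 + FBC
# ---------------------------------------------------------------------------


def _read_sbml(path: str) -> StoichiometricModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelValidationError(
            f"SBML parse error: {doc.getErrorLog().toString().strip()}"
        )
    sb = doc.getModel()
    if sb is None:
        raise ModelValidationError(f"{path!r} contains no SBML model")
    fbc = sb.getPlugin("fbc")
    if fbc is None:
        raise ModelValidationError("SBML model lacks the FBC package (need L3+FBC bounds)")

    params = {
        sb.getParameter(i).getId(): sb.getParameter(i).getValue()
        for i in range(sb.getNumParameters())
    }

    # SBML convention prefixes species/reaction ids with M_/R_; strip them as
    # the COBRA toolchain does so both dialects agree on identifiers
    def _sid(raw: str, prefix: str) -> str:
        return raw[len(prefix):] if raw.startswith(prefix) else raw

    mets = []
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are outside the balanced system
        mets.append(
            Metabolite(
                id=_sid(sp.getId(), "M_"), name=sp.getName(), compartment=sp.getCompartment()
            )
        )
    balanced = {m.id for m in mets}

    rxns = []
    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            sr = rx.getReactant(k)
            mid = _sid(sr.getSpecies(), "M_")
            if mid in balanced:
                stoich[mid] = stoich.get(mid, 0.0) - sr.getStoichiometry()
        for k in range(rx.getNumProducts()):
            sr = rx.getProduct(k)
            mid = _sid(sr.getSpecies(), "M_")
            if mid in balanced:
                stoich[mid] = stoich.get(mid, 0.0) + sr.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        if rfbc is None or not rfbc.isSetLowerFluxBound():
            raise ModelValidationError(f"reaction {rx.getId()!r} lacks FBC flux bounds")
        lb = params[rfbc.getLowerFluxBound()]
        ub = params[rfbc.getUpperFluxBound()]
        rxns.append(
            Reaction(id=_sid(rx.getId(), "R_"), stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
        )

    biomass_id = None
    obj = fbc.getActiveObjective()
    if obj is not None and obj.getNumFluxObjectives() > 0:
        biomass_id = _sid(obj.getFluxObjective(0).getReaction(), "R_")
    if biomass_id is None:
        raise ModelValidationError("SBML/FBC model has no active objective (biomass) reaction")
    return StoichiometricModel(metabolites=mets, reactions=rxns, biomass_id=biomass_id, id=sb.getId() or "model")


def read_model(path: str, format: str = "auto") -> StoichiometricModel:
    """Read a genome-scale model from COBRA-style JSON or SBML L3+FBC.

    ``format='auto'`` dispatches on the file extension (.json vs .xml/.sbml).
    """
    if format == "auto":
        low = str(path).lower()
        if low.endswith(".json"):
            format = "json"
        elif low.endswith((".xml", ".sbml")):
            format = "sbml"
        else:
            raise ValueError(f"cannot infer model format from {path!r}; pass format=")
    if format == "json":
        return _read_json(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r} (expected 'sbml' or 'json')")


def check_solution(model: StoichiometricModel, sol: FluxSolution) -> float:
    """Return max |S @ v| for an optimal solution (and check bounds).

    Raises AssertionError when the steady-state residual exceeds
    ``STEADY_STATE_TOL`` or any flux leaves its bounds by more than
    ``BOUND_TOL``.
    """
    if not sol.optimal:
        raise ValueError("can only check an optimal solution")
    v = np.array([sol.fluxes[rid] for rid in model.reaction_ids])
    resid = float(np.max(np.abs(model.stoichiometry_matrix() @ v))) if len(v) else 0.0
    if resid > STEADY_STATE_TOL:
        raise AssertionError(f"steady-state residual {resid:.3g} > {STEADY_STATE_TOL}")
    for r, vj in zip(model.reactions, v):
        if vj < r.lower_bound - BOUND_TOL or vj > r.upper_bound + BOUND_TOL:
            raise AssertionError(f"flux of {r.id!r} = {vj} outside [{r.lower_bound}, {r.upper_bound}]")
    return resid
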