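"""Per-protein amino-acid supply by two-step flux balance analysis.

The supply of a protein is the maximal steady-state flux the metabolic
network can push through a protein-specific amino-acid sink while the cell
keeps growing at its maximal rate on a basal amino-acid budget:

1. maximise the biomass flux to obtain the maximal growth rate ``mu`` under
   a fixed substrate (glucose) uptake;
2. replace the biomass reaction by a *partial biomass* whose amino-acid
   coefficients are scaled to a basal fraction ``beta`` (default 0.30, other
   coefficients untouched), fix its flux at ``mu``, add an irreversible sink
   consuming free amino acids in the protein's residue frequencies, and
   maximise that sink flux.

The maximum, in residue-equivalents * gDW^-1 * h^-1, is the protein's
amino-acid supply.  Because the whole construction is linear, supply rankings
across proteins are invariant to ``beta``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from .model_core import Reaction, StoichiometricModel, solve_lp
from ._aa_maps import AA_NAMES, IJO1366_AA_MAP

__all__ = [
    "AminoAcidMap",
    "SupplyResult",
    "max_growth",
    "make_partial_biomass",
    "make_protein_sink",
    "amino_acid_supply",
    "supply_table",
    "aa_map_from_names",
    "ijo1366_aa_map",
]

logger = logging.getLogger(__name__)

FREQ_TOL = 1e-9
#: relative relaxation applied to the fixed growth rate when lb=ub=mu is
#: numerically infeasible
MU_RELAX = 1e-6


@dataclass(frozen=True)
class AminoAcidMap:
    """Mapping one-letter residue code -> metabolite id in a model.

    Genome-scale maps carry all 20 canonical codes; toy models may use a
    subset alphabet.  ``validate`` checks every mapped metabolite exists.
    """

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("AminoAcidMap is empty")
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValueError("AminoAcidMap maps two codes to the same metabolite")

    def __getitem__(self, code: str) -> str:
        return self.mapping[code]

    def __contains__(self, code: str) -> bool:
        return code in self.mapping

    def codes(self) -> list[str]:
        return list(self.mapping)

    def validate(self, model: StoichiometricModel, require_all_20: bool = False) -> None:
        if require_all_20 and len(self.mapping) < 20:
            raise ValueError(f"map has {len(self.mapping)} codes, 20 required")
        missing = [mid for mid in self.mapping.values() if not model.has_metabolite(mid)]
        if missing:
            raise ValueError(f"mapped metabolites absent from model: {sorted(missing)}")


def ijo1366_aa_map() -> AminoAcidMap:
    """The shipped default for the E. coli iJO1366 model (cytosolic BiGG ids)."""
    return AminoAcidMap(dict(IJO1366_AA_MAP))


def aa_map_from_names(model: StoichiometricModel, compartment: str | None = None) -> AminoAcidMap:
    """Build a map by matching metabolite names against canonical amino-acid names.

    Used for models with opaque metabolite ids (e.g. the yeast consensus
    models).  When several compartments carry the same amino acid, pass the
    compartment of the biomass reaction's substrates.
    """
    mapping: dict[str, str] = {}
    for met in model.metabolites:
        if compartment is not None and met.compartment != compartment:
            continue
        # strip a trailing "[compartment]" tag common in yeast models
        name = met.name.lower().split("[")[0].strip()
        for code, names in AA_NAMES.items():
            if name in names and code not in mapping:
                mapping[code] = met.id
    if not mapping:
        raise ValueError("no amino-acid metabolites found by name matching")
    return AminoAcidMap(mapping)


@dataclass(frozen=True)
class SupplyResult:
    """Amino-acid supply of one protein.

    ``supply`` is the maximal sink flux (residue-equivalents gDW^-1 h^-1);
    ``None`` marks a protein whose sink LP was infeasible or whose sequence
    contains residues the model cannot supply.
    """

    protein_id: str
    supply: float | None
    mu: float
    basal_level: float


# ---------------------------------------------------------------------------
# step 1
# ---------------------------------------------------------------------------


def max_growth(model: StoichiometricModel) -> float:
    """Maximal growth rate mu = max v_biomass (substrate bound set by caller)."""
    sol = solve_lp(model, model.biomass_id, sense="max")
    if not sol.optimal:
        raise RuntimeError(f"growth LP not optimal: status={sol.status}")
    return float(sol.objective_value)


# ---------------------------------------------------------------------------
# step 2 building blocks
# ---------------------------------------------------------------------------


def make_partial_biomass(
    model: StoichiometricModel, aa_map: AminoAcidMap, beta: float
) -> StoichiometricModel:
    """Copy of the model whose biomass amino-acid coefficients are scaled by beta.

    Every non-amino-acid biomass coefficient is left unchanged; the input
    model is not modified.  Amino acids mapped but absent from the biomass
    reaction produce a warning, not an error.
    """
    if not (0.0 < beta <= 1.0):
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    out = model.copy()
    biomass = out.reaction(out.biomass_id)
    aa_mets = set(aa_map.mapping.values())
    absent = aa_mets - set(biomass.stoichiometry)
    if absent:
        warnings.warn(
            f"amino-acid metabolites not in biomass reaction, unscaled: {sorted(absent)}",
            stacklevel=2,
        )
    for mid in aa_mets & set(biomass.stoichiometry):
        biomass.stoichiometry[mid] *= beta
    return out


def make_protein_sink(
    model: StoichiometricModel,
    aa_map: AminoAcidMap,
    aa_freq: dict[str, float],
    sink_id: str = "protein_sink",
) -> tuple[StoichiometricModel, str]:
    """Add an irreversible sink consuming amino acids in the given frequencies.

    The sink consumes free amino-acid metabolites only — no polymerisation
    energy cost and no by-products — with coefficients equal to the residue
    frequencies, bounds [0, +inf).
    """
    if any(f < 0 for f in aa_freq.values()):
        raise ValueError("negative residue frequency")
    total = sum(aa_freq.values())
    if abs(total - 1.0) > FREQ_TOL:
        raise ValueError(f"residue frequencies sum to {total!r}, expected 1")
    unknown = set(aa_freq) - set(aa_map.codes())
    if unknown:
        raise KeyError(f"residue code(s) not in amino-acid map: {sorted(unknown)}")
    out = model.copy()
    stoich = {aa_map[code]: -float(f) for code, f in aa_freq.items() if f > 0}
    out.reactions.append(
        Reaction(id=sink_id, stoichiometry=stoich, lower_bound=0.0, upper_bound=float("inf"))
    )
    out.validate()
    return out, sink_id


def amino_acid_supply(
    model: StoichiometricModel,
    aa_map: AminoAcidMap,
    aa_freq: dict[str, float],
    beta: float,
    mu: float,
    protein_id: str = "protein",
) -> SupplyResult:
    """Two-step supply for one protein: fix partial biomass at mu, maximise sink.

    ``mu`` must come from :func:`max_growth` on the same base model and
    substrate bound.  On numerical infeasibility of the exact fixing
    ``lb = ub = mu`` the growth rate is relaxed by a relative ``MU_RELAX``
    and the relaxation logged.
    """
    partial = make_partial_biomass(model, aa_map, beta)
    sink_model, sink_id = make_protein_sink(partial, aa_map, aa_freq)
    biomass = sink_model.reaction(sink_model.biomass_id)
    biomass.lower_bound = biomass.upper_bound = mu
    sol = solve_lp(sink_model, sink_id, sense="max")
    if sol.status == "infeasible":
        relaxed = mu * (1.0 - MU_RELAX)
        logger.warning(
            "fixing partial biomass at mu=%.9g infeasible; retrying at %.9g", mu, relaxed
        )
        biomass.lower_bound = biomass.upper_bound = relaxed
        sol = solve_lp(sink_model, sink_id, sense="max")
    if not sol.optimal:
        return SupplyResult(protein_id=protein_id, supply=None, mu=mu, basal_level=beta)
    return SupplyResult(
        protein_id=protein_id, supply=float(sol.objective_value), mu=mu, basal_level=beta
    )


def supply_table(
    model: StoichiometricModel,
    aa_map: AminoAcidMap,
    proteome,
    beta: float = 0.3,
    substrate_uptake: float | None = None,
    substrate_exchange_id: str | None = None,
) -> list[SupplyResult]:
    """Supply for every protein in a proteome, mu computed once and reused.

    ``proteome`` is an iterable of records with ``id`` and ``aa_freq``
    attributes (see ``seq_features.ProteinRecord``).  Per-protein failures
    (unsupported residues, infeasible sink) yield ``supply=None`` rather than
    aborting; output order matches input order.

    When ``substrate_exchange_id`` is given, its lower bound is set to
    ``-substrate_uptake`` (uptake is negative exchange flux) before step 1.
    """
    proteome = list(proteome)
    if not proteome:
        raise ValueError("empty proteome")
    base = model.copy()
    if substrate_exchange_id is not None:
        if substrate_uptake is None:
            substrate_uptake = 10.0
        base.reaction(substrate_exchange_id).lower_bound = -float(substrate_uptake)
    mu = max_growth(base)

    # partial biomass and mu-fixing are shared by every protein
    partial = make_partial_biomass(base, aa_map, beta)
    biomass = partial.reaction(partial.biomass_id)
    biomass.lower_bound = biomass.upper_bound = mu

    results: list[SupplyResult] = []
    for prot in proteome:
        try:
            sink_model, sink_id = make_protein_sink(partial, aa_map, prot.aa_freq)
        except (KeyError, ValueError) as exc:
            logger.warning("protein %s: %s", prot.id, exc)
            results.append(SupplyResult(prot.id, None, mu, beta))
            continue
        sol = solve_lp(sink_model, sink_id, sense="max")
        if sol.status == "infeasible":
            relaxed = mu * (1.0 - MU_RELAX)
            logger.warning("protein %s: mu fixing infeasible, relaxing to %.9g", prot.id, relaxed)
            bm = sink_model.reaction(sink_model.biomass_id)
            bm.lower_bound = bm.upper_bound = relaxed
            sol = solve_lp(sink_model, sink_id, sense="max")
        supply = float(sol.objective_value) if sol.optimal else None
        results.append(SupplyResult(prot.id, supply, mu, beta))
    return results
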