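"""Independent brute-force oracles used only to cross-check implementations.

The LP oracle enumerates candidate vertices of the flux polytope
{v : S v = 0, lb <= v <= ub} by fixing every choice of n - rank(S) variables
at a finite bound, solving the remaining square system, and keeping feasible
solutions.  For bounded toy polytopes the optimum of a linear objective is
attained at such a vertex, so the maximum over candidates is the LP optimum.
Independent of the package's solver path by construction.
"""

from __future__ import annotations

import itertools

import numpy as np


def lp_vertex_oracle(model, objective_id: str, sense: str = "max") -> float | None:
    """LP optimum by vertex enumeration; None when no feasible vertex exists."""
    S = model.stoichiometry_matrix().toarray()
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    rxn_ids = model.reaction_ids
    j_obj = rxn_ids.index(objective_id)
    m, n = S.shape
    k = np.linalg.matrix_rank(S)
    n_fix = n - k

    best = None
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        if np.linalg.matrix_rank(A) < k:
            continue
        bound_choices = []
        for j in fixed:
            opts = []
            if np.isfinite(lb[j]):
                opts.append(lb[j])
            if np.isfinite(ub[j]) and ub[j] != lb[j]:
                opts.append(ub[j])
            if not opts:
                opts = [None]
            bound_choices.append(opts)
        for values in itertools.product(*bound_choices):
            if any(v is None for v in values):
                continue
            v = np.zeros(n)
            v[list(fixed)] = values
            rhs = -S[:, list(fixed)] @ np.array(values)
            x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.max(np.abs(A @ x - rhs)) > 1e-7:
                continue
            v[free] = x
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            val = v[j_obj]
            if best is None:
                best = val
            elif sense == "max":
                best = max(best, val)
            else:
                best = min(best, val)
    return best


def supply_vertex_oracle(model, aa_map, aa_freq, beta: float, mu: float) -> float | None:
    """Amino-acid supply via the vertex oracle on the step-2 model."""
    from aaflux.supply_fba import make_partial_biomass, make_protein_sink

    partial = make_partial_biomass(model, aa_map, beta)
    sink_model, sink_id = make_protein_sink(partial, aa_map, aa_freq)
    biomass = sink_model.reaction(sink_model.biomass_id)
    biomass.lower_bound = biomass.upper_bound = mu
    return lp_vertex_oracle(sink_model, sink_id, sense="max")
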