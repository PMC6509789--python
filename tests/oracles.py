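"""Independent oracles for cross-checking the LP machinery.

The implementation under test solves everything with scipy/HiGHS; these
helpers route the same problems through cobra's optlang/GLPK stack, an
entirely separate code path, or through brute-force enumeration.
"""

from __future__ import annotations

import numpy as np

from paretoflux import StoichiometricModel


def to_cobra(model: StoichiometricModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(m.id, compartment=m.compartment)
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()
                            if not model.metabolite(k).is_external})
        cr.bounds = (r.lower_bound, r.upper_bound)
    return cm


def cobra_optimum(model: StoichiometricModel, objective_rxn: str,
                  maximize: bool = True) -> float:
    cm = to_cobra(model)
    cm.objective = objective_rxn
    cm.objective_direction = "max" if maximize else "min"
    sol = cm.optimize()
    assert sol.status == "optimal", sol.status
    return sol.objective_value


def cobra_fva(model: StoichiometricModel, reaction_ids: list[str]) -> dict[str, tuple[float, float]]:
    from cobra.flux_analysis import flux_variability_analysis

    cm = to_cobra(model)
    frame = flux_variability_analysis(cm, reaction_list=reaction_ids, fraction_of_optimum=0.0)
    return {r: (frame.loc[r, "minimum"], frame.loc[r, "maximum"]) for r in reaction_ids}


def epsilon_constraint_front(
    model: StoichiometricModel, obj1_rxn: str, obj2_rxn: str, eps_values
) -> list[tuple[float, float]]:
    """Sweep objective-1 levels, maximizing objective 2 at each: the textbook
    two-objective Pareto construction, via the cobra/GLPK route."""
    out = []
    cm = to_cobra(model)
    for eps in eps_values:
        with cm:
            r1 = cm.reactions.get_by_id(obj1_rxn)
            r1.lower_bound = max(r1.lower_bound, eps)
            cm.objective = obj2_rxn
            sol = cm.optimize()
            if sol.status != "optimal":
                continue
            out.append((sol.fluxes[obj1_rxn], sol.objective_value))
    return out


def brute_force_pareto(vectors: np.ndarray, tol: float = 1e-6) -> list[int]:
    """Indices of non-dominated rows (maximization), O(N^2), after removing
    duplicates rounded to 6 decimals — the reference for pareto_filter."""
    seen = set()
    unique_idx = []
    for i, v in enumerate(vectors):
        key = tuple(np.round(v, 6))
        if key not in seen:
            seen.add(key)
            unique_idx.append(i)
    keep = []
    for i in unique_idx:
        dominated = False
        for j in unique_idx:
            if i == j:
                continue
            if np.all(vectors[j] >= vectors[i] - tol) and np.any(vectors[j] > vectors[i] + tol):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return keep
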