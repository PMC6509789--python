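"""Transcriptome-constrained flux prediction (GX-FBA).

Predicts the flux state after an environment or carbon-source transition by
maximizing agreement with measured gene-expression changes:

1. solve the pre-transition condition for a reference flux distribution
   (a centered representative of the alternate optima),
2. run FVA under the post-transition constraints with the biomass floor at
   zero to get each reaction's feasible envelope and its mean capacity,
3. map log2 fold changes onto reactions (complexes/isozymes take the
   largest consistent change; mixed-sign reactions are excluded), keeping
   only changes of at least the threshold (default +-0.5 log2, i.e. 50%),
4. maximize Z = sum_{i in T} log2fc_i * v_i / vbar_i under the
   post-transition constraints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .fba import FluxObjective, FluxSolution, FvaEnvelope, ModelProgram, fba, fva
from .lp import ZERO_FLUX_TOL
from .model import MediumConfig, StoichiometricModel, apply_medium, gpr_genes

__all__ = ["GxfbaProblem", "build_t_set", "run_gxfba", "EXPRESSION_THRESHOLD"]

log = logging.getLogger(__name__)

EXPRESSION_THRESHOLD = 0.5  # minimum |log2 fold change| to count as regulated


class GxfbaError(ValueError):
    pass


@dataclass
class GxfbaProblem:
    """Assembled inputs of the step-4 LP (kept for inspection/debugging)."""

    reference_flux: FluxSolution
    envelopes: FvaEnvelope
    mean_flux: dict[str, float]
    mean_active: float
    t_set: dict[str, float]
    objective_coefficients: dict[str, float] = field(default_factory=dict)


def build_t_set(
    model: StoichiometricModel,
    expression: Mapping[str, float],
    threshold: float = EXPRESSION_THRESHOLD,
) -> dict[str, float]:
    """Map gene log2 fold changes onto reactions.

    Per reaction: genes with |log2fc| below the threshold are ignored; among
    the rest the largest-magnitude value is taken if all share one sign,
    otherwise the reaction is excluded as inconsistent.
    """
    t: dict[str, float] = {}
    for rxn in model.reactions:
        if not rxn.gpr:
            continue
        values = [
            expression[g]
            for g in gpr_genes(rxn.gpr)
            if g in expression and abs(expression[g]) >= threshold
        ]
        if not values:
            continue
        if min(values) < 0 < max(values):
            log.debug("reaction %s excluded from T: mixed up/down regulation", rxn.id)
            continue
        t[rxn.id] = max(values, key=abs)
    return t


def run_gxfba(
    model: StoichiometricModel,
    medium1: MediumConfig,
    medium2: MediumConfig,
    expression: Mapping[str, float],
    objective1: FluxObjective | None = None,
    threshold: float = EXPRESSION_THRESHOLD,
    return_problem: bool = False,
) -> FluxSolution | tuple[FluxSolution, GxfbaProblem]:
    """Predict post-transition fluxes from pre-transition state + expression.

    The returned solution's objective value is Z, the expression-agreement
    score; its flux vector satisfies the post-transition constraints.
    """
    model1 = apply_medium(model, medium1)
    model2 = apply_medium(model, medium2)

    # step 1: reference state, centered among alternate optima
    reference = fba(model1, objective1, refine="min_total_flux")
    if not reference.optimal:
        raise GxfbaError(f"pre-transition condition is {reference.status}")

    # step 2: post-transition envelopes, biomass floor zero
    envelopes = fva(model2, biomass_fraction=0.0)
    mean_flux = {r: envelopes.midpoint(r) for r in envelopes.ranges}
    active = [r for r in envelopes.ranges if envelopes.width(r) > ZERO_FLUX_TOL]
    if active:
        mean_active = float(np.mean([abs(mean_flux[r]) for r in active]))
    else:
        mean_active = 0.0

    # step 3
    t_set = build_t_set(model, expression, threshold)
    if not t_set:
        raise GxfbaError(
            "no usable expression: every mapped gene change is below the "
            f"threshold (+-{threshold} log2) or inconsistent"
        )

    # step 4: Z = sum log2fc_i * v_i / vbar_i; zero-reference reactions fall
    # back to the mean active capacity, vanishing denominators are dropped
    coefficients: dict[str, float] = {}
    for rxn_id, log2fc in t_set.items():
        if rxn_id not in mean_flux:
            continue
        vbar = mean_flux[rxn_id]
        if abs(reference.fluxes.get(rxn_id, 0.0)) <= ZERO_FLUX_TOL:
            vbar = mean_active
        denom = abs(vbar)
        if denom <= ZERO_FLUX_TOL:
            log.warning(
                "reaction %s dropped from Z: mean flux capacity ~0", rxn_id
            )
            continue
        coefficients[rxn_id] = log2fc / denom
    if not coefficients:
        raise GxfbaError("no usable expression after denominator guards")

    prog = ModelProgram(model2)
    c = prog.cost(coefficients)
    res = prog.lp.solve(c, maximize=True)
    if not res.optimal:
        solution = FluxSolution(fluxes={}, objective_value=None, status=res.status)
    else:
        solution = prog.solution(res.x, float(res.objective), "optimal")
    if return_problem:
        problem = GxfbaProblem(
            reference_flux=reference,
            envelopes=envelopes,
            mean_flux=mean_flux,
            mean_active=mean_active,
            t_set=t_set,
            objective_coefficients=coefficients,
        )
        return solution, problem
    return solution
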