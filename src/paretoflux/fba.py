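"""Flux balance analysis core: FBA with parsimonious refinement, FVA,
absolute-value transport minimization, gene-knockout scanning, and
doubling-time utilities.

All programs share the steady-state constraints S.v = 0 over internal
metabolites with the model's flux bounds; the LP layer is scipy/HiGHS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .lp import FEASIBILITY_TOL, LinearProblem, ZERO_FLUX_TOL
from .model import StoichiometricModel, evaluate_gpr, gpr_genes, parse_gpr

__all__ = [
    "FluxObjective",
    "FluxSolution",
    "FvaEnvelope",
    "fba",
    "fva",
    "minimize_total_transport",
    "knockout_scan",
    "doubling_time",
    "fit_uptake_to_target",
]

log = logging.getLogger(__name__)

ESSENTIALITY_THRESHOLD = 1e-9


@dataclass(frozen=True)
class FluxObjective:
    """A linear flux objective: coefficient vector over reactions plus sense."""

    coefficients: Mapping[str, float]
    direction: Literal["maximize", "minimize"] = "maximize"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.coefficients or all(v == 0 for v in self.coefficients.values()):
            raise ValueError("objective needs at least one non-zero coefficient")
        if self.direction not in ("maximize", "minimize"):
            raise ValueError(f"bad direction {self.direction!r}")
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        if not self.label:
            object.__setattr__(self, "label", "+".join(self.coefficients))

    @classmethod
    def for_reaction(cls, rxn_id: str, direction: str = "maximize", label: str = "") -> "FluxObjective":
        return cls({rxn_id: 1.0}, direction, label or rxn_id)

    @property
    def sense(self) -> float:
        """+1 for maximize, -1 for minimize (used to convert to all-max space)."""
        return 1.0 if self.direction == "maximize" else -1.0

    def value(self, fluxes: Mapping[str, float]) -> float:
        return sum(c * fluxes.get(r, 0.0) for r, c in self.coefficients.items())


@dataclass
class FluxSolution:
    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded | ...

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes.get(rxn_id, 0.0)

    def total_flux(self) -> float:
        return sum(abs(v) for v in self.fluxes.values())


@dataclass
class FvaEnvelope:
    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.ranges

    def midpoint(self, rxn_id: str) -> float:
        lo, hi = self.ranges[rxn_id]
        return 0.5 * (lo + hi)

    def width(self, rxn_id: str) -> float:
        lo, hi = self.ranges[rxn_id]
        return hi - lo


# ---------------------------------------------------------------------------
# LP construction
# ---------------------------------------------------------------------------

class ModelProgram:
    """The model's steady-state LP plus an index map, reusable across solves."""

    def __init__(self, model: StoichiometricModel) -> None:
        self.model = model
        self.index = {r.id: j for j, r in enumerate(model.reactions)}
        S_int, _ = model.steady_state_matrix()
        lower = np.array([r.lower_bound for r in model.reactions])
        upper = np.array([r.upper_bound for r in model.reactions])
        lp = LinearProblem(lower, upper)
        for row in S_int:
            nz = {j: row[j] for j in np.nonzero(row)[0]}
            if nz:
                lp.add_eq(nz, 0.0)
        self.lp = lp

    def cost(self, coefficients: Mapping[str, float]) -> np.ndarray:
        c = np.zeros(self.lp.n)
        for rxn_id, coef in coefficients.items():
            if rxn_id not in self.index:
                raise KeyError(f"objective references unknown reaction {rxn_id!r}")
            c[self.index[rxn_id]] = coef
        return c

    def row(self, coefficients: Mapping[str, float]) -> dict[int, float]:
        return {self.index[r]: c for r, c in coefficients.items()}

    def solution(self, x: np.ndarray, objective: float | None, status: str) -> FluxSolution:
        fluxes = {r.id: float(x[j]) for j, r in enumerate(self.model.reactions)} if x is not None else {}
        return FluxSolution(fluxes=fluxes, objective_value=objective, status=status)


def _min_abs_flux(
    lp: LinearProblem, weights: np.ndarray
) -> tuple[np.ndarray | None, float | None, str]:
    """Minimize sum_j weights_j * |x_j| over the feasible set of ``lp``.

    Split formulation: auxiliary s_j >= |x_j| for every weighted variable.
    Returns (x, weighted sum, status).
    """
    n = lp.n
    idx = np.nonzero(weights)[0]
    aug = LinearProblem(
        np.concatenate([lp.lower, np.zeros(len(idx))]),
        np.concatenate([lp.upper, np.full(len(idx), np.inf)]),
        [(dict(c), r) for c, r in lp.eq_rows],
        [(dict(c), r) for c, r in lp.ub_rows],
    )
    for k, j in enumerate(idx):
        aug.add_ub({j: 1.0, n + k: -1.0}, 0.0)   # x_j - s_k <= 0
        aug.add_ub({j: -1.0, n + k: -1.0}, 0.0)  # -x_j - s_k <= 0
    c = np.zeros(aug.n)
    for k, j in enumerate(idx):
        c[n + k] = weights[j]
    res = aug.solve(c, maximize=False)
    if not res.optimal:
        return None, None, res.status
    return res.x[:n], float(res.objective), "optimal"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def fba(
    model: StoichiometricModel,
    objective: FluxObjective | None = None,
    refine: Literal["none", "min_total_flux"] = "min_total_flux",
) -> FluxSolution:
    """Optimize a linear flux objective at steady state.

    With ``refine="min_total_flux"`` (the default) the reported flux vector
    is, among alternate optima, the one minimizing the total absolute flux
    (the objective is first fixed to its optimum).  This makes individual
    flux routes deterministic and reproducible; the optimum value itself is
    unaffected.
    """
    if objective is None:
        if not model.biomass_reaction_id:
            raise ValueError("no objective given and model has no biomass reaction")
        objective = FluxObjective.for_reaction(model.biomass_reaction_id, label="growth")
    prog = ModelProgram(model)
    c = prog.cost(objective.coefficients)
    res = prog.lp.solve(c, maximize=objective.direction == "maximize")
    if not res.optimal:
        return FluxSolution(fluxes={}, objective_value=None, status=res.status)
    z_star = float(res.objective)
    if refine == "none":
        return prog.solution(res.x, z_star, "optimal")
    pinned = prog.lp.copy()
    pinned.add_eq({j: c[j] for j in np.nonzero(c)[0]}, z_star)
    x, _, status = _min_abs_flux(pinned, np.ones(pinned.n))
    if status != "optimal":  # numerically marginal; fall back to the raw vertex
        log.warning("parsimonious refinement failed (%s); returning unrefined solution", status)
        return prog.solution(res.x, z_star, "optimal")
    return prog.solution(x, z_star, "optimal")


def fva(
    model: StoichiometricModel,
    biomass_fraction: float = 0.0,
    reactions: list[str] | None = None,
) -> FvaEnvelope:
    """Per-reaction flux ranges at steady state.

    With ``biomass_fraction`` > 0 the biomass flux is floored at that
    fraction of its optimum before the per-reaction min/max pair of LPs.
    """
    if not 0.0 <= biomass_fraction <= 1.0:
        raise ValueError("biomass_fraction must be in [0, 1]")
    prog = ModelProgram(model)
    if biomass_fraction > 0.0:
        if not model.biomass_reaction_id:
            raise ValueError("biomass_fraction > 0 requires a biomass reaction")
        base = fba(model, refine="none")
        if not base.optimal:
            raise ValueError(f"base FBA problem is {base.status}")
        j = prog.index[model.biomass_reaction_id]
        prog.lp.add_lb({j: 1.0}, biomass_fraction * base.objective_value)
    targets = reactions if reactions is not None else model.reaction_ids
    ranges: dict[str, tuple[float, float]] = {}
    for rxn_id in targets:
        j = prog.index[rxn_id]
        c = np.zeros(prog.lp.n)
        c[j] = 1.0
        lo = prog.lp.solve(c, maximize=False)
        hi = prog.lp.solve(c, maximize=True)
        if not (lo.optimal and hi.optimal):
            raise ValueError(f"FVA subproblem for {rxn_id!r} is {lo.status}/{hi.status}")
        vmin, vmax = float(lo.objective), float(hi.objective)
        if vmin > vmax:  # solver jitter on a fixed flux
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rxn_id] = (vmin, vmax)
    return FvaEnvelope(ranges=ranges)


def minimize_total_transport(
    model: StoichiometricModel, fixed: Mapping[str, float] | None = None
) -> FluxSolution:
    """Minimize the sum of absolute exchange (transport) rates.

    ``fixed`` pins selected reaction fluxes (e.g. growth at its optimum)
    before the minimization.  The returned objective value is the achieved
    sum of |v| over exchange reactions.
    """
    work = model.copy()
    for rxn_id, value in (fixed or {}).items():
        rxn = work.reaction(rxn_id)
        rxn.lower_bound = rxn.upper_bound = value
    prog = ModelProgram(work)
    weights = np.zeros(prog.lp.n)
    for r in work.reactions:
        if r.is_exchange:
            weights[prog.index[r.id]] = 1.0
    x, total, status = _min_abs_flux(prog.lp, weights)
    if status != "optimal":
        return FluxSolution(fluxes={}, objective_value=None, status=status)
    return prog.solution(x, total, "optimal")


def knockout_scan(
    model: StoichiometricModel,
    objective: FluxObjective | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Single-gene knockout phenotypes for every gene in the model.

    For each gene, reactions whose GPR evaluates false without it are
    bounded to zero and the FBA optimum re-solved.  Genes whose optimum
    falls below 1e-9 are flagged essential.
    """
    if objective is None:
        objective = FluxObjective.for_reaction(model.biomass_reaction_id, label="growth")
    asts = {r.id: parse_gpr(r.gpr) for r in model.reactions if r.gpr}
    wild_type = fba(model, objective, refine="none")
    rows = []
    for gene in genes if genes is not None else model.genes:
        ko = {gene}
        disabled = [rxn_id for rxn_id, ast in asts.items() if not evaluate_gpr(ast, ko)]
        if not disabled:
            value, status = wild_type.objective_value, wild_type.status
        else:
            mutant = model.copy()
            for rxn_id in disabled:
                rxn = mutant.reaction(rxn_id)
                rxn.lower_bound = rxn.upper_bound = 0.0
            sol = fba(mutant, objective, refine="none")
            value, status = sol.objective_value, sol.status
        essential = status != "optimal" or abs(value) < ESSENTIALITY_THRESHOLD
        rows.append(
            {"gene": gene, "status": status, "objective_value": value,
             "n_disabled_reactions": len(disabled), "essential": essential}
        )
    return pd.DataFrame(rows)


def doubling_time(mu: float) -> float:
    """Doubling time ln(2)/mu in hours for a growth rate mu in 1/h."""
    if mu <= 0:
        raise ValueError(f"growth rate must be positive, got {mu}")
    return math.log(2.0) / mu


def fit_uptake_to_target(
    model: StoichiometricModel,
    dial: str,
    objective: FluxObjective,
    target: float,
    tol: float = 1e-6,
    bracket: tuple[float, float] = (0.0, 1e3),
    max_iter: int = 200,
) -> float:
    """Find the uptake cap on one exchange at which the FBA optimum hits a target.

    Bisection over the uptake capacity of ``dial`` (lower bound set to minus
    the cap), assuming the optimum is monotone non-decreasing in the cap.
    Raises if the target lies outside the achievable range of the bracket.
    """
    rxn = model.reaction(dial)
    if not rxn.is_exchange:
        raise ValueError(f"{dial!r} is not an exchange reaction")

    def optimum(cap: float) -> float:
        work = model.copy()
        r = work.reaction(dial)
        r.lower_bound = -cap
        sol = fba(work, objective, refine="none")
        if not sol.optimal:
            raise ValueError(f"FBA {sol.status} at {dial} uptake cap {cap}")
        return sol.objective_value

    lo, hi = bracket
    f_lo, f_hi = optimum(lo), optimum(hi)
    log.info("fit_uptake_to_target: bracket [%g, %g] -> objective [%g, %g]", lo, hi, f_lo, f_hi)
    if not (min(f_lo, f_hi) - tol <= target <= max(f_lo, f_hi) + tol):
        raise ValueError(
            f"target {target} outside achievable range [{f_lo}, {f_hi}] "
            f"for {dial} caps in [{lo}, {hi}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = optimum(mid)
        if abs(f_mid - target) <= tol or (hi - lo) < max(tol * 1e-3, 1e-12):
            return mid
        if (f_mid < target) == (f_lo <= f_hi):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)
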