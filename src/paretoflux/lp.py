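"""Thin internal LP interface over scipy's HiGHS solver.

One abstraction point for every linear program in the package (FBA, FVA,
absolute-value minimizations, NNC lattice solves), so that solver choice
and tolerances live in a single place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = ["LinearProblem", "LpResult", "SOLVER_ID", "FEASIBILITY_TOL", "ZERO_FLUX_TOL"]

SOLVER_ID = "scipy-highs"
FEASIBILITY_TOL = 1e-9
ZERO_FLUX_TOL = 1e-9


@dataclass
class LpResult:
    status: str  # optimal | infeasible | unbounded
    x: np.ndarray | None
    objective: float | None
    #: dual values, populated for optimal solutions
    duals_eq: np.ndarray | None = None
    duals_ub: np.ndarray | None = None
    duals_lower: np.ndarray | None = None
    duals_upper: np.ndarray | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class LinearProblem:
    """min/max c.x subject to A_eq x = b_eq, A_ub x <= b_ub, lb <= x <= ub."""

    lower: np.ndarray
    upper: np.ndarray
    eq_rows: list[tuple[dict[int, float], float]] = field(default_factory=list)
    ub_rows: list[tuple[dict[int, float], float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.lower)

    def add_eq(self, coeffs: dict[int, float], rhs: float) -> None:
        self.eq_rows.append((dict(coeffs), rhs))

    def add_ub(self, coeffs: dict[int, float], rhs: float) -> None:
        """a.x <= rhs"""
        self.ub_rows.append((dict(coeffs), rhs))

    def add_lb(self, coeffs: dict[int, float], rhs: float) -> None:
        """a.x >= rhs"""
        self.ub_rows.append(({i: -c for i, c in coeffs.items()}, -rhs))

    def copy(self) -> "LinearProblem":
        return LinearProblem(
            self.lower.copy(),
            self.upper.copy(),
            [(dict(c), r) for c, r in self.eq_rows],
            [(dict(c), r) for c, r in self.ub_rows],
        )

    def _dense(self, rows) -> tuple[np.ndarray, np.ndarray]:
        A = np.zeros((len(rows), self.n))
        b = np.zeros(len(rows))
        for i, (coeffs, rhs) in enumerate(rows):
            for j, c in coeffs.items():
                A[i, j] = c
            b[i] = rhs
        return A, b

    def solve(self, c: np.ndarray, maximize: bool = False) -> LpResult:
        sign = -1.0 if maximize else 1.0
        A_eq = b_eq = A_ub = b_ub = None
        if self.eq_rows:
            A_eq, b_eq = self._dense(self.eq_rows)
        if self.ub_rows:
            A_ub, b_ub = self._dense(self.ub_rows)
        res = linprog(
            sign * np.asarray(c, dtype=float),
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=np.column_stack([self.lower, self.upper]),
            method="highs",
            options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
        )
        status = _STATUS.get(res.status, "error")
        if status != "optimal":
            return LpResult(status=status, x=None, objective=None)
        return LpResult(
            status="optimal",
            x=res.x,
            objective=sign * res.fun,
            duals_eq=(sign * res.eqlin.marginals if self.eq_rows else None),
            duals_ub=(sign * res.ineqlin.marginals if self.ub_rows else None),
            duals_lower=sign * res.lower.marginals,
            duals_upper=sign * res.upper.marginals,
        )
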