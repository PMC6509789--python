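"""Multi-objective flux analysis via the Normalized Normal Constraint method.

Given n linear flux objectives on a stoichiometric model, the solver

1. computes the n anchor points (the single-objective "archetypes", each
   refined to the parsimonious member of its alternate optima),
2. normalizes objective space so that, in maximization sense, anchor k
   attains 1.0 in coordinate k and the worst anchor value (the nadir) maps
   to 0 — making the front independent of objective scales,
3. lays an even simplex lattice of weight vectors over the utopia
   hyperplane spanned by the normalized anchors (spacing 1/m, giving
   C(m+n-1, n-1) points),
4. at each lattice point p adds the n-1 normal half-space constraints
   (e_n - e_k).(z - p) <= 0 built from the utopia-plane direction vectors
   and maximizes the remaining (last) objective, and
5. filters the collected solutions for duplicates and Pareto dominance.

Infeasible lattice points are expected for non-convex reachable sets and
are recorded, not fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fba import FluxObjective, FluxSolution, ModelProgram, _min_abs_flux, fba
from .lp import SOLVER_ID
from .model import StoichiometricModel

__all__ = [
    "MofaProblem",
    "NncGeometry",
    "ParetoPoint",
    "ParetoFront",
    "compute_anchor_points",
    "generate_utopia_lattice",
    "solve_lattice_point",
    "pareto_filter",
    "run_mofa",
    "export_front",
    "load_front",
    "render_front",
]

log = logging.getLogger(__name__)

DOMINANCE_TOL = 1e-6
UNIQUE_DECIMALS = 6


@dataclass
class MofaProblem:
    model: StoichiometricModel
    objectives: Sequence[FluxObjective]
    spacing: int = 10

    def __post_init__(self) -> None:
        if len(self.objectives) < 2:
            raise ValueError("multi-objective analysis needs n >= 2 objectives")
        if self.spacing < 1:
            raise ValueError("spacing m must be >= 1")
        labels = [o.label for o in self.objectives]
        if len(set(labels)) != len(labels):
            raise ValueError(f"objective labels must be unique, got {labels}")

    @property
    def n(self) -> int:
        return len(self.objectives)


@dataclass
class NncGeometry:
    """Anchor points and the affine normalization of objective space."""

    #: anchor k's raw objective vector (row k), paper sense
    anchor_points: np.ndarray
    #: per-objective best value over anchors, maximization sense
    utopia_point: np.ndarray
    #: per-objective worst value over anchors, maximization sense
    nadir_point: np.ndarray
    #: senses (+1 maximize, -1 minimize) per objective
    senses: np.ndarray
    anchor_fluxes: list[FluxSolution] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.utopia_point)

    @property
    def span(self) -> np.ndarray:
        d = self.utopia_point - self.nadir_point
        return np.where(np.abs(d) > 1e-12, d, 1.0)  # degenerate objective guard

    def normalize(self, raw: np.ndarray) -> np.ndarray:
        """Map a raw objective vector to [0, 1]^n (maximization sense)."""
        return (self.senses * raw - self.nadir_point) / self.span

    @property
    def normalized_anchors(self) -> np.ndarray:
        return np.vstack([self.normalize(a) for a in self.anchor_points])


@dataclass
class ParetoPoint:
    lattice_weights: np.ndarray
    objective_values: np.ndarray  # raw, paper sense
    normalized: np.ndarray
    flux: FluxSolution


@dataclass
class ParetoFront:
    objectives: list[str]
    solutions: list[ParetoPoint]
    skipped: list[np.ndarray]
    geometry: NncGeometry
    provenance: dict = field(default_factory=dict)

    @property
    def n_unique(self) -> int:
        return len(self.solutions)


# ---------------------------------------------------------------------------

def compute_anchor_points(problem: MofaProblem) -> NncGeometry:
    """Anchor k = lexicographic optimum of objective k (then min total flux)."""
    n = problem.n
    anchors = np.zeros((n, n))
    fluxes: list[FluxSolution] = []
    for k, obj in enumerate(problem.objectives):
        sol = fba(problem.model, obj, refine="min_total_flux")
        if not sol.optimal:
            raise ValueError(
                f"anchor for objective {obj.label!r} is {sol.status}; "
                "cap the relevant exchange bounds to keep every objective bounded"
            )
        anchors[k] = [o.value(sol.fluxes) for o in problem.objectives]
        fluxes.append(sol)
    senses = np.array([o.sense for o in problem.objectives])
    hatted = anchors * senses  # maximization sense
    return NncGeometry(
        anchor_points=anchors,
        utopia_point=hatted.max(axis=0),
        nadir_point=hatted.min(axis=0),
        senses=senses,
        anchor_fluxes=fluxes,
    )


def generate_utopia_lattice(n: int, m: int) -> list[np.ndarray]:
    """Even simplex lattice: all w with w_i in {0, 1/m, ..., 1}, sum w = 1.

    Deterministic lexicographic order; C(m+n-1, n-1) points.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 objectives and spacing m >= 1")
    out: list[np.ndarray] = []
    point = np.zeros(n)

    def rec(k: int, remaining: int) -> None:
        if k == n - 1:
            point[k] = remaining / m
            out.append(point.copy())
            return
        for steps in range(remaining + 1):
            point[k] = steps / m
            rec(k + 1, remaining - steps)

    rec(0, m)
    assert len(out) == comb(m + n - 1, n - 1)
    return out


def solve_lattice_point(
    problem: MofaProblem,
    geometry: NncGeometry,
    weights: np.ndarray,
    refine: bool = True,
) -> ParetoPoint | None:
    """One NNC subproblem; None when the lattice point is infeasible.

    In normalized all-maximize space the utopia-plane point is
    p = sum_k w_k e_k over normalized anchors e_k.  The n-1 half-spaces
    (e_n - e_k).(z - p) <= 0 (k < n) cut the reachable set down to the slab
    normal to the utopia plane through p; the last objective is then
    maximized (and the flux vector refined to minimum total flux).  The
    inequality direction is the Messac normal constraint transformed to
    maximization sense (z = 1 - mu for the canonical minimization form),
    and is what makes corner weights recover the anchors exactly.
    """
    n = problem.n
    ebar = geometry.normalized_anchors
    p = weights @ ebar

    prog = ModelProgram(problem.model)
    # normalized objective k as an affine function of fluxes:
    #   zbar_k(v) = (s_k * c_k . v - nadir_k) / span_k
    span = geometry.span
    lin_rows = []  # per objective: (dict reaction-index -> coef, offset)
    for k, obj in enumerate(problem.objectives):
        row = {
            prog.index[r]: geometry.senses[k] * c / span[k]
            for r, c in obj.coefficients.items()
        }
        lin_rows.append((row, -geometry.nadir_point[k] / span[k]))
    for k in range(n - 1):
        a = ebar[n - 1] - ebar[k]
        coeffs: dict[int, float] = {}
        rhs = float(a @ p)
        for i in range(n):
            if abs(a[i]) < 1e-15:
                continue
            row, offset = lin_rows[i]
            for j, c in row.items():
                coeffs[j] = coeffs.get(j, 0.0) + a[i] * c
            rhs -= a[i] * offset
        prog.lp.add_ub(coeffs, rhs)

    last = problem.objectives[-1]
    c = prog.cost(last.coefficients)
    res = prog.lp.solve(c, maximize=last.direction == "maximize")
    if not res.optimal:
        return None
    if refine:
        pinned = prog.lp.copy()
        pinned.add_eq({j: c[j] for j in np.nonzero(c)[0]}, float(res.objective))
        x, _, status = _min_abs_flux(pinned, np.ones(pinned.n))
        if status != "optimal":
            x = res.x
    else:
        x = res.x
    flux = prog.solution(x, float(res.objective), "optimal")
    raw = np.array([o.value(flux.fluxes) for o in problem.objectives])
    return ParetoPoint(
        lattice_weights=np.asarray(weights, dtype=float),
        objective_values=raw,
        normalized=geometry.normalize(raw),
        flux=flux,
    )


def pareto_filter(points: list[ParetoPoint], tol: float = DOMINANCE_TOL) -> list[ParetoPoint]:
    """Drop duplicate and dominated solutions (maximization sense), stable order.

    Duplicates are detected on normalized vectors rounded to 6 decimals;
    dominance requires >= in every coordinate and > tol in at least one.
    """
    unique: list[ParetoPoint] = []
    seen: set[tuple] = set()
    for pt in points:
        key = tuple(np.round(pt.normalized, UNIQUE_DECIMALS))
        if key not in seen:
            seen.add(key)
            unique.append(pt)
    keep = []
    for i, a in enumerate(unique):
        dominated = False
        for j, b in enumerate(unique):
            if i == j:
                continue
            if np.all(b.normalized >= a.normalized - tol) and np.any(
                b.normalized > a.normalized + tol
            ):
                dominated = True
                break
        if not dominated:
            keep.append(a)
    return keep


def run_mofa(problem: MofaProblem, refine: bool = True) -> ParetoFront:
    """Full NNC pipeline: anchors, lattice, per-point solves, Pareto filter."""
    geometry = compute_anchor_points(problem)
    lattice = generate_utopia_lattice(problem.n, problem.spacing)
    log.info(
        "MOFA: %d objectives, spacing %d -> %d lattice points",
        problem.n, problem.spacing, len(lattice),
    )
    solutions: list[ParetoPoint] = []
    skipped: list[np.ndarray] = []
    for weights in lattice:
        pt = solve_lattice_point(problem, geometry, weights, refine=refine)
        if pt is None:
            skipped.append(np.asarray(weights))
        else:
            solutions.append(pt)
    filtered = pareto_filter(solutions)
    log.info(
        "MOFA: %d solved, %d infeasible, %d unique Pareto-optimal",
        len(solutions), len(skipped), len(filtered),
    )
    return ParetoFront(
        objectives=[o.label for o in problem.objectives],
        solutions=filtered,
        skipped=skipped,
        geometry=geometry,
        provenance={
            "spacing": problem.spacing,
            "n_objectives": problem.n,
            "n_lattice": len(lattice),
            "n_skipped": len(skipped),
            "dominance_tol": DOMINANCE_TOL,
            "solver": SOLVER_ID,
        },
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _front_frame(front: ParetoFront) -> pd.DataFrame:
    rows = []
    for pt in front.solutions:
        row: dict[str, float] = {}
        for k, label in enumerate(front.objectives):
            row[f"w_{label}"] = pt.lattice_weights[k]
        for k, label in enumerate(front.objectives):
            row[f"norm_{label}"] = pt.normalized[k]
        for k, label in enumerate(front.objectives):
            row[f"raw_{label}"] = pt.objective_values[k]
        rows.append(row)
    return pd.DataFrame(rows)


def export_front(front: ParetoFront, path: str | Path) -> None:
    """TSV matrix of the front: lattice weights, normalized and raw values."""
    if not front.solutions:
        raise ValueError("refusing to export an empty Pareto front")
    _front_frame(front).to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_front(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def render_front(front: ParetoFront, path: str | Path) -> None:
    """Static heat-map rendering of the normalized front (one row per solution)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = _front_frame(front)
    norm_cols = [c for c in frame.columns if c.startswith("norm_")]
    data = frame[norm_cols].to_numpy()
    order = np.argsort(-data[:, 0])
    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.05 * len(data) + 1)))
    im = ax.imshow(data[order], aspect="auto", cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(norm_cols)))
    ax.set_xticklabels([c[5:] for c in norm_cols], rotation=45, ha="right")
    ax.set_ylabel("Pareto-optimal solutions")
    fig.colorbar(im, ax=ax, label="normalized objective value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
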