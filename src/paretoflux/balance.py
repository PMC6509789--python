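"""Elemental-formula algebra, degree-of-reduction accounting, and balance checks.

The degree of reduction kappa of a compound is the number of available
electron equivalents per carbon mole, computed with the Roels valence
convention (C=+4, H=+1, O=-2, N=-3, S=+6, P=+5, minus the net charge).
Reference points: CO2 has kappa = 0, acetate kappa = 4, typical microbial
biomass kappa ~ 4.2.  The same arithmetic drives whole-reaction element /
charge balance checks and the boundary electron balance of flux solutions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .model import StoichiometricModel
    from .fba import FluxSolution

__all__ = [
    "ElementalFormula",
    "BalanceReport",
    "parse_formula",
    "degree_of_reduction",
    "electron_content",
    "check_overall_equation",
    "check_reaction_balance",
    "check_model_balance",
    "boundary_electron_balance",
]

# Roels valences: electrons made available per atom relative to the
# reference redox states H2O, CO2, NH3, SO4(2-), PO4(3-).
ROELS_VALENCE = {"C": 4.0, "H": 1.0, "O": -2.0, "N": -3.0, "S": 6.0, "P": 5.0}

_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba W Pt Au Hg Pb U".split()
)

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d+(?:\.\d+)?|\.\d+)?")
_CHARGE_RE = re.compile(r"([+-])(\d+)?$")


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formulas."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element counts (real-valued, e.g. per-C-mole biomass) plus net charge."""

    counts: Mapping[str, float]
    charge: float = 0.0

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("formula must contain at least one element")
        for el, n in self.counts.items():
            if el not in _ELEMENTS:
                raise FormulaError(f"unknown element symbol {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}")
        object.__setattr__(self, "counts", dict(self.counts))

    def __getitem__(self, element: str) -> float:
        return self.counts.get(element, 0.0)

    @property
    def carbon(self) -> float:
        return self.counts.get("C", 0.0)

    def __str__(self) -> str:
        body = "".join(
            f"{el}{_fmt(n)}" for el, n in sorted(self.counts.items(), key=_hill_key)
        )
        if self.charge:
            sign = "+" if self.charge > 0 else "-"
            mag = abs(self.charge)
            body += sign if mag == 1 else f"{sign}{_fmt(mag)}"
        return body


def _hill_key(item: tuple[str, float]) -> tuple[int, str]:
    # Hill order: C first, H second, then alphabetical.
    order = {"C": 0, "H": 1}
    return (order.get(item[0], 2), item[0])


def _fmt(n: float) -> str:
    if n == int(n):
        return "" if n == 1 else str(int(n))
    return f"{n:g}"


def parse_formula(text: str) -> ElementalFormula:
    """Parse Hill-style notation with real subscripts and a trailing charge.

    Accepts e.g. ``CO2``, ``CH1.93O0.54N0.22``, ``NH4+``, ``SO4-2``, ``Fe+3``.
    """
    s = text.strip()
    if not s:
        raise FormulaError("empty formula")
    charge = 0.0
    m = _CHARGE_RE.search(s)
    if m:
        sign, mag = m.groups()
        charge = float(mag or "1") * (1 if sign == "+" else -1)
        s = s[: m.start()]
    counts: dict[str, float] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if not m or m.group(1) not in _ELEMENTS:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0.0) + (float(num) if num else 1.0)
        pos = m.end()
    return ElementalFormula(counts=counts, charge=charge)


def electron_content(f: ElementalFormula) -> float:
    """Available electron equivalents per mole (the Roels numerator).

    Equals kappa times the carbon count for carbon compounds; gives 2 for H2
    and 0 for H2O, NH4+, CO2 by construction.
    """
    total = 0.0
    for el, n in f.counts.items():
        v = ROELS_VALENCE.get(el)
        if v is None:
            raise FormulaError(
                f"element {el!r} has no Roels valence; cannot count electrons"
            )
        total += v * n
    return total - f.charge


def degree_of_reduction(f: ElementalFormula) -> float:
    """Roels degree of reduction kappa, electron equivalents per C-mole."""
    if f.carbon <= 0:
        raise FormulaError("degree of reduction is per C-mole; formula has no carbon")
    return electron_content(f) / f.carbon


@dataclass
class BalanceReport:
    """Per-element and charge residuals (lhs minus rhs) of a conversion."""

    per_element_residual: dict[str, float]
    charge_residual: float
    tolerance: float
    #: populated by model-level checks
    reaction_id: str | None = None
    skipped_reason: str | None = None
    missing_formulas: list[str] = field(default_factory=list)

    @property
    def checked(self) -> bool:
        return self.skipped_reason is None

    @property
    def balanced(self) -> bool:
        """True when every element residual is within tolerance.

        The charge residual is reported but not gating: lumped overall
        equations rounded to two decimals are routinely element-balanced
        while carrying a small net charge imbalance.
        """
        if not self.checked:
            return False
        return all(abs(r) <= self.tolerance for r in self.per_element_residual.values())

    @property
    def worst(self) -> tuple[str, float] | None:
        if not self.per_element_residual:
            return None
        el = max(self.per_element_residual, key=lambda e: abs(self.per_element_residual[e]))
        return el, self.per_element_residual[el]


Side = Iterable[tuple[float, ElementalFormula]]


def check_overall_equation(lhs: Side, rhs: Side, tol: float = 0.02) -> BalanceReport:
    """Balance-check a lumped conversion equation given as coefficient/formula pairs."""
    residual: dict[str, float] = {}
    charge = 0.0
    for sign, side in ((1.0, lhs), (-1.0, rhs)):
        for coef, f in side:
            if coef < 0:
                raise ValueError("coefficients must be non-negative; put species on the other side")
            for el, n in f.counts.items():
                residual[el] = residual.get(el, 0.0) + sign * coef * n
            charge += sign * coef * f.charge
    return BalanceReport(per_element_residual=residual, charge_residual=charge, tolerance=tol)


def check_reaction_balance(
    model: "StoichiometricModel", reaction_id: str, tol: float = 1e-6
) -> BalanceReport:
    """Element/charge balance of one model reaction.

    Exchange (boundary) reactions are skipped, massless pseudo-metabolites
    (photons, lumped energy tokens) contribute nothing, and a missing formula
    marks the reaction "unchecked" rather than failed.
    """
    rxn = model.reaction(reaction_id)
    if rxn.is_exchange:
        return BalanceReport({}, 0.0, tol, reaction_id=reaction_id, skipped_reason="boundary")
    residual: dict[str, float] = {}
    charge = 0.0
    missing: list[str] = []
    for met_id, coef in rxn.stoichiometry.items():
        met = model.metabolite(met_id)
        if met.is_pseudo:
            continue
        if met.formula is None:
            missing.append(met_id)
            continue
        for el, n in met.formula.counts.items():
            residual[el] = residual.get(el, 0.0) - coef * n
        ch = met.charge if met.charge is not None else met.formula.charge
        charge -= coef * ch
    if missing:
        return BalanceReport(
            {}, 0.0, tol, reaction_id=reaction_id,
            skipped_reason="missing formulas", missing_formulas=missing,
        )
    return BalanceReport(residual, charge, tol, reaction_id=reaction_id)


def check_model_balance(model: "StoichiometricModel", tol: float = 1e-6) -> list[BalanceReport]:
    """Balance reports for every reaction; see check_reaction_balance."""
    return [check_reaction_balance(model, r.id, tol) for r in model.reactions]


def boundary_electron_balance(model: "StoichiometricModel", flux: "FluxSolution") -> float:
    """Net electron-equivalent flow across the model boundary.

    Sums electron content x flux over exchange reactions (export positive).
    Any steady-state flux vector of a fully electron-balanced network returns
    ~0: electrons entering as substrate leave in biomass, H2 or byproducts.
    """
    total = 0.0
    zero = 1e-12
    for rxn in model.reactions:
        if not rxn.is_exchange:
            continue
        v = flux.fluxes.get(rxn.id, 0.0)
        if abs(v) <= zero:
            continue
        (met_id, coef), = rxn.stoichiometry.items()
        met = model.metabolite(met_id)
        if met.is_pseudo:
            continue
        if met.formula is None:
            raise FormulaError(
                f"metabolite {met_id!r} on active exchange {rxn.id!r} has no formula"
            )
        # coef is -1 for the conventional "met ->" exchange; positive flux
        # then means export, so -coef*v is the molar export rate.
        total += electron_content(met.formula) * (-coef) * v
    return total
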