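"""Domain types for constraint-based metabolic models.

A :class:`StoichiometricModel` holds metabolites, reactions (with flux bounds
in mmol/gDW/h and optional boolean gene-protein-reaction rules) and derives
the m x n stoichiometric matrix S used by the LP machinery.  Exchange
reactions follow the community sign convention: a single-metabolite reaction
"met ->" whose positive flux is export and negative flux uptake.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .balance import ElementalFormula

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "MediumConfig",
    "GprError",
    "ModelValidationError",
    "parse_gpr",
    "evaluate_gpr",
    "gpr_genes",
    "apply_medium",
]

UNLIMITED = 1.0e6  # finite big-M standing in for "unbounded" exchange capacity


class ModelValidationError(ValueError):
    pass


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: ElementalFormula | None = None
    charge: float | None = None
    is_external: bool = False
    #: massless energy token (photon, lumped ATP equivalent): excluded from
    #: element and electron accounting.
    is_pseudo: bool = False


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = UNLIMITED
    gpr: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


class StoichiometricModel:
    """Metabolites, reactions and the derived stoichiometric matrix."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_reaction_id: str | None = None,
        maintenance_atp_reaction_id: str | None = None,
        id: str = "model",
    ) -> None:
        self.id = id
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.biomass_reaction_id = biomass_reaction_id
        self.maintenance_atp_reaction_id = maintenance_atp_reaction_id
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self.validate()

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            if r.gpr:
                for g in gpr_genes(r.gpr):
                    seen.setdefault(g, None)
        return list(seen)

    # -- matrix ----------------------------------------------------------
    @property
    def S(self) -> np.ndarray:
        """Full m x n stoichiometric matrix (external metabolites included)."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met_id, coef in r.stoichiometry.items():
                S[self._met_index[met_id], j] = coef
        return S

    def steady_state_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Rows of S for internal (balanced) metabolites only, with their ids."""
        keep = [i for i, m in enumerate(self.metabolites) if not m.is_external]
        return self.S[keep, :], [self.metabolites[i].id for i in keep]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        for r in self.reactions:
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
            if r.gpr:
                parse_gpr(r.gpr)  # raises GprError on bad syntax
        if self.biomass_reaction_id and self.biomass_reaction_id not in self._rxn_index:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        for m in self.metabolites:
            if m.is_external:
                for r in self.reactions:
                    if m.id in r.stoichiometry and not r.is_exchange:
                        raise ModelValidationError(
                            f"external metabolite {m.id!r} appears in internal "
                            f"reaction {r.id!r}"
                        )

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            [replace(m) for m in self.metabolites],
            [Reaction(r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound,
                      r.gpr, r.name) for r in self.reactions],
            self.biomass_reaction_id,
            self.maintenance_atp_reaction_id,
            id=self.id,
        )

    def __repr__(self) -> str:
        return (f"StoichiometricModel({self.id!r}, {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions)")


# ---------------------------------------------------------------------------
# GPR rules: boolean expressions over gene ids; AND = enzyme complex,
# OR = isozymes.
# ---------------------------------------------------------------------------

class GprError(ValueError):
    pass


_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")

# AST: ("and", [children]) | ("or", [children]) | ("gene", id)
GprAst = tuple


def parse_gpr(text: str) -> GprAst:
    tokens = _GPR_TOKEN.findall(text)
    if not tokens:
        raise GprError("empty GPR expression")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprAst:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and() -> GprAst:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_atom() -> GprAst:
        tok = peek()
        if tok is None:
            raise GprError(f"unexpected end of GPR expression {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GprError(f"unbalanced parentheses in {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprError(f"unexpected token {tok!r} in {text!r}")
        return ("gene", take())

    node = parse_or()
    if pos != len(tokens):
        raise GprError(f"trailing tokens in GPR expression {text!r}")
    return node


def gpr_genes(gpr: str | GprAst) -> list[str]:
    node = parse_gpr(gpr) if isinstance(gpr, str) else gpr
    out: list[str] = []

    def walk(n: GprAst) -> None:
        if n[0] == "gene":
            if n[1] not in out:
                out.append(n[1])
        else:
            for child in n[1]:
                walk(child)

    walk(node)
    return out


def evaluate_gpr(gpr: str | GprAst, knocked_out: set[str] | frozenset[str]) -> bool:
    """True iff the rule still evaluates true with the given genes removed."""
    node = parse_gpr(gpr) if isinstance(gpr, str) else gpr

    def walk(n: GprAst) -> bool:
        kind = n[0]
        if kind == "gene":
            return n[1] not in knocked_out
        if kind == "and":
            return all(walk(c) for c in n[1])
        return any(walk(c) for c in n[1])

    return walk(node)


# ---------------------------------------------------------------------------
# Medium configuration
# ---------------------------------------------------------------------------

@dataclass
class MediumConfig:
    """Exchange-reaction bounds, mmol/gDW/h, export-positive convention.

    Exchanges absent from ``entries`` are closed to uptake (lower bound 0)
    but left open to export, unless ``close_unlisted_exports`` is set.
    """

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)
    close_unlisted_exports: bool = False

    def __post_init__(self) -> None:
        for ex_id, (lb, ub) in self.entries.items():
            if lb > ub:
                raise ModelValidationError(f"medium entry {ex_id!r}: bounds out of order")

    @classmethod
    def from_dict(cls, data: Mapping) -> "MediumConfig":
        """Build from the YAML dialect::

            exchanges:
              EX_ac: {uptake_max: 1.96}
              EX_photon: {uptake_max: unlimited}
              EX_co2: {export_fixed: 0.23}
        """
        exchanges = data.get("exchanges", data)
        entries: dict[str, tuple[float, float]] = {}
        for ex_id, spec in exchanges.items():
            if spec is None:
                spec = {}
            if not isinstance(spec, Mapping):
                raise ModelValidationError(
                    f"medium entry {ex_id!r}: expected a mapping, got {spec!r}"
                )
            lb, ub = 0.0, UNLIMITED

            def num(v: object) -> float:
                if isinstance(v, str) and v.lower() in ("unlimited", "inf"):
                    return UNLIMITED
                return float(v)  # type: ignore[arg-type]

            if "lower" in spec:
                lb = num(spec["lower"])
            if "upper" in spec:
                ub = num(spec["upper"])
            if "uptake_max" in spec:
                lb = -num(spec["uptake_max"])
            if "uptake_min" in spec:
                ub = min(ub, -num(spec["uptake_min"]))
            if "export_max" in spec:
                ub = num(spec["export_max"])
            if "uptake_fixed" in spec:
                lb = ub = -num(spec["uptake_fixed"])
            if "export_fixed" in spec:
                lb = ub = num(spec["export_fixed"])
            entries[ex_id] = (lb, ub)
        return cls(entries=entries, close_unlisted_exports=bool(data.get("close_unlisted_exports", False)))


def apply_medium(model: StoichiometricModel, medium: MediumConfig) -> StoichiometricModel:
    """Return a copy of the model with exchange bounds set from the medium.

    Raises if a configured id does not resolve to an exchange reaction.
    """
    out = model.copy()
    exchange_ids = {r.id for r in out.exchange_reactions}
    for ex_id in medium.entries:
        if ex_id not in exchange_ids:
            raise ModelValidationError(
                f"medium entry {ex_id!r} is not an exchange reaction of the model"
            )
    for rxn in out.reactions:
        if not rxn.is_exchange:
            continue
        if rxn.id in medium.entries:
            rxn.lower_bound, rxn.upper_bound = medium.entries[rxn.id]
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
            if medium.close_unlisted_exports:
                rxn.upper_bound = 0.0
    return out
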