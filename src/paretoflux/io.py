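"""Readers and writers: SBML (Level 2/3, fbc), a tabular model dialect, and
YAML/TSV configs.

The tabular dialect is a TSV with columns ``reaction_id, equation, lower,
upper, gpr`` where equations look like ``ac + 3 atp -> c + 2 red`` (``->``,
``→`` and ``<->`` all accepted; an empty side denotes an exchange).  Lines
beginning with ``#`` may carry ``key: value`` metadata (``biomass``,
``maintenance``) and ``#met`` lines attach formulas, charges, compartments
and flags to metabolites.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Mapping

import yaml

from .balance import ElementalFormula, parse_formula
from .model import (
    MediumConfig,
    Metabolite,
    ModelValidationError,
    Reaction,
    StoichiometricModel,
    UNLIMITED,
    gpr_genes,
    parse_gpr,
)

__all__ = [
    "read_sbml",
    "write_sbml",
    "read_tabular_model",
    "write_tabular_model",
    "read_medium",
    "read_objectives",
    "read_expression",
]

_ANNOT_NS = "https://paretoflux.invalid/ns"


class SbmlError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _import_libsbml():
    import libsbml  # deferred: only needed for SBML paths

    return libsbml


def read_sbml(
    path: str | Path,
    biomass_reaction: str | None = None,
    maintenance_reaction: str | None = None,
    bounds_sidecar: str | Path | None = None,
) -> StoichiometricModel:
    """Read an SBML L2/L3 model.

    Flux bounds come from the fbc package when present, else from
    kinetic-law parameters (LOWER_BOUND/UPPER_BOUND), else from a sidecar
    YAML mapping reaction ids to ``[lower, upper]``.
    """
    libsbml = _import_libsbml()
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SbmlError(
                f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
            )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SbmlError(f"{path}: file contains no SBML model")
    fbc = sbml_model.getPlugin("fbc")

    sidecar: dict[str, tuple[float, float]] = {}
    if bounds_sidecar is not None:
        raw = yaml.safe_load(Path(bounds_sidecar).read_text())
        sidecar = {k: (float(v[0]), float(v[1])) for k, v in raw.items()}

    metabolites = []
    for sp in sbml_model.getListOfSpecies():
        formula = None
        charge = None
        sp_fbc = sp.getPlugin("fbc")
        if sp_fbc is not None and sp_fbc.isSetChemicalFormula():
            try:
                formula = parse_formula(sp_fbc.getChemicalFormula())
            except ValueError:
                formula = None
        if sp_fbc is not None and sp_fbc.isSetCharge():
            charge = float(sp_fbc.getCharge())
        is_pseudo = False
        if sp.isSetAnnotation():
            is_pseudo = "paretoflux:massless" in sp.getAnnotationString()
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                formula=formula,
                charge=charge,
                is_external=bool(sp.getBoundaryCondition()),
                is_pseudo=is_pseudo,
            )
        )
    met_ids = {m.id for m in metabolites}

    def resolve_bounds(rxn) -> tuple[float, float]:
        rxn_fbc = rxn.getPlugin("fbc")
        if rxn_fbc is not None and rxn_fbc.isSetLowerFluxBound():
            lo = sbml_model.getParameter(rxn_fbc.getLowerFluxBound())
            hi = sbml_model.getParameter(rxn_fbc.getUpperFluxBound())
            if lo is not None and hi is not None:
                return _clip(lo.getValue()), _clip(hi.getValue())
        kl = rxn.getKineticLaw()
        if kl is not None:
            lo = kl.getParameter("LOWER_BOUND")
            hi = kl.getParameter("UPPER_BOUND")
            if lo is not None and hi is not None:
                return _clip(lo.getValue()), _clip(hi.getValue())
        if rxn.getId() in sidecar:
            return sidecar[rxn.getId()]
        # last resort: infer from declared reversibility
        if rxn.isSetReversible() or kl is not None:
            return (-UNLIMITED if rxn.getReversible() else 0.0), UNLIMITED
        raise SbmlError(f"reaction {rxn.getId()!r} has no resolvable flux bounds")

    unresolved: list[str] = []
    reactions = []
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            if ref.getSpecies() in met_ids:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            if ref.getSpecies() in met_ids:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        try:
            lb, ub = resolve_bounds(rxn)
        except SbmlError:
            unresolved.append(rxn.getId())
            continue
        gpr = None
        rxn_fbc = rxn.getPlugin("fbc")
        if rxn_fbc is not None:
            assoc = rxn_fbc.getGeneProductAssociation()
            if assoc is not None:
                gpr = _association_to_gpr(assoc.getAssociation(), sbml_model)
        reactions.append(
            Reaction(rxn.getId(), stoich, lb, ub, gpr=gpr, name=rxn.getName() or "")
        )
    if unresolved:
        raise SbmlError(f"reactions without resolvable bounds: {unresolved}")

    if biomass_reaction is None and fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass_reaction = obj.getFluxObjective(0).getReaction()

    return StoichiometricModel(
        metabolites,
        reactions,
        biomass_reaction_id=biomass_reaction,
        maintenance_atp_reaction_id=maintenance_reaction,
        id=sbml_model.getId() or Path(path).stem,
    )


def _clip(v: float) -> float:
    if math.isinf(v):
        return math.copysign(UNLIMITED, v)
    return v


def _association_to_gpr(assoc, sbml_model) -> str | None:
    import libsbml

    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gp = sbml_model.getPlugin("fbc").getGeneProduct(assoc.getGeneProduct())
        return gp.getLabel() or gp.getId() if gp is not None else assoc.getGeneProduct()
    op = "and" if assoc.isFbcAnd() else "or"
    parts = [
        _association_to_gpr(assoc.getAssociation(i), sbml_model)
        for i in range(assoc.getNumAssociations())
    ]
    return "(" + f" {op} ".join(p for p in parts if p) + ")"


def write_sbml(model: StoichiometricModel, path: str | Path) -> None:
    """Write SBML L3V1 with the fbc v2 package (bounds, formulas, GPRs)."""
    if not model.reactions or not model.metabolites:
        raise ModelValidationError("refusing to write an empty model")
    libsbml = _import_libsbml()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.id))
    model_fbc = sbml_model.getPlugin("fbc")
    model_fbc.setStrict(False)

    compartments = {m.compartment for m in model.metabolites}
    for cid in sorted(compartments):
        comp = sbml_model.createCompartment()
        comp.setId(_sid(cid))
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(_sid(m.id))
        sp.setName(m.name or m.id)
        sp.setCompartment(_sid(m.compartment))
        sp.setBoundaryCondition(m.is_external)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        sp_fbc = sp.getPlugin("fbc")
        if m.formula is not None:
            sp_fbc.setChemicalFormula(_sbml_formula(m.formula))
        ch = m.charge if m.charge is not None else (m.formula.charge if m.formula else None)
        if ch is not None and ch == int(ch):
            sp_fbc.setCharge(int(ch))
        if m.is_pseudo:
            sp.setMetaId(f"meta_{_sid(m.id)}")
            sp.appendAnnotation(
                f'<paretoflux:massless xmlns:paretoflux="{_ANNOT_NS}">true</paretoflux:massless>'
            )

    # fbc flux-bound parameters, deduplicated by value
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    gene_ids: dict[str, str] = {}
    for g in model.genes:
        gp = model_fbc.createGeneProduct()
        gp.setId(_sid(f"G_{g}"))
        gp.setLabel(g)
        gene_ids[g] = _sid(f"G_{g}")

    for r in model.reactions:
        rxn = sbml_model.createReaction()
        rxn.setId(_sid(r.id))
        rxn.setName(r.name or r.id)
        rxn.setReversible(r.lower_bound < 0)
        rxn.setFast(False)
        for met_id, coef in r.stoichiometry.items():
            ref = rxn.createReactant() if coef < 0 else rxn.createProduct()
            ref.setSpecies(_sid(met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rxn_fbc = rxn.getPlugin("fbc")
        rxn_fbc.setLowerFluxBound(bound_param(r.lower_bound))
        rxn_fbc.setUpperFluxBound(bound_param(r.upper_bound))
        if r.gpr:
            assoc = rxn_fbc.createGeneProductAssociation()
            assoc.setAssociation(_gpr_to_infix(r.gpr, gene_ids), True, False)

    if model.biomass_reaction_id:
        obj = model_fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sid(model.biomass_reaction_id))
        fo.setCoefficient(1.0)
        model_fbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _sid(raw: str) -> str:
    s = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    return s if re.match(r"[A-Za-z_]", s) else f"_{s}"


def _sbml_formula(f: ElementalFormula) -> str:
    # fbc chemicalFormula forbids charge suffixes; keep counts only.
    parts = []
    for el, n in sorted(f.counts.items(), key=lambda kv: (kv[0] != "C", kv[0] != "H", kv[0])):
        if n == int(n):
            parts.append(el + ("" if n == 1 else str(int(n))))
        else:
            parts.append(f"{el}{n:g}")
    return "".join(parts)


def _gpr_to_infix(gpr: str, gene_ids: Mapping[str, str]) -> str:
    node = parse_gpr(gpr)

    def walk(n) -> str:
        if n[0] == "gene":
            return gene_ids.get(n[1], _sid(f"G_{n[1]}"))
        sep = f" {n[0]} "
        return "(" + sep.join(walk(c) for c in n[1]) + ")"

    return walk(node)


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "<=>", "->", "→")


def _parse_equation(eq: str, line_no: int) -> tuple[dict[str, float], bool]:
    arrow = None
    for a in _ARROWS:
        if a in eq:
            arrow = a
            break
    if arrow is None:
        raise ModelValidationError(f"line {line_no}: equation {eq!r} has no arrow")
    reversible = arrow in ("<->", "<=>")
    lhs_txt, rhs_txt = eq.split(arrow, 1)

    def parse_side(txt: str, sign: float, stoich: dict[str, float]) -> None:
        txt = txt.strip()
        if not txt:
            return
        for term in txt.split("+"):
            term = term.strip()
            if not term:
                raise ModelValidationError(f"line {line_no}: empty term in {eq!r}")
            m = re.match(r"^(\d+(?:\.\d+)?)\s+(\S+)$", term)
            if m:
                coef, met = float(m.group(1)), m.group(2)
            else:
                if re.match(r"^\d", term):
                    raise ModelValidationError(
                        f"line {line_no}: cannot parse term {term!r} in {eq!r}"
                    )
                coef, met = 1.0, term
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    stoich: dict[str, float] = {}
    parse_side(lhs_txt, -1.0, stoich)
    parse_side(rhs_txt, +1.0, stoich)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise ModelValidationError(f"line {line_no}: equation {eq!r} cancels to nothing")
    return stoich, reversible


def read_tabular_model(path: str | Path) -> StoichiometricModel:
    """Parse the TSV model dialect (see module docstring)."""
    meta: dict[str, str] = {}
    met_info: dict[str, dict] = {}
    reactions: list[Reaction] = []
    seen_rxn: set[str] = set()
    text = Path(path).read_text()
    header_skipped = False
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#met"):
            # "#met <id> formula=CH2O2 charge=0 compartment=c pseudo external"
            parts = line.split()
            if len(parts) < 2:
                raise ModelValidationError(f"line {line_no}: malformed #met line")
            info: dict = {}
            for p in parts[2:]:
                if "=" in p:
                    k, v = p.split("=", 1)
                    info[k] = v
                else:
                    info[p] = True
            met_info[parts[1]] = info
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*:\s*(\S+)", line)
            if m:
                meta[m.group(1)] = m.group(2)
            continue
        cols = line.split("\t")
        if not header_skipped and cols[0].strip().lower() == "reaction_id":
            header_skipped = True
            continue
        if len(cols) < 4:
            raise ModelValidationError(
                f"line {line_no}: expected at least 4 tab-separated columns"
            )
        rxn_id = cols[0].strip()
        if rxn_id in seen_rxn:
            raise ModelValidationError(f"line {line_no}: duplicate reaction id {rxn_id!r}")
        seen_rxn.add(rxn_id)
        stoich, reversible = _parse_equation(cols[1].strip(), line_no)
        lower = cols[2].strip()
        upper = cols[3].strip()
        lb = float(lower) if lower else (-UNLIMITED if reversible else 0.0)
        ub = float(upper) if upper else UNLIMITED
        gpr = cols[4].strip() if len(cols) > 4 and cols[4].strip() else None
        reactions.append(Reaction(rxn_id, stoich, lb, ub, gpr=gpr))

    met_ids: dict[str, None] = {}
    for r in reactions:
        for met_id in r.stoichiometry:
            met_ids.setdefault(met_id, None)
    metabolites = []
    for met_id in met_ids:
        info = met_info.get(met_id, {})
        formula = parse_formula(info["formula"]) if "formula" in info else None
        metabolites.append(
            Metabolite(
                id=met_id,
                compartment=str(info.get("compartment", "c")),
                formula=formula,
                charge=float(info["charge"]) if "charge" in info else None,
                is_external=bool(info.get("external", False)),
                is_pseudo=bool(info.get("pseudo", False)),
            )
        )
    return StoichiometricModel(
        metabolites,
        reactions,
        biomass_reaction_id=meta.get("biomass"),
        maintenance_atp_reaction_id=meta.get("maintenance"),
        id=meta.get("id", Path(path).stem),
    )


def write_tabular_model(model: StoichiometricModel, path: str | Path) -> None:
    lines = [f"# id: {model.id}"]
    if model.biomass_reaction_id:
        lines.append(f"# biomass: {model.biomass_reaction_id}")
    if model.maintenance_atp_reaction_id:
        lines.append(f"# maintenance: {model.maintenance_atp_reaction_id}")
    for m in model.metabolites:
        attrs = []
        if m.formula is not None:
            attrs.append(f"formula={_sbml_formula(m.formula)}")
        if m.charge is not None:
            attrs.append(f"charge={m.charge:g}")
        if m.compartment != "c":
            attrs.append(f"compartment={m.compartment}")
        if m.is_pseudo:
            attrs.append("pseudo")
        if m.is_external:
            attrs.append("external")
        if attrs:
            lines.append(f"#met {m.id} " + " ".join(attrs))
    lines.append("reaction_id\tequation\tlower\tupper\tgpr")
    for r in model.reactions:
        lhs = " + ".join(
            _term(-c, met) for met, c in r.stoichiometry.items() if c < 0
        )
        rhs = " + ".join(
            _term(c, met) for met, c in r.stoichiometry.items() if c > 0
        )
        eq = f"{lhs} -> {rhs}".strip()
        lines.append(
            f"{r.id}\t{eq}\t{r.lower_bound:g}\t{r.upper_bound:g}\t{r.gpr or ''}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _term(coef: float, met: str) -> str:
    return met if coef == 1 else f"{coef:g} {met}"


# ---------------------------------------------------------------------------
# Config readers
# ---------------------------------------------------------------------------

def read_medium(path: str | Path) -> MediumConfig:
    data = yaml.safe_load(Path(path).read_text())
    return MediumConfig.from_dict(data or {})


def read_objectives(path: str | Path) -> list:
    """Objectives YAML: a list of {label, direction, reaction | coefficients}."""
    from .fba import FluxObjective

    data = yaml.safe_load(Path(path).read_text())
    if isinstance(data, Mapping):
        data = data.get("objectives", [])
    objectives = []
    for entry in data:
        if "reaction" in entry:
            coefficients = {entry["reaction"]: 1.0}
        else:
            coefficients = {k: float(v) for k, v in entry["coefficients"].items()}
        objectives.append(
            FluxObjective(
                coefficients=coefficients,
                direction=entry.get("direction", "maximize"),
                label=entry.get("label", "|".join(coefficients)),
            )
        )
    return objectives


def read_expression(path: str | Path) -> dict[str, float]:
    """Expression TSV with columns gene_id, log2fc (header optional)."""
    out: dict[str, float] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = re.split(r"[\t,]", line)
        if cols[0].strip().lower() in ("gene_id", "gene"):
            continue
        if len(cols) < 2:
            raise ValueError(f"line {line_no}: expected gene_id and log2fc")
        out[cols[0].strip()] = float(cols[1])
    return out
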