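"""Synthetic toy-phototroph network and named study scenarios.

The toy emulates the architecture of anaerobic photoheterotrophic
metabolism in a purple non-sulfur bacterium: light-driven ATP supply
decoupled from carbon (LHC), acetate assimilation, two CO2-fixation routes
with different ATP costs (a CBB-like and a cheaper rTCA-like one), an
ATP-consuming nitrogenase-like H2-evolving electron sink, and export of a
reduced organic byproduct.  Coefficients are small integers so every LP
optimum is hand-checkable, and every internal reaction is element- and
electron-balanced under the fixture formulas (acetate-carbon kappa 4,
cell-carbon kappa 2, byproduct kappa 4, "red" a 2-electron H2-like carrier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .balance import parse_formula
from .fba import FluxObjective
from .model import (
    MediumConfig,
    Metabolite,
    Reaction,
    StoichiometricModel,
    UNLIMITED,
)

__all__ = ["make_toy", "ScenarioConfig", "paper_scenarios", "TOY_NAME_MAP"]


def make_toy(P: float = 50.0, A: float = 10.0) -> StoichiometricModel:
    """The toy phototroph, parameterized by photon cap P and acetate cap A.

    Both caps are uptake capacities in mmol/gDW/h.  CO2 uptake is closed by
    default (open it to study mixotrophic carbon fixation); H2, byproduct
    and biomass export are free.
    """
    if P < 0 or A < 0:
        raise ValueError("uptake caps must be non-negative")
    metabolites = [
        Metabolite("photon", name="photon", is_pseudo=True),
        Metabolite("atp", name="ATP equivalent", is_pseudo=True),
        Metabolite("ac", name="acetate carbon", formula=parse_formula("CH4O2")),
        Metabolite("c", name="cell carbon", formula=parse_formula("CH2O2")),
        Metabolite("red", name="reducing equivalent", formula=parse_formula("H2")),
        Metabolite("co2", name="carbon dioxide", formula=parse_formula("CO2")),
        Metabolite("h2", name="hydrogen", formula=parse_formula("H2")),
        Metabolite("byp", name="reduced byproduct", formula=parse_formula("CH4O2")),
        Metabolite("biomass", name="biomass", formula=parse_formula("C10H22O20")),
    ]
    reactions = [
        Reaction("LHC", {"photon": -1, "atp": 2}, 0, UNLIMITED, gpr="gLHC"),
        Reaction("ACT", {"ac": -1, "c": 1, "red": 1}, 0, UNLIMITED, gpr="gACT"),
        Reaction("OX", {"c": -1, "co2": 1, "red": 1}, 0, UNLIMITED, gpr="gOX"),
        Reaction("FIX_A", {"co2": -1, "red": -1, "atp": -3, "c": 1}, 0, UNLIMITED,
                 gpr="gCBB", name="CBB-like fixation"),
        Reaction("FIX_B", {"co2": -1, "red": -1, "atp": -2, "c": 1}, 0, UNLIMITED,
                 gpr="gRTCA", name="rTCA-like fixation"),
        Reaction("BIOSYN", {"c": -10, "red": -1, "atp": -15, "biomass": 1}, 0, UNLIMITED),
        Reaction("NIT", {"red": -1, "atp": -2, "h2": 1}, 0, UNLIMITED,
                 gpr="gNIF1 and gNIF2", name="nitrogenase-like H2 evolution"),
        Reaction("BYP", {"c": -1, "red": -1, "byp": 1}, 0, UNLIMITED,
                 gpr="gBYP1 or gBYP2"),
        Reaction("EX_photon", {"photon": -1}, -P, 0.0),
        Reaction("EX_ac", {"ac": -1}, -A, 0.0),
        Reaction("EX_co2", {"co2": -1}, 0.0, UNLIMITED),
        Reaction("EX_h2", {"h2": -1}, 0.0, UNLIMITED),
        Reaction("EX_byp", {"byp": -1}, 0.0, UNLIMITED),
        Reaction("EX_biomass", {"biomass": -1}, 0.0, UNLIMITED),
    ]
    return StoichiometricModel(
        metabolites, reactions, biomass_reaction_id="BIOSYN", id="toy_phototroph"
    )


#: role -> reaction/gene id on the toy; real genome-scale models supply their own
TOY_NAME_MAP: dict[str, str] = {
    "acetate_exchange": "EX_ac",
    "photon_exchange": "EX_photon",
    "co2_exchange": "EX_co2",
    "h2_exchange": "EX_h2",
    "succinate_exchange": "EX_byp",  # the toy's single reduced-byproduct export
    "phb_exchange": "EX_byp",
    "rubisco": "FIX_A",
    "biomass": "BIOSYN",
}


@dataclass
class ScenarioConfig:
    """A named study condition: medium deltas, pins and knockouts by role.

    Role names are resolved against a model through a name map, so the same
    scenario applies to the toy and to a genome-scale reconstruction.
    Unresolvable roles make the scenario inapplicable to that model (skipped
    with a warning by callers), not an error.
    """

    label: str
    description: str
    #: role -> medium spec in the MediumConfig YAML dialect
    medium: dict[str, dict] = field(default_factory=dict)
    #: role -> (lower, upper) pinned flux bounds
    pins: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: roles of reactions forced to zero
    blocked: list[str] = field(default_factory=list)
    objective_role: str = "biomass"
    objective_direction: str = "maximize"
    #: qualitative expectation, for documentation and sanity tests
    expected: str = ""

    def resolve(
        self, model: StoichiometricModel, name_map: Mapping[str, str]
    ) -> tuple[StoichiometricModel, FluxObjective]:
        """Apply the scenario to a model; raises KeyError on unresolvable roles."""
        work = model.copy()
        medium_entries = {}
        for role, spec in self.medium.items():
            medium_entries[_lookup(role, name_map, work)] = spec
        if medium_entries:
            from .model import apply_medium

            cfg = MediumConfig.from_dict({"exchanges": medium_entries})
            # scenario media adjust only the listed exchanges
            for ex_id, bounds in cfg.entries.items():
                rxn = work.reaction(ex_id)
                rxn.lower_bound, rxn.upper_bound = bounds
        for role, (lb, ub) in self.pins.items():
            rxn = work.reaction(_lookup(role, name_map, work))
            rxn.lower_bound, rxn.upper_bound = lb, ub
        for role in self.blocked:
            rxn = work.reaction(_lookup(role, name_map, work))
            rxn.lower_bound = rxn.upper_bound = 0.0
        objective = FluxObjective.for_reaction(
            _lookup(self.objective_role, name_map, work),
            direction=self.objective_direction,
            label=self.objective_role,
        )
        return work, objective


def _lookup(role: str, name_map: Mapping[str, str], model: StoichiometricModel) -> str:
    rxn_id = name_map.get(role, role)
    if not model.has_reaction(rxn_id):
        raise KeyError(f"role {role!r} -> {rxn_id!r} not present in model {model.id!r}")
    return rxn_id


# Measured/fitted condition parameters for photoheterotrophic acetate growth:
# acetate uptake 1.96 mmol/gDW/h, CO2 export 0.23 mmol/gDW/h, and the fitted
# light-limited photon uptake of 36.6 mmol/gDW/h.
ACETATE_UPTAKE = 1.96
CO2_EXPORT = 0.23
PHOTON_UPTAKE_FIT = 36.6


def paper_scenarios() -> list[ScenarioConfig]:
    """The study's condition ladder as reusable configs.

    Each config is resolved against a target model (toy or genome-scale)
    with a role/name map at run time.
    """
    return [
        ScenarioConfig(
            label="A-carbon-limited-archetype",
            description=(
                "Growth archetype with acetate uptake fixed at the measured "
                f"{ACETATE_UPTAKE} mmol/gDW/h and unlimited photons."
            ),
            medium={
                "acetate_exchange": {"uptake_fixed": ACETATE_UPTAKE},
                "photon_exchange": {"uptake_max": "unlimited"},
            },
            expected="fast growth, no reduced-byproduct export",
        ),
        ScenarioConfig(
            label="B-co2-pinned",
            description=(
                f"As A, with CO2 export pinned to the measured {CO2_EXPORT} "
                "mmol/gDW/h."
            ),
            medium={
                "acetate_exchange": {"uptake_fixed": ACETATE_UPTAKE},
                "photon_exchange": {"uptake_max": "unlimited"},
            },
            pins={"co2_exchange": (CO2_EXPORT, CO2_EXPORT)},
            expected="growth slower than A",
        ),
        ScenarioConfig(
            label="C-cbb-off",
            description="As A with the CBB carboxylation route blocked.",
            medium={
                "acetate_exchange": {"uptake_fixed": ACETATE_UPTAKE},
                "photon_exchange": {"uptake_max": "unlimited"},
            },
            blocked=["rubisco"],
            expected="growth slower than A; CO2 export ~21% of acetate uptake",
        ),
        ScenarioConfig(
            label="D-light-limited",
            description=(
                f"Acetate fixed at {ACETATE_UPTAKE} and photons capped at the "
                f"fitted light-limited value {PHOTON_UPTAKE_FIT} mmol/gDW/h."
            ),
            medium={
                "acetate_exchange": {"uptake_fixed": ACETATE_UPTAKE},
                "photon_exchange": {"uptake_max": PHOTON_UPTAKE_FIT},
            },
            expected="measured-growth regime; reduced byproducts exported",
        ),
        ScenarioConfig(
            label="F-succinate-blocked",
            description="As D with the reduced-byproduct (succinate) export blocked.",
            medium={
                "acetate_exchange": {"uptake_fixed": ACETATE_UPTAKE},
                "photon_exchange": {"uptake_max": PHOTON_UPTAKE_FIT},
            },
            blocked=["succinate_exchange"],
            expected="slightly lower growth; other organic acids exported",
        ),
        ScenarioConfig(
            label="G-h2-max",
            description="Maximum theoretical H2 production on acetate.",
            medium={
                "acetate_exchange": {"uptake_fixed": ACETATE_UPTAKE},
                "photon_exchange": {"uptake_max": "unlimited"},
            },
            objective_role="h2_exchange",
            expected="growth ceases; carbon fully oxidized to CO2",
        ),
        ScenarioConfig(
            label="N-starvation-phb",
            description=(
                "Nitrogen starvation on acetate: maximize storage-polymer "
                "(PHB subunit) export at fixed carbon and photon import."
            ),
            medium={
                "acetate_exchange": {"uptake_fixed": ACETATE_UPTAKE},
                "photon_exchange": {"uptake_max": PHOTON_UPTAKE_FIT},
            },
            objective_role="phb_exchange",
            expected="reduced storage compound exported at zero growth",
        ),
    ]
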