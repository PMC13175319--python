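"""L-fuculose pathway extension and elemental mass-balance checking.

The production route engineered into *E. coli* condenses lactaldehyde (LAD,
C3H6O2) with dihydroxyacetone phosphate (DHAP, C3H7O6P) via the fuculose-1-
phosphate aldolase FucA, then dephosphorylates fuculose-1-phosphate to
L-fuculose through innate sugar phosphatases. Competing reactions drain both
substrates and the product: FucO reduces LAD to 1,2-propanediol, AldA oxidizes
LAD to lactate, TpiA pulls DHAP into glycolysis, and FucI/FucK isomerize or
rephosphorylate the product. :func:`extend_with_fuculose_pathway` grafts this
whole reaction set — plus the boundary transport/exchange steps FBA needs to
carry net flux — onto any host model that supplies DHAP and the usual
cofactors.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from .model import (
    ConstraintModel,
    DEFAULT_LOWER,
    DEFAULT_UPPER,
    Metabolite,
    ModelError,
    Reaction,
)

__all__ = [
    "PathwayOptions",
    "ExtensionError",
    "extend_with_fuculose_pathway",
    "pathway_reaction_ids",
    "parse_formula",
    "check_mass_balance",
    "PATHWAY_GENES",
    "FORMULAS",
]

PATHWAY_GENES = ("fucA", "fucI", "fucK", "fucO", "aldA")

#: Elemental formulas of the pathway species (set on the new metabolites and,
#: when missing, on the host's DHAP so the aldolase reaction can be checked).
FORMULAS = {
    "lad": "C3H6O2",
    "dhap": "C3H7O6P",
    "fc1p": "C6H13O8P",
    "fcl": "C6H12O5",
    "fuc": "C6H12O5",
    "pdo": "C3H8O2",
    "lac": "C3H6O3",
    "h2o": "H2O",
    "pi": "H3O4P",
}


class ExtensionError(ModelError):
    """The host model cannot accept the pathway (missing species, id clash)."""


@dataclass
class PathwayOptions:
    """Toggles and bounds for the added reactions.

    ``lad_uptake_bound`` is the maximum lactaldehyde uptake rate in
    mmol·gDW⁻¹·h⁻¹ (default 5, mirroring the 10 g/L glucose : 5 mM LAD medium
    ratio against the conventional glucose uptake of 10). The FucI, FucK and
    AldA competing reactions are present by default so the knockout series can
    remove them.
    """

    include_isomerase: bool = True
    include_kinase: bool = True
    include_alda: bool = True
    lad_uptake_bound: float = 5.0
    fuculose_export: bool = True

    def __post_init__(self) -> None:
        if self.lad_uptake_bound < 0:
            raise ValueError("lad_uptake_bound must be >= 0")


#: Host metabolite ids the extension relies on; override via ``host_mets``.
DEFAULT_HOST_METS = {
    "dhap": "dhap_c",
    "nad": "nad_c",
    "nadh": "nadh_c",
    "atp": "atp_c",
    "adp": "adp_c",
    "h2o": "h2o_c",
    "pi": "pi_c",
    "lac": "lac_c",
}


def pathway_reaction_ids(options: PathwayOptions | None = None) -> list[str]:
    """Ids of the reactions the extension adds, honouring the toggles."""
    options = options or PathwayOptions()
    ids = ["LADt", "EX_lad", "FCPA", "FCP", "FUCO", "PDOt", "EX_pdo"]
    if options.fuculose_export:
        ids += ["FCLt", "EX_fcl"]
    if options.include_kinase:
        ids.append("FCLK")
    if options.include_isomerase:
        ids += ["FUCI", "FUCt", "EX_fuc"]
    if options.include_alda:
        ids.append("ALDA")
    return ids


def _new_met(model: ConstraintModel, mid: str, name: str, formula_key: str | None) -> None:
    if not model.has_metabolite(mid):
        model.metabolites.append(
            Metabolite(id=mid, name=name, formula=FORMULAS.get(formula_key))
        )


def extend_with_fuculose_pathway(
    model: ConstraintModel,
    options: PathwayOptions | None = None,
    host_mets: dict[str, str] | None = None,
) -> ConstraintModel:
    """Return a copy of ``model`` with the fuculose pathway grafted on.

    Added (all toggles on): LAD uptake (LADt, EX_lad), the FucA aldolase FCPA
    (dhap + lad ⇌ fc1p, reversible — the reverse reaction can reconvert the
    phosphate when dephosphorylation is slow), the phosphatase FCP
    (fc1p + h2o → fcl + pi; water/phosphate omitted if the host lacks them),
    the FucK kinase FCLK, the FucI isomerase FUCI with fucose export, the FucO
    oxidoreductase FUCO (reversible), the AldA dehydrogenase ALDA, and
    secretion-only transport/exchange for L-fuculose and 1,2-PDO.

    Non-destructive: every host reaction and bound is unchanged; removing the
    added reaction ids recovers the host exactly.
    """
    options = options or PathwayOptions()
    mets = dict(DEFAULT_HOST_METS)
    if host_mets:
        mets.update(host_mets)

    required = ["dhap", "nad", "nadh"]
    if options.include_kinase:
        required += ["atp", "adp"]
    for key in required:
        if not model.has_metabolite(mets[key]):
            raise ExtensionError(
                f"host model lacks required metabolite '{mets[key]}' (role '{key}'); "
                "provide a mapping via host_mets"
            )
    has_h2o = model.has_metabolite(mets["h2o"])
    has_pi = model.has_metabolite(mets["pi"])
    has_lac = model.has_metabolite(mets["lac"])

    out = model.copy()

    def irr(stoich, rid, name, gpr="", lb=0.0, ub=DEFAULT_UPPER):
        return Reaction(id=rid, name=name, stoichiometry=stoich, lower_bound=lb,
                        upper_bound=ub, gpr=gpr, subsystem="fuculose pathway")

    new_reactions: list[Reaction] = []

    # lactaldehyde supply
    _new_met(out, "lad_e", "lactaldehyde (extracellular)", "lad")
    _new_met(out, "lad_c", "lactaldehyde", "lad")
    new_reactions.append(irr({"lad_e": -1.0, "lad_c": 1.0}, "LADt", "lactaldehyde transport"))
    new_reactions.append(
        irr({"lad_e": -1.0}, "EX_lad", "lactaldehyde exchange",
            lb=-options.lad_uptake_bound)
    )

    # FucA aldolase (reversible) and innate phosphatase
    _new_met(out, "fc1p_c", "L-fuculose 1-phosphate", "fc1p")
    _new_met(out, "fcl_c", "L-fuculose", "fcl")
    dhap = out.get_metabolite(mets["dhap"])
    if dhap.formula is None:
        dhap.formula = FORMULAS["dhap"]
    new_reactions.append(
        irr({mets["dhap"]: -1.0, "lad_c": -1.0, "fc1p_c": 1.0}, "FCPA",
            "fuculose-1-phosphate aldolase (FucA)", gpr="fucA", lb=DEFAULT_LOWER)
    )
    fcp_stoich = {"fc1p_c": -1.0, "fcl_c": 1.0}
    if has_h2o:
        fcp_stoich[mets["h2o"]] = -1.0
    if has_pi:
        fcp_stoich[mets["pi"]] = 1.0
    new_reactions.append(irr(fcp_stoich, "FCP", "L-fuculose phosphatase (innate)"))

    # product drains: kinase, isomerase, export
    if options.include_kinase:
        new_reactions.append(
            irr({"fcl_c": -1.0, mets["atp"]: -1.0, "fc1p_c": 1.0, mets["adp"]: 1.0},
                "FCLK", "L-fuculose kinase (FucK)", gpr="fucK")
        )
    if options.include_isomerase:
        _new_met(out, "fuc_c", "L-fucose", "fuc")
        _new_met(out, "fuc_e", "L-fucose (extracellular)", "fuc")
        new_reactions.append(
            irr({"fcl_c": -1.0, "fuc_c": 1.0}, "FUCI",
                "L-fucose isomerase (FucI)", gpr="fucI", lb=DEFAULT_LOWER)
        )
        new_reactions.append(irr({"fuc_c": -1.0, "fuc_e": 1.0}, "FUCt", "L-fucose transport"))
        new_reactions.append(irr({"fuc_e": -1.0}, "EX_fuc", "L-fucose exchange"))
    if options.fuculose_export:
        _new_met(out, "fcl_e", "L-fuculose (extracellular)", "fcl")
        new_reactions.append(irr({"fcl_c": -1.0, "fcl_e": 1.0}, "FCLt", "L-fuculose transport"))
        new_reactions.append(irr({"fcl_e": -1.0}, "EX_fcl", "L-fuculose exchange"))

    # lactaldehyde sinks: 1,2-PDO (FucO, reversible) and lactate (AldA)
    _new_met(out, "pdo_c", "1,2-propanediol", "pdo")
    _new_met(out, "pdo_e", "1,2-propanediol (extracellular)", "pdo")
    new_reactions.append(
        irr({"lad_c": -1.0, mets["nadh"]: -1.0, "pdo_c": 1.0, mets["nad"]: 1.0},
            "FUCO", "1,2-PDO oxidoreductase (FucO)", gpr="fucO", lb=DEFAULT_LOWER)
    )
    new_reactions.append(irr({"pdo_c": -1.0, "pdo_e": 1.0}, "PDOt", "1,2-PDO transport"))
    new_reactions.append(irr({"pdo_e": -1.0}, "EX_pdo", "1,2-PDO exchange"))
    if options.include_alda:
        if not has_lac:
            _new_met(out, mets["lac"], "lactate", "lac")
        alda_stoich = {"lad_c": -1.0, mets["nad"]: -1.0,
                       mets["lac"]: 1.0, mets["nadh"]: 1.0}
        if has_h2o:
            alda_stoich[mets["h2o"]] = -1.0
        new_reactions.append(
            irr(alda_stoich, "ALDA", "lactaldehyde dehydrogenase (AldA)", gpr="aldA")
        )

    for rxn in new_reactions:
        if model.has_reaction(rxn.id):
            raise ExtensionError(f"reaction id '{rxn.id}' already present in host model")
    out.reactions.extend(new_reactions)
    for gene in PATHWAY_GENES:
        if gene not in out.genes:
            out.genes.append(gene)
    return out


# ---------------------------------------------------------------------------
# Elemental balance
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: Net formula gained by the first (reduced / phosphorylated) member of a
#: cofactor pair relative to the second. NADH carries two hydrogen atoms more
#: than NAD+ (hydride plus the balancing proton); ATP one HPO3 more than ADP.
DEFAULT_PAIR_DELTAS = {
    ("nadh_c", "nad_c"): "H2",
    ("atp_c", "adp_c"): "HO3P",
}


def parse_formula(formula: str) -> Counter:
    """Elemental formula string → element counts (e.g. C6H13O8P)."""
    counts: Counter = Counter()
    matched = ""
    for element, digits in _FORMULA_TOKEN.findall(formula):
        if not element:
            continue
        counts[element] += int(digits) if digits else 1
        matched += element + digits
    if matched != formula.replace(" ", ""):
        raise ValueError(f"cannot parse formula '{formula}'")
    return counts


def check_mass_balance(
    model: ConstraintModel,
    pair_deltas: dict[tuple[str, str], str] | None = None,
) -> dict[str, dict]:
    """Per-element imbalance report for every checkable internal reaction.

    Boundary (single-metabolite) and biomass reactions are excluded. A
    cofactor pair listed in ``pair_deltas`` with exactly opposite coefficients
    contributes only its net formula difference, so redox/phosphoryl carriers
    whose full structures are not annotated can still be balanced-by-pair.
    Reactions touching any remaining metabolite without a formula are reported
    as ``skipped``. Report-only: nothing raises.

    Returns ``{reaction_id: {"status": "balanced"|"imbalanced"|"skipped",
    "imbalance": {element: net}}}``.
    """
    pair_deltas = DEFAULT_PAIR_DELTAS if pair_deltas is None else pair_deltas
    formulas = {m.id: m.formula for m in model.metabolites}
    report: dict[str, dict] = {}

    for rxn in model.reactions:
        if rxn.is_exchange() or "biomass" in rxn.id.lower():
            continue
        stoich = dict(rxn.stoichiometry)
        totals: Counter = Counter()
        # fold matched cofactor pairs into their net delta
        for (first, second), delta in pair_deltas.items():
            if first in stoich and second in stoich and stoich[first] == -stoich[second]:
                for el, cnt in parse_formula(delta).items():
                    totals[el] += stoich[first] * cnt
                del stoich[first], stoich[second]
        if any(formulas.get(mid) is None for mid in stoich):
            report[rxn.id] = {"status": "skipped", "imbalance": {}}
            continue
        for mid, coef in stoich.items():
            for el, cnt in parse_formula(formulas[mid]).items():
                totals[el] += coef * cnt
        imbalance = {el: v for el, v in totals.items() if abs(v) > 1e-9}
        report[rxn.id] = {
            "status": "balanced" if not imbalance else "imbalanced",
            "imbalance": imbalance,
        }
    return report
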