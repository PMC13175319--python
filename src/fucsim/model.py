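"""Constraint-based metabolic model: data types, BiGG-dialect JSON I/O, GPR logic.

A :class:`ConstraintModel` is the in-memory form of a BiGG-style JSON document:
metabolites with compartment suffixes (``_c`` cytosol, ``_e`` extracellular),
reactions with signed stoichiometries and flux bounds in mmol·gDW⁻¹·h⁻¹, gene
ids, and boolean gene–reaction (GPR) rules. The stoichiometric matrix *S* and
the bound vectors assembled here are the inputs to flux balance analysis
(:mod:`fucsim.fba`).

Sign conventions follow the dominant constraint-based dialect: exchange
reactions are written ``met_e →`` so that negative flux is uptake and positive
flux is secretion; irreversible reactions default to bounds (0, 1000),
reversible ones to (−1000, 1000).
"""

from __future__ import annotations

import copy
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "ConstraintModel",
    "ModelError",
    "ParseError",
    "ValidationError",
    "parse_gpr",
    "gpr_genes",
    "evaluate_gpr",
    "parse_model",
    "write_model",
    "save_model",
    "validate_model",
    "assemble_matrix",
    "apply_deletions",
]

DEFAULT_UPPER = 1000.0
DEFAULT_LOWER = -1000.0


class ModelError(ValueError):
    """Base class for model construction and validation failures."""


class ParseError(ModelError):
    """The JSON document does not follow the expected schema."""


class ValidationError(ModelError):
    """The document parsed but violates a model invariant."""


@dataclass
class Metabolite:
    """A chemical species in a compartment.

    ``compartment`` is derived from the id suffix when omitted; ``formula`` is
    an optional elemental formula (e.g. ``"C3H6O2"`` for lactaldehyde) used by
    the mass-balance checker.
    """

    id: str
    name: str = ""
    compartment: str | None = None
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.compartment is None:
            self.compartment = self.id.rsplit("_", 1)[-1] if "_" in self.id else ""


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and an optional GPR rule.

    ``stoichiometry`` maps metabolite id → signed coefficient (negative =
    consumed). ``gpr`` is a boolean expression over gene ids using
    ``and``/``or``/parentheses; the empty string means "no gene association"
    (the reaction survives every deletion).
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER
    gpr: str = ""
    name: str = ""
    subsystem: str = ""

    def is_exchange(self) -> bool:
        """Boundary pseudo-reaction: touches exactly one metabolite."""
        return len(self.stoichiometry) == 1

    def is_reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class ConstraintModel:
    """Metabolites, reactions, genes and an objective — houses S, v-bounds, c."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective: str | None = None
    id: str = "model"

    # -- lookups -----------------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"reaction '{rid}' not in model '{self.id}'")

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"metabolite '{mid}' not in model '{self.id}'")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def has_metabolite(self, mid: str) -> bool:
        return any(m.id == mid for m in self.metabolites)

    def copy(self) -> "ConstraintModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------
# Expression trees are nested tuples: ("gene", gid), ("and", [children]) or
# ("or", [children]).  In the textual dialect AND binds tighter than OR.

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(expression: str):
    """Parse a gene_reaction_rule string into an expression tree.

    Returns ``None`` for an empty rule. Raises :class:`ParseError` on
    malformed input (unbalanced parentheses, dangling operators).
    """
    tokens = _GPR_TOKEN.findall(expression or "")
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def expect_atom():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ParseError(f"GPR rule '{expression}': expected gene, got end of input")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise ParseError(f"GPR rule '{expression}': unbalanced parentheses")
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ParseError(f"GPR rule '{expression}': unexpected token '{tok}'")
        pos += 1
        return ("gene", tok)

    def parse_and():
        nonlocal pos
        children = [expect_atom()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            children.append(expect_atom())
        return children[0] if len(children) == 1 else ("and", children)

    def parse_or():
        nonlocal pos
        children = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            children.append(parse_and())
        return children[0] if len(children) == 1 else ("or", children)

    node = parse_or()
    if pos != len(tokens):
        raise ParseError(f"GPR rule '{expression}': trailing tokens")
    return node


def gpr_genes(rule) -> set[str]:
    """All gene ids appearing as leaves of a rule (string or tree)."""
    if isinstance(rule, str):
        rule = parse_gpr(rule)
    if rule is None:
        return set()
    kind = rule[0]
    if kind == "gene":
        return {rule[1]}
    out: set[str] = set()
    for child in rule[1]:
        out |= gpr_genes(child)
    return out


def evaluate_gpr(rule, deleted_genes: Iterable[str]) -> bool:
    """Is the reaction retained after deleting ``deleted_genes``?

    A leaf evaluates to ``gene ∉ deleted``; AND/OR by boolean logic; an empty
    rule (no gene association) is always retained.
    """
    if isinstance(rule, str):
        rule = parse_gpr(rule)
    deleted = set(deleted_genes)
    if rule is None:
        return True

    def ev(node) -> bool:
        kind = node[0]
        if kind == "gene":
            return node[1] not in deleted
        if kind == "and":
            return all(ev(c) for c in node[1])
        return any(ev(c) for c in node[1])

    return ev(rule)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_model(model: ConstraintModel) -> tuple[list[str], list[str]]:
    """Check model invariants; returns ``(errors, warnings)`` message lists.

    Errors: duplicate ids, dangling metabolite references, empty
    stoichiometries, inverted bounds, missing objective reaction, GPR genes
    absent from the gene list. Warnings: exchange reactions whose single
    metabolite is not extracellular, compartment/suffix mismatches.
    """
    errors: list[str] = []
    warns: list[str] = []

    met_ids = model.metabolite_ids()
    seen: set[str] = set()
    for mid in met_ids:
        if mid in seen:
            errors.append(f"duplicate metabolite id '{mid}'")
        seen.add(mid)
    met_set = set(met_ids)

    seen = set()
    for rxn in model.reactions:
        if rxn.id in seen:
            errors.append(f"duplicate reaction id '{rxn.id}'")
        seen.add(rxn.id)
        if not rxn.stoichiometry:
            errors.append(f"reaction '{rxn.id}' has empty stoichiometry")
        if rxn.lower_bound > rxn.upper_bound:
            errors.append(
                f"reaction '{rxn.id}' has lower_bound {rxn.lower_bound} > "
                f"upper_bound {rxn.upper_bound}"
            )
        for mid in rxn.stoichiometry:
            if mid not in met_set:
                errors.append(
                    f"reaction '{rxn.id}' references metabolite '{mid}' absent from model"
                )
        gene_set = set(model.genes)
        for g in gpr_genes(rxn.gpr):
            if g not in gene_set:
                errors.append(f"reaction '{rxn.id}' GPR gene '{g}' not in model gene list")
        if rxn.is_exchange():
            mid = next(iter(rxn.stoichiometry))
            if mid in met_set and not mid.endswith("_e"):
                warns.append(
                    f"boundary reaction '{rxn.id}' touches non-extracellular '{mid}'"
                )

    for met in model.metabolites:
        if "_" in met.id and met.id.rsplit("_", 1)[-1] != met.compartment:
            warns.append(
                f"metabolite '{met.id}' compartment field '{met.compartment}' "
                "does not match id suffix"
            )

    if model.objective is not None and model.objective not in {r.id for r in model.reactions}:
        errors.append(f"objective '{model.objective}' is not a reaction in the model")

    return errors, warns


# ---------------------------------------------------------------------------
# BiGG-dialect JSON I/O
# ---------------------------------------------------------------------------

_REQUIRED_TOP = ("metabolites", "reactions", "genes")
_REQUIRED_RXN = ("id", "metabolites", "lower_bound", "upper_bound")


def parse_model(document) -> ConstraintModel:
    """Parse a BiGG-dialect JSON document into a validated model.

    ``document`` may be a dict, a JSON string, or a path to a ``.json`` file.
    The write→parse round trip is the identity on all semantic fields.
    """
    if isinstance(document, (str, Path)):
        text = None
        if isinstance(document, Path) or (
            not str(document).lstrip().startswith("{") and Path(str(document)).exists()
        ):
            text = Path(document).read_text()
        else:
            text = str(document)
        try:
            document = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(document, Mapping):
        raise ParseError("model document must be a JSON object")
    for key in _REQUIRED_TOP:
        if key not in document:
            raise ParseError(f"missing required key '{key}'")

    metabolites = []
    for entry in document["metabolites"]:
        if "id" not in entry:
            raise ParseError("metabolite entry missing required key 'id'")
        metabolites.append(
            Metabolite(
                id=entry["id"],
                name=entry.get("name", ""),
                compartment=entry.get("compartment") or None,
                formula=entry.get("formula") or None,
                charge=entry.get("charge"),
            )
        )

    reactions = []
    objective = None
    for entry in document["reactions"]:
        for key in _REQUIRED_RXN:
            if key not in entry:
                rid = entry.get("id", "<unnamed>")
                raise ParseError(f"reaction '{rid}' missing required key '{key}'")
        rxn = Reaction(
            id=entry["id"],
            stoichiometry={m: float(c) for m, c in entry["metabolites"].items()},
            lower_bound=float(entry["lower_bound"]),
            upper_bound=float(entry["upper_bound"]),
            gpr=entry.get("gene_reaction_rule", "") or "",
            name=entry.get("name", ""),
            subsystem=entry.get("subsystem", "") or "",
        )
        reactions.append(rxn)
        if float(entry.get("objective_coefficient", 0.0)) != 0.0:
            objective = rxn.id

    genes = []
    for entry in document["genes"]:
        genes.append(entry["id"] if isinstance(entry, Mapping) else str(entry))

    model = ConstraintModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective=document.get("objective", objective),
        id=document.get("id", "model"),
    )
    errors, warns = validate_model(model)
    if errors:
        raise ValidationError("; ".join(errors))
    for msg in warns:
        warnings.warn(msg, stacklevel=2)
    return model


def write_model(model: ConstraintModel) -> dict:
    """Serialize to a BiGG-dialect JSON-compatible dict (inverse of parse)."""
    doc = {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment or "",
                **({"formula": m.formula} if m.formula else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                "subsystem": r.subsystem,
                "objective_coefficient": 1.0 if r.id == model.objective else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
    }
    return doc


def save_model(model: ConstraintModel, path) -> None:
    Path(path).write_text(json.dumps(write_model(model), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Stoichiometric matrix and deletions
# ---------------------------------------------------------------------------

def assemble_matrix(model: ConstraintModel) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense stoichiometric matrix S with row/column label lists.

    Entry (i, j) is the coefficient of metabolite i in reaction j; rows follow
    model metabolite order, columns model reaction order. S is the equality
    constraint of the steady-state condition S·v = 0.
    """
    met_ids = model.metabolite_ids()
    rxn_ids = model.reaction_ids()
    index = {mid: i for i, mid in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            S[index[mid], j] = coef
    return S, met_ids, rxn_ids


def apply_deletions(model: ConstraintModel, deleted_genes: Iterable[str]) -> ConstraintModel:
    """Simulate gene knockouts: zero-bound every reaction whose GPR fails.

    Returns a copy; the input model is untouched. Deleting a gene absent from
    the model is a no-op and raises a warning. Idempotent and monotone: a
    superset of deletions zero-bounds a superset of reactions.
    """
    deleted = set(deleted_genes)
    unknown = deleted - set(model.genes)
    if unknown:
        warnings.warn(
            f"genes not in model (deletion is a no-op): {sorted(unknown)}", stacklevel=2
        )
    out = model.copy()
    for rxn in out.reactions:
        if rxn.gpr and not evaluate_gpr(rxn.gpr, deleted):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out
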