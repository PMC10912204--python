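"""Metabolic-model data structures, the JSON model dialect, and GPR logic.

A model is a stoichiometric network: metabolites with compartments, reactions
with signed stoichiometry, flux bounds (mmol/gDCW/h) and gene-protein-reaction
(GPR) boolean rules, plus a biomass objective reaction.  Exchange and transport
status is always derived from structure, never trusted from annotations: an
exchange reaction touches exactly one metabolite (a boundary reaction), a
transport reaction spans at least two compartments.

GPR grammar (case-insensitive keywords, parenthesized infix)::

    expr    := term ("or" term)*
    term    := factor ("and" factor)*
    factor  := GENE | "(" expr ")"
    GENE    := [A-Za-z0-9_.:-]+

OR nodes encode isozymes (any one gene suffices), AND nodes encode protein
complexes (every subunit required).  An empty GPR marks a spontaneous,
non-deletable reaction.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GPRExpression",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "ModelParseError",
    "parse_gpr",
    "evaluate_gpr",
    "parse_model",
    "serialize_model",
    "apply_gene_deletion",
    "classify_single_protein_reactions",
]

# Bounds are encoded with this magnitude standing in for "unconstrained",
# keeping every linear/quadratic program bounded.
INFINITY_BOUND = 1000.0


class ModelParseError(ValueError):
    """A model document is malformed (names the offending element)."""


class ModelValidationError(ValueError):
    """A structurally well-formed document violates model invariants."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRExpression:
    """Boolean expression tree over gene identifiers.

    ``op`` is ``"gene"`` (leaf, ``gene`` set), ``"and"`` or ``"or"``
    (``children`` non-empty).
    """

    op: str
    gene: str | None = None
    children: tuple["GPRExpression", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise ValueError("gene leaf requires a gene identifier")
        elif self.op in ("and", "or"):
            if not self.children:
                raise ValueError(f"empty {self.op!r} node in GPR")
        else:
            raise ValueError(f"unknown GPR node type {self.op!r}")

    @property
    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset([self.gene])  # type: ignore[list-item]
        out: set[str] = set()
        for child in self.children:
            out |= child.genes
        return frozenset(out)

    def contains_or(self) -> bool:
        if self.op == "or":
            return True
        return any(c.contains_or() for c in self.children)

    def evaluate(self, deleted_genes: Iterable[str]) -> bool:
        deleted = set(deleted_genes)
        if self.op == "gene":
            return self.gene not in deleted
        if self.op == "and":
            return all(c.evaluate(deleted) for c in self.children)
        return any(c.evaluate(deleted) for c in self.children)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        parts = []
        for child in self.children:
            text = child.to_string()
            if child.op != "gene" and child.op != self.op:
                text = f"({text})"
            parts.append(text)
        return f" {self.op} ".join(parts)


_GPR_TOKEN = re.compile(r"\(|\)|[A-Za-z0-9_.:-]+")


def parse_gpr(text: str) -> GPRExpression | None:
    """Parse a GPR rule string; returns None for an empty rule."""
    if text is None or not text.strip():
        return None
    tokens = _GPR_TOKEN.findall(text)
    if "".join(tokens).replace("(", "").replace(")", "") != re.sub(r"\s+", "", text).replace("(", "").replace(")", ""):
        raise ModelParseError(f"unrecognized characters in GPR rule {text!r}")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr() -> GPRExpression:
        node = parse_term()
        children = [node]
        while peek() is not None and peek().lower() == "or":
            take()
            children.append(parse_term())
        if len(children) == 1:
            return node
        return GPRExpression("or", children=tuple(children))

    def parse_term() -> GPRExpression:
        node = parse_factor()
        children = [node]
        while peek() is not None and peek().lower() == "and":
            take()
            children.append(parse_factor())
        if len(children) == 1:
            return node
        return GPRExpression("and", children=tuple(children))

    def parse_factor() -> GPRExpression:
        tok = peek()
        if tok is None:
            raise ModelParseError(f"truncated GPR rule {text!r}")
        if tok == "(":
            take()
            node = parse_expr()
            if peek() != ")":
                raise ModelParseError(f"unbalanced parentheses in GPR rule {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelParseError(f"unexpected token {tok!r} in GPR rule {text!r}")
        return GPRExpression("gene", gene=take())

    tree = parse_expr()
    if pos != len(tokens):
        raise ModelParseError(f"trailing tokens in GPR rule {text!r}")
    return tree


def evaluate_gpr(gpr: GPRExpression | None, deleted_genes: Iterable[str]) -> bool:
    """Truth value of a GPR with ``deleted_genes`` false, all others true.

    An empty GPR (spontaneous reaction) is always active.
    """
    if gpr is None:
        return True
    return gpr.evaluate(deleted_genes)


# ---------------------------------------------------------------------------
# Metabolites, reactions, models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    met_id: str
    compartment: str = "c"
    name: str = ""


@dataclass(frozen=True)
class Reaction:
    rxn_id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = -INFINITY_BOUND
    upper_bound: float = INFINITY_BOUND
    gpr: GPRExpression | None = None
    subsystem: str = ""
    ko_category: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """Stoichiometric network with bounds, GPRs and a biomass objective."""

    model_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str]
    objective_reaction: str

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.met_id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.rxn_id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    def compartment_of(self, met_id: str) -> str:
        return self._met_index[met_id].compartment

    # -- structural classification ---------------------------------------
    def is_exchange(self, rxn_id: str) -> bool:
        """Boundary reaction: exactly one participating metabolite."""
        return len(self.reaction(rxn_id).stoichiometry) == 1

    def is_transport(self, rxn_id: str) -> bool:
        """Stoichiometry spans two or more compartments."""
        mets = self.reaction(rxn_id).stoichiometry
        comps = {self.compartment_of(m) for m in mets}
        return len(comps) >= 2

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        violations: list[str] = []
        met_ids = [m.met_id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            violations.append(f"duplicate metabolite identifiers: {dupes}")
        rxn_ids = [r.rxn_id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            violations.append(f"duplicate reaction identifiers: {dupes}")
        met_set = set(met_ids)
        gene_set = set(self.genes)
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in met_set:
                    violations.append(
                        f"reaction {rxn.rxn_id!r} references unknown metabolite {met!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                violations.append(
                    f"reaction {rxn.rxn_id!r} has lower_bound > upper_bound"
                )
            if rxn.gpr is not None:
                for gene in rxn.gpr.genes:
                    if gene not in gene_set:
                        violations.append(
                            f"reaction {rxn.rxn_id!r} GPR references unknown gene {gene!r}"
                        )
        if self.objective_reaction not in set(rxn_ids):
            violations.append(
                f"objective reaction {self.objective_reaction!r} not in model"
            )
        if violations:
            raise ModelValidationError(violations)
        self._met_index = {m.met_id: m for m in self.metabolites}
        self._rxn_index = {r.rxn_id: r for r in self.reactions}

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=[copy.copy(r) for r in self.reactions],
            genes=list(self.genes),
            objective_reaction=self.objective_reaction,
        )

    def with_bounds(self, bounds: Mapping[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy of the model with the listed reactions re-bounded."""
        new_reactions = []
        for rxn in self.reactions:
            if rxn.rxn_id in bounds:
                lb, ub = bounds[rxn.rxn_id]
                new_reactions.append(replace(rxn, lower_bound=lb, upper_bound=ub))
            else:
                new_reactions.append(rxn)
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=new_reactions,
            genes=list(self.genes),
            objective_reaction=self.objective_reaction,
        )


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

def _model_from_dict(doc: Mapping) -> MetabolicModel:
    for key in ("model_id", "metabolites", "reactions", "genes", "objective_reaction"):
        if key not in doc:
            raise ModelParseError(f"model document missing required key {key!r}")
    metabolites = []
    for entry in doc["metabolites"]:
        if "met_id" not in entry:
            raise ModelParseError(f"metabolite entry missing 'met_id': {entry!r}")
        metabolites.append(
            Metabolite(
                met_id=entry["met_id"],
                compartment=entry.get("compartment", "c"),
                name=entry.get("name", ""),
            )
        )
    reactions = []
    for entry in doc["reactions"]:
        if "rxn_id" not in entry:
            raise ModelParseError(f"reaction entry missing 'rxn_id': {entry!r}")
        if "stoichiometry" not in entry:
            raise ModelParseError(
                f"reaction {entry['rxn_id']!r} missing 'stoichiometry'"
            )
        reactions.append(
            Reaction(
                rxn_id=entry["rxn_id"],
                stoichiometry={m: float(c) for m, c in entry["stoichiometry"].items()},
                lower_bound=float(entry.get("lower_bound", -INFINITY_BOUND)),
                upper_bound=float(entry.get("upper_bound", INFINITY_BOUND)),
                gpr=parse_gpr(entry.get("gpr", "")),
                subsystem=entry.get("subsystem", ""),
                ko_category=entry.get("ko_category"),
            )
        )
    model = MetabolicModel(
        model_id=doc["model_id"],
        metabolites=metabolites,
        reactions=reactions,
        genes=list(doc["genes"]),
        objective_reaction=doc["objective_reaction"],
    )
    # a parsed document must admit growth: the objective needs headroom
    # (programmatic knockouts may later zero it, which is fine)
    obj = model.reaction(model.objective_reaction)
    if obj.upper_bound <= 0:
        raise ModelValidationError(
            [f"objective reaction {model.objective_reaction!r} has non-positive upper bound"]
        )
    return model


def _model_from_sbml(path: str) -> MetabolicModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(path)
    metabolites = [
        Metabolite(met_id=m.id, compartment=m.compartment or "c", name=m.name or "")
        for m in cm.metabolites
    ]
    reactions = []
    for r in cm.reactions:
        reactions.append(
            Reaction(
                rxn_id=r.id,
                stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
                lower_bound=max(r.lower_bound, -INFINITY_BOUND),
                upper_bound=min(r.upper_bound, INFINITY_BOUND),
                gpr=parse_gpr(r.gene_reaction_rule),
                subsystem=r.subsystem or "",
            )
        )
    objective = None
    for r in cm.reactions:
        if r.objective_coefficient:
            objective = r.id
            break
    if objective is None:
        raise ModelParseError(f"SBML model {path!r} declares no objective reaction")
    return MetabolicModel(
        model_id=cm.id or "sbml_model",
        metabolites=metabolites,
        reactions=reactions,
        genes=sorted(g.id for g in cm.genes),
        objective_reaction=objective,
    )


def parse_model(source, dialect: str = "json") -> MetabolicModel:
    """Parse a model document.

    ``dialect="json"`` accepts a dict, a JSON string, or a path to a JSON
    file.  ``dialect="sbml"`` accepts a path to an SBML Level 3 (fbc) file and
    reads it through COBRApy.  Exchange/transport classification is always
    recomputed from structure.
    """
    if dialect == "sbml":
        return _model_from_sbml(str(source))
    if dialect != "json":
        raise ValueError(f"unknown model dialect {dialect!r}")
    if isinstance(source, Mapping):
        return _model_from_dict(source)
    text = str(source)
    if text.lstrip().startswith("{"):
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"malformed JSON model document: {exc}") from exc
    else:
        with open(text) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelParseError(
                    f"malformed JSON model document {text!r}: {exc}"
                ) from exc
    return _model_from_dict(doc)


def serialize_model(model: MetabolicModel) -> dict:
    """Lossless JSON-dialect document for ``model`` (parse round-trips)."""
    return {
        "model_id": model.model_id,
        "metabolites": [
            {"met_id": m.met_id, "compartment": m.compartment, "name": m.name}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "rxn_id": r.rxn_id,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string() if r.gpr is not None else "",
                "subsystem": r.subsystem,
                "ko_category": r.ko_category,
            }
            for r in model.reactions
        ],
        "genes": list(model.genes),
        "objective_reaction": model.objective_reaction,
    }


# ---------------------------------------------------------------------------
# Gene deletions and the single-protein reaction set
# ---------------------------------------------------------------------------

def apply_gene_deletion(model: MetabolicModel, deleted_genes: Iterable[str]) -> MetabolicModel:
    """Copy of ``model`` with reactions disabled by the deletion bounded to 0.

    A reaction is disabled when its GPR evaluates false with the deleted genes
    set false.  Spontaneous (empty-GPR) reactions are never affected.
    """
    deleted = set(deleted_genes)
    unknown = deleted - set(model.genes)
    if unknown:
        raise KeyError(f"unknown gene(s) in deletion: {sorted(unknown)}")
    bounds = {
        r.rxn_id: (0.0, 0.0)
        for r in model.reactions
        if r.gpr is not None and not r.gpr.evaluate(deleted)
    }
    if not bounds:
        return model.copy()
    return model.with_bounds(bounds)


def classify_single_protein_reactions(model: MetabolicModel) -> set[str]:
    """Reactions mediated by a single protein or a single protein complex.

    These are reactions with a non-empty GPR containing no OR node: one gene,
    or a pure-AND complex.  Isozyme-backed (OR) and spontaneous reactions are
    excluded, since their loss cannot be pinned on a single protein.
    """
    return {
        r.rxn_id
        for r in model.reactions
        if r.gpr is not None and not r.gpr.contains_or()
    }
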