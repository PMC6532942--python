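"""Genome-scale model container, GPR parsing, and reversible-reaction splitting.

The MILP layers downstream require every flux variable to be non-negative, so
reversible reactions are decomposed into a forward (alpha) and backward (beta)
child, each with bounds [0, M'] and a binary use indicator z; for a reversible
pair exactly one direction may be active (z_alpha + z_beta = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "GprNode",
    "GprParseError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "SplitReaction",
    "SplitModel",
    "parse_gpr",
    "read_model",
    "split_reversible",
]


class GprParseError(ValueError):
    """Raised for malformed GPR rule strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GprNode:
    """Node of a gene-protein-reaction boolean tree.

    kind is one of ``"gene"``, ``"and"``, ``"or"``.  AND nodes denote enzyme
    complexes (all genes required); OR nodes denote isoenzymes (any gene
    sufficient).
    """

    kind: str
    gene: str | None = None
    children: tuple["GprNode", ...] = ()

    def __post_init__(self):
        if self.kind == "gene":
            if not self.gene:
                raise ValueError("gene node requires a gene id")
        elif self.kind in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind} node requires >=2 children")
        else:
            raise ValueError(f"unknown GPR node kind: {self.kind}")

    def genes(self) -> set[str]:
        if self.kind == "gene":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        if self.kind == "gene":
            return self.gene
        sep = f" {self.kind} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.kind != "gene":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


def _tokenize_gpr(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(("lpar" if ch == "(" else "rpar", ch, i))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low == "and":
            tokens.append(("and", word, i))
        elif low == "or":
            tokens.append(("or", word, i))
        else:
            tokens.append(("gene", word, i))
        i = j
    return tokens


def parse_gpr(rule_text: str) -> GprNode | None:
    """Parse a GPR rule string into a :class:`GprNode` tree.

    Grammar: genes, parentheses, case-insensitive ``and`` / ``or``; ``and``
    binds tighter than ``or``.  An empty/whitespace string returns ``None``
    (the reaction carries no expression constraint).  Same-operator chains are
    flattened into one n-ary node.
    """
    tokens = _tokenize_gpr(rule_text)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def expect_factor() -> GprNode:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GprParseError("dangling connective or empty expression", len(rule_text))
        kind, word, at = tok
        if kind == "lpar":
            pos += 1
            node = expr()
            tok2 = peek()
            if tok2 is None or tok2[0] != "rpar":
                raise GprParseError("unbalanced parentheses: missing ')'", at)
            pos += 1
            return node
        if kind == "gene":
            pos += 1
            return GprNode("gene", gene=word)
        raise GprParseError(f"unexpected token {word!r}", at)

    def term() -> GprNode:
        nonlocal pos
        node = expect_factor()
        children = [node]
        while (tok := peek()) is not None and tok[0] == "and":
            pos += 1
            children.append(expect_factor())
        if len(children) == 1:
            return node
        flat: list[GprNode] = []
        for c in children:
            flat.extend(c.children if c.kind == "and" else [c])
        return GprNode("and", children=tuple(flat))

    def expr() -> GprNode:
        nonlocal pos
        node = term()
        children = [node]
        while (tok := peek()) is not None and tok[0] == "or":
            pos += 1
            children.append(term())
        if len(children) == 1:
            return node
        flat: list[GprNode] = []
        for c in children:
            flat.extend(c.children if c.kind == "or" else [c])
        return GprNode("or", children=tuple(flat))

    node = expr()
    tok = peek()
    if tok is not None:
        raise GprParseError(f"unexpected token {tok[1]!r}", tok[2])
    return node


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    id: str
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GprNode | None = None
    gpr_text: str = ""
    subsystem: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


class ModelValidationError(ValueError):
    pass


@dataclass
class MetabolicModel:
    """Stoichiometric model: metabolites, bounded reactions, GPR rules.

    ``stoichiometry`` maps ``(metabolite_id, reaction_id)`` to the
    stoichiometric coefficient S_mr (negative for substrates, positive for
    products).
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    stoichiometry: dict[tuple[str, str], float]
    genes: list[str] = field(default_factory=list)
    biomass_reaction_id: str | None = None
    id: str = "model"

    def __post_init__(self):
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    def metabolite(self, mid: str) -> Metabolite:
        return self._met_index[mid]

    def reaction(self, rid: str) -> Reaction:
        return self._rxn_index[rid]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def has_metabolite(self, mid: str) -> bool:
        return mid in self._met_index

    def reaction_stoichiometry(self, rid: str) -> dict[str, float]:
        return {m: c for (m, r), c in self.stoichiometry.items() if r == rid and c != 0}

    def unknown_gpr_genes(self) -> set[str]:
        known = set(self.genes)
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= r.gpr.genes() - known
        return out

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on structural defects."""
        if not self.reactions:
            raise ModelValidationError("model has no reactions")
        if not self.metabolites:
            raise ModelValidationError("model has no metabolites")
        if not self.stoichiometry:
            raise ModelValidationError("model has empty stoichiometry")
        for (m, r), c in self.stoichiometry.items():
            if c == 0:
                continue
            if m not in self._met_index:
                raise ModelValidationError(f"stoichiometry references unknown metabolite {m!r}")
            if r not in self._rxn_index:
                raise ModelValidationError(f"stoichiometry references unknown reaction {r!r}")
        for r in self.reactions:
            if not (r.lower_bound <= r.upper_bound):
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} > upper bound {r.upper_bound}"
                )
            if not (math.isfinite(r.lower_bound) and math.isfinite(r.upper_bound)):
                raise ModelValidationError(f"reaction {r.id!r}: non-finite bounds")
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in self._rxn_index:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )

    def validation_report(self) -> str:
        lines = [
            f"model: {self.id}",
            f"reactions: {len(self.reactions)}",
            f"metabolites: {len(self.metabolites)}",
            f"genes: {len(self.genes)}",
            f"reversible reactions: {sum(r.reversible for r in self.reactions)}",
            f"biomass reaction: {self.biomass_reaction_id}",
        ]
        unknown = self.unknown_gpr_genes()
        if unknown:
            lines.append(f"GPR genes absent from gene list: {sorted(unknown)}")
        try:
            self.validate()
            lines.append("status: OK")
        except ModelValidationError as e:
            lines.append(f"status: INVALID ({e})")
        return "\n".join(lines)


def _from_cobra(cm, biomass_reaction: str | None) -> MetabolicModel:
    metabolites = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "")
        for m in cm.metabolites
    ]
    reactions = []
    stoich: dict[tuple[str, str], float] = {}
    for r in cm.reactions:
        gpr_text = r.gene_reaction_rule or ""
        reactions.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=parse_gpr(gpr_text),
                gpr_text=gpr_text,
                subsystem=r.subsystem or "",
            )
        )
        for met, coef in r.metabolites.items():
            stoich[(met.id, r.id)] = float(coef)
    biomass = biomass_reaction
    if biomass is None:
        objective_rxns = [r.id for r in cm.reactions if r.objective_coefficient]
        if len(objective_rxns) == 1:
            biomass = objective_rxns[0]
        else:
            named = [r.id for r in cm.reactions if "biomass" in r.id.lower()]
            if named:
                biomass = named[0]
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=stoich,
        genes=[g.id for g in cm.genes],
        biomass_reaction_id=biomass,
        id=cm.id or "model",
    )
    model.validate()
    return model


def read_model(
    path: str | Path,
    format: str | None = None,
    biomass_reaction: str | None = None,
) -> MetabolicModel:
    """Read an SBML (Level 3 / fbc) or community-JSON model file.

    ``format`` is ``"sbml"`` or ``"json"``; inferred from the suffix when
    omitted.  The biomass reaction defaults to the single objective reaction,
    falling back to an id containing "biomass".
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        cm = cobra.io.load_json_model(str(path))
    elif format == "sbml":
        cm = cobra.io.read_sbml_model(str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")
    return _from_cobra(cm, biomass_reaction)


def to_cobra(model: MetabolicModel):
    """Convert to a COBRApy model (for writing fixtures and interop)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
            for m in model.metabolites}
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, lower_bound=r.lower_bound,
                            upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        rxns.append(cr)
    cm.add_reactions(rxns)
    for (mid, rid), coef in model.stoichiometry.items():
        if coef:
            cm.reactions.get_by_id(rid).add_metabolites({mets[mid]: coef})
    for r in model.reactions:
        if r.gpr_text:
            cm.reactions.get_by_id(r.id).gene_reaction_rule = r.gpr_text
    if model.biomass_reaction_id:
        cm.objective = model.biomass_reaction_id
    return cm


FORWARD = "fwd"
BACKWARD = "bwd"


@dataclass(frozen=True)
class SplitReaction:
    id: str
    parent_id: str
    direction: str  # FORWARD or BACKWARD
    lower_bound: float
    upper_bound: float


@dataclass
class SplitModel:
    """Direction-decomposed model: every split flux variable is >= 0."""

    parent: MetabolicModel
    split_reactions: list[SplitReaction]
    big_M: float
    # parent reaction id -> {direction: split id}
    children: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        self._index = {s.id: s for s in self.split_reactions}

    def split(self, sid: str) -> SplitReaction:
        return self._index[sid]

    def children_of(self, parent_id: str) -> dict[str, str]:
        return self.children[parent_id]

    def is_reversible_pair(self, parent_id: str) -> bool:
        return len(self.children[parent_id]) == 2

    def net_flux(self, parent_id: str, values: Mapping[str, float]) -> float:
        """Reconstruct the parent net flux v_alpha - v_beta from split values."""
        net = 0.0
        for direction, sid in self.children[parent_id].items():
            v = values[sid]
            net += v if direction == FORWARD else -v
        return net

    def stoich_coefficient(self, mid: str, sid: str) -> float:
        """Signed coefficient of metabolite mid in split reaction sid."""
        s = self._index[sid]
        c = self.parent.stoichiometry.get((mid, s.parent_id), 0.0)
        return c if s.direction == FORWARD else -c


def split_reversible(model: MetabolicModel, big_M: float = 1000.0) -> SplitModel:
    """Decompose reversible reactions into forward/backward children.

    Children have bounds within [0, big_M]; bounds tighter than big_M are
    preserved.  Irreversible reactions yield a single child in their allowed
    direction (a backward-only reaction, ub <= 0, maps to one backward child).
    """
    if big_M <= 0:
        raise ValueError(f"big_M must be positive, got {big_M}")
    model.validate()
    split_list: list[SplitReaction] = []
    children: dict[str, dict[str, str]] = {}
    for r in model.reactions:
        kids: dict[str, str] = {}
        if r.lower_bound < 0 and r.upper_bound > 0:
            kids[FORWARD] = f"{r.id}__fwd"
            split_list.append(SplitReaction(kids[FORWARD], r.id, FORWARD,
                                            0.0, min(r.upper_bound, big_M)))
            kids[BACKWARD] = f"{r.id}__bwd"
            split_list.append(SplitReaction(kids[BACKWARD], r.id, BACKWARD,
                                            0.0, min(-r.lower_bound, big_M)))
        elif r.upper_bound <= 0:
            kids[BACKWARD] = f"{r.id}__bwd"
            split_list.append(SplitReaction(kids[BACKWARD], r.id, BACKWARD,
                                            max(0.0, -r.upper_bound), min(-r.lower_bound, big_M)))
        else:
            kids[FORWARD] = f"{r.id}__fwd"
            split_list.append(SplitReaction(kids[FORWARD], r.id, FORWARD,
                                            max(0.0, r.lower_bound), min(r.upper_bound, big_M)))
        children[r.id] = kids
    return SplitModel(parent=model, split_reactions=split_list, big_M=big_M,
                      children=children)
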