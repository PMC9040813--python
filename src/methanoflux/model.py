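"""Core data structures for constraint-based metabolic models.

A model is a set of metabolites (with elemental formulas and a cytosolic
``c`` or extracellular ``e`` compartment), reactions (signed stoichiometries
with flux bounds in mmol h-1 gDCW-1 and boolean gene-protein-reaction rules),
and a designated biomass/objective reaction.  Exchange reactions cross the
system boundary and touch exactly one metabolite; by convention a negative
exchange flux is uptake and a positive one is secretion.
"""

from __future__ import annotations

import copy as _copy
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "GeneRule",
    "Reaction",
    "MetabolicModel",
    "Medium",
    "MassBalanceReport",
    "ModelValidationError",
    "check_mass_balance",
    "apply_medium",
    "evaluate_gene_rule",
]


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


# ---------------------------------------------------------------------------
# Metabolites
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` maps element symbols to non-negative integer counts
    (C, H, O and N at minimum for species subject to balance checking).
    An empty formula marks a lumped species (e.g. biomass) that cannot be
    balance-checked.
    """

    id: str
    name: str = ""
    formula: dict[str, int] = field(default_factory=dict)
    compartment: str = "c"

    def __post_init__(self) -> None:
        if self.compartment not in ("c", "e"):
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment must be 'c' or 'e', "
                f"got {self.compartment!r}"
            )
        for elem, count in self.formula.items():
            if not (isinstance(count, int) and count >= 0):
                raise ModelValidationError(
                    f"metabolite {self.id!r}: formula count for {elem} must be "
                    f"a non-negative integer, got {count!r}"
                )

    @property
    def formula_string(self) -> str:
        """Hill-ish string form, e.g. ``C6H13O9P``."""
        parts = []
        for elem in sorted(self.formula, key=lambda e: (e != "C", e != "H", e)):
            n = self.formula[elem]
            if n == 0:
                continue
            parts.append(elem + (str(n) if n != 1 else ""))
        return "".join(parts)

    @staticmethod
    def parse_formula(text: str) -> dict[str, int]:
        """Parse ``C6H13O9P`` into ``{"C": 6, "H": 13, "O": 9, "P": 1}``."""
        out: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse chemical formula {text!r}")
            pos = match.end()
            elem, count = match.groups()
            out[elem] = out.get(elem, 0) + (int(count) if count else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse chemical formula {text!r}")
        return out


# ---------------------------------------------------------------------------
# Gene rules
# ---------------------------------------------------------------------------


class GeneRule:
    """Boolean gene-protein-reaction association.

    Internally an AST: a gene id string, or ``("and", [...])`` /
    ``("or", [...])`` nodes.  An empty rule (``None`` tree) marks an orphan
    reaction, which is always active.
    """

    def __init__(self, tree=None):
        self.tree = tree

    # -- construction -------------------------------------------------------

    @classmethod
    def from_string(cls, text: str) -> "GeneRule":
        """Parse ``"gA and (gB or gC)"`` (case-insensitive and/or)."""
        text = text.strip()
        if not text:
            return cls(None)
        tokens = re.findall(r"\(|\)|[^\s()]+", text)
        pos = 0

        def parse_or():
            nonlocal pos
            terms = [parse_and()]
            while pos < len(tokens) and tokens[pos].lower() == "or":
                pos += 1
                terms.append(parse_and())
            return terms[0] if len(terms) == 1 else ("or", terms)

        def parse_and():
            nonlocal pos
            terms = [parse_atom()]
            while pos < len(tokens) and tokens[pos].lower() == "and":
                pos += 1
                terms.append(parse_atom())
            return terms[0] if len(terms) == 1 else ("and", terms)

        def parse_atom():
            nonlocal pos
            if pos >= len(tokens):
                raise ValueError(f"truncated gene rule: {text!r}")
            tok = tokens[pos]
            if tok == "(":
                pos += 1
                node = parse_or()
                if pos >= len(tokens) or tokens[pos] != ")":
                    raise ValueError(f"unbalanced parentheses in gene rule: {text!r}")
                pos += 1
                return node
            if tok == ")" or tok.lower() in ("and", "or"):
                raise ValueError(f"malformed gene rule: {text!r}")
            pos += 1
            return tok

        tree = parse_or()
        if pos != len(tokens):
            raise ValueError(f"trailing tokens in gene rule: {text!r}")
        return cls(tree)

    # -- queries ------------------------------------------------------------

    @property
    def is_empty(self) -> bool:
        return self.tree is None

    def genes(self) -> set[str]:
        out: set[str] = set()

        def walk(node):
            if node is None:
                return
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        walk(self.tree)
        return out

    def evaluate(self, deleted_genes: Iterable[str]) -> bool:
        """True if the reaction remains catalysable with ``deleted_genes`` off.

        An empty rule (orphan reaction) always evaluates active.
        """
        deleted = set(deleted_genes)

        def walk(node) -> bool:
            if isinstance(node, str):
                return node not in deleted
            op, children = node
            if op == "and":
                return all(walk(c) for c in children)
            return any(walk(c) for c in children)

        if self.tree is None:
            return True
        return walk(self.tree)

    def to_string(self) -> str:
        def walk(node, parent_op=None) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            inner = f" {op} ".join(walk(c, op) for c in children)
            if parent_op is not None and parent_op != op:
                return f"({inner})"
            return inner

        return "" if self.tree is None else walk(self.tree)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneRule) and self.tree == other.tree

    def __repr__(self) -> str:
        return f"GeneRule({self.to_string()!r})"


def evaluate_gene_rule(
    rule: GeneRule,
    deleted_genes: Iterable[str],
    known_genes: Iterable[str] | None = None,
) -> bool:
    """Evaluate a GPR rule with the given genes knocked out.

    When ``known_genes`` is provided, deleted ids that are not known genes
    trigger a warning and are ignored (they cannot affect any rule anyway).
    """
    deleted = set(deleted_genes)
    if known_genes is not None:
        unknown = deleted - set(known_genes)
        if unknown:
            warnings.warn(
                f"ignoring unknown gene ids in deletion set: {sorted(unknown)}",
                stacklevel=2,
            )
            deleted -= unknown
    return rule.evaluate(deleted)


# ---------------------------------------------------------------------------
# Reactions
# ---------------------------------------------------------------------------


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite ids to signed coefficients (negative =
    consumed).  Bounds are in mmol h-1 gDCW-1 (h-1 for the biomass reaction).
    ``is_exchange`` marks boundary pseudo-reactions, which must touch exactly
    one metabolite.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_rule: GeneRule = field(default_factory=GeneRule)
    pathway: str = ""
    is_exchange: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id!r} must touch exactly one "
                f"metabolite, touches {len(self.stoichiometry)}"
            )

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, value: tuple[float, float]) -> None:
        lb, ub = value
        if lb > ub:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {lb} exceeds upper bound {ub}"
            )
        self.lower_bound, self.upper_bound = float(lb), float(ub)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


class MetabolicModel:
    """A stoichiometric model: metabolites, reactions, genes, objective."""

    def __init__(
        self,
        model_id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        genes: Iterable[str] = (),
        objective_reaction_id: str | None = None,
    ) -> None:
        self.id = model_id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.genes: list[str] = list(dict.fromkeys(genes))
        self.objective_reaction_id = objective_reaction_id
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)

    # -- construction -------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                )
        for gene in rxn.gene_rule.genes():
            if gene not in self.genes:
                self.genes.append(gene)
        self.reactions[rxn.id] = rxn

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any invariant violation."""
        if self.objective_reaction_id is None:
            raise ModelValidationError("model has no objective reaction")
        if self.objective_reaction_id not in self.reactions:
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        known = set(self.genes)
        for rxn in self.reactions.values():
            missing = rxn.gene_rule.genes() - known
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} gene rule references unknown genes "
                    f"{sorted(missing)}"
                )

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- views ---------------------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense metabolites x reactions matrix in dict insertion order."""
        met_index = {mid: i for i, mid in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions.values()):
            for mid, coef in rxn.stoichiometry.items():
                S[met_index[mid], j] = coef
        return S

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )


# ---------------------------------------------------------------------------
# Medium
# ---------------------------------------------------------------------------


class Medium(dict):
    """Exchange reaction id -> maximum uptake flux magnitude (non-negative).

    Applied as a negative lower bound on the exchange; secretion (upper)
    bounds are untouched.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for rid, mag in self.items():
            if mag < 0:
                raise ModelValidationError(
                    f"medium uptake magnitude for {rid!r} must be non-negative"
                )


def apply_medium(
    model: MetabolicModel, medium: Mapping[str, float], default_closed: bool = True
) -> MetabolicModel:
    """Return a copy of ``model`` with exchange uptake bounds set from ``medium``.

    Listed exchanges get ``lower_bound = -magnitude``; with ``default_closed``
    every unlisted exchange gets ``lower_bound = 0`` (no uptake).  Secretion
    bounds are never modified.  Idempotent for a fixed medium.
    """
    out = model.copy()
    exchange_ids = {r.id for r in out.exchanges()}
    for rid, mag in medium.items():
        if rid not in out.reactions:
            raise ModelValidationError(f"medium key {rid!r} is not in the model")
        if rid not in exchange_ids:
            raise ModelValidationError(
                f"medium key {rid!r} is not an exchange reaction"
            )
        if mag < 0:
            raise ModelValidationError(
                f"medium uptake magnitude for {rid!r} must be non-negative"
            )
        out.reactions[rid].lower_bound = -float(mag)
    if default_closed:
        for rid in exchange_ids - set(medium):
            rxn = out.reactions[rid]
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out


# ---------------------------------------------------------------------------
# Mass balance
# ---------------------------------------------------------------------------


@dataclass
class MassBalanceReport:
    """Elemental balance report.

    ``imbalances`` lists ``(reaction_id, element, imbalance)`` for every
    checked reaction with a nonzero net elemental sum; ``uncheckable`` lists
    reactions skipped because a participating metabolite lacks a formula.
    """

    imbalances: list[tuple[str, str, float]]
    uncheckable: list[str]

    @property
    def balanced(self) -> bool:
        return not self.imbalances

    def __iter__(self):
        return iter(self.imbalances)


def check_mass_balance(
    model: MetabolicModel,
    elements: Iterable[str] = ("C", "H", "O", "N"),
    atol: float = 1e-6,
) -> MassBalanceReport:
    """Check elemental balance of every internal, non-biomass reaction.

    Exchange reactions and the objective (biomass) reaction are exempt: the
    former cross the system boundary by construction and the latter is a
    lumped pseudo-reaction.  A reaction touching a metabolite without a
    formula is reported as uncheckable rather than imbalanced.
    """
    elements = list(elements)
    imbalances: list[tuple[str, str, float]] = []
    uncheckable: list[str] = []
    for rxn in model.reactions.values():
        if rxn.is_exchange or rxn.id == model.objective_reaction_id:
            continue
        mets = [model.metabolites[mid] for mid in rxn.stoichiometry]
        if elements and any(not m.formula for m in mets):
            uncheckable.append(rxn.id)
            continue
        for elem in elements:
            total = sum(
                coef * model.metabolites[mid].formula.get(elem, 0)
                for mid, coef in rxn.stoichiometry.items()
            )
            if abs(total) > atol:
                imbalances.append((rxn.id, elem, total))
    return MassBalanceReport(imbalances, uncheckable)
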