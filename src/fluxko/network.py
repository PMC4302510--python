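"""Metabolic network data model, gene-protein-reaction rules, and fixtures.

A metabolic network is described by a stoichiometric matrix ``S`` over a set
of metabolites and reactions, together with the subset of irreversible
reactions.  The steady-state flux cone

    C = {v | S v = 0,  v_r >= 0 for r irreversible}

is the object every analysis in this package reasons about.  Only the
*supports* of vectors in ``C`` matter for coupling analysis, so the network
carries no finite flux bounds by default (bounds may be stored for the
optional bound-honoring mode).

Gene-protein-reaction (GPR) rules are boolean expressions over gene
identifiers stating when a reaction's catalyst is available.  The grammar
supports ``and``, ``or``, ``not`` and parentheses; ``not`` is included
because gene association semantics can require it (a reaction may be active
precisely when a gene is *off*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GeneRule",
    "Gene",
    "Not",
    "And",
    "Or",
    "GeneRuleSyntaxError",
    "parse_gene_rule",
    "MetabolicNetwork",
    "figure1_fixture",
    "random_network",
]


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------


class GeneRule:
    """Base class for boolean gene-association expression trees."""

    def evaluate(self, assignment: Mapping[str, bool]) -> bool:
        raise NotImplementedError

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash((type(self).__name__, self._key()))

    def _key(self):
        raise NotImplementedError


@dataclass(frozen=True, eq=False)
class Gene(GeneRule):
    name: str

    def evaluate(self, assignment):
        return bool(assignment[self.name])

    def genes(self):
        return frozenset({self.name})

    def _key(self):
        return self.name

    def __str__(self):
        return self.name


@dataclass(frozen=True, eq=False)
class Not(GeneRule):
    operand: GeneRule

    def evaluate(self, assignment):
        return not self.operand.evaluate(assignment)

    def genes(self):
        return self.operand.genes()

    def _key(self):
        return self.operand

    def __str__(self):
        return f"not {self._wrap(self.operand)}"

    @staticmethod
    def _wrap(x):
        return f"({x})" if isinstance(x, (And, Or)) else str(x)


@dataclass(frozen=True, eq=False)
class And(GeneRule):
    operands: tuple[GeneRule, ...]

    def evaluate(self, assignment):
        return all(op.evaluate(assignment) for op in self.operands)

    def genes(self):
        return frozenset().union(*(op.genes() for op in self.operands))

    def _key(self):
        return self.operands

    def __str__(self):
        return " and ".join(
            f"({op})" if isinstance(op, Or) else str(op) for op in self.operands
        )


@dataclass(frozen=True, eq=False)
class Or(GeneRule):
    operands: tuple[GeneRule, ...]

    def evaluate(self, assignment):
        return any(op.evaluate(assignment) for op in self.operands)

    def genes(self):
        return frozenset().union(*(op.genes() for op in self.operands))

    def _key(self):
        return self.operands

    def __str__(self):
        return " or ".join(str(op) for op in self.operands)


class GeneRuleSyntaxError(ValueError):
    """Malformed GPR expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_KEYWORDS = {"and", "or", "not"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(("paren", ch, i))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in _KEYWORDS:
            tokens.append((low, word, i))
        else:
            tokens.append(("ident", word, i))
        i = j
    return tokens


def parse_gene_rule(text: str) -> GeneRule:
    """Parse a boolean gene-association expression.

    Operators are case-insensitive ``and``/``or``/``not`` with precedence
    ``not`` > ``and`` > ``or``; parentheses group.  Identifiers are any
    whitespace-delimited word that is not an operator.

    Raises
    ------
    GeneRuleSyntaxError
        On empty input, unbalanced parentheses or dangling operators, with
        the offending character position.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GeneRuleSyntaxError("empty gene rule", 0)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> GeneRule:
        nonlocal pos
        parts = [parse_and()]
        while peek() is not None and peek()[0] == "or":
            pos += 1
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and() -> GeneRule:
        nonlocal pos
        parts = [parse_not()]
        while peek() is not None and peek()[0] == "and":
            pos += 1
            parts.append(parse_not())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_not() -> GeneRule:
        nonlocal pos
        tok = peek()
        if tok is not None and tok[0] == "not":
            pos += 1
            if peek() is None:
                raise GeneRuleSyntaxError("dangling 'not'", tok[2])
            return Not(parse_not())
        return parse_atom()

    def parse_atom() -> GeneRule:
        nonlocal pos
        tok = peek()
        if tok is None:
            last = tokens[-1]
            raise GeneRuleSyntaxError("dangling operator", last[2])
        kind, value, at = tok
        if kind == "ident":
            pos += 1
            return Gene(value)
        if kind == "paren" and value == "(":
            pos += 1
            inner = parse_or()
            closing = peek()
            if closing is None or closing[1] != ")":
                raise GeneRuleSyntaxError("unbalanced parenthesis", at)
            pos += 1
            return inner
        raise GeneRuleSyntaxError(f"unexpected token {value!r}", at)

    tree = parse_or()
    if pos != len(tokens):
        raise GeneRuleSyntaxError(
            f"unexpected token {tokens[pos][1]!r}", tokens[pos][2]
        )
    return tree


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetabolicNetwork:
    """A metabolic network: stoichiometry, reversibilities and GPR rules.

    Parameters
    ----------
    metabolites, reactions
        Ordered, unique identifier tuples.  Identifiers are opaque strings;
        all internal indexing is 0-based and all reported sets use the
        original identifiers.
    stoich
        Sparse map ``(metabolite_id, reaction_id) -> coefficient``.
    irreversible
        Subset of ``reactions`` restricted to non-negative flux.
    genes, gpr
        Declared gene identifiers and the partial map from reactions to
        :class:`GeneRule` trees.  A reaction with no rule cannot be removed
        by any gene knockout.
    bounds
        Optional finite flux bounds per reaction, kept only for the
        bound-honoring LP mode; ignored under cone semantics.
    """

    metabolites: tuple[str, ...]
    reactions: tuple[str, ...]
    stoich: Mapping[tuple[str, str], float]
    irreversible: frozenset[str]
    genes: frozenset[str] = frozenset()
    gpr: Mapping[str, GeneRule] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self):
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "irreversible", frozenset(self.irreversible))
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "stoich", dict(self.stoich))
        object.__setattr__(self, "gpr", dict(self.gpr))
        self._validate()

    def _validate(self):
        if len(set(self.metabolites)) != len(self.metabolites):
            raise ValueError("duplicate metabolite identifiers")
        if len(set(self.reactions)) != len(self.reactions):
            raise ValueError("duplicate reaction identifiers")
        mset, rset = set(self.metabolites), set(self.reactions)
        for (m, r), coeff in self.stoich.items():
            if m not in mset:
                raise ValueError(f"stoichiometry references unknown metabolite {m!r}")
            if r not in rset:
                raise ValueError(f"stoichiometry references unknown reaction {r!r}")
            if not np.isfinite(coeff):
                raise ValueError(f"non-finite coefficient for ({m!r}, {r!r})")
        if not self.irreversible <= rset:
            raise ValueError("irreversible set contains unknown reactions")
        for r, rule in self.gpr.items():
            if r not in rset:
                raise ValueError(f"GPR rule for unknown reaction {r!r}")
            undeclared = rule.genes() - self.genes
            if undeclared:
                raise ValueError(
                    f"GPR rule of {r!r} references undeclared genes {sorted(undeclared)}"
                )
        nonzero = {r for (m, r), c in self.stoich.items() if c != 0.0}
        empty = rset - nonzero
        if empty:
            warnings.warn(
                f"reactions with all-zero stoichiometry (free exchanges): {sorted(empty)}",
                stacklevel=3,
            )

    # -- derived views ----------------------------------------------------

    @property
    def reversible(self) -> frozenset[str]:
        return frozenset(self.reactions) - self.irreversible

    def metabolite_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.reactions)}

    def stoich_matrix(self) -> sp.csr_array:
        """The stoichiometric matrix ``S`` (metabolites x reactions)."""
        midx, ridx = self.metabolite_index(), self.reaction_index()
        rows, cols, data = [], [], []
        for (m, r), coeff in self.stoich.items():
            if coeff != 0.0:
                rows.append(midx[m])
                cols.append(ridx[r])
                data.append(float(coeff))
        return sp.csr_array(
            (data, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )

    def check_knockout_set(self, knockouts) -> frozenset[str]:
        K = frozenset(knockouts)
        unknown = K - set(self.reactions)
        if unknown:
            raise ValueError(f"unknown reactions in knockout set: {sorted(unknown)}")
        return K

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and self.irreversible == other.irreversible
            and self.genes == other.genes
            and self.gpr == other.gpr
            and self._clean_stoich() == other._clean_stoich()
        )

    def _clean_stoich(self):
        return {k: float(v) for k, v in self.stoich.items() if v != 0.0}


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def figure1_fixture() -> MetabolicNetwork:
    """The six-reaction worked example used throughout the test suite.

    Metabolites A-D; reactions (1 is the only reversible one):

    ====  ================  ==========
    id    stoichiometry     direction
    ====  ================  ==========
    1     <-> A             reversible exchange
    2     A -> B + C        irreversible
    3     B + C -> D        irreversible
    4     D ->              irreversible sink
    5     -> C              irreversible source
    6     C -> A + D        irreversible
    ====  ================  ==========

    Its flux cone is two-dimensional with generators (1,1,1,1,0,0) and
    (-1,0,0,1,1,1); the support lattice has exactly the elements
    ``{}, {1,2,3,4}, {1,4,5,6}, {2,3,4,5,6}, {1,2,3,4,5,6}``, so there is
    no blocked reaction, reactions 2,3 and 5,6 are partially coupled, and
    knocking out reaction 4 blocks the entire network.
    """
    stoich = {
        ("A", "1"): 1.0,
        ("A", "2"): -1.0,
        ("B", "2"): 1.0,
        ("C", "2"): 1.0,
        ("B", "3"): -1.0,
        ("C", "3"): -1.0,
        ("D", "3"): 1.0,
        ("D", "4"): -1.0,
        ("C", "5"): 1.0,
        ("C", "6"): -1.0,
        ("A", "6"): 1.0,
        ("D", "6"): 1.0,
    }
    return MetabolicNetwork(
        metabolites=("A", "B", "C", "D"),
        reactions=("1", "2", "3", "4", "5", "6"),
        stoich=stoich,
        irreversible=frozenset({"2", "3", "4", "5", "6"}),
    )


def random_network(
    n_metabolites: int,
    n_reactions: int,
    reversible_fraction: float,
    density: float,
    seed: int,
    n_exchanges: int = 2,
) -> MetabolicNetwork:
    """Generate a random test network, deterministic in ``seed``.

    Internal reactions draw coefficients from {-1, +1} independently per
    metabolite with probability ``density`` (at least one nonzero is
    forced).  ``n_exchanges`` single-metabolite exchange columns are
    appended so the network can carry flux across the system boundary.
    Every column (internal or exchange) is reversible with probability
    ``reversible_fraction``; with ``reversible_fraction=0`` all reactions
    are irreversible.
    """
    if n_metabolites < 1 or n_reactions < 1:
        raise ValueError("need at least one metabolite and one reaction")
    if not (0.0 <= reversible_fraction <= 1.0):
        raise ValueError("reversible_fraction must lie in [0, 1]")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    if n_exchanges < 0:
        raise ValueError("n_exchanges must be non-negative")

    rng = np.random.default_rng(seed)
    mets = tuple(f"M{i:02d}" for i in range(n_metabolites))
    internal = [f"R{i:02d}" for i in range(n_reactions)]
    exchanges = [f"X{i:02d}" for i in range(n_exchanges)]
    stoich: dict[tuple[str, str], float] = {}
    for r in internal:
        mask = rng.random(n_metabolites) < density
        if not mask.any():
            mask[rng.integers(n_metabolites)] = True
        signs = rng.choice([-1.0, 1.0], size=n_metabolites)
        for i, m in enumerate(mets):
            if mask[i]:
                stoich[(m, r)] = signs[i]
    for x in exchanges:
        m = mets[rng.integers(n_metabolites)]
        stoich[(m, x)] = float(rng.choice([-1.0, 1.0]))
    reactions = tuple(internal + exchanges)
    rev_mask = rng.random(len(reactions)) < reversible_fraction
    irreversible = frozenset(
        r for r, rev in zip(reactions, rev_mask) if not rev
    )
    return MetabolicNetwork(
        metabolites=mets,
        reactions=reactions,
        stoich=stoich,
        irreversible=irreversible,
    )
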