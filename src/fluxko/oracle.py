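"""Definition-level reference implementation for tiny networks.

For networks with a handful of reactions the entire support lattice
L = {supp v | v in C} can be enumerated outright: a reaction subset ``a``
belongs to L iff the maximal support achievable inside the sub-cone
``{v | v_i = 0 for i not in a}`` is exactly ``a``.  With the lattice in
hand, every coupling notion — blocked reactions, directional and partial
coupling, joint coupling of pairs or arbitrary sets — is decided by
exhaustive iteration over lattice elements, straight from the definitions
and with no shortcut shared with the production algorithms.  The test
suite uses this oracle to validate the LP/lattice machinery exactly on
random small networks.

Deliberately, the only primitive shared with the production path is the
raw LP feasibility call; no witness pooling, no bound refinement, no
representative compression.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .lp import ConeModel, LPConfig, Pathway
from .network import MetabolicNetwork

__all__ = ["EnumeratedLattice", "LatticeModel", "enumerate_lattice", "OracleAnalysis", "oracle_analysis"]


@dataclass(frozen=True)
class EnumeratedLattice:
    """The complete support lattice of a small network."""

    reactions: tuple[str, ...]
    elements: frozenset[frozenset[str]]

    @property
    def unblocked(self) -> frozenset[str]:
        out: set[str] = set()
        for a in self.elements:
            out |= a
        return frozenset(out)

    def max_below(self, knockouts) -> frozenset[str]:
        """Union of all elements disjoint from the knockout set."""
        K = frozenset(knockouts)
        out: set[str] = set()
        for a in self.elements:
            if a.isdisjoint(K):
                out |= a
        return frozenset(out)

    def blocks(self, knockouts, t: str) -> bool:
        """Plain blocking: no element avoids K while containing t."""
        return t not in self.max_below(knockouts)


def enumerate_lattice(
    net: MetabolicNetwork,
    config: LPConfig | None = None,
    max_reactions: int = 12,
) -> EnumeratedLattice:
    """Enumerate every support of a steady-state flux vector.

    Subsets are visited in order of increasing size; the union-closure law
    lets previously confirmed elements cover most candidates without any
    LP call (a subset equal to a union of known elements is itself an
    element).  Remaining members are decided by the maximal-support
    criterion, target by target, inside the sub-cone.
    """
    n = len(net.reactions)
    if n > max_reactions:
        raise ValueError(
            f"network has {n} reactions; oracle enumeration capped at {max_reactions}"
        )
    model = ConeModel(net, config)
    universe = frozenset(net.reactions)
    elements: list[frozenset[str]] = [frozenset()]
    for size in range(1, n + 1):
        for combo in itertools.combinations(sorted(net.reactions), size):
            a = frozenset(combo)
            covered: set[str] = set()
            for e in elements:
                if e <= a:
                    covered |= e
            if covered == a:
                elements.append(a)
                continue
            outside = universe - a
            feasible = True
            for t in sorted(a):
                if t in covered:
                    continue
                path = model.find_path(t, outside)
                if path is None:
                    feasible = False
                    break
                covered |= path.support
            if feasible and covered == a:
                elements.append(a)
    return EnumeratedLattice(reactions=net.reactions, elements=frozenset(elements))


class LatticeModel:
    """FindPath over an explicitly given lattice of reaction sets.

    Lets Algorithm 1 and everything above it run on a hand-specified
    qualitative model (no LP involved): a query for target t under
    knockouts K returns any lattice element containing t and disjoint from
    K.  Queries are counted in ``lp_calls`` for parity with the LP model.
    """

    def __init__(self, lattice: EnumeratedLattice):
        self.lattice = lattice
        self.reactions = lattice.reactions
        self.lp_calls = 0

    @classmethod
    def from_elements(cls, reactions, elements) -> "LatticeModel":
        """Build from generator sets; closes under union and adds the empty set."""
        gens = [frozenset(e) for e in elements]
        closed: set[frozenset[str]] = {frozenset()}
        for k in range(1, len(gens) + 1):
            for combo in itertools.combinations(gens, k):
                closed.add(frozenset().union(*combo))
        return cls(
            EnumeratedLattice(reactions=tuple(reactions), elements=frozenset(closed))
        )

    def find_path(self, target: str, knockouts=frozenset()) -> Pathway | None:
        K = frozenset(knockouts)
        if target in K:
            raise ValueError(f"target {target!r} is in the knockout set")
        self.lp_calls += 1
        candidates = [
            a
            for a in self.lattice.elements
            if target in a and a.isdisjoint(K)
        ]
        if not candidates:
            return None
        return Pathway(min(candidates, key=lambda a: (len(a), sorted(a))))


@dataclass(frozen=True)
class OracleAnalysis:
    """Every coupling notion, read off the enumerated lattice."""

    lattice: EnumeratedLattice
    blocked: frozenset[str]
    unblocked: frozenset[str]
    directional: frozenset[tuple[str, str]]  # ordered (r, s): r -> s, r != s
    classes: frozenset[frozenset[str]]
    joint: dict[frozenset[str], frozenset[str]]  # rep pair -> targets

    def multi_targets(self, knockouts) -> frozenset[str]:
        """Reactions jointly coupled to K per the general definition:
        blocked by K, by no non-empty proper subset, and not in K."""
        K = frozenset(knockouts)
        targets = set()
        for t in sorted(self.unblocked - K):
            if not self.lattice.blocks(K, t):
                continue
            minimal = True
            for size in range(1, len(K)):
                for sub in itertools.combinations(sorted(K), size):
                    if self.lattice.blocks(frozenset(sub), t):
                        minimal = False
                        break
                if not minimal:
                    break
            if minimal:
                targets.add(t)
        return frozenset(targets)


def oracle_analysis(lattice: EnumeratedLattice) -> OracleAnalysis:
    """Blocked set, couplings, classes and all pairwise joint couplings.

    Directional coupling r -> s is read as "every element avoiding r
    avoids s"; partial coupling is mutual directional coupling; joint
    couplings of representative pairs follow the pair definition verbatim
    (both single couplings absent, double knockout blocks the target).
    """
    unblocked = lattice.unblocked
    blocked = frozenset(lattice.reactions) - unblocked

    directional = set()
    for r in sorted(unblocked):
        for s in sorted(unblocked):
            if r == s:
                continue
            if all(s not in a for a in lattice.elements if r not in a):
                directional.add((r, s))

    rep_of: dict[str, str] = {}
    for r in sorted(unblocked):
        if r in rep_of:
            continue
        rep_of[r] = r
        for s in sorted(unblocked):
            if s not in rep_of and (r, s) in directional and (s, r) in directional:
                rep_of[s] = r
    classes_by_rep: dict[str, set[str]] = {}
    for r, rep in rep_of.items():
        classes_by_rep.setdefault(rep, set()).add(r)
    classes = frozenset(frozenset(c) for c in classes_by_rep.values())
    reps = sorted(classes_by_rep)

    joint: dict[frozenset[str], frozenset[str]] = {}
    for r, s in itertools.combinations(reps, 2):
        if (r, s) in directional or (s, r) in directional:
            continue
        targets = set()
        for t in sorted(unblocked - {r, s}):
            if (r, t) in directional or (s, t) in directional:
                continue
            if all(t not in a for a in lattice.elements if r not in a and s not in a):
                targets.add(t)
        joint[frozenset({r, s})] = frozenset(targets)

    return OracleAnalysis(
        lattice=lattice,
        blocked=blocked,
        unblocked=unblocked,
        directional=frozenset(directional),
        classes=classes,
        joint=joint,
    )
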