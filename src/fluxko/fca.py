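"""Maximal lattice elements under knockouts and flux coupling analysis.

The set L of supports of steady-state flux vectors is closed under union
(two pathways superposed are a pathway), so it is a finite lattice with a
unique maximal element 1_L — the set of unblocked reactions.  For a
knockout set K, the sub-lattice of elements disjoint from K again has a
maximal element, written here ``max_element(model, K).unblocked``: the
reactions that can still carry flux after removing K.

``max_element`` refines a lower bound (union of witness pathways found so
far) and an upper bound (reactions not yet proven blocked) until they meet;
each step either grows the lower bound by one FindPath success or shrinks
the upper bound by one FindPath failure.  Witness pathways are pooled and
reused across queries: a stored pathway disjoint from the current knockout
set proves all its members unblocked with zero LP calls, which is where
essentially all of the speed of a full double-knockout simulation comes
from.

Flux coupling analysis itself falls out of single-reaction knockouts:
``r -> s`` (knocking out r blocks s) holds iff s is missing from the
maximal element under {r}; mutual coupling partitions the unblocked
reactions into classes that are always active together (enzyme-subset-like
"reaction classes"), and one representative per class suffices for every
downstream knockout question.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Protocol

from .lp import ConeModel, LPConfig, Pathway
from .network import MetabolicNetwork

__all__ = [
    "PathwayModel",
    "WitnessPool",
    "MaximalElement",
    "max_element",
    "CouplingTable",
    "ClassPartition",
    "fca",
    "partial_classes",
]


class PathwayModel(Protocol):
    """Anything offering FindPath over a fixed reaction universe.

    The LP-backed :class:`~fluxko.lp.ConeModel` is the standard instance;
    :class:`~fluxko.oracle.LatticeModel` runs the same algorithms on an
    explicitly enumerated lattice, and alternative pathway semantics plug
    in the same way.
    """

    reactions: tuple[str, ...]
    lp_calls: int

    def find_path(self, target: str, knockouts=frozenset()) -> Pathway | None: ...


class WitnessPool:
    """Bounded FIFO pool of witness pathways reused as warm starts.

    Every stored pathway is a lattice element of the *unperturbed* network;
    when a knockout query arrives, pathways disjoint from the knockout set
    seed the lower bound for free.  Capacity defaults to 10000 with FIFO
    eviction.
    """

    def __init__(self, capacity: int = 10000):
        if capacity < 0:
            raise ValueError("capacity must be non-negative")
        self.capacity = capacity
        self._items: deque[Pathway] = deque()
        self._seen: set[frozenset[str]] = set()

    def add(self, pathway: Pathway) -> None:
        if not pathway.support or pathway.support in self._seen:
            return
        if self.capacity == 0:
            return
        if len(self._items) >= self.capacity:
            old = self._items.popleft()
            self._seen.discard(old.support)
        self._items.append(pathway)
        self._seen.add(pathway.support)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)


@dataclass(frozen=True)
class MaximalElement:
    """1_{L \\ K}: reactions unblocked after knocking out ``knockouts``."""

    knockouts: frozenset[str]
    unblocked: frozenset[str]
    lp_calls: int = 0


def max_element(
    model: PathwayModel,
    knockouts: Iterable[str] = frozenset(),
    pool: WitnessPool | None = None,
    known_unblocked: Iterable[str] | None = None,
) -> MaximalElement:
    """Compute the maximal lattice element avoiding ``knockouts``.

    Maintains ``lb <= 1_{L without K} <= ub``: ``ub`` starts from all
    reactions minus the knockouts (intersected with ``known_unblocked``,
    typically 1_L, when available), ``lb`` from the union of pooled
    witnesses disjoint from the knockout set.  Targets in ``ub - lb`` are
    tried in sorted order; each FindPath success extends ``lb`` with the
    whole witness support (stored in the pool), each failure removes the
    target from ``ub``.
    """
    K = frozenset(knockouts)
    universe = set(model.reactions)
    unknown = K - universe
    if unknown:
        raise ValueError(f"unknown reactions in knockout set: {sorted(unknown)}")
    ub = (set(known_unblocked) if known_unblocked is not None else universe) - K
    lb: set[str] = set()
    if pool is not None:
        for path in pool:
            if path.support.isdisjoint(K):
                lb |= path.support
    lb &= ub
    calls_before = model.lp_calls
    while lb != ub:
        t = min(ub - lb)
        path = model.find_path(t, K)
        if path is None:
            ub.discard(t)
        else:
            lb |= path.support
            if pool is not None:
                pool.add(path)
    return MaximalElement(K, frozenset(lb), model.lp_calls - calls_before)


# ---------------------------------------------------------------------------
# Coupling table and classes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CouplingTable:
    """Blocked reactions, directional couplings and partial-coupling classes.

    ``singles`` stores, per class representative r, the maximal element
    under the single knockout {r}; a knockout of any classmate has exactly
    the same effect, so queries for non-representatives are answered
    through ``rep_of``.
    """

    unblocked: frozenset[str]
    all_reactions: tuple[str, ...]
    rep_of: dict[str, str]
    singles: dict[str, frozenset[str]]
    lp_calls_blocked: int = 0
    lp_calls_couplings: int = 0

    @property
    def blocked(self) -> frozenset[str]:
        return frozenset(self.all_reactions) - self.unblocked

    @property
    def representatives(self) -> tuple[str, ...]:
        return tuple(sorted(self.singles))

    def class_of(self, r: str) -> frozenset[str]:
        rep = self.rep_of[r]
        return frozenset(s for s, p in self.rep_of.items() if p == rep)

    def unblocked_after(self, r: str) -> frozenset[str]:
        """1_{L without {r}} — identical for all classmates of r."""
        return self.singles[self.rep_of[r]]

    def blocked_by(self, r: str) -> frozenset[str]:
        """Unblocked reactions with zero flux once r is knocked out
        (always contains r and its classmates)."""
        return self.unblocked - self.unblocked_after(r)

    def coupled(self, r: str, s: str) -> bool:
        """Directional coupling r -> s: knocking out r blocks s."""
        if r not in self.unblocked or s not in self.unblocked:
            raise ValueError("coupling is defined for unblocked reactions")
        if r == s:
            return False
        return s not in self.unblocked_after(r)

    def partially_coupled(self, r: str, s: str) -> bool:
        return r != s and self.rep_of.get(r) == self.rep_of.get(s)

    def directional_pairs(self) -> list[tuple[str, str]]:
        """All ordered pairs (r, s), r != s, with r -> s (classmates included)."""
        out = []
        for r in sorted(self.unblocked):
            for s in sorted(self.blocked_by(r)):
                if s != r:
                    out.append((r, s))
        return out


@dataclass(frozen=True)
class ClassPartition:
    """Partition of the unblocked reactions into partial-coupling classes."""

    classes: tuple[frozenset[str], ...]
    representatives: tuple[str, ...]
    rep_of: dict[str, str]

    def class_of(self, r: str) -> frozenset[str]:
        rep = self.rep_of[r]
        return self.classes[self.representatives.index(rep)]

    def class_size(self, rep: str) -> int:
        return len(self.classes[self.representatives.index(rep)])


def fca(
    net_or_model: MetabolicNetwork | PathwayModel,
    config: LPConfig | None = None,
    pool: WitnessPool | None = None,
) -> tuple[CouplingTable, WitnessPool]:
    """Full flux coupling analysis via maximal elements.

    First computes 1_L (the blocked reactions), then discovers the
    partial-coupling classes incrementally: the smallest unassigned
    unblocked reaction r becomes a representative, the maximal element
    under {r} is computed with the shared witness pool, and every reaction
    blocked by r whose own single knockout also blocks r joins r's class.
    Returns the coupling table together with the pool for reuse by the
    double-knockout simulation.
    """
    model = _as_model(net_or_model, config)
    if pool is None:
        pool = WitnessPool()
    full = max_element(model, frozenset(), pool)
    unblocked = full.unblocked
    calls_blocked = full.lp_calls

    calls_before = model.lp_calls
    singles_cache: dict[str, frozenset[str]] = {}

    def single(r: str) -> frozenset[str]:
        if r not in singles_cache:
            singles_cache[r] = max_element(
                model, frozenset({r}), pool, known_unblocked=unblocked
            ).unblocked
        return singles_cache[r]

    rep_of: dict[str, str] = {}
    singles: dict[str, frozenset[str]] = {}
    for r in sorted(unblocked):
        if r in rep_of:
            continue
        rep_of[r] = r
        after_r = single(r)
        singles[r] = after_r
        for s in sorted(unblocked - after_r):
            if s == r or s in rep_of:
                continue
            if r not in single(s):  # mutual: s -> r as well
                rep_of[s] = r
    table = CouplingTable(
        unblocked=unblocked,
        all_reactions=model.reactions,
        rep_of=rep_of,
        singles=singles,
        lp_calls_blocked=calls_blocked,
        lp_calls_couplings=model.lp_calls - calls_before,
    )
    return table, pool


def partial_classes(table: CouplingTable) -> ClassPartition:
    """Extract the class partition (representative = smallest member)."""
    by_rep: dict[str, set[str]] = {}
    for r, rep in table.rep_of.items():
        by_rep.setdefault(rep, set()).add(r)
    reps = tuple(sorted(by_rep))
    classes = tuple(frozenset(by_rep[rep]) for rep in reps)
    return ClassPartition(classes=classes, representatives=reps, rep_of=dict(table.rep_of))


def _as_model(
    net_or_model: MetabolicNetwork | PathwayModel, config: LPConfig | None
) -> PathwayModel:
    if isinstance(net_or_model, MetabolicNetwork):
        return ConeModel(net_or_model, config)
    return net_or_model
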