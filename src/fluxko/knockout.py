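"""Double and multiple knockout simulation with joint-coupling extraction.

A reaction t is *jointly coupled* to an uncoupled pair {r, s} when the
double knockout blocks t although neither single knockout does.  Over a
support lattice this has a purely set-theoretic characterization,

    {r, s} -> t   iff   t in (1_{L\\{r}}  intersect  1_{L\\{s}}) minus 1_{L\\{r,s}},

which generalizes to a knockout set K via the maximal elements of all its
cardinality-(|K|-1) subsets.  The full double-knockout simulation therefore
needs exactly one maximal-element computation per *candidate pair*:
unordered pairs of class representatives neither of which is directionally
coupled to the other (a pair with a coupling is redundant — its effect
equals a single knockout).  Witness pathways from the FCA stage are shared
throughout.

Candidate sets for deeper knockouts (triples and beyond) are produced by
the same filtering idea: a d-subset of representatives survives filter
order m when it violates no coupling of order <= m (no internal directional
coupling for m = 1; additionally no member jointly coupled to a pair of the
others for m = 2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .fca import (
    ClassPartition,
    CouplingTable,
    MaximalElement,
    PathwayModel,
    WitnessPool,
    fca,
    max_element,
    partial_classes,
    _as_model,
)
from .lp import LPConfig
from .network import MetabolicNetwork

__all__ = [
    "JointCouplingRecord",
    "CandidateSet",
    "candidate_pairs",
    "double_knockout_analysis",
    "candidate_sets",
    "multi_knockout",
]


@dataclass(frozen=True)
class JointCouplingRecord:
    """Outcome of one double knockout {r, s} of class representatives.

    ``targets`` are the reactions jointly coupled to the pair (blocked by
    the double knockout but by neither single one); records with empty
    targets are retained, flagged ``has_joint_effect=False``, so that
    joint-effect ratios can be computed without re-running the simulation.
    """

    pair: tuple[str, str]
    targets: frozenset[str]
    unblocked_after: frozenset[str]
    has_joint_effect: bool

    def class_mapped(self, rep_of: dict[str, str]) -> "JointCouplingRecord":
        """Project pair and targets onto class representatives."""
        a, b = sorted(rep_of[x] for x in self.pair)
        return JointCouplingRecord(
            pair=(a, b),
            targets=frozenset(rep_of[t] for t in self.targets),
            unblocked_after=self.unblocked_after,
            has_joint_effect=self.has_joint_effect,
        )


@dataclass(frozen=True)
class CandidateSet:
    """d-subsets of representatives surviving coupling filters of order <= m."""

    d: int
    m: int
    members: frozenset[frozenset[str]]

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(sorted(self.members, key=sorted))


def candidate_pairs(
    partition: ClassPartition, table: CouplingTable
) -> CandidateSet:
    """All uncoupled unordered pairs of class representatives (K_{2,1})."""
    members = set()
    reps = partition.representatives
    for r, s in itertools.combinations(reps, 2):
        if s in table.unblocked_after(r) and r in table.unblocked_after(s):
            members.add(frozenset({r, s}))
    return CandidateSet(d=2, m=1, members=frozenset(members))


def double_knockout_analysis(
    net_or_model: MetabolicNetwork | PathwayModel,
    config: LPConfig | None = None,
    *,
    table: CouplingTable | None = None,
    pool: WitnessPool | None = None,
    use_representatives: bool = True,
    use_witnesses: bool = True,
) -> list[JointCouplingRecord]:
    """Complete double-knockout simulation.

    Runs FCA first when no ``table`` is supplied, then computes the maximal
    element under every candidate double knockout, sharing the witness
    pool, and extracts the jointly coupled targets.

    ``use_representatives=False`` iterates over *all* uncoupled unblocked
    pairs instead of representative pairs (variant A);
    ``use_witnesses=False`` additionally drops the witness pool for the
    double-knockout stage (variant B).  Both variants produce the same
    class-mapped joint couplings, only slower.
    """
    model = _as_model(net_or_model, config)
    if table is None:
        table, pool = fca(model, pool=pool)
    elif pool is None:
        pool = WitnessPool()
    dko_pool = pool if use_witnesses else None

    if use_representatives:
        partition = partial_classes(table)
        pairs = sorted(
            (tuple(sorted(p)) for p in candidate_pairs(partition, table).members)
        )
    else:
        pairs = [
            (r, s)
            for r, s in itertools.combinations(sorted(table.unblocked), 2)
            if s in table.unblocked_after(r) and r in table.unblocked_after(s)
        ]

    records = []
    for r, s in pairs:
        me = max_element(
            model, frozenset({r, s}), dko_pool, known_unblocked=table.unblocked
        )
        targets = (
            table.unblocked_after(r) & table.unblocked_after(s)
        ) - me.unblocked
        records.append(
            JointCouplingRecord(
                pair=(r, s),
                targets=frozenset(targets),
                unblocked_after=me.unblocked,
                has_joint_effect=bool(targets),
            )
        )
    return records


def candidate_sets(
    d: int,
    m: int,
    table: CouplingTable,
    joint: list[JointCouplingRecord] | None = None,
    max_d: int = 4,
) -> CandidateSet:
    """Candidate d-subsets of representatives for order-d knockouts (K_{d,m}).

    Filter order m = 1 removes subsets containing a directionally coupled
    ordered pair; m = 2 additionally removes subsets containing a pair
    jointly coupled to a third member (requires the double-knockout
    records).  Higher filter orders would need coupling data of order > 2,
    which this interface does not carry.
    """
    if d < 2 or d > max_d:
        raise ValueError(f"d must lie in [2, {max_d}]")
    if not (1 <= m <= d - 1):
        raise ValueError("filter order m must lie in {1, .., d-1}")
    if m > 2:
        raise ValueError("filter orders beyond 2 need higher-order coupling data")
    if m >= 2 and joint is None:
        raise ValueError("m = 2 filtering requires double-knockout records")

    reps = tuple(sorted({table.rep_of[r] for r in table.unblocked}))
    joint_targets: dict[frozenset[str], frozenset[str]] = {}
    if joint is not None:
        for rec in joint:
            joint_targets[frozenset(rec.pair)] = rec.targets

    members = set()
    for combo in itertools.combinations(reps, d):
        ok = True
        for a, b in itertools.permutations(combo, 2):
            if b not in table.unblocked_after(a):  # a -> b
                ok = False
                break
        if ok and m >= 2:
            for a, b in itertools.combinations(combo, 2):
                targets = joint_targets.get(frozenset({a, b}), frozenset())
                if any(c in targets for c in combo if c not in (a, b)):
                    ok = False
                    break
        if ok:
            members.add(frozenset(combo))
    return CandidateSet(d=d, m=m, members=frozenset(members))


def multi_knockout(
    net_or_model: MetabolicNetwork | PathwayModel,
    knockouts,
    config: LPConfig | None = None,
    *,
    table: CouplingTable | None = None,
    pool: WitnessPool | None = None,
    compute_targets: bool = True,
) -> tuple[MaximalElement, frozenset[str]]:
    """Effect of one specific multiple knockout of unblocked reactions.

    Returns the maximal element under K and, when requested, the reactions
    jointly coupled to K: blocked by K but by no proper subset, computed as

        (intersection over k of 1_{L \\ (K minus {k})})  minus  1_{L \\ K}.

    For |K| = 1 the degenerate convention returns the directional couplings
    of the single reaction (targets = reactions its knockout blocks).
    Members of K are never reported as targets.  K must consist of
    unblocked reactions.
    """
    model = _as_model(net_or_model, config)
    K = frozenset(knockouts)
    if not K:
        raise ValueError("knockout set must be non-empty")
    if table is None:
        table, pool = fca(model, pool=pool)
    elif pool is None:
        pool = WitnessPool()
    blocked_members = K - table.unblocked
    if blocked_members:
        raise ValueError(
            f"knockout set contains blocked reactions: {sorted(blocked_members)}"
        )
    me = max_element(model, K, pool, known_unblocked=table.unblocked)
    if not compute_targets:
        return me, frozenset()
    if len(K) == 1:
        targets = (table.unblocked - me.unblocked) - K
        return me, frozenset(targets)
    inter: frozenset[str] | None = None
    for k in sorted(K):
        sub = K - {k}
        if len(sub) == 1:
            part = table.unblocked_after(next(iter(sub)))
        else:
            part = max_element(
                model, sub, pool, known_unblocked=table.unblocked
            ).unblocked
        inter = part if inter is None else (inter & part)
    targets = (inter - me.unblocked) - K
    return me, frozenset(targets)
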