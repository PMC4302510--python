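"""Summary statistics over coupling and knockout results.

Three views, mirroring how knockout screens are usually reported:

* *Impact*: how much does an average (single or double) knockout block?
  Single impact of a representative r counts the coupling classes other
  than [r] that its knockout blocks (reaction variant: their reactions);
  double impact counts the *additional* classes blocked jointly, averaged
  over the pairs that have a joint effect at all, together with the
  percentage of candidate pairs showing any joint effect.
* *Options*: from the target's perspective — for an average unblocked
  reaction t, how many single reactions r (resp. expanded reaction pairs
  {r', s'}) would block it?  Reaction-level counting: classmates of t count
  as single options, and a representative-pair record expands to
  |[r]| * |[s]| reaction pairs.
* *Biomass blockers*: the same two questions asked for one distinguished
  (biomass) reaction, excluding its own class for single knockouts and any
  directionally coupled partner for double knockouts.

All statistics are pure functions of the coupling table, the class
partition and the double-knockout records; nothing is re-solved here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fca import ClassPartition, CouplingTable
from .knockout import JointCouplingRecord

__all__ = ["ImpactSummary", "OptionSummary", "BiomassSummary", "impact_stats", "option_stats", "biomass_blockers"]


@dataclass(frozen=True)
class ImpactSummary:
    n_unblocked: int
    n_classes: int
    single_mean_classes: float
    single_mean_reactions: float
    double_mean_additional_classes: float
    double_mean_additional_reactions: float
    double_ratio_percent: float


@dataclass(frozen=True)
class OptionSummary:
    single_mean_options: float
    double_mean_options: float


@dataclass(frozen=True)
class BiomassSummary:
    biomass_reaction_id: str
    class_size: int
    single_blocking_classes: int
    single_blocking_reactions: int
    double_blocking_class_pairs: int
    double_blocking_reaction_pairs: int


def _class_sizes(partition: ClassPartition) -> dict[str, int]:
    return {
        rep: len(cls)
        for rep, cls in zip(partition.representatives, partition.classes)
    }


def impact_stats(
    table: CouplingTable,
    partition: ClassPartition,
    records: list[JointCouplingRecord],
) -> ImpactSummary:
    """Average blocking impact of single and double knockouts.

    Blocked-by sets are unions of whole coupling classes, so the class
    count of a single knockout is the number of representatives (other
    than the knocked-out one) in its blocked-by set.  Double means are
    conditional on the pair having a joint effect; the ratio is the
    percentage of candidate pairs that do.
    """
    reps = partition.representatives
    if not reps:
        raise ValueError("impact statistics undefined without unblocked reactions")
    sizes = _class_sizes(partition)

    single_classes, single_reactions = [], []
    for r in reps:
        blocked = table.blocked_by(r)
        single_classes.append(
            sum(1 for rep in reps if rep != r and rep in blocked)
        )
        single_reactions.append(len(blocked) - sizes[r])

    effective = [rec for rec in records if rec.has_joint_effect]
    if effective:
        dbl_classes = [
            len({table.rep_of[t] for t in rec.targets}) for rec in effective
        ]
        dbl_reactions = [len(rec.targets) for rec in effective]
        mean_dc = sum(dbl_classes) / len(effective)
        mean_dr = sum(dbl_reactions) / len(effective)
    else:
        mean_dc = mean_dr = 0.0
    ratio = 100.0 * len(effective) / len(records) if records else 0.0

    return ImpactSummary(
        n_unblocked=len(table.unblocked),
        n_classes=len(reps),
        single_mean_classes=sum(single_classes) / len(reps),
        single_mean_reactions=sum(single_reactions) / len(reps),
        double_mean_additional_classes=mean_dc,
        double_mean_additional_reactions=mean_dr,
        double_ratio_percent=ratio,
    )


def option_stats(
    table: CouplingTable,
    partition: ClassPartition,
    records: list[JointCouplingRecord],
) -> OptionSummary:
    """Average number of knockout options per unblocked target reaction.

    Single options of t: unblocked reactions r whose knockout blocks t —
    every class whose knockout blocks t contributes its full size.  The
    count is reflexive (t's own knockout silences t, so t counts as one of
    its own options, as do its classmates).  Double options of t: records
    targeting t expand to |[r]| * |[s]| reaction pairs.  Both averaged over
    all of 1_L.
    """
    sizes = _class_sizes(partition)
    unblocked = sorted(table.unblocked)
    if not unblocked:
        return OptionSummary(0.0, 0.0)

    single_total = 0
    for t in unblocked:
        single_total += sum(
            sizes[rep]
            for rep in partition.representatives
            if t in table.blocked_by(rep)
        )

    double_total = 0
    for rec in records:
        if not rec.has_joint_effect:
            continue
        r, s = rec.pair
        weight = sizes[table.rep_of[r]] * sizes[table.rep_of[s]]
        double_total += weight * len(rec.targets)

    n = len(unblocked)
    return OptionSummary(single_total / n, double_total / n)


def biomass_blockers(
    table: CouplingTable,
    partition: ClassPartition,
    records: list[JointCouplingRecord],
    biomass_id: str,
) -> BiomassSummary:
    """Single and double knockouts that block one distinguished reaction.

    Single: classes (and their reactions) outside the biomass's own class
    whose knockout blocks it.  Double: representative pairs whose joint
    targets include the biomass, restricted to pairs where neither member
    is directionally coupled to it, expanded to reaction pairs by class
    sizes.
    """
    if biomass_id not in table.unblocked:
        raise ValueError(f"biomass reaction {biomass_id!r} is blocked or unknown")
    sizes = _class_sizes(partition)
    b_rep = table.rep_of[biomass_id]

    single_classes = [
        rep
        for rep in partition.representatives
        if rep != b_rep and biomass_id in table.blocked_by(rep)
    ]
    single_reactions = sum(sizes[rep] for rep in single_classes)

    class_pairs = 0
    reaction_pairs = 0
    for rec in records:
        if biomass_id not in rec.targets:
            continue
        r, s = rec.pair
        # joint coupling already excludes pairs with a member coupled to the
        # target, but guard explicitly per the reporting rule
        if biomass_id in table.blocked_by(r) or biomass_id in table.blocked_by(s):
            continue
        class_pairs += 1
        reaction_pairs += sizes[table.rep_of[r]] * sizes[table.rep_of[s]]

    return BiomassSummary(
        biomass_reaction_id=biomass_id,
        class_size=sizes[b_rep],
        single_blocking_classes=len(single_classes),
        single_blocking_reactions=single_reactions,
        double_blocking_class_pairs=class_pairs,
        double_blocking_reaction_pairs=reaction_pairs,
    )
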