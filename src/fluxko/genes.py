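"""Gene knockouts: GPR-mediated reaction removal and gene coupling.

Gene and reaction knockouts are not in 1-1 correspondence: one gene may
silence several reactions, and a reaction guarded by an ``or`` of isozymes
survives any single gene loss.  The map from a knocked-out gene set Γ to
its *associated reactions* K_Γ evaluates each reaction's GPR rule with the
genes of Γ switched off (and all others on); rules that evaluate false
contribute their reaction.  A reaction r is then *coupled* to the gene
knockout Γ when r is missing from the maximal lattice element after
knocking out K_Γ.

Two deliberate asymmetries with reaction analysis:

* No class representatives exist for genes — distinct gene pairs must all
  be tested.  Instead, results are memoized on the induced reaction set
  K_Γ, which is frequently shared between gene sets.
* Couplings of a double gene knockout are *not* filtered against the
  single-knockout results: with negation in a rule, a reaction can be
  associated to {g1} yet not to {g1, g2}, so minimality in the reaction
  sense does not apply.
"""

from __future__ import annotations

from dataclasses import dataclass
import itertools

from .fca import CouplingTable, PathwayModel, WitnessPool, fca, max_element, _as_model
from .lp import LPConfig
from .network import MetabolicNetwork

__all__ = ["GeneKnockoutRecord", "associated_reactions", "gene_coupling", "all_gene_knockouts"]


@dataclass(frozen=True)
class GeneKnockoutRecord:
    """Effect of knocking out a set of genes.

    ``associated`` is K_Γ (reactions whose GPR evaluates false);
    ``coupled`` is every unblocked reaction with zero flux in all steady
    states once the associated reactions are removed — it contains the
    unblocked part of K_Γ itself plus everything dragged down with it.
    """

    genes: frozenset[str]
    associated: frozenset[str]
    coupled: frozenset[str]


def associated_reactions(net: MetabolicNetwork, genes) -> frozenset[str]:
    """K_Γ: reactions silenced by knocking out all genes in ``genes``.

    Evaluates every GPR rule under the assignment g=False for g in Γ and
    g=True otherwise; reactions without a rule are never associated.
    """
    gamma = frozenset(genes)
    unknown = gamma - net.genes
    if unknown:
        raise ValueError(f"unknown gene identifiers: {sorted(unknown)}")
    assignment = {g: g not in gamma for g in net.genes}
    return frozenset(
        r for r, rule in net.gpr.items() if not rule.evaluate(assignment)
    )


def gene_coupling(
    net: MetabolicNetwork,
    genes,
    pool: WitnessPool | None = None,
    config: LPConfig | None = None,
    *,
    model: PathwayModel | None = None,
    table: CouplingTable | None = None,
) -> GeneKnockoutRecord:
    """Reactions coupled to the knockout of the gene set ``genes``.

    Computes K_Γ, drops its blocked members (already absent from every
    pathway), runs the maximal-element computation under the remainder and
    reports ``coupled = 1_L minus 1_{L without K_Γ}``.  An existing model /
    coupling table may be passed to share work across many gene queries.
    """
    if model is None:
        model = _as_model(net, config)
    if table is None:
        table, pool = fca(model, pool=pool)
    elif pool is None:
        pool = WitnessPool()
    gamma = frozenset(genes)
    associated = associated_reactions(net, gamma)
    ko = associated & table.unblocked
    if ko:
        me = max_element(model, ko, pool, known_unblocked=table.unblocked)
        coupled = table.unblocked - me.unblocked
    else:
        coupled = frozenset()
    return GeneKnockoutRecord(genes=gamma, associated=associated, coupled=coupled)


def all_gene_knockouts(
    net: MetabolicNetwork,
    order: int,
    config: LPConfig | None = None,
    *,
    model: PathwayModel | None = None,
    table: CouplingTable | None = None,
    pool: WitnessPool | None = None,
) -> list[GeneKnockoutRecord]:
    """All single (order 1) or pairwise (order 2) gene knockouts.

    Iterates deterministically over sorted genes resp. sorted gene pairs,
    sharing one witness pool, and memoizes the lattice computation on the
    induced unblocked knockout set, so gene sets with identical associated
    reactions cost one maximal-element computation.  Genes appearing in no
    rule still produce (empty) records, so the record count is |G| resp.
    |G|(|G|-1)/2.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if model is None:
        model = _as_model(net, config)
    if table is None:
        table, pool = fca(model, pool=pool)
    elif pool is None:
        pool = WitnessPool()

    cache: dict[frozenset[str], frozenset[str]] = {}

    def coupled_for(ko: frozenset[str]) -> frozenset[str]:
        if not ko:
            return frozenset()
        if ko not in cache:
            me = max_element(model, ko, pool, known_unblocked=table.unblocked)
            cache[ko] = table.unblocked - me.unblocked
        return cache[ko]

    if order == 1:
        gene_sets = [frozenset({g}) for g in sorted(net.genes)]
    else:
        gene_sets = [
            frozenset(pair) for pair in itertools.combinations(sorted(net.genes), 2)
        ]
    records = []
    for gamma in gene_sets:
        associated = associated_reactions(net, gamma)
        coupled = coupled_for(associated & table.unblocked)
        records.append(
            GeneKnockoutRecord(genes=gamma, associated=associated, coupled=coupled)
        )
    return records
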