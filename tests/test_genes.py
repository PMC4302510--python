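import itertools

import pytest

import fluxko as fk
from fluxko.fca import fca, max_element
from fluxko.oracle import LatticeModel, oracle_analysis


def _two_gene_net():
    """r1 needs g1; r2 survives unless both g1 and g2 are lost."""
    net = fk.MetabolicNetwork(
        ("A",),
        ("r1", "r2", "r3"),
        {("A", "r1"): 1.0, ("A", "r2"): 1.0, ("A", "r3"): -1.0},
        frozenset({"r1", "r2", "r3"}),
        genes=frozenset({"g1", "g2"}),
        gpr={
            "r1": fk.parse_gene_rule("g1"),
            "r2": fk.parse_gene_rule("g1 or g2"),
        },
    )
    return net


class TestAssociatedReactions:
    def test_single_gene(self):
        assert fk.associated_reactions(_two_gene_net(), {"g1"}) == {"r1"}

    def test_double_gene(self):
        assert fk.associated_reactions(_two_gene_net(), {"g1", "g2"}) == {"r1", "r2"}

    def test_negation_nuance(self):
        """With r = g1 or (not g2), r is associated to {g1} but NOT to
        {g1, g2}: losing g2 as well re-enables the reaction."""
        net = fk.MetabolicNetwork(
            ("A",),
            ("r", "sink"),
            {("A", "r"): 1.0, ("A", "sink"): -1.0},
            frozenset({"r", "sink"}),
            genes=frozenset({"g1", "g2"}),
            gpr={"r": fk.parse_gene_rule("g1 or not g2")},
        )
        assert fk.associated_reactions(net, {"g1"}) == {"r"}
        assert fk.associated_reactions(net, {"g1", "g2"}) == frozenset()

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError):
            fk.associated_reactions(_two_gene_net(), {"gX"})

    def test_empty_gene_set(self):
        assert fk.associated_reactions(_two_gene_net(), frozenset()) == frozenset()


def _figure1_with_rules():
    fig = fk.figure1_fixture()
    return fk.MetabolicNetwork(
        fig.metabolites, fig.reactions, fig.stoich, fig.irreversible,
        genes=frozenset({"gA", "gB", "gC"}),
        gpr={
            "2": fk.parse_gene_rule("gA"),
            "3": fk.parse_gene_rule("gA or gB"),
            "5": fk.parse_gene_rule("gC"),
            "6": fk.parse_gene_rule("gC"),
        },
    )


class TestGeneCoupling:
    def test_single_gene_knockouts_on_worked_example(self):
        net = _figure1_with_rules()
        records = {
            tuple(sorted(r.genes)): r for r in fk.all_gene_knockouts(net, 1)
        }
        assert records[("gA",)].associated == {"2"}
        assert records[("gA",)].coupled == {"2", "3"}   # classmate 3 follows
        assert records[("gB",)].coupled == frozenset()
        assert records[("gC",)].associated == {"5", "6"}
        assert records[("gC",)].coupled == {"5", "6"}

    def test_double_gene_knockout_reaches_joint_coupling(self):
        # K_{gA,gC} = {2,5,6}; the {2,5} joint coupling empties the lattice
        net = _figure1_with_rules()
        rec = fk.gene_coupling(net, {"gA", "gC"})
        assert rec.coupled == {"1", "2", "3", "4", "5", "6"}

    def test_whole_network_collapse_via_single_rule(self):
        fig = fk.figure1_fixture()
        net = fk.MetabolicNetwork(
            fig.metabolites, fig.reactions, fig.stoich, fig.irreversible,
            genes=frozenset({"gX"}),
            gpr={"4": fk.parse_gene_rule("gX")},
        )
        rec = fk.gene_coupling(net, {"gX"})
        assert rec.coupled == set(fig.reactions)

    def test_empty_gamma(self):
        rec = fk.gene_coupling(_figure1_with_rules(), frozenset())
        assert rec.associated == frozenset() and rec.coupled == frozenset()

    def test_definitional_identity(self):
        """coupled(Gamma) = 1_L minus max_element(K_Gamma intersect 1_L)."""
        net = _figure1_with_rules()
        model = fk.ConeModel(net)
        table, pool = fca(model)
        for gamma in [{"gA"}, {"gC"}, {"gA", "gB"}, {"gA", "gC"}]:
            rec = fk.gene_coupling(net, gamma, model=model, table=table, pool=pool)
            ko = fk.associated_reactions(net, gamma) & table.unblocked
            if ko:
                expect = table.unblocked - max_element(model, ko, pool).unblocked
            else:
                expect = frozenset()
            assert rec.coupled == expect

    def test_monotone_for_negation_free_rules(self):
        net = _figure1_with_rules()
        genes = sorted(net.genes)
        subsets = [
            frozenset(c)
            for k in range(len(genes) + 1)
            for c in itertools.combinations(genes, k)
        ]
        results = {g: fk.gene_coupling(net, g) for g in subsets}
        for small in subsets:
            for big in subsets:
                if small <= big:
                    assert results[small].associated <= results[big].associated
                    assert results[small].coupled <= results[big].coupled

    def test_memoization_shares_lattice_computations(self):
        """Two genes with identical rules: identical records, and the pair
        stage costs no LP beyond the memoized single computation."""
        fig = fk.figure1_fixture()
        net = fk.MetabolicNetwork(
            fig.metabolites, fig.reactions, fig.stoich, fig.irreversible,
            genes=frozenset({"g1", "g2"}),
            gpr={"5": fk.parse_gene_rule("g1 and g2")},
        )
        model_a = fk.ConeModel(net)
        table_a, pool_a = fca(model_a)
        before = model_a.lp_calls
        records = fk.all_gene_knockouts(net, 1, model=model_a, table=table_a, pool=pool_a)
        both_genes = model_a.lp_calls - before
        assert records[0].coupled == records[1].coupled == {"5", "6"}

        # identically prepared second model: one explicit lattice call for
        # K = {5} costs exactly what the two-gene iteration cost (the second
        # gene was answered from the memo)
        model_b = fk.ConeModel(net)
        table_b, pool_b = fca(model_b)
        before = model_b.lp_calls
        max_element(model_b, {"5"}, pool_b, known_unblocked=table_b.unblocked)
        one_computation = model_b.lp_calls - before
        assert both_genes == one_computation

    def test_record_counts_cover_all_genes(self):
        net = _figure1_with_rules()
        assert len(fk.all_gene_knockouts(net, 1)) == 3
        assert len(fk.all_gene_knockouts(net, 2)) == 3
        with pytest.raises(ValueError):
            fk.all_gene_knockouts(net, 3)

    def test_double_not_filtered_against_single(self):
        """Gene coupling keeps reactions already hit by a single knockout:
        coupled({g1,g2}) reports everything blocked by K_{g1,g2}, without
        subtracting the single-gene results."""
        net = _figure1_with_rules()
        single = fk.gene_coupling(net, {"gA"})
        double = fk.gene_coupling(net, {"gA", "gB"})
        assert single.coupled <= double.coupled
        assert "2" in double.coupled  # still reported although gA alone blocks it


class TestAbstractLatticeExample:
    """A gene whose associated reactions are {1,3}, on a qualitative model
    with couplings 3 -> 4 and {1,3} -> 6: four reactions end up coupled."""

    def _model(self):
        return LatticeModel.from_elements(
            reactions=("1", "2", "3", "4", "5", "6"),
            elements=[{"2"}, {"5"}, {"3", "4"}, {"1", "6"}, {"3", "6"}],
        )

    def test_stated_couplings_hold(self):
        analysis = oracle_analysis(self._model().lattice)
        assert ("3", "4") in analysis.directional
        assert ("1", "4") not in analysis.directional
        assert analysis.joint[frozenset({"1", "3"})] == {"6"}

    def test_coupled_set_has_size_four(self):
        model = self._model()
        unblocked = model.lattice.unblocked
        me = max_element(model, {"1", "3"})
        coupled = unblocked - me.unblocked
        assert coupled == {"1", "3", "4", "6"}
        assert len(coupled) == 4
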