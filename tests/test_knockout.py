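import pytest

import fluxko as fk
from .conftest import battery_network

FIG1_JOINT = {
    frozenset({"1", "2"}): {"4", "5", "6"},
    frozenset({"1", "5"}): {"2", "3", "4"},
    frozenset({"2", "5"}): {"1", "4"},
}


class TestCandidatePairs:
    def test_figure1(self, figure1_analysis):
        _, table, _, partition, _ = figure1_analysis
        cs = fk.candidate_pairs(partition, table)
        assert cs.members == frozenset(FIG1_JOINT)
        assert (cs.d, cs.m) == (2, 1)

    def test_blocking_representative_excluded_from_every_pair(self, figure1_analysis):
        # representative 4 blocks everything, so no candidate pair contains it
        _, table, _, partition, _ = figure1_analysis
        cs = fk.candidate_pairs(partition, table)
        assert all("4" not in pair for pair in cs.members)

    def test_fully_uncoupled_classes_give_all_pairs(self):
        net = fk.MetabolicNetwork(
            ("A", "B", "C"),
            ("a1", "a2", "b1", "b2", "c1", "c2"),
            {("A", "a1"): 1.0, ("A", "a2"): -1.0,
             ("B", "b1"): 1.0, ("B", "b2"): -1.0,
             ("C", "c1"): 1.0, ("C", "c2"): -1.0},
            frozenset(["a1", "a2", "b1", "b2", "c1", "c2"]),
        )
        table, _ = fk.fca(net)
        partition = fk.partial_classes(table)
        assert len(partition.classes) == 3
        assert len(fk.candidate_pairs(partition, table)) == 3


class TestDoubleKnockout:
    def test_figure1_joint_couplings(self, figure1_analysis):
        _, _, _, _, records = figure1_analysis
        got = {frozenset(r.pair): set(r.targets) for r in records}
        assert got == FIG1_JOINT
        assert all(r.has_joint_effect for r in records)

    def test_redundant_pairs_never_analysed(self, figure1_analysis):
        """{1,4} is equivalent to the single knockout of 4, and any pair with
        3 or 5's classmate is covered by its representative."""
        _, _, _, _, records = figure1_analysis
        pairs = [r.pair for r in records]
        assert ("1", "4") not in pairs
        assert all("3" not in p and "6" not in p for p in pairs)

    def test_record_order_deterministic_and_sorted(self, figure1_analysis):
        _, _, _, _, records = figure1_analysis
        assert [r.pair for r in records] == sorted(r.pair for r in records)
        assert all(r.pair == tuple(sorted(r.pair)) for r in records)

    def test_proposition1_invariants(self, figure1_analysis):
        _, table, _, _, records = figure1_analysis
        for rec in records:
            r, s = rec.pair
            assert rec.targets.isdisjoint({r, s})
            assert rec.targets.isdisjoint(table.blocked_by(r) | table.blocked_by(s))

    def test_symmetry_of_pair_order(self, figure1):
        model = fk.ConeModel(figure1)
        table, pool = fk.fca(model)
        me_rs, t_rs = fk.multi_knockout(model, ["1", "2"], table=table, pool=pool)
        me_sr, t_sr = fk.multi_knockout(model, ["2", "1"], table=table, pool=pool)
        assert me_rs.unblocked == me_sr.unblocked
        assert t_rs == t_sr


class TestCandidateSets:
    def test_triples_first_order_filter(self, figure1_analysis):
        _, table, _, _, records = figure1_analysis
        cs = fk.candidate_sets(3, 1, table)
        assert cs.members == {frozenset({"1", "2", "5"})}

    def test_triples_second_order_filter_removes_joint_pair(self, figure1_analysis):
        # {2,5} -> 1 eliminates the only surviving triple
        _, table, _, _, records = figure1_analysis
        cs = fk.candidate_sets(3, 2, table, records)
        assert cs.members == frozenset()

    def test_pairs_match_candidate_pairs(self, figure1_analysis):
        _, table, _, partition, _ = figure1_analysis
        assert (
            fk.candidate_sets(2, 1, table).members
            == fk.candidate_pairs(partition, table).members
        )

    def test_filter_order_preconditions(self, figure1_analysis):
        _, table, _, _, records = figure1_analysis
        with pytest.raises(ValueError):
            fk.candidate_sets(3, 2, table, None)
        with pytest.raises(ValueError):
            fk.candidate_sets(4, 3, table, records)
        with pytest.raises(ValueError):
            fk.candidate_sets(5, 1, table)
        with pytest.raises(ValueError):
            fk.candidate_sets(3, 0, table)


class TestMultiKnockout:
    def test_triple_knockout(self, figure1):
        me, targets = fk.multi_knockout(figure1, ["1", "2", "5"])
        assert me.unblocked == set()
        assert targets == set()

    def test_single_knockout_degenerates_to_directional_couplings(self, figure1):
        me, targets = fk.multi_knockout(figure1, ["4"])
        assert me.unblocked == set()
        assert targets == {"1", "2", "3", "5", "6"}

    def test_pair_targets(self, figure1):
        _, targets = fk.multi_knockout(figure1, ["2", "5"])
        assert targets == {"1", "4"}

    def test_blocked_member_rejected(self):
        net = fk.MetabolicNetwork(
            ("A", "B"),
            ("r_dead", "r_in", "r_out"),
            {("A", "r_dead"): -1.0, ("B", "r_in"): 1.0, ("B", "r_out"): -1.0},
            frozenset({"r_dead", "r_in", "r_out"}),
        )
        with pytest.raises(ValueError, match="blocked"):
            fk.multi_knockout(net, ["r_dead"])
        with pytest.raises(ValueError):
            fk.multi_knockout(net, [])


class TestVariants:
    @pytest.mark.parametrize("seed_index", [0, 7, 14])
    def test_variants_agree_class_mapped(self, seed_index):
        net = battery_network(seed_index)
        model = fk.ConeModel(net)
        table, pool = fk.fca(model)
        default = fk.double_knockout_analysis(model, table=table, pool=pool)
        variant_a = fk.double_knockout_analysis(
            model, table=table, use_representatives=False
        )
        variant_b = fk.double_knockout_analysis(
            model, table=table, use_representatives=False, use_witnesses=False
        )

        def mapped(records):
            out = {}
            for rec in records:
                m = rec.class_mapped(table.rep_of)
                if m.has_joint_effect:
                    out[m.pair] = m.targets
            return out

        assert mapped(default) == mapped(variant_a) == mapped(variant_b)
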