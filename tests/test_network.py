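import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluxko as fk
from fluxko.network import And, Gene, GeneRuleSyntaxError, Not, Or


class TestGeneRuleParser:
    @pytest.mark.parametrize(
        "text, assignment, expected",
        [
            ("g1 or g2", {"g1": False, "g2": True}, True),
            ("g1 or not g2", {"g1": False, "g2": True}, False),
            ("(a and b) or c", {"a": True, "b": False, "c": False}, False),
            ("a AND b OR c", {"a": False, "b": False, "c": True}, True),
            ("not a and b", {"a": False, "b": True}, True),  # not binds tighter
            ("not (a and b)", {"a": True, "b": False}, True),
            ("a or b and c", {"a": False, "b": True, "c": False}, False),
            ("not not a", {"a": True}, True),
        ],
    )
    def test_truth_table(self, text, assignment, expected):
        assert fk.parse_gene_rule(text).evaluate(assignment) is expected

    def test_precedence_structure(self):
        rule = fk.parse_gene_rule("a or b and not c")
        assert isinstance(rule, Or)
        assert isinstance(rule.operands[1], And)
        assert isinstance(rule.operands[1].operands[1], Not)

    @pytest.mark.parametrize(
        "text", ["", "(a or b", "a or", "and a", "a b", "a )"]
    )
    def test_syntax_errors_carry_position(self, text):
        with pytest.raises(GeneRuleSyntaxError) as exc:
            fk.parse_gene_rule(text)
        assert exc.value.position >= 0

    def test_genes_collected(self):
        rule = fk.parse_gene_rule("(b001 and b002) or not b003")
        assert rule.genes() == {"b001", "b002", "b003"}

    @given(
        st.recursive(
            st.sampled_from(["g1", "g2", "g3"]).map(Gene),
            lambda kids: st.one_of(
                kids.map(Not),
                st.tuples(kids, kids).map(And),
                st.tuples(kids, kids).map(Or),
            ),
            max_leaves=8,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_string_roundtrip(self, tree):
        """Printing a rule and re-parsing it preserves its truth table."""
        reparsed = fk.parse_gene_rule(str(tree))
        genes = sorted(tree.genes())
        for bits in range(2 ** len(genes)):
            assignment = {g: bool(bits >> i & 1) for i, g in enumerate(genes)}
            assert reparsed.evaluate(assignment) == tree.evaluate(assignment)


class TestFigure1Fixture:
    def test_reaction2_column(self, figure1):
        col = {m: figure1.stoich.get((m, "2"), 0.0) for m in "ABCD"}
        assert col == {"A": -1.0, "B": 1.0, "C": 1.0, "D": 0.0}

    def test_known_steady_state_vector(self, figure1):
        S = figure1.stoich_matrix().toarray()
        v = np.array([0, 1, 1, 2, 1, 1], dtype=float)
        assert np.allclose(S @ v, 0)
        # irreversibility: every entry for reactions 2..6 is non-negative
        assert (v[1:] >= 0).all()

    def test_flux_space_is_two_dimensional(self, figure1):
        S = figure1.stoich_matrix().toarray()
        assert S.shape == (4, 6)
        assert np.linalg.matrix_rank(S) == 4
        for basis in ([1, 1, 1, 1, 0, 0], [-1, 0, 0, 1, 1, 1]):
            assert np.allclose(S @ np.array(basis, dtype=float), 0)

    def test_coefficients_are_unit(self, figure1):
        assert set(figure1.stoich.values()) <= {1.0, -1.0}
        assert figure1.irreversible == {"2", "3", "4", "5", "6"}


class TestRandomNetwork:
    def test_seed_determinism(self):
        a = fk.random_network(4, 8, 0.25, 0.5, seed=7)
        b = fk.random_network(4, 8, 0.25, 0.5, seed=7)
        assert a == b

    def test_every_reaction_has_a_nonzero(self):
        net = fk.random_network(5, 6, 0.5, 0.1, seed=3)
        for r in net.reactions:
            assert any(rr == r and c != 0 for (m, rr), c in net.stoich.items())

    def test_zero_reversible_fraction_means_all_irreversible(self):
        net = fk.random_network(4, 6, 0.0, 0.5, seed=11)
        assert net.irreversible == frozenset(net.reactions)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_metabolites=0, n_reactions=3, reversible_fraction=0.5, density=0.5, seed=1),
            dict(n_metabolites=3, n_reactions=3, reversible_fraction=1.5, density=0.5, seed=1),
            dict(n_metabolites=3, n_reactions=3, reversible_fraction=0.5, density=0.0, seed=1),
        ],
    )
    def test_invalid_ranges(self, kwargs):
        with pytest.raises(ValueError):
            fk.random_network(**kwargs)


class TestNetworkValidation:
    def test_duplicate_reaction_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            fk.MetabolicNetwork(("A",), ("r", "r"), {("A", "r"): 1.0}, frozenset())

    def test_stoich_references_unknown(self):
        with pytest.raises(ValueError, match="unknown"):
            fk.MetabolicNetwork(("A",), ("r",), {("B", "r"): 1.0}, frozenset())

    def test_irreversible_subset(self):
        with pytest.raises(ValueError):
            fk.MetabolicNetwork(("A",), ("r",), {("A", "r"): 1.0}, frozenset({"x"}))

    def test_gpr_gene_must_be_declared(self):
        with pytest.raises(ValueError, match="undeclared"):
            fk.MetabolicNetwork(
                ("A",), ("r",), {("A", "r"): 1.0}, frozenset(),
                genes=frozenset(), gpr={"r": fk.parse_gene_rule("g9")},
            )

    def test_zero_column_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            fk.MetabolicNetwork(("A",), ("r", "x"), {("A", "r"): 1.0}, frozenset())
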