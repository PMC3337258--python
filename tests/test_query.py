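"""Query parsing, answering, algebra laws, and rendering round-trips."""

import itertools

import pytest

from goalont.fixtures import MEFV_QUERY
from goalont.model import (
    Conjunction,
    Existential,
    GENE_PRODUCT,
    Named,
)
from goalont.query import (
    AmbiguousNameError,
    NameIndex,
    QuerySyntaxError,
    UnknownNameError,
    answer_query,
    parse_query,
    render_description,
    render_expression,
)

TAAR4 = "GOAL:MGI_2685072"
MEFV = "GOAL:MGI_1859396"


class TestParse:
    def test_three_conjunct_singleton_query(self, mefv_deployment):
        expr = parse_query(
            "'inflammatory response gene product' and 'ion binding gene product' "
            "and 'mitochondrion gene product'",
            mefv_deployment.index,
        )
        assert expr == Conjunction((
            Named("GOAL:GO_0006954"), Named("GOAL:GO_0043167"), Named("GOAL:GO_0005739"),
        ))

    def test_single_atom(self, mefv_deployment):
        assert parse_query("'mitochondrion gene product'", mefv_deployment.index) \
            == Named("GOAL:GO_0005739")

    def test_existential_with_role(self, taar4_deployment):
        expr = parse_query(
            "is_capable_of_process some 'signal transduction'",
            taar4_deployment.index,
        )
        assert expr == Existential("is_capable_of_process", Named("GO:0007165"))

    def test_typographic_quotes_and_case_insensitivity(self, taar4_deployment):
        expr = parse_query("’Receptor Activity Gene Product’", taar4_deployment.index)
        assert expr == Named("GOAL:GO_0004872")

    def test_curie_atoms_with_either_separator(self, taar4_deployment):
        assert parse_query("GOAL:GO_0004930", taar4_deployment.index) \
            == parse_query("GOAL_GO_0004930".replace("GOAL_", "GOAL:"), taar4_deployment.index)
        assert parse_query("GO:0004930", taar4_deployment.index) == Named("GO:0004930")

    def test_parenthesized_filler(self, mefv_deployment):
        expr = parse_query(
            "'gene product' and is_capable_of_function some "
            "('ion binding' and 'metal ion binding')",
            mefv_deployment.index,
        )
        assert isinstance(expr, Conjunction)
        assert isinstance(expr.conjuncts[1], Existential)

    def test_unknown_label_lists_near_matches(self, taar4_deployment):
        with pytest.raises(UnknownNameError, match="did you mean"):
            parse_query("'receptor activity gene produkt'", taar4_deployment.index)

    def test_syntax_error_carries_position(self, taar4_deployment):
        with pytest.raises(QuerySyntaxError, match="position"):
            parse_query("'gene product' and and", taar4_deployment.index)
        with pytest.raises(QuerySyntaxError):
            parse_query("('gene product'", taar4_deployment.index)

    def test_ambiguous_label_reports_candidates(self, taar4_deployment):
        index = NameIndex.from_goal(taar4_deployment.goal)
        index.by_label["shared label"] = ["X:1", "X:2"]
        index.ids |= {"X:1", "X:2"}
        with pytest.raises(AmbiguousNameError):
            parse_query("'shared label'", index)


class TestAnswer:
    def test_each_taar4_singleton_returns_taar4(self, taar4_deployment):
        dep = taar4_deployment
        for term in ("GO:0016021", "GO:0004930", "GO:0007165"):
            singleton = dep.goal.singleton_index[term]
            assert dep.query(Named(singleton)).subclasses == {TAAR4}

    def test_ancestor_singletons_return_taar4(self, taar4_deployment):
        dep = taar4_deployment
        for term in ("GO:0004872", "GO:0016020", "GO:0008150"):
            singleton = dep.goal.singleton_index[term]
            assert dep.query(Named(singleton)).subclasses == {TAAR4}

    def test_root_query_returns_all_gene_products(self, mefv_deployment):
        dep = mefv_deployment
        result = dep.query("'gene product'")
        assert result.subclasses == dep.goal.gene_product_ids

    def test_mefv_five_conjunct_query_returns_exactly_mefv(self, mefv_deployment):
        assert mefv_deployment.query(MEFV_QUERY).subclasses == {MEFV}

    def test_shorthand_equals_expanded_form_for_every_term(self, mefv_deployment):
        """Querying S_X equals querying GeneProduct ⊓ ∃role.X, for all X."""
        from goalont.model import EquivalentClasses

        dep = mefv_deployment
        for term, singleton in dep.goal.singleton_index.items():
            # recover the role from the singleton's defining axiom
            defin = next(
                ax for ax in dep.goal.axioms
                if isinstance(ax, EquivalentClasses) and ax.a == Named(singleton)
            )
            role = defin.b.conjuncts[1].role
            shorthand = dep.query(Named(singleton))
            expanded = dep.query(Conjunction((
                Named(GENE_PRODUCT), Existential(role, Named(term)),
            )))
            assert shorthand.subclasses == expanded.subclasses, term

    def test_conjunction_equals_intersection_of_conjuncts(self, mefv_deployment):
        dep = mefv_deployment
        singles = [
            Named(dep.goal.singleton_index[t])
            for t in ("GO:0006954", "GO:0043167", "GO:0043231")
        ]
        conj = dep.query(Conjunction(tuple(singles))).subclasses
        inter = set.intersection(*(dep.query(s).subclasses for s in singles))
        assert conj == inter

    def test_adding_conjuncts_never_enlarges_results(self, mefv_deployment):
        dep = mefv_deployment
        terms = ["GO:0006954", "GO:0043167", "GO:0043231", "MP:0003009", "DOID:2914"]
        prev = dep.goal.gene_product_ids
        for k in range(1, len(terms) + 1):
            atoms = tuple(Named(dep.goal.singleton_index[t]) for t in terms[:k])
            expr = atoms[0] if k == 1 else Conjunction(atoms)
            cur = dep.query(expr).subclasses
            assert cur <= prev
            prev = cur

    def test_four_conjunct_relaxations_return_supersets(self, mefv_deployment):
        dep = mefv_deployment
        terms = ["GO:0006954", "GO:0043167", "GO:0043231", "MP:0003009", "DOID:2914"]
        for keep in itertools.combinations(terms, 4):
            expr = Conjunction(tuple(Named(dep.goal.singleton_index[t]) for t in keep))
            result = dep.query(expr).subclasses
            assert MEFV in result and len(result) >= 1

    def test_queries_leave_deployed_state_unchanged(self, mefv_deployment):
        dep = mefv_deployment
        before = dep.sub_map.state_hash()
        dep.query(MEFV_QUERY)
        dep.query("is_associated_with_disease some 'immune system disease'")
        dep.query("'gene product'")
        assert dep.sub_map.state_hash() == before

    def test_unknown_id_in_expression_is_an_error(self, taar4_deployment):
        with pytest.raises(UnknownNameError):
            answer_query(
                taar4_deployment.goal, taar4_deployment.sub_map,
                Named("GO:9999999"), norm=taar4_deployment.norm,
            )

    def test_expanded_form_is_equivalent_to_singleton_class(self, taar4_deployment):
        """The expanded query is recognized as the singleton it abbreviates."""
        dep = taar4_deployment
        result = dep.query(
            "'gene product' and is_capable_of_process some 'signal transduction'"
        )
        assert dep.goal.singleton_index["GO:0007165"] in result.equivalent


class TestRender:
    def test_taar4_description_mentions_gpcr_restriction(self, taar4_result):
        text = render_description(taar4_result.goal, TAAR4)
        assert "is_capable_of_function some 'G-protein coupled receptor activity'" in text
        assert "SubClassOf: 'Gene product'" in text

    def test_unknown_id_errors(self, taar4_result):
        with pytest.raises(KeyError):
            render_description(taar4_result.goal, "GOAL:MGI_0000000")

    def test_expression_render_parse_roundtrip_over_all_fixture_classes(
        self, mefv_deployment
    ):
        from goalont.model import EquivalentClasses, SubClassOf

        dep = mefv_deployment
        goal = dep.goal
        for ax in goal.axioms:
            exprs = []
            if isinstance(ax, SubClassOf):
                exprs = [ax.sub, ax.sup]
            elif isinstance(ax, EquivalentClasses):
                exprs = [ax.a, ax.b]
            for e in exprs:
                text = render_expression(goal, e, dep.index)
                assert parse_query(text, dep.index) == e
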