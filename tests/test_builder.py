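"""Gene-product classes, singleton defined classes, and assembly."""

import pytest

from goalont.annotations import AnnotationRecord, Aspect
from goalont.build import (
    ROLES,
    assemble,
    build_gene_product_classes,
    build_singleton_classes,
    mint_gene_class_id,
    mint_singleton_id,
)
from goalont.fixtures import taar4_fixture
from goalont.model import (
    Conjunction,
    EquivalentClasses,
    Existential,
    GENE_PRODUCT,
    Named,
    RoleInclusion,
    SubClassOf,
    validate_el,
)
from goalont.obo import Ontology, OntologyTerm
from goalont.pipeline import build_goal


def _record(gene, term, aspect, symbol="G", evidence="IEA"):
    return AnnotationRecord(gene, symbol, "", aspect, term, evidence)


def test_five_roles_exist_with_capability_hierarchy():
    assert set(ROLES) == {
        "is_capable_of_function", "is_capable_of_process", "is_located_in",
        "is_associated_with_phenotype", "is_associated_with_disease", "capable_of",
    }
    assert ROLES["is_capable_of_function"].super_roles == ("capable_of",)
    assert ROLES["is_capable_of_process"].super_roles == ("capable_of",)


def test_taar4_class_has_three_restrictions_and_symbol_label(taar4_result):
    goal = taar4_result.goal
    taar4 = "GOAL:MGI_2685072"
    assert goal.labels[taar4] == "Taar4"
    assert goal.labels[taar4 + "#definition"] == "trace amine-associated receptor 4"
    restrictions = [
        ax for ax in goal.axioms
        if isinstance(ax, SubClassOf) and ax.sub == Named(taar4)
        and isinstance(ax.sup, Existential)
    ]
    assert len(restrictions) == 3
    assert {(r.sup.role, r.sup.filler.id) for r in restrictions} == {
        ("is_located_in", "GO:0016021"),
        ("is_capable_of_function", "GO:0004930"),
        ("is_capable_of_process", "GO:0007165"),
    }
    assert all(("evidenceCode", "IEA") in r.annotations for r in restrictions)
    assert SubClassOf(Named(taar4), Named(GENE_PRODUCT)) in goal.axioms


def test_empty_record_list_builds_nothing():
    axioms, gene_ids = build_gene_product_classes([])
    assert len(axioms) == 0 and gene_ids == set()


def test_counting_identity_for_genes_and_records():
    # deterministic layout: 23 records over 7 genes
    counts = [4, 4, 4, 3, 3, 3, 2]
    assert sum(counts) == 23
    records = [
        _record(f"MGI:{g}", f"GO:00000{g}{i}", Aspect.FUNCTION, symbol=f"G{g}")
        for g, k in enumerate(counts)
        for i in range(k)
    ]
    axioms, gene_ids = build_gene_product_classes(records)
    assert len(gene_ids) == 7
    root_links = [
        ax for ax in axioms
        if isinstance(ax.sup, Named) and ax.sup.id == GENE_PRODUCT
    ]
    restrictions = [ax for ax in axioms if isinstance(ax.sup, Existential)]
    assert len(root_links) == 7 and len(restrictions) == 23
    assert len(axioms) == 30


def test_missing_aspect_role_is_an_error():
    with pytest.raises(ValueError, match="disease"):
        build_gene_product_classes(
            [_record("MGI:1", "DOID:1", Aspect.DISEASE)],
            {Aspect.FUNCTION: "is_capable_of_function"},
        )


def _ontology(name, n, prefix, obsolete=0):
    onto = Ontology(name=name)
    for i in range(n + obsolete):
        t = OntologyTerm(id=f"{prefix}:{i}", label=f"{name} term {i}")
        t.is_obsolete = i >= n
        onto.terms[t.id] = t
    return onto


def test_singleton_pattern_and_label():
    onto = Ontology(name="go")
    onto.terms["GO:0005739"] = OntologyTerm(id="GO:0005739", label="mitochondrion")
    labels = {}
    axioms, index = build_singleton_classes(
        {Aspect.COMPONENT: onto}, labels=labels
    )
    singleton = index["GO:0005739"]
    assert singleton == "GOAL:GO_0005739"
    assert labels[singleton] == "mitochondrion gene product"
    assert EquivalentClasses(
        Named(singleton),
        Conjunction((
            Named(GENE_PRODUCT),
            Existential("is_located_in", Named("GO:0005739")),
        )),
    ) in axioms


def test_singleton_count_reflects_supporting_ontology_sizes():
    ontologies = {
        Aspect.FUNCTION: _ontology("f", 12, "GO", obsolete=2),
        Aspect.PHENOTYPE: _ontology("p", 5, "MP"),
        Aspect.DISEASE: _ontology("d", 4, "DOID"),
    }
    axioms, index = build_singleton_classes(ontologies)
    assert len(index) == 12 + 5 + 4
    assert len(axioms) == 21


def test_empty_ontology_gives_no_singletons():
    axioms, index = build_singleton_classes({Aspect.FUNCTION: Ontology(name="f")})
    assert len(axioms) == 0 and index == {}


def test_assemble_is_deduplicating_and_stats_count_classes(taar4_result):
    goal = taar4_result.goal
    assert goal.stats.n_classes == (
        goal.stats.n_ontology_terms + goal.stats.n_singletons
        + goal.stats.n_gene_products + goal.stats.n_convenient_roots + 1
    )
    # role hierarchy axioms present
    assert RoleInclusion("is_capable_of_function", "capable_of") in goal.axioms
    # merging the same sets again yields an identical artifact
    again = build_goal(taar4_fixture()).goal
    assert again.dumps() == goal.dumps()


def test_id_pools_are_disjoint(mefv_result):
    goal = mefv_result.goal
    singles = set(goal.singleton_index.values())
    terms = set(goal.singleton_index)
    assert not (goal.gene_product_ids & singles)
    assert not (goal.gene_product_ids & terms)
    assert not (singles & terms)


def test_all_generated_axioms_are_el(mefv_result):
    validate_el(mefv_result.goal.axioms)


def test_gene_restrictions_use_existential_quantification_only(mefv_result):
    for ax in mefv_result.goal.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named) \
                and ax.sub.id in mefv_result.goal.gene_product_ids:
            assert isinstance(ax.sup, (Named, Existential))


def test_artifact_json_roundtrip(mefv_result):
    goal = mefv_result.goal
    back = goal.__class__.loads(goal.dumps())
    assert list(back.axioms) == list(goal.axioms)
    assert back.gene_product_ids == goal.gene_product_ids
    assert back.singleton_index == goal.singleton_index
    assert back.labels == goal.labels
    assert back.dumps() == goal.dumps()


def test_minting_is_deterministic():
    assert mint_gene_class_id("MGI:2685072") == "GOAL:MGI_2685072"
    assert mint_singleton_id("GO:0004930") == "GOAL:GO_0004930"
    assert mint_singleton_id("MP:0003009") == "GOAL:MP_0003009"


def test_classified_gene_is_under_singletons_of_term_and_ancestors(mefv_deployment):
    """Every annotation (g, a, X) puts g under S_X and S_Y for ancestors Y."""
    dep = mefv_deployment
    goal = dep.goal
    mefv = "GOAL:MGI_1859396"
    subs = dep.sub_map.subsumers_of(mefv)
    # annotated deep term and its ancestors, via the singleton index
    for term in ("GO:0002526", "GO:0006954", "GO:0006952",
                 "GO:0005509", "GO:0046872", "GO:0043167",
                 "MP:0008565", "MP:0003009", "DOID:0050557", "DOID:2914"):
        assert goal.singleton_index[term] in subs
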