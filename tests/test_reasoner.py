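"""EL normalization and saturation against independent oracles."""

import pytest
from hypothesis import given, settings, strategies as st

from helpers.oracles import (
    graph_ancestors,
    naive_entailed_subsumers,
    restrict_to_signature,
)
from goalont.fixtures import random_el_axioms, taar4_fixture
from goalont.model import (
    AxiomSet,
    Conjunction,
    EquivalentClasses,
    Existential,
    Named,
    RoleInclusion,
    SubClassOf,
    TOP,
)
from goalont.pipeline import build_goal
from goalont.query import classify
from goalont.reasoner import (
    FRESH_PREFIX,
    build_taxonomy,
    extend_saturation,
    normalize,
    saturate,
)


def _signature(axioms):
    return {c for c in AxiomSet(axioms).class_signature()}


def _project(sub_map, signature):
    return {
        x: frozenset(a for a in s if a in signature or a == TOP)
        for x, s in sub_map.subsumers.items()
        if x in signature
    }


class TestNormalize:
    def test_already_normal_axiom_is_unchanged(self):
        norm = normalize([SubClassOf(Named("X:A"), Named("X:B"))])
        assert norm.nf1 == [("X:A", "X:B")]
        assert not (norm.nf2 or norm.nf3 or norm.nf4 or norm.fresh_names)

    def test_equivalence_with_conjunction_and_existential(self):
        # A ≡ B ⊓ ∃r.C splits into both directions with one fresh filler name
        ax = EquivalentClasses(
            Named("X:A"),
            Conjunction((Named("X:B"), Existential("r", Named("X:C")))),
        )
        norm = normalize([ax])
        assert len(norm.fresh_names) == 1
        (fresh,) = norm.fresh_names
        assert ("X:A", "X:B") in norm.nf1
        assert ("X:A", "r", "X:C") in norm.nf3
        assert ("r", "X:C", fresh) in norm.nf4
        assert ("X:B", fresh, "X:A") in norm.nf2 or (fresh, "X:B", "X:A") in norm.nf2

    def test_singleton_pattern_normal_forms(self):
        ax = EquivalentClasses(
            Named("GOAL:GO_1"),
            Conjunction((Named("GOAL:gene_product"),
                         Existential("rho", Named("GO:1")))),
        )
        norm = normalize([ax])
        # unfoldings S ⊑ G and S ⊑ ∃ρ.X
        assert ("GOAL:GO_1", "GOAL:gene_product") in norm.nf1
        assert ("GOAL:GO_1", "rho", "GO:1") in norm.nf3
        # recognition direction: G ⊓ F ⊑ S with ∃ρ.X ⊑ F
        (fresh,) = [f for f, e in norm.fresh_names.items()
                    if isinstance(e, Existential)]
        assert ("rho", "GO:1", fresh) in norm.nf4
        assert any(set(pair[:2]) == {"GOAL:gene_product", fresh} and pair[2] == "GOAL:GO_1"
                   for pair in norm.nf2)

    def test_normalization_preserves_entailments_over_signature(self):
        for seed in range(15):
            axioms = random_el_axioms(seed, n_classes=12, n_axioms=25)
            sig = _signature(axioms)
            ours = _project(saturate(normalize(axioms)), sig)
            oracle = restrict_to_signature(naive_entailed_subsumers(axioms), sig)
            assert ours == oracle, f"seed {seed}"


class TestSaturate:
    def test_transitivity(self):
        sat = saturate(normalize([
            SubClassOf(Named("X:A"), Named("X:B")),
            SubClassOf(Named("X:B"), Named("X:C")),
        ]))
        assert "X:C" in sat.subsumers_of("X:A")

    def test_reflexivity_and_top(self):
        sat = saturate(normalize([SubClassOf(Named("X:A"), Named("X:B"))]))
        for x in ("X:A", "X:B"):
            assert x in sat.subsumers_of(x) and TOP in sat.subsumers_of(x)

    def test_taar4_inferred_under_receptor_activity_gene_product(self):
        dep = classify(build_goal(taar4_fixture()).goal)
        receptor_singleton = dep.goal.singleton_index["GO:0004872"]
        assert dep.goal.labels[receptor_singleton] == "receptor activity gene product"
        assert receptor_singleton in dep.sub_map.subsumers_of("GOAL:MGI_2685072")

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_naive_fixpoint_oracle(self, seed):
        axioms = random_el_axioms(seed, n_classes=30, n_axioms=60)
        sig = _signature(axioms)
        ours = _project(saturate(normalize(axioms)), sig)
        oracle = restrict_to_signature(naive_entailed_subsumers(axioms), sig)
        assert ours == oracle

    def test_is_a_cycles_become_equivalences(self):
        sat = saturate(normalize([
            SubClassOf(Named("X:A"), Named("X:B")),
            SubClassOf(Named("X:B"), Named("X:C")),
            SubClassOf(Named("X:C"), Named("X:A")),
        ]))
        for x in ("X:A", "X:B", "X:C"):
            assert {"X:A", "X:B", "X:C"} <= sat.subsumers_of(x)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000), st.integers(5, 40))
    def test_monotonicity_adding_axioms_never_shrinks_subsumers(self, seed, cut):
        axioms = random_el_axioms(seed, n_classes=15, n_axioms=45)
        small = saturate(normalize(axioms[:cut]))
        big = saturate(normalize(axioms))
        sig = _signature(axioms[:cut])
        for x in sig:
            have = {a for a in small.subsumers_of(x) if a in sig}
            assert have <= big.subsumers_of(x)

    def test_saturating_a_saturated_map_is_a_noop(self):
        axioms = random_el_axioms(3, n_classes=20, n_axioms=40)
        norm = normalize(axioms)
        sat = saturate(norm)
        again, _ = extend_saturation(sat, norm, [])
        assert again.subsumers == sat.subsumers
        assert again.role_edges == sat.role_edges

    def test_pure_hierarchy_matches_graph_ancestors(self):
        edges = [("N:%d" % i, "N:%d" % (i // 2)) for i in range(1, 40)]
        sat = saturate(normalize([
            SubClassOf(Named(c), Named(p)) for c, p in edges
        ]))
        ancestors = graph_ancestors(edges)
        for node, ancs in ancestors.items():
            assert sat.subsumers_of(node) == ancs | {node, TOP}

    def test_saturation_size_is_polynomial(self):
        axioms = random_el_axioms(11, n_classes=25, n_axioms=60)
        norm = normalize(axioms)
        sat = saturate(norm)
        n = len(sat.subsumers)
        assert sum(len(s) for s in sat.subsumers.values()) <= n * n

    def test_role_hierarchy_propagates_edges(self):
        sat = saturate(normalize([
            SubClassOf(Named("X:A"), Existential("f", Named("X:B"))),
            RoleInclusion("f", "g"),
            SubClassOf(Existential("g", Named("X:B")), Named("X:C")),
        ]))
        assert "X:C" in sat.subsumers_of("X:A")

    def test_role_chain_rule_behind_flag(self):
        axioms = [
            SubClassOf(Named("X:A"), Existential("part_of", Named("X:B"))),
            SubClassOf(Named("X:B"), Existential("part_of", Named("X:C"))),
        ]
        without = saturate(normalize(axioms))
        assert ("X:A", "X:C") not in without.role_edges.get("part_of", set())
        with_chain = saturate(normalize(
            axioms, role_chains=[("part_of", "part_of", "part_of")]
        ))
        assert ("X:A", "X:C") in with_chain.role_edges["part_of"]


class TestTaxonomy:
    def test_mutual_subsumption_merges_into_one_group(self):
        sat = saturate(normalize([
            SubClassOf(Named("X:A"), Named("X:B")),
            SubClassOf(Named("X:B"), Named("X:A")),
        ]))
        tax = build_taxonomy(sat, {"X:A", "X:B"})
        assert tax.equivalence_groups == [("X:A", "X:B")]

    def test_chain_is_transitively_reduced(self):
        sat = saturate(normalize([
            SubClassOf(Named("X:A"), Named("X:B")),
            SubClassOf(Named("X:B"), Named("X:C")),
        ]))
        tax = build_taxonomy(sat, {"X:A", "X:B", "X:C"})
        assert tax.direct_super["X:A"] == {"X:B"}
        assert tax.direct_super["X:B"] == {"X:C"}

    @pytest.mark.parametrize("seed", range(10))
    def test_taxonomy_reachability_equals_entailment(self, seed):
        axioms = random_el_axioms(seed, n_classes=15, n_axioms=35)
        sig = _signature(axioms)
        sat = saturate(normalize(axioms))
        tax = build_taxonomy(sat, sig)
        for x in sig:
            reach = set()
            for rep in tax.ancestors(x) | {tax.representative[x]}:
                group = next(g for g in tax.equivalence_groups if g[0] == rep)
                reach |= set(group)
            entailed = {a for a in sat.subsumers_of(x) if a in sig}
            assert reach == entailed

    def test_fresh_names_never_appear(self, mefv_deployment):
        dep = mefv_deployment
        visible = {c for c in dep.sub_map.subsumers if not c.startswith(FRESH_PREFIX)}
        tax = build_taxonomy(dep.sub_map, visible)
        assert not any(
            m.startswith(FRESH_PREFIX) for g in tax.equivalence_groups for m in g
        )
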