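"""Assembly of the GOAL ontology.

Each annotated gene becomes a primitive class under the ``Gene product``
root, with one existential restriction per surviving annotation.  Each
supporting-ontology term X gets one "singleton" defined class

    'X gene product'  ≡  'Gene product'  ⊓  ∃role.X

so that, after classification, arbitrary conjunctive queries over the
supporting ontologies can be phrased as intersections of named classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .annotations import AnnotationRecord, Aspect
from .model import (
    AxiomSet,
    Axiom,
    Conjunction,
    EquivalentClasses,
    Existential,
    GENE_PRODUCT,
    GOAL_PREFIX,
    Named,
    RoleInclusion,
    SubClassOf,
    axiom_from_json,
    axiom_to_json,
    curie_local,
    curie_prefix,
    normalize_curie,
    validate_el,
)
from .obo import Ontology

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Role:
    name: str
    super_roles: tuple[str, ...] = ()
    range_hint: Optional[Aspect] = None


# The five annotation roles; the two capability roles sit under the relation
# ontology's capable_of.
ROLES: dict[str, Role] = {
    r.name: r
    for r in [
        Role("is_capable_of_function", ("capable_of",), Aspect.FUNCTION),
        Role("is_capable_of_process", ("capable_of",), Aspect.PROCESS),
        Role("is_located_in", (), Aspect.COMPONENT),
        Role("is_associated_with_phenotype", (), Aspect.PHENOTYPE),
        Role("is_associated_with_disease", (), Aspect.DISEASE),
        Role("capable_of", ()),
    ]
}

ASPECT_ROLE: dict[Aspect, str] = {
    Aspect.FUNCTION: "is_capable_of_function",
    Aspect.PROCESS: "is_capable_of_process",
    Aspect.COMPONENT: "is_located_in",
    Aspect.PHENOTYPE: "is_associated_with_phenotype",
    Aspect.DISEASE: "is_associated_with_disease",
}


def mint_gene_class_id(gene_id: str) -> str:
    """MGI:2685072 → GOAL:MGI_2685072 (deterministic, diffable)."""
    return f"{GOAL_PREFIX}:{curie_prefix(gene_id)}_{curie_local(gene_id)}"


def mint_singleton_id(term_id: str) -> str:
    """GO:0004930 → GOAL:GO_0004930."""
    return f"{GOAL_PREFIX}:{curie_prefix(term_id)}_{curie_local(term_id)}"


@dataclass
class BuildStats:
    n_gene_products: int = 0
    n_singletons: int = 0
    n_ontology_terms: int = 0
    n_convenient_roots: int = 0
    n_classes: int = 0
    n_axioms: int = 0

    def to_json(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GoalOntology:
    axioms: AxiomSet = field(default_factory=AxiomSet)
    gene_product_ids: set[str] = field(default_factory=set)
    singleton_index: dict[str, str] = field(default_factory=dict)  # term → singleton
    labels: dict[str, str] = field(default_factory=dict)
    roles: dict[str, Role] = field(default_factory=lambda: dict(ROLES))
    stats: BuildStats = field(default_factory=BuildStats)

    def label_of(self, class_id: str) -> str:
        return self.labels.get(class_id, class_id)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "format": "goalont/1",
            "axioms": [axiom_to_json(a) for a in self.axioms],
            "gene_product_ids": sorted(self.gene_product_ids),
            "singleton_index": dict(sorted(self.singleton_index.items())),
            "labels": dict(sorted(self.labels.items())),
            "roles": {
                r.name: {"super_roles": list(r.super_roles),
                         "range_hint": r.range_hint.value if r.range_hint else None}
                for r in self.roles.values()
            },
            "stats": self.stats.to_json(),
        }

    @classmethod
    def from_json(cls, payload: Mapping) -> "GoalOntology":
        if payload.get("format") != "goalont/1":
            raise ValueError(f"unsupported artifact format: {payload.get('format')!r}")
        roles = {
            name: Role(
                name,
                tuple(spec["super_roles"]),
                Aspect(spec["range_hint"]) if spec["range_hint"] else None,
            )
            for name, spec in payload["roles"].items()
        }
        obj = cls(
            axioms=AxiomSet(axiom_from_json(a) for a in payload["axioms"]),
            gene_product_ids=set(payload["gene_product_ids"]),
            singleton_index=dict(payload["singleton_index"]),
            labels=dict(payload["labels"]),
            roles=roles,
        )
        obj.stats = BuildStats(**payload["stats"])
        return obj

    def dumps(self) -> str:
        return json.dumps(self.to_json(), indent=1, sort_keys=False)

    @classmethod
    def loads(cls, text: str) -> "GoalOntology":
        return cls.from_json(json.loads(text))


def build_gene_product_classes(
    records: Sequence[AnnotationRecord],
    aspect_role_map: Optional[Mapping[Aspect, str]] = None,
    labels: Optional[dict[str, str]] = None,
    include_bare_genes: bool = False,
) -> tuple[AxiomSet, set[str]]:
    """One primitive class per annotated gene.

    Per gene: a minted named class (labelled with the gene symbol), one
    ``gene ⊑ GeneProduct`` axiom, and one ``gene ⊑ ∃role.term`` axiom per
    record, annotated with the record's evidence codes.  Genes with no
    surviving records appear only when ``include_bare_genes`` is set.
    """
    role_map = dict(aspect_role_map or ASPECT_ROLE)
    missing = {r.aspect for r in records if r.aspect not in role_map}
    if missing:
        raise ValueError(
            "no role mapped for aspect(s): " + ", ".join(sorted(a.value for a in missing))
        )
    axioms = AxiomSet()
    gene_ids: set[str] = set()
    by_gene: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    for gene_id in sorted(by_gene):
        recs = by_gene[gene_id]
        cls_id = mint_gene_class_id(gene_id)
        gene_ids.add(cls_id)
        axioms.add(SubClassOf(Named(cls_id), Named(GENE_PRODUCT)))
        if labels is not None:
            symbol = next((r.gene_symbol for r in recs if r.gene_symbol), gene_id)
            labels[cls_id] = symbol
            name = next((r.gene_name for r in recs if r.gene_name), "")
            if name:
                labels.setdefault(cls_id + "#definition", name)
        for rec in recs:
            anns = tuple(
                ("evidenceCode", code)
                for code in rec.evidence_code.split("|")
                if code
            )
            axioms.add(
                SubClassOf(
                    Named(cls_id),
                    Existential(role_map[rec.aspect], Named(rec.term_id)),
                    anns,
                )
            )
    # include_bare_genes has no effect here (records imply non-bare genes);
    # the pipeline uses it to keep genes whose records were all filtered out.
    return axioms, gene_ids


def build_singleton_classes(
    ontologies: Mapping[Aspect, Ontology],
    aspect_role_map: Optional[Mapping[Aspect, str]] = None,
    extra_terms: Optional[Mapping[Aspect, Mapping[str, str]]] = None,
    labels: Optional[dict[str, str]] = None,
) -> tuple[AxiomSet, dict[str, str]]:
    """One defined class per supporting-ontology term.

    For every non-obsolete term X of aspect *a* with role ρ(a):

        S_X ≡ GeneProduct ⊓ ∃ρ(a).X      labelled '<X label> gene product'

    ``extra_terms`` lets the pipeline include classes that are not parsed
    terms (the minted convenient roots), as ``{aspect: {id: label}}``.
    Returns the axioms plus the term→singleton index.
    """
    role_map = dict(aspect_role_map or ASPECT_ROLE)
    axioms = AxiomSet()
    index: dict[str, str] = {}
    label_owner: dict[str, tuple[str, str]] = {}  # label → (singleton, ontology name)
    for aspect in sorted(ontologies, key=lambda a: a.value):
        ontology = ontologies[aspect]
        role = role_map[aspect]
        terms: list[tuple[str, str]] = [
            (t.id, t.label) for t in ontology.non_obsolete()
        ]
        if extra_terms and aspect in extra_terms:
            terms.extend(extra_terms[aspect].items())
        for term_id, term_label in sorted(terms):
            singleton = mint_singleton_id(term_id)
            index[term_id] = singleton
            axioms.add(
                EquivalentClasses(
                    Named(singleton),
                    Conjunction((Named(GENE_PRODUCT), Existential(role, Named(term_id)))),
                )
            )
            if labels is not None:
                lab = f"{term_label or term_id} gene product"
                if lab in label_owner and label_owner[lab][0] != singleton:
                    log.info(
                        "singleton label collision on %r; disambiguating with %s",
                        lab, ontology.name,
                    )
                    lab = f"{term_label or term_id} gene product ({ontology.name or aspect.value})"
                label_owner[lab] = (singleton, ontology.name)
                labels[singleton] = lab
    return axioms, index


# The paper's Gene product root is displayed with five existential
# restrictions (one per role).  Asserting them would make every gene product
# an entailed member of every top-level singleton, collapsing those queries,
# so by default they are carried as documentation annotations only; the
# assert_root_restrictions flag emits them as logical axioms.
ROOT_RESTRICTION_DOC = (
    ("doc:restriction", "is_capable_of_function some 'molecular function'"),
    ("doc:restriction", "is_located_in some 'cellular component'"),
    ("doc:restriction", "is_capable_of_process some 'biological process'"),
    ("doc:restriction", "is_associated_with_phenotype some 'phenotype'"),
    ("doc:restriction", "is_associated_with_disease some 'disease'"),
)


def assemble(
    ontology_axioms: Iterable[AxiomSet],
    gene_axioms: AxiomSet,
    gene_ids: set[str],
    singleton_axioms: AxiomSet,
    singleton_index: Mapping[str, str],
    labels: Mapping[str, str],
    roles: Optional[Mapping[str, Role]] = None,
    n_ontology_terms: int = 0,
    n_convenient_roots: int = 0,
    assert_root_restrictions: bool = False,
    root_ranges: Optional[Mapping[Aspect, str]] = None,
) -> GoalOntology:
    """Merge everything into one GoalOntology with role hierarchy and stats.

    Merging is deduplicating, so assembling the same axiom set twice yields
    an identical artifact.
    """
    roles = dict(roles or ROLES)
    merged = AxiomSet()
    for ax_set in ontology_axioms:
        merged.extend(ax_set)
    merged.extend(gene_axioms)
    merged.extend(singleton_axioms)
    for role in roles.values():
        for sup in role.super_roles:
            merged.add(RoleInclusion(role.name, sup))
    if assert_root_restrictions and root_ranges:
        for aspect, range_root in sorted(root_ranges.items(), key=lambda kv: kv[0].value):
            merged.add(
                SubClassOf(
                    Named(GENE_PRODUCT),
                    Existential(ASPECT_ROLE[aspect], Named(range_root)),
                )
            )
    validate_el(merged)

    goal = GoalOntology(
        axioms=merged,
        gene_product_ids=set(gene_ids),
        singleton_index=dict(singleton_index),
        labels={GENE_PRODUCT: "Gene product", **labels},
        roles=roles,
    )
    # disjointness of the three id pools is a structural invariant
    singles = set(goal.singleton_index.values())
    overlap = (goal.gene_product_ids & singles) | (
        set(goal.singleton_index) & (goal.gene_product_ids | singles)
    )
    if overlap:
        raise ValueError(f"id pools overlap: {sorted(overlap)[:5]}")
    goal.stats = BuildStats(
        n_gene_products=len(goal.gene_product_ids),
        n_singletons=len(singles),
        n_ontology_terms=n_ontology_terms,
        n_convenient_roots=n_convenient_roots,
        n_classes=len(goal.gene_product_ids) + len(singles) + n_ontology_terms
        + n_convenient_roots + 1,
        n_axioms=len(merged),
    )
    return goal
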