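"""End-to-end build: parse sources, filter annotations, assemble, classify.

This is the programmatic face of the ``goal build`` command and the entry
point used by the example scripts and the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .annotations import (
    AnnotationRecord,
    Aspect,
    FilterConfig,
    FilterReport,
    ReportColumnMap,
    filter_annotations,
    map_omim_to_disease,
    read_gaf,
    read_geno_disease_report,
    read_omim_mapping,
)
from .build import (
    ASPECT_ROLE,
    GoalOntology,
    assemble,
    build_gene_product_classes,
    build_singleton_classes,
)
from .fixtures import FixtureSet, GO_NAMESPACE
from .obo import Ontology, OntologyTerm, add_convenient_root, ontology_to_axioms, parse_obo

log = logging.getLogger(__name__)

_NAMESPACE_ASPECT = {ns: aspect for aspect, ns in GO_NAMESPACE.items()}


@dataclass
class BuildConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    column_map: ReportColumnMap = field(default_factory=ReportColumnMap)
    relation_policy: dict[str, str] = field(default_factory=dict)
    default_relations: bool = True
    assert_root_restrictions: bool = False
    include_bare_genes: bool = False
    phenotype_root_label: str = "phenotype"
    disease_root_label: str = "disease"


@dataclass
class BuildResult:
    goal: GoalOntology
    filter_report: FilterReport
    records: list[AnnotationRecord]
    ontologies: dict[Aspect, Ontology]
    unmapped_omim: int = 0


def split_go_by_namespace(go: Ontology) -> dict[Aspect, Ontology]:
    """Split a parsed GO file into one ontology view per namespace/aspect.

    Terms without a recognized namespace are left out with a log line —
    each singleton class needs an unambiguous role, which the namespace
    determines.
    """
    views = {
        aspect: Ontology(name=f"{go.name or 'go'}:{ns}")
        for ns, aspect in _NAMESPACE_ASPECT.items()
    }
    for term in go.terms.values():
        aspect = _NAMESPACE_ASPECT.get(term.namespace)
        if aspect is None:
            log.info("GO term %s has no recognized namespace; skipped", term.id)
            continue
        views[aspect].terms[term.id] = term
    return views


def build_goal(sources: FixtureSet, config: Optional[BuildConfig] = None) -> BuildResult:
    """Run the whole build: ingest → filter → gene classes → singletons.

    ``sources`` holds the raw file texts (any may be empty).  Convenient
    roots are added to the phenotype and disease ontologies when they are
    present, and every supporting-ontology term label is registered so that
    queries can be written against labels.
    """
    config = config or BuildConfig()
    labels: dict[str, str] = {}
    ontologies: dict[Aspect, Ontology] = {}
    ontology_axioms = []
    extra_terms: dict[Aspect, dict[str, str]] = {}
    n_terms = 0
    n_roots = 0
    root_ranges: dict[Aspect, str] = {}

    if sources.go_obo:
        go = parse_obo(sources.go_obo, name="go")
        for aspect, view in split_go_by_namespace(go).items():
            ontologies[aspect] = view
            ontology_axioms.append(
                ontology_to_axioms(view, config.relation_policy, config.default_relations)
            )
            n_terms += len(view.non_obsolete())
            ns_root = next(iter(view.roots), None)
            if ns_root:
                root_ranges[aspect] = ns_root
    for aspect, text, root_label in (
        (Aspect.PHENOTYPE, sources.mp_obo, config.phenotype_root_label),
        (Aspect.DISEASE, sources.doid_obo, config.disease_root_label),
    ):
        if not text:
            continue
        onto = parse_obo(text, name=aspect.value)
        axioms = ontology_to_axioms(onto, config.relation_policy, config.default_relations)
        axioms, root_id = add_convenient_root(axioms, onto, root_label, labels)
        ontologies[aspect] = onto
        ontology_axioms.append(axioms)
        extra_terms[aspect] = {root_id: root_label}
        n_terms += len(onto.non_obsolete())
        n_roots += 1
        root_ranges[aspect] = root_id

    for onto in ontologies.values():
        for term in onto.non_obsolete():
            if term.label:
                labels.setdefault(term.id, term.label)

    records: list[AnnotationRecord] = []
    if sources.gaf:
        gaf_records, gaf_report = read_gaf(sources.gaf)
        records.extend(gaf_records)
        if gaf_report.skipped_not or gaf_report.skipped_short:
            log.info(
                "GAF: skipped %d NOT rows, %d short rows",
                gaf_report.skipped_not, gaf_report.skipped_short,
            )
    unmapped = 0
    if sources.geno_report:
        phen, omim_pairs = read_geno_disease_report(
            sources.geno_report, config.column_map
        )
        records.extend(phen)
        if sources.omim_map:
            mapping = read_omim_mapping(sources.omim_map)
            symbols = {r.gene_id: r.gene_symbol for r in records if r.gene_symbol}
            disease, unmapped = map_omim_to_disease(omim_pairs, mapping, symbols)
            records.extend(disease)

    surviving, report = filter_annotations(records, ontologies, config.filter)

    gene_axioms, gene_ids = build_gene_product_classes(
        surviving, ASPECT_ROLE, labels, config.include_bare_genes
    )
    singleton_axioms, singleton_index = build_singleton_classes(
        ontologies, ASPECT_ROLE, extra_terms, labels
    )
    goal = assemble(
        ontology_axioms,
        gene_axioms,
        gene_ids,
        singleton_axioms,
        singleton_index,
        labels,
        n_ontology_terms=n_terms,
        n_convenient_roots=n_roots,
        assert_root_restrictions=config.assert_root_restrictions,
        root_ranges=root_ranges,
    )
    return BuildResult(
        goal=goal,
        filter_report=report,
        records=surviving,
        ontologies=ontologies,
        unmapped_omim=unmapped,
    )
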