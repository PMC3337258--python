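"""Fixture inputs: packaged micro-corpora and a seeded synthetic generator.

Everything downstream (OBO parsing, GAF ingestion, building, classification,
querying) can be exercised without any download.  Two micro-fixtures mirror
the worked examples of the system this package re-implements:

* :func:`taar4_fixture` — the Taar4 receptor gene with its three GO
  annotations (integral to membrane, G-protein coupled receptor activity,
  signal transduction) and hand-chosen named ancestors.
* :func:`mefv_fixture` — three genes of which exactly one (Mefv, the
  Mediterranean fever gene) is annotated with *deep* terms whose ancestors
  are the five classes of the published immune-system-disease query, so the
  five-conjunct conjunction returns exactly that gene and its justification
  requires inference up the hierarchy.

The synthetic generator emits the same external formats together with a
ground-truth manifest (ancestor closures and expected singleton-query
answers) computed by independent graph code, never by the reasoner.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .annotations import Aspect
from .build import mint_gene_class_id
from .model import (
    Axiom,
    Conjunction,
    EquivalentClasses,
    Existential,
    Named,
    RoleInclusion,
    SubClassOf,
)
from .obo import mint_root_id

GO_NAMESPACE = {
    Aspect.FUNCTION: "molecular_function",
    Aspect.PROCESS: "biological_process",
    Aspect.COMPONENT: "cellular_component",
}
GO_NAMESPACE_ROOT = {
    Aspect.FUNCTION: "GO:0003674",
    Aspect.PROCESS: "GO:0008150",
    Aspect.COMPONENT: "GO:0005575",
}


@dataclass
class FixtureSet:
    """Textual inputs in the exact dialects the ingest modules consume."""

    go_obo: str = ""
    mp_obo: str = ""
    doid_obo: str = ""
    gaf: str = ""
    geno_report: str = ""
    omim_map: str = ""
    manifest: dict = field(default_factory=dict)


def _obo(name: str, terms: list[dict]) -> str:
    lines = ["format-version: 1.2", f"ontology: {name}"]
    for t in terms:
        lines += ["", "[Term]", f"id: {t['id']}"]
        if t.get("name"):
            lines.append(f"name: {t['name']}")
        if t.get("namespace"):
            lines.append(f"namespace: {t['namespace']}")
        if t.get("obsolete"):
            lines.append("is_obsolete: true")
        for p in t.get("is_a", []):
            lines.append(f"is_a: {p}")
        for rel, tgt in t.get("rel", []):
            lines.append(f"relationship: {rel} {tgt}")
    return "\n".join(lines) + "\n"


def _gaf_row(gene_id: str, symbol: str, go_id: str, evidence: str, aspect: str,
             name: str = "", qualifier: str = "") -> str:
    db, local = gene_id.split(":", 1)
    cols = [db, local, symbol, qualifier, go_id, f"{db}:ref", evidence, "",
            aspect, name, "", "protein", "taxon:10090", "20111004", db, "", ""]
    return "\t".join(cols)


# ---------------------------------------------------------------------------
# Taar4 micro-fixture
# ---------------------------------------------------------------------------

def taar4_fixture() -> FixtureSet:
    """The Taar4 worked example: one gene, three GO annotations."""
    go = _obo("go-micro", [
        {"id": "GO:0003674", "name": "molecular_function", "namespace": "molecular_function"},
        {"id": "GO:0004872", "name": "receptor activity", "namespace": "molecular_function",
         "is_a": ["GO:0003674"]},
        {"id": "GO:0004930", "name": "G-protein coupled receptor activity",
         "namespace": "molecular_function", "is_a": ["GO:0004872"]},
        {"id": "GO:0005575", "name": "cellular_component", "namespace": "cellular_component"},
        {"id": "GO:0016020", "name": "membrane", "namespace": "cellular_component",
         "is_a": ["GO:0005575"]},
        {"id": "GO:0016021", "name": "integral to membrane", "namespace": "cellular_component",
         "is_a": ["GO:0016020"]},
        {"id": "GO:0008150", "name": "biological_process", "namespace": "biological_process"},
        {"id": "GO:0007165", "name": "signal transduction", "namespace": "biological_process",
         "is_a": ["GO:0008150"]},
    ])
    name = "trace amine-associated receptor 4"
    gaf = "\n".join([
        "!gaf-version: 2.0",
        _gaf_row("MGI:2685072", "Taar4", "GO:0016021", "IEA", "C", name),
        _gaf_row("MGI:2685072", "Taar4", "GO:0004930", "IEA", "F", name),
        _gaf_row("MGI:2685072", "Taar4", "GO:0007165", "IEA", "P", name),
    ]) + "\n"
    return FixtureSet(go_obo=go, gaf=gaf)


# ---------------------------------------------------------------------------
# Mefv micro-fixture
# ---------------------------------------------------------------------------

def mefv_fixture() -> FixtureSet:
    """Three genes; only Mefv satisfies all five conjuncts of the query

        'inflammatory response gene product'
        and 'ion binding gene product'
        and 'intracellular membrane-bounded organelle gene product'
        and 'abnormal cytokine secretion gene product'
        and 'immune system disease gene product'

    and it does so only through annotations to strictly deeper terms.
    """
    go = _obo("go-micro", [
        {"id": "GO:0008150", "name": "biological_process", "namespace": "biological_process"},
        {"id": "GO:0006952", "name": "defense response", "namespace": "biological_process",
         "is_a": ["GO:0008150"]},
        {"id": "GO:0006954", "name": "inflammatory response", "namespace": "biological_process",
         "is_a": ["GO:0006952"]},
        {"id": "GO:0002526", "name": "acute inflammatory response",
         "namespace": "biological_process", "is_a": ["GO:0006954"]},
        {"id": "GO:0003674", "name": "molecular_function", "namespace": "molecular_function"},
        {"id": "GO:0005488", "name": "binding", "namespace": "molecular_function",
         "is_a": ["GO:0003674"]},
        {"id": "GO:0043167", "name": "ion binding", "namespace": "molecular_function",
         "is_a": ["GO:0005488"]},
        {"id": "GO:0046872", "name": "metal ion binding", "namespace": "molecular_function",
         "is_a": ["GO:0043167"]},
        {"id": "GO:0005509", "name": "calcium ion binding", "namespace": "molecular_function",
         "is_a": ["GO:0046872"]},
        {"id": "GO:0005575", "name": "cellular_component", "namespace": "cellular_component"},
        {"id": "GO:0043226", "name": "organelle", "namespace": "cellular_component",
         "is_a": ["GO:0005575"]},
        {"id": "GO:0043231", "name": "intracellular membrane-bounded organelle",
         "namespace": "cellular_component", "is_a": ["GO:0043226"]},
        {"id": "GO:0005739", "name": "mitochondrion", "namespace": "cellular_component",
         "is_a": ["GO:0043231"]},
    ])
    mp = _obo("mp-micro", [
        {"id": "MP:0005387", "name": "immune system phenotype"},
        {"id": "MP:0005376", "name": "homeostasis/metabolism phenotype"},
        {"id": "MP:0003009", "name": "abnormal cytokine secretion",
         "is_a": ["MP:0005387"]},
        {"id": "MP:0008565", "name": "increased interleukin-1 secretion",
         "is_a": ["MP:0003009"]},
    ])
    doid = _obo("doid-micro", [
        {"id": "DOID:2914", "name": "immune system disease"},
        {"id": "DOID:0014667", "name": "disease of metabolism"},
        {"id": "DOID:0050557", "name": "familial Mediterranean fever",
         "is_a": ["DOID:2914"]},
    ])
    gaf = "\n".join([
        "!gaf-version: 2.0",
        # Mefv: deep terms only — ancestors cover the query's GO conjuncts
        _gaf_row("MGI:1859396", "Mefv", "GO:0002526", "IDA", "P", "Mediterranean fever"),
        _gaf_row("MGI:1859396", "Mefv", "GO:0005509", "IEA", "F", "Mediterranean fever"),
        _gaf_row("MGI:1859396", "Mefv", "GO:0005739", "IDA", "C", "Mediterranean fever"),
        # Tnf: four of five conjuncts (no disease association)
        _gaf_row("MGI:0000100", "Tnf", "GO:0006954", "IDA", "P", "tumor necrosis factor"),
        _gaf_row("MGI:0000100", "Tnf", "GO:0043167", "IEA", "F", "tumor necrosis factor"),
        _gaf_row("MGI:0000100", "Tnf", "GO:0043231", "IEA", "C", "tumor necrosis factor"),
        # Alb: component only, plus a non-immune disease
        _gaf_row("MGI:0000101", "Alb", "GO:0005739", "IDA", "C", "albumin"),
    ]) + "\n"
    geno = "\n".join([
        "#gene id\tsymbol\tMP terms\tOMIM ids",
        "MGI:1859396\tMefv\tMP:0008565\tOMIM:249100",
        "MGI:0000100\tTnf\tMP:0003009\t",
        "MGI:0000101\tAlb\t\tOMIM:103600",
    ]) + "\n"
    omim = "\n".join([
        "#OMIM\tdisease term",
        "OMIM:249100\tDOID:0050557",
        "OMIM:103600\tDOID:0014667",
    ]) + "\n"
    return FixtureSet(go_obo=go, mp_obo=mp, doid_obo=doid, gaf=gaf,
                      geno_report=geno, omim_map=omim)


MEFV_QUERY = (
    "'inflammatory response gene product' "
    "and 'ion binding gene product' "
    "and 'intracellular membrane-bounded organelle gene product' "
    "and 'abnormal cytokine secretion gene product' "
    "and 'immune system disease gene product'"
)


# ---------------------------------------------------------------------------
# Filter-arithmetic demo fixture (20 GAF records → 14 survivors)
# ---------------------------------------------------------------------------

def filter_demo_fixture() -> FixtureSet:
    """20 annotation records: 3 RIKEN, 2 to GO namespace roots, 1 duplicate.

    An independent hand count leaves 14 survivors.
    """
    terms = [
        {"id": "GO:0003674", "name": "molecular_function", "namespace": "molecular_function"},
        {"id": "GO:0008150", "name": "biological_process", "namespace": "biological_process"},
        {"id": "GO:0005575", "name": "cellular_component", "namespace": "cellular_component"},
    ]
    for i in range(1, 7):
        terms.append({
            "id": f"GO:090000{i}", "name": f"function term {i}",
            "namespace": "molecular_function", "is_a": ["GO:0003674"],
        })
    go = _obo("go-filter-demo", terms)
    rows = ["!gaf-version: 2.0"]
    # 14 ordinary keepers (one of them duplicated below)
    for i in range(1, 15):
        term = f"GO:090000{(i % 6) + 1}"
        rows.append(_gaf_row(f"MGI:40000{i:02d}", f"Gene{i}", term, "IEA", "F"))
    # 3 RIKEN rows (symbol suffix / name substring conventions)
    rows.append(_gaf_row("MGI:4100001", "2310001A01Rik", "GO:0900001", "IEA", "F"))
    rows.append(_gaf_row("MGI:4100002", "9530077C05Rik", "GO:0900002", "IEA", "F"))
    rows.append(_gaf_row("MGI:4100003", "GeneX", "GO:0900003", "IEA", "F",
                         name="RIKEN cDNA 4930447C04 gene"))
    # 2 annotations to GO namespace roots
    rows.append(_gaf_row("MGI:4000001", "Gene1", "GO:0003674", "IEA", "F"))
    rows.append(_gaf_row("MGI:4000002", "Gene2", "GO:0008150", "IEA", "P"))
    # 1 exact duplicate of the first keeper (different evidence code)
    rows.append(_gaf_row("MGI:4000001", "Gene1", "GO:0900002", "IDA", "F"))
    return FixtureSet(go_obo=go, gaf="\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Parameters of a seeded synthetic corpus.

    Identical spec + seed yields byte-identical files.  The generated is_a
    graphs are acyclic by construction (terms only point to strictly
    shallower levels).
    """

    seed: int = 0
    terms_per_aspect: dict[Aspect, int] = field(default_factory=lambda: {
        Aspect.FUNCTION: 50,
        Aspect.PROCESS: 50,
        Aspect.COMPONENT: 30,
        Aspect.PHENOTYPE: 20,
        Aspect.DISEASE: 10,
    })
    max_depth: int = 6
    multiparent_prob: float = 0.15
    n_genes: int = 100
    annotations_per_gene: dict[Aspect, tuple[int, int]] = field(default_factory=lambda: {
        Aspect.FUNCTION: (0, 3),
        Aspect.PROCESS: (0, 3),
        Aspect.COMPONENT: (0, 2),
        Aspect.PHENOTYPE: (0, 2),
        Aspect.DISEASE: (0, 1),
    })
    riken_fraction: float = 0.0
    root_annotation_prob: float = 0.0
    obsolete_prob: float = 0.05


_ID_BASE = {
    Aspect.FUNCTION: ("GO", 1000000),
    Aspect.PROCESS: ("GO", 2000000),
    Aspect.COMPONENT: ("GO", 3000000),
    Aspect.PHENOTYPE: ("MP", 1000000),
    Aspect.DISEASE: ("DOID", 1000000),
}


def generate(spec: SyntheticSpec) -> FixtureSet:
    """Emit a complete synthetic corpus plus its ground-truth manifest.

    The manifest carries, per term, the true ancestor set (graph closure on
    the generated DAG via networkx — deliberately independent of the
    reasoner) and the expected answer to that term's singleton query:
    every gene annotated in the matching aspect to the term or any of its
    descendants.
    """
    rng = random.Random(spec.seed)
    if spec.max_depth < 1 and any(n > 1 for n in spec.terms_per_aspect.values()):
        raise ValueError("max_depth < 1 cannot host more than one term per aspect")

    graph = nx.DiGraph()  # edge child → parent
    aspect_terms: dict[Aspect, list[dict]] = {}
    roots: dict[Aspect, list[str]] = {}
    obsolete: set[str] = set()

    for aspect in Aspect:
        n = spec.terms_per_aspect.get(aspect, 0)
        prefix, base = _ID_BASE[aspect]
        terms: list[dict] = []
        if aspect in GO_NAMESPACE_ROOT:
            root_ids = [GO_NAMESPACE_ROOT[aspect]]
            terms.append({"id": root_ids[0], "name": GO_NAMESPACE[aspect],
                          "namespace": GO_NAMESPACE[aspect]})
        else:
            # phenotype/disease ontologies get two roots, so the pipeline's
            # convenient-root step has real work to do
            root_ids = [f"{prefix}:{base + 1}", f"{prefix}:{base + 2}"]
            for k, rid in enumerate(root_ids, start=1):
                terms.append({"id": rid, "name": f"{aspect.value} root {k}"})
        roots[aspect] = root_ids
        levels: dict[int, list[str]] = {0: list(root_ids)}
        for i in range(n):
            tid = f"{prefix}:{base + 10 + i}"
            is_obsolete = rng.random() < spec.obsolete_prob
            term = {"id": tid, "name": f"{aspect.value} term {i}",
                    "namespace": GO_NAMESPACE.get(aspect, "")}
            if is_obsolete:
                term["obsolete"] = True
                obsolete.add(tid)
                terms.append(term)
                continue
            depth = rng.randint(1, spec.max_depth)
            while depth - 1 not in levels or not levels[depth - 1]:
                depth -= 1
            parents = [rng.choice(levels[depth - 1])]
            if rng.random() < spec.multiparent_prob:
                shallower = [
                    t for d in range(depth) for t in levels.get(d, ())
                    if t not in parents
                ]
                if shallower:
                    parents.append(rng.choice(shallower))
            term["is_a"] = parents
            levels.setdefault(depth, []).append(tid)
            terms.append(term)
            for p in parents:
                graph.add_edge(tid, p)
        for rid in root_ids:
            graph.add_node(rid)
        aspect_terms[aspect] = terms

    # --- genes and annotations -------------------------------------------
    go_roots = set(GO_NAMESPACE_ROOT.values())
    annotations: dict[str, list[tuple[Aspect, str]]] = {}
    genes: list[tuple[str, str, str]] = []  # (id, symbol, name)
    for g in range(spec.n_genes):
        gid = f"MGI:{5000000 + g}"
        if rng.random() < spec.riken_fraction:
            symbol = f"{2300000 + g}A{g % 24:02d}Rik"
            name = f"RIKEN cDNA {2300000 + g}A{g % 24:02d} gene"
        else:
            symbol = f"Gene{g}"
            name = f"synthetic gene {g}"
        genes.append((gid, symbol, name))
        anns: list[tuple[Aspect, str]] = []
        for aspect in Aspect:
            lo, hi = spec.annotations_per_gene.get(aspect, (0, 0))
            pool = [
                t["id"] for t in aspect_terms[aspect]
                if t["id"] not in obsolete and t["id"] not in roots[aspect]
            ]
            if not pool:
                continue
            for _ in range(rng.randint(lo, hi)):
                if aspect in GO_NAMESPACE_ROOT and rng.random() < spec.root_annotation_prob:
                    anns.append((aspect, GO_NAMESPACE_ROOT[aspect]))
                else:
                    anns.append((aspect, rng.choice(pool)))
        annotations[gid] = sorted(set(anns), key=lambda x: (x[0].value, x[1]))

    # --- files -------------------------------------------------------------
    go_terms = (aspect_terms[Aspect.FUNCTION] + aspect_terms[Aspect.PROCESS]
                + aspect_terms[Aspect.COMPONENT])
    go_obo = _obo("go-synthetic", go_terms)
    mp_obo = _obo("mp-synthetic", aspect_terms[Aspect.PHENOTYPE])
    doid_obo = _obo("doid-synthetic", aspect_terms[Aspect.DISEASE])

    gaf_rows = ["!gaf-version: 2.0", "!synthetic corpus"]
    geno_rows = ["#gene id\tsymbol\tMP terms\tOMIM ids"]
    omim_of = {
        t["id"]: f"OMIM:{600000 + i}"
        for i, t in enumerate(aspect_terms[Aspect.DISEASE])
    }
    omim_rows = ["#OMIM id\tdisease term"] + [
        f"{omim}\t{tid}" for tid, omim in sorted(omim_of.items())
    ]
    aspect_letter = {Aspect.FUNCTION: "F", Aspect.PROCESS: "P", Aspect.COMPONENT: "C"}
    for gid, symbol, name in genes:
        mp_terms, omim_ids = [], []
        for aspect, tid in annotations[gid]:
            if aspect in aspect_letter:
                gaf_rows.append(
                    _gaf_row(gid, symbol, tid, "IEA", aspect_letter[aspect], name)
                )
            elif aspect is Aspect.PHENOTYPE:
                mp_terms.append(tid)
            else:
                omim_ids.append(omim_of[tid])
        if mp_terms or omim_ids:
            geno_rows.append(
                f"{gid}\t{symbol}\t{';'.join(mp_terms)}\t{';'.join(omim_ids)}"
            )

    # --- ground truth (graph closure, independent of the reasoner) ---------
    ancestors = {
        t: sorted(nx.descendants(graph, t)) for t in graph.nodes
    }
    descendants_or_self: dict[str, set[str]] = {
        t: {t} | set(nx.ancestors(graph, t)) for t in graph.nodes
    }
    annotated: dict[tuple[Aspect, str], set[str]] = {}
    for gid, _, name in genes:
        if "RIKEN" in name:
            continue  # RIKEN genes are filtered out by the pipeline
        for aspect, tid in annotations[gid]:
            if tid in go_roots:
                continue  # root annotations are filtered out
            annotated.setdefault((aspect, tid), set()).add(gid)
    singleton_answers: dict[str, list[str]] = {}
    for aspect in Aspect:
        for t in aspect_terms[aspect]:
            tid = t["id"]
            if tid in obsolete:
                continue
            hits: set[str] = set()
            for d in descendants_or_self[tid]:
                hits |= annotated.get((aspect, d), set())
            singleton_answers[tid] = sorted(mint_gene_class_id(g) for g in hits)

    manifest = {
        "seed": spec.seed,
        "ancestors": ancestors,
        "singleton_answers": singleton_answers,
        "n_genes": spec.n_genes,
        "convenient_roots": {
            Aspect.PHENOTYPE.value: mint_root_id("phenotype"),
            Aspect.DISEASE.value: mint_root_id("disease"),
        },
    }
    return FixtureSet(
        go_obo=go_obo,
        mp_obo=mp_obo,
        doid_obo=doid_obo,
        gaf="\n".join(gaf_rows) + "\n",
        geno_report="\n".join(geno_rows) + "\n",
        omim_map="\n".join(omim_rows) + "\n",
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Random EL ontologies (for reasoner stress tests)
# ---------------------------------------------------------------------------

def random_el_axioms(
    seed: int,
    n_classes: int = 30,
    n_axioms: int = 60,
    n_roles: int = 3,
    with_equivalences: bool = True,
) -> list[Axiom]:
    """A seeded random EL ontology over classes C0..Cn and roles r0..rk.

    Draws a mix of named subsumptions, conjunction subsumptions (both
    directions), existential restrictions (both directions), equivalences
    and role inclusions — everything the EL fragment allows, nothing more.
    Cycles and mutual subsumptions are allowed; the reasoner must cope.
    """
    rng = random.Random(seed)
    classes = [f"T:C{i}" for i in range(n_classes)]
    roles = [f"r{i}" for i in range(n_roles)]

    def named() -> Named:
        return Named(rng.choice(classes))

    def expr(depth: int = 2) -> object:
        kind = rng.random()
        if depth == 0 or kind < 0.5:
            return named()
        if kind < 0.8:
            return Existential(rng.choice(roles), expr(depth - 1))
        return Conjunction((expr(depth - 1), expr(depth - 1)))

    axioms: list[Axiom] = []
    for _ in range(n_axioms):
        roll = rng.random()
        if roll < 0.45:
            axioms.append(SubClassOf(named(), named()))
        elif roll < 0.65:
            axioms.append(SubClassOf(expr(1), named()))
        elif roll < 0.85:
            axioms.append(SubClassOf(named(), expr(2)))
        elif roll < 0.95 and with_equivalences:
            axioms.append(EquivalentClasses(named(), expr(2)))
        else:
            r, s = rng.choice(roles), rng.choice(roles)
            axioms.append(RoleInclusion(r, s))
    return axioms
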