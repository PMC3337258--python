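"""OBO 1.2 flat-file ingestion and translation to EL axioms.

Only the tag subset that carries logical or labelling content is parsed:
``id``, ``name``, ``namespace``, ``is_a``, ``relationship`` and
``is_obsolete`` in ``[Term]`` stanzas, plus ``[Typedef]`` ids as role names.
Everything else (synonyms, xrefs, intersection_of cross-products, ...) is
ignored with a log line — none of it participates in the class hierarchy
this package builds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Optional

from .model import (
    AxiomSet,
    Existential,
    GOAL_PREFIX,
    Named,
    SubClassOf,
    normalize_curie,
)

log = logging.getLogger(__name__)

_SEMANTIC_TAGS = {"id", "name", "namespace", "is_a", "relationship", "is_obsolete"}


class OboParseError(ValueError):
    """Raised for malformed OBO input; message carries the line number."""


@dataclass
class OntologyTerm:
    id: str
    label: str = ""
    namespace: str = ""
    is_obsolete: bool = False
    parents: list[str] = field(default_factory=list)
    relationships: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Ontology:
    """Parsed OBO content.

    ``dangling`` records parent / relationship targets referenced but not
    defined in the file — they are never silently dropped, and are declared
    as bare classes during axiom generation.
    """

    name: str = ""
    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    typedefs: list[str] = field(default_factory=list)

    @property
    def roots(self) -> set[str]:
        return {
            t.id
            for t in self.terms.values()
            if not t.is_obsolete and not t.parents
        }

    @property
    def dangling(self) -> set[str]:
        known = set(self.terms)
        out = set()
        for t in self.terms.values():
            for p in t.parents:
                if p not in known:
                    out.add(p)
            for _, tgt in t.relationships:
                if tgt not in known:
                    out.add(tgt)
        return out

    def non_obsolete(self) -> list[OntologyTerm]:
        return [t for t in self.terms.values() if not t.is_obsolete]


def _strip_comment(value: str) -> str:
    # OBO trailing comments start with " ! "
    idx = value.find("!")
    if idx >= 0:
        return value[:idx].strip()
    return value.strip()


def parse_obo(source: IO[str] | str, name: str = "") -> Ontology:
    """Parse OBO 1.2 text into an :class:`Ontology`.

    Raises :class:`OboParseError` (with a line number) for a ``[Term]``
    stanza lacking an ``id`` or for a duplicate id.  Unknown tags are
    ignored with a debug log line.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()

    ontology = Ontology(name=name)
    stanza_type: Optional[str] = None
    stanza_start = 0
    current: dict[str, list[str]] = {}

    def flush() -> None:
        if stanza_type is None:
            return
        if stanza_type == "Typedef":
            tid = current.get("id", [None])[0]
            if tid:
                ontology.typedefs.append(tid)
            return
        if stanza_type != "Term":
            return
        ids = current.get("id")
        if not ids:
            raise OboParseError(f"line {stanza_start}: [Term] stanza without id")
        term_id = normalize_curie(ids[0])
        if term_id in ontology.terms:
            raise OboParseError(f"line {stanza_start}: duplicate term id {term_id}")
        term = OntologyTerm(id=term_id)
        term.label = current.get("name", [""])[0]
        term.namespace = current.get("namespace", [""])[0]
        term.is_obsolete = current.get("is_obsolete", ["false"])[0].lower() == "true"
        if term.is_obsolete:
            # obsolete terms carry no edges after parsing
            ontology.terms[term_id] = term
            return
        for raw in current.get("is_a", []):
            term.parents.append(normalize_curie(_strip_comment(raw)))
        for raw in current.get("relationship", []):
            parts = _strip_comment(raw).split()
            if len(parts) != 2:
                raise OboParseError(
                    f"line {stanza_start}: malformed relationship {raw!r}"
                )
            term.relationships.append((parts[0], normalize_curie(parts[1])))
        ontology.terms[term_id] = term

    for lineno, raw_line in enumerate(lines, start=1):
        line = raw_line.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            stanza_type = line[1:-1]
            stanza_start = lineno
            current = {}
            continue
        if ":" not in line:
            log.debug("ignoring malformed line %d: %s", lineno, line)
            continue
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = value.strip()
        if stanza_type is None:
            continue  # header tags are not needed
        if stanza_type == "Typedef":
            if tag == "id":
                current.setdefault("id", []).append(value)
            continue
        if tag not in _SEMANTIC_TAGS:
            log.debug("ignoring tag %r at line %d", tag, lineno)
            continue
        if tag in ("is_a", "relationship"):
            current.setdefault(tag, []).append(value)
        else:
            current.setdefault(tag, []).append(
                _strip_comment(value) if tag == "id" else value
            )
    flush()
    return ontology


def serialize_obo(ontology: Ontology) -> str:
    """Write an :class:`Ontology` back out in the supported tag subset.

    ``parse_obo(serialize_obo(o))`` is a fixpoint over that subset.
    """
    chunks = ["format-version: 1.2", f"ontology: {ontology.name}" if ontology.name else ""]
    for term in ontology.terms.values():
        lines = ["", "[Term]", f"id: {term.id}"]
        if term.label:
            lines.append(f"name: {term.label}")
        if term.namespace:
            lines.append(f"namespace: {term.namespace}")
        if term.is_obsolete:
            lines.append("is_obsolete: true")
        for p in term.parents:
            lines.append(f"is_a: {p}")
        for rel, tgt in term.relationships:
            lines.append(f"relationship: {rel} {tgt}")
        chunks.append("\n".join(lines))
    for td in ontology.typedefs:
        chunks.append("\n".join(["", "[Typedef]", f"id: {td}"]))
    return "\n".join(c for c in chunks if c != "") + "\n"


def ontology_to_axioms(
    ontology: Ontology,
    relation_policy: Optional[Mapping[str, str]] = None,
    default_relations: bool = True,
) -> AxiomSet:
    """Translate parsed terms to EL axioms.

    ``is_a: P`` becomes ``term ⊑ P``; ``relationship: r T`` becomes
    ``term ⊑ ∃r.T`` with the role taken from ``relation_policy`` (falling
    back, when ``default_relations``, to a role of the same name).
    Obsolete terms emit nothing.
    """
    policy = dict(relation_policy or {})
    missing = sorted(
        {
            rel
            for t in ontology.non_obsolete()
            for rel, _ in t.relationships
            if rel not in policy
        }
    )
    if missing and not default_relations:
        raise ValueError(f"no relation policy for: {', '.join(missing)}")
    for rel in missing:
        policy[rel] = rel

    axioms = AxiomSet()
    for term in ontology.non_obsolete():
        for parent in term.parents:
            axioms.add(SubClassOf(Named(term.id), Named(parent)))
        for rel, tgt in term.relationships:
            axioms.add(SubClassOf(Named(term.id), Existential(policy[rel], Named(tgt))))
    return axioms


def mint_root_id(root_label: str) -> str:
    slug = "".join(c if c.isalnum() else "_" for c in root_label.strip().lower())
    return f"{GOAL_PREFIX}:root_{slug}"


def add_convenient_root(
    axioms: AxiomSet,
    ontology: Ontology,
    root_label: str,
    labels: Optional[dict[str, str]] = None,
) -> tuple[AxiomSet, str]:
    """Mint an artificial root class and put every existing root under it.

    Supporting ontologies without a single root (the phenotype and disease
    ontologies) get one so that a uniform singleton class can be defined
    over the whole ontology.  Idempotent; returns the (possibly pre-existing)
    root id together with the extended axiom set.
    """
    if not ontology.roots:
        raise ValueError(f"ontology {ontology.name!r} has no roots")
    for term in ontology.terms.values():
        if term.label == root_label:
            raise ValueError(f"root label {root_label!r} collides with {term.id}")
    root_id = mint_root_id(root_label)
    out = AxiomSet(axioms)
    for r in sorted(ontology.roots):
        if r != root_id:
            out.add(SubClassOf(Named(r), Named(root_id)))
    if labels is not None:
        labels[root_id] = root_label
    return out, root_id
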