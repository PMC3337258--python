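"""Core logical model: term identifiers, EL class expressions, axioms.

The ontology is kept inside the EL fragment of OWL 2: named classes,
conjunction and existential restriction only.  That restriction is what makes
classification polynomial and is relied on throughout the reasoner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Union

# Reserved identifiers.  TOP plays the role of owl:Thing; GENE_PRODUCT is the
# root primitive class under which every gene-product class is asserted.
TOP = "owl:Thing"
GENE_PRODUCT = "GOAL:gene_product"
GOAL_PREFIX = "GOAL"

_CURIE_RE = re.compile(r"^[A-Za-z0-9_.-]+[:_][A-Za-z0-9_.-]+$")


def normalize_curie(raw: str) -> str:
    """Normalize a CURIE so that ``GO_0004930`` and ``GO:0004930`` coincide.

    The underscore and colon separators are used interchangeably in the
    source material; internally the colon form is canonical.  Identifiers
    already containing a colon are returned with surrounding space stripped.
    """
    s = raw.strip()
    if not s:
        raise ValueError("empty identifier")
    if ":" in s:
        prefix, local = s.split(":", 1)
        return f"{prefix.strip()}:{local.strip()}"
    if "_" in s:
        prefix, local = s.split("_", 1)
        # Only split on the first underscore when it looks like PREFIX_LOCAL
        if prefix and local:
            return f"{prefix}:{local}"
    raise ValueError(f"not a CURIE: {raw!r}")


def is_valid_term_id(s: str) -> bool:
    return s == TOP or bool(_CURIE_RE.match(s))


def curie_local(term_id: str) -> str:
    """Local part of a CURIE (after the first colon)."""
    return term_id.split(":", 1)[1]


def curie_prefix(term_id: str) -> str:
    return term_id.split(":", 1)[0]


# ---------------------------------------------------------------------------
# Class expressions (EL only)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Named:
    """A named class, referenced by its term id."""
    id: str

    def __str__(self) -> str:
        return self.id


@dataclass(frozen=True)
class Conjunction:
    """Intersection of two or more class expressions."""
    conjuncts: tuple["ClassExpression", ...]

    def __post_init__(self) -> None:
        if len(self.conjuncts) < 2:
            raise ValueError("conjunction needs at least two conjuncts")

    def __str__(self) -> str:
        return "(" + " and ".join(str(c) for c in self.conjuncts) + ")"


@dataclass(frozen=True)
class Existential:
    """Existential restriction ``role some filler``."""
    role: str
    filler: "ClassExpression"

    def __str__(self) -> str:
        return f"({self.role} some {self.filler})"


ClassExpression = Union[Named, Conjunction, Existential]


def conjunction_of(parts: Iterable[ClassExpression]) -> ClassExpression:
    """Build a conjunction, flattening nesting and collapsing singletons."""
    flat: list[ClassExpression] = []
    for p in parts:
        if isinstance(p, Conjunction):
            flat.extend(p.conjuncts)
        else:
            flat.append(p)
    seen: list[ClassExpression] = []
    for p in flat:
        if p not in seen:
            seen.append(p)
    if not seen:
        raise ValueError("empty conjunction")
    if len(seen) == 1:
        return seen[0]
    return Conjunction(tuple(seen))


def expression_signature(expr: ClassExpression) -> set[str]:
    """All named class ids and role names occurring in an expression."""
    out: set[str] = set()
    stack = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, Named):
            out.add(e.id)
        elif isinstance(e, Existential):
            out.add(e.role)
            stack.append(e.filler)
        else:
            stack.extend(e.conjuncts)
    return out


# ---------------------------------------------------------------------------
# Axioms
# ---------------------------------------------------------------------------

Annotations = tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class SubClassOf:
    sub: ClassExpression
    sup: ClassExpression
    # annotations (e.g. evidence codes) never affect entailment, so they are
    # excluded from equality/hash: two axioms with the same logical content
    # are one axiom, and AxiomSet merges their annotations.
    annotations: Annotations = field(default=(), compare=False)

    def __str__(self) -> str:
        return f"SubClassOf({self.sub} {self.sup})"


@dataclass(frozen=True)
class EquivalentClasses:
    a: ClassExpression
    b: ClassExpression
    annotations: Annotations = field(default=(), compare=False)

    def __str__(self) -> str:
        return f"EquivalentClasses({self.a} {self.b})"


@dataclass(frozen=True)
class RoleInclusion:
    sub: str
    sup: str
    annotations: Annotations = field(default=(), compare=False)

    def __str__(self) -> str:
        return f"SubObjectPropertyOf({self.sub} {self.sup})"


Axiom = Union[SubClassOf, EquivalentClasses, RoleInclusion]


def axiom_signature(ax: Axiom) -> set[str]:
    if isinstance(ax, RoleInclusion):
        return {ax.sub, ax.sup}
    if isinstance(ax, SubClassOf):
        return expression_signature(ax.sub) | expression_signature(ax.sup)
    return expression_signature(ax.a) | expression_signature(ax.b)


class AxiomSet:
    """An ordered, deduplicating collection of axioms.

    Insertion order is preserved (so downstream processing is deterministic);
    adding an axiom whose logical content is already present merges its
    annotations into the existing one instead of duplicating it.
    """

    def __init__(self, axioms: Iterable[Axiom] = ()) -> None:
        self._axioms: dict[Axiom, Annotations] = {}
        for ax in axioms:
            self.add(ax)

    def add(self, axiom: Axiom) -> None:
        if axiom in self._axioms:
            existing = self._axioms[axiom]
            merged = list(existing)
            for pair in axiom.annotations:
                if pair not in merged:
                    merged.append(pair)
            self._axioms[axiom] = tuple(merged)
        else:
            self._axioms[axiom] = axiom.annotations

    def extend(self, axioms: Iterable[Axiom]) -> None:
        for ax in axioms:
            self.add(ax)

    def annotations_for(self, axiom: Axiom) -> Annotations:
        return self._axioms[axiom]

    def __iter__(self) -> Iterator[Axiom]:
        for ax, anns in self._axioms.items():
            if anns != ax.annotations:
                yield _with_annotations(ax, anns)
            else:
                yield ax

    def __len__(self) -> int:
        return len(self._axioms)

    def __contains__(self, axiom: Axiom) -> bool:
        return axiom in self._axioms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AxiomSet):
            return NotImplemented
        return list(self) == list(other)

    def signature(self) -> set[str]:
        out: set[str] = set()
        for ax in self._axioms:
            out |= axiom_signature(ax)
        return out

    def class_signature(self) -> set[str]:
        roles = set()
        for ax in self._axioms:
            if isinstance(ax, RoleInclusion):
                roles.update((ax.sub, ax.sup))
            else:
                for e in _subexpressions(ax):
                    if isinstance(e, Existential):
                        roles.add(e.role)
        return self.signature() - roles

    def to_functional_lines(self) -> list[str]:
        """Line-oriented functional-style rendering, one axiom per line."""
        lines = []
        for ax in self:
            ann = ""
            if ax.annotations:
                ann = " # " + "; ".join(f"{k}={v}" for k, v in ax.annotations)
            lines.append(str(ax) + ann)
        return lines


def _subexpressions(ax: Axiom) -> Iterator[ClassExpression]:
    tops: tuple[ClassExpression, ...]
    if isinstance(ax, SubClassOf):
        tops = (ax.sub, ax.sup)
    elif isinstance(ax, EquivalentClasses):
        tops = (ax.a, ax.b)
    else:
        return
    stack = list(tops)
    while stack:
        e = stack.pop()
        yield e
        if isinstance(e, Existential):
            stack.append(e.filler)
        elif isinstance(e, Conjunction):
            stack.extend(e.conjuncts)


def _with_annotations(ax: Axiom, anns: Annotations) -> Axiom:
    if isinstance(ax, SubClassOf):
        return SubClassOf(ax.sub, ax.sup, anns)
    if isinstance(ax, EquivalentClasses):
        return EquivalentClasses(ax.a, ax.b, anns)
    return RoleInclusion(ax.sub, ax.sup, anns)


def validate_el(axioms: Iterable[Axiom]) -> None:
    """Profile check: every axiom must be within the EL fragment.

    The model types can only express EL constructs, so this validates
    structural well-formedness (conjunction arity, known variants) and acts
    as the seam where a richer model would be rejected.
    """
    for ax in axioms:
        if isinstance(ax, RoleInclusion):
            continue
        if isinstance(ax, (SubClassOf, EquivalentClasses)):
            for e in _subexpressions(ax):
                if isinstance(e, Conjunction) and len(e.conjuncts) < 2:
                    raise ValueError(f"malformed conjunction in {ax}")
                if not isinstance(e, (Named, Conjunction, Existential)):
                    raise ValueError(f"non-EL expression in {ax}")
        else:
            raise ValueError(f"unsupported axiom type: {ax!r}")


# ---------------------------------------------------------------------------
# JSON round-tripping for expressions and axioms
# ---------------------------------------------------------------------------

def expression_to_json(expr: ClassExpression) -> object:
    if isinstance(expr, Named):
        return expr.id
    if isinstance(expr, Existential):
        return ["some", expr.role, expression_to_json(expr.filler)]
    return ["and"] + [expression_to_json(c) for c in expr.conjuncts]


def expression_from_json(obj: object) -> ClassExpression:
    if isinstance(obj, str):
        return Named(obj)
    assert isinstance(obj, list) and obj, f"bad expression payload: {obj!r}"
    if obj[0] == "some":
        return Existential(obj[1], expression_from_json(obj[2]))
    if obj[0] == "and":
        return Conjunction(tuple(expression_from_json(c) for c in obj[1:]))
    raise ValueError(f"bad expression payload: {obj!r}")


def axiom_to_json(ax: Axiom) -> object:
    anns = [list(p) for p in ax.annotations]
    if isinstance(ax, SubClassOf):
        return ["sub", expression_to_json(ax.sub), expression_to_json(ax.sup), anns]
    if isinstance(ax, EquivalentClasses):
        return ["equiv", expression_to_json(ax.a), expression_to_json(ax.b), anns]
    return ["role", ax.sub, ax.sup, anns]


def axiom_from_json(obj: object) -> Axiom:
    assert isinstance(obj, list) and len(obj) == 4
    kind, a, b, anns = obj
    annotations = tuple((k, v) for k, v in anns)
    if kind == "sub":
        return SubClassOf(expression_from_json(a), expression_from_json(b), annotations)
    if kind == "equiv":
        return EquivalentClasses(expression_from_json(a), expression_from_json(b), annotations)
    if kind == "role":
        return RoleInclusion(a, b, annotations)
    raise ValueError(f"bad axiom payload: {obj!r}")
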