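"""Conjunctive DL queries in a Manchester-syntax subset.

Queries are parsed from text like

    'signal transduction gene product' and 'receptor activity gene product'

or the logically equivalent expanded form

    'gene product' and is_capable_of_process some 'signal transduction'

classified as a fresh defined class in a scratch overlay, and answered with
the gene-product subclasses of that class.  The deployed classification is
never mutated: queries are side-effect-free.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .build import GoalOntology
from .model import (
    ClassExpression,
    Conjunction,
    EquivalentClasses,
    Existential,
    GENE_PRODUCT,
    Named,
    SubClassOf,
    TOP,
    conjunction_of,
    is_valid_term_id,
    normalize_curie,
)
from .reasoner import (
    FRESH_PREFIX,
    NormalizedAxiomSet,
    SubsumptionMap,
    extend_saturation,
    normalize,
    saturate,
)

QUERY_CLASS = "GOAL:__query__"


class QuerySyntaxError(ValueError):
    """Syntax error with the offending position in the query string."""

    def __init__(self, message: str, position: int):
        super().__init__(f"at position {position}: {message}")
        self.position = position


class UnknownNameError(ValueError):
    """A label or CURIE that does not resolve, with nearest matches."""

    def __init__(self, name: str, candidates: Sequence[str]):
        hint = f"; did you mean: {', '.join(candidates)}" if candidates else ""
        super().__init__(f"unknown name {name!r}{hint}")
        self.candidates = list(candidates)


class AmbiguousNameError(ValueError):
    def __init__(self, name: str, ids: Sequence[str]):
        super().__init__(f"label {name!r} is ambiguous: {', '.join(sorted(ids))}")
        self.ids = list(ids)


@dataclass
class NameIndex:
    """Case-insensitive label → id resolution plus known ids and roles."""

    ids: set[str] = field(default_factory=set)
    by_label: dict[str, list[str]] = field(default_factory=dict)
    roles: set[str] = field(default_factory=set)
    labels: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_goal(cls, goal: GoalOntology) -> "NameIndex":
        idx = cls()
        idx.ids = {c for c in goal.axioms.class_signature() if is_valid_term_id(c)}
        idx.ids |= goal.gene_product_ids | set(goal.singleton_index.values())
        idx.ids.add(GENE_PRODUCT)
        idx.roles = set(goal.roles)
        for cid, label in goal.labels.items():
            if "#" in cid:
                continue
            idx.ids.add(cid)
            idx.labels[cid] = label
            idx.by_label.setdefault(label.lower(), [])
            if cid not in idx.by_label[label.lower()]:
                idx.by_label[label.lower()].append(cid)
        return idx

    def resolve_label(self, label: str) -> str:
        hits = self.by_label.get(label.lower(), [])
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise AmbiguousNameError(label, hits)
        near = difflib.get_close_matches(label.lower(), self.by_label.keys(), n=3)
        raise UnknownNameError(label, [f"'{n}'" for n in near])

    def resolve_curie(self, raw: str) -> str:
        cid = normalize_curie(raw)
        if cid in self.ids:
            return cid
        near = difflib.get_close_matches(cid, self.ids, n=3)
        raise UnknownNameError(raw, near)


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

_QUOTES = "'’‘"
_WORD_RE = re.compile(r"[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(("paren", ch, i))
            i += 1
            continue
        if ch in _QUOTES:
            j = i + 1
            while j < n and text[j] not in _QUOTES:
                j += 1
            if j >= n:
                raise QuerySyntaxError("unterminated quoted label", i)
            tokens.append(("label", text[i + 1 : j], i))
            i = j + 1
            continue
        m = _WORD_RE.match(text, i)
        assert m is not None
        word = m.group(0)
        low = word.lower()
        if low in ("and", "some"):
            tokens.append((low, word, i))
        else:
            tokens.append(("word", word, i))
        i = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], index: NameIndex, length: int):
        self.tokens = tokens
        self.index = index
        self.pos = 0
        self.length = length

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of query", self.length)
        self.pos += 1
        return tok

    def parse_expression(self) -> ClassExpression:
        parts = [self.parse_term()]
        while True:
            tok = self.peek()
            if tok is None or tok[0] != "and":
                break
            self.take()
            parts.append(self.parse_term())
        return conjunction_of(parts) if len(parts) > 1 else parts[0]

    def parse_term(self) -> ClassExpression:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("expected a class expression", self.length)
        kind, value, pos = tok
        if kind == "word" and value in self.index.roles:
            self.take()
            nxt = self.take()
            if nxt[0] != "some":
                raise QuerySyntaxError(
                    f"expected 'some' after role {value!r}", nxt[2]
                )
            return Existential(value, self.parse_primary())
        return self.parse_primary()

    def parse_primary(self) -> ClassExpression:
        kind, value, pos = self.take()
        if kind == "paren" and value == "(":
            inner = self.parse_expression()
            closing = self.take()
            if closing[:2] != ("paren", ")"):
                raise QuerySyntaxError("expected ')'", closing[2])
            return inner
        if kind == "label":
            return Named(self.index.resolve_label(value))
        if kind == "word":
            if ":" in value or "_" in value:
                return Named(self.index.resolve_curie(value))
            # bare unquoted label word (single-word labels are allowed)
            return Named(self.index.resolve_label(value))
        raise QuerySyntaxError(f"unexpected {value!r}", pos)


def parse_query(text: str, index: NameIndex) -> ClassExpression:
    """Parse a Manchester-style conjunctive query against a name index."""
    tokens = _tokenize(text)
    if not tokens:
        raise QuerySyntaxError("empty query", 0)
    parser = _Parser(tokens, index, len(text))
    expr = parser.parse_expression()
    trailing = parser.peek()
    if trailing is not None:
        raise QuerySyntaxError(f"unexpected trailing {trailing[1]!r}", trailing[2])
    return expr


# ---------------------------------------------------------------------------
# Answering
# ---------------------------------------------------------------------------

@dataclass
class QueryResult:
    query: ClassExpression
    equivalent: set[str]
    subclasses: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def sorted_subclasses(self, goal: GoalOntology) -> list[str]:
        return sorted(self.subclasses, key=lambda c: (goal.label_of(c), c))


@dataclass
class Deployment:
    """A classified GOAL ontology: build once, query many times."""

    goal: GoalOntology
    norm: NormalizedAxiomSet
    sub_map: SubsumptionMap
    index: NameIndex

    def query(self, text_or_expr: str | ClassExpression, **kw) -> QueryResult:
        expr = (
            parse_query(text_or_expr, self.index)
            if isinstance(text_or_expr, str)
            else text_or_expr
        )
        return answer_query(self.goal, self.sub_map, expr, norm=self.norm, **kw)


def classify(goal: GoalOntology, role_chains: Iterable[tuple[str, str, str]] = ()) -> Deployment:
    """Normalize and saturate the full ontology (the deploy-time step)."""
    norm = normalize(goal.axioms, role_chains=role_chains)
    sub_map = saturate(norm)
    return Deployment(goal, norm, sub_map, NameIndex.from_goal(goal))


def _is_named_conjunction(expr: ClassExpression) -> Optional[list[str]]:
    if isinstance(expr, Named):
        return [expr.id]
    if isinstance(expr, Conjunction) and all(
        isinstance(c, Named) for c in expr.conjuncts
    ):
        return [c.id for c in expr.conjuncts]  # type: ignore[union-attr]
    return None


def answer_query(
    goal: GoalOntology,
    sub_map: SubsumptionMap,
    q: ClassExpression,
    norm: Optional[NormalizedAxiomSet] = None,
    compute_equivalents: bool = True,
    with_descriptions: bool = False,
) -> QueryResult:
    """Answer a conjunctive query against a deployed classification.

    A fresh defined class ``Q ≡ q`` is classified in a scratch overlay
    (copy-on-write), so the deployed ``sub_map`` is observably unchanged.
    Purely-named conjunctions take a fast path that intersects precomputed
    subsumer sets.  Results are restricted to gene-product classes.
    """
    for name in _expression_ids(q):
        if name not in sub_map.subsumers and name != TOP:
            raise UnknownNameError(name, [])

    named = _is_named_conjunction(q)
    equivalent: set[str] = set()
    if named is not None:
        subclasses = {
            x
            for x in goal.gene_product_ids
            if all(c in sub_map.subsumers_of(x) for c in named)
        }
        if len(named) == 1 and compute_equivalents:
            c = named[0]
            equivalent = {
                y
                for y in sub_map.subsumers_of(c)
                if y != c and not y.startswith(FRESH_PREFIX) and y != TOP
                and c in sub_map.subsumers_of(y)
            }
            return QueryResult(q, equivalent, subclasses,
                               _maybe_descr(goal, subclasses, with_descriptions))
        if not compute_equivalents:
            return QueryResult(q, set(), subclasses,
                               _maybe_descr(goal, subclasses, with_descriptions))
    if norm is None:
        norm = normalize(goal.axioms)
    overlay, _ = extend_saturation(
        sub_map, norm, [EquivalentClasses(Named(QUERY_CLASS), q)]
    )
    subclasses = {
        x
        for x in goal.gene_product_ids
        if QUERY_CLASS in overlay.subsumers_of(x)
    }
    if compute_equivalents:
        equivalent = {
            y
            for y in overlay.subsumers_of(QUERY_CLASS)
            if y not in (QUERY_CLASS, TOP)
            and not y.startswith(FRESH_PREFIX)
            and QUERY_CLASS in overlay.subsumers_of(y)
        }
    return QueryResult(q, equivalent, subclasses,
                       _maybe_descr(goal, subclasses, with_descriptions))


def _maybe_descr(goal: GoalOntology, ids: set[str], enabled: bool) -> dict[str, str]:
    if not enabled:
        return {}
    return {i: render_description(goal, i) for i in sorted(ids)}


def _expression_ids(expr: ClassExpression) -> set[str]:
    out: set[str] = set()
    stack = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, Named):
            out.add(e.id)
        elif isinstance(e, Existential):
            stack.append(e.filler)
        else:
            stack.extend(e.conjuncts)
    return out


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_expression(goal: GoalOntology, expr: ClassExpression,
                      index: Optional[NameIndex] = None) -> str:
    """Render an expression in the same dialect parse_query accepts.

    A named class is shown by its label when that label resolves uniquely;
    otherwise by its CURIE, so that parse(render(x)) is the identity.
    """
    if index is None:
        index = NameIndex.from_goal(goal)

    def atom(e: ClassExpression, top: bool) -> str:
        if isinstance(e, Named):
            label = goal.labels.get(e.id)
            if label and index.by_label.get(label.lower()) == [e.id]:
                return f"'{label}'"
            return e.id
        if isinstance(e, Existential):
            s = f"{e.role} some {atom(e.filler, False)}"
            return s if top else f"({s})"
        s = " and ".join(atom(c, False) for c in e.conjuncts)
        return s if top else f"({s})"

    return atom(expr, True)


def render_description(goal: GoalOntology, class_id: str,
                       index: Optional[NameIndex] = None) -> str:
    """Manchester-style description of a class's asserted axioms."""
    known = goal.axioms.class_signature() | goal.gene_product_ids | {GENE_PRODUCT}
    if class_id not in known and class_id not in goal.labels:
        raise KeyError(f"unknown class: {class_id}")
    if index is None:
        index = NameIndex.from_goal(goal)
    lines = [f"Class: {class_id}"]
    label = goal.labels.get(class_id)
    if label:
        lines.append(f"  Label: {label!r}")
    definition = goal.labels.get(class_id + "#definition")
    if definition:
        lines.append(f"  Definition: {definition!r}")
    for ax in goal.axioms:
        if isinstance(ax, SubClassOf) and ax.sub == Named(class_id):
            ann = "".join(
                f"  [{k}={v}]" for k, v in ax.annotations
            )
            lines.append(
                f"  SubClassOf: {render_expression(goal, ax.sup, index)}{ann}"
            )
        elif isinstance(ax, EquivalentClasses) and ax.a == Named(class_id):
            lines.append(
                f"  EquivalentTo: {render_expression(goal, ax.b, index)}"
            )
    return "\n".join(lines)
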