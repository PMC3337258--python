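"""Independent oracles for the reasoner and explanation tests.

Everything here is deliberately naive: plain loops applied until nothing
changes, no worklists, no indexes, plus a structurally different
normalization.  These implementations share no code paths with the package
internals they check.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

from goalont.model import (
    Axiom,
    ClassExpression,
    Conjunction,
    EquivalentClasses,
    Existential,
    Named,
    RoleInclusion,
    SubClassOf,
    TOP,
)


# ---------------------------------------------------------------------------
# Independent normalization: canonical string-named subexpressions
# ---------------------------------------------------------------------------

def _canon(expr: ClassExpression) -> str:
    if isinstance(expr, Named):
        return expr.id
    if isinstance(expr, Existential):
        return f"<{expr.role}.{_canon(expr.filler)}>"
    parts = sorted(_canon(c) for c in expr.conjuncts)
    return "<and:" + "|".join(parts) + ">"


def oracle_normal_forms(axioms: Iterable[Axiom]):
    """Normalize with canonical names (not counters) for every subexpression.

    Returns (nf1, nf2, nf3, nf4, role_incl, classes) with nf2 kept n-ary:
    (frozenset of conjunct names, conclusion).
    """
    nf1: set[tuple[str, str]] = set()
    nf2: set[tuple[frozenset, str]] = set()
    nf3: set[tuple[str, str, str]] = set()
    nf4: set[tuple[str, str, str]] = set()
    roles: set[tuple[str, str]] = set()
    classes: set[str] = set()

    def define(expr: ClassExpression) -> str:
        """Name for expr plus defining axioms in both directions."""
        name = _canon(expr)
        if name in classes:
            return name
        classes.add(name)
        if isinstance(expr, Named):
            return name
        if isinstance(expr, Existential):
            f = define(expr.filler)
            nf3.add((name, expr.role, f))
            nf4.add((expr.role, f, name))
        else:
            parts = [define(c) for c in expr.conjuncts]
            for p in parts:
                nf1.add((name, p))
            nf2.add((frozenset(parts), name))
        return name

    def sub(a: ClassExpression, b: ClassExpression) -> None:
        nf1.add((define(a), define(b)))

    for ax in axioms:
        if isinstance(ax, SubClassOf):
            sub(ax.sub, ax.sup)
        elif isinstance(ax, EquivalentClasses):
            sub(ax.a, ax.b)
            sub(ax.b, ax.a)
        elif isinstance(ax, RoleInclusion):
            roles.add((ax.sub, ax.sup))
    return nf1, nf2, nf3, nf4, roles, classes


def naive_entailed_subsumers(
    axioms: Iterable[Axiom],
    extra_classes: Iterable[str] = (),
) -> dict[str, set[str]]:
    """Apply all completion rules until no change; no worklist, no indexes."""
    nf1, nf2, nf3, nf4, role_incl, classes = oracle_normal_forms(axioms)
    classes = set(classes) | set(extra_classes)
    S = {x: {x, TOP} for x in classes}
    R: dict[str, set[tuple[str, str]]] = {}
    changed = True
    while changed:
        changed = False

        def add_sub(x: str, a: str) -> None:
            nonlocal changed
            if a not in S[x]:
                S[x].add(a)
                changed = True

        def add_edge(r: str, x: str, y: str) -> None:
            nonlocal changed
            pairs = R.setdefault(r, set())
            if (x, y) not in pairs:
                pairs.add((x, y))
                if y not in S:
                    S[y] = {y, TOP}
                changed = True

        for x in list(S):
            for a, b in nf1:
                if a in S[x]:
                    add_sub(x, b)
            for parts, b in nf2:
                if parts <= S[x]:
                    add_sub(x, b)
            for a, r, b in nf3:
                if a in S[x]:
                    add_edge(r, x, b)
        for r, pairs in list(R.items()):
            for x, y in list(pairs):
                for rr, b, a in nf4:
                    if rr == r and b in S[y]:
                        add_sub(x, a)
                for sub_r, sup_r in role_incl:
                    if sub_r == r:
                        add_edge(sup_r, x, y)
    return S


def naive_entails(axioms: Iterable[Axiom], sub: str, sup: str) -> bool:
    S = naive_entailed_subsumers(axioms, extra_classes=[sub])
    return sup == TOP or sup in S.get(sub, {sub})


def restrict_to_signature(
    subsumers: dict[str, set[str]], signature: set[str]
) -> dict[str, frozenset[str]]:
    """Project subsumer sets onto the original (non-fresh) signature."""
    return {
        x: frozenset(a for a in s if a in signature or a == TOP)
        for x, s in subsumers.items()
        if x in signature
    }


# ---------------------------------------------------------------------------
# Graph-ancestor oracle (pure is_a hierarchies)
# ---------------------------------------------------------------------------

def graph_ancestors(edges: Sequence[tuple[str, str]]) -> dict[str, set[str]]:
    """Transitive ancestors over child→parent edges, computed by BFS."""
    parents: dict[str, set[str]] = {}
    nodes: set[str] = set()
    for c, p in edges:
        parents.setdefault(c, set()).add(p)
        nodes.update((c, p))
    out = {}
    for n in nodes:
        seen: set[str] = set()
        stack = [n]
        while stack:
            for p in parents.get(stack.pop(), ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        out[n] = seen
    return out


# ---------------------------------------------------------------------------
# Exhaustive justification enumeration
# ---------------------------------------------------------------------------

def enumerate_minimal_justifications(
    axioms: Sequence[Axiom],
    sub: str,
    sup: str,
    fixed: Sequence[Axiom] = (),
    max_size: int | None = None,
) -> set[frozenset[Axiom]]:
    """All minimal entailing subsets, by exhaustive subset enumeration.

    Subsets are visited in increasing size; supersets of an already-found
    justification are skipped, so every reported set is minimal.
    """
    axioms = list(axioms)
    limit = max_size if max_size is not None else len(axioms)
    found: set[frozenset[Axiom]] = set()
    for size in range(0, limit + 1):
        for combo in itertools.combinations(axioms, size):
            s = frozenset(combo)
            if any(j <= s for j in found):
                continue
            if naive_entails(list(combo) + list(fixed), sub, sup):
                found.add(s)
    return found
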