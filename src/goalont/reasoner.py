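"""Polynomial-time EL classification by completion-rule saturation.

Axioms are first brought into the usual EL normal forms

    NF1  A ⊑ B          NF2  A1 ⊓ A2 ⊑ B
    NF3  A ⊑ ∃r.B       NF4  ∃r.B ⊑ A

over named classes only (complex subexpressions are replaced by fresh
names with defining axioms, a conservative extension).  A worklist then
computes the least fixpoint of the completion rules

    R1  X⊑A, A⊑B                 ⟹  X⊑B
    R2  X⊑A1, X⊑A2, A1⊓A2⊑B      ⟹  X⊑B
    R3  X⊑A, A⊑∃r.B              ⟹  (X,B) ∈ R(r)
    R4  (X,Y)∈R(r), Y⊑A, ∃r.A⊑B  ⟹  X⊑B
    R5  (X,Y)∈R(r), r⊑s          ⟹  (X,Y) ∈ R(s)
    R6  (X,Y)∈R(r), (Y,Z)∈R(s), r∘s⊑t ⟹ (X,Z) ∈ R(t)   [optional]

The worklist is FIFO and axioms are indexed in input order, so runs are
bit-reproducible.  Saturation size is bounded by (#classes)².
"""

from __future__ import annotations

import hashlib
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    Axiom,
    AxiomSet,
    ClassExpression,
    Conjunction,
    EquivalentClasses,
    Existential,
    Named,
    RoleInclusion,
    SubClassOf,
    TOP,
    validate_el,
)

FRESH_PREFIX = "_fresh:"


@dataclass
class NormalizedAxiomSet:
    nf1: list[tuple[str, str]] = field(default_factory=list)
    nf2: list[tuple[str, str, str]] = field(default_factory=list)
    nf3: list[tuple[str, str, str]] = field(default_factory=list)  # (A, r, B)
    nf4: list[tuple[str, str, str]] = field(default_factory=list)  # (r, B, A)
    role_inclusions: list[tuple[str, str]] = field(default_factory=list)
    role_chains: list[tuple[str, str, str]] = field(default_factory=list)
    fresh_names: dict[str, ClassExpression] = field(default_factory=dict)
    classes: set[str] = field(default_factory=set)
    _expr_cache: dict[ClassExpression, str] = field(default_factory=dict)
    _counter: int = 0

    def copy(self) -> "NormalizedAxiomSet":
        return NormalizedAxiomSet(
            nf1=list(self.nf1),
            nf2=list(self.nf2),
            nf3=list(self.nf3),
            nf4=list(self.nf4),
            role_inclusions=list(self.role_inclusions),
            role_chains=list(self.role_chains),
            fresh_names=dict(self.fresh_names),
            classes=set(self.classes),
            _expr_cache=dict(self._expr_cache),
            _counter=self._counter,
        )

    # -- normalization ------------------------------------------------------

    def _fresh(self, expr: ClassExpression) -> str:
        self._counter += 1
        name = f"{FRESH_PREFIX}{self._counter}"
        self.fresh_names[name] = expr
        self.classes.add(name)
        return name

    def _atom(self, expr: ClassExpression) -> str:
        """Named class standing for ``expr``; fresh names get full definitions."""
        if isinstance(expr, Named):
            self.classes.add(expr.id)
            return expr.id
        cached = self._expr_cache.get(expr)
        if cached is not None:
            return cached
        if isinstance(expr, Existential):
            filler = self._atom(expr.filler)
            name = self._fresh(expr)
            self.nf3.append((name, expr.role, filler))
            self.nf4.append((expr.role, filler, name))
        else:
            atoms = [self._atom(c) for c in expr.conjuncts]
            name = self._fresh(expr)
            for a in atoms:
                self.nf1.append((name, a))
            self._chain_nf2(atoms, name)
        self._expr_cache[expr] = name
        return name

    def _chain_nf2(self, atoms: Sequence[str], conclusion: str) -> None:
        """Binarize ``a1 ⊓ ... ⊓ an ⊑ conclusion``."""
        acc = atoms[0]
        for i, nxt in enumerate(atoms[1:], start=1):
            if i == len(atoms) - 1:
                self.nf2.append((acc, nxt, conclusion))
            else:
                aux = self._fresh(Conjunction(tuple(Named(a) for a in atoms[: i + 1])))
                self.nf2.append((acc, nxt, aux))
                acc = aux

    def _subclass(self, sub: ClassExpression, sup: ClassExpression) -> None:
        if isinstance(sup, Conjunction):
            for c in sup.conjuncts:
                self._subclass(sub, c)
            return
        if isinstance(sup, Existential):
            lhs = self._atom(sub)
            self.nf3.append((lhs, sup.role, self._atom(sup.filler)))
            return
        # sup is Named
        self.classes.add(sup.id)
        if isinstance(sub, Named):
            self.classes.add(sub.id)
            self.nf1.append((sub.id, sup.id))
        elif isinstance(sub, Existential):
            self.nf4.append((sub.role, self._atom(sub.filler), sup.id))
        else:
            atoms = [self._atom(c) for c in sub.conjuncts]
            self._chain_nf2(atoms, sup.id)

    def add_axioms(self, axioms: Iterable[Axiom]) -> "NormalizedAxiomSet":
        """Normalize and append; returns the *delta* as its own record."""
        mark = (
            len(self.nf1), len(self.nf2), len(self.nf3), len(self.nf4),
            len(self.role_inclusions), len(self.role_chains), set(self.classes),
        )
        for ax in axioms:
            validate_el([ax])
            if isinstance(ax, SubClassOf):
                self._subclass(ax.sub, ax.sup)
            elif isinstance(ax, EquivalentClasses):
                self._subclass(ax.a, ax.b)
                self._subclass(ax.b, ax.a)
            elif isinstance(ax, RoleInclusion):
                self.role_inclusions.append((ax.sub, ax.sup))
            else:  # pragma: no cover - validate_el rejects earlier
                raise ValueError(f"non-EL axiom: {ax!r}")
        n1, n2, n3, n4, ri, rc, old_classes = mark
        delta = NormalizedAxiomSet(
            nf1=self.nf1[n1:],
            nf2=self.nf2[n2:],
            nf3=self.nf3[n3:],
            nf4=self.nf4[n4:],
            role_inclusions=self.role_inclusions[ri:],
            role_chains=self.role_chains[rc:],
            classes=self.classes - old_classes,
        )
        return delta


def normalize(
    axioms: Iterable[Axiom],
    role_chains: Iterable[tuple[str, str, str]] = (),
) -> NormalizedAxiomSet:
    """Bring an axiom set into EL normal form (deterministic fresh names)."""
    norm = NormalizedAxiomSet()
    norm.role_chains.extend(role_chains)
    norm.add_axioms(axioms)
    return norm


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

@dataclass
class SubsumptionMap:
    """Saturated output: entailed subsumers per class plus role successors."""

    subsumers: dict[str, set[str]] = field(default_factory=dict)
    role_edges: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def entails(self, sub: str, sup: str) -> bool:
        if sup == TOP or sub == sup:
            return True
        return sup in self.subsumers.get(sub, ())

    def subsumers_of(self, cls: str) -> set[str]:
        return self.subsumers.get(cls, {cls, TOP})

    def subclasses_of(self, sup: str) -> set[str]:
        return {x for x, s in self.subsumers.items() if sup in s}

    def copy(self) -> "SubsumptionMap":
        return SubsumptionMap(
            subsumers={k: set(v) for k, v in self.subsumers.items()},
            role_edges={r: set(p) for r, p in self.role_edges.items()},
        )

    def state_hash(self) -> str:
        h = hashlib.sha256()
        for x in sorted(self.subsumers):
            h.update(x.encode())
            for a in sorted(self.subsumers[x]):
                h.update(b"\x00" + a.encode())
            h.update(b"\x01")
        for r in sorted(self.role_edges):
            h.update(r.encode())
            for pair in sorted(self.role_edges[r]):
                h.update(("|".join(pair)).encode())
        return h.hexdigest()


class _Saturator:
    def __init__(self, norm: NormalizedAxiomSet):
        self.norm = norm
        self.nf1_idx: dict[str, list[str]] = {}
        for a, b in norm.nf1:
            self.nf1_idx.setdefault(a, []).append(b)
        self.nf2_idx: dict[str, list[tuple[str, str]]] = {}
        for a1, a2, b in norm.nf2:
            self.nf2_idx.setdefault(a1, []).append((a2, b))
            if a1 != a2:
                self.nf2_idx.setdefault(a2, []).append((a1, b))
        self.nf3_idx: dict[str, list[tuple[str, str]]] = {}
        for a, r, b in norm.nf3:
            self.nf3_idx.setdefault(a, []).append((r, b))
        self.nf4_idx: dict[tuple[str, str], list[str]] = {}
        self.nf4_by_filler: dict[str, list[tuple[str, str]]] = {}
        for r, b, a in norm.nf4:
            self.nf4_idx.setdefault((r, b), []).append(a)
            self.nf4_by_filler.setdefault(b, []).append((r, a))
        self.role_sups = _role_closure(norm.role_inclusions)
        self.chain_left: dict[str, list[tuple[str, str]]] = {}
        self.chain_right: dict[str, list[tuple[str, str]]] = {}
        for r, s, t in norm.role_chains:
            self.chain_left.setdefault(r, []).append((s, t))
            self.chain_right.setdefault(s, []).append((r, t))

        self.S: dict[str, set[str]] = {}
        self.R: dict[str, set[tuple[str, str]]] = {}
        # preds[Y][r] = {X : (X,Y) ∈ R(r)}; succs mirrors it for chains
        self.preds: dict[str, dict[str, set[str]]] = {}
        self.succs: dict[str, dict[str, set[str]]] = {}
        self.queue: deque = deque()

    # -- state mutation -----------------------------------------------------

    def ensure_class(self, x: str) -> None:
        if x not in self.S:
            self.S[x] = {x, TOP}
            self.queue.append((x, x))
            self.queue.append((x, TOP))

    def add_sub(self, x: str, a: str) -> None:
        s = self.S[x]
        if a not in s:
            s.add(a)
            self.queue.append((x, a))

    def add_edge(self, r: str, x: str, y: str) -> None:
        pairs = self.R.setdefault(r, set())
        if (x, y) not in pairs:
            pairs.add((x, y))
            self.ensure_class(y)
            self.preds.setdefault(y, {}).setdefault(r, set()).add(x)
            if self.chain_left or self.chain_right:
                self.succs.setdefault(x, {}).setdefault(r, set()).add(y)
            self.queue.append((r, x, y))

    # -- seeding ------------------------------------------------------------

    def init_full(self) -> None:
        for x in sorted(self.norm.classes):
            self.ensure_class(x)

    def init_from(self, base: SubsumptionMap, delta: NormalizedAxiomSet) -> None:
        """Adopt an already-saturated state and seed only the delta axioms.

        Saturation is monotone, so re-deriving only the consequences that
        involve a new axiom (or a new class) reaches the same fixpoint as
        saturating from scratch.
        """
        self.S = {k: set(v) for k, v in base.subsumers.items()}
        self.R = {r: set(p) for r, p in base.role_edges.items()}
        for r, pairs in self.R.items():
            for x, y in pairs:
                self.preds.setdefault(y, {}).setdefault(r, set()).add(x)
                if self.chain_left or self.chain_right:
                    self.succs.setdefault(x, {}).setdefault(r, set()).add(y)
        for x in sorted(delta.classes):
            self.ensure_class(x)
        for a, b in delta.nf1:
            for x, s in self.S.items():
                if a in s:
                    self.add_sub(x, b)
        for a1, a2, b in delta.nf2:
            for x, s in self.S.items():
                if a1 in s and a2 in s:
                    self.add_sub(x, b)
        for a, r, b in delta.nf3:
            for x, s in list(self.S.items()):
                if a in s:
                    self.add_edge(r, x, b)
        for r, b, a in delta.nf4:
            for x, y in list(self.R.get(r, ())):
                if b in self.S.get(y, ()):
                    self.add_sub(x, a)
        if delta.role_inclusions:
            # a new inclusion can affect any role below it in the closure,
            # so re-propagate every stored edge through the (new) closure
            for q, pairs in list(self.R.items()):
                for sup in self.role_sups.get(q, ()):
                    for x, y in list(pairs):
                        self.add_edge(sup, x, y)
        for r, s, t in delta.role_chains:
            for x, y in list(self.R.get(r, ())):
                for z in self.succs.get(y, {}).get(s, ()):
                    self.add_edge(t, x, z)

    # -- fixpoint -----------------------------------------------------------

    def run(self) -> SubsumptionMap:
        queue = self.queue
        S = self.S
        nf1_idx, nf2_idx, nf3_idx = self.nf1_idx, self.nf2_idx, self.nf3_idx
        nf4_idx, nf4_by_filler = self.nf4_idx, self.nf4_by_filler
        add_sub, add_edge = self.add_sub, self.add_edge
        preds = self.preds
        while queue:
            item = queue.popleft()
            if len(item) == 2:  # subsumption fact X ⊑ A
                x, a = item
                for b in nf1_idx.get(a, ()):  # R1
                    add_sub(x, b)
                sx = S[x]
                for a2, b in nf2_idx.get(a, ()):  # R2
                    if a2 in sx:
                        add_sub(x, b)
                for r, b in nf3_idx.get(a, ()):  # R3
                    add_edge(r, x, b)
                # R4, driven from the Y⊑A side
                px = preds.get(x)
                if px:
                    for r, b in nf4_by_filler.get(a, ()):
                        for xp in px.get(r, ()):
                            add_sub(xp, b)
            else:  # role edge (X,Y) ∈ R(r)
                r, x, y = item
                for a in list(S[y]):  # R4, driven from the edge side
                    for b in nf4_idx.get((r, a), ()):
                        add_sub(x, b)
                for s in self.role_sups.get(r, ()):  # R5
                    add_edge(s, x, y)
                # R6 role chains (optional)
                if self.chain_left or self.chain_right:
                    for s, t in self.chain_left.get(r, ()):
                        for z in self.succs.get(y, {}).get(s, ()):
                            add_edge(t, x, z)
                    for rr, t in self.chain_right.get(r, ()):
                        for xp in preds.get(x, {}).get(rr, ()):
                            add_edge(t, xp, y)
        return SubsumptionMap(subsumers=S, role_edges=self.R)


def _role_closure(inclusions: Sequence[tuple[str, str]]) -> dict[str, set[str]]:
    """Strict super-roles of each role, transitively closed."""
    direct: dict[str, set[str]] = {}
    for r, s in inclusions:
        direct.setdefault(r, set()).add(s)
    closed: dict[str, set[str]] = {}
    for r in direct:  # BFS; cyclic inclusions (equivalent roles) are fine
        out: set[str] = set()
        stack = [r]
        while stack:
            for s in direct.get(stack.pop(), ()):
                if s not in out:
                    out.add(s)
                    stack.append(s)
        closed[r] = out
    return closed


def saturate(norm: NormalizedAxiomSet) -> SubsumptionMap:
    """Least fixpoint of the completion rules over a normalized axiom set."""
    sat = _Saturator(norm)
    sat.init_full()
    return sat.run()


def extend_saturation(
    base: SubsumptionMap,
    norm: NormalizedAxiomSet,
    extra_axioms: Iterable[Axiom],
) -> tuple[SubsumptionMap, NormalizedAxiomSet]:
    """Saturate ``base`` extended with new axioms, without touching ``base``.

    Returns the new map and the extended normalized set; the inputs are
    left unmodified (the query engine's statelessness contract).
    """
    combined = norm.copy()
    delta = combined.add_axioms(extra_axioms)
    sat = _Saturator(combined)
    sat.init_from(base, delta)
    return sat.run(), combined


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass
class Taxonomy:
    """Direct (transitively reduced) hierarchy over equivalence groups."""

    equivalence_groups: list[tuple[str, ...]] = field(default_factory=list)
    direct_super: dict[str, set[str]] = field(default_factory=dict)
    direct_sub: dict[str, set[str]] = field(default_factory=dict)
    representative: dict[str, str] = field(default_factory=dict)

    def ancestors(self, cls: str) -> set[str]:
        rep = self.representative[cls]
        out: set[str] = set()
        stack = [rep]
        while stack:
            for p in self.direct_super.get(stack.pop(), ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def render_tree(self, labels: Optional[Mapping[str, str]] = None) -> str:
        labels = labels or {}
        roots = sorted(
            rep for rep in self.representative.values()
            if not self.direct_super.get(rep)
        )
        lines: list[str] = []

        def walk(rep: str, depth: int, seen: frozenset) -> None:
            name = labels.get(rep, rep)
            group = next(g for g in self.equivalence_groups if g[0] == rep)
            extra = "" if len(group) == 1 else " [= " + ", ".join(group[1:]) + "]"
            lines.append("  " * depth + name + extra)
            for c in sorted(self.direct_sub.get(rep, ())):
                if c not in seen:
                    walk(c, depth + 1, seen | {rep})

        for rep in sorted(set(roots)):
            walk(rep, 0, frozenset())
        return "\n".join(lines)


def build_taxonomy(sub_map: SubsumptionMap, visible: set[str]) -> Taxonomy:
    """Merge mutually-subsuming classes and transitively reduce the DAG.

    ``visible`` excludes normalization fresh names (and anything else the
    caller wants hidden, e.g. ⊤).  Deterministic: groups keyed by their
    lexicographically smallest member.
    """
    visible = {v for v in visible if v != TOP}
    rep: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for x in sorted(visible):
        if x in rep:
            continue
        sx = sub_map.subsumers_of(x)
        members = sorted(
            y for y in sx
            if y in visible and x in sub_map.subsumers_of(y)
        )
        if x not in members:
            members = sorted(members + [x])
        r = members[0]
        for m in members:
            rep[m] = r
        groups[r] = members
    # group-level strict ancestors
    sup_sets: dict[str, set[str]] = {}
    for r in groups:
        sup_sets[r] = {
            rep[a]
            for a in sub_map.subsumers_of(r)
            if a in visible and rep[a] != r
        }
    direct_super: dict[str, set[str]] = {r: set() for r in groups}
    direct_sub: dict[str, set[str]] = {r: set() for r in groups}
    for r, sups in sup_sets.items():
        for a in sups:
            # a is direct unless reachable through another strict ancestor
            if not any(a in sup_sets[b] for b in sups if b != a):
                direct_super[r].add(a)
                direct_sub[a].add(r)
    return Taxonomy(
        equivalence_groups=sorted(tuple(g) for g in groups.values()),
        direct_super=direct_super,
        direct_sub=direct_sub,
        representative=rep,
    )
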