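"""Black-box justifications: minimal asserted-axiom sets behind an entailment.

The algorithm is reasoner-agnostic: the EL saturator is used purely as an
entailment oracle over candidate axiom subsets.  A signature-guided
expansion phase grows a candidate set until it entails the target, a
contraction phase then deletes axioms one at a time (in input order, so the
first justification is reproducible), and a hitting-set tree enumerates
further justifications on demand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .build import GoalOntology
from .model import Axiom, ClassExpression, EquivalentClasses, Named, axiom_signature
from .reasoner import normalize, saturate
from .query import QUERY_CLASS


@dataclass(frozen=True)
class Justification:
    target: tuple[str, str]
    axioms: frozenset[Axiom]


@dataclass
class ExplanationResult:
    entailed: bool
    justifications: list[Justification]


def _entails(axioms: Iterable[Axiom], sub: str, sup: str) -> bool:
    sat = saturate(normalize(axioms))
    return sat.entails(sub, sup)


def justify(
    goal: GoalOntology,
    sub: str,
    sup: str | ClassExpression,
    max_justifications: int = 1,
) -> ExplanationResult:
    """Compute minimal justifications for ``sub ⊑ sup``.

    ``sup`` may be a named class or an arbitrary (EL) query expression; in
    the latter case a definitional axiom for the query class is treated as
    fixed context rather than as part of any justification.  Returns an
    explicit "not entailed" result when the entailment does not hold.
    Each returned set entails the target on its own and is minimal: removing
    any single axiom breaks the entailment.
    """
    asserted = list(goal.axioms)
    fixed: list[Axiom] = []
    if isinstance(sup, str):
        sup_id = sup
    else:
        sup_id = QUERY_CLASS
        fixed = [EquivalentClasses(Named(QUERY_CLASS), sup)]

    def entails(subset: Iterable[Axiom]) -> bool:
        return _entails(list(subset) + fixed, sub, sup_id)

    if not entails(asserted):
        return ExplanationResult(entailed=False, justifications=[])

    def find_one(allowed: list[Axiom]) -> Optional[frozenset[Axiom]]:
        if not entails(allowed):
            return None
        grown = _expand_with(allowed, entails, sub)
        return _contract_with(grown, entails)

    first = find_one(asserted)
    assert first is not None
    results = [Justification((sub, sup_id), first)]
    if max_justifications == 1:
        return ExplanationResult(True, results)

    # Reiter-style hitting-set tree over the removal of single axioms
    seen = {first}
    stack: list[list[Axiom]] = [
        [a for a in asserted if a != ax] for ax in sorted(first, key=str)
    ]
    while stack and (max_justifications <= 0 or len(results) < max_justifications):
        allowed = stack.pop(0)
        j = find_one(allowed)
        if j is None:
            continue
        if j not in seen:
            seen.add(j)
            results.append(Justification((sub, sup_id), j))
        for ax in sorted(j, key=str):
            branch = [a for a in allowed if a != ax]
            stack.append(branch)
    return ExplanationResult(True, results)


def _expand_with(axioms: Sequence[Axiom], entails, sub: str) -> list[Axiom]:
    remaining = list(axioms)
    selected: list[Axiom] = []
    frontier = {sub}
    while remaining:
        pulled = [ax for ax in remaining if axiom_signature(ax) & frontier]
        if not pulled:
            break
        for ax in pulled:
            remaining.remove(ax)
            selected.append(ax)
            frontier |= axiom_signature(ax)
        if entails(selected):
            return selected
    return list(axioms)


def _contract_with(candidate: list[Axiom], entails) -> frozenset[Axiom]:
    kept = list(candidate)
    for ax in list(candidate):
        trial = [a for a in kept if a != ax]
        if entails(trial):
            kept = trial
    return frozenset(kept)
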