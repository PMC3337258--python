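"""Why is Mefv an answer to the five-conjunct query?

The justification is the minimal set of *asserted* axioms that entails the
subsumption.  None of the query's five terms is asserted on Mefv directly:
the gene is annotated to deeper terms, and the is_a edges plus the
singleton definitions carry the entailment upward.
"""

from goalont import build_goal, classify, justify, mefv_fixture
from goalont.fixtures import MEFV_QUERY
from goalont.query import parse_query, render_expression
from goalont.model import EquivalentClasses, RoleInclusion, SubClassOf

dep = classify(build_goal(mefv_fixture()).goal)
query = parse_query(MEFV_QUERY, dep.index)
result = justify(dep.goal, "GOAL:MGI_1859396", query)

(just,) = result.justifications
print(f"minimal justification: {len(just.axioms)} asserted axioms")
for ax in sorted(just.axioms, key=str):
    if isinstance(ax, SubClassOf):
        print(f"  {render_expression(dep.goal, ax.sub, dep.index)}"
              f"  SubClassOf  {render_expression(dep.goal, ax.sup, dep.index)}")
    elif isinstance(ax, EquivalentClasses):
        print(f"  {render_expression(dep.goal, ax.a, dep.index)}"
              f"  EquivalentTo  {render_expression(dep.goal, ax.b, dep.index)}")

# Removing any one axiom above breaks the entailment (verified internally
# by re-running the reasoner on the reduced set).
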