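"""Conjunctive multi-ontology querying on the Mefv micro-corpus.

Three genes are annotated across GO, a phenotype ontology and a disease
ontology.  Intersecting five singleton classes — spanning process,
function, component, phenotype and disease — narrows the answer to the one
gene (Mefv) whose deep annotations entail *all five* conjuncts.
"""

from goalont import build_goal, classify, mefv_fixture
from goalont.fixtures import MEFV_QUERY

dep = classify(build_goal(mefv_fixture()).goal)

conjuncts = [c.strip() for c in MEFV_QUERY.split(" and ")]
for k in range(1, len(conjuncts) + 1):
    query = " and ".join(conjuncts[:k])
    hits = dep.query(query)
    symbols = [dep.goal.label_of(g) for g in hits.sorted_subclasses(dep.goal)]
    print(f"{k} conjunct(s): {symbols}")

# Each added conjunct can only shrink the result set (queries are
# intersections); the full five-conjunct query returns exactly Mefv.
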