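"""Build the single-gene worked example and query it.

The Taar4 receptor gene carries three GO annotations.  Building turns it
into one primitive OWL class with three existential restrictions; every GO
term gets a singleton defined class ('X gene product'), so querying an
*ancestor* term's singleton still finds the gene by subsumption — the
query-expansion behaviour GO browsers implement by hand, obtained here from
the reasoner alone.
"""

from goalont import build_goal, classify, render_description, taar4_fixture

result = build_goal(taar4_fixture())
print(render_description(result.goal, "GOAL:MGI_2685072"))
print()

dep = classify(result.goal)
for query in (
    "'G-protein coupled receptor activity gene product'",  # annotated term
    "'receptor activity gene product'",                    # its parent
    "'membrane gene product'",                             # component parent
):
    hits = dep.query(query)
    symbols = [dep.goal.label_of(g) for g in hits.sorted_subclasses(dep.goal)]
    print(f"{query:55s} -> {symbols}")

# All three queries return Taar4: the gene is annotated to descendants of
# each queried term, and classification propagates it upward.
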