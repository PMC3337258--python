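"""Generate a seeded synthetic corpus, build, classify, and cross-check.

The generator emits OBO / GAF / report / mapping files plus a ground-truth
manifest computed by independent graph closure.  Running the real pipeline
over the generated files and comparing singleton-query answers to the
manifest is the package's end-to-end self-check.
"""

import random

from goalont import Named, SyntheticSpec, build_goal, classify, generate
from goalont.annotations import Aspect

spec = SyntheticSpec(
    seed=11,
    terms_per_aspect={
        Aspect.FUNCTION: 120, Aspect.PROCESS: 120, Aspect.COMPONENT: 60,
        Aspect.PHENOTYPE: 40, Aspect.DISEASE: 20,
    },
    n_genes=200,
)
fx = generate(spec)
result = build_goal(fx)
print("filter report:", result.filter_report)
print("build stats:  ", result.goal.stats)

dep = classify(result.goal)
rng = random.Random(0)
sample = rng.sample(sorted(fx.manifest["singleton_answers"]), 25)
mismatches = 0
for term in sample:
    got = dep.query(Named(result.goal.singleton_index[term]),
                    compute_equivalents=False).subclasses
    mismatches += got != set(fx.manifest["singleton_answers"][term])
print(f"sampled {len(sample)} singleton queries; mismatches vs ground truth: {mismatches}")
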