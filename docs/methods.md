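# Methods

## Representation

The package models annotations as OWL 2 EL axioms over three kinds of
classes:

* **Gene-product primitive classes.**  One named class per annotated gene,
  minted deterministically (`MGI:2685072 → GOAL:MGI_2685072`), asserted
  under the `Gene product` root and given one existential restriction
  `∃role.term` per surviving annotation.  Evidence codes ride along as
  axiom annotations and never influence entailment; duplicate
  (gene, role, term) restrictions are emitted once with merged codes.
* **Singleton defined classes.**  One per non-obsolete supporting-ontology
  term X: `'X gene product' ≡ GeneProduct ⊓ ∃ρ.X`.  These are the only
  defined classes in the build; conjunctive queries are intersections of
  them (or of arbitrary `role some filler` expressions in the same
  dialect).
* **Roles.**  Five annotation roles — `is_capable_of_function`,
  `is_capable_of_process` (both under `capable_of`), `is_located_in`,
  `is_associated_with_phenotype`, `is_associated_with_disease` — each
  ranging over one aspect's ontology.

Two representation choices were genuinely open:

* The `Gene product` root could itself carry five existential restrictions
  (one per role).  Asserting them logically would make *every* gene
  product an entailed subclass of every top-level singleton (e.g.
  'disease gene product'), collapsing exactly the queries those singletons
  exist for.  The root is therefore declared bare by default; the five
  restrictions are carried as documentation annotations, and an
  `assert_root_restrictions` flag emits them as axioms for anyone who
  wants the literal form.
* Genes whose annotations are all filtered away are omitted by default
  (`include_bare_genes` keeps them as bare subclasses of the root); a bare
  gene class answers no singleton query and mostly adds noise.

Phenotype and disease ontologies frequently lack a single root, so a
"convenient root" class is minted under the reserved `GOAL:` prefix and
every pre-existing root is placed beneath it; the operation is idempotent
and provably (tested by oracle) does not change entailments among
pre-existing classes.

## Ingestion and filters

OBO 1.2 parsing covers the semantic tag subset `id`, `name`, `namespace`,
`is_a`, `relationship`, `is_obsolete` (plus `[Typedef]` ids as role
names); other tags are ignored with a log line.  `GO_0004930` and
`GO:0004930` normalize to the same identifier.  Dangling `is_a` targets
are kept as declared-but-bare classes — GO slims routinely reference
out-of-file terms.  `is_a` cycles are accepted; the reasoner resolves them
into equivalence groups.  OBO relationship types beyond `is_a` are
translated as existential restrictions under a configurable
`relation_policy` (default: a role of the same name), since which types a
given corpus should retain is a per-corpus decision.

GAF 2.0 rows map DB+ID→gene, GO_ID→term, Evidence→evidence code,
Aspect F/P/C→function/process/component; `NOT`-qualified rows are dropped
(the representation has no negation), short rows are skipped and counted.
The genotype-disease report is column-mapped configuration-side because
its layout is release-dependent; OMIM→disease-term mapping is expected to
be partial and unmapped pairs are counted, not fatal.

Corpus filters: RIKEN cDNA clone genes (symbol ending `Rik` or name
containing `RIKEN cDNA` — the MGI naming conventions, both configurable),
annotations to the three GO namespace roots (`GO:0008150`, `GO:0003674`,
`GO:0005575`, configurable), unresolvable or obsolete terms, and an
optional evidence-code allowlist (default: keep all — electronic and
manual annotations are not distinguished at build time).  Exact
(gene, aspect, term) duplicates are merged with evidence union.  The
`FilterReport` satisfies
`surviving = input − riken − root_terms − unresolvable − evidence − merged_duplicates`,
checked on every run; filtering is idempotent.

## Reasoner

Classification uses the standard EL completion-rule calculus.  Axioms are
normalized to NF1–NF4 (`A⊑B`, `A1⊓A2⊑B`, `A⊑∃r.B`, `∃r.B⊑A`); complex
subexpressions are replaced by fresh names (`_fresh:n`, deterministic
counter order) with defining axioms in both directions — a conservative
extension, so entailments over the original signature are unchanged
(property-tested against an independent normalizer).  A FIFO worklist then
saturates rules R1–R5 (plus an optional R6 for role chains such as
`part_of ∘ part_of ⊑ part_of`, off by default — it is needed only for
part-of propagation experiments, not for the core build).  Each rule
application is O(1) amortized via indexes on the normal forms; runs are
bit-reproducible.  Saturation size is bounded by (#classes)², asserted in
tests.  No disjointness axioms exist in the build, so ⊥ is representable
but never derived.

The taxonomy step merges mutually-subsuming classes into equivalence
groups (keyed by lexicographically smallest member), hides normalization
names, and computes direct edges by transitive reduction.

## Queries

Queries are parsed from a Manchester-syntax subset: quoted labels (straight
or typographic quotes) or CURIEs as atoms, infix `and`, `role some filler`,
parentheses; label matching is case-insensitive and ambiguity is reported
with all candidates.  Answering classifies a fresh defined class `Q ≡ q`
in a *scratch overlay*: the deployed saturation is copied copy-on-write and
extended by incremental re-saturation seeded only from the new axioms
(monotonicity of the calculus guarantees the same fixpoint as saturating
from scratch, which the oracle tests confirm).  The deployed state hash is
identical before and after any query.  Purely-named conjunctions take a
fast path intersecting precomputed subsumer sets.  Results are restricted
to gene-product classes and ordered by (symbol, id).

Two laws follow from the semantics and are enforced by tests: querying a
singleton `S_X` equals querying its expansion `GeneProduct ⊓ ∃ρ.X`, and a
conjunction's answer is the intersection of its conjuncts' answers (hence
anti-tone in the number of conjuncts).

## Explanations

Justifications are computed black-box, reusing the saturator purely as an
entailment oracle: signature-guided expansion from the subclass grows a
candidate set until it entails the target, contraction deletes axioms one
at a time in input order (so the first justification is reproducible), and
a hitting-set tree enumerates alternatives on demand
(`max_justifications=1` by default, `0` = all).  Every returned set is
re-verified to entail the target and to be minimal.  On ontologies of ≤12
axioms the enumeration is tested to coincide exactly with brute-force
enumeration of all minimal entailing subsets.

## Synthetic data

The generator emits the exact external dialects the ingest code consumes
(OBO 1.2, 17-column GAF 2.0, a column-mapped TSV report, a two-column OMIM
map) from a seeded `SyntheticSpec`; identical spec + seed gives
byte-identical files.  Term DAGs are built level-wise (acyclic by
construction) with a configurable multi-parent probability; GO aspects
root at the three real namespace roots, phenotype/disease ontologies get
two roots each so the convenient-root step always has work.  Knobs cover
RIKEN-gene fraction, root-annotation probability and obsolete-term
probability so each filter can be exercised.

The ground-truth manifest (ancestor closures; expected singleton-query
answers = genes annotated to a term or any descendant, in the matching
aspect) is computed by networkx graph closure on the generated DAG — code
deliberately disjoint from the reasoner, so pipeline-vs-manifest agreement
is a genuine end-to-end check.  What the generator does **not** emulate:
realistic term-name text, realistic annotation-depth distributions, GAF
qualifier variety beyond `NOT`, and cross-aspect dependencies between a
gene's annotations; passing tests therefore demonstrate correctness of the
machinery, not statistical realism of any corpus.

Two packaged micro-corpora pin the worked examples: a single receptor gene
(Taar4) with three GO annotations and hand-chosen named ancestors, and a
three-gene corpus in which only Mefv satisfies a five-conjunct
cross-ontology query, and only via annotations to strictly deeper terms —
so its justification necessarily contains hierarchy edges.

## Problem sizes and numerics

The test suite runs oracle comparisons on 100 random EL ontologies
(≤30 classes, ≤60 axioms), exhaustive justification enumeration on
≤12-axiom ontologies, and one end-to-end scale run at 20,000 terms /
5,000 genes (~45,000 classes, ~75,000 axioms), which classifies in well
under a minute and is spot-checked against the manifest on a 200-term
sample.  The acceptance script uses a 900-term / 400-gene synthetic corpus
and checks *every* singleton query.  There is no floating-point arithmetic
anywhere in the core: all results are exact set computations, and all
orderings (worklist, fresh names, result rows) are fixed so outputs are
reproducible to the byte.

## Known limitations

* Only the EL fragment: no disjunction, complement, universal restriction,
  cardinality or nominals, in queries or axioms.
* OBO `intersection_of` cross-products and GO annotation extensions
  (e.g. `occurs_in` couplings of process and location) are not translated;
  the generic `relationship` → existential translation and the optional
  role-chain rule are the extension points.
* Corpus-scale figures depend on the database snapshot ingested; the
  packaged fixtures reproduce the logical patterns, not any historical
  corpus counts.
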