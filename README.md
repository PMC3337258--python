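# goalont — logic-based querying of gene-product annotations

`goalont` turns flat gene-product annotations — GO term assignments from a
GAF file, phenotype and disease associations from curation reports — into a
description-logic class hierarchy that can be *queried across ontologies at
once*, with automated reasoning doing the query expansion that tools like
AmiGO implement by hand, and with minimal-axiom explanations for every
answer.

It is aimed at bio-ontology engineers and computational biologists who want
questions like *"which genes are annotated with an inflammatory-response
process, an ion-binding function, an organelle location, an
abnormal-cytokine-secretion phenotype, **and** an immune-system disease?"*
answered by subsumption reasoning rather than by joining five tables.

## The representation

Three supporting ontologies (GO, a mammalian phenotype ontology, a human
disease ontology, all in OBO 1.2 format) are translated into OWL 2 EL
axioms.  Each annotated gene product *g* becomes a **primitive class**:

```
g  ⊑  GeneProduct
g  ⊑  ∃ is_capable_of_function . F      (one per annotation, with the
g  ⊑  ∃ is_capable_of_process  . P       evidence code carried as an
g  ⊑  ∃ is_located_in          . C       axiom annotation)
g  ⊑  ∃ is_associated_with_phenotype . M
g  ⊑  ∃ is_associated_with_disease   . D
```

and each supporting-ontology term *X* gets one **singleton defined class**

```
'X gene product'  ≡  GeneProduct ⊓ ∃ ρ(X) . X
```

where ρ maps the term's aspect to the matching role.  After one deploy-time
classification, any conjunction of singleton classes is a query, and the
reasoner returns every gene product entailed below it — including genes
annotated only to *descendants* of the queried terms.  Because everything
stays inside the EL fragment (conjunction and existential restriction
only), classification is polynomial and interactive-speed: the bundled
completion-rule reasoner saturates a ~45,000-class build in well under a
minute on one CPU.

Modules: OBO parsing (`goalont.obo`), GAF/report ingestion and corpus
filters (`goalont.annotations`), axiom generation (`goalont.build`,
`goalont.pipeline`), the EL reasoner (`goalont.reasoner`), Manchester-style
conjunctive queries (`goalont.query`), black-box justifications
(`goalont.explain`), and seeded fixture/corpus generation
(`goalont.fixtures`).

## Worked example

`examples/taar4_walkthrough.py` builds the packaged single-gene corpus (the
mouse trace-amine receptor gene Taar4 with three GO annotations) and
queries it:

```
Class: GOAL:MGI_2685072
  Label: 'Taar4'
  Definition: 'trace amine-associated receptor 4'
  SubClassOf: 'Gene product'
  SubClassOf: is_located_in some 'integral to membrane'  [evidenceCode=IEA]
  SubClassOf: is_capable_of_function some 'G-protein coupled receptor activity'  [evidenceCode=IEA]
  SubClassOf: is_capable_of_process some 'signal transduction'  [evidenceCode=IEA]

'G-protein coupled receptor activity gene product'      -> ['Taar4']
'receptor activity gene product'                        -> ['Taar4']
'membrane gene product'                                 -> ['Taar4']
```

The last two lines are the point: Taar4 is *not* annotated to 'receptor
activity' or 'membrane', but classification places it under those terms'
singleton classes because its annotations are to their descendants.

`examples/conjunctive_query.py` runs a five-conjunct cross-ontology query
on a three-gene corpus; each added conjunct narrows the answer
(`['Mefv', 'Tnf']` → … → `['Mefv']`), and `examples/explain_entailment.py`
prints the 17-axiom minimal justification showing that the answer rests
entirely on deep annotations propagated up the hierarchies.

## Command line

```
goal fixture mefv --out-dir corpus/
goal build --go-obo corpus/go.obo --mp-obo corpus/mp.obo --doid-obo corpus/doid.obo \
           --gaf corpus/annotations.gaf --geno-report corpus/geno_disease.tsv \
           --omim-map corpus/omim_map.tsv --out goal.json
goal query goal.json --dl "'inflammatory response gene product' and 'immune system disease gene product'"
goal explain goal.json --sub GOAL:MGI_1859396 --sup "'immune system disease gene product'"
```

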