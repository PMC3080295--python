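# signet

Gene-signature discovery by the predictive integration of Gene Ontology
functional similarity and gene co-expression.

## The problem

Small two-condition expression studies (for example, a treated-vs-untreated
progenitor-cell cohort profiled on microarrays with six samples per arm) are
too underpowered for purely data-driven biomarker discovery. `signet`
implements an integrated k-nearest-neighbour strategy that anchors the search
on *query genes* — either expert-chosen candidates or genes selected by a
SAM-style differential-expression screen — and expands each query into a
neighbourhood of functionally related, co-expressed genes. The query plus its
neighbourhood forms a *biosignature* whose ability to separate the two
conditions is then measured with a linear max-margin classifier.

It is intended for computational biologists working with gene-level
expression matrices, GO annotations (GAF) and ontology structure (OBO), and
optionally a protein–protein interaction edge list as a baseline.

## The method

For a query gene *g\_i* and a candidate *g\_j*, two unit-interval scores are
fused:

* **GO-based similarity** `SIM(g_i, g_j)`: Lin's information-content measure
  between GO terms, `sim(t1, t2) = 2·IC(MICA) / (IC(t1) + IC(t2))` with
  `IC(t) = −log p(t)` and MICA the most informative common ancestor,
  aggregated over the genes' annotation sets `A_i`, `A_j` by the maximum
  inter-set term similarity (a best-match-average variant is available).
  Annotation probabilities `p(t)` count distinct genes annotated to `t` or
  any descendant; IEA-coded (electronically inferred) annotations are
  excluded by default.
* **Co-expression** `|r|`: the absolute Pearson correlation of the two genes'
  standardized expression profiles, mapping [−1, 1] onto [0, 1].

The fused score is their mean, `s = (SIM + |r|) / 2`, and the k top-ranked
candidates form the query's neighbourhood (k = 1..20 is the supported sweep
range). Biosignatures are evaluated as treated-vs-untreated classifiers under
two encodings — one feature per gene, or one feature per query holding the
mean expression of the query and its neighbours — with a linear SVM
(C = 100), leave-one-out cross-validation, and the area under the ROC curve
computed from the pooled held-out decision scores.

A synthetic-cohort generator with planted co-expressed, functionally
coherent, treatment-responsive modules makes the whole pipeline testable
without any external downloads.

## Worked example

```python
import signet as sg

# two planted modules in a 6-vs-6 cohort of 500 genes
config = sg.SimulationConfig(
    n_genes=500, modules=sg.default_modules(n_modules=2, module_size=5), seed=42
)
matrix = sg.generate_expression(config)
graph, annotations = sg.generate_ontology(config)

model = sg.build_ontology_model(graph, annotations, "BP")
profiles = sg.profiles_from_annotations(annotations, "BP")
knn = sg.IntegratedKNN(ontology_model=model, profiles=profiles, k=5).fit(matrix)

queries = [m.query for m in config.modules]
neighborhoods = knn.kneighbors(queries, k=5)
for q, nb in neighborhoods.items():
    print(q, "->", [f"{g} ({s:.2f})" for g, s in nb.members])

signatures = [
    sg.Biosignature("queries-only", queries, {}, "individual_gene"),
    sg.Biosignature("queries+5NN", queries, neighborhoods, "integrated_neighborhood"),
]
print(sg.compare_models(signatures, knn.matrix_).to_string(index=False))
```

Output:

```
QUERY1 -> ['MOD1_M4 (0.98)', 'MOD1_M2 (0.98)', 'MOD1_M1 (0.98)', 'MOD1_M3 (0.98)', 'MOD1_M5 (0.96)']
QUERY2 -> ['MOD2_M4 (0.99)', 'MOD2_M1 (0.99)', 'MOD2_M2 (0.97)', 'MOD2_M3 (0.96)', 'MOD2_M5 (0.94)']
        name          representation  n_features      auc
queries-only         individual_gene           2 0.944444
 queries+5NN integrated_neighborhood           2 0.944444
```

Each query's neighbourhood recovers exactly its planted module members, with
fused scores near 1 (shared deep GO term plus strong co-expression). Both
signature encodings then classify the 12 samples with a LOOCV AUC of 0.94 —
in this cohort the planted treatment effect sits on the queries too, so the
query-only model is already strong; the neighbourhood encoding shows its
advantage when the module rather than the query carries the response (see
`docs/methods.md`).

The same pipeline is scriptable from the shell:

```sh
signet simulate --seed 3 --out cohort/
signet dequery --expr cohort/expression.tsv --labels cohort/labels.tsv --out queries.txt
signet report --queries cohort/queries.txt --expr cohort/expression.tsv \
    --labels cohort/labels.tsv --obo cohort/ontology.obo --gaf cohort/annotations.gaf \
    --edges cohort/ppi_edges.tsv --k 15 --out report/
```

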