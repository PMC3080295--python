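# Methods

This note documents the models, parameters, numerical choices and known
limitations of the `signet` pipeline.

## GO-based functional similarity

An ontology namespace (BP by default; MF and CC supported) is modelled as a
DAG with child-to-parent `is_a` and `part_of` edges. For a corpus of gene
annotations, the annotation probability of a term is

    p(t) = |genes annotated to t or any descendant of t| / |genes annotated in the namespace|

and its information content is `IC(t) = −ln p(t)`. Counts propagate over both
edge types; the logarithm base is natural (any base cancels in Lin's ratio
and affects only raw IC values). Terms with no annotated genes carry no IC
and cannot be scored.

Term–term similarity is Lin's measure, `2·IC(MICA) / (IC(t1) + IC(t2))`,
where the MICA is the common ancestor with maximal IC (ties broken by
ascending term id — the tie-break never changes the similarity value, only
which ancestor is reported). A pair whose terms both have `IC = 0` (e.g.
root against root) is assigned similarity 0: the shared information content
is zero, so declaring identity would be misleading.

Gene-level similarity aggregates term similarities over the two genes'
direct annotation sets. The default is the highest between-term similarity
over all inter-set pairs (`max_pair`); a best-match-average variant
(symmetrised mean of each term's best match) is available because the two
schemes are the common choices for set aggregation and they bracket most
others. Genes with no non-IEA annotation in the namespace are undefined
(NaN) and drop out of candidate pools, mirroring the practical situation
where sparse MF annotation degrades MF-based models.

## Integrated kNN retrieval

Expression rows are standardized to mean 0, sample standard deviation 1
across all samples (treated and untreated pooled — pooling maximizes the
effective sample size at n = 12 and the correlation step does not condition
on treatment). Zero-variance rows are excluded with a warning. Absolute
Pearson correlation maps co-expression onto [0, 1]; since Lin-based SIM is
already unit-interval by construction, no further rescaling is applied
before fusion. The fused score is the equal-weight mean `(SIM + |r|) / 2`;
no alternative weighting is implemented.

Candidates are ranked by fused score with ties broken by ascending gene id,
which makes retrieval deterministic across platforms; the k-neighbourhood is
exactly the k-prefix of the full descending sort, so raising k only appends
members. The query is never its own neighbour; other query genes remain
eligible neighbours unless `exclude_queries` is set. A PPI baseline
(`ppi_neighbors`) returns direct interaction partners, and
`neighborhood_overlap` compares two methods' neighbourhoods per query with a
two-sided one-sample t-test of the shared counts against mean 0 (all-equal
counts degenerate the t statistic; the p-value is then 1 when the mean is 0
and 0 otherwise).

## Biosignature classification

Two encodings feed the classifier: one standardized expression column per
distinct signature gene (`individual_gene`), or one column per query holding
the per-sample mean of the query and its neighbourhood members
(`integrated_neighborhood`). Classification uses a linear SVM with
complexity constant C = 100 and no class weighting; any max-margin linear
solver meeting that configuration is acceptable (the implementation uses
scikit-learn's libsvm backend). Evaluation is leave-one-out
cross-validation; each held-out sample contributes its signed distance to
the separating hyperplane, and the AUC over the pooled held-out scores is
computed with the pairwise-concordance (Mann–Whitney) formula
`(concordant + 0.5·ties) / (n_pos·n_neg)`, which the tests cross-check
against a threshold-sweep trapezoid to 1e-9. Standardization is a single
global pre-processing step, not re-fit per fold; with 12 samples the
resulting leakage is small but real, and is accepted to keep the pipeline
order fixed.

A caveat that matters at this scale: the pooled-score LOOCV AUC is
pessimistically biased under the null when the feature count is very small
(measured here: mean null AUC ≈ 0.25 with one noise feature and ≈ 0.40 with
three, at 6-vs-6 samples), because removing a sample makes its class the
training minority and shifts its held-out score the wrong way. At the
six-feature scale of a six-query neighbourhood signature the bias is
negligible (mean null AUC within one standard error of 0.5 over hundreds of
permutations), so null-calibration checks are run at that design scale.
Comparisons between two models evaluated on the same folds (neighbourhood vs
query-only) are paired and unaffected by the common bias component.

## Differential-expression query selection

The moderated statistic is `d = (mean_t − mean_c) / (s + s0)` with `s` the
pooled standard error of the mean difference. The fudge factor `s0` defaults
to the median of the per-gene pooled standard errors — a deliberate
simplification of the original percentile-tuning search, which is out of
scope; `s0` is user-settable. False discovery rates use a label-permutation
null: `q(g)` is the median across permutations of the count of null |d|
values exceeding |d(g)|, divided by the observed exceedance count, clipped
to [0, 1], and monotonized by a cumulative minimum from the
least-significant end so q never decreases with increasing |d|. When the
requested number of permutations exceeds the number of distinct label
assignments, the assignment set is enumerated exhaustively (the result is
then seed-independent). Fold change is the anti-log ratio of group means,
`2^(mean_t − mean_c)`, on the assumption of log2-scale intensities; the
selection filter is two-sided (≥ τ or ≤ 1/τ, default τ = 1.7) combined with
a q ceiling (default 0.01).

A known property of this permutation scheme: genes carrying genuine signal
contaminate the null in strongly-overlapping label permutations, so the
q-value of the lowest-ranked true positives saturates near
(median null count)/rank rather than 0. Recovery of planted signals is
therefore assessed as a rate over replicates, not as an exact set match.

## Synthetic cohorts

The generator emulates a small two-condition microarray study. Defaults: 6
treated vs 6 untreated samples, 500 genes, unit noise scale, values offset
to a log2-intensity baseline of 8. Each planted module (query + members)
follows a latent-factor model `sqrt(ρ)·f + sqrt(1−ρ)·ε` with a shared
per-module factor, giving unit marginal variance and expected pairwise
correlation exactly ρ (default 0.8); treated samples add δ standard
deviations (default 2) to module genes. The factor model was chosen over an
explicit covariance matrix for O(n) generation and exact control of the
expected correlation. A module's query can be given its own treatment
effect (`query_delta`), e.g. 0 to model the empirically important case
where the neighbourhood, not the query gene, carries the response — this is
the regime in which the integrated-neighbourhood encoding demonstrably
dominates the query-only model. Because the factor is shared, neighbourhood
averaging removes only the idiosyncratic noise share `(1−ρ)/(k+1)`; when
the query itself responds as strongly as its members, the two encodings are
nearly equivalent by construction.

The companion ontology generator builds a balanced term tree (default 40
terms, branching 3) and annotates each module's genes to a dedicated deep
leaf term, placing different modules on different depth-1 branches so that
modules share information only through the root; background genes are
annotated to shallow terms, and a small fraction receives additional
IEA-coded records to exercise evidence filtering. The PPI generator plants
query–member edges at a configurable fidelity, rewiring the remainder
randomly.

What the generator does not emulate: probe-level artefacts (dye bias,
spatial effects), heavy-tailed intensity noise, annotation depth
heterogeneity of real GO, or correlated background modules. Passing tests
therefore demonstrate the correctness and calibration of the machinery on
the stated generative model, not performance on any particular real cohort.

## Problem sizes used in checks

Automated checks run at the cohort scale the generator defaults describe:
500 genes (300 for the paired model-comparison replicates), 6-vs-6 samples,
modules of 15 members at k = 15, 50 replicates for recovery, 100 for the
paired AUC comparison, 200 label permutations for null AUC calibration and
500 for the permutation-FDR null.

## Known limitations

* Neighbourhood retrieval scores candidates per query in a Python loop;
  at genome scale (> 20k genes, thousands of queries) the term-pair cache
  helps but a vectorised SIM kernel would be needed.
* The SAM simplification (median-SE `s0`, symmetric cutoffs) will not
  bit-match the original SAM software.
* Cross-namespace fusion of BP and MF similarities is deliberately not
  provided; namespaces are analysed independently.
* LOOCV AUC at one or two features carries the pessimistic null bias
  described above; prefer signatures with several queries, or interpret
  single-feature AUCs against a permutation null rather than against 0.5.
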