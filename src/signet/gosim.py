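"""GO-based gene functional similarity.

Builds an annotation-probability model over one ontology namespace, computes
Lin's information-content term similarity

    sim(t1, t2) = 2 * IC(MICA) / (IC(t1) + IC(t2)),

where the MICA is the common ancestor (over is_a/part_of paths) with maximal
information content IC(t) = -log p(t), and aggregates term similarities into
a gene-level similarity SIM(g_i, g_j) over the genes' annotation sets — by
the maximum over all inter-set term pairs (default) or by the best-match
average variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import AnnotationTable, DataError, namespace_subgraph

#: Sentinel for gene pairs whose similarity is undefined (empty profile).
UNDEFINED = float("nan")

AGGREGATIONS = ("max_pair", "best_match_average")


@dataclass
class GeneFunctionalProfile:
    """A gene's direct (evidence-filtered) term annotations in one namespace."""

    gene_id: str
    namespace: str
    term_set: frozenset

    def __bool__(self) -> bool:
        return bool(self.term_set)


@dataclass
class OntologyModel:
    """Per-namespace ontology DAG with annotation probabilities and IC.

    ``dag`` has child-to-parent edges; ``p(t)`` is the fraction of annotated
    genes in the namespace that are annotated to ``t`` or any of its
    descendants; ``IC(t) = -ln p(t)``. Terms with no annotated genes in the
    corpus carry no IC and are unscoreable.
    """

    namespace: str
    dag: nx.MultiDiGraph
    probability: dict = field(default_factory=dict)
    ic: dict = field(default_factory=dict)
    n_genes: int = 0
    _ancestor_cache: dict = field(default_factory=dict, repr=False)

    def ancestors(self, term: str) -> frozenset:
        """All ancestors of ``term`` including itself (is_a/part_of closure)."""
        cached = self._ancestor_cache.get(term)
        if cached is None:
            if term not in self.dag:
                raise DataError(f"unknown term {term!r} in {self.namespace}")
            cached = frozenset(nx.descendants(self.dag, term)) | {term}
            self._ancestor_cache[term] = cached
        return cached

    def scoreable(self, term: str) -> bool:
        return term in self.ic


def build_ontology_model(
    ontology_graph: nx.MultiDiGraph,
    annotations: AnnotationTable,
    namespace: str,
) -> OntologyModel:
    """Estimate per-term annotation probability and IC for one namespace.

    ``p(t)`` counts distinct genes annotated to ``t`` or any descendant,
    divided by the number of genes annotated anywhere in the namespace;
    counts propagate over both is_a and part_of edges.
    """
    dag = namespace_subgraph(ontology_graph, namespace)
    ann = annotations.for_namespace(namespace).records
    ann = ann[ann["term_id"].isin(dag.nodes)]
    if ann.empty:
        raise DataError(f"no annotations fall in namespace {namespace}")
    model = OntologyModel(namespace=namespace, dag=dag)
    gene_count: dict[str, set] = {}
    for gene, term in zip(ann["gene_id"], ann["term_id"]):
        for anc in model.ancestors(term):
            gene_count.setdefault(anc, set()).add(gene)
    total = len(set(ann["gene_id"]))
    model.n_genes = total
    for term, genes in gene_count.items():
        p = len(genes) / total
        model.probability[term] = p
        model.ic[term] = -math.log(p)
    return model


def lin_similarity(t1: str, t2: str, model: OntologyModel) -> float:
    """Lin term-term similarity in [0, 1].

    Returns 0 when the only shared information is the root (IC = 0) or when
    both terms themselves carry zero information content.
    """
    for t in (t1, t2):
        if not model.scoreable(t):
            raise DataError(
                f"term {t!r} is unscoreable in namespace {model.namespace}"
            )
    ic1, ic2 = model.ic[t1], model.ic[t2]
    if ic1 + ic2 == 0.0:
        return 0.0  # e.g. root vs root: no shared information content
    common = model.ancestors(t1) & model.ancestors(t2)
    mica_ic = max((model.ic[t] for t in common if model.scoreable(t)), default=0.0)
    return min(1.0, 2.0 * mica_ic / (ic1 + ic2))


def mica(t1: str, t2: str, model: OntologyModel) -> str | None:
    """Most informative common ancestor; ties broken by ascending term id."""
    common = sorted(model.ancestors(t1) & model.ancestors(t2))
    best, best_ic = None, -1.0
    for t in common:
        ic = model.ic.get(t)
        if ic is not None and ic > best_ic:
            best, best_ic = t, ic
    return best


def profiles_from_annotations(
    annotations: AnnotationTable, namespace: str
) -> dict[str, GeneFunctionalProfile]:
    """One functional profile per gene with >= 1 annotation in the namespace."""
    ann = annotations.for_namespace(namespace).records
    out: dict[str, GeneFunctionalProfile] = {}
    for gene, sub in ann.groupby("gene_id"):
        out[str(gene)] = GeneFunctionalProfile(
            gene_id=str(gene),
            namespace=namespace,
            term_set=frozenset(sub["term_id"]),
        )
    return out


def gene_similarity(
    profile_i: GeneFunctionalProfile,
    profile_j: GeneFunctionalProfile,
    model: OntologyModel,
    aggregation: str = "max_pair",
    _term_sim_cache: dict | None = None,
) -> float:
    """Gene-level SIM(g_i, g_j) in [0, 1], symmetric in its arguments.

    ``max_pair`` takes the highest between-term similarity over all
    inter-set pairs; ``best_match_average`` averages each term's best match
    in the other set, symmetrised over both directions. Terms not scoreable
    in the model are ignored; if either gene retains no scoreable term the
    similarity is undefined (NaN) and the gene drops out of candidate pools.
    """
    if aggregation not in AGGREGATIONS:
        raise DataError(f"aggregation must be one of {AGGREGATIONS}")
    if not (profile_i.namespace == profile_j.namespace == model.namespace):
        raise DataError("profiles and model must share a namespace")
    terms_i = sorted(t for t in profile_i.term_set if model.scoreable(t))
    terms_j = sorted(t for t in profile_j.term_set if model.scoreable(t))
    if not terms_i or not terms_j:
        return UNDEFINED

    cache = _term_sim_cache if _term_sim_cache is not None else {}

    def sim(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        val = cache.get(key)
        if val is None:
            val = lin_similarity(a, b, model)
            cache[key] = val
        return val

    if aggregation == "max_pair":
        return max(sim(a, b) for a in terms_i for b in terms_j)
    rows = [max(sim(a, b) for b in terms_j) for a in terms_i]
    cols = [max(sim(a, b) for a in terms_i) for b in terms_j]
    return (sum(rows) + sum(cols)) / (len(terms_i) + len(terms_j))


def pairwise_gene_similarity(
    queries,
    candidates,
    profiles: dict[str, GeneFunctionalProfile],
    model: OntologyModel,
    aggregation: str = "max_pair",
) -> pd.DataFrame:
    """SIM for every (query, candidate) pair; genes without a profile get NaN.

    Returns a DataFrame indexed by query with candidate columns.
    """
    cache: dict = {}
    out = np.full((len(list(queries)), len(list(candidates))), np.nan)
    queries, candidates = list(queries), list(candidates)
    for i, q in enumerate(queries):
        pq = profiles.get(q)
        if not pq:
            continue
        for j, c in enumerate(candidates):
            pc = profiles.get(c)
            if not pc:
                continue
            out[i, j] = gene_similarity(
                pq, pc, model, aggregation, _term_sim_cache=cache
            )
    return pd.DataFrame(out, index=queries, columns=candidates)


def write_similarity_table(sim: pd.DataFrame, path) -> None:
    """Write pairwise similarities as a three-column TSV (gene_i, gene_j, SIM)."""
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tSIM\n")
        for gi in sim.index:
            for gj in sim.columns:
                v = sim.at[gi, gj]
                if not np.isnan(v):
                    fh.write(f"{gi}\t{gj}\t{v:.6g}\n")
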