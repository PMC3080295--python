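"""Synthetic two-condition microarray cohorts with planted gene modules.

The generator emulates a small treated-vs-untreated expression study
(default 6 vs 6 samples, a few hundred genes) in which each planted module —
a query gene plus its member genes — is simultaneously

* co-expressed: module genes load on a shared latent factor with loading
  sqrt(rho), so the expected pairwise Pearson correlation within a module
  is rho;
* functionally coherent: module genes share a deep (high-IC) ontology term,
  while background genes are annotated to shallow terms near the root;
* treatment-responsive: treated samples receive an additive shift of
  delta standard deviations on module genes.

A companion interaction-network generator plants query-member edges with a
configurable fidelity, the remainder being random — a controllable baseline
for neighbourhood-overlap comparisons. All generators take explicit seeds
and never touch global random state; outputs can be written in the exact
text formats the loaders in :mod:`signet.data_io` read back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import (
    AnnotationTable,
    DataError,
    ExpressionMatrix,
    InteractionNetwork,
    write_expression,
    write_labels,
)


@dataclass
class ModuleSpec:
    """One planted module: a query gene, its members, and effect sizes."""

    query: str
    members: list
    rho: float = 0.8  # within-module correlation, in [0, 1)
    delta: float = 2.0  # treatment effect in sd units
    #: treatment effect on the query itself; None means same as members.
    #: Setting 0 models a query whose neighbourhood, not the query gene,
    #: carries the treatment response.
    query_delta: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise DataError("module rho must lie in [0, 1)")
        if self.query in self.members:
            raise DataError("query gene cannot be listed among members")

    @property
    def genes(self) -> list[str]:
        return [self.query, *self.members]


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic cohort."""

    n_genes: int = 500
    n_treated: int = 6
    n_control: int = 6
    modules: list = field(default_factory=list)
    annotation_depth: int = 4
    noise_sd: float = 1.0
    baseline: float = 8.0  # log2-intensity offset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treated < 2 or self.n_control < 2:
            raise DataError("each condition needs >= 2 samples")
        seen: set[str] = set()
        for m in self.modules:
            overlap = seen & set(m.genes)
            if overlap:
                raise DataError(
                    f"module gene(s) {sorted(overlap)} appear in multiple modules"
                )
            seen |= set(m.genes)
        if len(seen) > self.n_genes:
            raise DataError("module genes exceed n_genes")

    @property
    def module_genes(self) -> list[str]:
        return [g for m in self.modules for g in m.genes]

    def gene_ids(self) -> list[str]:
        """Module genes first, then background genes GENE0001..."""
        named = self.module_genes
        n_noise = self.n_genes - len(named)
        return named + [f"GENE{i:04d}" for i in range(1, n_noise + 1)]

    def sample_ids(self) -> list[str]:
        return [f"T{i+1}" for i in range(self.n_treated)] + [
            f"C{i+1}" for i in range(self.n_control)
        ]

    def label_spec(self) -> dict:
        return {
            s: ("treated" if s.startswith("T") else "untreated")
            for s in self.sample_ids()
        }


def default_modules(n_modules: int = 2, module_size: int = 5) -> list[ModuleSpec]:
    """Convenience module layout: QUERY1..n with MODi_Mj members."""
    return [
        ModuleSpec(
            query=f"QUERY{i+1}",
            members=[f"MOD{i+1}_M{j+1}" for j in range(module_size)],
        )
        for i in range(n_modules)
    ]


def generate_ontology(
    config: SimulationConfig,
    n_terms: int = 40,
    branching: int = 3,
    seed: int | None = None,
) -> tuple[nx.MultiDiGraph, AnnotationTable]:
    """A rooted term DAG plus annotations tying modules to deep terms.

    The DAG is a balanced tree of the given branching factor (truncated at
    ``n_terms`` nodes) with edges pointing child -> parent. Each module's
    genes are all annotated to a dedicated deep leaf term, giving them high
    pairwise similarity; background genes are annotated to shallow terms
    (children of the root), which share information only through the root.
    Every gene receives at least one experimentally-coded (non-IEA)
    annotation; a few extra IEA records exercise evidence filtering.
    """
    if n_terms < 3:
        raise DataError("n_terms must be >= 3")
    if branching < 1:
        raise DataError("branching must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    root = terms[0]
    graph = nx.MultiDiGraph()
    depth = {root: 0}
    graph.add_node(root, name="root", namespace="biological_process")
    for i, t in enumerate(terms[1:], start=1):
        parent = terms[(i - 1) // branching]
        graph.add_node(t, name=f"term {i}", namespace="biological_process")
        graph.add_edge(t, parent, key="is_a")
        depth[t] = depth[parent] + 1
    graph.graph["alt_id_map"] = {}

    leaves = [t for t in terms if graph.in_degree(t) == 0 and t != root]
    shallow_terms = [t for t in terms[1:] if depth[t] == 1] or terms[1:2]

    # spread module terms across distinct depth-1 branches so that modules
    # share information only through the root (pairwise Lin sim ~ 0)
    def branch(t: str) -> str:
        while depth[t] > 1:
            t = next(iter(graph.successors(t)))
        return t

    by_branch: dict[str, list] = {}
    for leaf in sorted(leaves, key=lambda t: (-depth[t], t)):
        by_branch.setdefault(branch(leaf), []).append(leaf)
    branches = sorted(by_branch, key=lambda b: -depth[by_branch[b][0]])
    deep_terms = []
    used: set[str] = set()
    i = 0
    while len(deep_terms) < len(config.modules) and len(used) < len(leaves):
        pool = by_branch[branches[i % len(branches)]]
        pick = next((t for t in pool if t not in used), None)
        if pick is not None:
            deep_terms.append(pick)
            used.add(pick)
        i += 1
    if len(deep_terms) < len(config.modules):
        raise DataError("not enough leaf terms for the configured modules")

    rows = []
    for m, module in enumerate(config.modules):
        module_term = deep_terms[m]
        for g in module.genes:
            rows.append((g, module_term, "IDA", "BP"))
    background = [g for g in config.gene_ids() if g not in set(config.module_genes)]
    for g in background:
        t = shallow_terms[int(rng.integers(len(shallow_terms)))]
        rows.append((g, t, "IDA", "BP"))
    # electronic annotations on a few genes, to be dropped by non-IEA filters
    for g in background[: max(1, len(background) // 20)]:
        rows.append((g, root, "IEA", "BP"))
    records = pd.DataFrame(
        rows, columns=["gene_id", "term_id", "evidence_code", "namespace"]
    )
    return graph, AnnotationTable(records)


def generate_expression(config: SimulationConfig) -> ExpressionMatrix:
    """Latent-factor expression matrix with planted module structure.

    Module genes follow sqrt(rho) * f + sqrt(1 - rho) * eps with a shared
    per-module factor f, giving unit marginal variance and expected pairwise
    correlation rho; treated samples add delta (in sd units) to module
    genes. Background genes are i.i.d. noise. All values are scaled by
    ``noise_sd`` and offset by ``baseline`` to sit on a log2-intensity scale.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    samples = config.sample_ids()
    n = len(samples)
    treated = np.array([s.startswith("T") for s in samples])

    data = rng.standard_normal((config.n_genes, n))
    gene_index = {g: i for i, g in enumerate(genes)}
    for module in config.modules:
        f = rng.standard_normal(n)
        for g in module.genes:
            i = gene_index[g]
            data[i] = np.sqrt(module.rho) * f + np.sqrt(1.0 - module.rho) * data[i]
            delta = module.delta
            if g == module.query and module.query_delta is not None:
                delta = module.query_delta
            data[i, treated] += delta
    values = pd.DataFrame(
        data * config.noise_sd + config.baseline, index=genes, columns=samples
    )
    labels = pd.Series(config.label_spec(), name="label").reindex(samples)
    return ExpressionMatrix(values=values, labels=labels)


def generate_ppi(
    config: SimulationConfig,
    fidelity: float = 1.0,
    seed: int | None = None,
    n_background_edges: int = 0,
) -> InteractionNetwork:
    """Interaction network planting query-member edges at a given fidelity.

    A ``fidelity`` fraction of the query-member module edges is included;
    the remainder of that edge budget is rewired to random gene pairs, plus
    ``n_background_edges`` extra random edges. fidelity 1 makes every module
    member adjacent to its query; fidelity 0 yields a fully random network
    of the same size.
    """
    if not (0.0 <= fidelity <= 1.0):
        raise DataError("fidelity must lie in [0, 1]")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    genes = config.gene_ids()
    module_edges = [
        (m.query, member) for m in config.modules for member in m.members
    ]
    n_keep = int(round(fidelity * len(module_edges)))
    keep_idx = rng.choice(len(module_edges), size=n_keep, replace=False)
    edges = {frozenset(module_edges[i]) for i in keep_idx}
    n_random = len(module_edges) - n_keep + n_background_edges
    while n_random > 0:
        a, b = rng.choice(len(genes), size=2, replace=False)
        e = frozenset((genes[a], genes[b]))
        if e not in edges:
            edges.add(e)
            n_random -= 1
    return InteractionNetwork(edges=edges, source_tag="synthetic")


def write_obo(graph: nx.MultiDiGraph, path) -> None:
    """Write a term DAG as a minimal OBO 1.2 file readable by the loader."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(graph.nodes):
            data = graph.nodes[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            fh.write(f"namespace: {data.get('namespace', 'biological_process')}\n")
            for _, parent, key in sorted(graph.out_edges(term, keys=True)):
                if key == "is_a":
                    fh.write(f"is_a: {parent} ! {graph.nodes[parent].get('name', '')}\n")
                else:
                    fh.write(f"relationship: {key} {parent}\n")


def write_gaf(annotations: AnnotationTable, path) -> None:
    """Write annotations as a GAF 2.1 file readable by the loader."""
    aspect = {"BP": "P", "MF": "F", "CC": "C"}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for rec in annotations.records.itertuples(index=False):
            cols = [
                "SYN",  # DB
                rec.gene_id,  # DB Object ID
                rec.gene_id,  # DB Object Symbol
                "",  # Qualifier
                rec.term_id,  # GO ID
                "SYN:0001",  # DB:Reference
                rec.evidence_code,
                "",  # With/From
                aspect[rec.namespace],
                "",  # DB Object Name
                "",  # Synonym
                "protein",
                "taxon:9606",
                "20110330",
                "SYN",
                "",
                "",
            ]
            fh.write("\t".join(cols) + "\n")


def write_edges(network: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\t{b}\n")


def write_dataset(config: SimulationConfig, out_dir) -> dict:
    """Generate and write a full cohort; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = generate_expression(config)
    graph, annotations = generate_ontology(config)
    network = generate_ppi(config)
    paths = {
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "obo": out / "ontology.obo",
        "gaf": out / "annotations.gaf",
        "edges": out / "ppi_edges.tsv",
        "queries": out / "queries.txt",
    }
    write_expression(matrix, paths["expression"])
    write_labels(matrix, paths["labels"])
    write_obo(graph, paths["obo"])
    write_gaf(annotations, paths["gaf"])
    write_edges(network, paths["edges"])
    paths["queries"].write_text(
        "".join(f"{m.query}\n" for m in config.modules)
    )
    return {k: str(v) for k, v in paths.items()}
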