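"""Readers, validators and exporters for the external file formats.

Formats handled here: tab-separated expression matrices with a sample-label
mapping, OBO ontologies (via :mod:`obonet`), GAF 2.x gene annotation files,
two/three-column interaction edge lists, and SIF/GraphML network export.
All loaders are deterministic: identical files yield identical objects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: GO namespace codes used throughout the package.
NAMESPACES = ("BP", "MF", "CC")

_NAMESPACE_LONG = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

_ASPECT_TO_NAMESPACE = {"P": "BP", "F": "MF", "C": "CC"}

#: GO evidence codes recognised in GAF files (GAF 2.x vocabulary).
EVIDENCE_CODES = frozenset(
    {
        "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",  # experimental
        "HTP", "HDA", "HMP", "HGI", "HEP",  # high-throughput
        "PHYLO", "IBA", "IBD", "IKR", "IRD",  # phylogenetic
        "ISS", "ISO", "ISA", "ISM", "IGC", "RCA",  # computational
        "TAS", "NAS", "IC", "ND",  # author/curator statements
        "IEA",  # electronic
    }
)


class DataError(ValueError):
    """Raised when an input file violates a format or consistency contract."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log-scale intensities with condition labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene identifiers, columns by unique sample
        identifiers. Must be free of missing values.
    labels : pandas.Series or None
        Per-sample binary condition labels indexed like the columns, e.g.
        ``"treated"`` / ``"untreated"``.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise DataError(f"duplicate gene ids: {list(dupes)[:5]}")
        if not self.values.columns.is_unique:
            raise DataError("duplicate sample ids in expression matrix")
        if self.values.isna().any().any():
            raise DataError("expression matrix contains missing values")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.columns)
            if self.labels.isna().any():
                missing = self.labels.index[self.labels.isna()].tolist()
                raise DataError(f"samples without a condition label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def binary_labels(self, positive: str | None = None) -> np.ndarray:
        """Return 0/1 labels; the lexicographically larger class is positive
        unless ``positive`` names the positive class explicitly."""
        if self.labels is None:
            raise DataError("expression matrix carries no labels")
        classes = sorted(set(self.labels))
        if len(classes) != 2:
            raise DataError(f"expected exactly two classes, got {classes}")
        if positive is None:
            positive = "treated" if "treated" in classes else classes[-1]
        return (self.labels.to_numpy() == positive).astype(int)


@dataclass
class InteractionNetwork:
    """An undirected gene-gene interaction network without self-loops."""

    edges: set[frozenset]
    source_tag: str = ""

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise DataError(f"self-loop or malformed edge: {set(e)}")

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def neighbors(self, gene: str) -> set[str]:
        """Direct interaction partners (graph distance 1); empty if absent."""
        return {g for e in self.edges if gene in e for g in e if g != gene}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g


@dataclass
class AnnotationTable:
    """Gene-term association records parsed from a GAF file.

    ``records`` has columns ``gene_id``, ``term_id``, ``evidence_code``,
    ``namespace`` (one of BP/MF/CC).
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "term_id", "evidence_code", "namespace"]
        )
    )

    def __post_init__(self) -> None:
        bad_ns = set(self.records["namespace"]) - set(NAMESPACES)
        if bad_ns:
            raise DataError(f"unknown namespaces in annotation table: {bad_ns}")
        bad_ev = set(self.records["evidence_code"]) - EVIDENCE_CODES
        if bad_ev:
            raise DataError(f"unrecognised evidence codes: {bad_ev}")

    def __len__(self) -> int:
        return len(self.records)

    def for_namespace(self, namespace: str) -> "AnnotationTable":
        if namespace not in NAMESPACES:
            raise DataError(f"namespace must be one of {NAMESPACES}")
        sub = self.records[self.records["namespace"] == namespace]
        return AnnotationTable(sub.reset_index(drop=True))

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene_id"])


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(
    path,
    label_spec: dict | None = None,
    *,
    impute_missing: bool = False,
    duplicate_tolerance: float = 1e-9,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene ids, header sample ids).

    Duplicate gene rows are averaged; duplicates that disagree by more than
    ``duplicate_tolerance`` are still averaged but logged as a warning
    (arrays often carry replicate probes per gene). Missing values are
    rejected unless ``impute_missing`` enables per-gene mean imputation.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise DataError(f"cannot parse expression file {path}: {exc}") from exc
    df.index = df.index.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            gene = bad.index[0] if len(bad) else "?"
            raise DataError(
                f"non-numeric value in column {col!r}, gene row {gene!r}"
            )
    if df.index.has_duplicates:
        grouped = df.groupby(level=0, sort=False)
        spread = grouped.max() - grouped.min()
        conflicting = spread.max(axis=1) > duplicate_tolerance
        if conflicting.any():
            ids = spread.index[conflicting].tolist()
            logger.warning(
                "conflicting duplicate rows averaged for gene ids: %s", ids
            )
        else:
            logger.warning(
                "identical duplicate rows collapsed for %d gene ids",
                int(df.index.duplicated().sum()),
            )
        df = grouped.mean()
    if df.isna().any().any():
        if impute_missing:
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
        else:
            gene = df.index[df.isna().any(axis=1)][0]
            raise DataError(
                f"missing values (first at gene {gene!r}); "
                "pass impute_missing=True for per-gene mean imputation"
            )
    labels = None
    if label_spec is not None:
        labels = pd.Series(
            {s: label_spec[s] for s in df.columns if s in label_spec},
            name="label",
        )
        unknown = [s for s in df.columns if s not in label_spec]
        if unknown:
            raise DataError(f"samples missing from label_spec: {unknown}")
    return ExpressionMatrix(values=df.astype(float), labels=labels)


def read_labels(path) -> dict:
    """Read a two-column TSV of ``sample<TAB>condition`` into a mapping."""
    spec: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"label line is not two columns: {line!r}")
            spec[parts[0]] = parts[1]
    return spec


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t")


def write_labels(matrix: ExpressionMatrix, path) -> None:
    if matrix.labels is None:
        raise DataError("matrix carries no labels to write")
    matrix.labels.to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def read_obo(path) -> nx.MultiDiGraph:
    """Read an OBO 1.2/1.4 ontology into a child-to-parent MultiDiGraph.

    Obsolete terms are excluded. ``alt_id`` aliases are recorded in the
    graph attribute ``alt_id_map`` (alias -> canonical id). Only ``is_a``
    and ``part_of`` edges are retained. Raises on cyclic structures.
    """
    graph = obonet.read_obo(path)  # skips obsolete stanzas by default
    keep = nx.MultiDiGraph()
    keep.add_nodes_from(graph.nodes(data=True))
    for child, parent, key in graph.edges(keys=True):
        if key in ("is_a", "part_of"):
            keep.add_edge(child, parent, key=key)
    alt_map: dict[str, str] = {}
    for node, data in keep.nodes(data=True):
        for alt in data.get("alt_id", []):
            alt_map[alt] = node
    keep.graph["alt_id_map"] = alt_map
    if not nx.is_directed_acyclic_graph(keep):
        cycle = nx.find_cycle(keep)
        raise DataError(f"ontology contains a cycle: {cycle}")
    return keep


def resolve_term(graph: nx.MultiDiGraph, term_id: str) -> str | None:
    """Map a term id (possibly an alt_id) to its canonical id, or None."""
    if term_id in graph:
        return term_id
    return graph.graph.get("alt_id_map", {}).get(term_id)


def namespace_subgraph(graph: nx.MultiDiGraph, namespace: str) -> nx.MultiDiGraph:
    """Extract the DAG of one namespace (BP, MF or CC)."""
    if namespace not in NAMESPACES:
        raise DataError(f"namespace must be one of {NAMESPACES}")
    nodes = [
        n
        for n, d in graph.nodes(data=True)
        if _NAMESPACE_LONG.get(d.get("namespace", ""), d.get("namespace")) == namespace
    ]
    sub = graph.subgraph(nodes).copy()
    sub.graph["alt_id_map"] = {
        a: c for a, c in graph.graph.get("alt_id_map", {}).items() if c in sub
    }
    return sub


# ---------------------------------------------------------------------------
# annotations (GAF)
# ---------------------------------------------------------------------------

def read_gaf(
    path,
    exclude_evidence: set[str] | frozenset[str] = frozenset({"IEA"}),
    *,
    use_symbol: bool = True,
) -> AnnotationTable:
    """Read a GAF 2.x annotation file.

    Records carrying an excluded evidence code (default: IEA, inferred from
    electronic annotation) or a ``NOT`` qualifier are dropped. Malformed
    lines are skipped; their count is logged.
    """
    rows = []
    malformed = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                malformed += 1
                continue
            qualifier, go_id, evidence, aspect = cols[3], cols[4], cols[6], cols[8]
            gene = cols[2] if use_symbol else cols[1]
            if not gene or not go_id.startswith("GO:") or aspect not in _ASPECT_TO_NAMESPACE:
                malformed += 1
                continue
            if evidence not in EVIDENCE_CODES:
                malformed += 1
                continue
            if "NOT" in qualifier.split("|"):
                continue
            if evidence in exclude_evidence:
                continue
            rows.append((gene, go_id, evidence, _ASPECT_TO_NAMESPACE[aspect]))
    if malformed:
        logger.warning("skipped %d malformed GAF lines in %s", malformed, path)
    if not rows:
        warnings.warn(f"no usable annotation records in {path}", stacklevel=2)
    records = pd.DataFrame(
        rows, columns=["gene_id", "term_id", "evidence_code", "namespace"]
    ).drop_duplicates(ignore_index=True)
    return AnnotationTable(records)


# ---------------------------------------------------------------------------
# interaction networks
# ---------------------------------------------------------------------------

def read_edges(path, source_tag: str = "") -> InteractionNetwork:
    """Read a two/three-column TSV edge list (gene, gene[, weight]).

    Self-loops are dropped with a warning; reversed duplicates collapse to
    one undirected edge.
    """
    edges: set[frozenset] = set()
    self_loops = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"edge line has fewer than two columns: {line!r}")
            a, b = parts[0], parts[1]
            if a == b:
                self_loops += 1
                continue
            edges.add(frozenset((a, b)))
    if self_loops:
        logger.warning("dropped %d self-loop edges in %s", self_loops, path)
    return InteractionNetwork(edges=edges, source_tag=source_tag or str(path))


def export_network(
    edges,
    path,
    fmt: str = "sif",
    *,
    relation: str = "assoc",
    nodes=None,
) -> None:
    """Export a weighted or unweighted network as SIF or GraphML.

    ``edges`` is an iterable of ``(gene_a, gene_b)`` or
    ``(gene_a, gene_b, weight)`` tuples.
    """
    fmt = fmt.lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            seen = set()
            for edge in sorted(tuple(e) for e in edges):
                a, b = edge[0], edge[1]
                key = frozenset((a, b))
                if key in seen:
                    continue
                seen.add(key)
                fh.write(f"{a}\t{relation}\t{b}\n")
            covered = {g for e in seen for g in e}
            for node in sorted(set(nodes or []) - covered):
                fh.write(f"{node}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        if nodes:
            g.add_nodes_from(nodes)
        for edge in edges:
            if len(edge) >= 3:
                g.add_edge(edge[0], edge[1], weight=float(edge[2]))
            else:
                g.add_edge(edge[0], edge[1])
        nx.write_graphml(g, path)
    else:
        raise DataError(f"unsupported network format {fmt!r}; use sif or graphml")


def read_sif(path, source_tag: str = "") -> InteractionNetwork:
    """Read a SIF file back into an :class:`InteractionNetwork`."""
    edges: set[frozenset] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) >= 3:
                a, b = parts[0], parts[2]
                if a != b:
                    edges.add(frozenset((a, b)))
    return InteractionNetwork(edges=edges, source_tag=source_tag or str(path))
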