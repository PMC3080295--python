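"""Shared fixtures: a hand-built toy ontology corpus and a small cohort."""

import networkx as nx
import pandas as pd
import pytest

from signet.data_io import AnnotationTable
from signet.gosim import build_ontology_model, profiles_from_annotations
from signet.synthetic_data import SimulationConfig, default_modules, generate_expression


def _bp_node(graph, term, name):
    graph.add_node(term, name=name, namespace="biological_process")


@pytest.fixture(scope="session")
def toy_graph():
    """Five-term DAG: root R with children P1, P2; X, Y children of P1.

    Term ids use the GO prefix so they round-trip through OBO/GAF writers.
    """
    g = nx.MultiDiGraph()
    for term, name in [
        ("GO:0000001", "root"),
        ("GO:0000002", "P1"),
        ("GO:0000003", "P2"),
        ("GO:0000004", "X"),
        ("GO:0000005", "Y"),
    ]:
        _bp_node(g, term, name)
    g.add_edge("GO:0000002", "GO:0000001", key="is_a")
    g.add_edge("GO:0000003", "GO:0000001", key="is_a")
    g.add_edge("GO:0000004", "GO:0000002", key="is_a")
    g.add_edge("GO:0000005", "GO:0000002", key="is_a")
    g.graph["alt_id_map"] = {}
    return g


@pytest.fixture(scope="session")
def toy_annotations():
    """Four-gene corpus: p(X) = p(Y) = p(P2) = 1/4, p(P1) = 1/2, p(root) = 1."""
    records = pd.DataFrame(
        [
            ("g1", "GO:0000004", "IDA", "BP"),  # X
            ("g2", "GO:0000005", "IDA", "BP"),  # Y
            ("g3", "GO:0000003", "IDA", "BP"),  # P2
            ("g4", "GO:0000001", "TAS", "BP"),  # root
        ],
        columns=["gene_id", "term_id", "evidence_code", "namespace"],
    )
    return AnnotationTable(records)


@pytest.fixture(scope="session")
def toy_model(toy_graph, toy_annotations):
    return build_ontology_model(toy_graph, toy_annotations, "BP")


@pytest.fixture(scope="session")
def toy_profiles(toy_annotations):
    return profiles_from_annotations(toy_annotations, "BP")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=120, modules=default_modules(n_modules=2, module_size=5), seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_expression(small_config)
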