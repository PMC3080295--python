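"""Integrated k-nearest-neighbour retrieval of gene neighbourhoods.

Each candidate gene is scored against a query by the arithmetic mean of two
unit-interval components: GO-based functional similarity SIM and the absolute
Pearson co-expression |r| (the absolute value maps correlations from [-1, 1]
onto [0, 1]; SIM is unit-interval by construction, so no further rescaling is
applied). The k top-ranked candidates form the query's neighbourhood.

The :class:`IntegratedKNN` estimator follows the scikit-learn idiom: configure
on construction, ``fit`` on an expression matrix, then ``kneighbors`` per
query list. A protein-interaction baseline and an overlap statistic between
two neighbourhood methods are provided for comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data_io import DataError, ExpressionMatrix, InteractionNetwork
from .gosim import OntologyModel, gene_similarity

logger = logging.getLogger(__name__)


@dataclass
class IntegratedScore:
    """Score components for one (query, candidate) pair."""

    query_gene: str
    candidate_gene: str
    go_sim: float
    abs_corr: float

    @property
    def fused(self) -> float:
        return fuse(self.go_sim, self.abs_corr)


@dataclass
class Neighborhood:
    """A query's ranked k-neighbourhood: (gene, fused score), descending."""

    query_gene: str
    k: int
    members: list

    def __post_init__(self) -> None:
        scores = [s for _, s in self.members]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise DataError("neighbourhood members must be sorted descending")
        if self.query_gene in {g for g, _ in self.members}:
            raise DataError("query gene cannot be its own neighbour")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)


def standardize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sample sd 1 across experiments.

    Zero-variance rows cannot be standardized; they are excluded with a
    warning (they carry no correlation signal either).
    """
    values = matrix.values
    sd = values.std(axis=1, ddof=1)
    constant = sd <= 0
    if constant.any():
        dropped = values.index[constant].tolist()
        warnings.warn(
            f"excluded {len(dropped)} zero-variance gene rows "
            f"(first: {dropped[:3]})",
            stacklevel=2,
        )
        values = values.loc[~constant]
        sd = sd.loc[~constant]
    out = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(values=out, labels=matrix.labels)


def pearson_abs(x, y) -> float:
    """Absolute Pearson correlation |r| in [0, 1]; NaN for constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DataError("pearson_abs needs two equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(1.0, abs(r)))


def fuse(go_sim: float, abs_corr: float) -> float:
    """Equal-weight fusion s = (SIM + |r|) / 2; NaN if either is undefined."""
    if np.isnan(go_sim) or np.isnan(abs_corr):
        return float("nan")
    if not (0.0 <= go_sim <= 1.0 and 0.0 <= abs_corr <= 1.0):
        raise DataError("fused components must lie in [0, 1]")
    return (go_sim + abs_corr) / 2.0


def retrieve_neighbors(query: str, k: int, scores: dict) -> Neighborhood:
    """Top-k candidates by fused score; ties broken by ascending gene id.

    ``scores`` maps candidate gene -> fused score; NaN scores are excluded.
    Equals the k-prefix of the full descending sort, so raising k only
    appends members.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    defined = [(g, s) for g, s in scores.items() if not np.isnan(s) and g != query]
    if not defined:
        warnings.warn(f"empty candidate pool for query {query!r}", stacklevel=2)
    ranked = sorted(defined, key=lambda gs: (-gs[1], gs[0]))
    return Neighborhood(query_gene=query, k=k, members=ranked[:k])


class IntegratedKNN(BaseEstimator):
    """Query-driven gene neighbourhood retriever fusing GO similarity and
    absolute co-expression.

    Parameters
    ----------
    ontology_model : OntologyModel
        Namespace-specific IC model from :func:`signet.gosim.build_ontology_model`.
    profiles : dict[str, GeneFunctionalProfile]
        Per-gene annotation profiles in the model's namespace; genes absent
        here (no non-IEA annotation) are excluded from candidate pools.
    k : int, default 15
        Neighbourhood size; the study design sweeps k = 1..20.
    aggregation : {"max_pair", "best_match_average"}, default "max_pair"
        Term-set aggregation for SIM.
    exclude_queries : bool, default False
        If True, other query genes are removed from each query's candidate
        pool; by default they remain eligible neighbours.

    Attributes
    ----------
    matrix_ : ExpressionMatrix
        Row-standardized expression (zero-variance genes dropped).
    candidate_pool_ : list[str]
        Genes with both expression and a non-empty functional profile.
    """

    def __init__(
        self,
        ontology_model: OntologyModel = None,
        profiles: dict = None,
        k: int = 15,
        aggregation: str = "max_pair",
        exclude_queries: bool = False,
    ):
        self.ontology_model = ontology_model
        self.profiles = profiles
        self.k = k
        self.aggregation = aggregation
        self.exclude_queries = exclude_queries

    def fit(self, expression: ExpressionMatrix, y=None) -> "IntegratedKNN":
        if self.ontology_model is None or self.profiles is None:
            raise DataError("IntegratedKNN requires ontology_model and profiles")
        self.matrix_ = standardize(expression)
        self.candidate_pool_ = [
            g for g in self.matrix_.gene_ids if self.profiles.get(g)
        ]
        self._term_sim_cache: dict = {}
        return self

    def score_pairs(self, query: str) -> pd.DataFrame:
        """All defined score components (SIM, |r|, fused) for one query."""
        self._check_fitted()
        pq = self.profiles.get(query)
        if not pq or query not in self.matrix_.values.index:
            return pd.DataFrame(columns=["go_sim", "abs_corr", "fused"])
        xq = self.matrix_.values.loc[query].to_numpy()
        rows = {}
        for cand in self.candidate_pool_:
            if cand == query:
                continue
            sim = gene_similarity(
                pq,
                self.profiles[cand],
                self.ontology_model,
                self.aggregation,
                _term_sim_cache=self._term_sim_cache,
            )
            r = pearson_abs(xq, self.matrix_.values.loc[cand].to_numpy())
            s = fuse(sim, r)
            if not np.isnan(s):
                rows[cand] = (sim, r, s)
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["go_sim", "abs_corr", "fused"]
        )

    def kneighbors(self, queries, k: int | None = None) -> dict[str, Neighborhood]:
        """Ranked neighbourhood per query gene at size ``k`` (default self.k)."""
        self._check_fitted()
        k = self.k if k is None else k
        queries = list(queries)
        out = {}
        query_set = set(queries)
        for q in queries:
            table = self.score_pairs(q)
            scores = dict(zip(table.index, table["fused"]))
            if self.exclude_queries:
                scores = {g: s for g, s in scores.items() if g not in query_set}
            if q in self.matrix_.values.index and self.profiles.get(q):
                out[q] = retrieve_neighbors(q, k, scores)
            else:
                warnings.warn(
                    f"query {q!r} lacks expression or annotations; "
                    "empty neighbourhood",
                    stacklevel=2,
                )
                out[q] = Neighborhood(query_gene=q, k=k, members=[])
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "matrix_"):
            raise DataError("IntegratedKNN is not fitted; call fit() first")


def ppi_neighbors(query: str, network: InteractionNetwork) -> set[str]:
    """Direct interaction partners of ``query`` (distance 1); empty if absent."""
    return network.neighbors(query)


def neighborhood_overlap(
    neighborhoods_a: dict,
    neighborhoods_b: dict,
    k: int | None = None,
) -> tuple[pd.Series, float]:
    """Per-query shared-neighbour counts between two methods, plus a
    two-sided one-sample t-test of the counts against mean 0.

    ``neighborhoods_a`` maps query -> Neighborhood (or plain gene iterable);
    both mappings must cover the same queries. With fewer than two queries
    the p-value is undefined (NaN).
    """
    if set(neighborhoods_a) != set(neighborhoods_b):
        raise DataError("both methods must cover the same query set")

    def genes(nb):
        # ranked neighbourhoods truncate to their k-prefix; unranked gene
        # sets (e.g. PPI partners) are compared whole
        if isinstance(nb, Neighborhood):
            members = nb.genes
            return set(members[:k]) if k is not None else set(members)
        return set(nb)

    counts = pd.Series(
        {
            q: len(genes(neighborhoods_a[q]) & genes(neighborhoods_b[q]))
            for q in sorted(neighborhoods_a)
        },
        name="shared",
        dtype=float,
    )
    if len(counts) < 2:
        return counts, float("nan")
    if counts.std(ddof=1) == 0:
        # all counts equal: t-test degenerate; p = 1.0 when mean is 0
        p = 1.0 if counts.mean() == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(counts, popmean=0.0).pvalue)
    return counts, p


def overlap_sweep(
    neighborhoods_a: dict,
    neighborhoods_b: dict,
    k_range=range(1, 21),
) -> pd.DataFrame:
    """Overlap counts and t-test p-values across a range of k values."""
    rows = []
    for k in k_range:
        counts, p = neighborhood_overlap(neighborhoods_a, neighborhoods_b, k=k)
        rows.append({"k": k, "mean_shared": counts.mean(), "p_value": p})
    return pd.DataFrame(rows)
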