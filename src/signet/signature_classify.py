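"""Biosignature encoding and treated-vs-untreated classification.

A biosignature is a set of query genes plus their retrieved neighbourhoods.
Two input representations feed the classifier:

* ``individual_gene`` — one feature per distinct gene (queries and all
  neighbourhood members present in the expression matrix);
* ``integrated_neighborhood`` — one feature per query, the per-sample mean
  expression over the query and its neighbourhood members.

Classification uses a linear maximum-margin model (SVM, complexity constant
C = 100, linear kernel) evaluated by leave-one-out cross-validation; each
held-out sample contributes its signed distance to the separating hyperplane,
and the pooled held-out scores yield the ROC curve and AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .data_io import DataError, ExpressionMatrix
from .knn_integration import Neighborhood

logger = logging.getLogger(__name__)

REPRESENTATIONS = ("individual_gene", "integrated_neighborhood")

#: Classifier configuration fixed by the study design.
DEFAULT_MODEL_CONFIG = {"kernel": "linear", "C": 100.0}


@dataclass
class Biosignature:
    """Query genes with their ranked neighbourhoods and a representation mode."""

    name: str
    query_genes: list
    neighborhoods: dict = field(default_factory=dict)
    representation: str = "integrated_neighborhood"

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise DataError(
                f"representation must be one of {REPRESENTATIONS}"
            )
        if len(set(self.query_genes)) != len(self.query_genes):
            raise DataError("duplicate query genes in biosignature")

    def member_genes(self, query: str) -> list[str]:
        nb = self.neighborhoods.get(query)
        if nb is None:
            return []
        return nb.genes if isinstance(nb, Neighborhood) else sorted(nb)

    def all_genes(self) -> list[str]:
        """Distinct genes: queries plus every neighbourhood member."""
        seen: dict[str, None] = {}
        for q in self.query_genes:
            seen.setdefault(q)
            for g in self.member_genes(q):
                seen.setdefault(g)
        return list(seen)


@dataclass
class ClassifierEvaluation:
    """Pooled held-out decision scores with the derived ROC curve and AUC."""

    scores: pd.Series
    labels: np.ndarray
    roc_points: list
    auc: float
    model_config: dict = field(default_factory=lambda: dict(DEFAULT_MODEL_CONFIG))


def build_features(
    signature: Biosignature, matrix: ExpressionMatrix
) -> pd.DataFrame:
    """Encode a biosignature as a samples x features matrix.

    ``individual_gene``: one column per distinct signature gene present in
    the matrix. ``integrated_neighborhood``: one column per query, holding
    the mean expression of {query} ∪ neighbourhood members per sample.
    Genes absent from the matrix are dropped with a warning; a signature
    resolving to zero features is an error.
    """
    values = matrix.values
    present = set(values.index)
    missing = [g for g in signature.all_genes() if g not in present]
    if missing:
        warnings.warn(
            f"{len(missing)} signature genes absent from expression matrix "
            f"(first: {missing[:3]})",
            stacklevel=2,
        )
    if signature.representation == "individual_gene":
        genes = [g for g in signature.all_genes() if g in present]
        if not genes:
            raise DataError(f"signature {signature.name!r} resolves to no features")
        feats = values.loc[genes].T
        feats.columns = genes
        return feats
    cols = {}
    for q in signature.query_genes:
        group = [g for g in [q, *signature.member_genes(q)] if g in present]
        if not group:
            continue
        cols[q] = values.loc[group].mean(axis=0)
    if not cols:
        raise DataError(f"signature {signature.name!r} resolves to no features")
    return pd.DataFrame(cols, index=values.columns)


def roc_auc(scores, labels) -> tuple[list, float]:
    """ROC points and AUC from graded scores.

    AUC uses the pairwise-concordance (Mann-Whitney) form:
    (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg). ROC points come
    from the full score-threshold sweep.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("roc_auc requires both classes present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = float((greater + 0.5 * ties) / (len(pos) * len(neg)))
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def loocv_evaluate(
    features: pd.DataFrame,
    labels,
    model_config: dict | None = None,
) -> ClassifierEvaluation:
    """Leave-one-out evaluation of a linear max-margin classifier.

    For each sample the model is trained on all others and the held-out
    sample's signed distance to the hyperplane is recorded; ROC and AUC are
    computed over the pooled held-out scores. Requires >= 2 samples per
    class so no training fold loses a class.
    """
    config = dict(DEFAULT_MODEL_CONFIG)
    if model_config:
        config.update(model_config)
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise DataError("features and labels disagree on sample count")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise DataError("LOOCV needs two classes with >= 2 samples each")
    held_out = np.empty(len(y))
    for i in range(len(y)):
        mask = np.arange(len(y)) != i
        if np.ptp(X[mask], axis=0).max() == 0 and np.ptp(X, axis=0).max() == 0:
            held_out[i] = 0.0  # all-constant features carry no signal
            continue
        clf = SVC(kernel=config["kernel"], C=config["C"])
        clf.fit(X[mask], y[mask])
        held_out[i] = float(clf.decision_function(X[i : i + 1])[0])
    index = features.index if isinstance(features, pd.DataFrame) else None
    points, auc = roc_auc(held_out, y)
    return ClassifierEvaluation(
        scores=pd.Series(held_out, index=index, name="decision_score"),
        labels=y,
        roc_points=points,
        auc=auc,
        model_config=config,
    )


class SignatureEncoder(BaseEstimator, TransformerMixin):
    """scikit-learn transformer turning an expression matrix into signature
    features, composable with sklearn pipelines.

    Operates on X of shape (n_samples, n_genes) with ``gene_ids`` giving the
    column order, or directly on an :class:`ExpressionMatrix` via
    :meth:`transform_matrix`.
    """

    def __init__(self, signature: Biosignature = None, gene_ids: list = None):
        self.signature = signature
        self.gene_ids = gene_ids

    def fit(self, X, y=None) -> "SignatureEncoder":
        if self.signature is None or self.gene_ids is None:
            raise DataError("SignatureEncoder requires signature and gene_ids")
        self.feature_names_ = list(
            build_features(
                self.signature,
                ExpressionMatrix(
                    pd.DataFrame(
                        np.zeros((len(self.gene_ids), 1)),
                        index=self.gene_ids,
                        columns=["_probe"],
                    )
                ),
            ).columns
        )
        return self

    def transform(self, X) -> np.ndarray:
        matrix = ExpressionMatrix(
            pd.DataFrame(
                np.asarray(X, dtype=float).T,
                index=self.gene_ids,
                columns=pd.RangeIndex(np.asarray(X).shape[0]),
            )
        )
        return build_features(self.signature, matrix).to_numpy()

    def transform_matrix(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        return build_features(self.signature, matrix)


def evaluate_signature(
    signature: Biosignature,
    matrix: ExpressionMatrix,
    model_config: dict | None = None,
) -> ClassifierEvaluation:
    """Encode a signature against the matrix and run LOOCV in one step."""
    features = build_features(signature, matrix)
    return loocv_evaluate(features, matrix.binary_labels(), model_config)


def compare_models(
    signatures,
    matrix: ExpressionMatrix,
    model_config: dict | None = None,
) -> pd.DataFrame:
    """Evaluate a family of signatures; returns (name, representation,
    n_features, auc) sorted by AUC descending."""
    rows = []
    for sig in signatures:
        ev = evaluate_signature(sig, matrix, model_config)
        rows.append(
            {
                "name": sig.name,
                "representation": sig.representation,
                "n_features": build_features(sig, matrix).shape[1],
                "auc": ev.auc,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("auc", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def k_sweep(
    retriever,
    queries,
    matrix: ExpressionMatrix,
    k_range=range(1, 21),
    representation: str = "integrated_neighborhood",
    model_config: dict | None = None,
) -> pd.DataFrame:
    """AUC as a function of neighbourhood size k.

    ``retriever`` is a fitted :class:`signet.knn_integration.IntegratedKNN`.
    Retrieval is done once at max(k_range); smaller neighbourhoods are its
    prefixes (the ranking is a full sort, so prefixes are exact).
    """
    k_range = list(k_range)
    full = retriever.kneighbors(queries, k=max(k_range))
    rows = []
    for k in k_range:
        nbh = {
            q: Neighborhood(query_gene=q, k=k, members=nb.members[:k])
            for q, nb in full.items()
        }
        sig = Biosignature(
            name=f"queries+{k}NN",
            query_genes=list(queries),
            neighborhoods=nbh,
            representation=representation,
        )
        ev = evaluate_signature(sig, matrix, model_config)
        rows.append({"k": k, "auc": ev.auc})
    return pd.DataFrame(rows)
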