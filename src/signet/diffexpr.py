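"""SAM-style differential expression for data-driven query selection.

The moderated difference statistic is

    d(g) = (mean_treated - mean_control) / (s(g) + s0),

with s(g) the pooled standard error of the group-mean difference and s0 a
small positive "fudge factor" that damps the statistic for genes with tiny
variance. Here s0 defaults to the median of the per-gene pooled standard
errors, a simplification of the original percentile-tuning search, and is
user-settable. False discovery rates come from a label-permutation null:
q(g) is the median count of null |d| values exceeding |d(g)| across
permutations, divided by the observed exceedance count, clipped to [0, 1]
and monotonized so q never decreases as |d| decreases.

Query genes are those passing both a two-sided fold-change filter on the
anti-logged group means and a q-value ceiling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data_io import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-gene differential expression summary."""

    gene_id: str
    d_stat: float
    fold_change: float
    q_value: float


def _pooled_se(treated: np.ndarray, control: np.ndarray) -> float:
    n1, n2 = len(treated), len(control)
    pooled_var = (
        (n1 - 1) * np.var(treated, ddof=1) + (n2 - 1) * np.var(control, ddof=1)
    ) / (n1 + n2 - 2)
    return float(np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2)))


def d_statistic(treated, control, s0: float = 0.0) -> float:
    """Moderated standardized group-mean difference (treated minus control)."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(treated) < 2 or len(control) < 2:
        raise DataError("each group needs >= 2 samples")
    if s0 < 0:
        raise DataError("s0 must be non-negative")
    s = _pooled_se(treated, control)
    denom = s + s0
    if denom == 0.0:
        return float("nan")  # zero variance in both groups and s0 = 0
    return float((treated.mean() - control.mean()) / denom)


def _d_vector(values: np.ndarray, treated_mask: np.ndarray, s0: float) -> np.ndarray:
    """Vectorised d over all gene rows for one label assignment."""
    t = values[:, treated_mask]
    c = values[:, ~treated_mask]
    n1, n2 = t.shape[1], c.shape[1]
    pooled_var = (
        (n1 - 1) * t.var(axis=1, ddof=1) + (n2 - 1) * c.var(axis=1, ddof=1)
    ) / (n1 + n2 - 2)
    s = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (t.mean(axis=1) - c.mean(axis=1)) / denom
    d[denom == 0.0] = np.nan
    return d


def default_s0(values: np.ndarray, treated_mask: np.ndarray) -> float:
    """Median per-gene pooled standard error (simplified fudge factor)."""
    t = values[:, treated_mask]
    c = values[:, ~treated_mask]
    n1, n2 = t.shape[1], c.shape[1]
    pooled_var = (
        (n1 - 1) * t.var(axis=1, ddof=1) + (n2 - 1) * c.var(axis=1, ddof=1)
    ) / (n1 + n2 - 2)
    return float(np.median(np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))))


def _permutation_masks(
    n_samples: int, n_treated: int, n_perm: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Label reassignments of size n_treated; exhaustive when few exist."""
    from math import comb

    total = comb(n_samples, n_treated)
    if n_perm >= total:
        masks = []
        for idx in combinations(range(n_samples), n_treated):
            m = np.zeros(n_samples, dtype=bool)
            m[list(idx)] = True
            masks.append(m)
        return masks
    masks = []
    for _ in range(n_perm):
        m = np.zeros(n_samples, dtype=bool)
        m[rng.choice(n_samples, size=n_treated, replace=False)] = True
        masks.append(m)
    return masks


def permutation_fdr(
    matrix: ExpressionMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    s0: float | None = None,
) -> pd.DataFrame:
    """Per-gene d-statistic, anti-log fold change and permutation q-value.

    Returns a DataFrame indexed by gene with columns ``d_stat``,
    ``fold_change`` and ``q_value``. ``fold_change`` is 2**(mean_t - mean_c),
    i.e. the ratio of anti-logged group means for log2-scale data.
    """
    if matrix.labels is None:
        raise DataError("permutation_fdr needs labelled samples")
    if n_perm < 100:
        raise DataError("n_perm must be >= 100")
    y = matrix.binary_labels().astype(bool)
    values = matrix.values.to_numpy(dtype=float)
    if s0 is None:
        s0 = default_s0(values, y)
    d_obs = _d_vector(values, y, s0)
    abs_d = np.abs(d_obs)
    rng = np.random.default_rng(seed)
    masks = _permutation_masks(values.shape[1], int(y.sum()), n_perm, rng)

    # observed exceedance: number of genes with |d| >= |d(g)|, ties included
    sorted_abs = np.sort(abs_d[~np.isnan(abs_d)])
    obs_exceed = len(sorted_abs) - np.searchsorted(sorted_abs, abs_d, side="left")

    null_counts = np.empty((len(masks), len(abs_d)))
    for i, m in enumerate(masks):
        null_abs = np.sort(np.abs(_d_vector(values, m, s0)))
        null_abs = null_abs[~np.isnan(null_abs)]
        null_counts[i] = len(null_abs) - np.searchsorted(
            null_abs, abs_d, side="left"
        )
    median_null = np.median(null_counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.clip(median_null / obs_exceed, 0.0, 1.0)
    q[np.isnan(abs_d)] = np.nan

    # monotonize: sort by |d| descending, cumulative min from the
    # least-significant end, so q never decreases as |d| grows
    finite = ~np.isnan(abs_d)
    idx = np.argsort(-abs_d[finite], kind="stable")
    q_sorted = q[finite][idx]
    q_mono = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_out = q.copy()
    q_out[np.flatnonzero(finite)[idx]] = q_mono

    mean_t = values[:, y].mean(axis=1)
    mean_c = values[:, ~y].mean(axis=1)
    return pd.DataFrame(
        {
            "d_stat": d_obs,
            "fold_change": np.power(2.0, mean_t - mean_c),
            "q_value": q_out,
        },
        index=matrix.values.index,
    )


def select_queries(
    de_results: pd.DataFrame,
    fold_change_min: float = 1.7,
    fdr_max: float = 0.01,
) -> list[str]:
    """Genes passing the two-sided fold-change filter and q ceiling,
    ordered by |d_stat| descending."""
    if fold_change_min <= 0:
        raise DataError("fold_change_min must be positive")
    fc = de_results["fold_change"]
    passing = de_results[
        ((fc >= fold_change_min) | (fc <= 1.0 / fold_change_min))
        & (de_results["q_value"] <= fdr_max)
    ]
    if passing.empty:
        warnings.warn("no genes pass the fold-change and FDR thresholds", stacklevel=2)
        return []
    ordered = passing.reindex(
        passing["d_stat"].abs().sort_values(ascending=False, kind="stable").index
    )
    return list(ordered.index)


class SAMSelector(BaseEstimator):
    """scikit-learn-style selector of differentially expressed genes.

    ``fit`` expects X of shape (n_samples, n_genes) and binary y, following
    the sklearn orientation; fitted attributes expose per-gene statistics.

    Parameters
    ----------
    fold_change_min : float, default 1.7
        Two-sided anti-log fold-change threshold.
    fdr_max : float, default 0.01
        Permutation q-value ceiling.
    n_perm : int, default 1000
        Number of label permutations (exhaustive if fewer exist).
    s0 : float or None
        Fudge factor; None uses the median pooled standard error.
    random_state : int, default 0
    """

    def __init__(
        self,
        fold_change_min: float = 1.7,
        fdr_max: float = 0.01,
        n_perm: int = 1000,
        s0: float | None = None,
        random_state: int = 0,
    ):
        self.fold_change_min = fold_change_min
        self.fdr_max = fdr_max
        self.n_perm = n_perm
        self.s0 = s0
        self.random_state = random_state

    def fit(self, X, y, gene_ids=None) -> "SAMSelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(X.shape[1])]
        values = pd.DataFrame(
            X.T, index=list(gene_ids), columns=[f"s{i}" for i in range(X.shape[0])]
        )
        labels = pd.Series(
            np.where(y == 1, "treated", "untreated"), index=values.columns
        )
        matrix = ExpressionMatrix(values=values, labels=labels)
        self.results_ = permutation_fdr(
            matrix, n_perm=self.n_perm, seed=self.random_state, s0=self.s0
        )
        self.selected_ = select_queries(
            self.results_, self.fold_change_min, self.fdr_max
        )
        self.support_ = self.results_.index.isin(self.selected_)
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.support_]
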