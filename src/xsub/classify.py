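"""Centroid-based tumor subtype classification.

Expression subtypes (e.g. the four glioblastoma classes Proneural,
Neural, Classical, Mesenchymal) are represented by centroids: the mean
standardized expression of each classifier gene within a labeled class.
Query samples — possibly from another species, after ortholog mapping
and standardization — are assigned either to the class whose centroid
they are most Pearson-correlated with, or to the nearest centroid in
Euclidean distance.  Both routes are exposed because their agreement on
real cohorts is itself a validation surface; :func:`agreement` measures
it.

Unsupervised average-linkage clustering with correlation distance is
provided for visualization-grade grouping of samples.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

__all__ = [
    "CentroidModel",
    "SubtypeCall",
    "train_centroids",
    "classify_correlation",
    "classify_nearest_centroid",
    "misclassification_rate",
    "agreement",
    "hierarchical_cluster",
]


@dataclass(frozen=True)
class CentroidModel:
    """Per-class mean standardized expression over a fixed gene list."""

    centroids: pd.DataFrame  # classifier genes x classes

    def __post_init__(self) -> None:
        if self.centroids.index.has_duplicates or self.centroids.columns.has_duplicates:
            raise ValueError("duplicate classifier genes or class names")
        if not np.all(np.isfinite(self.centroids.to_numpy())):
            raise ValueError("centroid matrix contains non-finite values")

    @property
    def classifier_genes(self) -> list[str]:
        return list(self.centroids.index)

    @property
    def class_names(self) -> list[str]:
        return list(self.centroids.columns)

    def restrict(self, genes: Sequence[str]) -> "CentroidModel":
        """The model reduced to a subset of its classifier genes.

        Mirrors retraining a published classifier on the orthologs that
        survive cross-platform mapping (e.g. 723 of 840 genes).
        """
        missing = [g for g in genes if g not in self.centroids.index]
        if missing:
            raise ValueError(f"genes not in model: {missing[:10]}")
        return CentroidModel(self.centroids.loc[list(genes)])


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    assigned_class: str
    per_class_scores: Mapping[str, float]
    method: str  # "correlation" or "nearest_centroid"
    tie: bool = False


def _require_standardized(matrix: ExpressionMatrix, what: str) -> None:
    if matrix.state != "standardized":
        raise ValueError(f"{what} must be standardized (state={matrix.state!r})")


def train_centroids(
    train: ExpressionMatrix,
    labels: Mapping[str, str],
    classifier_genes: Sequence[str],
    class_names: Sequence[str] | None = None,
) -> CentroidModel:
    """Average standardized expression per class over the classifier genes.

    ``class_names`` fixes the class (column) order; by default classes
    appear in first-encountered sample order.
    """
    _require_standardized(train, "training matrix")
    missing = [g for g in classifier_genes if g not in train.data.index]
    if missing:
        raise ValueError(f"classifier genes absent from training matrix: {missing[:10]}")
    unlabeled = [s for s in train.sample_ids if s not in labels]
    if unlabeled:
        raise ValueError(f"training samples without a label: {unlabeled[:10]}")

    if class_names is None:
        seen: list[str] = []
        for s in train.sample_ids:
            if labels[s] not in seen:
                seen.append(labels[s])
        class_names = seen
    sub = train.data.loc[list(classifier_genes)]
    cols = {}
    for cls in class_names:
        members = [s for s in train.sample_ids if labels[s] == cls]
        if not members:
            raise ValueError(f"class {cls!r} has no training samples")
        cols[cls] = sub[members].to_numpy().mean(axis=1)
    return CentroidModel(pd.DataFrame(cols, index=list(classifier_genes)))


def _query_matrix(query: ExpressionMatrix, model: CentroidModel) -> np.ndarray:
    missing = [g for g in model.classifier_genes if g not in query.data.index]
    if missing:
        raise ValueError(f"query lacks classifier genes: {missing[:10]}")
    return query.data.loc[model.classifier_genes].to_numpy()


def _calls_from_scores(
    scores: pd.DataFrame, method: str, better_is_higher: bool
) -> list[SubtypeCall]:
    calls = []
    classes = list(scores.columns)
    for sample, row in scores.iterrows():
        vals = row.to_numpy()
        extreme = vals.max() if better_is_higher else vals.min()
        winners = [c for c, v in zip(classes, vals) if v == extreme]
        calls.append(
            SubtypeCall(
                sample_id=str(sample),
                assigned_class=winners[0],  # first class in model order on ties
                per_class_scores=dict(row),
                method=method,
                tie=len(winners) > 1,
            )
        )
    return calls


def classify_correlation(
    query: ExpressionMatrix, model: CentroidModel
) -> tuple[list[SubtypeCall], pd.DataFrame]:
    """Assign each query sample to the most-correlated centroid.

    Returns the calls and the full samples x classes Pearson correlation
    matrix (heatmap-ready).  Correlations are computed over the
    classifier genes with population (divisor n) covariance; the divisor
    cancels in r.
    """
    _require_standardized(query, "query matrix")
    X = _query_matrix(query, model)  # genes x samples
    C = model.centroids.to_numpy()  # genes x classes

    Xc = X - X.mean(axis=0)
    Cc = C - C.mean(axis=0)
    xn = np.linalg.norm(Xc, axis=0)
    cn = np.linalg.norm(Cc, axis=0)
    if np.any(xn == 0):
        bad = query.sample_ids[int(np.flatnonzero(xn == 0)[0])]
        raise ValueError(f"sample {bad!r} has zero variance over classifier genes")
    if np.any(cn == 0):
        bad = model.class_names[int(np.flatnonzero(cn == 0)[0])]
        raise ValueError(f"centroid {bad!r} has zero variance over classifier genes")
    corr = (Xc.T @ Cc) / np.outer(xn, cn)
    corr_df = pd.DataFrame(corr, index=query.sample_ids, columns=model.class_names)
    return _calls_from_scores(corr_df, "correlation", better_is_higher=True), corr_df


def classify_nearest_centroid(
    query: ExpressionMatrix, model: CentroidModel
) -> tuple[list[SubtypeCall], pd.DataFrame]:
    """Assign each query sample to the closest centroid (Euclidean).

    Distances are taken over standardized values of the classifier
    genes.  Returns the calls and the samples x classes distance matrix.
    """
    _require_standardized(query, "query matrix")
    X = _query_matrix(query, model)
    C = model.centroids.to_numpy()
    diff = X[:, :, None] - C[:, None, :]  # genes x samples x classes
    dist = np.sqrt((diff ** 2).sum(axis=0))
    if np.any(X.std(axis=0) == 0):
        bad = query.sample_ids[int(np.flatnonzero(X.std(axis=0) == 0)[0])]
        raise ValueError(f"sample {bad!r} has zero variance over classifier genes")
    dist_df = pd.DataFrame(dist, index=query.sample_ids, columns=model.class_names)
    return _calls_from_scores(dist_df, "nearest_centroid", better_is_higher=False), dist_df


def _index_calls(calls: Sequence[SubtypeCall]) -> dict[str, str]:
    return {c.sample_id: c.assigned_class for c in calls}


def misclassification_rate(calls: Sequence[SubtypeCall], truth: Mapping[str, str]) -> float:
    """Fraction of calls whose assigned class differs from the truth label."""
    if not calls:
        raise ValueError("no calls given")
    missing = [c.sample_id for c in calls if c.sample_id not in truth]
    if missing:
        raise ValueError(f"samples without truth label: {missing[:10]}")
    wrong = sum(1 for c in calls if c.assigned_class != truth[c.sample_id])
    return wrong / len(calls)


def agreement(calls_a: Sequence[SubtypeCall], calls_b: Sequence[SubtypeCall]) -> float:
    """Fraction of samples on which two call lists assign the same class."""
    a, b = _index_calls(calls_a), _index_calls(calls_b)
    if set(a) != set(b):
        raise ValueError("call lists cover different sample sets")
    if not a:
        raise ValueError("no calls given")
    return sum(1 for s in a if a[s] == b[s]) / len(a)


def hierarchical_cluster(
    matrix: ExpressionMatrix, genes: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of samples with distance 1 - Pearson r.

    Returns the SciPy linkage matrix and the sample ids in leaf-input
    order.  Deterministic for a fixed input order; no leaf-order
    optimization is applied.
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    data = matrix.data if genes is None else matrix.data.loc[list(genes)]
    X = data.to_numpy()
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = matrix.sample_ids[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"sample {bad!r} has zero variance over the clustering genes")
    corr = np.corrcoef(X.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    Z = linkage(squareform(dist, checks=False), method="average")
    return Z, matrix.sample_ids
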