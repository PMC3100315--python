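"""Rank-based single-sample gene-set enrichment.

Each sample's expression vector is replaced by ranks (highest expression
gets rank N, ties averaged).  Walking the genes from the top of the
ranking downward, a running sum rises by ``rank**p / sum(rank**p over
set members)`` at each gene in the set and falls by ``1/(N - N_hit)`` at
each gene outside it; the weight exponent defaults to p = 1/5.  The
enrichment score is the signed sum of the walk's two extremes: the
maximum above zero plus the minimum below zero, so ES lies in [-1, 1]
and a set split between both ends of the ranking cancels itself.

Because hit increments and miss decrements each sum to one, the walk
always returns to zero at the end — a useful invariant for testing.

Two gene lists can be contrasted per sample by z-scoring each list's ES
across samples and ranking samples by the difference z_A - z_B; this is
the score used downstream to stratify patients.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, GeneSetCollection

__all__ = [
    "GseaConfig",
    "EnrichmentMatrix",
    "rank_sample",
    "enrichment_score",
    "enrichment_matrix",
    "es_difference_ranking",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GseaConfig:
    """Scoring conventions.

    weight_exponent
        Exponent p applied to the rank when weighting hits (default 0.2,
        i.e. 1/5).
    The rank direction (descending expression walks first) and the
    average-rank tie rule are fixed conventions, recorded here so they
    travel with every result.
    """

    weight_exponent: float = 0.2
    rank_direction: str = "descending_expression_is_top"
    tie_rule: str = "average_rank"

    def __post_init__(self) -> None:
        if not self.weight_exponent > 0:
            raise ValueError("weight_exponent must be positive")


def rank_sample(values: Sequence[float]) -> np.ndarray:
    """Ranks with the highest expression receiving rank N, ties averaged."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("ranking needs at least 2 genes")
    if not np.all(np.isfinite(arr)):
        raise ValueError("expression values must be finite")
    return rankdata(arr, method="average")


def enrichment_score(
    ranks: np.ndarray,
    gene_ids: Sequence[str],
    gene_set: Iterable[str],
    config: GseaConfig | None = None,
) -> float:
    """ES of one gene set against one ranked sample.

    The walk visits genes by descending rank; rank ties are visited in
    stable input-gene order.
    """
    config = config or GseaConfig()
    ranks = np.asarray(ranks, dtype=float)
    n = ranks.size
    if n != len(gene_ids):
        raise ValueError("ranks and gene_ids length mismatch")
    members = set(gene_set)
    hit = np.fromiter((g in members for g in gene_ids), dtype=bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the gene universe")
    if n_hit == n:
        raise ValueError("gene set equals the whole universe; miss decrement undefined")

    order = np.argsort(-ranks, kind="stable")
    hit_ord = hit[order]
    weights = ranks[order] ** config.weight_exponent
    denom = weights[hit_ord].sum()
    steps = np.where(hit_ord, weights / denom, -1.0 / (n - n_hit))
    walk = np.cumsum(steps)
    return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))


@dataclass(frozen=True)
class EnrichmentMatrix:
    """Gene-set x sample ES values plus the scoring config used."""

    scores: pd.DataFrame
    config: GseaConfig = field(default_factory=GseaConfig)

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def zscores(self, datasets: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Per-set z-scores of ES across samples (sample SD, divisor n-1).

        With ``datasets`` given, z-scoring is done within each dataset's
        samples separately.  A set with zero ES spread gets all-zero z
        with a warning rather than dividing by zero.
        """
        return _zscore_frame(self.scores, datasets)


def _zscore_frame(frame: pd.DataFrame, datasets: Mapping[str, str] | None) -> pd.DataFrame:
    def _z(block: pd.DataFrame) -> pd.DataFrame:
        vals = block.to_numpy(dtype=float)
        mean = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=1, keepdims=True) if vals.shape[1] > 1 else np.zeros_like(mean)
        out = np.zeros_like(vals)
        ok = sd[:, 0] > 0
        out[ok] = (vals[ok] - mean[ok]) / sd[ok]
        for name in block.index[~ok]:
            warnings.warn(f"gene set {name!r} has zero ES spread; z-scores set to 0")
        return pd.DataFrame(out, index=block.index, columns=block.columns)

    if datasets is None:
        return _z(frame)
    missing = [s for s in frame.columns if s not in datasets]
    if missing:
        raise ValueError(f"samples without dataset label: {missing[:10]}")
    parts = []
    for ds in dict.fromkeys(datasets[s] for s in frame.columns):
        cols = [s for s in frame.columns if datasets[s] == ds]
        parts.append(_z(frame[cols]))
    return pd.concat(parts, axis=1)[frame.columns]


def enrichment_matrix(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection | Mapping[str, Iterable[str]],
    config: GseaConfig | None = None,
) -> EnrichmentMatrix:
    """ES for every (gene set, sample) pair, computed per sample.

    Set members absent from the matrix's gene universe are dropped (the
    count is logged); a set left with no member is a hard error.
    """
    config = config or GseaConfig()
    genes = matrix.gene_ids
    universe = set(genes)
    effective: dict[str, set] = {}
    for name, members in sets.items():
        inside = set(members) & universe
        dropped = len(set(members)) - len(inside)
        if dropped:
            logger.info("enrichment_matrix: set %s: %d of %d genes absent from matrix",
                        name, dropped, len(set(members)))
        if not inside:
            raise ValueError(f"gene set {name!r} has no gene in the expression matrix")
        effective[name] = inside

    values = matrix.values
    out = np.empty((len(effective), matrix.shape[1]))
    set_names = list(effective)
    for j, sample in enumerate(matrix.sample_ids):
        ranks = rank_sample(values[:, j])
        for i, name in enumerate(set_names):
            try:
                out[i, j] = enrichment_score(ranks, genes, effective[name], config)
            except ValueError as exc:
                raise ValueError(f"set {name!r}, sample {sample!r}: {exc}") from exc
    scores = pd.DataFrame(out, index=set_names, columns=matrix.sample_ids)
    return EnrichmentMatrix(scores=scores, config=config)


def es_difference_ranking(
    matrix: ExpressionMatrix,
    set_up_a: Iterable[str],
    set_up_b: Iterable[str],
    config: GseaConfig | None = None,
    datasets: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Rank samples by the z-scored ES difference of two gene lists.

    score(s) = z_A(s) - z_B(s), where z_X is the across-sample z-score of
    the ES for list X (within each dataset when ``datasets`` is given).
    Returns a DataFrame with columns ``sample_id, dataset, score, rank``
    sorted by descending score; ties break by sample id.
    """
    if matrix.shape[1] < 2:
        raise ValueError("ranking needs at least 2 samples")
    enr = enrichment_matrix(matrix, {"up_a": set(set_up_a), "up_b": set(set_up_b)}, config)
    z = enr.zscores(datasets)
    score = z.loc["up_a"] - z.loc["up_b"]
    frame = pd.DataFrame({
        "sample_id": score.index,
        "dataset": [datasets[s] if datasets else "" for s in score.index],
        "score": score.to_numpy(),
    })
    frame = frame.sort_values(["score", "sample_id"], ascending=[False, True], kind="stable")
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame.reset_index(drop=True)
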