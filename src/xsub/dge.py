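"""Two-group differential expression with FDR control.

Input is a log-scale, gene-level expression matrix and a two-group
sample labeling (e.g. two tumor genotypes).  Per gene the module
computes the mean difference (group A - group B) and a two-sample t
statistic in one of two variance modes:

``welch``
    Welch's unequal-variance t with Satterthwaite degrees of freedom.
``moderated``
    An empirical-Bayes-style statistic: the pooled per-gene variance
    s2_g (d_g = n_A + n_B - 2 df) is shrunk toward the across-gene mean
    variance s0^2 as s~2_g = (d0*s0^2 + d_g*s2_g) / (d0 + d_g), and the
    t statistic is referred to d_g + d0 degrees of freedom.  The prior
    weight d0 may be given, or estimated from the spread of the log
    sample variances (trigamma method of moments); homogeneous variances
    yield d0 = inf, i.e. a pooled z-like test.

P-values are two-sided and adjusted by Benjamini-Hochberg step-up.  The
two derived gene lists (up in A / up in B) take genes with adjusted
p strictly below the FDR cutoff, split by the sign of the difference.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, OrthologMap

__all__ = [
    "DgeResult",
    "differential_expression",
    "derive_gene_lists",
    "map_gene_list",
    "estimate_prior_df",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DgeResult:
    """Per-gene two-group comparison results.

    ``table`` is indexed by gene with columns ``diff`` (mean A - mean B),
    ``stat``, ``pvalue``, ``padj`` and ``zero_variance`` (genes whose
    Welch statistic was undefined and fell back to the moderated one).
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    mode: str
    d0: float
    fdr_cutoff: float = 0.1


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as in empirical-Bayes fits)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior_df(s2: np.ndarray, d_g: int) -> float:
    """Estimate the moderated prior df d0 from per-gene variances.

    Matches the observed variance of log(s2_g) to
    trigamma(d_g/2) + trigamma(d0/2); if the observed spread is no
    larger than the sampling spread, the variances look homogeneous and
    d0 = inf is returned (full pooling).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf
    excess = np.var(np.log(s2), ddof=1) - special.polygamma(1, d_g / 2.0)
    if excess <= 1e-8:
        return np.inf
    return 2.0 * _trigamma_inverse(float(excess))


def differential_expression(
    matrix: ExpressionMatrix,
    groups: Mapping[str, str],
    variance_mode: str = "welch",
    d0: float | None = None,
    group_a: str | None = None,
    group_b: str | None = None,
    fdr_cutoff: float = 0.1,
) -> DgeResult:
    """Per-gene two-group comparison; see module docstring for the model.

    ``groups`` maps every sample of interest to one of two labels.  By
    default the two labels in sorted order become (A, B); pass
    ``group_a``/``group_b`` to fix the direction of ``diff`` explicitly.
    """
    labels = sorted({groups[s] for s in matrix.sample_ids if s in groups})
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 group labels among samples, got {labels}")
        group_a, group_b = labels[0], labels[1]
    a_cols = [s for s in matrix.sample_ids if groups.get(s) == group_a]
    b_cols = [s for s in matrix.sample_ids if groups.get(s) == group_b]
    na, nb = len(a_cols), len(b_cols)
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >=2 samples (got {na} in {group_a!r}, {nb} in {group_b!r})")

    A = matrix.data[a_cols].to_numpy(dtype=float)
    B = matrix.data[b_cols].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)
    diff = mean_a - mean_b

    d_g = na + nb - 2
    s2_pooled = ((na - 1) * var_a + (nb - 1) * var_b) / d_g
    s0_sq = float(s2_pooled.mean())
    if s0_sq == 0:
        raise ValueError("all genes have zero within-group variance")

    if variance_mode == "moderated":
        d0_val = estimate_prior_df(s2_pooled, d_g) if d0 is None else float(d0)
        stat, pval = _moderated_stat(diff, s2_pooled, na, nb, d_g, d0_val, s0_sq)
        zero_var = np.zeros_like(diff, dtype=bool)
    elif variance_mode == "welch":
        d0_val = estimate_prior_df(s2_pooled, d_g) if d0 is None else float(d0)
        se_sq = var_a / na + var_b / nb
        zero_var = se_sq == 0
        stat = np.zeros_like(diff)
        pval = np.ones_like(diff)
        ok = ~zero_var
        stat[ok] = diff[ok] / np.sqrt(se_sq[ok])
        df_num = se_sq[ok] ** 2
        df_den = (var_a[ok] / na) ** 2 / (na - 1) + (var_b[ok] / nb) ** 2 / (nb - 1)
        df = df_num / df_den
        pval[ok] = 2.0 * stats.t.sf(np.abs(stat[ok]), df)
        if zero_var.any():
            # Welch is undefined at zero spread; fall back to the shrunk variance
            m_stat, m_pval = _moderated_stat(diff, s2_pooled, na, nb, d_g, d0_val, s0_sq)
            stat[zero_var] = m_stat[zero_var]
            pval[zero_var] = m_pval[zero_var]
            logger.info("differential_expression: %d genes with zero within-group variance "
                        "used the moderated fallback", int(zero_var.sum()))
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")

    padj = multipletests(pval, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"diff": diff, "stat": stat, "pvalue": pval, "padj": padj, "zero_variance": zero_var},
        index=matrix.gene_ids,
    )
    return DgeResult(table=table, group_a=group_a, group_b=group_b,
                     mode=variance_mode, d0=d0_val, fdr_cutoff=fdr_cutoff)


def _moderated_stat(diff, s2_pooled, na, nb, d_g, d0, s0_sq):
    if np.isinf(d0):
        s2_tilde = np.full_like(s2_pooled, s0_sq)
        df = np.inf
    else:
        s2_tilde = (d0 * s0_sq + d_g * s2_pooled) / (d0 + d_g)
        df = d_g + d0
    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    stat = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df):
        pval = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        pval = 2.0 * stats.t.sf(np.abs(stat), df)
    pval = np.where((diff == 0) & (se == 0), 1.0, pval)
    return stat, pval


def derive_gene_lists(result: DgeResult, cutoff: float | None = None) -> tuple[set, set]:
    """Split significant genes by direction: (up in A, up in B).

    Uses strict inequality at the FDR cutoff, so boundary genes are
    excluded deterministically.
    """
    cutoff = result.fdr_cutoff if cutoff is None else cutoff
    t = result.table
    sig = t["padj"] < cutoff
    up_a = set(t.index[sig & (t["diff"] > 0)])
    up_b = set(t.index[sig & (t["diff"] < 0)])
    return up_a, up_b


def map_gene_list(genes: Iterable[str], ortholog_map: OrthologMap) -> set:
    """Rename a gene list through the ortholog map, dropping unmapped genes."""
    genes = set(genes)
    mapped = {ortholog_map[g] for g in genes if g in ortholog_map}
    logger.info("map_gene_list: %d of %d genes mapped", len(mapped), len(genes))
    if genes and not mapped:
        warnings.warn("no gene in the list could be mapped through the ortholog map")
    return mapped
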