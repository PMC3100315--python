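"""Probe collapsing, ortholog mapping and standardization.

Cross-platform comparison of mouse and human tumors requires three
deterministic reductions before any centroid or enrichment arithmetic:

1. *collapse*: when several array probes interrogate one gene, keep the
   probe with the largest across-sample interquartile range (the most
   informative probe); no values are averaged or rescaled.
2. *ortholog mapping*: restrict a gene-level matrix to the genes covered
   by a one-to-one reciprocal-best-match ortholog map and rename rows
   into the other species' namespace.
3. *standardization*: a z-score linear transform so that expression is
   directly comparable to classifier centroids.  The default mode
   standardizes across genes within each sample (every sample column
   ends with mean 0, unit SD over genes), which is the robust choice for
   highly homogeneous cohorts; a per-gene mode is also provided.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, OrthologMap

__all__ = ["collapse_probes", "map_to_orthologs", "standardize", "intersect_datasets"]

logger = logging.getLogger(__name__)

#: probe id -> gene symbol; many probes may map to one gene
ProbeMap = Mapping[str, str]


def collapse_probes(probe_matrix: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level by maximal IQR.

    For each gene the winning probe is the one whose across-sample
    interquartile range (linear-interpolation quartiles) is largest;
    ties break to the lexicographically smallest probe id.  The winning
    probe's row is carried over bit-identically.
    """
    if probe_matrix.shape[1] < 2:
        raise ValueError("collapse_probes needs at least 2 samples (IQR of one value is degenerate)")
    unmapped = [p for p in probe_matrix.gene_ids if p not in probe_map]
    if unmapped:
        raise ValueError(f"probes missing from probe map: {unmapped[:10]}")

    values = probe_matrix.values
    q75, q25 = np.percentile(values, [75, 25], axis=1)
    iqr = q75 - q25

    best: dict[str, tuple[float, str, int]] = {}  # gene -> (iqr, probe_id, row)
    gene_order: list[str] = []
    for row, probe in enumerate(probe_matrix.gene_ids):
        gene = probe_map[probe]
        if gene not in best:
            gene_order.append(gene)
            best[gene] = (iqr[row], probe, row)
        else:
            cur_iqr, cur_probe, _ = best[gene]
            if iqr[row] > cur_iqr or (iqr[row] == cur_iqr and probe < cur_probe):
                best[gene] = (iqr[row], probe, row)

    rows = [best[g][2] for g in gene_order]
    data = pd.DataFrame(values[rows], index=gene_order, columns=probe_matrix.sample_ids)
    logger.info("collapse_probes: %d probes -> %d genes", probe_matrix.shape[0], len(gene_order))
    return probe_matrix.with_data(data, state="collapsed")


def map_to_orthologs(
    matrix: ExpressionMatrix,
    ortholog_map: OrthologMap,
    direction: str = "source_to_target",
    species: str | None = None,
) -> ExpressionMatrix:
    """Restrict ``matrix`` to mapped genes and rename into the other namespace.

    ``direction`` selects whether matrix rows are looked up in the map's
    source (``source_to_target``) or target (``target_to_source``)
    namespace.  Row order is preserved; the mapped/unmapped split is
    logged.
    """
    if direction == "source_to_target":
        mapping: Mapping[str, str] = ortholog_map
    elif direction == "target_to_source":
        mapping = ortholog_map.inverse()
    else:
        raise ValueError(f"unknown direction {direction!r}")

    keep = [g for g in matrix.gene_ids if g in mapping]
    if not keep:
        raise ValueError("no matrix gene could be mapped through the ortholog map")
    logger.info(
        "map_to_orthologs: %d of %d genes mapped (%d dropped)",
        len(keep), matrix.shape[0], matrix.shape[0] - len(keep),
    )
    data = matrix.data.loc[keep]
    data.index = [mapping[g] for g in keep]
    return ExpressionMatrix(data=data, species=species or matrix.species, state=matrix.state)


def standardize(matrix: ExpressionMatrix, mode: str = "across_genes_per_sample") -> ExpressionMatrix:
    """Z-score the matrix (sample SD, divisor n-1).

    ``across_genes_per_sample`` (default): each sample column is centered
    and scaled using its own across-gene mean and SD.
    ``across_samples_per_gene``: each gene row is standardized across
    samples instead.
    """
    values = matrix.values.astype(float)
    if mode == "across_genes_per_sample":
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ValueError(f"sample {matrix.sample_ids[flat[0]]!r} has zero spread across genes")
        out = (values - mean) / sd
    elif mode == "across_samples_per_gene":
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=1, keepdims=True)
        flat = np.flatnonzero(sd[:, 0] == 0)
        if flat.size:
            raise ValueError(f"gene {matrix.gene_ids[flat[0]]!r} has zero spread across samples")
        out = (values - mean) / sd
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    data = pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids)
    return matrix.with_data(data, state="standardized")


def intersect_datasets(matrices: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict all matrices to their common genes, in a shared order.

    The shared order is the first matrix's gene order filtered to the
    intersection, so outputs are directly row-comparable.
    """
    if not matrices:
        raise ValueError("no matrices given")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("gene intersection across datasets is empty")
    order = [g for g in matrices[0].gene_ids if g in common]
    logger.info("intersect_datasets: %d shared genes", len(order))
    return [m.with_data(m.data.loc[order]) for m in matrices]
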