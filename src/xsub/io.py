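"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats:

* expression matrices as TSV (genes x samples) or GCT #1.2,
* gene sets as GMT,
* ortholog maps as two-column TSV (source gene, target gene),
* survival tables as TSV with columns ``sample, time, event, dataset``.

All readers validate hard: duplicate identifiers, non-numeric cells,
non-injective ortholog pairs and invalid survival rows raise
``ValueError`` naming the offending entry, so downstream stages only
ever see well-formed containers.
"""

from __future__ import annotations

import io as _stdio
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, OrthologMap, SurvivalRecord

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_survival",
    "write_survival",
]


def _parse_matrix_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Convert a string-typed frame to floats, locating any bad cell."""
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-numeric expression value {frame.iat[r, c]!r} at "
            f"gene {frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    return numeric.astype(float)


def read_expression(path, dialect: str = "tsv", species: str = "synthetic") -> ExpressionMatrix:
    """Read an expression matrix from ``path``.

    ``dialect="tsv"`` expects a header row of sample ids and gene/probe
    ids in the first column.  ``dialect="gct"`` expects the GCT #1.2
    layout (version line, dimension line, then Name/Description columns);
    the Description column is ignored.
    """
    path = Path(path)
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    elif dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(f"unsupported GCT version line {version!r}; expected '#1.2'")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise ValueError("malformed GCT dimension line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            frame = pd.read_csv(fh, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        frame = frame.drop(columns=frame.columns[0])  # Description column
        if frame.shape != (n_rows, n_cols):
            raise ValueError(
                f"GCT dimension line says {(n_rows, n_cols)} but table is {frame.shape}"
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'gct'")
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    frame.index = frame.index.astype(str)
    frame.index.name = None
    frame.columns.name = None
    return ExpressionMatrix(data=_parse_matrix_frame(frame), species=species)


def write_expression(path, matrix: ExpressionMatrix, dialect: str = "tsv") -> None:
    """Write ``matrix`` to ``path`` in the given dialect (full precision)."""
    path = Path(path)
    if dialect == "tsv":
        frame = matrix.data.copy()
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t", float_format="%.17g")
    elif dialect == "gct":
        body = matrix.data.copy()
        body.insert(0, "Description", "na")
        body.index.name = "Name"
        buf = _stdio.StringIO()
        body.to_csv(buf, sep="\t", float_format="%.17g")
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            fh.write(buf.getvalue())
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'gct'")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has no genes")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: GMT line has no genes")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = set(genes)
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return GeneSetCollection(sets, descriptions)


def write_gmt(path, sets: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for name in sets:
            desc = sets.descriptions.get(name, "na") or "na"
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_ortholog_map(path) -> OrthologMap:
    """Read a two-column (source gene, target gene) table.

    A header row is recognised (and skipped) when its first field is one
    of ``source``, ``from`` or ``human`` (case-insensitive); otherwise
    every non-comment line is a pair.
    """
    pairs: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            src, tgt = fields[0].strip(), fields[1].strip()
            if lineno == 1 and src.lower() in {"source", "from", "human"}:
                continue
            if not src or not tgt:
                raise ValueError(f"{path}:{lineno}: empty gene symbol")
            if src in pairs and pairs[src] != tgt:
                raise ValueError(
                    f"{path}:{lineno}: source {src!r} mapped to both {pairs[src]!r} and {tgt!r}"
                )
            pairs[src] = tgt
    if not pairs:
        raise ValueError(f"no ortholog pairs found in {path}")
    return OrthologMap(pairs)  # raises on duplicated targets


def write_ortholog_map(path, omap: OrthologMap) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for src in omap:
            fh.write(f"{src}\t{omap[src]}\n")


_SURVIVAL_COLUMNS = ("sample", "time", "event", "dataset")


def read_survival(path) -> list[SurvivalRecord]:
    """Read a survival table with columns sample, time, event, dataset."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "dataset": str})
    missing = [c for c in _SURVIVAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing survival columns {missing}")
    records = []
    for row in frame.itertuples(index=False):
        event = float(row.event)
        if event not in (0.0, 1.0):
            raise ValueError(f"sample {row.sample!r}: event must be 0 or 1, got {row.event}")
        records.append(
            SurvivalRecord(
                sample_id=str(row.sample),
                time=float(row.time),
                event=int(event),
                dataset=str(row.dataset),
            )
        )
    return records


def write_survival(path, records: Iterable[SurvivalRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SURVIVAL_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.time:.17g}\t{r.event}\t{r.dataset}\n")
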