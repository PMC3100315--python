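"""Typed in-memory containers shared by every stage of the pipeline.

The pipeline moves expression data between species and processing states:
a matrix starts as probe- or gene-level summarized intensities
(``state="summarized"``), may be collapsed from probes to genes
(``"collapsed"``), and is z-scored before any centroid comparison
(``"standardized"``).  Gene identifiers are case-sensitive symbols;
cross-species matching goes exclusively through an :class:`OrthologMap`,
never through case-folding, so mapping loss is always explicit.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "OrthologMap",
    "SurvivalRecord",
    "SPECIES",
    "STATES",
]

SPECIES = frozenset({"human", "mouse", "synthetic"})
STATES = frozenset({"summarized", "collapsed", "standardized"})


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix.

    Parameters
    ----------
    data
        DataFrame with gene/probe ids as the index and sample ids as
        columns.  All entries must be finite; missing values are not
        supported (RMA-style summarized matrices are complete, and both
        ranks and IQR become ambiguous with missingness).
    species
        One of ``human``, ``mouse`` or ``synthetic``.
    state
        Processing state tag; see module docstring.
    """

    data: pd.DataFrame
    species: str = "synthetic"
    state: str = "summarized"

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {sorted(SPECIES)}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {sorted(STATES)}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("empty expression matrix")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, state: str | None = None) -> "ExpressionMatrix":
        """Return a copy carrying ``data`` (and optionally a new state tag)."""
        return ExpressionMatrix(data=data, species=self.species, state=state or self.state)


class GeneSetCollection(Mapping):
    """Named gene sets with GMT semantics: unique names, non-empty sets."""

    def __init__(self, sets: Mapping[str, object], descriptions: Mapping[str, str] | None = None):
        built: dict[str, frozenset] = {}
        for name, genes in sets.items():
            fs = frozenset(genes)
            if name in built:
                raise ValueError(f"duplicate gene-set name: {name!r}")
            if not fs:
                raise ValueError(f"gene set {name!r} is empty")
            built[name] = fs
        self._sets = built
        self.descriptions = dict(descriptions or {})

    def __getitem__(self, name: str) -> frozenset:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:
        sizes = ", ".join(f"{k}({len(v)})" for k, v in self._sets.items())
        return f"GeneSetCollection[{sizes}]"


class OrthologMap(Mapping):
    """One-to-one gene symbol map between two species.

    Reciprocal-best-match orthology implies injectivity in both
    directions; construction fails loudly on any violation rather than
    silently resolving many-to-many families.
    """

    def __init__(self, pairs: Mapping[str, str]):
        forward = dict(pairs)
        targets: dict[str, str] = {}
        for src, tgt in forward.items():
            if tgt in targets:
                raise ValueError(
                    f"targets must be unique: {targets[tgt]!r} and {src!r} both map to {tgt!r}"
                )
            targets[tgt] = src
        self._forward = forward
        self._backward = targets

    def __getitem__(self, source: str) -> str:
        return self._forward[source]

    def __iter__(self) -> Iterator[str]:
        return iter(self._forward)

    def __len__(self) -> int:
        return len(self._forward)

    def inverse(self) -> "OrthologMap":
        """The target-to-source map (valid by injectivity)."""
        return OrthologMap(self._backward)


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in days, event=1 for observed death."""

    sample_id: str
    time: float
    event: int
    dataset: str = ""

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"sample {self.sample_id!r}: time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"sample {self.sample_id!r}: event must be 0 or 1, got {self.event}")
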