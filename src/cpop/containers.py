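"""Core data containers: expression matrices and clinical outcomes.

Everything downstream assumes the orientation *samples in rows, genes in
columns* and that expression values are already on a log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneExpressionMatrix", "OutcomeVector"]


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class GeneExpressionMatrix:
    """A samples x genes matrix of log-scale expression values.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Log-scale expression; all entries must be finite.
    sample_ids : list of str
        Unique sample identifiers, one per row.
    gene_ids : list of str
        Unique official gene symbols, one per column.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"row count {n} does not match {len(self.sample_ids)} sample ids"
            )
        if p != len(self.gene_ids):
            raise ValueError(
                f"column count {p} does not match {len(self.gene_ids)} gene ids"
            )
        if p < 2:
            raise ValueError("need at least 2 genes to build ratio features")
        _check_unique(self.gene_ids, "gene symbol")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GeneExpressionMatrix":
        """Build from a DataFrame with sample index and gene columns."""
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.gene_ids)

    def subset_genes(self, genes: list[str]) -> "GeneExpressionMatrix":
        """Restrict to `genes`, in the given order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing}")
        cols = [index[g] for g in genes]
        return GeneExpressionMatrix(self.values[:, cols], list(self.sample_ids),
                                    list(genes))


@dataclass
class OutcomeVector:
    """Clinical outcome aligned to an expression matrix.

    ``kind`` is either ``"binary"`` (0/1 class labels) or ``"survival"``
    (time in months plus a 0/1 event indicator; 1 = event observed).
    """

    kind: str
    sample_ids: list[str]
    class_label: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample id")
        n = len(self.sample_ids)
        if self.kind == "binary":
            if self.class_label is None:
                raise ValueError("binary outcome requires class labels")
            self.class_label = np.asarray(self.class_label, dtype=float)
            if self.class_label.shape != (n,):
                raise ValueError("class labels must match sample ids")
            if not np.all(np.isin(self.class_label, (0.0, 1.0))):
                raise ValueError("binary class labels must be 0 or 1")
        elif self.kind == "survival":
            if self.time is None or self.event is None:
                raise ValueError("survival outcome requires time and event")
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=float)
            if self.time.shape != (n,) or self.event.shape != (n,):
                raise ValueError("time/event must match sample ids")
            if np.any(self.time < 0) or not np.all(np.isfinite(self.time)):
                raise ValueError("survival times must be finite and >= 0")
            if not np.all(np.isin(self.event, (0.0, 1.0))):
                raise ValueError("event indicators must be 0 or 1")
        else:
            raise ValueError(f"unknown outcome kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def check_aligned(self, X: GeneExpressionMatrix) -> None:
        if self.sample_ids != X.sample_ids:
            raise ValueError("outcome sample ids do not match expression matrix")

    def subset(self, idx: np.ndarray) -> "OutcomeVector":
        ids = [self.sample_ids[i] for i in idx]
        if self.kind == "binary":
            return OutcomeVector("binary", ids, class_label=self.class_label[idx])
        return OutcomeVector("survival", ids, time=self.time[idx],
                             event=self.event[idx])

    def to_dataframe(self) -> pd.DataFrame:
        if self.kind == "binary":
            return pd.DataFrame({"sample_id": self.sample_ids,
                                 "class": self.class_label.astype(int)})
        return pd.DataFrame({"sample_id": self.sample_ids, "time": self.time,
                             "event": self.event.astype(int)})
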