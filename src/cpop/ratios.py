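"""All-pairs log-ratio features and cross-dataset instability weights.

Given a log-scale expression matrix X with p genes, the log-ratio matrix Z
has one column per unordered gene pair (l, m), l < m in the canonical
(lexicographic) gene order, holding X[:, l] - X[:, m].  Because the inputs
are log-scale this realises log(x_l) - log(x_m): a feature that is exactly
invariant to any per-sample global shift in log-space, which is the
mechanism that makes models built on Z transferable across platforms.

The instability weight of feature j across two datasets is
``w_j = |mean(Z1[:, j]) - mean(Z2[:, j])|``: a large weight means the
feature's location disagrees between the datasets, and downstream model
fitting penalises it more heavily.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .containers import GeneExpressionMatrix

__all__ = [
    "LogRatioMatrix",
    "FeatureWeights",
    "build_log_ratio_matrix",
    "compute_feature_weights",
    "feature_id",
    "split_feature_id",
    "MAX_GENES_DEFAULT",
]

#: Guard against accidental dense materialisation of huge pair spaces.
#: p genes produce p(p-1)/2 ratio columns; targeted assays stay well below this.
MAX_GENES_DEFAULT = 1500

_SEP = "--"


def feature_id(gene_l: str, gene_m: str) -> str:
    """Canonical identifier for the ratio of two genes (order preserved)."""
    return f"{gene_l}{_SEP}{gene_m}"


def split_feature_id(fid: str) -> tuple[str, str]:
    left, sep, right = fid.partition(_SEP)
    if not sep or not left or not right:
        raise ValueError(f"malformed ratio feature id: {fid!r}")
    return left, right


@dataclass
class LogRatioMatrix:
    """Samples x q matrix of pairwise log-ratio features."""

    values: np.ndarray
    feature_ids: list[str]
    source_genes: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.source_genes)
        q = p * (p - 1) // 2
        if self.values.ndim != 2:
            raise ValueError("ratio values must be a 2-D matrix")
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length does not match column count")
        if len(self.feature_ids) != q:
            raise ValueError(
                f"expected q = p(p-1)/2 = {q} features for p = {p} genes, "
                f"got {len(self.feature_ids)}"
            )
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def columns(self, fids: list[str]) -> np.ndarray:
        """Values of the requested features, in the requested order."""
        index = {f: j for j, f in enumerate(self.feature_ids)}
        try:
            cols = [index[f] for f in fids]
        except KeyError as e:
            raise KeyError(f"unknown ratio feature {e.args[0]!r}") from None
        return self.values[:, cols]


@dataclass
class FeatureWeights:
    """Non-negative per-feature weights aligned to a LogRatioMatrix."""

    feature_ids: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.feature_ids),):
            raise ValueError("weight vector length does not match feature ids")
        if not np.all(np.isfinite(self.w)) or np.any(self.w < 0):
            raise ValueError("weights must be finite and non-negative")


def build_log_ratio_matrix(
    X: GeneExpressionMatrix, max_genes: int = MAX_GENES_DEFAULT
) -> LogRatioMatrix:
    """Construct the all-pairs log-ratio matrix Z from log-scale expression.

    Column for the pair (l, m) with l < m in the gene order of `X` equals
    ``X[:, l] - X[:, m]``.  The gene order of `X` is used as-is; align and
    sort gene sets first (see :func:`cpop.io.align_common_genes`) when
    combining datasets.

    Raises
    ------
    ValueError
        If `X` has more than `max_genes` genes (dense Z would be huge), or
        contains non-finite values.
    """
    p = X.n_genes
    if p > max_genes:
        raise ValueError(
            f"{p} genes would produce {p * (p - 1) // 2} ratio features; "
            f"raise max_genes (currently {max_genes}) to force this"
        )
    genes = X.gene_ids
    iu = np.triu_indices(p, k=1)
    # column (l, m) = gene_l - gene_m, enumerated in row-major (l, m) order
    Z = X.values[:, iu[0]] - X.values[:, iu[1]]
    fids = [feature_id(genes[l], genes[m]) for l, m in zip(iu[0], iu[1])]
    return LogRatioMatrix(Z, fids, list(genes), list(X.sample_ids))


def compute_feature_weights(
    Z1: LogRatioMatrix,
    Z2: LogRatioMatrix,
    weight_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> FeatureWeights:
    """Cross-dataset instability weights for each shared ratio feature.

    The default weight is the absolute difference of the two column means.
    A custom ``weight_fn(column_of_Z1, column_of_Z2) -> float >= 0`` may be
    supplied to plug in other instability measures.
    """
    if Z1.feature_ids != Z2.feature_ids:
        set2 = set(Z2.feature_ids)
        for j, f in enumerate(Z1.feature_ids):
            if j >= len(Z2.feature_ids) or Z2.feature_ids[j] != f:
                other = Z2.feature_ids[j] if j < len(Z2.feature_ids) else "<absent>"
                raise ValueError(
                    "feature ids of the two ratio matrices differ: first "
                    f"divergence at position {j}: {f!r} vs {other!r}"
                    + ("" if f in set2 else f" ({f!r} absent from second matrix)")
                )
    if weight_fn is None:
        w = np.abs(Z1.values.mean(axis=0) - Z2.values.mean(axis=0))
    else:
        w = np.array(
            [weight_fn(Z1.values[:, j], Z2.values[:, j])
             for j in range(Z1.n_features)],
            dtype=float,
        )
    return FeatureWeights(list(Z1.feature_ids), w)
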