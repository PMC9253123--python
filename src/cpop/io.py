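"""Reading and writing expression matrices, outcome tables and models.

Expression files are delimited text (CSV or TSV, sniffed from the
extension) with a header row of gene symbols and the first column holding
sample identifiers; ``transpose=True`` accepts the genes-in-rows layout.
Outcome tables are CSV/TSV with a ``sample_id`` column plus either
``class`` (0/1) or ``time`` and ``event`` columns.  Models are stored as
versioned JSON; loading refuses unknown versions rather than guessing.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GeneExpressionMatrix, OutcomeVector
from .core import CPOPConfig, CPOPModel

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_outcome_table",
    "write_outcome_table",
    "align_common_genes",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = 1


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_expression_matrix(path, transpose: bool = False,
                           log_transform: bool = False,
                           offset: float = 1.0) -> GeneExpressionMatrix:
    """Read a delimited expression file into samples x genes orientation.

    With ``log_transform=True`` every value is replaced by
    ``log2(value + offset)``; use this for raw (count-like) input, since
    everything downstream assumes log-scale values.

    Raises
    ------
    ValueError
        For non-numeric cells (naming the offending row and column),
        duplicated gene symbols, or fewer than two genes.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen, dups = set(), set()
    for name in header:
        if name in seen:
            dups.add(name)
        seen.add(name)
    if dups:
        what = "sample id" if transpose else "gene symbol"
        raise ValueError(
            f"duplicated {what}(s) in header of {path.name}: {sorted(dups)}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicated gene symbol(s) in {path.name}: {dups}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(
                f"non-numeric value in {path.name} at sample {row!r}, "
                f"gene {col!r}: {df.loc[row, col]!r}")
        df[col] = converted
    if df.isna().any().any():
        raise ValueError(f"missing values in {path.name}")
    values = df.to_numpy(dtype=float)
    if log_transform:
        if np.any(values + offset <= 0):
            raise ValueError(
                f"log transform undefined: values <= -offset ({-offset}) "
                f"present in {path.name}")
        values = np.log2(values + offset)
    return GeneExpressionMatrix(values, list(df.index), list(df.columns))


def write_expression_matrix(X: GeneExpressionMatrix, path) -> None:
    path = Path(path)
    X.to_dataframe().to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_outcome_table(path) -> OutcomeVector:
    """Read an outcome table; the kind is inferred from its columns."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols:
        raise ValueError(f"{path.name} lacks a 'sample_id' column")
    ids = df[cols["sample_id"]].astype(str).tolist()
    if "class" in cols:
        return OutcomeVector("binary", ids,
                             class_label=df[cols["class"]].to_numpy(float))
    if "time" in cols and "event" in cols:
        return OutcomeVector("survival", ids,
                             time=df[cols["time"]].to_numpy(float),
                             event=df[cols["event"]].to_numpy(float))
    raise ValueError(
        f"{path.name} must contain either a 'class' column or both "
        "'time' and 'event' columns")


def write_outcome_table(y: OutcomeVector, path) -> None:
    path = Path(path)
    y.to_dataframe().to_csv(path, sep=_sep_for(path), index=False)


def align_common_genes(
    matrices: list[GeneExpressionMatrix],
) -> list[GeneExpressionMatrix]:
    """Restrict every matrix to the shared genes, in lexicographic order.

    Gene matching is by exact symbol string.  Sample rows are untouched.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to align")
    common = set(matrices[0].gene_ids)
    for X in matrices[1:]:
        common &= set(X.gene_ids)
    if len(common) < 2:
        counts = ", ".join(f"matrix {i}: {X.n_genes} genes"
                           for i, X in enumerate(matrices))
        raise ValueError(
            f"gene intersection has {len(common)} gene(s); need >= 2 "
            f"({counts})")
    order = sorted(common)
    return [X.subset_genes(order) for X in matrices]


# --------------------------------------------------------------------------
# model serialisation


def save_model(model: CPOPModel, path) -> None:
    """Write a trained model to versioned JSON (full float precision)."""
    ztr = model.training_ratio_columns
    payload = {
        "format": "cpop-model",
        "version": MODEL_FORMAT_VERSION,
        "family": model.family,
        "source_genes": model.source_genes,
        "s1": model.s1,
        "s2": model.s2,
        "beta1": model.beta1,
        "beta2": model.beta2,
        "beta_avg": model.beta_avg,
        "intercept1": model.intercept1,
        "intercept2": model.intercept2,
        "intercept_avg": model.intercept_avg,
        "config": asdict(model.config),
        "iteration_trace": model.iteration_trace,
        "training_feature_means": model.training_feature_means,
        "training_feature_variances": model.training_feature_variances,
        "training_ratio_columns": None if ztr is None else {
            "index": list(ztr.index),
            "columns": list(ztr.columns),
            "values": ztr.to_numpy().tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> CPOPModel:
    """Load a model saved by :func:`save_model`.

    Raises
    ------
    ValueError
        If the file is not a model file or its version is unknown.
    """
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "cpop-model":
        raise ValueError(f"{path} is not a CPOP model file")
    version = payload.get("version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {version!r} "
            f"(this build reads version {MODEL_FORMAT_VERSION})")
    ztr = payload["training_ratio_columns"]
    frame = None
    if ztr is not None:
        frame = pd.DataFrame(np.asarray(ztr["values"], dtype=float),
                             index=ztr["index"], columns=ztr["columns"])
    return CPOPModel(
        family=payload["family"],
        source_genes=payload["source_genes"],
        s1=payload["s1"],
        s2=payload["s2"],
        beta1={k: float(v) for k, v in payload["beta1"].items()},
        beta2={k: float(v) for k, v in payload["beta2"].items()},
        beta_avg={k: float(v) for k, v in payload["beta_avg"].items()},
        intercept1=payload["intercept1"],
        intercept2=payload["intercept2"],
        intercept_avg=payload["intercept_avg"],
        config=CPOPConfig(**payload["config"]),
        iteration_trace=payload["iteration_trace"],
        training_feature_means=payload["training_feature_means"],
        training_feature_variances=payload["training_feature_variances"],
        training_ratio_columns=frame,
    )
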