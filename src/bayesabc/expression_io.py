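"""Reading and writing expression matrices, annotations and fitted models.

All formats are plain text: tab-separated matrices and annotation
tables (a flag switches to comma separation) and a small JSON document
for fitted mixture models.  Matrices are genes-in-rows by default with
a header row of sample identifiers and gene symbols in the first
column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gmm_bayes import DecisionBorder, GaussianComponent, GaussianMixtureModel

__all__ = [
    "ExpressionMatrix",
    "ParseError",
    "DomainError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotations",
    "write_annotations",
    "filter_genes",
    "write_model",
    "read_model",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = 1


class ParseError(ValueError):
    """A file was structurally invalid (bad cell, duplicate id, bad header)."""


class DomainError(ValueError):
    """Values violated the domain contract (e.g., negative expression)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative raw expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("expression values must form a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DomainError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ParseError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParseError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("expression values must be finite")
        if np.any(self.values < 0):
            g, s = map(int, np.argwhere(self.values < 0)[0])
            raise DomainError(
                f"negative expression value {self.values[g, s]!r} at "
                f"gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


def _sep(comma: bool) -> str:
    return "," if comma else "\t"


def read_expression_matrix(
    path, samples_in_rows: bool = False, comma: bool = False
) -> ExpressionMatrix:
    """Read a delimited matrix; first column ids, header row ids.

    ``samples_in_rows`` transposes after reading so the result is
    always genes x samples.  Non-numeric or empty cells raise
    :class:`ParseError` naming the offending row and column; negative
    values raise :class:`DomainError`.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep(comma), index_col=0, dtype=str)
    if raw.index.has_duplicates or raw.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate row or column identifiers")
    bad = raw.apply(pd.to_numeric, errors="coerce").isna().to_numpy()
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        cell = raw.iloc[i, j]
        raise ParseError(
            f"{path}: non-numeric cell {cell!r} at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r}"
        )
    # astype goes through the exact strtod, unlike to_numeric's fast path
    numeric = raw.astype("float64")
    if samples_in_rows:
        numeric = numeric.T
    return ExpressionMatrix.from_frame(numeric)


def write_expression_matrix(
    matrix: ExpressionMatrix, path, samples_in_rows: bool = False, comma: bool = False
) -> None:
    frame = matrix.to_frame()
    if samples_in_rows:
        frame = frame.T
    # 17 significant digits: exact decimal round-trip for doubles
    frame.to_csv(path, sep=_sep(comma), float_format="%.17g")


def read_annotations(path, comma: bool = False) -> pd.DataFrame:
    """Read a sample annotation table with required columns sample_id, label.

    Returns a DataFrame indexed by sample_id with a ``label`` column;
    any further columns are preserved untouched.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep(comma), dtype=str)
    for col in ("sample_id", "label"):
        if col not in table.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    return table.set_index("sample_id")


def write_annotations(annotations: pd.DataFrame, path, comma: bool = False) -> None:
    annotations.to_csv(path, sep=_sep(comma), index_label="sample_id")


def filter_genes(
    matrix: ExpressionMatrix, whitelist
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep genes whose symbol is in ``whitelist``, preserving matrix order.

    Returns the filtered matrix and the whitelist symbols absent from
    the matrix.  An empty intersection is an error: there would be
    nothing left to analyze.
    """
    whitelist = set(whitelist)
    if not whitelist:
        raise DomainError("gene whitelist is empty")
    keep = [i for i, g in enumerate(matrix.gene_ids) if g in whitelist]
    missing = sorted(whitelist.difference(matrix.gene_ids))
    if not keep:
        raise DomainError("no whitelist gene is present in the matrix")
    return (
        ExpressionMatrix(
            gene_ids=[matrix.gene_ids[i] for i in keep],
            sample_ids=list(matrix.sample_ids),
            values=matrix.values[keep, :],
        ),
        missing,
    )


def write_model(
    model: GaussianMixtureModel, path, border: DecisionBorder | None = None
) -> None:
    """Serialize a fitted mixture to JSON at full float precision."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "components": [{"w": c.w, "m": c.m, "s": c.s} for c in model.components],
        "log_base": model.log_base,
        "pseudocount": model.pseudocount,
        "loglik": model.loglik,
        "aic": model.aic,
        "n_points": model.n_points,
        "decision_border": (
            None if border is None else {"x_log": border.x_log, "x_raw": border.x_raw}
        ),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path) -> tuple[GaussianMixtureModel, DecisionBorder | None]:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid model JSON ({exc})") from exc
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise ParseError(f"{path}: missing format_version field")
    if doc["format_version"] != MODEL_FORMAT_VERSION:
        raise ParseError(
            f"{path}: model format version {doc['format_version']} "
            f"not supported (expected {MODEL_FORMAT_VERSION})"
        )
    try:
        model = GaussianMixtureModel(
            components=tuple(
                GaussianComponent(c["w"], c["m"], c["s"]) for c in doc["components"]
            ),
            log_base=doc["log_base"],
            pseudocount=doc.get("pseudocount", 0.0),
            loglik=doc["loglik"],
            aic=doc["aic"],
            n_points=doc["n_points"],
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: malformed model document ({exc})") from exc
    border = None
    if doc.get("decision_border") is not None:
        border = DecisionBorder(
            x_log=doc["decision_border"]["x_log"],
            x_raw=doc["decision_border"]["x_raw"],
        )
    return model, border
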