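"""Reading, writing and filtering of expression matrices and companion tables.

The pipeline's raw input is a genes x subjects matrix of (log-intensity)
expression values restricted to one pre-computed co-expression module.
Subject metadata (RNA integrity number, ethnicity group, age) drive the
quality filter applied before any correlation is computed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SubjectMetadata",
    "ExpressionParseError",
    "load_expression",
    "write_expression",
    "load_metadata",
    "filter_subjects",
    "drop_zero_variance",
    "read_gene_set",
    "write_gene_set",
    "write_edge_list",
]


class ExpressionParseError(ValueError):
    """Raised when an expression matrix file or object violates its contract."""


@dataclass
class ExpressionMatrix:
    """Genes x subjects numeric matrix with identifier lists.

    Invariants: finite values, >=3 genes, >=2 subjects, unique ids, and
    shape consistent with the id lists. Violations raise
    :class:`ExpressionParseError` at construction.
    """

    gene_ids: list[str]
    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ExpressionParseError("expression values must be a 2-D matrix")
        n_genes, n_subjects = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.subject_ids) != n_subjects:
            raise ExpressionParseError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.subject_ids)} subject ids"
            )
        if n_genes < 3:
            raise ExpressionParseError("need at least 3 genes")
        if n_subjects < 2:
            raise ExpressionParseError("need at least 2 subjects")
        for label, ids in (("gene", self.gene_ids), ("subject", self.subject_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ExpressionParseError(f"duplicate {label} id(s): {sorted(dupes)}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            genes = [self.gene_ids[i] for i in np.unique(np.nonzero(bad)[0])]
            raise ExpressionParseError(f"non-finite values in gene(s): {genes}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.subject_ids)


@dataclass(frozen=True)
class SubjectMetadata:
    """Per-subject quality and demographic record."""

    subject_id: str
    rin: float
    group: str
    age: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.rin < 0:
            raise ValueError(f"RIN must be >= 0, got {self.rin} for {self.subject_id}")


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in ids:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") else ","


def load_expression(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a genes x subjects delimited text matrix.

    First row holds subject ids, first column gene ids. ``delimiter=None``
    auto-detects tab vs comma from the header line.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ExpressionParseError(f"cannot parse {path}: {exc}") from exc
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(d) for d in df.dtypes]]
    if len(non_numeric):
        raise ExpressionParseError(
            f"non-numeric cells in column(s): {list(non_numeric)}"
        )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        subject_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression(m: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a matrix in the same dialect :func:`load_expression` reads.

    Uses ``repr`` floats so that a round trip is bitwise exact.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["gene_id", *m.subject_ids])
        for gid, row in zip(m.gene_ids, m.values):
            w.writerow([gid, *(repr(float(v)) for v in row)])


def load_metadata(path: str | Path, delimiter: str | None = None) -> list[SubjectMetadata]:
    """Read a subject metadata table with columns subject_id, rin, group, age."""
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter)
    required = {"subject_id", "rin", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ExpressionParseError(f"metadata missing column(s): {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectMetadata(
                subject_id=str(row["subject_id"]),
                rin=float(row["rin"]),
                group=str(row["group"]),
                age=float(row["age"]) if "age" in df.columns else float("nan"),
            )
        )
    dupes = _duplicates([r.subject_id for r in records])
    if dupes:
        raise ExpressionParseError(f"duplicate subject id(s) in metadata: {sorted(dupes)}")
    return records


def filter_subjects(
    m: ExpressionMatrix,
    meta: Iterable[SubjectMetadata],
    min_rin: float = 7.0,
    allowed_groups: set[str] | None = None,
) -> ExpressionMatrix:
    """Keep subjects with RIN strictly above ``min_rin`` and group in
    ``allowed_groups`` (``None`` = all groups). Column order is preserved.

    Tissue quality motivates the strict inequality: samples at exactly the
    cutoff are rejected.
    """
    by_id = {r.subject_id: r for r in meta}
    missing = [s for s in m.subject_ids if s not in by_id]
    if missing:
        raise KeyError(f"subject(s) missing from metadata: {missing}")
    keep = [
        j
        for j, s in enumerate(m.subject_ids)
        if by_id[s].rin > min_rin
        and (allowed_groups is None or by_id[s].group in allowed_groups)
    ]
    if not keep:
        raise ValueError("no subjects survive the filter")
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        subject_ids=[m.subject_ids[j] for j in keep],
        values=m.values[:, keep],
    )


def drop_zero_variance(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes constant across subjects (Pearson correlation undefined).

    Emits a warning naming the dropped genes; returns ``m`` unchanged when
    every gene varies.
    """
    sd = m.values.std(axis=1)
    flat = sd == 0
    if not flat.any():
        return m
    dropped = [g for g, f in zip(m.gene_ids, flat) if f]
    warnings.warn(f"dropping zero-variance gene(s): {dropped}", stacklevel=2)
    keep = ~flat
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        subject_ids=list(m.subject_ids),
        values=m.values[keep],
    )


def read_gene_set(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_edge_list(
    edges: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """TSV edge list ``geneA geneB weight``."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["geneA", "geneB", "weight"])
        for a, b, wt in edges:
            w.writerow([a, b, repr(float(wt))])
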