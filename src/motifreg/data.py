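"""Labeled matrices, the (G, M, T) dataset container, and text I/O.

The common data currency is :class:`LabeledMatrix`: a dense real matrix with
unique row and column identifiers.  Three of them form a
:class:`RegulatoryDataset`:

* ``G`` — gene expression, genes x experiments,
* ``M`` — motif occurrence counts in promoters, genes x motifs,
* ``T`` — transcription-factor expression, TFs x experiments,

with the gene axis shared between G and M and the experiment axis shared
between G and T.

Matrices travel as a fixed TSV dialect: first row = column identifiers,
first column = row identifiers, tab-separated, decimal point, UTF-8.  The
reader is strict: ragged rows are a format error, missing cells ("" or NA)
are rejected unless row-mean imputation is requested.  Promoter sequences
are read from FASTA via Biopython.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, FormatError, ValidationError

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NA", "N/A", "NAN", "NULL"}


def _check_ids(ids: Sequence[str], axis: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if any(i == "" for i in ids):
        raise ValidationError(f"empty identifier on {axis} axis")
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate identifier on {axis} axis: {dup!r}")
    return ids


@dataclass(frozen=True)
class LabeledMatrix:
    """A dense real matrix with unique row/column identifiers.

    Invariants enforced at construction: shape matches the identifier
    lists, identifiers are unique and non-empty, and every value is finite
    (missing values must be rejected or imputed at load time, never
    stored).
    """

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError(f"matrix must be 2-D, got {values.ndim}-D")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", _check_ids(self.row_ids, "row"))
        object.__setattr__(self, "col_ids", _check_ids(self.col_ids, "column"))
        if values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} column ids"
            )
        if values.size and not np.isfinite(values).all():
            raise ValidationError("matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def row_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.row_ids)}

    def col_index(self) -> dict[str, int]:
        return {c: j for j, c in enumerate(self.col_ids)}

    def loc(self, row: str, col: str) -> float:
        return float(self.values[self.row_index()[row], self.col_index()[col]])

    def select(
        self,
        rows: Iterable[str] | None = None,
        cols: Iterable[str] | None = None,
    ) -> "LabeledMatrix":
        """Sub-matrix restricted/reordered to the given identifiers."""
        rows = list(self.row_ids) if rows is None else list(rows)
        cols = list(self.col_ids) if cols is None else list(cols)
        ri, ci = self.row_index(), self.col_index()
        try:
            r_idx = [ri[r] for r in rows]
            c_idx = [ci[c] for c in cols]
        except KeyError as exc:
            raise ValidationError(f"unknown identifier {exc.args[0]!r}") from exc
        return LabeledMatrix(
            self.values[np.ix_(r_idx, c_idx)], tuple(rows), tuple(cols)
        )

    def with_values(self, values: np.ndarray) -> "LabeledMatrix":
        """Same labels, new values (shape-checked by the constructor)."""
        return LabeledMatrix(values, self.row_ids, self.col_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.row_ids), columns=list(self.col_ids)
        )

    @classmethod
    def from_frame(cls, frame) -> "LabeledMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            tuple(str(i) for i in frame.index),
            tuple(str(c) for c in frame.columns),
        )


@dataclass(frozen=True)
class SequenceRecord:
    """A promoter (or any DNA) sequence with its gene identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty identifier")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class RegulatoryDataset:
    """Aligned (G, M, T) triple.

    G is genes x experiments expression, M genes x motifs occurrence
    counts, T TFs x experiments expression.  G and M share the gene axis
    (same identifiers, same order); G and T share the experiment axis.
    """

    G: LabeledMatrix
    M: LabeledMatrix
    T: LabeledMatrix

    def __post_init__(self) -> None:
        if self.G.row_ids != self.M.row_ids:
            raise ValidationError("G and M must list the same genes in the same order")
        if self.G.col_ids != self.T.col_ids:
            raise ValidationError(
                "G and T must list the same experiments in the same order"
            )
        if min(self.n_genes, self.n_experiments, self.n_motifs, self.n_tfs) < 1:
            raise ValidationError("all four dimensions must be >= 1")

    @property
    def n_genes(self) -> int:
        return len(self.G.row_ids)

    @property
    def n_experiments(self) -> int:
        return len(self.G.col_ids)

    @property
    def n_motifs(self) -> int:
        return len(self.M.col_ids)

    @property
    def n_tfs(self) -> int:
        return len(self.T.row_ids)

    @property
    def genes(self) -> tuple[str, ...]:
        return self.G.row_ids

    @property
    def experiments(self) -> tuple[str, ...]:
        return self.G.col_ids

    @property
    def motifs(self) -> tuple[str, ...]:
        return self.M.col_ids

    @property
    def tfs(self) -> tuple[str, ...]:
        return self.T.row_ids

    def replace(self, **kwargs) -> "RegulatoryDataset":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Labeled-matrix TSV dialect
# ---------------------------------------------------------------------------
# A hand-written reader: the dialect is 6 lines of logic, and the contract
# distinguishes a ragged (short) data row — a format error — from an empty
# cell — a missing value — which generic CSV readers conflate by padding.


def _parse_cell(token: str) -> float | None:
    if token.strip().upper() in _MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"cell {token!r} is not a number") from None


def read_matrix_tsv(path: str | Path, impute_missing: bool = False) -> LabeledMatrix:
    """Read a labeled matrix from the TSV dialect.

    With ``impute_missing``, empty/NA cells are replaced by the row mean of
    the observed cells; a row with no observed cell is a validation error.
    Without it, any missing cell is an error.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    col_ids = header[1:]
    if not col_ids:
        raise FormatError(f"{path}: header has no column identifiers")
    row_ids: list[str] = []
    rows: list[list[float | None]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        fields = line.split("\t")
        if len(fields) != len(col_ids) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(col_ids) + 1} fields, "
                f"got {len(fields)}"
            )
        row_ids.append(fields[0])
        try:
            rows.append([_parse_cell(tok) for tok in fields[1:]])
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")

    values = np.empty((len(rows), len(col_ids)))
    for i, row in enumerate(rows):
        observed = [v for v in row if v is not None]
        if len(observed) < len(row):
            if not impute_missing:
                raise ValidationError(
                    f"{path}: missing value in row {row_ids[i]!r} "
                    "(pass impute_missing=True to impute row means)"
                )
            if not observed:
                raise ValidationError(
                    f"{path}: row {row_ids[i]!r} has no observed values to impute from"
                )
            mean = math.fsum(observed) / len(observed)
            row = [mean if v is None else v for v in row]
        values[i] = row
    return LabeledMatrix(values, tuple(row_ids), tuple(col_ids))


def write_matrix_tsv(mat: LabeledMatrix, path: str | Path) -> None:
    """Write a labeled matrix in the dialect accepted by :func:`read_matrix_tsv`.

    Floats are written with 17 significant digits, enough for a bit-exact
    read-back.  Identifiers containing tabs or newlines are rejected.
    """
    path = Path(path)
    for ident in (*mat.row_ids, *mat.col_ids):
        if "\t" in ident or "\n" in ident or "\r" in ident:
            raise ValidationError(
                f"identifier {ident!r} contains a tab/newline and cannot be "
                "written in the TSV dialect"
            )
    buf = StringIO()
    buf.write("id\t" + "\t".join(mat.col_ids) + "\n")
    for i, rid in enumerate(mat.row_ids):
        cells = "\t".join(format(v, ".17g") for v in mat.values[i])
        buf.write(f"{rid}\t{cells}\n")
    try:
        path.write_text(buf.getvalue(), encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write matrix to {path}: {exc}") from exc


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read promoter sequences; ids are the first header token, sequences
    are uppercased, file order is preserved.  Duplicate ids are an error;
    an empty file yields an empty list."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if text.strip() and not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: not FASTA (first record lacks a '>' header)")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def align_dataset(
    G: LabeledMatrix, M: LabeledMatrix, T: LabeledMatrix
) -> RegulatoryDataset:
    """Restrict G/M to their common genes and G/T to their common
    experiments, everything reordered to G's ordering (the canonical one).

    Dropped identifier counts are reported via logging; an empty
    intersection on either axis raises :class:`AlignmentError`.
    """
    m_genes = set(M.row_ids)
    t_exps = set(T.col_ids)
    genes = [g for g in G.row_ids if g in m_genes]
    exps = [e for e in G.col_ids if e in t_exps]
    if not genes:
        raise AlignmentError("no genes shared between G rows and M rows")
    if not exps:
        raise AlignmentError("no experiments shared between G columns and T columns")
    dropped_g = (len(G.row_ids) - len(genes)) + (len(M.row_ids) - len(genes))
    dropped_e = (len(G.col_ids) - len(exps)) + (len(T.col_ids) - len(exps))
    if dropped_g or dropped_e:
        logger.info(
            "alignment dropped %d gene rows and %d experiment columns",
            dropped_g,
            dropped_e,
        )
    return RegulatoryDataset(
        G=G.select(genes, exps),
        M=M.select(genes, None),
        T=T.select(None, exps),
    )
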