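"""Motif-matrix and annotation-matrix construction.

Two ways of building the genes x attributes matrix M:

* k-mer scanning of promoter sequences (``count_kmers``), optionally
  followed by presence-based frequency filtering and binarization; and
* binary Gene Ontology annotation matrices (``build_go_matrix``), where
  GO terms take the place of motifs and entry (g, s) is 1 iff gene g is
  annotated with term s.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import LabeledMatrix, SequenceRecord
from .errors import FormatError, ParameterError, ValidationError

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def all_kmers(k: int) -> tuple[str, ...]:
    """All 4^k k-mers over {A,C,G,T} in lexicographic order."""
    return tuple("".join(p) for p in itertools.product(_BASES, repeat=k))


def reverse_complement(kmer: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(kmer))


def _kmer_code(window: str) -> int | None:
    """Lexicographic index of a window, or None if it has a non-ACGT base."""
    code = 0
    for base in window:
        digit = _BASE_INDEX.get(base)
        if digit is None:
            return None
        code = code * 4 + digit
    return code


def count_kmers(
    records: Sequence[SequenceRecord], k: int, revcomp: bool = False
) -> LabeledMatrix:
    """Count overlapping k-mer windows per sequence.

    Rows are record ids, columns all 4^k k-mers in lexicographic order.
    Windows containing a non-ACGT character are skipped.  With ``revcomp``
    each valid window also increments its reverse complement's column (so
    a palindromic window counts twice in its own column).
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    kmers = all_kmers(k)
    counts = np.zeros((len(records), len(kmers)))
    rc_code = None
    if revcomp:
        rc_code = np.array([_kmer_code(reverse_complement(km)) for km in kmers])
    for i, rec in enumerate(records):
        seq = rec.sequence
        for start in range(len(seq) - k + 1):
            code = _kmer_code(seq[start : start + k])
            if code is None:
                continue
            counts[i, code] += 1
            if rc_code is not None:
                counts[i, rc_code[code]] += 1
    return LabeledMatrix(counts, tuple(r.id for r in records), kmers)


def filter_frequent_motifs(M: LabeledMatrix, fraction: float) -> LabeledMatrix:
    """Keep the top ``floor(fraction * m)`` motifs by presence.

    Presence of a motif is the number of genes with a positive count.
    Motifs whose presence ties exactly at the selection boundary are all
    excluded, so the survivor set is unambiguous; ties strictly above the
    boundary are kept.  Column order of survivors is preserved.
    """
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    m = len(M.col_ids)
    if m < 1:
        raise ValidationError("motif matrix has no columns")
    presence = (M.values > 0).sum(axis=0)
    keep_n = int(np.floor(fraction * m))
    if keep_n == 0:
        return LabeledMatrix(M.values[:, :0], M.row_ids, ())
    order = np.sort(presence)[::-1]
    boundary = order[keep_n - 1]
    if keep_n < m and order[keep_n] == boundary:
        survivors = presence > boundary
    else:
        survivors = presence >= boundary
    cols = [c for c, keep in zip(M.col_ids, survivors) if keep]
    return M.select(None, cols)


def binarize_motif_matrix(M: LabeledMatrix) -> LabeledMatrix:
    """Replace counts by presence indicators (1 where count > 0)."""
    if (M.values < 0).any():
        raise ValidationError("motif matrix has negative entries")
    return M.with_values((M.values > 0).astype(float))


@dataclass(frozen=True)
class AnnotationTable:
    """Gene -> term annotation pairs (duplicates collapsed at load)."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        unique: list[tuple[str, str]] = []
        for gene, term in self.pairs:
            if not gene or not term:
                raise ValidationError("annotation pair with empty identifier")
            if (gene, term) not in seen:
                seen.add((gene, term))
                unique.append((str(gene), str(term)))
        object.__setattr__(self, "pairs", tuple(unique))

    @property
    def terms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, term in self.pairs:
            seen.setdefault(term)
        return tuple(seen)


def read_annotation_pairs(path: str | Path) -> AnnotationTable:
    """Read two-column tab-separated (gene, term) pairs."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        pairs.append((fields[0], fields[1]))
    return AnnotationTable(tuple(pairs))


def build_go_matrix(
    ann: AnnotationTable, genes: Sequence[str], top_n: int
) -> LabeledMatrix:
    """Binary genes x terms annotation matrix over the most-annotated terms.

    Selects the ``top_n`` terms annotating the most genes among ``genes``
    (ties at the boundary broken by term-id lexicographic order); entry
    (g, s) is 1 iff the (g, s) pair is annotated.
    """
    if top_n < 1:
        raise ParameterError(f"top_n must be >= 1, got {top_n}")
    gene_set = set(genes)
    counts: dict[str, int] = {}
    for gene, term in ann.pairs:
        if gene in gene_set:
            counts[term] = counts.get(term, 0) + 1
    if not counts:
        raise ValidationError("no annotation term covers any of the listed genes")
    terms = sorted(counts, key=lambda s: (-counts[s], s))[:top_n]
    annotated = set(ann.pairs)
    values = np.zeros((len(genes), len(terms)))
    for i, gene in enumerate(genes):
        for j, term in enumerate(terms):
            if (gene, term) in annotated:
                values[i, j] = 1.0
    return LabeledMatrix(values, tuple(genes), tuple(terms))
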