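"""Binary patient × gene mutation matrices and the coverage/exclusivity primitives.

A study of somatic mutations across a cohort is summarized as an m × n binary
incidence matrix A: ``A[i, g] = 1`` iff gene g carries a somatic mutation in
patient i.  Everything downstream (recurrence testing, weight maximization,
MCMC sampling) reads the matrix through three primitives:

* ``support(g)``  — the set of patients in which gene g is mutated,
* ``coverage(M)`` — the set of patients with a mutation in at least one gene
  of the gene set M,
* ``weight(M)``   — 2·|coverage(M)| − Σ_g |support(g)|, which rewards covering
  many patients while penalizing every mutation beyond the first per patient.

Two plain-text encodings are supported: a dense TSV with a header row, and a
sparse two-column patient/gene pair list (with an optional explicit gene
universe so that never-mutated genes survive a round trip).
"""

from __future__ import annotations

import csv
import io
import logging
import os
from typing import Iterable, Sequence, TextIO

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MutationMatrix",
    "MatrixFormatError",
    "UnknownLabelError",
    "as_gene_set",
    "read_matrix",
    "write_matrix",
    "read_gene_universe",
    "support",
    "coverage",
    "coverage_overlap",
    "weight",
]

#: A gene set is an ordered tuple of distinct gene labels.
GeneSet = tuple[str, ...]


class MatrixFormatError(ValueError):
    """Raised when an input stream violates the matrix file contract."""


class UnknownLabelError(KeyError):
    """Raised when a patient or gene label is absent from the matrix."""


def as_gene_set(genes: Iterable[str]) -> GeneSet:
    """Normalize an iterable of gene labels into a duplicate-free tuple.

    Order of first appearance is preserved; duplicates are an error because
    the weight function is defined on *sets* of genes.
    """
    out = tuple(genes)
    if len(set(out)) != len(out):
        raise ValueError(f"gene set contains duplicate labels: {out!r}")
    return out


class MutationMatrix:
    """An immutable m × n binary patient × gene mutation matrix.

    Parameters
    ----------
    entries
        Array-like of shape (m, n) with values in {0, 1}.
    patient_ids, gene_ids
        Unique string labels for rows and columns.  Internally all indexing
        is 0-based positional; labels exist only at the I/O boundary.

    Per-gene supports and column sums are cached on first use, so that the
    search algorithms, which score many overlapping gene sets, pay O(Σ|Γ(g)|)
    per evaluation rather than re-scanning the matrix.
    """

    def __init__(
        self,
        entries: np.ndarray | Sequence[Sequence[int]],
        patient_ids: Sequence[str],
        gene_ids: Sequence[str],
    ) -> None:
        arr = np.asarray(entries)
        if arr.ndim != 2:
            raise ValueError(f"entries must be 2-D, got shape {arr.shape}")
        if arr.size == 0 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("matrix must have at least one patient and one gene")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("matrix entries must all be 0 or 1")
        self._data = arr.astype(np.uint8)
        self._data.setflags(write=False)

        self.patient_ids: tuple[str, ...] = tuple(str(p) for p in patient_ids)
        self.gene_ids: tuple[str, ...] = tuple(str(g) for g in gene_ids)
        if len(self.patient_ids) != arr.shape[0]:
            raise ValueError("patient_ids length does not match row count")
        if len(self.gene_ids) != arr.shape[1]:
            raise ValueError("gene_ids length does not match column count")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient labels")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene labels")

        self._patient_index = {p: i for i, p in enumerate(self.patient_ids)}
        self._gene_index = {g: j for j, g in enumerate(self.gene_ids)}
        self._bool = self._data.astype(bool)
        self._bool.setflags(write=False)
        self._colsums = self._data.sum(axis=0, dtype=np.int64)
        self._colsums.setflags(write=False)
        self._support_cache: dict[int, np.ndarray] = {}

    # ------------------------------------------------------------------ shape
    @property
    def m(self) -> int:
        """Number of patients (rows)."""
        return self._data.shape[0]

    @property
    def n(self) -> int:
        """Number of genes (columns)."""
        return self._data.shape[1]

    @property
    def entries(self) -> np.ndarray:
        """Read-only uint8 view of the incidence matrix."""
        return self._data

    @property
    def boolean_entries(self) -> np.ndarray:
        """Read-only boolean view of the incidence matrix."""
        return self._bool

    @property
    def column_sums(self) -> np.ndarray:
        """Per-gene mutation counts |Γ(g)| as an int64 vector."""
        return self._colsums

    # ------------------------------------------------------------- label maps
    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise UnknownLabelError(f"unknown gene label: {gene!r}") from None

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        """Map a gene set to column indices, validating existence/uniqueness."""
        labels = as_gene_set(genes)
        return np.array([self.gene_index(g) for g in labels], dtype=np.intp)

    def patient_index(self, patient: str) -> int:
        try:
            return self._patient_index[patient]
        except KeyError:
            raise UnknownLabelError(f"unknown patient label: {patient!r}") from None

    def entry(self, patient: str, gene: str) -> int:
        return int(self._data[self.patient_index(patient), self.gene_index(gene)])

    # -------------------------------------------------------------- primitives
    def support_indices(self, gene_idx: int) -> np.ndarray:
        """Row indices of patients mutated in the given column (cached)."""
        cached = self._support_cache.get(gene_idx)
        if cached is None:
            cached = np.flatnonzero(self._bool[:, gene_idx])
            cached.setflags(write=False)
            self._support_cache[gene_idx] = cached
        return cached

    def multiplicity(self, gene_idx: np.ndarray) -> np.ndarray:
        """Per-patient count of mutated genes among the given columns."""
        if len(gene_idx) == 0:
            return np.zeros(self.m, dtype=np.int64)
        return self._bool[:, gene_idx].sum(axis=1, dtype=np.int64)

    def weight_by_index(self, gene_idx: np.ndarray) -> int:
        """W(M) = 2|Γ(M)| − Σ_g |Γ(g)| for a set given as column indices."""
        if len(gene_idx) == 0:
            return 0
        mult = self.multiplicity(gene_idx)
        cov = int(np.count_nonzero(mult))
        return 2 * cov - int(self._colsums[gene_idx].sum())

    # ------------------------------------------------------------- restriction
    def subset_genes(self, keep: Iterable[str]) -> "MutationMatrix":
        """New matrix restricted to the given genes (order as given)."""
        idx = self.gene_indices(keep)
        return MutationMatrix(
            self._data[:, idx],
            self.patient_ids,
            [self.gene_ids[j] for j in idx],
        )

    def drop_genes(self, drop: Iterable[str]) -> "MutationMatrix":
        """New matrix with the given gene columns removed."""
        gone = set(as_gene_set(drop))
        for g in gone:
            self.gene_index(g)  # validate
        keep = [g for g in self.gene_ids if g not in gone]
        if not keep:
            raise ValueError("cannot drop every gene from the matrix")
        return self.subset_genes(keep)

    # ---------------------------------------------------------------- equality
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationMatrix):
            return NotImplemented
        return (
            self.patient_ids == other.patient_ids
            and self.gene_ids == other.gene_ids
            and np.array_equal(self._data, other._data)
        )

    def __repr__(self) -> str:
        return f"MutationMatrix(m={self.m}, n={self.n})"


# ---------------------------------------------------------------------------
# Set-level primitives (label interface)
# ---------------------------------------------------------------------------

def support(matrix: MutationMatrix, gene: str) -> set[str]:
    """Γ(g): the set of patients in which ``gene`` is mutated."""
    idx = matrix.gene_index(gene)
    return {matrix.patient_ids[i] for i in matrix.support_indices(idx)}


def coverage(matrix: MutationMatrix, genes: Iterable[str]) -> set[str]:
    """Γ(M) = ∪_{g∈M} Γ(g): patients with ≥1 mutation in the set."""
    idx = matrix.gene_indices(genes)
    if len(idx) == 0:
        return set()
    mult = matrix.multiplicity(idx)
    return {matrix.patient_ids[i] for i in np.flatnonzero(mult)}


def coverage_overlap(matrix: MutationMatrix, genes: Iterable[str]) -> int:
    """ω(M) = Σ_g |Γ(g)| − |Γ(M)|, the excess mutations beyond one per covered
    patient.  Zero iff the mutations in M are mutually exclusive."""
    idx = matrix.gene_indices(genes)
    if len(idx) == 0:
        return 0
    mult = matrix.multiplicity(idx)
    return int(matrix.column_sums[idx].sum()) - int(np.count_nonzero(mult))


def weight(matrix: MutationMatrix, genes: Iterable[str]) -> int:
    """W(M) = |Γ(M)| − ω(M) = 2|Γ(M)| − Σ_g |Γ(g)|.

    High weight means the set covers many patients (coverage) with few
    patients mutated in more than one member (exclusivity).  W(∅) = 0 and
    W({g}) = |Γ(g)|.
    """
    return matrix.weight_by_index(matrix.gene_indices(genes))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

DENSE_TSV = "dense-tsv"
PAIR_LIST = "pair-list"


def _as_text_stream(source, mode: str):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def read_gene_universe(source: TextIO | str | os.PathLike) -> GeneSet:
    """Read a gene-universe declaration: one gene label per line."""
    stream, owned = _as_text_stream(source, "r")
    try:
        genes = [line.strip() for line in stream if line.strip()]
    finally:
        if owned:
            stream.close()
    return as_gene_set(genes)


def read_matrix(
    source: TextIO | str | os.PathLike,
    format: str = DENSE_TSV,
    *,
    gene_universe: Sequence[str] | None = None,
) -> MutationMatrix:
    """Parse a mutation matrix from a text stream or path.

    Parameters
    ----------
    format
        ``"dense-tsv"``: header row ``patient<TAB>gene1<TAB>…``, one row per
        patient, cells strictly ``0`` or ``1``.
        ``"pair-list"``: two tab-separated columns ``patient<TAB>gene``, one
        mutation event per line; duplicate pairs collapse to a single 1 with
        a logged warning.
    gene_universe
        Full ordered gene axis for the pair-list format, so that genes with
        no mutation events exist in the matrix.  Ignored for dense TSV.
    """
    stream, owned = _as_text_stream(source, "r")
    try:
        if format == DENSE_TSV:
            return _read_dense(stream)
        if format == PAIR_LIST:
            return _read_pairs(stream, gene_universe)
        raise ValueError(f"unknown matrix format: {format!r}")
    finally:
        if owned:
            stream.close()


def _read_dense(stream: TextIO) -> MutationMatrix:
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise MatrixFormatError("empty matrix file") from None
    if not header or header[0] != "patient":
        raise MatrixFormatError("dense TSV must start with a 'patient' header column")
    gene_ids = header[1:]
    if not gene_ids:
        raise MatrixFormatError("dense TSV declares no gene columns")
    if len(set(gene_ids)) != len(gene_ids):
        raise MatrixFormatError("duplicate gene label in header")

    patient_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != len(gene_ids) + 1:
            raise MatrixFormatError(
                f"line {lineno}: expected {len(gene_ids) + 1} fields, got {len(row)}"
            )
        patient_ids.append(row[0])
        parsed = []
        for cell in row[1:]:
            if cell == "0":
                parsed.append(0)
            elif cell == "1":
                parsed.append(1)
            else:
                raise MatrixFormatError(f"line {lineno}: non-binary cell {cell!r}")
        rows.append(parsed)
    if not rows:
        raise MatrixFormatError("dense TSV contains no patient rows")
    if len(set(patient_ids)) != len(patient_ids):
        raise MatrixFormatError("duplicate patient label")
    return MutationMatrix(np.array(rows, dtype=np.uint8), patient_ids, gene_ids)


def _read_pairs(stream: TextIO, gene_universe: Sequence[str] | None) -> MutationMatrix:
    reader = csv.reader(stream, delimiter="\t")
    pairs: list[tuple[str, str]] = []
    for lineno, row in enumerate(reader, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 2:
            raise MatrixFormatError(f"line {lineno}: expected 'patient<TAB>gene'")
        pairs.append((row[0], row[1]))
    if not pairs:
        raise MatrixFormatError("pair list contains no mutation events")

    patient_ids: list[str] = []
    patient_pos: dict[str, int] = {}
    for p, _ in pairs:
        if p not in patient_pos:
            patient_pos[p] = len(patient_ids)
            patient_ids.append(p)

    if gene_universe is not None:
        gene_ids = list(as_gene_set(gene_universe))
        gene_pos = {g: j for j, g in enumerate(gene_ids)}
        for _, g in pairs:
            if g not in gene_pos:
                raise MatrixFormatError(
                    f"gene {g!r} appears in pair list but not in the declared universe"
                )
    else:
        gene_ids = []
        gene_pos = {}
        for _, g in pairs:
            if g not in gene_pos:
                gene_pos[g] = len(gene_ids)
                gene_ids.append(g)

    data = np.zeros((len(patient_ids), len(gene_ids)), dtype=np.uint8)
    seen: set[tuple[str, str]] = set()
    for p, g in pairs:
        if (p, g) in seen:
            logger.warning("duplicate mutation event (%s, %s) collapsed to one", p, g)
            continue
        seen.add((p, g))
        data[patient_pos[p], gene_pos[g]] = 1
    return MutationMatrix(data, patient_ids, gene_ids)


def write_matrix(
    matrix: MutationMatrix,
    sink: TextIO | str | os.PathLike,
    format: str = DENSE_TSV,
) -> None:
    """Serialize a matrix; ``read_matrix(write_matrix(x))`` is the identity
    (for the pair list, given the same gene universe)."""
    stream, owned = _as_text_stream(sink, "w")
    try:
        if format == DENSE_TSV:
            writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
            writer.writerow(["patient", *matrix.gene_ids])
            for i, p in enumerate(matrix.patient_ids):
                writer.writerow([p, *matrix.entries[i].tolist()])
        elif format == PAIR_LIST:
            writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
            for i, p in enumerate(matrix.patient_ids):
                for j in np.flatnonzero(matrix.entries[i]):
                    writer.writerow([p, matrix.gene_ids[j]])
        else:
            raise ValueError(f"unknown matrix format: {format!r}")
    finally:
        if owned:
            stream.close()


def matrix_to_string(matrix: MutationMatrix, format: str = DENSE_TSV) -> str:
    """Convenience: serialize to an in-memory string."""
    buf = io.StringIO()
    write_matrix(matrix, buf, format)
    return buf.getvalue()
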