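"""Entity-indexed containers and on-disk formats for miRNA-drug networks.

The central objects are :class:`AssociationMatrix` (binary miRNA x drug
resistance matrix) and :class:`SimilarityMatrix` (square symmetric matrix
over one entity type).  All readers produce matrices whose row/column order
is the lexicographic order of the identifier strings, so repeated runs on
the same input files are bit-reproducible.

On-disk formats are plain text: association edge lists as two-column TSV,
miRNA sequences as FASTA, similarity matrices as dense TSV with an
identifier header row and column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

ROLE_MIRNA = "miRNA"
ROLE_DRUG = "drug"
_VALID_ROLES = (ROLE_MIRNA, ROLE_DRUG)

#: similarity kinds whose diagonal must be exactly 1
_UNIT_DIAG_KINDS = ("GIP", "sequence", "fused")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered, unique identifiers for one entity type (miRNAs or drugs).

    The position of an identifier in ``ids`` is its row/column position in
    every matrix bound to this index; :meth:`position` is the inverse map.
    """

    ids: tuple[str, ...]
    role: str
    _pos: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.role not in _VALID_ROLES:
            raise DataError(f"role must be one of {_VALID_ROLES}, got {self.role!r}")
        ids = tuple(self.ids)
        object.__setattr__(self, "ids", ids)
        pos = {name: i for i, name in enumerate(ids)}
        if len(pos) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate identifiers in index: {dupes[:5]}")
        object.__setattr__(self, "_pos", pos)

    def position(self, entity_id: str) -> int:
        try:
            return self._pos[entity_id]
        except KeyError:
            raise KeyError(f"unknown {self.role} identifier: {entity_id!r}") from None

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._pos


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary miRNA x drug association matrix with its entity indices."""

    A: np.ndarray
    row_index: EntityIndex
    col_index: EntityIndex

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if A.ndim != 2:
            raise DataError("association matrix must be 2-D")
        if not np.isin(A, (0, 1)).all():
            raise DataError("association matrix entries must be 0 or 1")
        if A.shape != (len(self.row_index), len(self.col_index)):
            raise DataError(
                f"matrix shape {A.shape} does not match indices "
                f"({len(self.row_index)}, {len(self.col_index)})"
            )
        if self.row_index.role != ROLE_MIRNA or self.col_index.role != ROLE_DRUG:
            raise DataError("rows must be indexed by miRNAs and columns by drugs")
        object.__setattr__(self, "A", A.astype(np.int8))

    @property
    def nm(self) -> int:
        return len(self.row_index)

    @property
    def nd(self) -> int:
        return len(self.col_index)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix bound to one entity type.

    ``kind`` labels the provenance of the scores: ``"GIP"`` (Gaussian
    interaction-profile kernel), ``"sequence"``, ``"chemical"`` or
    ``"fused"``.
    """

    S: np.ndarray
    index: EntityIndex
    kind: str

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        n = len(self.index)
        if S.shape != (n, n):
            raise DataError(f"similarity matrix shape {S.shape} != ({n}, {n})")
        if np.abs(S - S.T).max(initial=0.0) > 1e-12:
            raise DataError("similarity matrix is not symmetric within 1e-12")
        if S.size and (S.min() < -1e-12 or S.max() > 1 + 1e-12):
            raise DataError("similarity entries must lie in [0, 1]")
        if self.kind in _UNIT_DIAG_KINDS and n and np.abs(np.diag(S) - 1).max() > 1e-12:
            raise DataError(f"{self.kind} similarity must have unit diagonal")
        object.__setattr__(self, "S", np.clip(S, 0.0, 1.0))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_HEADER_MIRNA = {"mirna", "mirna_id", "microrna", "mir"}
_HEADER_DRUG = {"drug", "drug_id", "compound"}


def load_associations(path: str | Path) -> AssociationMatrix:
    """Read a two-column (miRNA, drug) edge list TSV into a binary matrix.

    Lines starting with ``#`` and blank lines are skipped; an optional
    header line (column names like ``miRNA_id``/``drug_id``) is detected and
    dropped.  Duplicate pairs are collapsed (count logged).  Identifiers are
    sorted lexicographically to fix the matrix layout.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise DataError(f"{path}:{lineno}: expected 2 tab-separated fields, got {line!r}")
            a, b = fields[0].strip(), fields[1].strip()
            if not edges and a.lower() in _HEADER_MIRNA and b.lower() in _HEADER_DRUG:
                continue  # header line
            edges.append((a, b))
    if not edges:
        raise DataError(f"{path}: no association records found")

    unique = set(edges)
    n_dup = len(edges) - len(unique)
    if n_dup:
        logger.info("%s: collapsed %d duplicate association(s)", path, n_dup)

    mirnas = EntityIndex(tuple(sorted({m for m, _ in unique})), ROLE_MIRNA)
    drugs = EntityIndex(tuple(sorted({d for _, d in unique})), ROLE_DRUG)
    A = np.zeros((len(mirnas), len(drugs)), dtype=np.int8)
    for m, d in unique:
        A[mirnas.position(m), drugs.position(d)] = 1
    return AssociationMatrix(A, mirnas, drugs)


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write an association matrix back to the edge-list TSV format."""
    path = Path(path)
    rows, cols = np.nonzero(assoc.A)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# miRNA_id\tdrug_id\n")
        for i, j in zip(rows, cols):
            fh.write(f"{assoc.row_index.ids[i]}\t{assoc.col_index.ids[j]}\n")


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read miRNA sequences from FASTA, keyed by the first header token.

    Sequences are upper-cased and DNA-style T is normalized to U so
    miRBase-style RNA and DNA inputs agree.  Duplicate identifiers and
    empty sequences are errors.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise DataError(f"{path}: duplicate FASTA identifier {record.id!r}")
        seq = str(record.seq).upper().replace("T", "U")
        if not seq:
            raise DataError(f"{path}: empty sequence for {record.id!r}")
        seqs[record.id] = seq
    if not seqs:
        raise DataError(f"{path}: no FASTA records found")
    return seqs


def load_similarity_matrix(
    path: str | Path, index: EntityIndex, kind: str = "chemical"
) -> SimilarityMatrix:
    """Read a dense similarity TSV and align it to ``index`` order.

    The file must have an identifier header row and column covering a
    subset of ``index``.  Entities absent from the file get 0 off-diagonal
    and 1 on the diagonal.  Small asymmetries (<= 1e-8) are silently
    averaged out; larger ones are warned about and averaged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise DataError(f"{path}: row and column identifier sets differ")
    unknown = [i for i in df.index if i not in index]
    if unknown:
        raise DataError(f"{path}: identifiers not in index: {unknown[:5]}")

    S = df.to_numpy(dtype=float)
    if S.size and (S.min() < -1e-8 or S.max() > 1 + 1e-8):
        raise DataError(f"{path}: similarity values outside [0, 1]")
    asym = np.abs(S - S.T).max(initial=0.0)
    if asym > 1e-8:
        logger.warning("%s: asymmetry %.3g exceeds 1e-8; symmetrizing as (S+S^T)/2", path, asym)
    S = (S + S.T) / 2.0

    full = np.eye(len(index))
    pos = [index.position(i) for i in df.index]
    full[np.ix_(pos, pos)] = S
    np.fill_diagonal(full, 1.0)
    return SimilarityMatrix(np.clip(full, 0.0, 1.0), index, kind)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as dense TSV with identifier headers."""
    pd.DataFrame(sim.S, index=list(sim.index.ids), columns=list(sim.index.ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def write_predictions(
    records: Iterable[tuple[str, str, float, int]] | np.ndarray,
    path: str | Path,
    assoc: AssociationMatrix | None = None,
) -> None:
    """Write ranked prediction scores as TSV.

    ``records`` is either an iterable of ``(miRNA_id, drug_id, score,
    known_label)`` tuples, or a full nm x nd score matrix together with the
    ``assoc`` whose indices and entries supply identifiers and labels.
    Rows are sorted by score descending, ties broken by (miRNA_id, drug_id).
    """
    if isinstance(records, np.ndarray):
        if assoc is None:
            raise DataError("a score matrix requires the association matrix for labels")
        if records.shape != assoc.A.shape:
            raise DataError(f"score matrix shape {records.shape} != {assoc.A.shape}")
        rows = [
            (assoc.row_index.ids[i], assoc.col_index.ids[j], float(records[i, j]), int(assoc.A[i, j]))
            for i in range(assoc.nm)
            for j in range(assoc.nd)
        ]
    else:
        rows = [(str(m), str(d), float(s), int(l)) for m, d, s, l in records]

    if any(not math.isfinite(s) for _, _, s, _ in rows):
        raise DataError("prediction scores must be finite")
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("miRNA_id\tdrug_id\tscore\tknown_label\n")
        for m, d, s, l in rows:
            fh.write(f"{m}\t{d}\t{s:.10g}\t{l}\n")
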