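"""HeteSim meta-path relevance between miRNA-drug pairs.

A meta-path is a sequence of node types over the alphabet {M, D}
constraining walks through the heterogeneous network; here all paths start
at a miRNA, end at a drug, and have length (edge count) 2..4, which gives
14 distinct paths.  Each edge type has a row-stochastic relation matrix:
I_MD and I_DM are the row-normalized association matrix and its transpose,
I_MM and I_DD the row-normalized similarity networks.

The HeteSim score of a pair (m_a, d_b) along path rho splits the path at
its midpoint: the relevance is the cosine between row ``a`` of the left
half's reachability matrix and row ``b`` of the *reversed* right half's
reachability matrix (both end at the midpoint type, so the vectors are
commensurate).  Odd-length paths have no central node; the two scores from
the two admissible split points are averaged.  All relation matrices are
nonnegative, so every score lies in [0, 1].
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import reduce
from pathlib import Path

import numpy as np

from .netdata import DataError, AssociationMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_MAX_LEN = 4


@dataclass(frozen=True)
class MetaPath:
    """Typed node sequence from miRNA to drug, e.g. ``MDD``."""

    nodes: str

    def __post_init__(self) -> None:
        if not set(self.nodes) <= {"M", "D"}:
            raise DataError(f"meta-path nodes must be M or D, got {self.nodes!r}")
        if not (self.nodes.startswith("M") and self.nodes.endswith("D")):
            raise DataError(f"meta-path must run miRNA -> drug, got {self.nodes!r}")
        if not 2 <= self.length <= 4:
            raise DataError(f"meta-path length must be in [2, 4], got {self.length}")

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.nodes) - 1

    @property
    def name(self) -> str:
        return self.nodes


@dataclass(frozen=True)
class RelationMatrices:
    """Row-stochastic single-step transition matrices per edge type."""

    I_MM: np.ndarray
    I_MD: np.ndarray
    I_DD: np.ndarray
    I_DM: np.ndarray

    def for_edge(self, src: str, dst: str) -> np.ndarray:
        return {"MM": self.I_MM, "MD": self.I_MD, "DD": self.I_DD, "DM": self.I_DM}[src + dst]


@dataclass(frozen=True)
class HeteSimFeatures:
    """nm x nd x P score tensor with the canonical meta-path order."""

    scores: np.ndarray
    path_order: tuple[MetaPath, ...]

    @property
    def n_paths(self) -> int:
        return len(self.path_order)


def _row_normalize(M: np.ndarray, context: str) -> np.ndarray:
    sums = M.sum(axis=1, keepdims=True)
    zero = (sums == 0).ravel()
    if zero.any():
        logger.warning("%s: %d all-zero row(s) left as zero", context, int(zero.sum()))
    out = np.zeros_like(M, dtype=float)
    np.divide(M, sums, out=out, where=sums > 0)
    return out


def relation_matrices(
    assoc: AssociationMatrix, SM: SimilarityMatrix, SD: SimilarityMatrix
) -> RelationMatrices:
    """Row-normalize A, A^T, SM and SD into single-step relation matrices."""
    A = assoc.A.astype(float)
    return RelationMatrices(
        I_MM=_row_normalize(SM.S, "I_MM"),
        I_MD=_row_normalize(A, "I_MD"),
        I_DD=_row_normalize(SD.S, "I_DD"),
        I_DM=_row_normalize(A.T, "I_DM"),
    )


def enumerate_metapaths(max_len: int = DEFAULT_MAX_LEN) -> list[MetaPath]:
    """All miRNA -> drug meta-paths with 2 <= length <= max_len.

    Canonical order: by length ascending, then lexicographic with M < D,
    so trained models using this feature order are portable.  At
    max_len=4 there are 2 + 4 + 8 = 14 paths.
    """
    if max_len < 2:
        raise DataError(f"max_len must be >= 2, got {max_len}")
    order = {"M": 0, "D": 1}
    paths: list[MetaPath] = []
    for length in range(2, max_len + 1):
        interiors = sorted(
            itertools.product("MD", repeat=length - 1),
            key=lambda nodes: [order[n] for n in nodes],
        )
        paths.extend(MetaPath("M" + "".join(mid) + "D") for mid in interiors)
    return paths


def path_matrix(path: MetaPath | str, R: RelationMatrices) -> np.ndarray:
    """Reachability matrix: ordered product of the path's relation matrices."""
    nodes = path.nodes if isinstance(path, MetaPath) else path
    return path_matrix_seq(nodes, R)


def _split_scores(nodes: str, split: int, R: RelationMatrices) -> np.ndarray:
    """Cosine scores for one split point (``split`` = node count of the left half)."""
    left = nodes[:split]
    right = nodes[split - 1 :]
    L = path_matrix_seq(left, R)
    Rrev = path_matrix_seq(right[::-1], R)
    num = L @ Rrev.T
    ln = np.linalg.norm(L, axis=1)
    rn = np.linalg.norm(Rrev, axis=1)
    denom = np.outer(ln, rn)
    out = np.zeros_like(num)
    np.divide(num, denom, out=out, where=denom > 0)
    return np.clip(out, 0.0, 1.0)


def path_matrix_seq(nodes: str, R: RelationMatrices) -> np.ndarray:
    """Reachability product for an arbitrary node-type sequence (any endpoints)."""
    if len(nodes) < 2:
        raise DataError("a path needs at least one edge")
    return reduce(np.matmul, (R.for_edge(a, b) for a, b in zip(nodes, nodes[1:])))


def hetesim_scores(path: MetaPath | str, R: RelationMatrices) -> np.ndarray:
    """nm x nd HeteSim relevance matrix for one meta-path.

    Even length: single midpoint split.  Odd length: average of the two
    split-point scores (node counts (l+1)/2 and (l+3)/2 on the left).
    Pairs whose left or reversed-right reachability row is all zero score 0.
    """
    nodes = path.nodes if isinstance(path, MetaPath) else MetaPath(path).nodes
    l = len(nodes) - 1
    if l % 2 == 0:
        return _split_scores(nodes, l // 2 + 1, R)
    s1 = _split_scores(nodes, (l + 1) // 2, R)
    s2 = _split_scores(nodes, (l + 3) // 2, R)
    return (s1 + s2) / 2.0


def hetesim_features(
    assoc: AssociationMatrix,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    max_len: int = DEFAULT_MAX_LEN,
) -> HeteSimFeatures:
    """Stack HeteSim score matrices over all meta-paths in canonical order."""
    R = relation_matrices(assoc, SM, SD)
    paths = enumerate_metapaths(max_len)
    scores = np.stack([hetesim_scores(p, R) for p in paths], axis=2)
    return HeteSimFeatures(scores=scores, path_order=tuple(paths))


def write_hetesim_long(
    feats: HeteSimFeatures, assoc: AssociationMatrix, path: str | Path
) -> None:
    """Export the feature tensor as long-format TSV (miRNA, drug, path, score)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("miRNA_id\tdrug_id\tpath_name\tscore\n")
        for i, m in enumerate(assoc.row_index.ids):
            for j, d in enumerate(assoc.col_index.ids):
                for k, p in enumerate(feats.path_order):
                    fh.write(f"{m}\t{d}\t{p.name}\t{feats.scores[i, j, k]:.10g}\n")
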