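"""Similarity networks: GIP kernel, sequence similarity, and fusion.

Three sources of pairwise similarity feed the heterogeneous network:

* **Gaussian interaction-profile (GIP) kernel** similarity, computed from
  the rows (miRNAs) or columns (drugs) of the binary association matrix:
  ``GSM(i, j) = exp(-delta_m * ||A(i,:) - A(j,:)||^2)`` with the bandwidth
  ``delta_m = delta'_m / mean_i ||A(i,:)||^2`` normalized by the mean
  squared profile norm.
* **Sequence similarity** between miRNAs, ``1 - d(i, j) / (len_i + len_j)``
  where ``d`` is the unit-cost Levenshtein edit distance.
* **Chemical-structure similarity** between drugs, consumed as a
  precomputed matrix (see :func:`mdrlink.netdata.load_similarity_matrix`).

Sequence (resp. chemical) similarity is the primary signal and the GIP
kernel the fallback: the fused network takes the primary value wherever it
is nonzero and the GIP value elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import edlib
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .netdata import DataError, EntityIndex, AssociationMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GipParams:
    """Bandwidth prime delta' of the GIP kernel (per entity type)."""

    bandwidth_prime: float = 1.0

    def __post_init__(self) -> None:
        if self.bandwidth_prime <= 0:
            raise DataError("GIP bandwidth prime must be positive")


def gip_similarity(
    assoc: AssociationMatrix, axis: str, params: GipParams = GipParams()
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel similarity over one entity type.

    ``axis="miRNA"`` uses rows of A (profiles over drugs); ``axis="drug"``
    uses columns.  The bandwidth is ``delta'`` divided by the mean squared
    norm of the interaction profiles, so an all-zero association matrix is
    an error (undefined bandwidth).
    """
    if axis == "miRNA":
        profiles = assoc.A.astype(float)
        index = assoc.row_index
    elif axis == "drug":
        profiles = assoc.A.T.astype(float)
        index = assoc.col_index
    else:
        raise DataError(f"axis must be 'miRNA' or 'drug', got {axis!r}")

    mean_sq_norm = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq_norm == 0.0:
        raise DataError("association matrix has no interactions; GIP bandwidth undefined")
    delta = params.bandwidth_prime / mean_sq_norm

    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    S = np.exp(-delta * sq_dists)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    return SimilarityMatrix(S, index, "GIP")


def levenshtein_distance(s1: str, s2: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute) between sequences."""
    if not s1 or not s2:
        return len(s1) + len(s2)
    return int(edlib.align(s1, s2, task="distance")["editDistance"])


def sequence_similarity(
    seqs: Mapping[str, str], index: EntityIndex
) -> SimilarityMatrix:
    """Length-normalized edit similarity ``1 - d(i,j)/(len_i + len_j)``.

    The normalization bounds every value in [0, 1].  Index entries with no
    sequence get zero similarity to everything (diagonal stays 1) and are
    logged; the GIP fallback covers them at fusion time.  A pair of empty
    sequences would be 0/0 and is defined as similarity 0 with a warning.
    """
    n = len(index)
    S = np.eye(n)
    present = [i for i, name in enumerate(index.ids) if name in seqs]
    missing = [name for name in index.ids if name not in seqs]
    if missing:
        logger.info(
            "%d of %d identifiers have no sequence; their similarity rows are zero",
            len(missing), n,
        )
    for a_pos, i in enumerate(present):
        si = seqs[index.ids[i]]
        for j in present[a_pos + 1 :]:
            sj = seqs[index.ids[j]]
            total = len(si) + len(sj)
            if total == 0:
                logger.warning("both sequences empty for (%s, %s); similarity set to 0",
                               index.ids[i], index.ids[j])
                val = 0.0
            else:
                val = 1.0 - levenshtein_distance(si, sj) / total
            S[i, j] = S[j, i] = val
    return SimilarityMatrix(S, index, "sequence")


def integrate_similarity(
    primary: SimilarityMatrix, fallback: SimilarityMatrix
) -> SimilarityMatrix:
    """Fuse two similarity networks: primary where nonzero, else fallback.

    Used with (sequence, GIP) for miRNAs and (chemical, GIP) for drugs.
    The diagonal is forced to 1.  Idempotent when the primary matrix has
    no off-diagonal zeros.
    """
    if primary.index.ids != fallback.index.ids or primary.index.role != fallback.index.role:
        raise DataError("cannot fuse similarity matrices with different indices")
    S = np.where(primary.S != 0.0, primary.S, fallback.S)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, primary.index, "fused")
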