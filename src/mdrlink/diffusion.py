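"""Inclined random-walk-with-restart diffusion features and SVD reduction.

Each drug ``d_x`` (resp. miRNA ``m_y``) acts as a *walker* that roams the
miRNA (resp. drug) similarity network.  The walk is "inclined": the
transition matrix is biased, per walker, toward nodes whose *group weight*
ties them to the walker.  The group of a drug is the set of miRNAs it is
associated with; the group weight ``W_MM(d_i, m_j)`` is the similarity mass
from that group to ``m_j``, max-normalized over drugs (and symmetrically
for ``W_DD``).

For walker ``d_x`` the unnormalized transition score from ``m_i`` to
``m_j`` is ``W_DD(m_j, d_x)`` when positive (the incline) and
``SM(m_i, m_j)`` otherwise; column normalization then makes the matrix
column-stochastic, so propagation ``P_{t+1} = (1-r) T P_t + r P0``
conserves probability mass.  The stationary vectors of all walkers are
stacked into the diffusion feature matrices ``P_D`` (nd x nm) and ``P_M``
(nm x nd), then reduced to ``d`` dimensions by a truncated SVD embedding
``X = U_d * Sigma_d^(1/2)``.

Per-walker transition matrices are built lazily, one at a time, so peak
storage is O(nm^2 + nd^2) regardless of the number of walkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .netdata import DataError, AssociationMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_RESTART = 0.7
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    """Restart walk failed to converge; carries the last L1 residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class HetNet:
    """Heterogeneous adjacency [[SM, A], [A^T, SD]] with components retained."""

    G: np.ndarray
    SM: np.ndarray
    SD: np.ndarray
    A: np.ndarray


@dataclass(frozen=True)
class GroupWeights:
    """Group weight matrices W_MM (nd x nm) and W_DD (nm x nd)."""

    W_MM: np.ndarray
    W_DD: np.ndarray


@dataclass(frozen=True)
class DiffusionFeatures:
    """Stationary walk distributions and their SVD reductions.

    Row ``x`` of ``P_D`` is the stationary distribution over miRNAs of drug
    walker ``d_x``; row ``y`` of ``P_M`` the distribution over drugs of
    miRNA walker ``m_y``.  ``X_D``/``X_M`` are the d-dimensional truncated
    SVD embeddings (None until :meth:`reduced` is called).
    """

    P_D: np.ndarray
    P_M: np.ndarray
    r: float
    X_D: np.ndarray | None = None
    X_M: np.ndarray | None = None
    d: int | None = None

    def reduced(self, d: int) -> "DiffusionFeatures":
        """Return a copy with X_D and X_M set to the d-dim SVD embeddings."""
        return replace(self, X_D=svd_reduce(self.P_D, d), X_M=svd_reduce(self.P_M, d), d=d)


def build_hetnet(
    assoc: AssociationMatrix, SM: SimilarityMatrix, SD: SimilarityMatrix
) -> HetNet:
    """Assemble the (nm+nd) x (nm+nd) heterogeneous adjacency matrix."""
    A = assoc.A.astype(float)
    nm, nd = A.shape
    if SM.S.shape != (nm, nm) or SD.S.shape != (nd, nd):
        raise DataError(
            f"similarity shapes {SM.S.shape}, {SD.S.shape} do not match association {A.shape}"
        )
    G = np.block([[SM.S, A], [A.T, SD.S]])
    return HetNet(G=G, SM=SM.S, SD=SD.S, A=A)


def group_weights(
    assoc: AssociationMatrix, SM: SimilarityMatrix, SD: SimilarityMatrix
) -> GroupWeights:
    """Similarity mass from each entity's association group, max-normalized.

    ``W_MM(d_i, m_j)`` sums ``SM(m_k, m_j)`` over the miRNAs ``m_k``
    associated with drug ``d_i``, then divides each column (fixed ``m_j``)
    by its maximum over drugs; columns that are entirely zero stay zero.
    ``W_DD`` is the mirror construction through ``SD``.  Drugs or miRNAs
    with empty groups yield all-zero rows.
    """
    A = assoc.A.astype(float)
    group_mm = A.T @ SM.S  # (nd, nm): mass from DM(d_i) to m_j
    group_dd = A @ SD.S    # (nm, nd): mass from DD(m_j) to d_i
    return GroupWeights(W_MM=_max_normalize_columns(group_mm),
                        W_DD=_max_normalize_columns(group_dd))


def _max_normalize_columns(M: np.ndarray) -> np.ndarray:
    col_max = M.max(axis=0)
    out = np.zeros_like(M)
    nz = col_max > 0
    out[:, nz] = M[:, nz] / col_max[nz]
    return out


def _column_normalize(ST: np.ndarray, context: str) -> np.ndarray:
    sums = ST.sum(axis=0)
    zero = sums == 0
    if zero.any():
        logger.warning("%s: %d all-zero column(s) left as zero", context, int(zero.sum()))
    T = np.zeros_like(ST)
    T[:, ~zero] = ST[:, ~zero] / sums[~zero]
    return T


def walker_transition_m(
    SM: SimilarityMatrix, W_DD: np.ndarray, walker_drug: int
) -> np.ndarray:
    """Column-stochastic nm x nm transition matrix for drug walker ``d_x``.

    Column ``j`` is constant ``W_DD(m_j, d_x)`` whenever that weight is
    positive (incline toward miRNAs tied to the walker), else falls back to
    the similarity column ``SM(:, m_j)``; columns are then normalized to
    sum to 1 (all-zero columns stay zero with a warning).
    """
    incline = W_DD[:, walker_drug]  # (nm,) indexed by target m_j
    ST = np.where(incline[None, :] > 0, incline[None, :], SM.S)
    return _column_normalize(ST, f"walker_transition_m(d_{walker_drug})")


def walker_transition_d(
    SD: SimilarityMatrix, W_MM: np.ndarray, walker_mirna: int
) -> np.ndarray:
    """Column-stochastic nd x nd transition matrix for miRNA walker ``m_y``."""
    incline = W_MM[:, walker_mirna]  # (nd,) indexed by target d_j
    ST = np.where(incline[None, :] > 0, incline[None, :], SD.S)
    return _column_normalize(ST, f"walker_transition_d(m_{walker_mirna})")


def restart_walk(
    T: np.ndarray,
    P0: np.ndarray,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Iterate ``P <- (1-r) T P + r P0`` to the stationary distribution.

    Convergence is an L1 change below ``tol``.  The contraction factor is
    (1-r), so r near 1 converges almost immediately; r=1 returns P0.
    """
    if not 0 < r <= 1:
        raise DataError(f"restart probability must be in (0, 1], got {r}")
    P0 = np.asarray(P0, dtype=float)
    if abs(P0.sum() - 1.0) > 1e-8:
        raise DataError("initial vector must sum to 1")
    P = P0.copy()
    for _ in range(max_iter):
        P_next = (1.0 - r) * (T @ P) + r * P0
        residual = float(np.abs(P_next - P).sum())
        P = P_next
        if residual < tol:
            return P
    raise ConvergenceError(
        f"restart walk did not converge in {max_iter} iterations (residual {residual:.3g})",
        residual,
    )


def diffusion_features(
    assoc: AssociationMatrix,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> DiffusionFeatures:
    """Run every walker's inclined restart walk and stack the stationaries.

    Drug walker ``d_x`` restarts uniformly over the miRNAs associated with
    it; miRNA walkers mirror this over drugs.  An entity with no
    associations gets a uniform restart over all nodes (warned), keeping
    its feature row a valid distribution.
    """
    A = assoc.A.astype(float)
    nm, nd = A.shape
    gw = group_weights(assoc, SM, SD)

    P_D = np.empty((nd, nm))
    for x in range(nd):
        P_D[x] = restart_walk(
            walker_transition_m(SM, gw.W_DD, x), _restart_vector(A[:, x], f"drug {x}"),
            r=r, tol=tol, max_iter=max_iter,
        )
    P_M = np.empty((nm, nd))
    for y in range(nm):
        P_M[y] = restart_walk(
            walker_transition_d(SD, gw.W_MM, y), _restart_vector(A[y, :], f"miRNA {y}"),
            r=r, tol=tol, max_iter=max_iter,
        )
    return DiffusionFeatures(P_D=P_D, P_M=P_M, r=r)


def _restart_vector(profile: np.ndarray, context: str) -> np.ndarray:
    total = profile.sum()
    if total == 0:
        logger.warning("%s has no associations; uniform restart vector used", context)
        return np.full(profile.shape, 1.0 / profile.size)
    return profile / total


def svd_reduce(P: np.ndarray, d: int) -> np.ndarray:
    """Truncated-SVD embedding ``X = U_d Sigma_d^(1/2)`` of a feature matrix.

    Singular values are taken in descending order; if rank(P) < d the
    missing columns are zero so the embedding width is always exactly
    ``d``.  Each left singular vector's sign is canonicalized (largest-
    magnitude entry positive) to make the embedding deterministic.
    """
    if d < 1:
        raise DataError(f"reduced dimension must be >= 1, got {d}")
    P = np.asarray(P, dtype=float)
    U, s, _ = np.linalg.svd(P, full_matrices=False)
    # rank cutoff relative to the largest singular value
    rank_tol = max(P.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > rank_tol).sum())
    k = min(d, rank)
    X = np.zeros((P.shape[0], d))
    if k:
        Uk = U[:, :k]
        signs = np.sign(Uk[np.abs(Uk).argmax(axis=0), np.arange(k)])
        signs[signs == 0] = 1.0
        X[:, :k] = Uk * signs * np.sqrt(s[:k])
    if rank < d:
        logger.info("svd_reduce: rank %d < d=%d; %d zero column(s) padded", rank, d, d - rank)
    return X
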