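import logging

import numpy as np
import pytest

from mdrlink.netdata import (
    AssociationMatrix,
    EntityIndex,
    SimilarityMatrix,
    ROLE_DRUG,
    ROLE_MIRNA,
)


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("mdrlink").setLevel(logging.WARNING)


def make_assoc(A):
    """AssociationMatrix from a literal matrix, with generated identifiers."""
    A = np.asarray(A)
    nm, nd = A.shape
    return AssociationMatrix(
        A,
        EntityIndex(tuple(f"m{i:02d}" for i in range(nm)), ROLE_MIRNA),
        EntityIndex(tuple(f"d{j:02d}" for j in range(nd)), ROLE_DRUG),
    )


def make_sim(S, role=ROLE_MIRNA, kind="fused"):
    """SimilarityMatrix from a literal matrix, with generated identifiers."""
    S = np.asarray(S, dtype=float)
    prefix = "m" if role == ROLE_MIRNA else "d"
    index = EntityIndex(tuple(f"{prefix}{i:02d}" for i in range(S.shape[0])), role)
    return SimilarityMatrix(S, index, kind)


def random_network(rng, nm, nd, density=0.4):
    """Random binary association matrix guaranteed nonzero per row/column."""
    A = (rng.random((nm, nd)) < density).astype(int)
    for i in np.flatnonzero(A.sum(axis=1) == 0):
        A[i, rng.integers(nd)] = 1
    for j in np.flatnonzero(A.sum(axis=0) == 0):
        A[rng.integers(nm), j] = 1
    return A


def random_similarity(rng, n):
    """Random symmetric similarity matrix with unit diagonal, entries in (0, 1]."""
    S = rng.uniform(0.05, 1.0, size=(n, n))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return S


@pytest.fixture
def toy_assoc():
    # 4 miRNAs x 3 drugs with every row/column populated
    return make_assoc(
        [[1, 0, 1],
         [1, 1, 0],
         [0, 1, 0],
         [0, 0, 1]]
    )


@pytest.fixture
def toy_sims(toy_assoc):
    rng = np.random.default_rng(42)
    SM = make_sim(random_similarity(rng, toy_assoc.nm), ROLE_MIRNA)
    SD = make_sim(random_similarity(rng, toy_assoc.nd), ROLE_DRUG)
    return SM, SD
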