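"""Synthetic miRNA-drug networks with planted co-cluster structure.

The generator emulates the three real inputs of the pipeline — a
resistance edge list, miRNA sequences, and a drug chemical-similarity
matrix — with a shared planted signal: miRNAs and drugs are assigned
round-robin to k clusters, associations occur with probability ``p_in``
within a cluster and ``p_out`` across, sequences mutate away from one
prototype per cluster, and drug similarity is high (0.8) within and low
(0.2) between clusters plus noise.  Every feature family the pipeline
extracts (sequence, GIP, chemical, diffusion, HeteSim) therefore carries
the same recoverable cluster signal, which is what the end-to-end
cross-validation tests exercise.

Rows or columns left with no association get one forced within-cluster
edge (logged) so the GIP bandwidth normalization stays defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .netdata import (
    DataError,
    AssociationMatrix,
    EntityIndex,
    SimilarityMatrix,
    ROLE_DRUG,
    ROLE_MIRNA,
    write_associations,
    write_similarity_matrix,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class SimConfig:
    """Planted-structure generator settings (defaults = study conditions)."""

    n_mirna: int = 100
    n_drug: int = 60
    k_clusters: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    seq_len: int = 22
    mutation_rate: float = 0.1
    sim_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_in <= self.p_out:
            raise DataError("planted structure requires p_in > p_out")
        if self.k_clusters > min(self.n_mirna, self.n_drug):
            raise DataError("k_clusters cannot exceed min(n_mirna, n_drug)")
        if self.sim_noise < 0:
            raise DataError("sim_noise must be nonnegative")


@dataclass(frozen=True)
class ClusterLabels:
    """Cluster assignment of each miRNA and drug (round-robin)."""

    mirna: np.ndarray
    drug: np.ndarray


def _mirna_ids(n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"miR-{i:0{width}d}" for i in range(n))


def _drug_ids(n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"drug-{i:0{width}d}" for i in range(n))


def simulate_network(cfg: SimConfig) -> tuple[AssociationMatrix, ClusterLabels]:
    """Planted bipartite association matrix: P(edge) = p_in within cluster."""
    rng = np.random.default_rng(cfg.seed)
    m_lab = np.arange(cfg.n_mirna) % cfg.k_clusters
    d_lab = np.arange(cfg.n_drug) % cfg.k_clusters
    same = m_lab[:, None] == d_lab[None, :]
    prob = np.where(same, cfg.p_in, cfg.p_out)
    A = (rng.random((cfg.n_mirna, cfg.n_drug)) < prob).astype(np.int8)

    # every entity needs >= 1 edge so GIP bandwidths stay defined
    n_forced = 0
    for i in np.flatnonzero(A.sum(axis=1) == 0):
        A[i, rng.choice(np.flatnonzero(d_lab == m_lab[i]))] = 1
        n_forced += 1
    for j in np.flatnonzero(A.sum(axis=0) == 0):
        A[rng.choice(np.flatnonzero(m_lab == d_lab[j])), j] = 1
        n_forced += 1
    if n_forced:
        logger.info("forced %d within-cluster edge(s) for empty rows/columns", n_forced)

    assoc = AssociationMatrix(
        A,
        EntityIndex(_mirna_ids(cfg.n_mirna), ROLE_MIRNA),
        EntityIndex(_drug_ids(cfg.n_drug), ROLE_DRUG),
    )
    return assoc, ClusterLabels(mirna=m_lab, drug=d_lab)


def simulate_sequences(labels: ClusterLabels, cfg: SimConfig) -> dict[str, str]:
    """Cluster-prototype sequences with per-position substitution noise.

    Each cluster gets one random prototype over {A, C, G, U}; each member
    copies it and substitutes each position, independently with
    probability ``mutation_rate``, by one of the three other bases.
    """
    if cfg.seq_len < 10:
        raise DataError("seq_len must be >= 10")
    rng = np.random.default_rng(cfg.seed + 1)
    protos = rng.integers(0, 4, size=(cfg.k_clusters, cfg.seq_len))
    seqs: dict[str, str] = {}
    for name, lab in zip(_mirna_ids(cfg.n_mirna), labels.mirna):
        seq = protos[lab].copy()
        hit = rng.random(cfg.seq_len) < cfg.mutation_rate
        # substitute with one of the 3 other bases so the rate is exact
        seq[hit] = (seq[hit] + rng.integers(1, 4, size=hit.sum())) % 4
        seqs[name] = "".join(_BASES[seq])
    return seqs


def simulate_drug_similarity(labels: ClusterLabels, cfg: SimConfig) -> SimilarityMatrix:
    """Block similarity 0.8 within / 0.2 between clusters plus uniform noise."""
    rng = np.random.default_rng(cfg.seed + 2)
    n = cfg.n_drug
    same = labels.drug[:, None] == labels.drug[None, :]
    S = np.where(same, 0.8, 0.2).astype(float)
    if cfg.sim_noise > 0:
        noise = rng.uniform(-cfg.sim_noise, cfg.sim_noise, size=(n, n))
        S += np.triu(noise, 1) + np.triu(noise, 1).T
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, EntityIndex(_drug_ids(n), ROLE_DRUG), "chemical")


def simulate_all(cfg: SimConfig) -> tuple[AssociationMatrix, dict[str, str], SimilarityMatrix, ClusterLabels]:
    """Convenience wrapper generating all three inputs plus labels."""
    assoc, labels = simulate_network(cfg)
    return assoc, simulate_sequences(labels, cfg), simulate_drug_similarity(labels, cfg), labels


def write_fixture(out_dir: str | Path, cfg: SimConfig) -> dict[str, Path]:
    """Emit the exact on-disk formats the readers consume, plus labels TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assoc, seqs, drug_sim, labels = simulate_all(cfg)

    paths = {
        "associations": out / "associations.tsv",
        "sequences": out / "mirna_sequences.fasta",
        "drug_similarity": out / "drug_similarity.tsv",
        "labels": out / "cluster_labels.tsv",
    }
    write_associations(assoc, paths["associations"])
    with paths["sequences"].open("w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    write_similarity_matrix(drug_sim, paths["drug_similarity"])
    with paths["labels"].open("w", encoding="utf-8") as fh:
        fh.write("entity_id\trole\tcluster\n")
        for name, lab in zip(assoc.row_index.ids, labels.mirna):
            fh.write(f"{name}\tmiRNA\t{lab}\n")
        for name, lab in zip(assoc.col_index.ids, labels.drug):
            fh.write(f"{name}\tdrug\t{lab}\n")
    return paths
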