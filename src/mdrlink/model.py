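"""Model/Results interface over the full prediction pipeline.

:class:`MirnaDrugResistanceModel` is constructed from the association
matrix plus the optional association-independent similarity inputs
(miRNA sequences, drug chemical similarity).  ``fit()`` extracts the
network features, samples negatives, trains the SVM and returns a
:class:`ResistanceResults` carrying the fitted model, the score matrix
over all miRNA-drug pairs, training diagnostics and a ``summary()``
table.  Cross-validation and leave-one-drug-out ranking are model-level
protocols because they refit the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .netdata import (
    AssociationMatrix,
    SimilarityMatrix,
    load_associations,
    load_fasta,
    load_similarity_matrix,
    write_predictions,
)
from .similarity import sequence_similarity
from .classifier import (
    DrugRanking,
    MetricsReport,
    ModelConfig,
    NetworkFeatures,
    PairDataset,
    PipelineConfig,
    TrainedModel,
    _features_from_network,
    compute_metrics,
    cross_validate,
    network_features,
    predict_scores,
    rank_drug_leave_out,
    sample_pairs,
    train_svm,
)
from .synthetic import SimConfig, simulate_all


class MirnaDrugResistanceModel:
    """miRNA-drug resistance link predictor on a heterogeneous network.

    Parameters
    ----------
    assoc
        Binary miRNA x drug association matrix.
    sequences
        Optional mapping miRNA id -> RNA sequence; enables the sequence
        similarity channel (GIP fallback covers missing ids).
    drug_similarity
        Optional precomputed chemical-structure similarity matrix.
    pipeline, config
        Feature-extraction and SVM settings.
    """

    def __init__(
        self,
        assoc: AssociationMatrix,
        sequences: Mapping[str, str] | None = None,
        drug_similarity: SimilarityMatrix | None = None,
        pipeline: PipelineConfig = PipelineConfig(),
        config: ModelConfig = ModelConfig(),
    ):
        self.assoc = assoc
        self.sequences = dict(sequences) if sequences else None
        self.seq_sim = (
            sequence_similarity(self.sequences, assoc.row_index)
            if self.sequences else None
        )
        self.drug_similarity = drug_similarity
        self.pipeline = pipeline
        self.config = config

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        associations: str | Path,
        fasta: str | Path | None = None,
        drug_similarity: str | Path | None = None,
        pipeline: PipelineConfig = PipelineConfig(),
        config: ModelConfig = ModelConfig(),
    ) -> "MirnaDrugResistanceModel":
        """Build the model from the on-disk formats (edge TSV, FASTA, TSV)."""
        assoc = load_associations(associations)
        seqs = load_fasta(fasta) if fasta else None
        dsim = (
            load_similarity_matrix(drug_similarity, assoc.col_index)
            if drug_similarity else None
        )
        return cls(assoc, seqs, dsim, pipeline=pipeline, config=config)

    @classmethod
    def from_synthetic(
        cls,
        sim_config: SimConfig = SimConfig(),
        pipeline: PipelineConfig = PipelineConfig(),
        config: ModelConfig = ModelConfig(),
    ) -> "MirnaDrugResistanceModel":
        """Build the model on a planted-structure synthetic network."""
        assoc, seqs, dsim, _ = simulate_all(sim_config)
        return cls(assoc, seqs, dsim, pipeline=pipeline, config=config)

    # -- estimation --------------------------------------------------------

    def fit(self, ratio: float = 3.0, seed: int = 0) -> "ResistanceResults":
        """Extract features, sample negatives, train the SVM."""
        nf = network_features(self.assoc, self.seq_sim, self.drug_similarity, self.pipeline)
        train = _features_from_network(
            sample_pairs(self.assoc, ratio=ratio, seed=seed), nf
        )
        trained = train_svm(train, self.config)
        return ResistanceResults(model=self, network=nf, train_data=train,
                                 trained=trained, seed=seed, ratio=ratio)

    def cross_validate(
        self, k: int = 10, ratio: float = 3.0, seed: int = 0, leakage_mode: str = "strict"
    ) -> MetricsReport:
        """Stratified k-fold CV; see :func:`mdrlink.classifier.cross_validate`."""
        return cross_validate(
            self.assoc, self.seq_sim, self.drug_similarity,
            cfg=self.config, pipeline=self.pipeline,
            k=k, ratio=ratio, seed=seed, leakage_mode=leakage_mode,
        )

    def rank_drug_leave_out(
        self, drug_id: str, ratio: float = 3.0, seed: int = 0, score_cutoff: float = 0.95
    ) -> DrugRanking:
        """Hold one drug out, retrain, rank all miRNAs against it."""
        return rank_drug_leave_out(
            self.assoc, drug_id, self.seq_sim, self.drug_similarity,
            cfg=self.config, pipeline=self.pipeline,
            ratio=ratio, seed=seed, score_cutoff=score_cutoff,
        )


@dataclass
class ResistanceResults:
    """Fitted pipeline: trained SVM, feature products and diagnostics."""

    model: MirnaDrugResistanceModel
    network: NetworkFeatures
    train_data: PairDataset
    trained: TrainedModel
    seed: int
    ratio: float
    _score_matrix: np.ndarray | None = field(default=None, repr=False)

    # -- prediction --------------------------------------------------------

    def predict(self, pairs: np.ndarray | None = None, score_mode: str | None = None) -> np.ndarray:
        """Scores for given (miRNA pos, drug pos) pairs, or all pairs if None."""
        if pairs is None:
            nm, nd = self.model.assoc.nm, self.model.assoc.nd
            pairs = np.column_stack(
                [np.repeat(np.arange(nm), nd), np.tile(np.arange(nd), nm)]
            )
        ds = _features_from_network(
            PairDataset(np.asarray(pairs, dtype=int), np.zeros(len(pairs), dtype=int)),
            self.network,
        )
        return predict_scores(self.trained, ds.features, score_mode=score_mode)

    def score_matrix(self) -> np.ndarray:
        """nm x nd matrix of calibrated scores for every miRNA-drug pair."""
        if self._score_matrix is None:
            nm, nd = self.model.assoc.nm, self.model.assoc.nd
            self._score_matrix = self.predict().reshape(nm, nd)
        return self._score_matrix

    def write_predictions(self, path: str | Path) -> None:
        """Ranked all-pairs prediction TSV (miRNA, drug, score, known label)."""
        write_predictions(self.score_matrix(), path, assoc=self.model.assoc)

    # -- diagnostics -------------------------------------------------------

    def training_metrics(self) -> dict[str, float]:
        """Apparent (resubstitution) metrics on the training pair sample."""
        scores = predict_scores(self.trained, self.train_data.features)
        threshold = 0.5 if self.trained.config.score_mode == "probability" else 0.0
        return compute_metrics(self.train_data.labels, scores, threshold=threshold)

    def summary(self) -> str:
        """Human-readable fit summary."""
        a = self.model.assoc
        m = self.training_metrics()
        pos = int(self.train_data.labels.sum())
        lines = [
            "miRNA-Drug Resistance SVM",
            "=" * 58,
            f"miRNAs: {a.nm}    drugs: {a.nd}    known associations: {a.n_associations}",
            f"training pairs: {len(self.train_data)} ({pos} positive, "
            f"{len(self.train_data) - pos} negative; ratio {self.ratio:g}, seed {self.seed})",
            f"feature width: {self.train_data.features.shape[1]} "
            f"(groups: {', '.join(self.model.pipeline.feature_groups)}; "
            f"d={self.model.pipeline.d}, max path len={self.model.pipeline.max_path_len})",
            f"restart probability r: {self.model.pipeline.r:g}",
            f"SVM: RBF kernel, C={self.trained.config.C:g}, "
            f"gamma={self.trained.gamma:.4g}, support vectors={len(self.trained.alpha)}",
            "-" * 58,
            "training (resubstitution) metrics:",
            "  " + "  ".join(f"{k.upper()}={v:.4f}" for k, v in m.items()),
            "=" * 58,
        ]
        return "\n".join(lines)
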