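"""Pair feature assembly, negative sampling, SVM training and evaluation.

Each candidate (miRNA, drug) pair is described by a 14 + 2d feature vector
(114 at the default d = 50): the 14 HeteSim meta-path scores, the d-dim
diffusion embedding of the drug (row of X_D) and of the miRNA (row of
X_M).  Known resistance associations are the positives; negatives are
drawn uniformly from the unknown pairs at a 3:1 negative:positive ratio.

The classifier is a soft-margin RBF-kernel SVM (penalty C = 64).  The
fitted model exposes its dual coefficients, support vectors and bias, so
the kernel decision function ``f(x) = sum_i alpha_i y_i K(x_i, x) + b``
can be evaluated directly and the dual feasibility conditions
(0 <= alpha_i <= C, sum_i alpha_i y_i = 0) can be checked.  Probability
scores come from a monotone sigmoid calibration of the decision values
fitted on the training data, so the two score modes rank identically.

Cross-validation supports two leakage modes: ``"paper"`` computes network
features once from the full association matrix before splitting (the
protocol many published link predictors use), while the default
``"strict"`` recomputes GIP similarities, diffusion and HeteSim features
per fold with the test fold's positive associations masked out of A.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .netdata import DataError, AssociationMatrix, SimilarityMatrix
from .similarity import GipParams, gip_similarity, integrate_similarity, sequence_similarity
from .diffusion import (
    DEFAULT_MAX_ITER,
    DEFAULT_RESTART,
    DEFAULT_TOL,
    DiffusionFeatures,
    diffusion_features,
)
from .hetesim import DEFAULT_MAX_LEN, HeteSimFeatures, hetesim_features

logger = logging.getLogger(__name__)

FEATURE_GROUPS = ("hetesim", "diffusion")


@dataclass(frozen=True)
class PipelineConfig:
    """Network feature extraction settings.

    r: restart probability of the inclined walks; d: SVD embedding
    dimension; max_path_len: longest HeteSim meta-path (14 paths at 4);
    bandwidth primes parameterize the GIP kernels.
    """

    r: float = DEFAULT_RESTART
    d: int = 50
    max_path_len: int = DEFAULT_MAX_LEN
    gip_mirna: GipParams = field(default_factory=GipParams)
    gip_drug: GipParams = field(default_factory=GipParams)
    feature_groups: tuple[str, ...] = FEATURE_GROUPS
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER

    def __post_init__(self) -> None:
        if not self.feature_groups:
            raise DataError("feature_groups must be nonempty")
        unknown = set(self.feature_groups) - set(FEATURE_GROUPS)
        if unknown:
            raise DataError(f"unknown feature groups: {sorted(unknown)}")

    @property
    def feature_width(self) -> int:
        width = 0
        if "hetesim" in self.feature_groups:
            width += sum(2 ** (l - 1) for l in range(2, self.max_path_len + 1))
        if "diffusion" in self.feature_groups:
            width += 2 * self.d
        return width


@dataclass(frozen=True)
class ModelConfig:
    """SVM settings: penalty C, RBF width rule, score mode, standardization."""

    C: float = 64.0
    kernel_gamma: float | str = "scale"
    score_mode: str = "probability"
    standardize: bool = True
    classifier_factory: Callable | None = None  # pluggable-classifier hook

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise DataError("penalty parameter C must be positive")
        if self.score_mode not in ("probability", "decision"):
            raise DataError(f"score_mode must be 'probability' or 'decision', got {self.score_mode!r}")


@dataclass
class PairDataset:
    """Labeled (miRNA position, drug position) pairs with optional features."""

    pairs: np.ndarray  # (n, 2) int
    labels: np.ndarray  # (n,) in {0, 1}
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.pairs.shape != (len(self.labels), 2):
            raise DataError("pairs must be (n, 2) matching labels length")
        seen = {tuple(p) for p in self.pairs}
        if len(seen) != len(self.pairs):
            raise DataError("duplicate pairs in dataset")

    def subset(self, idx: np.ndarray) -> "PairDataset":
        return PairDataset(
            self.pairs[idx], self.labels[idx],
            None if self.features is None else self.features[idx],
        )

    def __len__(self) -> int:
        return len(self.labels)


def sample_pairs(
    assoc: AssociationMatrix,
    ratio: float = 3.0,
    seed: int = 0,
    exclude_drugs: Sequence[int] = (),
) -> PairDataset:
    """All positive pairs plus floor(ratio * n_pos) uniform negatives.

    Negatives are drawn without replacement from the zero entries of A
    using ``seed``; if fewer zero cells exist than requested, all are taken
    with a warning.  ``exclude_drugs`` removes whole drug columns from both
    positives and negative candidates (used by leave-one-drug-out).
    """
    if ratio <= 0:
        raise DataError("negative:positive ratio must be positive")
    mask = np.ones(assoc.nd, dtype=bool)
    mask[list(exclude_drugs)] = False
    pos = np.argwhere((assoc.A == 1) & mask[None, :])
    neg_cand = np.argwhere((assoc.A == 0) & mask[None, :])
    if len(pos) == 0 or len(neg_cand) == 0:
        raise DataError("association matrix needs at least one positive and one zero entry")

    n_neg = math.floor(ratio * len(pos))
    rng = np.random.default_rng(seed)
    if n_neg > len(neg_cand):
        logger.warning(
            "requested %d negatives but only %d unknown pairs exist; taking all",
            n_neg, len(neg_cand),
        )
        n_neg = len(neg_cand)
    neg = neg_cand[rng.choice(len(neg_cand), size=n_neg, replace=False)]
    pairs = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(n_neg, dtype=int)])
    return PairDataset(pairs, labels)


# ---------------------------------------------------------------------------
# network feature extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkFeatures:
    """Per-network feature products: fused similarities, HeteSim, embeddings."""

    SM: SimilarityMatrix
    SD: SimilarityMatrix
    hetesim: HeteSimFeatures | None
    diffusion: DiffusionFeatures | None


def network_features(
    assoc: AssociationMatrix,
    seq_sim: SimilarityMatrix | None = None,
    drug_sim: SimilarityMatrix | None = None,
    cfg: PipelineConfig = PipelineConfig(),
) -> NetworkFeatures:
    """Build fused similarity networks and every requested feature family.

    GIP kernels are always recomputed from ``assoc`` (they depend on it);
    sequence and chemical similarities are association-independent inputs
    and may be precomputed once.  When absent, the GIP kernel alone serves
    as the similarity network.
    """
    GSM = gip_similarity(assoc, "miRNA", cfg.gip_mirna)
    GSD = gip_similarity(assoc, "drug", cfg.gip_drug)
    SM = integrate_similarity(seq_sim, GSM) if seq_sim is not None else GSM
    SD = integrate_similarity(drug_sim, GSD) if drug_sim is not None else GSD

    het = (
        hetesim_features(assoc, SM, SD, cfg.max_path_len)
        if "hetesim" in cfg.feature_groups else None
    )
    diff = None
    if "diffusion" in cfg.feature_groups:
        diff = diffusion_features(
            assoc, SM, SD, r=cfg.r, tol=cfg.tol, max_iter=cfg.max_iter
        ).reduced(cfg.d)
    return NetworkFeatures(SM=SM, SD=SD, hetesim=het, diffusion=diff)


def assemble_features(
    pairs: PairDataset | np.ndarray,
    H: HeteSimFeatures | None = None,
    X_M: np.ndarray | None = None,
    X_D: np.ndarray | None = None,
) -> PairDataset:
    """Per-pair feature rows [HeteSim scores | X_D row of drug | X_M row of miRNA].

    Width is (number of meta-paths) + 2d when both families are present;
    either family may be omitted for ablation runs.
    """
    if isinstance(pairs, PairDataset):
        ds = pairs
    else:
        pairs = np.asarray(pairs, dtype=int)
        ds = PairDataset(pairs, np.zeros(len(pairs), dtype=int))
    if H is None and (X_M is None or X_D is None):
        raise DataError("at least one feature family (HeteSim or diffusion) is required")

    i, j = ds.pairs[:, 0], ds.pairs[:, 1]
    blocks = []
    if H is not None:
        if i.size and (i.max() >= H.scores.shape[0] or j.max() >= H.scores.shape[1]):
            raise DataError("pair position out of range of HeteSim tensor")
        blocks.append(H.scores[i, j, :])
    if X_M is not None and X_D is not None:
        if i.size and (i.max() >= X_M.shape[0] or j.max() >= X_D.shape[0]):
            raise DataError("pair position out of range of diffusion embeddings")
        blocks.append(X_D[j])
        blocks.append(X_M[i])
    return PairDataset(ds.pairs, ds.labels, np.hstack(blocks))


def _features_from_network(ds: PairDataset, nf: NetworkFeatures) -> PairDataset:
    diff = nf.diffusion
    return assemble_features(
        ds,
        H=nf.hetesim,
        X_M=None if diff is None else diff.X_M,
        X_D=None if diff is None else diff.X_D,
    )


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Fitted SVM with scaler, sigmoid calibration, and exposed dual solution.

    ``dual_coef`` holds alpha_i * y_i for the support vectors (so the
    decision function is ``sum_i dual_coef_i K(sv_i, x) + intercept``);
    ``alpha`` are the nonnegative Lagrange multipliers themselves.
    """

    svc: SVC
    scaler: StandardScaler | None
    calibration: tuple[float, float]  # (slope, bias) of sigmoid on decision values
    config: ModelConfig
    feature_width: int

    @property
    def dual_coef(self) -> np.ndarray:
        return self.svc.dual_coef_.ravel()

    @property
    def alpha(self) -> np.ndarray:
        return np.abs(self.dual_coef)

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def intercept(self) -> float:
        return float(self.svc.intercept_[0])

    @property
    def gamma(self) -> float:
        return float(self.svc._gamma)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.feature_width:
            raise DataError(
                f"feature width {X.shape[-1] if X.ndim == 2 else '?'} "
                f"does not match training width {self.feature_width}"
            )
        return self.scaler.transform(X) if self.scaler is not None else X

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed margins of the kernel decision function."""
        return self.svc.decision_function(self._transform(X))

    def kernel_decision_function(self, X: np.ndarray) -> np.ndarray:
        """Evaluate sum_i alpha_i y_i K(x_i, x) + b explicitly from the duals."""
        Xs = self._transform(X)
        sv = self.support_vectors
        sq = ((Xs[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-self.gamma * sq)
        return K @ self.dual_coef + self.intercept


def train_svm(train: PairDataset, cfg: ModelConfig = ModelConfig()) -> TrainedModel:
    """Fit the soft-margin RBF SVM (dual problem with 0 <= alpha <= C).

    Features are optionally z-scored with training statistics.  A 1-D
    logistic sigmoid is fitted to the training decision values for the
    probability score mode; being monotone, it preserves the decision-value
    ranking exactly.
    """
    if train.features is None:
        raise DataError("training dataset has no assembled features")
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise DataError("training data must contain both classes")

    X = train.features.astype(float)
    scaler = None
    if cfg.standardize:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)

    if cfg.classifier_factory is not None:
        svc = cfg.classifier_factory()
    else:
        svc = SVC(C=cfg.C, kernel="rbf", gamma=cfg.kernel_gamma)
    svc.fit(X, train.labels)

    dec = svc.decision_function(X)
    lr = LogisticRegression(C=1e6).fit(dec.reshape(-1, 1), train.labels)
    slope, bias = float(lr.coef_[0, 0]), float(lr.intercept_[0])
    if slope <= 0:
        logger.warning("sigmoid calibration slope %.3g is not positive", slope)
    return TrainedModel(
        svc=svc, scaler=scaler, calibration=(slope, bias),
        config=cfg, feature_width=train.features.shape[1],
    )


def predict_scores(model: TrainedModel, features: np.ndarray, score_mode: str | None = None) -> np.ndarray:
    """Pair scores: calibrated probabilities in [0, 1] or raw signed margins."""
    mode = score_mode or model.config.score_mode
    dec = model.decision_function(features)
    if mode == "decision":
        return dec
    slope, bias = model.calibration
    return expit(slope * dec + bias)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Per-fold classification metrics and their arithmetic means."""

    folds: tuple[Mapping[str, float], ...]
    mean: Mapping[str, float]

    @classmethod
    def from_folds(cls, folds: Sequence[Mapping[str, float]]) -> "MetricsReport":
        keys = folds[0].keys()
        mean = {k: float(np.mean([f[k] for f in folds])) for k in keys}
        return cls(folds=tuple(dict(f) for f in folds), mean=mean)

    def to_json(self, path: str | Path) -> None:
        payload = {"folds": [dict(f) for f in self.folds], "mean": dict(self.mean)}
        Path(path).write_text(json.dumps(payload, indent=2))


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """AUC plus thresholded Recall/ACC/Pre/F1/MCC from the confusion counts.

    AUC is the probability that a random positive outranks a random
    negative, ties counting one half.  MCC is zero when any marginal of
    the confusion table is empty.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise DataError("metrics need both classes present")

    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())

    recall = tp / (tp + fn) if tp + fn else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den else 0.0

    ranks = rankdata(scores)  # mid-ranks handle ties as 1/2
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    return {"auc": float(auc), "acc": acc, "pre": pre, "recall": recall, "f1": f1, "mcc": mcc}


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------

def _mask_positives(assoc: AssociationMatrix, pairs: np.ndarray) -> AssociationMatrix:
    A = assoc.A.copy()
    A[pairs[:, 0], pairs[:, 1]] = 0
    return AssociationMatrix(A, assoc.row_index, assoc.col_index)


def cross_validate(
    assoc: AssociationMatrix,
    seq_sim: SimilarityMatrix | None = None,
    drug_sim: SimilarityMatrix | None = None,
    cfg: ModelConfig = ModelConfig(),
    pipeline: PipelineConfig = PipelineConfig(),
    k: int = 10,
    ratio: float = 3.0,
    seed: int = 0,
    leakage_mode: str = "strict",
) -> MetricsReport:
    """Stratified k-fold cross-validation of the full pipeline.

    ``leakage_mode="paper"`` extracts network features once from the full
    association matrix; ``"strict"`` re-extracts them for every fold with
    that fold's positive test associations zeroed out of A, so the
    classifier never sees information derived from the links it is asked
    to recover.
    """
    if k < 2:
        raise DataError(f"cross-validation needs k >= 2, got {k}")
    if leakage_mode not in ("strict", "paper"):
        raise DataError(f"leakage_mode must be 'strict' or 'paper', got {leakage_mode!r}")

    ds = sample_pairs(assoc, ratio=ratio, seed=seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))

    if leakage_mode == "paper":
        nf_full = network_features(assoc, seq_sim, drug_sim, pipeline)
        full = _features_from_network(ds, nf_full)

    folds = []
    for train_idx, test_idx in skf.split(ds.pairs, ds.labels):
        if leakage_mode == "paper":
            train, test = full.subset(train_idx), full.subset(test_idx)
        else:
            test_pos = ds.pairs[test_idx][ds.labels[test_idx] == 1]
            masked = _mask_positives(assoc, test_pos)
            nf = network_features(masked, seq_sim, drug_sim, pipeline)
            train = _features_from_network(ds.subset(train_idx), nf)
            test = _features_from_network(ds.subset(test_idx), nf)
        model = train_svm(train, cfg)
        scores = predict_scores(model, test.features)
        threshold = 0.5 if (cfg.score_mode == "probability") else 0.0
        folds.append(compute_metrics(test.labels, scores, threshold=threshold))
    return MetricsReport.from_folds(folds)


def rank_drug_leave_out(
    assoc: AssociationMatrix,
    drug_id: str,
    seq_sim: SimilarityMatrix | None = None,
    drug_sim: SimilarityMatrix | None = None,
    cfg: ModelConfig = ModelConfig(),
    pipeline: PipelineConfig = PipelineConfig(),
    ratio: float = 3.0,
    seed: int = 0,
    score_cutoff: float = 0.95,
) -> "DrugRanking":
    """Hold out one drug, retrain, and rank every miRNA against it.

    The drug's column is zeroed in A, its cells are excluded from the
    training pair sample, network features are recomputed from the masked
    matrix, and all nm miRNAs are scored against the held-out drug.
    """
    x = assoc.col_index.position(drug_id)
    masked = _mask_positives(
        assoc, np.column_stack([np.arange(assoc.nm), np.full(assoc.nm, x)])
    )
    nf = network_features(masked, seq_sim, drug_sim, pipeline)
    train = _features_from_network(
        sample_pairs(masked, ratio=ratio, seed=seed, exclude_drugs=[x]), nf
    )
    model = train_svm(train, cfg)

    query = np.column_stack([np.arange(assoc.nm), np.full(assoc.nm, x)])
    feats = _features_from_network(PairDataset(query, np.zeros(assoc.nm, dtype=int)), nf)
    scores = predict_scores(model, feats.features, score_mode="probability")

    order = sorted(
        range(assoc.nm), key=lambda i: (-scores[i], assoc.row_index.ids[i])
    )
    return DrugRanking(
        drug_id=drug_id,
        mirna_ids=tuple(assoc.row_index.ids[i] for i in order),
        scores=scores[order],
        known=assoc.A[order, x].astype(int),
        score_cutoff=score_cutoff,
    )


@dataclass(frozen=True)
class DrugRanking:
    """Descending ranking of all miRNAs against one held-out drug."""

    drug_id: str
    mirna_ids: tuple[str, ...]
    scores: np.ndarray
    known: np.ndarray  # 1 if the held-out association was originally present
    score_cutoff: float

    @property
    def above_cutoff(self) -> tuple[str, ...]:
        return tuple(
            m for m, s in zip(self.mirna_ids, self.scores) if s > self.score_cutoff
        )

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("rank\tmiRNA_id\tscore\tknown_label\tabove_cutoff\n")
            for rank, (m, s, l) in enumerate(zip(self.mirna_ids, self.scores, self.known), 1):
                fh.write(f"{rank}\t{m}\t{s:.10g}\t{int(l)}\t{int(s > self.score_cutoff)}\n")
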