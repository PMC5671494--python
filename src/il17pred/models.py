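"""Classifier training and application.

Two model families, parameterized the way the field's standard packages
expose them:

* **SVM** — soft-margin SVM with linear (t0), polynomial (t1) or RBF (t2)
  kernel. Kernels: linear ``x.y``; polynomial ``(x.y + 1)^d``; RBF
  ``exp(-g * ||x - y||^2)``. The trade-off constant ``c`` penalizes
  misclassified negatives; the cost factor ``j`` multiplies the penalty of
  training errors on positives (``C+ = j * c``), the conventional handle for
  class imbalance. Decision scores are raw (unsquashed) margin values.
* **RF** — random forest of ``ntree`` classification trees, each grown on a
  bootstrap sample with ``mtry`` features considered per split. The decision
  score is the fraction of trees voting positive, in [0, 1].

Features are fed to the SVM on the percent scale of the composition
equations, without standardization; an optional ``scale`` flag is available
but off by default. The default decision threshold is 0.5.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .dataio import EpitopeDataset, Peptide
from .features import (
    AAPWeights,
    FEATURE_DIM,
    FEATURE_KINDS,
    corpus_fingerprint,
    feature_matrix,
    train_aap_weights,
)

MODEL_FORMAT_VERSION = 1
DEFAULT_THRESHOLD = 0.5

KERNEL_NAMES = {"linear": "t0", "polynomial": "t1", "rbf": "t2"}


class ModelFormatError(ValueError):
    """Raised on unreadable, corrupted, or version-mismatched model files."""


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "polynomial"
    c: float = 1.0
    d: int = 2  # polynomial degree (t1 only)
    g: float = 0.005  # RBF gamma (t2 only)
    j: float = 1.0  # cost factor on positive-class training errors
    scale: bool = False  # optional feature standardization, off by default

    def __post_init__(self) -> None:
        if self.kernel not in KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.kernel!r}; use {list(KERNEL_NAMES)}")
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.kernel == "polynomial" and self.d < 1:
            raise ValueError("polynomial degree d must be >= 1")
        if self.kernel == "rbf" and self.g <= 0:
            raise ValueError("RBF gamma g must be > 0")
        if self.j < 0:
            raise ValueError("cost factor j must be >= 0")


@dataclass(frozen=True)
class RFConfig:
    ntree: int = 500
    mtry: int | None = None  # default floor(sqrt(dimension)) when unset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def resolved_mtry(self, dim: int) -> int:
        mtry = self.mtry if self.mtry is not None else int(np.sqrt(dim))
        if mtry > dim:
            raise ValueError(f"mtry={mtry} exceeds feature dimension {dim}")
        return mtry


@dataclass
class TrainedModel:
    """A fitted classifier plus the frozen feature pipeline that feeds it."""

    feature_kind: str
    family: str  # "SVM" or "RF"
    config: SVMConfig | RFConfig
    estimator: object
    threshold: float = DEFAULT_THRESHOLD
    aap_weights: AAPWeights | None = None
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None
    fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.feature_kind == "AAP" and self.aap_weights is None:
            raise ValueError("AAP models require trained AAP weights")

    def min_peptide_length(self) -> int:
        return 1 if self.feature_kind == "AAC" else 2


def _design_matrix(model: TrainedModel, peptides: Sequence[Peptide]) -> np.ndarray:
    X = feature_matrix(peptides, model.feature_kind, model.aap_weights)
    if model.scaler_mean is not None:
        X = (X - model.scaler_mean) / model.scaler_std
    return X


def _check_two_classes(train: EpitopeDataset) -> None:
    if not train.positives or not train.negatives:
        raise ValueError("training requires both classes non-empty")


def train_svm(
    train: EpitopeDataset,
    feature_kind: str = "DPC",
    config: SVMConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> TrainedModel:
    """Fit a soft-margin SVM on composition features of a labeled corpus.

    For AAP features, the dipeptide propensity weights are trained on
    ``train`` itself and frozen into the returned model.
    """
    _check_two_classes(train)
    config = config or SVMConfig()
    if feature_kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {feature_kind!r}")

    aap = train_aap_weights(train) if feature_kind == "AAP" else None
    X = feature_matrix(train.all_peptides(), feature_kind, aap)
    y = np.array(train.labels())

    mean = std = None
    if config.scale:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        X = (X - mean) / std

    if config.kernel == "linear":
        est = SVC(kernel="linear", C=config.c)
    elif config.kernel == "polynomial":
        # (x.y + 1)^d: gamma=1, coef0=1
        est = SVC(kernel="poly", degree=config.d, gamma=1.0, coef0=1.0, C=config.c)
    else:
        est = SVC(kernel="rbf", gamma=config.g, C=config.c)
    est.set_params(class_weight={1: config.j if config.j > 0 else 1e-12, 0: 1.0},
                   cache_size=500)
    est.fit(X, y)

    return TrainedModel(
        feature_kind=feature_kind,
        family="SVM",
        config=config,
        estimator=est,
        threshold=threshold,
        aap_weights=aap,
        scaler_mean=mean,
        scaler_std=std,
        fingerprint=corpus_fingerprint(train),
    )


def train_rf(
    train: EpitopeDataset,
    feature_kind: str = "DPC",
    config: RFConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> TrainedModel:
    """Fit a random forest; deterministic given ``config.seed``."""
    _check_two_classes(train)
    config = config or RFConfig()
    if feature_kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {feature_kind!r}")

    aap = train_aap_weights(train) if feature_kind == "AAP" else None
    X = feature_matrix(train.all_peptides(), feature_kind, aap)
    y = np.array(train.labels())
    mtry = config.resolved_mtry(X.shape[1])

    est = RandomForestClassifier(
        n_estimators=config.ntree,
        max_features=mtry,
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(X, y)

    return TrainedModel(
        feature_kind=feature_kind,
        family="RF",
        config=config,
        estimator=est,
        threshold=threshold,
        aap_weights=aap,
        fingerprint=corpus_fingerprint(train),
    )


def _rf_vote_matrix(est: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Per-tree hard votes, shape (ntree, n); entries in {0, 1}."""
    votes = np.array([tree.predict(X) for tree in est.estimators_])
    # trees predict class indices into est.classes_
    return np.array([est.classes_[v.astype(int)] for v in votes], dtype=float)


def decision_scores(
    model: TrainedModel, peptides: Sequence[Peptide], return_votes: bool = False
):
    """Raw decision score per peptide, order preserved.

    SVM scores are unbounded margin values; RF scores are vote fractions in
    [0, 1]. With ``return_votes`` (RF debug mode) also returns the per-tree
    vote matrix.
    """
    min_len = model.min_peptide_length()
    for pep in peptides:
        if len(pep) < min_len:
            raise ValueError(
                f"peptide {pep.id!r} shorter than {min_len} "
                f"(required by {model.feature_kind} features)"
            )
    if len(peptides) == 0:
        empty = np.empty(0)
        return (empty, np.empty((0, 0))) if return_votes else empty
    X = _design_matrix(model, peptides)
    if model.family == "SVM":
        scores = model.estimator.decision_function(X)
        return (scores, None) if return_votes else scores
    votes = _rf_vote_matrix(model.estimator, X)
    scores = votes.mean(axis=0)
    return (scores, votes) if return_votes else scores


def predict_labels(
    model: TrainedModel,
    peptides: Sequence[Peptide],
    threshold: float | None = None,
) -> list[dict]:
    """Classify peptides: label "inducer" iff score >= threshold.

    The threshold defaults to the model's stored cutoff; SVM thresholds are
    on the raw decision scale (they may be negative), RF thresholds on vote
    fractions.
    """
    thr = model.threshold if threshold is None else threshold
    scores = decision_scores(model, peptides)
    return [
        {
            "id": pep.id,
            "sequence": pep.seq,
            "score": float(s),
            "label": "inducer" if s >= thr else "non-inducer",
            "threshold": thr,
        }
        for pep, s in zip(peptides, scores)
    ]


def _model_metadata(model: TrainedModel) -> dict:
    return {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_kind": model.feature_kind,
        "family": model.family,
        "threshold": model.threshold,
        "fingerprint": model.fingerprint,
        "residue_order": "ACDEFGHIKLMNPQRSTVWY",
        "dipeptide_order": "row-major (first residue major)",
    }


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a model to a single self-contained file.

    Layout: a joblib archive holding a metadata dict (format version,
    feature kind and ordering, threshold, corpus fingerprint), the fitted
    estimator, the AAP weight table when present, and any scaler state.
    """
    payload = {
        "metadata": _model_metadata(model),
        "config": model.config,
        "estimator": model.estimator,
        "aap_weights": model.aap_weights,
        "scaler_mean": model.scaler_mean,
        "scaler_std": model.scaler_std,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    try:
        payload = joblib.load(path)
        meta = payload["metadata"]
    except Exception as exc:  # unreadable / truncated file
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    version = meta.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format version {version!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    if meta["feature_kind"] == "AAP" and payload.get("aap_weights") is None:
        raise ModelFormatError("AAP model file is missing its weight table")
    return TrainedModel(
        feature_kind=meta["feature_kind"],
        family=meta["family"],
        config=payload["config"],
        estimator=payload["estimator"],
        threshold=meta["threshold"],
        aap_weights=payload.get("aap_weights"),
        scaler_mean=payload.get("scaler_mean"),
        scaler_std=payload.get("scaler_std"),
        fingerprint=meta.get("fingerprint", ""),
    )


def model_fingerprint(model: TrainedModel) -> str:
    """Short stable identifier for provenance records."""
    h = hashlib.sha256(repr(_model_metadata(model)).encode())
    h.update(repr(model.config).encode())
    return h.hexdigest()[:12]


def write_prediction_tsv(rows: Sequence[dict], model: TrainedModel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# model\t{model.family}\t{model.feature_kind}\t{model_fingerprint(model)}\n")
        fh.write("id\tsequence\tscore\tlabel\tthreshold\n")
        for r in rows:
            fh.write(
                f"{r['id']}\t{r['sequence']}\t{r['score']:.6g}\t{r['label']}\t{r['threshold']:g}\n"
            )
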