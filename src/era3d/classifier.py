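"""k-NN beat classification with SMOTE balancing and subject majority voting.

The classifier is a lazy k-nearest-neighbor model on normalized restitution
intervals: the training matrix is stored verbatim and a query beat's
posterior probability of the PAF class is the fraction of its k nearest
training neighbors (Euclidean distance in normalized space) carrying the PAF
label.  k is restricted to odd values so per-beat majority votes cannot tie.

Because PAF cohorts are much smaller than control cohorts, the minority
class is oversampled to parity before classification with SMOTE: each
synthetic beat lies uniformly on the segment between a random minority beat
and one of its k_smote nearest minority neighbors.  Oversampling operates in
the same normalized space as classification so "neighboring" means the same
thing in both steps.

A subject's final label is the majority of its per-beat predicted labels;
an exact 50/50 split resolves to PAF (screening favors sensitivity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .annotator import CONTROL, PAF
from .features import (
    DegenerateDataError,
    FeatureSet,
    NormalizationParams,
    resolve_feature_set,
)

__all__ = [
    "KNNModel",
    "BeatPrediction",
    "SubjectPrediction",
    "smote_oversample",
    "balance_classes",
    "knn_fit",
    "knn_posterior",
    "knn_posterior_batch",
    "predict_subject",
    "save_model",
    "load_model",
]

#: Canonical SMOTE neighbor count.
DEFAULT_K_SMOTE = 5

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class BeatPrediction:
    """Per-beat k-NN outcome: PAF posterior and thresholded label."""

    posterior_paf: float
    predicted_label: str


@dataclass(frozen=True)
class SubjectPrediction:
    """Subject-level majority-vote outcome."""

    subject_id: str
    vote_fraction_paf: float
    final_label: str
    n_beats: int
    mean_posterior_paf: float


@dataclass(frozen=True)
class KNNModel:
    """Stored (lazy) k-NN model over normalized restitution features."""

    matrix: np.ndarray
    labels: np.ndarray
    k: int
    normalization: NormalizationParams
    feature_set: FeatureSet


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def smote_oversample(
    minority_rows: np.ndarray,
    n_synthetic: int,
    k_smote: int = DEFAULT_K_SMOTE,
    rng_seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Generate synthetic minority rows on segments between near neighbors.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ U[0, 1]``, ``x``
    a minority row drawn uniformly with replacement (the real-world class
    ratio is rarely integer, so fractional oversampling is required), and
    ``x_nn`` one of its ``k_smote`` nearest minority neighbors, also drawn
    uniformly.  Deterministic for a given seed.
    """
    minority_rows = np.atleast_2d(np.asarray(minority_rows, dtype=float))
    m = len(minority_rows)
    if n_synthetic < 0:
        raise ValueError("n_synthetic must be >= 0")
    if m < k_smote + 1:
        raise DegenerateDataError(
            f"SMOTE needs at least k_smote+1={k_smote + 1} minority rows, got {m}"
        )
    if n_synthetic == 0:
        return np.empty((0, minority_rows.shape[1]))

    nn = NearestNeighbors(n_neighbors=k_smote + 1).fit(minority_rows)
    _, idx = nn.kneighbors(minority_rows)
    # drop each row's own index from its neighbor list (guard against
    # duplicate points putting self elsewhere than position 0)
    neighbors = np.empty((m, k_smote), dtype=int)
    for i in range(m):
        row = idx[i][idx[i] != i]
        neighbors[i] = row[:k_smote] if len(row) >= k_smote else idx[i][1:][:k_smote]

    rng = _rng(rng_seed)
    base = rng.integers(0, m, size=n_synthetic)
    pick = rng.integers(0, k_smote, size=n_synthetic)
    u = rng.random(n_synthetic)
    x = minority_rows[base]
    x_nn = minority_rows[neighbors[base, pick]]
    return x + u[:, None] * (x_nn - x)


def balance_classes(
    matrix: np.ndarray,
    labels: np.ndarray,
    rng_seed: int | np.random.Generator | None = None,
    k_smote: int = DEFAULT_K_SMOTE,
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by appending SMOTE rows for the minority class.

    Majority rows are untouched; synthetic rows (carrying the minority
    label) are appended after the originals.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if counts[0] == counts[1]:
        return matrix, labels
    minority = classes[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    synthetic = smote_oversample(
        matrix[labels == minority], deficit, k_smote=k_smote, rng_seed=rng_seed
    )
    out_matrix = np.vstack([matrix, synthetic])
    out_labels = np.concatenate([labels, np.full(deficit, minority, dtype=object)])
    return out_matrix, out_labels


def knn_fit(
    matrix: np.ndarray,
    labels: np.ndarray,
    k: int,
    normalization: NormalizationParams,
    feature_set: str | FeatureSet,
) -> KNNModel:
    """Store the (already normalized) training data as a k-NN model.

    k must be odd — a per-beat majority over an even neighbor count could
    tie — and no larger than the number of training rows.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if matrix.ndim != 2 or len(matrix) != len(labels):
        raise ValueError("matrix and labels must align row-wise")
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the {len(matrix)} training rows")
    return KNNModel(
        matrix=matrix,
        labels=labels,
        k=int(k),
        normalization=normalization,
        feature_set=resolve_feature_set(feature_set),
    )


def knn_posterior(model: KNNModel, query_row: np.ndarray) -> BeatPrediction:
    """Exact k-NN posterior for one normalized query row.

    Uses a partial sort (``np.partition``) of squared Euclidean distances;
    distance ties at the k-th neighbor are resolved in favor of the earliest
    training rows by index, making the result deterministic.
    """
    query_row = np.asarray(query_row, dtype=float).ravel()
    if query_row.shape[0] != model.matrix.shape[1]:
        raise ValueError(
            f"query has {query_row.shape[0]} features, model expects "
            f"{model.matrix.shape[1]}"
        )
    d2 = np.einsum("ij,ij->i", model.matrix - query_row, model.matrix - query_row)
    k = model.k
    kth = np.partition(d2, k - 1)[k - 1] if k < len(d2) else d2.max()
    closer = np.flatnonzero(d2 < kth)
    at_kth = np.flatnonzero(d2 == kth)
    chosen = np.concatenate([closer, at_kth[: k - len(closer)]])
    posterior = float(np.mean(model.labels[chosen] == PAF))
    return BeatPrediction(
        posterior_paf=posterior,
        predicted_label=PAF if posterior > 0.5 else CONTROL,
    )


def knn_posterior_batch(model: KNNModel, queries: np.ndarray) -> np.ndarray:
    """PAF posteriors for many normalized query rows at once (tree-backed).

    Distance ties, a measure-zero event for continuous features, may be
    ordered differently than :func:`knn_posterior`'s earliest-index rule;
    the result is still deterministic for fixed inputs.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if queries.shape[1] != model.matrix.shape[1]:
        raise ValueError("query dimensionality does not match the model")
    nn = NearestNeighbors(n_neighbors=model.k).fit(model.matrix)
    _, idx = nn.kneighbors(queries)
    return (model.labels[idx] == PAF).mean(axis=1)


def predict_subject(
    model: KNNModel, subject_beats: np.ndarray, subject_id: str = ""
) -> SubjectPrediction:
    """Majority vote over a subject's per-beat predictions.

    Each beat is labeled PAF when its posterior exceeds 0.5 (odd k, so no
    per-beat ties); the subject is PAF when the PAF vote fraction is >= 0.5,
    the exact tie deliberately resolving to the positive class.
    """
    subject_beats = np.atleast_2d(np.asarray(subject_beats, dtype=float))
    if len(subject_beats) == 0:
        raise ValueError(f"subject {subject_id!r} has no beats: unclassifiable")
    posteriors = knn_posterior_batch(model, subject_beats)
    votes = posteriors > 0.5
    vote_fraction = float(votes.mean())
    return SubjectPrediction(
        subject_id=subject_id,
        vote_fraction_paf=vote_fraction,
        final_label=PAF if vote_fraction >= 0.5 else CONTROL,
        n_beats=len(subject_beats),
        mean_posterior_paf=float(posteriors.mean()),
    )


def save_model(model: KNNModel, path: str | Path) -> None:
    """Serialize a model to a versioned JSON archive (bit-exact round-trip).

    JSON float serialization uses shortest-round-trip repr, so every stored
    value reloads to the identical IEEE-754 double.
    """
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "k": model.k,
        "feature_set": model.feature_set.name,
        "columns": list(model.feature_set.columns),
        "normalization": {
            "mean": model.normalization.mean.tolist(),
            "sd": model.normalization.sd.tolist(),
        },
        "matrix": model.matrix.tolist(),
        "labels": model.labels.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> KNNModel:
    """Load a model saved by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    normalization = NormalizationParams(
        mean=np.array(payload["normalization"]["mean"], dtype=float),
        sd=np.array(payload["normalization"]["sd"], dtype=float),
    )
    return knn_fit(
        matrix=np.array(payload["matrix"], dtype=float),
        labels=np.array(payload["labels"], dtype=object),
        k=payload["k"],
        normalization=normalization,
        feature_set=FeatureSet(payload["feature_set"], tuple(payload["columns"])),
    )
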