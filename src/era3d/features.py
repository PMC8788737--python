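"""Beat-level feature matrices for restitution-interval classification.

Classification runs on the three pairwise interval combinations (QT–RR,
TQ–RR, QT–TQ) and on the full 3D triplet (RR, QT, TQ).  Intervals are
z-scored column-wise by the training set's mean and sample SD; standardized
Euclidean distance on raw intervals is then identical to plain Euclidean
distance on the normalized columns, so a single code path serves both.
Normalization statistics are always fitted on the real training beats only
(before any oversampling) and applied unchanged to training, synthetic, and
test beats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotator import RestitutionBeat, beats_to_frame

__all__ = [
    "FeatureSet",
    "FEATURE_SETS",
    "resolve_feature_set",
    "NormalizationParams",
    "DegenerateDataError",
    "build_matrix",
    "normalization_fit",
    "normalization_apply",
    "export_scatter",
    "read_interval_table",
]

_INTERVAL_COLUMNS = ("rr_s", "qt_s", "tq_s")


class DegenerateDataError(ValueError):
    """Feature data unusable for normalization (e.g. zero-variance column)."""


@dataclass(frozen=True)
class FeatureSet:
    """Named, ordered selection of interval columns."""

    name: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 2 <= len(self.columns) <= 3:
            raise ValueError("feature set must have 2 or 3 columns")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("feature-set columns must be distinct")
        for c in self.columns:
            if c not in _INTERVAL_COLUMNS:
                raise ValueError(f"unknown interval column {c!r}")


FEATURE_SETS: dict[str, FeatureSet] = {
    "RR_QT": FeatureSet("RR_QT", ("rr_s", "qt_s")),
    "RR_TQ": FeatureSet("RR_TQ", ("rr_s", "tq_s")),
    "QT_TQ": FeatureSet("QT_TQ", ("qt_s", "tq_s")),
    "RR_QT_TQ": FeatureSet("RR_QT_TQ", ("rr_s", "qt_s", "tq_s")),
}


def resolve_feature_set(fs: str | FeatureSet) -> FeatureSet:
    if isinstance(fs, FeatureSet):
        return fs
    try:
        return FEATURE_SETS[fs]
    except KeyError:
        raise ValueError(
            f"unknown feature set {fs!r}; choose from {sorted(FEATURE_SETS)}"
        ) from None


def _as_frame(beats: list[RestitutionBeat] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(beats, pd.DataFrame):
        return beats
    return beats_to_frame(beats)


def build_matrix(
    beats: list[RestitutionBeat] | pd.DataFrame,
    feature_set: str | FeatureSet,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (matrix, class labels, subject ids), one row per beat."""
    fs = resolve_feature_set(feature_set)
    frame = _as_frame(beats)
    if len(frame) == 0:
        raise ValueError("no beats to build a feature matrix from")
    matrix = frame[list(fs.columns)].to_numpy(dtype=float)
    labels = frame["class_label"].to_numpy(dtype=object)
    subjects = frame["subject_id"].to_numpy(dtype=object)
    return matrix, labels, subjects


@dataclass(frozen=True)
class NormalizationParams:
    """Per-column mean and sample SD (seconds) of the fitting data."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have matching shapes")
        if np.any(self.sd <= 0):
            raise DegenerateDataError("all column SDs must be positive")


def normalization_fit(matrix: np.ndarray) -> NormalizationParams:
    """Column means and sample SDs (n-1 denominator) of a feature matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    sd = matrix.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise DegenerateDataError(f"zero-variance column(s) {bad}")
    return NormalizationParams(mean=matrix.mean(axis=0), sd=sd)


def normalization_apply(
    matrix: np.ndarray, params: NormalizationParams
) -> np.ndarray:
    """z = (x - mean) / sd, column-wise, using the fitted statistics."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != len(params.mean):
        raise ValueError(
            f"matrix has {matrix.shape[-1]} columns, params expect "
            f"{len(params.mean)}"
        )
    return (matrix - params.mean) / params.sd


def export_scatter(
    beats: list[RestitutionBeat] | pd.DataFrame,
    feature_set: str | FeatureSet,
    path: str | Path,
) -> None:
    """Write the selected interval columns plus class label for 2D/3D plotting."""
    fs = resolve_feature_set(feature_set)
    frame = _as_frame(beats)
    if len(frame) == 0:
        raise ValueError("no beats to export")
    frame[list(fs.columns) + ["class_label"]].to_csv(
        path, index=False, lineterminator="\n"
    )


def read_interval_table(path: str | Path) -> pd.DataFrame:
    """Read an annotator-format interval table (the classifier's input)."""
    frame = pd.read_csv(path)
    missing = {"subject_id", "class_label", "rr_s", "qt_s", "tq_s"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: interval table missing columns {sorted(missing)}")
    frame["subject_id"] = frame["subject_id"].astype(str)
    frame["class_label"] = frame["class_label"].astype(str)
    return frame
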