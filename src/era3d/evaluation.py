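"""Repeated stratified random-subsampling cross-validation and metrics.

Model performance is estimated by repeatedly splitting the cohort *by
subject* — never by beat — into a stratified training set (by default 48
control + 7 PAF subjects) and a test set (the remaining subjects, 7 + 3 for
the default 55/10 cohort).  Each of the (default 1000) runs uses a training
subject combination not seen in any earlier run.  Within a run, for each
feature set: normalization is fitted on the real training beats, the
training set is SMOTE-balanced, and for every odd k in the grid the test
beats are scored.  Metrics (TPR, TNR, ROC-AUC with PAF positive) are
recorded at two levels:

* beat level — pooled per-beat predictions/posteriors over all test beats;
* subject level — majority-vote labels and PAF vote fractions per subject.

Run distributions are summarized as mean with 2.5th/97.5th percentiles, and
beat- vs subject-level metrics are compared with the exact two-sided
Wilcoxon signed-rank test (the paired per-run differences are non-Gaussian).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .annotator import CONTROL, PAF
from .classifier import DEFAULT_K_SMOTE, balance_classes
from .features import build_matrix, normalization_apply, normalization_fit

__all__ = [
    "CVConfig",
    "CVResult",
    "MetricSummary",
    "stratified_split",
    "run_cv",
    "confusion_rates",
    "roc_auc",
    "summarize",
    "summarize_runs",
    "wilcoxon_signed_rank",
    "percent_increase",
]

DEFAULT_K_GRID = tuple(range(3, 42, 2))
DEFAULT_FEATURE_SETS = ("RR_QT", "RR_TQ", "QT_TQ", "RR_QT_TQ")

#: Largest n for which the Wilcoxon null is computed exactly.
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation design: split sizes, k grid, feature sets, seed."""

    n_runs: int = 1000
    n_train_control: int = 48
    n_train_paf: int = 7
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    feature_sets: tuple[str, ...] = DEFAULT_FEATURE_SETS
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if any(k < 1 or k % 2 == 0 for k in self.k_grid):
            raise ValueError(f"all k must be positive odd integers: {self.k_grid}")
        if not self.k_grid or not self.feature_sets:
            raise ValueError("k_grid and feature_sets must be non-empty")


@dataclass
class CVResult:
    """Tidy per-run metrics plus optional per-subject score records."""

    metrics: pd.DataFrame
    subject_scores: pd.DataFrame | None = None


@dataclass(frozen=True)
class MetricSummary:
    """Mean with 2.5th/97.5th percentile band, plus +/- offsets from the mean."""

    mean: float
    p2_5: float
    p97_5: float

    @property
    def plus(self) -> float:
        return self.p97_5 - self.mean

    @property
    def minus(self) -> float:
        return self.mean - self.p2_5


def _cohort_subjects(beats: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Sorted control and PAF subject id lists; one class per subject."""
    by_subject = beats.groupby("subject_id")["class_label"].unique()
    mixed = [s for s, v in by_subject.items() if len(v) > 1]
    if mixed:
        raise ValueError(f"subjects with conflicting class labels: {mixed}")
    controls = sorted(s for s, v in by_subject.items() if v[0] == CONTROL)
    pafs = sorted(s for s, v in by_subject.items() if v[0] == PAF)
    return controls, pafs


def stratified_split(
    subjects: dict[str, str] | pd.DataFrame,
    config: CVConfig,
    run_seed: int | np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Split subject ids into stratified training and test sets.

    ``subjects`` maps subject id -> class label (or is a beat table from
    which that map is derived).  Exactly ``n_train_control`` controls and
    ``n_train_paf`` PAF subjects (with all their beats) form the training
    set; every remaining subject is held out.  Deterministic per seed.
    """
    if isinstance(subjects, pd.DataFrame):
        controls, pafs = _cohort_subjects(subjects)
    else:
        controls = sorted(s for s, c in subjects.items() if c == CONTROL)
        pafs = sorted(s for s, c in subjects.items() if c == PAF)
    tc, tp = config.n_train_control, config.n_train_paf
    if len(controls) < tc + 1 or len(pafs) < tp + 1:
        raise ValueError(
            f"cohort ({len(controls)} control / {len(pafs)} PAF) cannot supply "
            f"{tc}/{tp} training subjects plus at least one held-out per class"
        )
    rng = run_seed if isinstance(run_seed, np.random.Generator) else np.random.default_rng(run_seed)
    train_c = rng.choice(controls, size=tc, replace=False)
    train_p = rng.choice(pafs, size=tp, replace=False)
    train = sorted(train_c) + sorted(train_p)
    test = sorted(set(controls) - set(train_c)) + sorted(set(pafs) - set(train_p))
    return train, test


def confusion_rates(
    predictions: np.ndarray, truths: np.ndarray, positive: str = PAF
) -> tuple[float, float]:
    """(TPR, TNR) = (TP/(TP+FN), TN/(TN+FP)); NaN when a truth class is absent."""
    predictions = np.asarray(predictions, dtype=object)
    truths = np.asarray(truths, dtype=object)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    if len(truths) == 0:
        raise ValueError("empty inputs")
    pos = truths == positive
    pred_pos = predictions == positive
    tpr = float(pred_pos[pos].mean()) if pos.any() else float("nan")
    tnr = float((~pred_pos[~pos]).mean()) if (~pos).any() else float("nan")
    return tpr, tnr


def roc_auc(scores: np.ndarray, truths: np.ndarray, positive: str = PAF) -> float:
    """ROC-AUC by the rank (Mann-Whitney) formulation, ties counted 1/2.

    Equals the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=object)
    if scores.shape != truths.shape:
        raise ValueError("scores and truths must have equal length")
    pos = truths == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def summarize(values: np.ndarray | list[float]) -> MetricSummary:
    """Mean and linear-interpolation 2.5th/97.5th percentiles over CV runs.

    NaNs (metrics undefined on a run) are excluded.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("no finite values to summarize")
    p2_5, p97_5 = np.percentile(values, [2.5, 97.5], method="linear")
    return MetricSummary(mean=float(values.mean()), p2_5=float(p2_5), p97_5=float(p97_5))


def summarize_runs(metrics: pd.DataFrame) -> pd.DataFrame:
    """Summary table (mean, percentile band, +/- offsets, n) per
    (feature_set, level, k, metric) cell of a run_cv metrics table."""
    rows = []
    for (fs_name, level, k), group in metrics.groupby(
        ["feature_set", "level", "k"], sort=True
    ):
        for metric in ("tpr", "tnr", "auc"):
            vals = group[metric].to_numpy(dtype=float)
            n_missing = int(np.isnan(vals).sum())
            s = summarize(vals)
            rows.append(
                {
                    "feature_set": fs_name,
                    "level": level,
                    "k": k,
                    "metric": metric,
                    "mean": s.mean,
                    "p2_5": s.p2_5,
                    "p97_5": s.p97_5,
                    "plus": s.plus,
                    "minus": s.minus,
                    "n_runs": len(vals) - n_missing,
                    "n_missing": n_missing,
                }
            )
    return pd.DataFrame(rows)


def wilcoxon_signed_rank(paired_a: np.ndarray, paired_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped first (at least 5 non-zero pairs are
    required).  For n <= 25 the null distribution of W+ is computed exactly
    by dynamic programming over rank sums (identical to enumerating all 2^n
    sign assignments); beyond that, a normal approximation with tie and
    continuity corrections is used.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero: test degenerate")
    if n < 5:
        raise ValueError(f"need >= 5 non-zero differences, got {n}")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= WILCOXON_EXACT_MAX_N:
        # doubled ranks are integers even with .5 average ranks
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        # pmf over 2*W+ under the symmetric null, by subset-sum convolution
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: total + 1 - r]
        counts /= 2.0**n
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum()
        p_ge = counts[w2:].sum()
        return float(min(1.0, 2.0 * min(p_le, p_ge)))

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise ValueError("all differences tied: variance zero")
    # continuity correction toward the mean
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def percent_increase(baseline: float, improved: float) -> float:
    """100 * (improved - baseline) / baseline; NaN for a zero baseline."""
    if baseline == 0:
        return float("nan")
    return 100.0 * (improved - baseline) / baseline


def _subject_groups(subject_ids: np.ndarray) -> dict[str, np.ndarray]:
    """Map subject id -> row indices, preserving first-appearance order."""
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(subject_ids):
        groups.setdefault(s, []).append(i)
    return {s: np.asarray(ix) for s, ix in groups.items()}


def run_cv(
    beats: pd.DataFrame,
    config: CVConfig = CVConfig(),
    collect_subject_scores: bool = False,
) -> CVResult:
    """Run the full repeated stratified-subsampling cross-validation.

    ``beats`` is an interval table (columns subject_id, class_label, rr_s,
    qt_s, tq_s).  Training-subject combinations are kept duplicate-free
    across runs by rejection sampling on a seen-set; an error is raised if
    ``n_runs`` exceeds the number of distinct combinations.  All randomness
    descends from ``config.master_seed``.

    Returns a :class:`CVResult` whose ``metrics`` table has one row per
    (run, k, feature_set, level) with tpr/tnr/auc, and, when requested,
    a ``subject_scores`` table of per-test-subject vote fractions and mean
    posteriors (the majority-vote score plots).
    """
    controls, pafs = _cohort_subjects(beats)
    tc, tp = config.n_train_control, config.n_train_paf
    n_combos = math.comb(len(controls), tc) * math.comb(len(pafs), tp)
    if config.n_runs > n_combos:
        raise ValueError(
            f"n_runs={config.n_runs} exceeds the {n_combos} distinct "
            f"training-subject combinations"
        )

    subject_class = dict(
        zip(beats["subject_id"].astype(str), beats["class_label"].astype(str))
    )
    rng = np.random.default_rng(config.master_seed)
    k_max = max(config.k_grid)
    seen: set[frozenset[str]] = set()
    records: list[dict] = []
    score_records: list[dict] = []

    beats = beats.reset_index(drop=True)
    subject_rows = _subject_groups(beats["subject_id"].astype(str).to_numpy())

    for run_id in range(config.n_runs):
        while True:
            train_subjects, test_subjects = stratified_split(subject_class, config, rng)
            key = frozenset(train_subjects)
            if key not in seen:
                seen.add(key)
                break
        train_rows = np.concatenate([subject_rows[s] for s in train_subjects])
        test_rows = np.concatenate([subject_rows[s] for s in test_subjects])
        train_beats = beats.iloc[train_rows]
        test_beats = beats.iloc[test_rows]
        y_test = test_beats["class_label"].to_numpy(dtype=object)
        test_subject_ids = test_beats["subject_id"].astype(str).to_numpy()
        test_groups = _subject_groups(test_subject_ids)
        subject_truth = np.array(
            [subject_class[s] for s in test_groups], dtype=object
        )

        for fs_name in config.feature_sets:
            x_train, y_train, _ = build_matrix(train_beats, fs_name)
            x_test, _, _ = build_matrix(test_beats, fs_name)
            norm = normalization_fit(x_train)
            z_train = normalization_apply(x_train, norm)
            z_test = normalization_apply(x_test, norm)
            smote_seed = int(rng.integers(2**31))
            z_bal, y_bal = balance_classes(
                z_train, y_train, rng_seed=smote_seed, k_smote=DEFAULT_K_SMOTE
            )
            nn = NearestNeighbors(n_neighbors=min(k_max, len(z_bal))).fit(z_bal)
            _, idx = nn.kneighbors(z_test)
            paf_neighbor = (y_bal[idx] == PAF).astype(float)
            cum_paf = paf_neighbor.cumsum(axis=1)

            for k in config.k_grid:
                if k > len(z_bal):
                    continue
                posteriors = cum_paf[:, k - 1] / k
                beat_pred = np.where(posteriors > 0.5, PAF, CONTROL).astype(object)
                tpr_b, tnr_b = confusion_rates(beat_pred, y_test)
                try:
                    auc_b = roc_auc(posteriors, y_test)
                except ValueError:
                    auc_b = float("nan")
                records.append(
                    dict(run_id=run_id, k=k, feature_set=fs_name, level="beat",
                         tpr=tpr_b, tnr=tnr_b, auc=auc_b)
                )

                vote_fracs = np.array(
                    [float((posteriors[ix] > 0.5).mean()) for ix in test_groups.values()]
                )
                subj_pred = np.where(vote_fracs >= 0.5, PAF, CONTROL).astype(object)
                tpr_s, tnr_s = confusion_rates(subj_pred, subject_truth)
                try:
                    auc_s = roc_auc(vote_fracs, subject_truth)
                except ValueError:
                    auc_s = float("nan")
                records.append(
                    dict(run_id=run_id, k=k, feature_set=fs_name, level="subject",
                         tpr=tpr_s, tnr=tnr_s, auc=auc_s)
                )
                if collect_subject_scores:
                    for (subj, ix), vf in zip(test_groups.items(), vote_fracs):
                        score_records.append(
                            dict(
                                run_id=run_id, k=k, feature_set=fs_name,
                                subject_id=subj, class_label=subject_class[subj],
                                vote_fraction_paf=vf,
                                mean_posterior_paf=float(posteriors[ix].mean()),
                            )
                        )

    metrics = pd.DataFrame(records)
    scores = pd.DataFrame(score_records) if collect_subject_scores else None
    return CVResult(metrics=metrics, subject_scores=scores)
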