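"""Synthetic sinus-rhythm ECG and restitution-cohort generators.

Two generators provide fully specified ground truth for testing the
annotation and classification layers, since real clinical equine recordings
are not publicly shareable.

**Waveform generator.**  Each heartbeat is a sum of five Gaussian bumps
(P, Q, R, S, T) — the classic analytic ECG morphology — placed at cumulative
RR positions, plus white Gaussian noise and sinusoidal baseline wander.
Wave center offsets are specified relative to the R apex at a reference RR
of 1.0 s; the P and T centers scale linearly with each beat's own RR so
that, across the 25–90 bpm operating range, the T peak stays at a fixed
fraction (~1/3) of the cycle after R — inside the detector's
[RR/8, RR/2] search window — mimicking rate adaptation of repolarization.
Q, R, and S keep fixed offsets (QRS duration varies little with rate).
Ground truth records every analytic extremum position; the true T end is
defined two T-widths past the T center (~95% of the wave's area).

**Cohort generator.**  Two-class cohorts of (RR, QT, TQ) triplets cluster
around an inclined plane in 3D: a plane point plus in-plane Gaussian
scatter (an RR-like direction and a QT/TQ trade-off direction), small
off-plane scatter, and a per-subject random offset along the RR-like
direction (horses differ mostly in resting heart rate).  PAF subjects are
additionally shifted by a configurable 3-vector, by default off-plane —
the arrhythmogenic substrate as a displacement of the restitution manifold.
Triplets violating positivity or the RR/TQ < 2.4 s beat filter are
rejection-resampled.

All generators are bit-deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .annotator import CONTROL, PAF
from .ecg_io import ECGSignal

__all__ = [
    "Wave",
    "BeatTemplateParams",
    "RhythmParams",
    "CohortParams",
    "GroundTruth",
    "generate_rr_sequence",
    "synthesize_ecg",
    "generate_cohort",
    "class_shift",
    "noise_sd_for_snr_db",
    "DEFAULT_TEMPLATE",
]

#: Operating heart-rate range of the annotation algorithm (bpm).
MIN_HR_BPM = 25.0
MAX_HR_BPM = 90.0
MAX_INTERVAL_S = 2.4


@dataclass(frozen=True)
class Wave:
    """One Gaussian ECG wave component.

    ``center`` is the offset (s) of the extremum from the R apex at the
    reference RR of 1.0 s; ``width`` is the Gaussian SD (s); ``amplitude``
    is in mV (negative for downward deflections).
    """

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("wave width must be positive")


@dataclass(frozen=True)
class BeatTemplateParams:
    """Gaussian-component beat template (equine lead-II proportions).

    The default emulates the slope contrast the derivative-threshold
    detector relies on: a narrow high-slope QRS (deep sharp Q into a tall
    R) against small, slow P and T waves whose upstrokes stay below the
    high-dV threshold.  ``t_polarity`` of -1 inverts the T wave (the
    detector's median-deviation criterion must find either polarity).  P
    and T centers are rate-scaled (multiplied by the beat's RR in seconds);
    the P wave is placed relative to the R it precedes.
    """

    p: Wave = Wave(0.08, -0.25, 0.050)
    q: Wave = Wave(-0.60, -0.07, 0.012)
    r: Wave = Wave(1.00, 0.0, 0.015)
    s: Wave = Wave(-0.12, 0.040, 0.015)
    t: Wave = Wave(0.18, 0.33, 0.050)
    t_polarity: int = 1

    def __post_init__(self) -> None:
        if self.t_polarity not in (-1, 1):
            raise ValueError("t_polarity must be +1 or -1")
        if not abs(self.r.amplitude) > max(abs(self.q.amplitude), abs(self.s.amplitude)):
            raise ValueError("R amplitude must dominate Q and S")
        if not self.p.center < self.q.center < self.r.center < self.s.center < self.t.center:
            raise ValueError("wave centers must be ordered P < Q < R < S < T")


@dataclass(frozen=True)
class RhythmParams:
    """Rhythm, noise, and sampling parameters of the waveform generator.

    The default ``fs`` of 500 Hz emulates a telemetric recorder's native
    sampling rate; the preprocessing chain then resamples to 125 Hz before
    annotation, exactly as with real exports.
    """

    mean_hr_bpm: float = 40.0
    rr_cv: float = 0.05
    noise_sd_mv: float = 0.01
    baseline_amp_mv: float = 0.05
    baseline_freq_hz: float = 0.25
    fs: float = 500.0
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not MIN_HR_BPM <= self.mean_hr_bpm <= MAX_HR_BPM:
            raise ValueError(
                f"mean_hr_bpm must lie in [{MIN_HR_BPM:g}, {MAX_HR_BPM:g}] "
                f"(the annotator's operating range), got {self.mean_hr_bpm}"
            )
        if self.rr_cv < 0 or self.noise_sd_mv < 0:
            raise ValueError("rr_cv and noise_sd_mv must be >= 0")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic fiducials and intervals of a synthesized signal.

    Index arrays have one entry per fully contained beat; the interval
    arrays (``rr_s``, ``qt_s``, ``tq_s``) have one entry per adjacent beat
    pair, aligned with the earlier beat of each pair, computed from the
    un-quantized analytic wave positions.
    """

    q_idx: np.ndarray
    r_idx: np.ndarray
    t_peak_idx: np.ndarray
    t_end_idx: np.ndarray
    rr_s: np.ndarray
    qt_s: np.ndarray
    tq_s: np.ndarray
    fs: float

    @property
    def n_beats(self) -> int:
        return len(self.r_idx)


DEFAULT_TEMPLATE = BeatTemplateParams()

_RR_LO = 60.0 / MAX_HR_BPM  # 0.667 s
_RR_HI = MAX_INTERVAL_S     # 2.4 s


def generate_rr_sequence(params: RhythmParams, n: int | None = None) -> np.ndarray:
    """Draw an RR-interval sequence (seconds).

    ``RR_i = (60 / HR) * (1 + eps_i)`` with Gaussian ``eps`` of the given
    coefficient of variation, rejection-truncated to [60/90, 2.4) s so every
    interval respects the 25–90 bpm operating range.  ``n`` defaults to
    enough intervals to cover ``duration_s``.
    """
    mean_rr = 60.0 / params.mean_hr_bpm
    if not _RR_LO <= mean_rr <= _RR_HI:
        raise ValueError(f"mean RR {mean_rr:g}s outside the generable range")
    if params.rr_cv == 0 and mean_rr >= _RR_HI:
        raise ValueError(
            "RR truncation region is empty: mean RR at the 2.4 s bound with zero CV"
        )
    if n is None:
        n = int(np.ceil(params.duration_s / mean_rr)) + 3
    rng = np.random.default_rng(params.seed)
    rr = mean_rr * (1.0 + rng.normal(0.0, params.rr_cv, size=n))
    for _ in range(1000):
        bad = (rr < _RR_LO) | (rr >= _RR_HI)
        if not bad.any():
            return rr
        rr[bad] = mean_rr * (1.0 + rng.normal(0.0, params.rr_cv, size=int(bad.sum())))
    raise ValueError("RR truncation region is effectively empty for these parameters")


def noise_sd_for_snr_db(clean_rms_mv: float, snr_db: float) -> float:
    """Noise SD giving the requested power SNR against a clean-signal RMS."""
    return clean_rms_mv / 10.0 ** (snr_db / 20.0)


def with_snr(
    template: BeatTemplateParams, rhythm: RhythmParams, snr_db: float
) -> RhythmParams:
    """Return rhythm params whose white-noise SD realizes the given SNR.

    The SNR is defined against the RMS of the clean (noise- and
    wander-free) waveform rendered with the same template and rhythm.
    """
    clean = replace(rhythm, noise_sd_mv=0.0, baseline_amp_mv=0.0)
    sig, _ = synthesize_ecg(template, clean)
    rms = float(np.sqrt(np.mean(sig.samples**2)))
    return replace(rhythm, noise_sd_mv=noise_sd_for_snr_db(rms, snr_db))


def _add_wave(
    v: np.ndarray, t: np.ndarray, fs: float, center: float, amp: float, width: float
) -> None:
    """Add one Gaussian bump in place, over a +/-6 sigma local window."""
    lo = max(0, int((center - 6 * width) * fs))
    hi = min(len(v), int((center + 6 * width) * fs) + 2)
    if hi > lo:
        x = t[lo:hi] - center
        v[lo:hi] += amp * np.exp(-0.5 * (x / width) ** 2)


def synthesize_ecg(
    template: BeatTemplateParams = DEFAULT_TEMPLATE,
    rhythm: RhythmParams = RhythmParams(),
) -> tuple[ECGSignal, GroundTruth]:
    """Render a synthetic single-lead ECG with analytic ground truth.

    Beats are placed at cumulative RR positions starting 0.6 s into the
    trace; only beats whose P-to-T-end extent lies fully inside the signal
    enter the ground truth.  The true T end is ``t.center * RR + 2 * t.width``
    after the R apex.
    """
    fs = rhythm.fs
    n = round(rhythm.duration_s * fs)
    t_axis = np.arange(n) / fs
    v = np.zeros(n)

    rr_seq = generate_rr_sequence(rhythm, n=int(np.ceil(rhythm.duration_s * 1.6)) + 5)
    r_times = [0.6]
    for rr in rr_seq:
        nxt = r_times[-1] + rr
        if nxt >= rhythm.duration_s:
            break
        r_times.append(nxt)
    r_times_arr = np.asarray(r_times)
    rr_fwd = np.diff(r_times_arr)  # forward RR of each beat but the last
    # the last beat has no forward RR; reuse the previous one for wave placement
    rr_for_wave = np.append(rr_fwd, rr_fwd[-1] if len(rr_fwd) else 60.0 / rhythm.mean_hr_bpm)
    rr_prev = np.insert(rr_fwd, 0, rr_for_wave[0])  # preceding RR (P placement)

    q_t, r_t, tp_t, te_t = [], [], [], []
    keep = []
    for i, tau in enumerate(r_times_arr):
        p_c = tau + template.p.center * rr_prev[i]
        q_c = tau + template.q.center
        s_c = tau + template.s.center
        t_c = tau + template.t.center * rr_for_wave[i]
        t_end = t_c + 2 * template.t.width
        _add_wave(v, t_axis, fs, p_c, template.p.amplitude, template.p.width)
        _add_wave(v, t_axis, fs, q_c, template.q.amplitude, template.q.width)
        _add_wave(v, t_axis, fs, tau, template.r.amplitude, template.r.width)
        _add_wave(v, t_axis, fs, s_c, template.s.amplitude, template.s.width)
        _add_wave(
            v, t_axis, fs, t_c, template.t_polarity * template.t.amplitude,
            template.t.width,
        )
        inside = (p_c - 6 * template.p.width) >= 0 and (
            t_end + 2 * template.t.width
        ) * fs < n
        keep.append(inside)
        q_t.append(q_c)
        r_t.append(tau)
        tp_t.append(t_c)
        te_t.append(t_end)

    rng = np.random.default_rng(rhythm.seed + 1)
    if rhythm.noise_sd_mv > 0:
        v = v + rng.normal(0.0, rhythm.noise_sd_mv, size=n)
    if rhythm.baseline_amp_mv > 0:
        v = v + rhythm.baseline_amp_mv * np.sin(
            2 * np.pi * rhythm.baseline_freq_hz * t_axis
        )

    keep_arr = np.asarray(keep)
    q_t, r_t, tp_t, te_t = (np.asarray(x)[keep_arr] for x in (q_t, r_t, tp_t, te_t))
    rr_true = np.diff(r_t)
    qt_true = (te_t - q_t)[:-1]
    tq_true = q_t[1:] - tp_t[:-1]
    truth = GroundTruth(
        q_idx=np.rint(q_t * fs).astype(int),
        r_idx=np.rint(r_t * fs).astype(int),
        t_peak_idx=np.rint(tp_t * fs).astype(int),
        t_end_idx=np.rint(te_t * fs).astype(int),
        rr_s=rr_true,
        qt_s=qt_true,
        tq_s=tq_true,
        fs=fs,
    )
    sig = ECGSignal(samples=v, fs=fs, lead="II", source_id=f"synthetic-{rhythm.seed}")
    return sig, truth


# --- cohort generator -------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class CohortParams:
    """Two-class (RR, QT, TQ) cohort clustered around an inclined plane.

    The plane passes through ``plane_point`` and is spanned by ``basis_rr``
    (the RR-like direction, coupling QT ~ a + b*RR and TQ ~ RR - QT) and
    ``basis_tradeoff`` (QT vs TQ at fixed RR).  ``sigma_in_plane`` gives the
    scatter SDs along those two directions; ``sigma_off_plane`` the SD along
    the plane normal; ``subject_sd`` the SD of the per-subject offset along
    the RR-like direction.  ``shift`` displaces every PAF beat.
    Default subject counts mirror a 55-control / 10-PAF cohort with a few
    hundred usable beats per subject.
    """

    n_control: int = 55
    n_paf: int = 10
    beats_per_subject: tuple[int, int] = (500, 800)
    plane_point: tuple[float, float, float] = (1.5, 0.645, 0.955)
    basis_rr: tuple[float, float, float] = (1.0, 0.33, 0.67)
    basis_tradeoff: tuple[float, float, float] = (0.0, 1.0, -1.0)
    sigma_in_plane: tuple[float, float] = (0.25, 0.02)
    sigma_off_plane: float = 0.01
    subject_sd: float = 0.12
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_paf < 1:
            raise ValueError("subject counts must be >= 1")
        lo, hi = self.beats_per_subject
        if not 1 <= lo <= hi:
            raise ValueError("beats_per_subject must be an increasing range >= 1")
        if min(*self.sigma_in_plane, self.sigma_off_plane, self.subject_sd) < 0:
            raise ValueError("dispersions must be >= 0")

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the cohort plane."""
        return _unit(np.cross(self.basis_rr, self.basis_tradeoff))


def class_shift(params: CohortParams, delta_sd: float, direction=None) -> np.ndarray:
    """A between-class shift of ``delta_sd`` pooled within-class SDs.

    ``direction`` defaults to the plane normal.  The pooled SD along a unit
    direction d follows analytically from the generator's covariance:
    subject and in-plane variances project through the basis vectors,
    off-plane variance through the normal.
    """
    d = _unit(params.normal if direction is None else direction)
    b1, b2 = _unit(params.basis_rr), _unit(params.basis_tradeoff)
    s1, s2 = params.sigma_in_plane
    var = (
        (s1**2 + params.subject_sd**2) * float(d @ b1) ** 2
        + s2**2 * float(d @ b2) ** 2
        + params.sigma_off_plane**2 * float(d @ params.normal) ** 2
    )
    return delta_sd * np.sqrt(var) * d


def generate_cohort(params: CohortParams = CohortParams()) -> pd.DataFrame:
    """Draw a two-class cohort of per-beat restitution triplets.

    Returns an interval table (subject_id, class_label, segment_id,
    beat_index, rr_s, qt_s, tq_s).  Beats violating positivity or
    RR/TQ < 2.4 s are rejection-resampled per subject; a rejection rate
    above 99% raises (infeasible parameters).
    """
    rng = np.random.default_rng(params.seed)
    b1, b2 = _unit(params.basis_rr), _unit(params.basis_tradeoff)
    nrm = params.normal
    p0 = np.asarray(params.plane_point, dtype=float)
    shift = np.asarray(params.shift, dtype=float)
    s1, s2 = params.sigma_in_plane
    lo, hi = params.beats_per_subject

    frames = []
    subjects = [(f"C{i:03d}", CONTROL) for i in range(params.n_control)] + [
        (f"P{i:03d}", PAF) for i in range(params.n_paf)
    ]
    for subject_id, label in subjects:
        n_beats = int(rng.integers(lo, hi + 1))
        u_subj = rng.normal(0.0, params.subject_sd)
        center = p0 + u_subj * b1 + (shift if label == PAF else 0.0)
        collected = np.empty((0, 3))
        attempts = 0
        drawn = 0
        while len(collected) < n_beats:
            need = n_beats - len(collected)
            batch = max(need, 32)
            pts = (
                center
                + rng.normal(0.0, s1, size=(batch, 1)) * b1
                + rng.normal(0.0, s2, size=(batch, 1)) * b2
                + rng.normal(0.0, params.sigma_off_plane, size=(batch, 1)) * nrm
            )
            ok = (
                (pts > 0).all(axis=1)
                & (pts[:, 0] < MAX_INTERVAL_S)
                & (pts[:, 2] < MAX_INTERVAL_S)
            )
            collected = np.vstack([collected, pts[ok][:need]])
            drawn += batch
            attempts += 1
            if attempts > 50 and len(collected) < 0.01 * drawn:
                raise ValueError(
                    "cohort parameters rejected >99% of draws: infeasible"
                )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "class_label": label,
                    "segment_id": "sim",
                    "beat_index": np.arange(n_beats),
                    "rr_s": collected[:, 0],
                    "qt_s": collected[:, 1],
                    "tq_s": collected[:, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
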