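"""Shared fixtures: synthetic signals and cohorts at test-friendly sizes."""

from __future__ import annotations

import numpy as np
import pytest

from era3d import annotator as ann
from era3d import synthetic_data as sd
from era3d.ecg_io import lowpass_zero_phase, resample_signal


def preprocess_chain(sig, fs_target=125.0):
    """Recorder-rate signal -> analysis-rate filtered signal."""
    return lowpass_zero_phase(resample_signal(sig, fs_target))


def make_ecg(hr=40.0, seed=0, snr_db=20.0, duration_s=60.0, template=sd.DEFAULT_TEMPLATE):
    """Synthesize at 500 Hz with the given SNR and preprocess to 125 Hz."""
    rhythm = sd.RhythmParams(mean_hr_bpm=hr, seed=seed, duration_s=duration_s)
    rhythm = sd.with_snr(template, rhythm, snr_db)
    sig, truth = sd.synthesize_ecg(template, rhythm)
    return preprocess_chain(sig), truth


def truth_at_fs(truth: sd.GroundTruth, fs: float) -> dict[str, np.ndarray]:
    """Ground-truth fiducial indices converted to another sampling rate."""
    conv = fs / truth.fs
    return {
        name: np.rint(getattr(truth, f"{name}_idx") * conv).astype(int)
        for name in ("q", "r", "t_peak", "t_end")
    }


@pytest.fixture(scope="session")
def clean_ecg():
    """Noise- and wander-free 60 s recording at 40 bpm, preprocessed to 125 Hz."""
    rhythm = sd.RhythmParams(
        mean_hr_bpm=40.0, seed=7, noise_sd_mv=0.0, baseline_amp_mv=0.0
    )
    sig, truth = sd.synthesize_ecg(rhythm=rhythm)
    return preprocess_chain(sig), truth


@pytest.fixture(scope="session")
def noisy_ecg():
    """60 s recording at 40 bpm with SNR 20 dB, preprocessed to 125 Hz."""
    return make_ecg(hr=40.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Toy two-class cohort: 8 control / 4 PAF subjects, ~40 beats each."""
    params = sd.CohortParams(
        n_control=8, n_paf=4, beats_per_subject=(35, 45), seed=3
    )
    return sd.generate_cohort(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
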