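import numpy as np
import pytest

from fallwalk.cohort import CohortConfig, generate_cohort, generate_recordings
from fallwalk.preprocess import Window, dominant_frequency_vt, segment_windows


def tone_window(freqs_amps, fs=100.0, duration=10.0, wid="w0", subject="S0"):
    """A window whose VT channel is a sum of pure tones; AP/ML are quiet."""
    t = np.arange(int(duration * fs)) / fs
    vt = np.zeros_like(t)
    for f, a in freqs_amps:
        vt += a * np.sin(2 * np.pi * f * t)
    values = np.vstack([0.01 * np.sin(2 * np.pi * 1.0 * t), 0.01 * np.cos(2 * np.pi * 1.0 * t), vt])
    return Window(window_id=wid, subject_id=subject, values=values, sampling_rate=fs)


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects, half fallers, with default signatures."""
    return generate_cohort(20, 0.5, seed=7)


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    subjects, signatures = small_cohort
    bouts = generate_recordings(
        subjects, signatures, bouts_per_subject=2, bout_duration_s=30.0, sampling_rate=25.0, seed=8
    )
    windows = [w for b in bouts for w in segment_windows(b, 10.0)]
    for w in windows:
        dominant_frequency_vt(w)
    return subjects, windows
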