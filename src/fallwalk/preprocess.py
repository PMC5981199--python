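"""Windowing and spectral gait filtering of locomotion bouts.

Bouts are cut into fixed-duration (default 10 s) non-overlapping triaxial
windows — the unit the classifiers consume.  Each window's *dominant vertical
frequency* is the argmax-power frequency of the vertical channel's
periodogram after mean removal; windows whose dominant frequency is at or
below a threshold (default 0.2 Hz, boundary inclusive) are flagged as
non-gait and can be excluded before training and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .cohort import AccelBout


@dataclass
class Window:
    """A fixed-duration triaxial acceleration segment.

    ``values`` has shape (3, n_samples) ordered AP, ML, VT in g.
    """

    window_id: str
    subject_id: str
    values: np.ndarray
    sampling_rate: float
    source_bout: str | None = None
    dominant_vt_freq: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[0] != 3:
            raise ValueError("values must have shape (3, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def segment_windows(bout: AccelBout, window_s: float = 10.0, overlap_s: float = 0.0) -> list[Window]:
    """Cut a bout into consecutive windows; a trailing remainder is discarded.

    A bout shorter than one window yields an empty list.  Windows inherit the
    bout's subject.  Overlap is off by default and exposed only for
    sensitivity checks.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0.0 <= overlap_s < window_s:
        raise ValueError("overlap_s must be in [0, window_s)")
    wlen = int(round(window_s * bout.sampling_rate))
    step = int(round((window_s - overlap_s) * bout.sampling_rate))
    n = bout.samples.shape[0]
    bout_tag = bout.bout_id or f"{bout.subject_id}_bout"
    windows = []
    for k, start in enumerate(range(0, n - wlen + 1, step)):
        seg = bout.samples[start : start + wlen].T  # (3, wlen)
        windows.append(
            Window(
                window_id=f"{bout_tag}_w{k:03d}",
                subject_id=bout.subject_id,
                values=seg,
                sampling_rate=bout.sampling_rate,
                source_bout=bout_tag,
            )
        )
    return windows


def dominant_frequency_vt(window: Window) -> float:
    """Dominant frequency (Hz) of the vertical channel.

    Rectangular-window periodogram of the mean-removed VT channel; the DC bin
    is excluded from the argmax.  Resolution is 1/window duration (0.1 Hz for
    10-s windows).  A constant (zero-variance) channel returns 0 Hz and flags
    the window degenerate.
    """
    vt = window.values[2]
    if np.ptp(vt) == 0.0:
        window.dominant_vt_freq = 0.0
        window.degenerate = True
        return 0.0
    freqs, power = periodogram(vt, fs=window.sampling_rate, window="boxcar", detrend="constant")
    i = int(np.argmax(power[1:])) + 1  # skip the DC bin
    f = float(freqs[i])
    window.dominant_vt_freq = f
    window.degenerate = False
    return f


def filter_gait_windows(
    windows: list[Window], threshold: float = 0.2
) -> tuple[list[Window], list[Window]]:
    """Partition windows into (retained, excluded) by dominant VT frequency.

    Windows with dominant frequency <= threshold (inclusive) or a degenerate
    constant VT channel are excluded; order is preserved and the two lists
    form a disjoint, exhaustive partition of the input.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    retained, excluded = [], []
    for w in windows:
        if w.dominant_vt_freq is None:
            dominant_frequency_vt(w)
        if w.degenerate or w.dominant_vt_freq <= threshold:
            excluded.append(w)
        else:
            retained.append(w)
    return retained, excluded


def windows_to_array(windows: list[Window]) -> tuple[np.ndarray, list[str]]:
    """Stack windows into an (n, 3, samples) array plus the subject id list."""
    if not windows:
        raise ValueError("no windows")
    X = np.stack([w.values for w in windows])
    return X, [w.subject_id for w in windows]


def standardize_windows(
    X: np.ndarray, mode: str = "none", stats: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray] | None]:
    """Optional input standardization for an (n, 3, samples) window batch.

    ``mode='window'`` z-scores each window's channels individually, removing
    per-subject amplitude scale and the gravity offset; ``mode='global'``
    standardizes with per-channel statistics (pass ``stats`` fitted on the
    training partition to avoid leakage); ``mode='none'`` is the identity.
    Returns the transformed batch and the statistics used.
    """
    if mode == "none":
        return X, None
    if mode == "window":
        mu = X.mean(axis=2, keepdims=True)
        sd = X.std(axis=2, keepdims=True)
        sd[sd == 0] = 1.0
        return (X - mu) / sd, None
    if mode == "global":
        if stats is None:
            mu = X.mean(axis=(0, 2), keepdims=True)
            sd = X.std(axis=(0, 2), keepdims=True)
            sd[sd == 0] = 1.0
            stats = (mu, sd)
        return (X - stats[0]) / stats[1], stats
    raise ValueError(f"unknown standardization mode {mode!r}")


def window_index(windows: list[Window], retained_ids: set[str] | None = None) -> pd.DataFrame:
    rows = []
    for w in windows:
        rows.append(
            {
                "window_id": w.window_id,
                "subject_id": w.subject_id,
                "dominant_vt_freq": w.dominant_vt_freq,
                "retained_flag": (retained_ids is None) or (w.window_id in retained_ids),
            }
        )
    return pd.DataFrame(rows)


def save_windows(windows: list[Window], h5_path, index_csv=None, retained_ids: set[str] | None = None) -> None:
    """Persist windows as an HDF5 tensor plus an optional CSV index."""
    X, _ = windows_to_array(windows)
    with h5py.File(h5_path, "w") as fh:
        fh.create_dataset("windows", data=X)
        fh.create_dataset("window_id", data=np.array([w.window_id for w in windows], dtype="S"))
        fh.create_dataset("subject_id", data=np.array([w.subject_id for w in windows], dtype="S"))
        fh.attrs["sampling_rate"] = windows[0].sampling_rate
    if index_csv is not None:
        window_index(windows, retained_ids).to_csv(index_csv, index=False)


def load_windows(h5_path) -> list[Window]:
    with h5py.File(h5_path, "r") as fh:
        X = fh["windows"][...]
        wids = [s.decode() for s in fh["window_id"][...]]
        sids = [s.decode() for s in fh["subject_id"][...]]
        fs = float(fh.attrs["sampling_rate"])
    return [Window(window_id=w, subject_id=s, values=x, sampling_rate=fs) for w, s, x in zip(wids, sids, X)]
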