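"""Synthetic cohorts of older adults with per-subject gait signatures.

The cohort generator stands in for a week-long daily-life trunk-accelerometry
study: each subject carries a lower-back triaxial sensor (anteroposterior,
mediolateral and vertical axes, ±6 g range) and is labelled a *faller* if they
fell during a six-month follow-up.  Since no such raw dataset is distributable,
this module draws subjects, their anthropometric attributes and an individual
*gait signature* — step frequency, per-axis amplitudes, harmonic content,
phases and cycle-to-cycle variability — and synthesises locomotion bouts from
those signatures.

Faller status perturbs the signature (higher variability, slightly lower step
frequency) so the label is recoverable in principle; both effects are
configurable and can be switched off to generate null cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AXES = ("AP", "ML", "VT")
SENSOR_RANGE_G = 6.0


@dataclass(frozen=True)
class SubjectRecord:
    """One study participant: identity, prospective-fall label and attributes."""

    subject_id: str
    fall_status: int  # 1 = fell within the 6-month follow-up
    gender: int  # binary category (1 = male under the default attribute model)
    age: float  # years
    weight: float  # kg
    height: float  # cm

    def __post_init__(self) -> None:
        if self.fall_status not in (0, 1):
            raise ValueError(f"fall_status must be 0 or 1, got {self.fall_status}")
        for name in ("age", "weight", "height"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")


@dataclass
class GaitSignature:
    """Subject-specific parameters of the harmonic gait model."""

    subject_id: str
    step_frequency: float  # Hz, fundamental of the vertical/AP axes
    amplitude_per_axis: np.ndarray  # g, shape (3,) ordered AP, ML, VT
    harmonic_weights: np.ndarray  # relative power of harmonics 2..H
    phase_offsets: np.ndarray  # rad, shape (3,)
    variability: float  # cycle-to-cycle frequency/amplitude jitter coefficient
    noise_sd: float  # g

    def __post_init__(self) -> None:
        self.amplitude_per_axis = np.asarray(self.amplitude_per_axis, float)
        self.harmonic_weights = np.asarray(self.harmonic_weights, float)
        self.phase_offsets = np.asarray(self.phase_offsets, float)
        if np.any(self.amplitude_per_axis < 0) or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")
        if not np.all(np.isfinite(self.harmonic_weights)):
            raise ValueError("harmonic_weights must be finite")

    @property
    def n_harmonics(self) -> int:
        """Highest harmonic index H (fundamental counts as harmonic 1)."""
        return 1 + len(self.harmonic_weights)


@dataclass
class AccelBout:
    """One locomotion bout: a triaxial acceleration series for one subject."""

    subject_id: str
    sampling_rate: float  # Hz
    samples: np.ndarray  # shape (n, 3), g, columns AP/ML/VT
    bout_kind: str = "gait"  # "gait" or "non-gait"
    bout_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.sampling_rate


@dataclass
class CohortConfig:
    """Distributions for attributes, signatures and bout synthesis.

    Attribute marginals default to the emulated study population: mean age
    75.3 y (sd 6.8), height 170.6 cm (sd 8.8), 74.1% in one gender category.
    The printed weight summary is internally inconsistent (mean 49.2 kg versus
    quartiles 64.0/81.8 kg); the default follows the quartile-implied centre
    (72.9 kg) and IQR-implied spread, with the mean exposed here so either
    reading can be configured.  Attributes are drawn independently.
    """

    male_fraction: float = 0.741
    age_mean: float = 75.3
    age_sd: float = 6.8
    weight_mean: float = 72.9
    weight_sd: float = 13.3
    height_mean: float = 170.6
    height_sd: float = 8.8

    # gait signature draws
    step_freq_band: tuple[float, float] = (1.2, 2.4)
    amplitude_mean: tuple[float, float, float] = (0.25, 0.18, 0.35)  # AP, ML, VT in g
    amplitude_sd: float = 0.06
    n_harmonics: int = 3  # harmonics 2..(n_harmonics+1) on top of the fundamental
    harmonic_weight_range: tuple[float, float] = (0.05, 0.5)
    variability_range: tuple[float, float] = (0.02, 0.08)
    noise_sd: float = 0.05

    # faller perturbation: variability × delta, step frequency − freq_shift
    faller_delta: float = 1.5
    faller_freq_shift: float = 0.2  # Hz

    # non-gait contaminant bouts: dominant vertical frequency at or below this
    nongait_freq_bound: float = 0.2  # Hz

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def generate_cohort(
    n_subjects: int,
    faller_fraction: float = 0.341,
    attribute_model: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[list[SubjectRecord], list[GaitSignature]]:
    """Draw a cohort of subjects and their gait signatures.

    Exactly ``round(n_subjects * faller_fraction)`` subjects are fallers
    (e.g. 101 of 296 at the default 34.1% prevalence).  Faller signatures are
    perturbed by the configured effect so the label is learnable from the
    acceleration signal; set ``faller_delta=1`` and ``faller_freq_shift=0`` for
    a null cohort.  Fully reproducible from ``seed``.
    """
    if n_subjects < 2:
        raise ValueError(f"n_subjects must be >= 2, got {n_subjects}")
    if not 0.0 < faller_fraction < 1.0:
        raise ValueError(f"faller_fraction must be in (0, 1), got {faller_fraction}")
    cfg = attribute_model or CohortConfig()
    rng = np.random.default_rng(seed)

    n_fallers = int(round(n_subjects * faller_fraction))
    status = np.zeros(n_subjects, int)
    status[:n_fallers] = 1
    rng.shuffle(status)

    width = max(3, len(str(n_subjects - 1)))
    subjects: list[SubjectRecord] = []
    signatures: list[GaitSignature] = []
    lo, hi = cfg.step_freq_band
    for i in range(n_subjects):
        sid = f"S{i:0{width}d}"
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                fall_status=int(status[i]),
                gender=int(rng.random() < cfg.male_fraction),
                age=float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 40.0, 110.0)),
                weight=float(np.clip(rng.normal(cfg.weight_mean, cfg.weight_sd), 30.0, 160.0)),
                height=float(np.clip(rng.normal(cfg.height_mean, cfg.height_sd), 130.0, 210.0)),
            )
        )
        step = float(rng.uniform(lo, hi))
        variability = float(rng.uniform(*cfg.variability_range))
        if status[i] == 1:
            step = max(lo, step - cfg.faller_freq_shift)
            variability *= cfg.faller_delta
        amps = np.abs(rng.normal(cfg.amplitude_mean, cfg.amplitude_sd))
        weights = rng.uniform(*cfg.harmonic_weight_range, size=cfg.n_harmonics)
        weights *= 0.5 ** np.arange(cfg.n_harmonics)  # decaying harmonic power
        signatures.append(
            GaitSignature(
                subject_id=sid,
                step_frequency=step,
                amplitude_per_axis=amps,
                harmonic_weights=weights,
                phase_offsets=rng.uniform(0.0, 2.0 * np.pi, size=3),
                variability=variability,
                noise_sd=cfg.noise_sd,
            )
        )
    return subjects, signatures


def _stride_phase(
    duration_s: float, sampling_rate: float, frequency: float, variability: float, rng: np.random.Generator
) -> np.ndarray:
    """Gait-cycle phase (in cycles) with per-cycle frequency jitter."""
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    n_cycles = int(np.ceil(duration_s * frequency * 2.0)) + 2
    f_cycle = frequency * (1.0 + variability * rng.standard_normal(n_cycles))
    f_cycle = np.clip(f_cycle, 0.1, None)
    boundaries = np.concatenate([[0.0], np.cumsum(1.0 / f_cycle)])
    return np.interp(t, boundaries, np.arange(n_cycles + 1, dtype=float))


def generate_bout(
    signature: GaitSignature,
    duration_s: float,
    sampling_rate: float,
    bout_kind: str = "gait",
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    config: CohortConfig | None = None,
) -> AccelBout:
    """Synthesize one locomotion (or contaminant) bout from a signature.

    Gait bouts sum the step-frequency fundamental and its harmonics with
    per-cycle jitter and Gaussian sensor noise; the mediolateral fundamental
    sits at half the step frequency, reflecting the left/right stride
    alternation.  Non-gait bouts are slow cyclic trunk movement whose dominant
    vertical frequency is, by construction, at or below the configured bound
    (default 0.2 Hz) — e.g. cycling-like motion without distinct steps.
    All samples are clipped to the ±6 g sensor range.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if bout_kind not in ("gait", "non-gait"):
        raise ValueError(f"bout_kind must be 'gait' or 'non-gait', got {bout_kind!r}")
    cfg = config or CohortConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    out = np.empty((n, 3))

    if bout_kind == "gait":
        f_max = signature.step_frequency * signature.n_harmonics
        if sampling_rate <= 2.0 * f_max:
            raise ValueError(
                f"sampling_rate {sampling_rate} Hz is at or below the Nyquist limit "
                f"for harmonic content up to {f_max:.2f} Hz"
            )
        phase = _stride_phase(duration_s, sampling_rate, signature.step_frequency, signature.variability, rng)
        # amplitude weights of harmonics 1..H, unit-power normalised
        alphas = np.concatenate([[1.0], np.sqrt(signature.harmonic_weights)])
        alphas /= np.sqrt(np.sum(alphas**2))
        # per-cycle amplitude jitter, indexed by the completed cycle count
        cyc = np.floor(phase).astype(int)
        amp_jit = 1.0 + signature.variability * rng.standard_normal(cyc.max() + 1)
        jitter = amp_jit[cyc]
        for c in range(3):
            fund = phase / 2.0 if AXES[c] == "ML" else phase
            s = np.zeros(n)
            for h, a in enumerate(alphas, start=1):
                s += a * np.sin(2.0 * np.pi * h * fund + h * signature.phase_offsets[c])
            out[:, c] = signature.amplitude_per_axis[c] * jitter * s
    else:
        f_slow = rng.uniform(0.05, max(0.06, cfg.nongait_freq_bound - 0.02))
        for c in range(3):
            out[:, c] = signature.amplitude_per_axis[c] * np.sin(
                2.0 * np.pi * f_slow * t + signature.phase_offsets[c]
            )

    out += rng.normal(0.0, signature.noise_sd, size=out.shape)
    out[:, 2] += 1.0  # gravity offset on the vertical axis
    np.clip(out, -SENSOR_RANGE_G, SENSOR_RANGE_G, out=out)
    return AccelBout(subject_id=signature.subject_id, sampling_rate=sampling_rate, samples=out, bout_kind=bout_kind)


def generate_recordings(
    subjects: list[SubjectRecord],
    signatures: list[GaitSignature],
    bouts_per_subject: int | tuple[int, int] = 5,
    bout_duration_s: float = 60.0,
    sampling_rate: float = 25.0,
    contamination_rate: float = 0.0,
    seed: int = 0,
    config: CohortConfig | None = None,
) -> list[AccelBout]:
    """Generate a bout inventory for a whole cohort.

    ``bouts_per_subject`` is either a fixed count or an inclusive (lo, hi)
    range drawn uniformly per subject.  Each bout is independently a non-gait
    contaminant with probability ``contamination_rate``.
    """
    if not subjects:
        raise ValueError("cohort is empty")
    if not 0.0 <= contamination_rate < 1.0:
        raise ValueError(f"contamination_rate must be in [0, 1), got {contamination_rate}")
    sig_of = {s.subject_id: s for s in signatures}
    missing = [s.subject_id for s in subjects if s.subject_id not in sig_of]
    if missing:
        raise ValueError(f"subjects without signatures: {missing[:5]}")
    rng = np.random.default_rng(seed)
    bouts: list[AccelBout] = []
    for subj in subjects:
        if isinstance(bouts_per_subject, tuple):
            k = int(rng.integers(bouts_per_subject[0], bouts_per_subject[1] + 1))
        else:
            k = int(bouts_per_subject)
        for j in range(k):
            kind = "non-gait" if rng.random() < contamination_rate else "gait"
            bout = generate_bout(
                sig_of[subj.subject_id], bout_duration_s, sampling_rate, kind, rng=rng, config=config
            )
            bout.bout_id = f"{subj.subject_id}_b{j:03d}"
            bouts.append(bout)
    return bouts


# ---------------------------------------------------------------------------
# on-disk formats


def cohort_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in subjects])


def write_cohort_csv(subjects: list[SubjectRecord], path) -> None:
    cohort_to_frame(subjects).to_csv(path, index=False)


def write_bout_csv(bout: AccelBout, path) -> None:
    t = np.arange(bout.samples.shape[0]) / bout.sampling_rate
    pd.DataFrame(
        {"time_s": t, "accAP_g": bout.samples[:, 0], "accML_g": bout.samples[:, 1], "accVT_g": bout.samples[:, 2]}
    ).to_csv(path, index=False)


def write_manifest(path, seed: int, config: CohortConfig | None = None, **extra) -> None:
    payload = {"seed": seed, "config": (config or CohortConfig()).to_dict(), **extra}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
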