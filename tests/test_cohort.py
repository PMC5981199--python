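"""Synthetic cohort generator: determinism, label structure, signal content."""

import numpy as np
import pytest
from scipy.signal import periodogram
from sklearn.metrics import roc_auc_score

from fallwalk.cohort import (
    CohortConfig,
    GaitSignature,
    SubjectRecord,
    generate_bout,
    generate_cohort,
    generate_recordings,
)


class TestGenerateCohort:
    def test_faller_count_at_study_prevalence(self):
        subjects, _ = generate_cohort(296, 0.341, seed=0)
        assert sum(s.fall_status for s in subjects) == 101

    def test_small_cohort_counts_and_unique_ids(self):
        subjects, sigs = generate_cohort(10, 0.5, seed=1)
        assert sum(s.fall_status for s in subjects) == 5
        assert len({s.subject_id for s in subjects}) == 10
        assert {g.subject_id for g in sigs} == {s.subject_id for s in subjects}

    def test_determinism(self):
        a = generate_cohort(15, 0.4, seed=42)
        b = generate_cohort(15, 0.4, seed=42)
        assert [s.__dict__ for s in a[0]] == [s.__dict__ for s in b[0]]
        for ga, gb in zip(a[1], b[1]):
            assert ga.step_frequency == gb.step_frequency
            assert np.array_equal(ga.amplitude_per_axis, gb.amplitude_per_axis)

    def test_attributes_positive_and_step_frequency_in_band(self):
        cfg = CohortConfig()
        subjects, sigs = generate_cohort(50, 0.341, cfg, seed=3)
        for s in subjects:
            assert s.age > 0 and s.weight > 0 and s.height > 0
            assert s.fall_status in (0, 1) and s.gender in (0, 1)
        lo, hi = cfg.step_freq_band
        for g in sigs:
            assert lo <= g.step_frequency <= hi

    def test_faller_effect_perturbs_variability(self):
        subjects, sigs = generate_cohort(200, 0.5, CohortConfig(faller_delta=1.5), seed=4)
        status = {s.subject_id: s.fall_status for s in subjects}
        v_fall = [g.variability for g in sigs if status[g.subject_id] == 1]
        v_non = [g.variability for g in sigs if status[g.subject_id] == 0]
        assert np.mean(v_fall) > np.mean(v_non)

    @pytest.mark.parametrize("n,frac", [(1, 0.5), (10, 0.0), (10, 1.0), (10, -0.1)])
    def test_invalid_inputs_rejected(self, n, frac):
        with pytest.raises(ValueError):
            generate_cohort(n, frac, seed=0)


class TestGenerateBout:
    def _signature(self, step=2.0, var=0.0, noise=0.0, harmonics=(), amps=(0.3, 0.2, 0.4)):
        return GaitSignature(
            subject_id="S0",
            step_frequency=step,
            amplitude_per_axis=np.array(amps),
            harmonic_weights=np.array(harmonics),
            phase_offsets=np.zeros(3),
            variability=var,
            noise_sd=noise,
        )

    def test_gait_bout_dominant_vt_frequency_matches_step(self):
        sig = self._signature(step=2.0, var=0.02, noise=0.05, harmonics=(0.3, 0.1))
        bout = generate_bout(sig, 10.0, 100.0, seed=5)
        assert bout.samples.shape == (1000, 3)
        # independent periodogram oracle on the vertical channel
        f, p = periodogram(bout.samples[:, 2] - bout.samples[:, 2].mean(), fs=100.0, window="boxcar")
        assert abs(f[np.argmax(p[1:]) + 1] - 2.0) <= 0.1 + 1e-9

    def test_nongait_bout_dominant_vt_frequency_below_bound(self):
        sig = self._signature(noise=0.02)
        for seed in range(5):
            bout = generate_bout(sig, 10.0, 100.0, bout_kind="non-gait", seed=seed)
            f, p = periodogram(bout.samples[:, 2] - bout.samples[:, 2].mean(), fs=100.0, window="boxcar")
            assert f[np.argmax(p[1:]) + 1] <= 0.2 + 1e-9

    def test_pure_sinusoid_when_noise_variability_harmonics_zero(self):
        sig = self._signature(step=2.0, var=0.0, noise=0.0)
        bout = generate_bout(sig, 10.0, 100.0, seed=0)
        ap = bout.samples[:, 0]
        # RMS of a pure sinusoid of amplitude A is A/sqrt(2)
        assert np.isclose(np.sqrt(np.mean(ap**2)), 0.3 / np.sqrt(2), rtol=1e-3)
        assert np.isclose(ap.max(), 0.3, atol=1e-3)
        vt = bout.samples[:, 2] - 1.0  # remove the gravity offset
        assert np.isclose(np.sqrt(np.mean(vt**2)), 0.4 / np.sqrt(2), rtol=1e-3)

    def test_sensor_range_clipping(self):
        sig = self._signature(amps=(10.0, 10.0, 10.0), noise=1.0)
        bout = generate_bout(sig, 5.0, 50.0, seed=1)
        assert np.all(np.abs(bout.samples) <= 6.0)

    def test_nyquist_rejection(self):
        sig = self._signature(step=2.0, harmonics=(0.3, 0.2, 0.1))  # content up to 8 Hz
        with pytest.raises(ValueError, match="Nyquist"):
            generate_bout(sig, 5.0, 10.0, seed=0)

    def test_determinism(self):
        sig = self._signature(var=0.05, noise=0.05, harmonics=(0.2,))
        a = generate_bout(sig, 8.0, 25.0, seed=9)
        b = generate_bout(sig, 8.0, 25.0, seed=9)
        assert np.array_equal(a.samples, b.samples)


class TestGenerateRecordings:
    def test_contamination_fraction_within_binomial_bounds(self):
        subjects, sigs = generate_cohort(100, 0.341, seed=11)
        bouts = generate_recordings(
            subjects, sigs, bouts_per_subject=10, bout_duration_s=10.0, sampling_rate=25.0,
            contamination_rate=0.2, seed=12,
        )
        assert len(bouts) == 1000
        n_non = sum(b.bout_kind == "non-gait" for b in bouts)
        # binomial(1000, 0.2) 99% interval
        lo = 200 - 2.576 * np.sqrt(1000 * 0.2 * 0.8)
        hi = 200 + 2.576 * np.sqrt(1000 * 0.2 * 0.8)
        assert lo <= n_non <= hi

    def test_zero_contamination_all_gait(self):
        subjects, sigs = generate_cohort(5, 0.4, seed=13)
        bouts = generate_recordings(subjects, sigs, bouts_per_subject=3, bout_duration_s=10.0,
                                    sampling_rate=25.0, seed=14)
        assert all(b.bout_kind == "gait" for b in bouts)
        assert all(any(b.subject_id == s.subject_id for s in subjects) for b in bouts)

    def test_determinism_and_rejections(self):
        subjects, sigs = generate_cohort(4, 0.5, seed=15)
        a = generate_recordings(subjects, sigs, 2, 10.0, 25.0, 0.3, seed=16)
        b = generate_recordings(subjects, sigs, 2, 10.0, 25.0, 0.3, seed=16)
        assert all(np.array_equal(x.samples, y.samples) and x.bout_kind == y.bout_kind for x, y in zip(a, b))
        with pytest.raises(ValueError):
            generate_recordings([], [], 2, 10.0, 25.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            generate_recordings(subjects, sigs, 2, 10.0, 25.0, 1.0, seed=0)


class TestLabelSignalCoupling:
    def test_oracle_auc_above_chance_with_faller_effect(self):
        """With delta > 1 the true generative variability separates the classes."""
        subjects, sigs = generate_cohort(120, 0.341, CohortConfig(faller_delta=1.5), seed=17)
        y = np.array([s.fall_status for s in subjects])
        v = np.array([g.variability for g in sigs])
        assert roc_auc_score(y, v) > 0.65

    def test_null_cohort_oracle_auc_near_half(self):
        cfg = CohortConfig(faller_delta=1.0, faller_freq_shift=0.0)
        subjects, sigs = generate_cohort(300, 0.341, cfg, seed=18)
        y = np.array([s.fall_status for s in subjects])
        v = np.array([g.variability for g in sigs])
        assert 0.4 < roc_auc_score(y, v) < 0.6

    def test_signature_separability_by_spectral_centroid(self):
        """Low-noise windows are assignable to their generating subject."""
        cfg = CohortConfig(variability_range=(0.005, 0.01), noise_sd=0.005)
        subjects, sigs = generate_cohort(6, 0.5, cfg, seed=19)
        X, labels = [], []
        for g in sigs:
            for k in range(4):
                b = generate_bout(g, 10.0, 50.0, seed=1000 + hash(g.subject_id) % 500 + k, config=cfg)
                _, p = periodogram(b.samples[:, 2] - b.samples[:, 2].mean(), fs=50.0, window="boxcar")
                X.append(p / p.sum())
                labels.append(g.subject_id)
        X = np.array(X)
        correct = 0
        for i in range(len(X)):
            centroids = {}
            for sid in set(labels):
                rows = [j for j in range(len(X)) if labels[j] == sid and j != i]
                centroids[sid] = X[rows].mean(axis=0)
            pred = min(centroids, key=lambda s: np.sum((X[i] - centroids[s]) ** 2))
            correct += pred == labels[i]
        assert correct / len(X) >= 0.9
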