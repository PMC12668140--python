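"""Staging pipeline: NMF features, classifier, LOSO hygiene, persistence."""

import numpy as np
import pytest

from sleepphys import staging as stg
from sleepphys.sigproc import Spectrogram


def make_spec(power):
    power = np.asarray(power, dtype=float)
    f = np.arange(power.shape[1]) * 0.2
    centers = np.arange(power.shape[0]) * 2.5 + 2.5
    return Spectrogram(power=power, frequencies=f, window_centers=centers,
                       window_s=5, step_s=2.5)


@pytest.fixture
def three_mode_spectra(rng):
    """Spectrogram rows drawn from 3 nonnegative spectral modes + noise."""
    n_f = 50
    modes = np.zeros((3, n_f))
    modes[0, 2:10] = 5.0          # delta-like
    modes[1, 25:35] = 4.0         # theta-like
    modes[2, :] = 1.0             # broadband
    weights = rng.uniform(0.2, 2.0, size=(300, 3))
    x = weights @ modes + rng.uniform(0, 0.02, size=(300, n_f))
    return make_spec(x)


class TestNMF:
    def test_exact_low_rank_input_fully_captured(self, rng):
        w = rng.uniform(0.1, 1, size=(100, 2))
        h = rng.uniform(0.1, 1, size=(2, 30))
        model = stg.fit_nmf(make_spec(w @ h), k=2, seed=0)
        assert model.variance_captured >= 0.999

    def test_three_mode_spectra_mostly_captured(self, three_mode_spectra):
        model = stg.fit_nmf(three_mode_spectra, k=6, seed=0)
        assert model.variance_captured >= 0.90

    def test_duplicate_spectrum_rank_one(self):
        row = np.linspace(1, 5, 30)
        x = np.tile(row, (40, 1))
        model = stg.fit_nmf(make_spec(x), k=1, seed=0)
        assert model.variance_captured >= 0.999

    def test_negative_input_rejected(self):
        f = np.arange(30) * 0.2
        with pytest.raises(ValueError):
            spec = Spectrogram.__new__(Spectrogram)  # bypass validation
            spec.power = -np.ones((10, 30))
            spec.frequencies = f
            spec.window_centers = np.arange(10) * 2.5
            spec.window_s, spec.step_s, spec.n_tapers = 5, 2.5, 1
            stg.fit_nmf(spec, k=2)

    def test_transform_recovers_basis_rows(self, three_mode_spectra):
        model = stg.fit_nmf(three_mode_spectra, k=3, seed=0)
        loadings = stg.transform_nmf(model, make_spec(model.basis))
        # basis vector j projects (almost) onto coordinate j
        for j in range(3):
            assert loadings[j].argmax() == j

    def test_zero_window_zero_loadings(self, three_mode_spectra):
        model = stg.fit_nmf(three_mode_spectra, k=3, seed=0)
        loadings = stg.transform_nmf(model, make_spec(np.zeros((4, 50))))
        assert np.allclose(loadings, 0.0)

    def test_grid_mismatch_rejected(self, three_mode_spectra):
        model = stg.fit_nmf(three_mode_spectra, k=3, seed=0)
        with pytest.raises(ValueError):
            stg.transform_nmf(model, make_spec(np.ones((4, 40))))


class TestFeatures:
    def test_assembles_eight_columns(self, rng):
        n = 20
        fm = stg.assemble_features(rng.uniform(size=(n, 6)), rng.uniform(size=n),
                                   rng.uniform(size=n), np.arange(n) * 2.5)
        assert fm.features.shape == (n, 8)

    def test_standardizer_frozen_from_training(self, rng):
        train = rng.normal(5, 2, size=(200, 8))
        test = rng.normal(0, 1, size=(50, 8))
        std = stg.Standardizer.fit(train)
        zt = std.transform(train)
        assert np.allclose(zt.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(zt.std(axis=0), 1, atol=1e-9)
        zh = std.transform(test)
        # held-out data standardized with training parameters, not its own
        assert not np.allclose(zh.mean(axis=0), 0, atol=0.5)

    def test_balancing_downsamples_to_rarest(self, rng):
        y = np.array([0] * 100 + [1] * 50 + [2] * 10)
        x = rng.normal(size=(160, 8))
        xb, yb = stg.balance_classes(x, y, seed=0)
        assert np.bincount(yb).tolist() == [10, 10, 10]


class TestClassifier:
    @pytest.fixture
    def clusters(self, rng):
        x = np.vstack([rng.normal(m, 0.3, size=(150, 8))
                       for m in (0.0, 3.0, 6.0)])
        y = np.repeat([0, 1, 2], 150)
        return x, y

    def test_separable_clusters_learned_perfectly(self, clusters):
        x, y = clusters
        clf = stg.train_classifier(x, y, seed=0)
        assert (clf.predict(x) == y).mean() == 1.0

    def test_shuffled_labels_at_chance(self, clusters, rng):
        x, y = clusters
        y_shuf = rng.permutation(y)
        clf = stg.train_classifier(x[:300], y_shuf[:300], seed=0)
        acc = (clf.predict(x[300:]) == y_shuf[300:]).mean()
        assert abs(acc - 1 / 3) < 0.2

    def test_same_seed_identical_predictions(self, clusters):
        x, y = clusters
        p1 = stg.train_classifier(x, y, seed=7).predict(x)
        p2 = stg.train_classifier(x, y, seed=7).predict(x)
        assert np.array_equal(p1, p2)

    def test_missing_class_rejected(self, rng):
        x = rng.normal(size=(40, 8))
        with pytest.raises(ValueError):
            stg.train_classifier(x, np.repeat([0, 1], 20), seed=0)


class TestPersistenceFilter:
    def _h(self, labels):
        labels = np.asarray(labels)
        return stg.Hypnogram(labels=labels,
                             window_centers=np.arange(labels.size) * 2.5)

    def test_short_rem_run_absorbed_into_nrem(self):
        y = [1] * 30 + [2] * 14 + [1] * 30
        out = stg.persistence_filter(self._h(y), min_run=15)
        assert (out.labels == 1).all()

    def test_uniform_input_unchanged(self):
        out = stg.persistence_filter(self._h([1] * 50), min_run=15)
        assert (out.labels == 1).all()

    def test_short_middle_run_absorbed_into_preceding(self):
        y = [0] * 20 + [1] * 5 + [0] * 15
        out = stg.persistence_filter(self._h(y), min_run=15)
        assert (out.labels == 0).all()

    def test_leading_short_run_joins_following_state(self):
        y = [2] * 5 + [0] * 30
        out = stg.persistence_filter(self._h(y), min_run=15)
        assert (out.labels == 0).all()

    def test_idempotent(self, rng):
        y = rng.integers(0, 3, size=300)
        once = stg.persistence_filter(self._h(y), min_run=15)
        twice = stg.persistence_filter(once, min_run=15)
        assert np.array_equal(once.labels, twice.labels)

    def test_never_introduces_new_labels(self, rng):
        y = rng.choice([0, 1], size=200)        # no REM in input
        out = stg.persistence_filter(self._h(y), min_run=15)
        assert set(np.unique(out.labels)) <= set(np.unique(y))

    def test_surviving_runs_meet_minimum(self, rng):
        y = rng.integers(0, 3, size=400)
        out = stg.persistence_filter(self._h(y), min_run=15)
        bounds = np.flatnonzero(np.diff(out.labels)) + 1
        lengths = np.diff(np.concatenate([[0], bounds, [out.labels.size]]))
        assert (lengths[:-1] >= 15).all()       # terminal remnant exempt


class TestLOSO:
    def _subject(self, rng, n=240, shuffle_labels=False, snr=1.0):
        """Subject whose spectrogram rows and RMS features encode the state."""
        y = np.repeat(rng.permutation(np.repeat([0, 1, 2], n // 3 + 1))[:n // 20],
                      20)[:n]
        n_f = 40
        modes = np.zeros((3, n_f))
        modes[0, 20:30] = 2.0
        modes[1, 2:10] = 6.0
        modes[2, 10:18] = 4.0
        power = (modes[y] * snr
                 + rng.uniform(0, 1.0, size=(n, n_f)))
        emg = np.where(y == 0, 10.0, 2.0) * snr + rng.normal(0, 1, n)
        acc = np.where(y == 0, 1.0, 0.1) * snr + rng.normal(0, 0.05, n)
        h = stg.Hypnogram(labels=y, window_centers=np.arange(n) * 2.5)
        return make_spec(power), np.abs(emg), np.abs(acc), h

    def test_identical_separable_subjects_score_high(self, rng):
        subs = [self._subject(rng) for _ in range(2)]
        rep = stg.loso_cv(spectrograms=[s[0] for s in subs],
                          emg_rms=[s[1] for s in subs],
                          accel_rms=[s[2] for s in subs],
                          labels=[s[3] for s in subs], seed=0, min_run=5)
        assert rep.overall_accuracy >= 0.95

    def test_uninformative_features_near_chance(self, rng):
        subs = []
        for _ in range(3):
            spec, emg, acc, h = self._subject(rng)
            shuffled = stg.Hypnogram(labels=rng.permutation(h.labels),
                                     window_centers=h.window_centers)
            subs.append((spec, emg, acc, shuffled))
        rep = stg.loso_cv(spectrograms=[s[0] for s in subs],
                          emg_rms=[s[1] for s in subs],
                          accel_rms=[s[2] for s in subs],
                          labels=[s[3] for s in subs], seed=0, min_run=1)
        assert rep.overall_accuracy < 0.55

    def test_confusion_rows_match_class_counts(self, rng):
        subs = [self._subject(rng) for _ in range(2)]
        rep = stg.loso_cv(spectrograms=[s[0] for s in subs],
                          emg_rms=[s[1] for s in subs],
                          accel_rms=[s[2] for s in subs],
                          labels=[s[3] for s in subs], seed=0, min_run=5)
        true_counts = np.zeros(3, dtype=int)
        for s in subs:
            true_counts += np.bincount(s[3].labels, minlength=3)
        assert np.array_equal(rep.confusion.sum(axis=1), true_counts)

    def test_single_subject_rejected(self, rng):
        s = self._subject(rng)
        with pytest.raises(ValueError):
            stg.loso_cv(spectrograms=[s[0]], emg_rms=[s[1]],
                        accel_rms=[s[2]], labels=[s[3]])
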