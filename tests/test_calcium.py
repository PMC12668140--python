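"""ΔF/F conditioning, transient detection, and state preference."""

import numpy as np
import pytest

from sleepphys import calcium as ca
from sleepphys import synthio as syn
from sleepphys.staging import Hypnogram


def make_h(labels, step=2.5):
    labels = np.asarray(labels)
    return Hypnogram(labels=labels,
                     window_centers=np.arange(labels.size) * step + step / 2)


class TestDetrendNormalize:
    def test_pure_cubic_removed_exactly(self):
        t = np.linspace(0, 10, 400)
        raw = 5.0 + 0.3 * t - 0.05 * t ** 2 + 0.002 * t ** 3
        dff = ca.detrend_normalize(raw)
        assert np.abs(dff).max() < 1e-10

    def test_transient_amplitude_in_dff_units(self):
        """A transient that doubles the baseline reads as ~1.0 ΔF/F."""
        n = 2000
        base = 100.0
        raw = np.full(n, base)
        raw[1000:1010] += base          # 100% transient
        dff = ca.detrend_normalize(raw)
        assert dff.max() == pytest.approx(1.0, rel=0.05)

    def test_offset_affects_only_scale(self):
        rng = np.random.default_rng(0)
        raw = 50 + rng.normal(0, 1, 1000)
        d1 = ca.detrend_normalize(raw)
        d2 = ca.detrend_normalize(raw + 50)
        # same shape, rescaled by the mean ratio
        assert np.allclose(d1, d2 * (raw.mean() + 50) / raw.mean(), atol=1e-9)

    def test_zero_mean_trace_rejected(self):
        x = np.sin(np.linspace(0, 20 * np.pi, 1000))
        x -= x.mean()
        with pytest.raises(ValueError):
            ca.detrend_normalize(x)


class TestDetectTransients:
    def test_flat_trace_no_events(self):
        train = ca.detect_transients(np.zeros(1000), fs=4.0)
        assert train.n_events == 0

    def test_three_well_separated_peaks(self):
        fs = 4.0
        dff = np.zeros(400)
        for t0 in (50.0, 55.0, 60.0):       # 5 s apart
            dff[int(t0 * fs)] = 1.5
        train = ca.detect_transients(dff, fs=fs)
        assert train.n_events == 3

    def test_close_pair_keeps_only_higher(self):
        fs = 4.0
        dff = np.zeros(200)
        dff[100] = 1.5
        dff[102] = 1.8                       # 0.5 s later
        train = ca.detect_transients(dff, fs=fs)
        assert train.n_events == 1
        assert train.event_times_s[0] == pytest.approx(102 / fs)

    def test_subthreshold_height_ignored(self):
        dff = np.zeros(200)
        dff[100] = 0.9                       # below the 1.0 height bar
        assert ca.detect_transients(dff, fs=4.0).n_events == 0

    def test_low_prominence_shoulder_ignored(self):
        # second peak clears the height bar but its saddle to the higher
        # neighboring peak only drops to 0.9, so prominence = 0.4 < 0.8
        dff = np.zeros(400)
        dff[100] = 2.0
        dff[101:200] = 0.9
        dff[200] = 1.3
        train = ca.detect_transients(dff, fs=4.0)
        assert train.n_events == 1
        assert train.event_times_s[0] == pytest.approx(25.0)

    def test_recovers_synthetic_ground_truth(self):
        """Recall and precision >= 0.95 against generator truth at the
        default noise level (0.1 ΔF/F)."""
        states = syn.StateSequence(np.tile([0, 1, 2], 480), window_s=2.5)
        tp = fp = fn = 0
        for seed in range(5):
            trace, truth = syn.synthesize_calcium(
                states, {0: 0.5, 1: 2.0, 2: 1.0}, noise_sd=0.1, seed=seed)
            det = ca.detect_transients(trace, fs=4.0)
            matched = np.zeros(truth.size, dtype=bool)
            for et in det.event_times_s:
                d = np.abs(truth - et)
                j = d.argmin() if truth.size else None
                if j is not None and d[j] <= 1.0 and not matched[j]:
                    matched[j] = True
                    tp += 1
                else:
                    fp += 1
            fn += int((~matched).sum())
        assert tp / (tp + fn) >= 0.95        # recall
        assert tp / (tp + fp) >= 0.95        # precision


class TestDetect2P:
    def test_gaussian_noise_tail_fraction(self, rng):
        x = rng.standard_normal(200_000) * 0.05 + 10.0
        mask = ca.detect_transients_2p(x, fs=4.0)
        assert mask.mean() == pytest.approx(0.00135, abs=0.002)

    def test_plateau_detected_as_single_period(self, rng):
        x = rng.standard_normal(4000) * 0.05 + 10.0
        x[2000:2100] += 5 * 0.05 * 3          # far above 3 SD
        mask = ca.detect_transients_2p(x, fs=4.0)
        periods = ca.mask_to_periods(mask, fs=4.0)
        long = [p for p in periods if p[1] - p[0] > 5]
        assert len(long) == 1
        assert long[0][0] == pytest.approx(500.0, abs=2.0)

    def test_constant_trace_no_events(self):
        mask = ca.detect_transients_2p(np.full(1000, 7.0), fs=4.0)
        assert not mask.any()


class TestStateRates:
    def test_simple_rate(self):
        h = make_h(np.ones(240, dtype=int))          # 10 min NREM
        ev = ca.TransientTrain(np.linspace(10, 590, 10), fs=4.0)
        rates, counts, minutes = ca.state_rates(ev, h, 2.5)
        assert rates[1] == pytest.approx(1.0)
        assert counts[1] == 10 and minutes[1] == pytest.approx(10.0)

    def test_events_only_in_wake(self):
        h = make_h(np.repeat([0, 1], 120))
        ev = ca.TransientTrain(np.array([10.0, 50.0, 100.0]), fs=4.0)
        rates, counts, _ = ca.state_rates(ev, h, 2.5)
        assert counts[0] == 3 and counts[1] == 0
        assert rates[1] == 0.0

    def test_zero_exposure_rate_undefined(self):
        h = make_h(np.zeros(120, dtype=int))         # wake only
        ev = ca.TransientTrain(np.array([5.0]), fs=4.0)
        rates, _, _ = ca.state_rates(ev, h, 2.5)
        assert np.isnan(rates[2])

    def test_poisson_rates_recovered(self):
        """Generating rates recovered within 10% at 60 min exposure/state."""
        labels = np.tile(np.repeat([0, 1, 2], 24), 60)   # 1 min blocks x 60
        states = syn.StateSequence(labels, window_s=2.5)
        h = make_h(labels)
        gen = np.array([1.0, 3.0, 2.0])
        errs = []
        for seed in range(10):
            _, truth = syn.synthesize_calcium(states, gen, seed=seed)
            ev = ca.TransientTrain(truth, fs=4.0)
            rates, _, minutes = ca.state_rates(ev, h, 2.5)
            assert np.allclose(minutes, 60.0)
            errs.append(np.abs(rates - gen) / gen)
        assert np.mean(errs) <= 0.10


class TestStatePreference:
    def test_symmetric_two_state(self):
        pref = ca.state_preference(np.array([1.0, 1.0, np.nan]))
        assert pref.s[0] == pytest.approx(0.5)

    def test_published_median_rates_give_nrem_preference(self):
        """The NREM/REM/wake median rates 0.5076/0.2437/0.0677 yield
        S_NREM = 0.620."""
        rates = np.array([0.0677, 0.5076, 0.2437])   # W, N, R
        pref = ca.state_preference(rates)
        assert pref.s[1] == pytest.approx(0.620, abs=0.001)
        assert pref.preferred_state == 1

    def test_all_zero_cell_excluded(self):
        pref = ca.state_preference(np.zeros(3))
        assert not pref.included and pref.preferred_state is None

    def test_scale_invariance(self, rng):
        rates = rng.uniform(0.1, 2.0, 3)
        s1 = ca.state_preference(rates).s
        s2 = ca.state_preference(rates * 7.3).s
        assert np.allclose(s1, s2)

    def test_s_sums_to_one(self, rng):
        for _ in range(20):
            rates = rng.uniform(0, 2.0, 3)
            if rates.sum() == 0:
                continue
            assert np.nansum(ca.state_preference(rates).s) == pytest.approx(1.0)

    def test_preferred_by_count_not_rate(self):
        # higher rate in REM but more total transients in NREM
        rates = np.array([0.1, 1.0, 2.0])
        counts = np.array([5, 60, 20])
        pref = ca.state_preference(rates, counts=counts)
        assert pref.preferred_state == 1

    def test_count_tie_broken_by_exposure(self):
        rates = np.array([1.0, 0.5, 0.0])
        counts = np.array([10, 10, 0])
        pref = ca.state_preference(rates, counts=counts,
                                   exposure_min=np.array([10.0, 20.0, 5.0]))
        assert pref.preferred_state == 1


class TestSurvivor:
    def test_all_ones(self):
        assert ca.survivor_at(np.ones(10)) == 1.0

    def test_published_fraction(self):
        """44 of 83 cells above S = 0.5 gives P(0.5) = 0.53."""
        s = np.concatenate([np.full(44, 0.8), np.full(39, 0.2)])
        assert ca.survivor_at(s, 0.5) == pytest.approx(44 / 83, abs=1e-9)
        assert round(ca.survivor_at(s, 0.5), 2) == 0.53

    def test_none_above_threshold(self):
        assert ca.survivor_at(np.full(5, 0.1), 0.5) == 0.0

    def test_curve_right_continuous_and_decreasing(self, rng):
        grid, p = ca.survivor_curve(rng.uniform(size=50))
        assert p[0] == 1.0
        assert (np.diff(p) <= 0).all()


class TestSimplex:
    def test_uniform_preference_maps_to_centroid(self):
        xy, _ = ca.simplex_coordinates(np.array([[1 / 3, 1 / 3, 1 / 3]]))
        centroid = np.array([[0.5, np.sqrt(3) / 6]])
        assert np.allclose(xy, centroid)

    def test_pure_state_maps_to_vertex(self):
        xy, props = ca.simplex_coordinates(np.array([[1.0, 0.0, 0.0]]))
        assert np.allclose(xy, [[0.0, 0.0]])
        assert props[0] == 1.0

    def test_nrem_biased_cohort(self, rng):
        s = rng.dirichlet([1, 6, 1], size=200)
        _, props = ca.simplex_coordinates(s)
        assert props[1] == max(props)

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ca.simplex_coordinates(np.array([[0.5, 0.2, 0.2]]))
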