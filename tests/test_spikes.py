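import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socioscope import spikes as spk
from socioscope.behavior import Bout, BoutSet
from socioscope.io_model import SpikeTrain

from conftest import sine_lfp


@pytest.fixture(scope="module")
def tone_phase():
    """Phase of a 5 Hz tone over 100 s at 1 kHz (peak at t = k/5 -> 0°)."""
    lfp = sine_lfp(5.0, duration_s=100.0, fs=1000.0, phase=np.pi / 2)  # cosine
    return spk.instantaneous_phase(lfp, (4.0, 7.0))


def times_from_phases(phases_deg, rng, duration_s=100.0, f0=5.0):
    """Spike times of a 5 Hz-locked unit with the given phases."""
    phases = np.mod(np.asarray(phases_deg, dtype=float), 360.0)
    cycles = rng.integers(1, int(duration_s * f0) - 1, size=len(phases))
    return np.sort((cycles + phases / 360.0) / f0)


class TestClassifyUnits:
    @pytest.mark.parametrize(
        "rate,width,expected",
        [
            (12.0, 0.3, "FS"),
            (5.0, 0.8, "RS"),
            (5.0, 0.4, "unclassified"),
            (10.0, 0.8, "unclassified"),  # boundary rate is neither
            (15.0, 0.9, "FS"),  # rate criterion dominates for fast units
        ],
    )
    def test_classification_rules(self, rate, width, expected):
        df = pd.DataFrame(
            {"unit_id": ["u0"], "baseline_rate_hz": [rate], "spike_width_ms": [width]}
        )
        assert spk.classify_units(df)["unit_class"].iloc[0] == expected

    def test_nonfinite_features_rejected(self):
        df = pd.DataFrame(
            {"unit_id": ["u0"], "baseline_rate_hz": [np.nan], "spike_width_ms": [0.5]}
        )
        with pytest.raises(ValueError):
            spk.classify_units(df)


class TestInstantaneousPhase:
    def test_phase_advances_360_per_cycle(self, tone_phase):
        unwrapped = np.unwrap(np.radians(tone_phase.phase_deg))
        slope = np.polyfit(np.arange(len(unwrapped)) / 1000.0, unwrapped, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 5.0, rel=0.01)

    def test_peaks_map_to_zero_degrees(self, tone_phase):
        # tone peaks at t = k / 5 s
        peaks = (np.arange(10, 400, 10) / 5.0 * 1000).astype(int)
        assert np.allclose(tone_phase.phase_deg[peaks], 0.0, atol=1.0)

    def test_long_oscillation_phase_histogram_uniform(self, tone_phase):
        counts, _ = np.histogram(tone_phase.phase_deg, bins=12, range=(-180, 180))
        assert counts.max() / counts.min() < 1.1

    def test_band_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            spk.instantaneous_phase(sine_lfp(5.0, fs=100.0, duration_s=5.0), (30, 60))


class TestPhaseDistribution:
    def test_smoothing_conserves_mass(self):
        v = np.zeros(12)
        v[4] = 120.0
        sm = spk.circular_gaussian_smooth(v)
        assert sm.sum() == pytest.approx(v.sum())
        assert sm[4] == sm.max()
        assert sm[3] == pytest.approx(sm[5])  # symmetric spread into neighbors

    def test_smoothing_matches_brute_force_convolution(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 10, 12)
        sm = spk.circular_gaussian_smooth(v)
        kernel = np.exp(-0.5 * np.array([min(j, 12 - j) for j in range(12)]) ** 2)
        # wrap tails exactly as the implementation defines the kernel
        offs = np.arange(12)
        kernel = sum(np.exp(-0.5 * (offs + m * 12.0) ** 2) for m in range(-3, 4))
        kernel /= kernel.sum()
        oracle = np.array(
            [sum(v[j] * kernel[(i - j) % 12] for j in range(12)) for i in range(12)]
        )
        assert np.allclose(sm, oracle)

    def test_uniform_spikes_give_flat_distribution(self, tone_phase):
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0, 100.0, 20_000))
        dist = spk.phase_distribution(times, tone_phase)
        assert dist.n_spikes == 20_000
        assert dist.rate_hz.max() / dist.rate_hz.min() < 1.1

    def test_zero_spikes_flagged(self, tone_phase):
        with pytest.warns(UserWarning):
            dist = spk.phase_distribution(np.empty(0), tone_phase)
        assert dist.n_spikes == 0
        assert np.allclose(dist.rate_hz, 0.0)


class TestMvl:
    def test_perfect_locking_and_uniform_limits(self):
        assert spk.mean_vector_length(np.full(100, 42.0))[0] == pytest.approx(1.0)
        uniform = np.arange(0, 360, 15.0) - 180.0
        assert spk.mean_vector_length(uniform)[0] == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_bessel_ratio(self):
        from scipy.special import i0, i1

        rng = np.random.default_rng(2)
        phases = np.degrees(rng.vonmises(0.5, 1.0, 20_000))
        mvl, pref = spk.mean_vector_length(phases)
        assert mvl == pytest.approx(i1(1.0) / i0(1.0), abs=0.02)
        assert pref == pytest.approx(np.degrees(0.5), abs=5.0)

    def test_monotone_in_concentration(self):
        rng = np.random.default_rng(3)
        mvls = [
            spk.mean_vector_length(np.degrees(rng.vonmises(0.0, k, 20_000)))[0]
            for k in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a < b for a, b in zip(mvls, mvls[1:]))

    @settings(max_examples=20, deadline=None)
    @given(rotation=st.floats(-180, 180), seed=st.integers(0, 100))
    def test_invariant_to_global_phase_rotation(self, rotation, seed):
        rng = np.random.default_rng(seed)
        phases = np.degrees(rng.vonmises(0.0, 1.5, 500))
        rotated = np.mod(phases + rotation + 180.0, 360.0) - 180.0
        m1, _ = spk.mean_vector_length(phases)
        m2, _ = spk.mean_vector_length(rotated)
        assert m1 == pytest.approx(m2, abs=1e-9)

    def test_binned_variant_attenuated_by_kernel(self, tone_phase):
        # smoothing with a circular Gaussian of SD sigma shrinks the
        # resultant by exp(-sigma^2/2); the binned variant shows exactly
        # that bias relative to the raw-phase estimator (hence raw default)
        rng = np.random.default_rng(4)
        times = times_from_phases(np.degrees(rng.vonmises(0.0, 2.0, 5000)), rng)
        dist = spk.phase_distribution(times, tone_phase)
        raw, pref_raw = spk.mean_vector_length(tone_phase.at_times(times))
        binned, pref_binned = spk.mean_vector_length(dist, method="binned")
        sigma = np.pi / 6  # one 30° bin
        assert binned == pytest.approx(raw * np.exp(-(sigma**2) / 2), abs=0.03)
        assert pref_binned == pytest.approx(pref_raw, abs=10.0)


class TestShuffleNull:
    def test_locked_unit_significant(self, tone_phase):
        rng = np.random.default_rng(5)
        times = times_from_phases(np.degrees(rng.vonmises(0.0, 2.0, 1000)), rng)
        res = spk.shuffle_null(times, tone_phase, n_shuffle=1000, seed=6)
        assert res.significant
        assert res.p_value < 0.001

    def test_same_seed_bit_reproducible(self, tone_phase):
        rng = np.random.default_rng(7)
        times = np.sort(rng.uniform(0, 100, 200))
        r1 = spk.shuffle_null(times, tone_phase, n_shuffle=200, seed=11)
        r2 = spk.shuffle_null(times, tone_phase, n_shuffle=200, seed=11)
        assert np.array_equal(r1.shuffle_mvls, r2.shuffle_mvls)
        assert r1.p_value == r2.p_value

    def test_low_count_flagged(self, tone_phase):
        with pytest.warns(UserWarning, match="low-count"):
            res = spk.shuffle_null(np.array([1.0, 2.0, 3.0]), tone_phase, n_shuffle=100, seed=0)
        assert res.low_count

    def test_too_few_shuffles_rejected(self, tone_phase):
        with pytest.raises(ValueError):
            spk.shuffle_null(np.arange(20.0), tone_phase, n_shuffle=50)


class TestBehaviorLockedMvl:
    @staticmethod
    def _bouts():
        bouts = [Bout("approach", 10.0 * k, 10.0 * k + 5.0) for k in range(0, 10, 2)]
        bouts += [Bout("leaving", 10.0 * k, 10.0 * k + 5.0) for k in range(1, 10, 2)]
        return BoutSet(sorted(bouts, key=lambda b: b.start_s), np.empty((0, 2)), (0.0, 100.0))

    def _unit(self, tone_phase, kappa_appr, kappa_leav, seed=0, n_per_state=800):
        rng = np.random.default_rng(seed)
        bouts = self._bouts()
        times = []
        for state, kappa in (("approach", kappa_appr), ("leaving", kappa_leav)):
            ivs = bouts.intervals(state)
            phases = (
                np.degrees(rng.vonmises(0.0, kappa, n_per_state))
                if kappa > 0
                else rng.uniform(-180, 180, n_per_state)
            )
            t = times_from_phases(phases, rng)
            # map into bout windows by rejection
            keep = np.zeros(len(t), dtype=bool)
            for s, e in ivs:
                keep |= (t >= s) & (t < e)
            times.append(t[keep])
        all_times = np.sort(np.concatenate(times))
        return SpikeTrain("u0", all_times, 15.0, 0.3), bouts

    def test_state_specific_locking_retained(self, tone_phase):
        unit, bouts = self._unit(tone_phase, 0.0, 1.5)
        appr, leav, excluded = spk.behavior_locked_mvl(unit, tone_phase, bouts, 500, seed=1)
        assert leav.significant and not appr.significant
        assert not excluded
        assert leav.mvl > appr.mvl

    def test_locked_in_both_states_excluded(self, tone_phase):
        unit, bouts = self._unit(tone_phase, 2.0, 2.0)
        appr, leav, excluded = spk.behavior_locked_mvl(unit, tone_phase, bouts, 500, seed=2)
        assert appr.significant and leav.significant
        assert excluded and appr.excluded_behavior_irrelevant

    def test_locked_in_neither_retained(self, tone_phase):
        unit, bouts = self._unit(tone_phase, 0.0, 0.0)
        appr, leav, excluded = spk.behavior_locked_mvl(unit, tone_phase, bouts, 500, seed=3)
        assert not excluded

    def test_missing_bout_state_errors(self, tone_phase):
        unit, _ = self._unit(tone_phase, 0.0, 1.0)
        only_appr = BoutSet([Bout("approach", 0.0, 5.0)], np.empty((0, 2)), (0.0, 100.0))
        with pytest.raises(ValueError, match="leaving"):
            spk.behavior_locked_mvl(unit, tone_phase, only_appr, 100)
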