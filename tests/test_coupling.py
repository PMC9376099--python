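"""Modulation index, spike-field coherence, surrogates, correlograms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavepipe.coupling import (
    MIResult,
    mi_surrogate_z,
    modulation_index,
    phase_amplitude_distribution,
    sfc_poisson_surrogate_z,
    spike_cross_correlogram,
    spike_delay_histogram,
    spike_field_coherence,
    intersite_sfc,
)
from wavepipe.synth import CouplingSpec, SpikeSpec, generate_locked_spikes, generate_pac_signal


def brute_force_mi(phase, amplitude, n_bins=20):
    """Independent, naively coded MI: explicit loops, (-pi, pi] bins,
    per-trial means averaged before normalization."""
    phase = np.atleast_2d(phase)
    amplitude = np.atleast_2d(amplitude)
    width = 2 * math.pi / n_bins
    per_trial = []
    for ph_row, amp_row in zip(phase, amplitude):
        sums = [0.0] * n_bins
        counts = [0] * n_bins
        for ph, amp in zip(ph_row, amp_row):
            j = 0
            while not (-math.pi + (j + 1) * width >= ph):
                j += 1
            j = min(j, n_bins - 1)
            sums[j] += amp
            counts[j] += 1
        per_trial.append([s / c if c else math.nan for s, c in zip(sums, counts)])
    means = []
    for j in range(n_bins):
        vals = [row[j] for row in per_trial if not math.isnan(row[j])]
        means.append(sum(vals) / len(vals))
    total = sum(means)
    p = [m / total for m in means]
    kl = sum(pj * math.log(pj / (1.0 / n_bins)) for pj in p if pj > 0)
    return kl / math.log(n_bins)


class TestModulationIndex:
    def test_uniform_distribution_gives_zero(self):
        res = MIResult.from_distribution(np.full(20, 1 / 20))
        assert res.mi == 0.0

    def test_single_bin_mass_gives_one(self):
        p = np.zeros(20)
        p[7] = 1.0
        res = MIResult.from_distribution(p)
        assert np.isclose(res.mi, 1.0)
        assert np.isclose(res.preferred_phase,
                          -np.pi + (7 + 0.5) * 2 * np.pi / 20)

    def test_matches_brute_force_oracle(self):
        _, phase, truth = generate_pac_signal(CouplingSpec(depth=0.5),
                                              duration=30.0,
                                              sampling_rate=250.0, seed=11)
        amp = truth["fast_amplitude"]
        mine = modulation_index(phase, amp).mi
        oracle = brute_force_mi(phase, amp)
        assert abs(mine - oracle) < 1e-12

    def test_matches_oracle_multitrial(self, rng):
        phase = rng.uniform(-np.pi, np.pi, size=(5, 400))
        amp = rng.gamma(2.0, 1.0, size=(5, 400))
        assert abs(modulation_index(phase, amp).mi
                   - brute_force_mi(phase, amp)) < 1e-12

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_amplitude_rescaling(self, scale):
        rng = np.random.default_rng(5)
        phase = rng.uniform(-np.pi, np.pi, 2000)
        amp = rng.gamma(2.0, 1.0, 2000)
        a = modulation_index(phase, amp).mi
        b = modulation_index(phase, scale * amp).mi
        assert abs(a - b) < 1e-12

    def test_invariant_under_joint_rotation(self):
        """Rotating phase by a whole number of bins rotates the preferred
        phase but leaves MI unchanged."""
        rng = np.random.default_rng(6)
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = 1.0 + 0.5 * np.cos(phase - 0.3)
        shift = 3 * 2 * np.pi / 20
        rotated = np.angle(np.exp(1j * (phase + shift)))
        a = modulation_index(phase, amp)
        b = modulation_index(rotated, 1.0 + 0.5 * np.cos(rotated - 0.3 - shift))
        assert abs(a.mi - b.mi) < 1e-12

    def test_rejects_empty_window(self):
        with pytest.raises(ValueError):
            modulation_index(np.array([]), np.array([]))


class TestMiSurrogates:
    def test_observed_equal_to_surrogate_mean_gives_zero_z(self):
        """Phase-independent amplitude: observed MI sits inside the null."""
        rng = np.random.default_rng(7)
        phase = rng.uniform(-np.pi, np.pi, 20000)
        amp = rng.gamma(2.0, 1.0, 20000)
        z, _ = mi_surrogate_z(phase, amp, n_surr=100, seed=8)
        assert abs(z) < 3.0

    def test_coupled_signal_strongly_significant(self):
        sig, phase, _ = generate_pac_signal(CouplingSpec(depth=1.0),
                                            duration=60.0,
                                            sampling_rate=500.0,
                                            noise_std=0.5, seed=9)
        from wavepipe.timefreq import analytic_signal, butterworth_band, edge_mask

        amp = np.abs(analytic_signal(butterworth_band(sig, (30, 50), 500.0)))
        m = edge_mask(phase.size, 500.0, 3.0)
        z, res = mi_surrogate_z(phase[m], amp[m], n_surr=100, seed=10)
        assert z > 5.0

    def test_deterministic_for_fixed_seed(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.gamma(2.0, 1.0, 5000)
        z1, _ = mi_surrogate_z(phase, amp, n_surr=20, seed=3)
        z2, _ = mi_surrogate_z(phase, amp, n_surr=20, seed=3)
        assert z1 == z2


class TestSpikeFieldCoherence:
    def test_spikes_at_single_phase_give_mi_one(self):
        fs = 1000.0
        rng = np.random.default_rng(3)
        phase = rng.uniform(-np.pi, np.pi, 20000)
        spike_idx = rng.choice(20000, 150, replace=False)
        phase[spike_idx] = 0.0  # spikes placed exactly at phase 0
        spikes = np.sort(spike_idx) / fs
        res = spike_field_coherence(spikes, phase, fs)
        assert np.isclose(res.mi, 1.0)
        assert abs(res.preferred_phase) < 2 * np.pi / 20

    def test_locked_spikes_recovered(self):
        _, phase, _ = generate_pac_signal(CouplingSpec(), duration=120.0,
                                          sampling_rate=500.0, seed=12)
        spec = SpikeSpec(baseline_rate=10.0, kappa=1.0,
                         preferred_phase=np.pi / 3)
        train = generate_locked_spikes(phase, spec, sampling_rate=500.0,
                                       seed=13)
        z, res = sfc_poisson_surrogate_z(train.spike_times, phase, 500.0,
                                         n_surr=100, seed=14)
        assert z > 3.0
        err = np.angle(np.exp(1j * (res.preferred_phase_mean - np.pi / 3)))
        assert abs(err) < 0.35

    def test_unlocked_spikes_usually_not_significant(self):
        hits = 0
        for seed in range(10):
            _, phase, _ = generate_pac_signal(CouplingSpec(), duration=30.0,
                                              sampling_rate=250.0,
                                              seed=20 + seed)
            train = generate_locked_spikes(
                phase, SpikeSpec(baseline_rate=10.0, kappa=0.0),
                sampling_rate=250.0, seed=40 + seed)
            z, _ = sfc_poisson_surrogate_z(train.spike_times, phase, 250.0,
                                           n_surr=60, seed=60 + seed)
            hits += abs(z) > 1.96
        assert hits <= 1

    def test_zero_spikes_undefined_not_zero(self):
        phase = np.zeros(1000)
        with pytest.raises(ValueError, match="undefined"):
            spike_field_coherence(np.array([]), phase, 1000.0)

    def test_intersite_identical_code_path(self):
        _, phase, _ = generate_pac_signal(CouplingSpec(), duration=30.0,
                                          sampling_rate=250.0, seed=15)
        train = generate_locked_spikes(
            phase, SpikeSpec(baseline_rate=5.0, kappa=1.0),
            sampling_rate=250.0, seed=16)
        a = spike_field_coherence(train.spike_times, phase, 250.0)
        b = intersite_sfc(train.spike_times, phase, 250.0)
        assert a.mi == b.mi and a.preferred_phase == b.preferred_phase

    def test_merged_trials_consistency(self):
        """Counting over one long window equals trial-wise counting with
        equal trial weights when trials tile the window."""
        fs = 250.0
        _, phase, _ = generate_pac_signal(CouplingSpec(), duration=40.0,
                                          sampling_rate=fs, seed=17)
        train = generate_locked_spikes(
            phase, SpikeSpec(baseline_rate=8.0, kappa=1.5),
            sampling_rate=fs, seed=18)
        merged = spike_field_coherence(train.spike_times, phase, fs)
        stim = np.arange(0.0, 40.0, 2.0)
        trialed = spike_field_coherence(train.spike_times, phase, fs,
                                        stim_times=stim, window=(0.0, 2.0))
        np.testing.assert_allclose(merged.p, trialed.p, atol=1e-12)


class TestCorrelograms:
    def test_identical_trains_peak_at_zero(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 10, 200))
        lags, prob = spike_cross_correlogram(t, t)
        assert lags[np.argmax(prob)] == pytest.approx(0.0, abs=1e-9)

    def test_shifted_train_peak_at_shift(self):
        t = np.sort(np.random.default_rng(1).uniform(0, 20, 300))
        lags, prob = spike_cross_correlogram(t, t + 0.03)
        assert abs(lags[np.argmax(prob)] - 0.03) <= 0.005

    def test_independent_poisson_flat(self):
        rng = np.random.default_rng(2)
        a = np.sort(rng.uniform(0, 200, 2000))
        b = np.sort(rng.uniform(0, 200, 2000))
        lags, prob = spike_cross_correlogram(a, b, lag_range=(-0.1, 0.1),
                                             bin_width=0.01)
        counts = prob * a.size
        expected = counts.mean()
        assert np.all(np.abs(counts - expected) <= 3 * np.sqrt(expected))

    def test_pre_post_windows(self):
        stim = np.array([5.0])
        a = np.array([4.8, 5.1])
        b = np.array([4.85, 5.13])
        out = spike_delay_histogram(a, b, stim)
        lags_pre, pre = out["pre"]
        lags_post, post = out["post"]
        assert lags_pre[np.argmax(pre)] == pytest.approx(0.05, abs=0.005)
        assert lags_post[np.argmax(post)] == pytest.approx(0.03, abs=0.005)

    def test_empty_train_zero_histogram(self):
        lags, prob = spike_cross_correlogram(np.array([]), np.array([1.0]))
        assert np.allclose(prob, 0.0)
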