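"""Synthetic multichannel recordings with known ground truth.

Every downstream stage of the pipeline (mode decomposition, kinematics,
ITPC, PAC, spike-field coupling, CSD) gets its recovery test from this
module: planar traveling waves on an ECoG-style grid, slow-phase ->
fast-amplitude coupled oscillations, von-Mises phase-locked Poisson spike
trains, and closed-form laminar potential phantoms.

Ground truth is attached to the generated objects (``TrialEnsemble.ground_truth``
or returned alongside) so tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .containers import GridGeometry, LaminarRecording, SpikeTrain, TrialEnsemble

__all__ = [
    "WaveSpec",
    "CouplingSpec",
    "SpikeSpec",
    "pink_noise",
    "raised_cosine_envelope",
    "generate_traveling_wave",
    "generate_pac_signal",
    "generate_locked_spikes",
    "generate_laminar_phantom",
]


def raised_cosine_envelope(
    t: np.ndarray, onset: float, duration: float, rise: float = 0.010
) -> np.ndarray:
    """Raised-cosine burst: cosine ramps of length ``rise`` at both ends.

    Models a brief evoked response to a ~10 ms flash: zero before ``onset``,
    smooth rise to a plateau, smooth fall ending at ``onset + duration``.
    """
    t = np.asarray(t, dtype=float)
    env = np.zeros_like(t)
    rise = min(rise, duration / 2)
    u = t - onset
    ramp_up = (u >= 0) & (u < rise)
    plateau = (u >= rise) & (u <= duration - rise)
    ramp_dn = (u > duration - rise) & (u <= duration)
    env[ramp_up] = 0.5 * (1 - np.cos(np.pi * u[ramp_up] / rise))
    env[plateau] = 1.0
    env[ramp_dn] = 0.5 * (1 - np.cos(np.pi * (duration - u[ramp_dn]) / rise))
    return env


@dataclass(frozen=True)
class WaveSpec:
    """Ground-truth planar traveling wave.

    The noiseless component at electrode position ``p`` (mm) and
    peristimulus time ``t`` (s) is::

        amplitude * envelope(t) * cos(2*pi*f*t - phi_space(p) + initial_phase)

    with ``phi_space(p) = (2*pi/lambda) * (direction . p)`` for a constant
    spatial wavelength ``lambda``.  ``direction`` is the propagation
    direction (phase delay increases along it).  A spatially varying local
    wavelength may be supplied via ``wavelength_fn`` (mm/cycle as a function
    of distance along ``direction``); the spatial phase is then the
    integral of ``2*pi / wavelength_fn``.
    """

    direction: tuple[float, float]
    wavelength_mm: float
    freq_hz: float
    onset: float = 0.0
    duration: float = 0.5
    amplitude: float = 1.0
    initial_phase: float = 0.0
    rise: float = 0.010
    envelope: Callable[[np.ndarray], np.ndarray] | None = None
    wavelength_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError("direction must be a unit 2-vector")
        if self.wavelength_mm <= 0:
            raise ValueError("spatial_wavelength must be positive")
        if self.freq_hz <= 0:
            raise ValueError("temporal_frequency must be positive")

    def envelope_at(self, t: np.ndarray) -> np.ndarray:
        if self.envelope is not None:
            return np.asarray(self.envelope(t), dtype=float)
        return raised_cosine_envelope(t, self.onset, self.duration, self.rise)

    def spatial_phase(self, positions: np.ndarray) -> np.ndarray:
        """Accumulated spatial phase (rad) at each electrode position."""
        d = np.asarray(self.direction, dtype=float)
        s = positions @ d  # distance along propagation direction, mm
        if self.wavelength_fn is None:
            return 2 * np.pi * s / self.wavelength_mm
        # integrate 2*pi / lambda(s') from 0 to s on a dense grid
        lo, hi = min(s.min(), 0.0), max(s.max(), 0.0)
        grid = np.linspace(lo, hi, 4001)
        k_local = 2 * np.pi / np.asarray(self.wavelength_fn(grid), dtype=float)
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (k_local[1:] + k_local[:-1]) * np.diff(grid))]
        )
        cum -= np.interp(0.0, grid, cum)  # phase 0 at the origin
        return np.interp(s, grid, cum)

    def local_wavelength(self, positions: np.ndarray) -> np.ndarray:
        """Ground-truth local wavelength (mm/cycle) at each position."""
        if self.wavelength_fn is None:
            return np.full(len(positions), self.wavelength_mm)
        d = np.asarray(self.direction, dtype=float)
        return np.asarray(self.wavelength_fn(positions @ d), dtype=float)


@dataclass(frozen=True)
class CouplingSpec:
    """Slow-phase -> fast-amplitude coupling ground truth.

    ``depth`` in [0, 1] scales the modulation of the fast-band amplitude:
    ``a_fast(t) = baseline * (1 + depth * cos(slow_phase - preferred_phase))``.
    """

    slow_band: tuple[float, float] = (3.0, 6.0)
    fast_band: tuple[float, float] = (30.0, 50.0)
    depth: float = 0.5
    preferred_phase: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("coupling depth must be in [0, 1]")
        if self.slow_band[1] > self.fast_band[0]:
            raise ValueError("slow and fast bands must be disjoint")


@dataclass(frozen=True)
class SpikeSpec:
    """Von-Mises phase-locked Poisson unit.

    Intensity proportional to exp(kappa * cos(phase - preferred_phase)),
    normalized so the time-averaged rate equals ``baseline_rate``.
    """

    baseline_rate: float = 5.0
    kappa: float = 0.0
    preferred_phase: float = 0.0
    depth_um: float = 400.0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0.5:
            raise ValueError("baseline_rate must exceed 0.5 spikes/s")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


def pink_noise(
    shape: tuple[int, ...],
    sampling_rate: float,
    exponent: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f**exponent.

    Generated by spectrally shaping white Gaussian noise along the last
    axis; the DC component is zeroed.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def generate_traveling_wave(
    geometry: GridGeometry,
    wave: WaveSpec | Sequence[WaveSpec],
    n_trials: int = 100,
    phase_jitter_sd: float = 0.2,
    snr_db: float | None = 10.0,
    noise_std: float | None = None,
    noise_exponent: float = 1.0,
    sampling_rate: float = 1000.0,
    pre: float = 0.4,
    post: float = 1.0,
    seed: int = 0,
) -> TrialEnsemble:
    """Simulate stimulus-aligned epochs carrying planar traveling waves.

    Trial-to-trial variability enters only through the initial phase
    (Gaussian jitter, sd ``phase_jitter_sd`` rad) and the additive 1/f
    background.  Noise level is set either by ``noise_std`` (same units as
    wave amplitude) or by ``snr_db``, the ratio of the strongest wave's
    plateau RMS to the noise SD.  Deterministic for a fixed ``seed``.
    """
    waves = [wave] if isinstance(wave, WaveSpec) else list(wave)
    if not waves:
        raise ValueError("at least one WaveSpec required")
    f_max = max(w.freq_hz for w in waves)
    if sampling_rate < 4 * f_max:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz < 4x max wave frequency {f_max} Hz"
        )
    if noise_std is None:
        if snr_db is None:
            noise_std = 0.0
        else:
            a = max(w.amplitude for w in waves)
            noise_std = (a / np.sqrt(2)) / 10 ** (snr_db / 20.0)

    n_samples = int(round((pre + post) * sampling_rate))
    t = -pre + np.arange(n_samples) / sampling_rate
    rng = np.random.default_rng(seed)

    lfp = np.zeros((n_trials, geometry.n_channels, n_samples))
    jitters = []
    for w in waves:
        phi_sp = w.spatial_phase(geometry.positions)  # (channels,)
        env = w.envelope_at(t)  # (time,)
        jit = rng.normal(0.0, phase_jitter_sd, size=n_trials)
        jitters.append(jit)
        carrier_phase = (
            2 * np.pi * w.freq_hz * t[None, None, :]
            - phi_sp[None, :, None]
            + w.initial_phase
            + jit[:, None, None]
        )
        lfp += w.amplitude * env[None, None, :] * np.cos(carrier_phase)
    if noise_std > 0:
        lfp += noise_std * pink_noise(
            (n_trials, geometry.n_channels, n_samples), sampling_rate,
            exponent=noise_exponent, rng=rng,
        )

    truth = {
        "waves": [
            {
                "direction": list(w.direction),
                "wavelength_mm": w.wavelength_mm,
                "freq_hz": w.freq_hz,
                "onset": w.onset,
                "duration": w.duration,
                "amplitude": w.amplitude,
                "initial_phase": w.initial_phase,
                "local_wavelength_mm": w.local_wavelength(geometry.positions).tolist(),
                "trial_phase_jitter": jitters[i].tolist(),
            }
            for i, w in enumerate(waves)
        ],
        "noise_std": float(noise_std),
        "noise_exponent": float(noise_exponent),
        "phase_jitter_sd": float(phase_jitter_sd),
        "seed": int(seed),
    }
    return TrialEnsemble(
        lfp=lfp,
        sampling_rate=sampling_rate,
        t_axis=t,
        geometry=geometry,
        pre_window=pre,
        post_window=post,
        ground_truth=truth,
    )


def generate_pac_signal(
    coupling: CouplingSpec,
    duration: float = 60.0,
    sampling_rate: float = 1000.0,
    slow_amplitude: float = 1.0,
    fast_baseline: float = 0.5,
    fm_depth: float = 0.1,
    noise_std: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Single-channel series with slow-phase -> fast-amplitude coupling.

    Returns ``(signal, slow_phase, ground_truth)``.  The fast-band envelope
    is exactly ``fast_baseline * (1 + depth * cos(slow_phase - preferred))``;
    with ``depth == 0`` the fast amplitude is independent of the slow phase.

    The slow oscillation's instantaneous frequency wanders slowly around
    the band center (fractional sd ``fm_depth``, clipped to the band), as
    real narrowband rhythms do; a strictly periodic carrier would make
    circular-shift surrogates blind to the coupling (a shift would merely
    rotate the preferred phase).
    """
    f_slow = 0.5 * (coupling.slow_band[0] + coupling.slow_band[1])
    f_fast = 0.5 * (coupling.fast_band[0] + coupling.fast_band[1])
    if duration < 10.0 / f_slow:
        raise ValueError("duration must cover at least 10 slow cycles")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    if fm_depth > 0:
        from scipy import signal as sps

        drift = rng.standard_normal(n)
        sos = sps.butter(2, 0.5, btype="lowpass", fs=sampling_rate, output="sos")
        drift = sps.sosfiltfilt(sos, drift)
        drift /= max(drift.std(), 1e-12)
        f_inst = np.clip(
            f_slow * (1.0 + fm_depth * drift),
            coupling.slow_band[0],
            coupling.slow_band[1],
        )
    else:
        f_inst = np.full(n, f_slow)
    slow_phase_unwrapped = (
        2 * np.pi * np.cumsum(f_inst) / sampling_rate + rng.uniform(0, 2 * np.pi)
    )
    slow_phase = np.angle(np.exp(1j * slow_phase_unwrapped))
    amp_fast = fast_baseline * (
        1.0 + coupling.depth * np.cos(slow_phase - coupling.preferred_phase)
    )
    signal = slow_amplitude * np.cos(slow_phase_unwrapped) + amp_fast * np.cos(
        2 * np.pi * f_fast * t + rng.uniform(0, 2 * np.pi)
    )
    if noise_std > 0:
        signal = signal + noise_std * pink_noise((n,), sampling_rate, rng=rng)
    truth = {
        "f_slow": f_slow,
        "f_fast": f_fast,
        "depth": coupling.depth,
        "preferred_phase": coupling.preferred_phase,
        "fast_amplitude": amp_fast,
        "seed": int(seed),
    }
    return signal, slow_phase, truth


def generate_locked_spikes(
    slow_phase: np.ndarray,
    spec: SpikeSpec,
    sampling_rate: float = 1000.0,
    seed: int = 0,
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes phase-locked to a slow oscillation.

    The instantaneous rate is ``baseline_rate * exp(kappa*cos(phase - mu))``
    normalized by its empirical time average, so the expected total count is
    exactly ``baseline_rate * duration`` regardless of ``kappa``.
    """
    phase = np.asarray(slow_phase, dtype=float)
    if not np.all(np.isfinite(phase)):
        raise ValueError("phase series must be finite")
    rng = np.random.default_rng(seed)
    mod = np.exp(spec.kappa * np.cos(phase - spec.preferred_phase))
    rate = spec.baseline_rate * mod / mod.mean()
    dt = 1.0 / sampling_rate
    counts = rng.poisson(rate * dt)
    idx = np.repeat(np.arange(phase.size), counts)
    times = (idx + rng.uniform(0.0, 1.0, size=idx.size)) * dt
    times.sort()
    return SpikeTrain(
        unit_id="synthetic",
        spike_times=times,
        depth_um=spec.depth_um,
        duration=phase.size * dt,
    )


def generate_laminar_phantom(
    depth_profile: Callable[[np.ndarray], np.ndarray],
    n_channels: int = 32,
    dz_um: float = 25.0,
    z0_um: float = 0.0,
    timecourse: np.ndarray | None = None,
    sampling_rate: float = 1000.0,
) -> LaminarRecording:
    """Closed-form laminar potential phantom phi(z) (x) timecourse.

    ``depth_profile`` maps depth in um to potential; the default timecourse
    is a single constant sample, giving a static depth profile against
    which the CSD second-difference formula can be checked analytically.
    """
    if n_channels < 5:
        raise ValueError("need at least 5 channels for CSD")
    z = z0_um + dz_um * np.arange(n_channels)
    profile = np.asarray(depth_profile(z), dtype=float)
    if timecourse is None:
        timecourse = np.ones(1)
    timecourse = np.asarray(timecourse, dtype=float)
    phi = profile[:, None] * timecourse[None, :]
    return LaminarRecording(phi=phi, z_um=z, sampling_rate=sampling_rate)
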