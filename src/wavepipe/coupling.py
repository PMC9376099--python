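"""Phase-amplitude coupling, spike-field coherence, and spike correlations.

The common statistic is the Kullback-Leibler modulation index (MI): the
slow-band phase is cut into 20 bins on (-pi, pi], the mean fast-band
amplitude (PAC) or mean spike count (SFC) per bin is averaged over
trials, normalized to a distribution p, and MI = KL(p || uniform) /
log(n_bins), so MI = 0 for no coupling and 1 when all mass falls in one
bin.  Significance comes from surrogates that destroy the phase-amplitude
(circular phase shifts) or phase-spike (rate-matched Poisson trains)
relationship while preserving everything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MIResult",
    "phase_bin_index",
    "phase_amplitude_distribution",
    "modulation_index",
    "mi_surrogate_z",
    "spike_field_coherence",
    "sfc_poisson_surrogate_z",
    "intersite_sfc",
    "spike_cross_correlogram",
    "spike_delay_histogram",
]


def phase_bin_index(phase: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Bin index on (-pi, pi], left-open / right-closed equal bins."""
    delta = 2 * np.pi / n_bins
    idx = np.ceil((np.asarray(phase) + np.pi) / delta).astype(int) - 1
    return np.clip(idx, 0, n_bins - 1)


def bin_centers(n_bins: int = 20) -> np.ndarray:
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class MIResult:
    """Modulation index with its phase-bin distribution.

    ``preferred_phase`` is the center of the maximal bin;
    ``preferred_phase_mean`` the distribution-weighted circular mean.
    """

    mi: float
    p: np.ndarray
    preferred_phase: float
    preferred_phase_mean: float
    n_bins: int

    @classmethod
    def from_distribution(cls, p: np.ndarray) -> "MIResult":
        p = np.asarray(p, dtype=float)
        n = p.size
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("p must be a normalized distribution")
        nz = p > 0
        mi = float(np.sum(p[nz] * np.log(p[nz] * n)) / np.log(n))
        centers = bin_centers(n)
        resultant = np.sum(p * np.exp(1j * centers))
        return cls(
            mi=mi,
            p=p,
            preferred_phase=float(centers[np.argmax(p)]),
            preferred_phase_mean=float(np.angle(resultant)),
            n_bins=n,
        )


def phase_amplitude_distribution(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 20
) -> np.ndarray:
    """Normalized mean-amplitude-per-phase-bin distribution.

    ``phase`` and ``amplitude`` may be 1-D (single trial) or 2-D
    (trials x time); per-trial bin means are averaged over trials *before*
    normalization.  A bin empty in one trial is skipped in the average; a
    bin empty in every trial triggers a pooled-sample fallback (logged).
    """
    phase = np.atleast_2d(np.asarray(phase, dtype=float))
    amplitude = np.atleast_2d(np.asarray(amplitude, dtype=float))
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have matching shapes")
    if phase.size == 0:
        raise ValueError("empty window")
    n_trials = phase.shape[0]
    idx = phase_bin_index(phase, n_bins)
    means = np.full((n_trials, n_bins), np.nan)
    for k in range(n_trials):
        sums = np.bincount(idx[k], weights=amplitude[k], minlength=n_bins)
        counts = np.bincount(idx[k], minlength=n_bins)
        ok = counts > 0
        means[k, ok] = sums[ok] / counts[ok]
    with np.errstate(invalid="ignore"):
        mean_per_bin = np.nanmean(means, axis=0)
    if np.any(np.isnan(mean_per_bin)):
        logger.warning("empty phase bins; falling back to pooled samples")
        sums = np.bincount(idx.ravel(), weights=amplitude.ravel(), minlength=n_bins)
        counts = np.bincount(idx.ravel(), minlength=n_bins)
        if np.any(counts == 0):
            raise ValueError("phase bins empty even after pooling trials")
        mean_per_bin = sums / counts
    return mean_per_bin / mean_per_bin.sum()


def modulation_index(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 20
) -> MIResult:
    """KL modulation index of fast amplitude against slow phase.

    Callers restrict ``phase``/``amplitude`` to the analysis window
    (canonically the first 900 ms post-stimulus per trial) before calling.
    """
    p = phase_amplitude_distribution(phase, amplitude, n_bins)
    return MIResult.from_distribution(p)


def mi_surrogate_z(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_bins: int = 20,
    n_surr: int = 100,
    min_shift_frac: float = 0.05,
    seed: int = 0,
) -> tuple[float, MIResult]:
    """MI z-scored against circular phase-shift surrogates.

    Each surrogate circularly shifts every trial's phase series by an
    independent random number of samples, breaking the phase-amplitude
    relationship while preserving both marginals; shifts stay at least
    ``min_shift_frac`` of the series length away from zero so a surrogate
    never nearly reproduces the original alignment.  Returns
    (z, observed MIResult); z is NaN if the surrogate SD is 0.
    """
    phase = np.atleast_2d(np.asarray(phase, dtype=float))
    amplitude = np.atleast_2d(np.asarray(amplitude, dtype=float))
    observed = modulation_index(phase, amplitude, n_bins)
    rng = np.random.default_rng(seed)
    n = phase.shape[1]
    lo = max(1, int(min_shift_frac * n))
    surr = np.empty(n_surr)
    for s in range(n_surr):
        shifts = rng.integers(lo, n - lo + 1, size=phase.shape[0])
        shifted = np.stack(
            [np.roll(phase[k], shifts[k]) for k in range(phase.shape[0])]
        )
        surr[s] = modulation_index(shifted, amplitude, n_bins).mi
    sd = surr.std(ddof=1)
    z = (observed.mi - surr.mean()) / sd if sd > 0 else np.nan
    if not np.isfinite(z):
        logger.warning("undefined MI z-score: zero surrogate variance")
    return float(z), observed


def _spike_phase_counts(
    spike_times: np.ndarray,
    phase: np.ndarray,
    sampling_rate: float,
    stim_times: np.ndarray | None,
    window: tuple[float, float],
    n_bins: int,
) -> np.ndarray:
    """Per-trial spike counts per phase bin, (trials, n_bins)."""
    spike_times = np.asarray(spike_times, dtype=float)
    phase = np.asarray(phase, dtype=float)
    if stim_times is None:
        windows = [(0.0, phase.size / sampling_rate)]
    else:
        windows = [(st + window[0], st + window[1]) for st in np.atleast_1d(stim_times)]
    counts = np.zeros((len(windows), n_bins))
    for k, (t0, t1) in enumerate(windows):
        sel = spike_times[(spike_times >= t0) & (spike_times < t1)]
        if sel.size == 0:
            continue
        si = np.clip((sel * sampling_rate).astype(int), 0, phase.size - 1)
        idx = phase_bin_index(phase[si], n_bins)
        counts[k] = np.bincount(idx, minlength=n_bins)
    return counts


def spike_field_coherence(
    spike_times: np.ndarray,
    phase: np.ndarray,
    sampling_rate: float,
    stim_times: np.ndarray | None = None,
    window: tuple[float, float] = (0.0, 0.9),
    n_bins: int = 20,
) -> MIResult:
    """Spike-field coherence as an MI on spike counts per field-phase bin.

    ``phase`` is the continuous slow-band phase of the field (canonically
    the CSD at the unit's depth).  For each trial the spikes falling in
    ``window`` relative to the stimulus are counted per phase bin; the
    per-trial counts are averaged over trials, normalized, and fed through
    the same KL statistic as PAC.  Raises if no spike falls in any window
    (the statistic is undefined, not zero).
    """
    counts = _spike_phase_counts(
        spike_times, phase, sampling_rate, stim_times, window, n_bins
    )
    mean_counts = counts.mean(axis=0)
    if mean_counts.sum() == 0:
        raise ValueError("no spikes in the analysis window; SFC undefined")
    return MIResult.from_distribution(mean_counts / mean_counts.sum())


# intersite SFC is the identical computation with the field phase taken
# from the other region; exposing it by name keeps call sites readable
intersite_sfc = spike_field_coherence


def sfc_poisson_surrogate_z(
    spike_times: np.ndarray,
    phase: np.ndarray,
    sampling_rate: float,
    stim_times: np.ndarray | None = None,
    window: tuple[float, float] = (0.0, 0.9),
    n_bins: int = 20,
    n_surr: int = 100,
    rate_window: float = 0.2,
    seed: int = 0,
) -> tuple[float, MIResult]:
    """SFC z-scored against rate-matched Poisson surrogate trains.

    The unit's rate is estimated by a ``rate_window`` (200 ms) boxcar slid
    sample by sample over the spike train; surrogate trains are simulated
    from that rate, preserving slow rate modulations but destroying
    phase locking.  Returns (z, observed MIResult).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    phase = np.asarray(phase, dtype=float)
    observed = spike_field_coherence(
        spike_times, phase, sampling_rate, stim_times, window, n_bins
    )
    n = phase.size
    delta = np.zeros(n)
    si = np.clip((spike_times * sampling_rate).astype(int), 0, n - 1)
    np.add.at(delta, si, 1.0)
    half = int(round(rate_window * sampling_rate)) // 2
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    rate = np.convolve(delta, kernel, mode="same") * sampling_rate  # spikes/s
    if rate.max() == 0:
        raise ValueError("all-zero rate estimate")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    surr = np.empty(n_surr)
    for s in range(n_surr):
        counts = rng.poisson(rate * dt)
        idx = np.repeat(np.arange(n), counts)
        st = np.sort((idx + rng.uniform(0, 1, idx.size)) * dt)
        try:
            surr[s] = spike_field_coherence(
                st, phase, sampling_rate, stim_times, window, n_bins
            ).mi
        except ValueError:
            surr[s] = np.nan
    ok = np.isfinite(surr)
    sd = surr[ok].std(ddof=1) if ok.sum() > 1 else 0.0
    z = (observed.mi - surr[ok].mean()) / sd if sd > 0 else np.nan
    return float(z), observed


def spike_cross_correlogram(
    times_ref: np.ndarray,
    times_other: np.ndarray,
    stim_times: np.ndarray | None = None,
    window: tuple[float, float] = (0.0, 0.5),
    lag_range: tuple[float, float] = (-0.1, 0.1),
    bin_width: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlogram of pairwise spike delays, normalized per reference
    spike.

    Delay = other-spike time - reference-spike time, histogrammed over
    ``lag_range`` for reference spikes falling in ``window`` relative to
    each stimulus (or over the whole train when ``stim_times`` is None).
    Returns (lag bin centers, firing probability per bin).  Empty inputs
    yield an all-zero histogram.
    """
    times_ref = np.asarray(times_ref, dtype=float)
    times_other = np.asarray(times_other, dtype=float)
    # bins centered on integer multiples of bin_width so zero lag is a center
    n_half = int(round(lag_range[1] / bin_width))
    n_half_lo = int(round(-lag_range[0] / bin_width))
    edges = bin_width * (np.arange(-n_half_lo, n_half + 1) + 0.5)
    edges = np.concatenate([[edges[0] - bin_width], edges])
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(centers.size)
    if stim_times is None:
        refs = times_ref
    else:
        masks = [
            (times_ref >= st + window[0]) & (times_ref < st + window[1])
            for st in np.atleast_1d(stim_times)
        ]
        refs = times_ref[np.logical_or.reduce(masks)] if masks else times_ref[:0]
    if refs.size == 0 or times_other.size == 0:
        logger.warning("empty spike train; returning zero correlogram")
        return centers, hist
    for t in refs:
        lo = np.searchsorted(times_other, t + edges[0])
        hi = np.searchsorted(times_other, t + edges[-1])
        if hi > lo:
            hist += np.histogram(times_other[lo:hi] - t, bins=edges)[0]
    return centers, hist / refs.size


def spike_delay_histogram(
    times_ref: np.ndarray,
    times_other: np.ndarray,
    stim_times: np.ndarray,
    pre_window: tuple[float, float] = (-0.5, 0.0),
    post_window: tuple[float, float] = (0.0, 0.5),
    lag_range: tuple[float, float] = (-0.1, 0.1),
    bin_width: float = 0.005,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pre- vs post-stimulus cross-correlograms of two units.

    Returns {'pre': (lags, prob), 'post': (lags, prob)}; transiently
    synchronized pairs are flat pre-stimulus and peaked post-stimulus at
    the lag set by their phase relationship to the shared wave.
    """
    return {
        "pre": spike_cross_correlogram(
            times_ref, times_other, stim_times, pre_window, lag_range, bin_width
        ),
        "post": spike_cross_correlogram(
            times_ref, times_other, stim_times, post_window, lag_range, bin_width
        ),
    }
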