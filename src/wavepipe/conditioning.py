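"""Broadband filtering, downsampling, re-referencing, epoching and QC.

All conditioning steps are zero-phase (forward-backward application of
linear filters), so peristimulus latencies measured downstream are not
biased by filter delay.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .containers import GridGeometry, RawRecording, TrialEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "broadband_filter",
    "downsample",
    "mean_rereference",
    "epoch_trials",
    "vep_inclusion",
    "onset_latency",
    "reject_noise_channels",
    "reject_artifact_trials",
]


def _design_broadband_fir(
    sampling_rate: float,
    band: tuple[float, float],
    numtaps: int | None = None,
) -> np.ndarray:
    """Least-squares linear-phase low-pass at the upper band edge.

    The upper transition band spans [f_hi, 1.15*f_hi].
    """
    nyq = sampling_rate / 2.0
    f_lo, f_hi = band
    if f_hi >= nyq:
        raise ValueError(f"upper band edge {f_hi} Hz >= Nyquist {nyq} Hz")
    if f_lo < 0 or f_lo >= f_hi:
        raise ValueError("invalid band")
    f_stop = min(1.15 * f_hi, 0.99 * nyq)
    transition = f_stop - f_hi
    if numtaps is None:
        numtaps = int(np.ceil(3.3 * sampling_rate / transition))
    numtaps |= 1  # odd length -> type-I linear phase
    return sps.firls(numtaps, [0, f_hi, f_stop, nyq], [1, 1, 0, 0],
                     fs=sampling_rate)


def broadband_filter(
    raw: RawRecording,
    band: tuple[float, float] = (0.1, 325.0),
    numtaps: int | None = None,
) -> RawRecording:
    """Zero-phase broadband FIR filter (least-squares design).

    The low-frequency edge is realized as exact per-channel mean removal:
    a true FIR transition at a sub-Hz edge would require a kernel longer
    than typical records, whereas mean subtraction removes the constant
    (DC) component exactly, is zero-phase, and perturbs in-band components
    only at O(1/n_samples).
    """
    h = _design_broadband_fir(raw.sampling_rate, band, numtaps)
    x = raw.samples - raw.samples.mean(axis=-1, keepdims=True)
    padlen = min(3 * len(h), raw.n_samples - 1)
    out = sps.filtfilt(h, [1.0], x, axis=-1, padlen=padlen)
    return RawRecording(
        samples=out,
        sampling_rate=raw.sampling_rate,
        channel_ids=list(raw.channel_ids),
        geometry=raw.geometry,
    )


def downsample(raw: RawRecording, target_rate: float = 1000.0) -> RawRecording:
    """Polyphase resampling to ``target_rate`` (anti-alias filter included).

    The caller is expected to have applied :func:`broadband_filter` first
    when the band of interest approaches the new Nyquist frequency.
    """
    if target_rate > raw.sampling_rate:
        raise ValueError("target rate exceeds original sampling rate")
    if target_rate == raw.sampling_rate:
        return raw
    from fractions import Fraction

    frac = Fraction(target_rate / raw.sampling_rate).limit_denominator(10000)
    out = sps.resample_poly(raw.samples, frac.numerator, frac.denominator, axis=-1)
    return RawRecording(
        samples=out,
        sampling_rate=target_rate,
        channel_ids=list(raw.channel_ids),
        geometry=raw.geometry,
    )


def mean_rereference(ensemble: TrialEnsemble) -> TrialEnsemble:
    """Subtract the across-channel mean at every trial and time point.

    Removes the common (volume-conducted) component; idempotent.
    """
    if ensemble.n_channels < 2:
        raise ValueError("mean re-referencing requires at least 2 channels")
    lfp = ensemble.lfp - ensemble.lfp.mean(axis=1, keepdims=True)
    return TrialEnsemble(
        lfp=lfp,
        sampling_rate=ensemble.sampling_rate,
        t_axis=ensemble.t_axis,
        geometry=ensemble.geometry,
        pre_window=ensemble.pre_window,
        post_window=ensemble.post_window,
        ground_truth=ensemble.ground_truth,
    )


def epoch_trials(
    raw: RawRecording,
    stim_times: np.ndarray,
    pre: float = 0.4,
    post: float = 1.0,
) -> TrialEnsemble:
    """Cut stimulus-aligned epochs over the half-open window [-pre, post).

    Each epoch has exactly ``round((pre + post) * fs)`` samples; time 0 is
    the sample at the stimulus onset.  Trials whose window would exceed the
    recording bounds are dropped with a logged warning.
    """
    fs = raw.sampling_rate
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    n_len = n_pre + n_post
    epochs = []
    for st in np.atleast_1d(np.asarray(stim_times, dtype=float)):
        i0 = int(round(st * fs)) - n_pre
        i1 = i0 + n_len
        if i0 < 0 or i1 > raw.n_samples:
            logger.warning("dropping trial at %.3f s: window outside recording", st)
            continue
        epochs.append(raw.samples[:, i0:i1])
    t_axis = (np.arange(n_len) - n_pre) / fs
    lfp = (
        np.stack(epochs, axis=0)
        if epochs
        else np.empty((0, raw.n_channels, n_len))
    )
    return TrialEnsemble(
        lfp=lfp,
        sampling_rate=fs,
        t_axis=t_axis,
        geometry=raw.geometry,
        pre_window=pre,
        post_window=post,
    )


def _prestim_stats(ensemble: TrialEnsemble, channel: int) -> tuple[np.ndarray, float]:
    """Trial-average over the channel and SD of its pre-stimulus part."""
    avg = ensemble.lfp[:, channel, :].mean(axis=0)
    pre_mask = ensemble.t_axis < 0
    sd = float(avg[pre_mask].std(ddof=0))
    return avg, sd


def vep_inclusion(
    ensemble: TrialEnsemble, channel: int, threshold_sd: float = 5.0
) -> tuple[bool, float]:
    """Visual-evoked-potential inclusion rule for a channel.

    True iff |trial-average| within 0-100 ms post-stimulus exceeds
    ``threshold_sd`` standard deviations of the pre-stimulus trial average.
    Returns (included, peak z).
    """
    if ensemble.pre_window < 0.1:
        raise ValueError("need at least 100 ms of pre-stimulus baseline")
    avg, sd = _prestim_stats(ensemble, channel)
    if sd == 0:
        raise ValueError("degenerate input: zero pre-stimulus SD")
    mask = ensemble.time_mask(0.0, 0.1)
    peak_z = float(np.max(np.abs(avg[mask])) / sd)
    return peak_z > threshold_sd, peak_z


def onset_latency(
    ensemble: TrialEnsemble,
    channel: int,
    threshold_sd: float = 3.0,
    n_consecutive: int = 3,
) -> float | None:
    """VEP onset latency in ms.

    First post-stimulus time at which the trial-average exceeds
    ``threshold_sd`` pre-stimulus SDs for ``n_consecutive`` consecutive
    samples; None if no such run exists.
    """
    avg, sd = _prestim_stats(ensemble, channel)
    if sd == 0:
        raise ValueError("degenerate input: zero pre-stimulus SD")
    baseline = avg[ensemble.t_axis < 0].mean()
    post = ensemble.t_axis >= 0
    above = (avg[post] - baseline) > threshold_sd * sd
    run = 0
    t_post = ensemble.t_axis[post]
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= n_consecutive:
            return float(t_post[i - n_consecutive + 1] * 1000.0)
    return None


def reject_noise_channels(
    raw: RawRecording, sd_factor: float = 8.0
) -> tuple[RawRecording, list[int]]:
    """Automated stand-in for manual noise-channel rejection.

    A channel is rejected if its SD exceeds ``sd_factor`` times the median
    channel SD, or if it is flat (zero SD).  Returns the cleaned recording
    and the rejected flat indices.  Geometry is dropped when channels are
    removed (the lattice is no longer complete).
    """
    sds = raw.samples.std(axis=1)
    med = np.median(sds)
    bad = np.where((sds == 0) | (sds > sd_factor * med))[0]
    if bad.size == 0:
        return raw, []
    keep = np.setdiff1d(np.arange(raw.n_channels), bad)
    out = RawRecording(
        samples=raw.samples[keep],
        sampling_rate=raw.sampling_rate,
        channel_ids=[raw.channel_ids[i] for i in keep],
        geometry=None,
    )
    return out, bad.tolist()


def reject_artifact_trials(
    ensemble: TrialEnsemble, sd_factor: float = 10.0
) -> tuple[TrialEnsemble, list[int]]:
    """Drop trials containing samples beyond ``sd_factor`` robust SDs.

    Robust SD is 1.4826 * MAD over the whole ensemble.  Stand-in for manual
    motion-artifact rejection.
    """
    mad = np.median(np.abs(ensemble.lfp - np.median(ensemble.lfp)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        return ensemble, []
    peak = np.max(np.abs(ensemble.lfp), axis=(1, 2))
    bad = np.where(peak > sd_factor * robust_sd)[0]
    if bad.size == 0:
        return ensemble, []
    keep = np.setdiff1d(np.arange(ensemble.n_trials), bad)
    out = TrialEnsemble(
        lfp=ensemble.lfp[keep],
        sampling_rate=ensemble.sampling_rate,
        t_axis=ensemble.t_axis,
        geometry=ensemble.geometry,
        pre_window=ensemble.pre_window,
        post_window=ensemble.post_window,
        ground_truth=ensemble.ground_truth,
    )
    return out, bad.tolist()
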