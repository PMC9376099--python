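"""Current source density from laminar probes and cortical-layer assignment.

CSD is the (negated) second spatial derivative of the laminar LFP,
evaluated with a five-point-span second difference::

    CSD(z) = -[phi(z + 2*dz) - 2*phi(z) + phi(z - 2*dz)] / (2*dz)^2

Current sinks are negative, sources positive.  Boundary channels are
handled Vaknin-style by duplicating the outermost channels to extend the
potential profile by one span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import LaminarRecording

__all__ = ["LayerMap", "compute_csd", "assign_layers_v1", "assign_layers_depth"]


@dataclass
class LayerMap:
    """Per-channel cortical layer labels, contiguous in depth."""

    labels: list[str]
    granular_channel: int | None = None
    surface_channel: int | None = None


def compute_csd(rec: LaminarRecording) -> np.ndarray:
    """Second-spatial-difference CSD, (depths, time).

    Interior channels use the five-point-span formula; the two channels at
    each boundary use duplicated-endpoint (Vaknin) padding.
    """
    if rec.n_channels < 5:
        raise ValueError("CSD requires at least 5 channels")
    dz = rec.dz_um
    phi = np.pad(rec.phi, ((2, 2), (0, 0)), mode="edge")
    csd = -(phi[4:, :] - 2 * phi[2:-2, :] + phi[:-4, :]) / (2 * dz) ** 2
    return csd


def assign_layers_v1(
    csd: np.ndarray,
    t_axis: np.ndarray,
    sink_threshold_sd: float = 3.0,
    n_consecutive: int = 3,
) -> LayerMap:
    """Granular-referenced layer assignment for a V1 probe.

    The channel with the earliest post-stimulus current sink (CSD below
    -``sink_threshold_sd`` pre-stimulus SDs for ``n_consecutive``
    consecutive samples) is labeled granular (layer 4); channels above it
    supragranular, below it infragranular.  Ties at the same onset sample
    go to the shallower channel.
    """
    t_axis = np.asarray(t_axis, dtype=float)
    pre = t_axis < 0
    post = t_axis >= 0
    if not pre.any() or not post.any():
        raise ValueError("t_axis must span the stimulus (0)")
    mu = csd[:, pre].mean(axis=1, keepdims=True)
    sd = csd[:, pre].std(axis=1, keepdims=True)
    if np.any(sd == 0):
        sd = np.where(sd == 0, np.inf, sd)
    below = (csd[:, post] - mu) < -sink_threshold_sd * sd
    onset = np.full(csd.shape[0], np.inf)
    for ch in range(csd.shape[0]):
        run = 0
        for i, b in enumerate(below[ch]):
            run = run + 1 if b else 0
            if run >= n_consecutive:
                onset[ch] = i - n_consecutive + 1
                break
    if not np.isfinite(onset).any():
        raise ValueError("no evoked sink")
    granular = int(np.argmin(onset))  # argmin ties -> shallower channel
    labels = (
        ["supragranular"] * granular
        + ["granular"]
        + ["infragranular"] * (csd.shape[0] - granular - 1)
    )
    return LayerMap(labels=labels, granular_channel=granular)


def detect_surface_channel(csd: np.ndarray, rms_fraction: float = 0.1) -> int:
    """First channel from the top whose evoked-CSD RMS exceeds a fraction
    of the probe maximum; channels above it are outside cortex (their CSD
    has converged to zero)."""
    rms = np.sqrt((csd**2).mean(axis=1))
    thresh = rms_fraction * rms.max()
    active = np.where(rms > thresh)[0]
    if active.size == 0:
        raise ValueError("no active channels")
    return int(active[0])


def assign_layers_depth(
    rec: LaminarRecording,
    csd: np.ndarray | None = None,
    surface_channel: int | None = None,
    superficial_extent_um: float = 350.0,
    deep_extent_um: float = 400.0,
) -> LayerMap:
    """Depth-banded layer assignment (association-cortex scheme).

    Starting at the cortical surface channel (detected from the CSD when
    not given), the first 350 um are superficial layers, the next 400 um
    deep layers, anything beyond is unassigned.
    """
    if surface_channel is None:
        if csd is None:
            csd = compute_csd(rec)
        surface_channel = detect_surface_channel(csd)
    depth_in_cortex = rec.z_um - rec.z_um[surface_channel]
    labels = []
    for d in depth_in_cortex:
        if d < 0:
            labels.append("above_surface")
        elif d < superficial_extent_um:  # first 350 um
            labels.append("superficial")
        elif d < superficial_extent_um + deep_extent_um:  # next 400 um
            labels.append("deep")
        else:
            labels.append("unassigned")
    if depth_in_cortex[-1] < superficial_extent_um:
        import logging

        logging.getLogger(__name__).warning(
            "probe spans only %.0f um of cortex; partial layer map",
            depth_in_cortex[-1],
        )
    return LayerMap(labels=labels, surface_channel=surface_channel)
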