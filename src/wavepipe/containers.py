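"""Core data containers shared across the pipeline.

The common currency is the :class:`TrialEnsemble` — stimulus-aligned LFP
epochs of shape (trials, channels, time) with a peristimulus time axis and
the electrode geometry attached.  Laminar-probe data live in
:class:`LaminarRecording`; sorted units in :class:`SpikeTrain`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """Rectangular surface-electrode grid in stereotaxic coordinates.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions.  Rows run along the anteroposterior (AP) axis,
        columns along the mediolateral (ML) axis.
    pitch_mm
        Center-to-center electrode spacing in mm.
    positions
        (n_rows * n_cols, 2) array of (ML, AP) coordinates in mm, ordered
        row-major (row 0 first).
    """

    n_rows: int
    n_cols: int
    pitch_mm: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (self.n_rows * self.n_cols, 2):
            raise ValueError(
                f"positions shape {pos.shape} does not match "
                f"{self.n_rows}x{self.n_cols} grid"
            )
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.any(d <= 0):
            raise ValueError("electrode positions must be distinct")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @classmethod
    def rectangular(
        cls,
        n_rows: int = 11,
        n_cols: int = 6,
        pitch_mm: float = 0.5,
        origin: tuple[float, float] = (0.0, 0.0),
    ) -> "GridGeometry":
        """Standard ECoG grid: 6 columns x 11 rows, 500 um pitch.

        ``origin`` is the (ML, AP) coordinate of the (row 0, col 0)
        electrode; columns advance along +ML, rows along -AP (the grid
        extends caudally from the origin).
        """
        ml = origin[0] + pitch_mm * np.arange(n_cols)
        ap = origin[1] - pitch_mm * np.arange(n_rows)
        mlg, apg = np.meshgrid(ml, ap)  # (rows, cols)
        pos = np.column_stack([mlg.ravel(), apg.ravel()])
        return cls(n_rows=n_rows, n_cols=n_cols, pitch_mm=pitch_mm, positions=pos)

    def as_grid_index(self) -> np.ndarray:
        """(n_rows, n_cols) array of flat channel indices (row-major)."""
        return np.arange(self.n_channels).reshape(self.n_rows, self.n_cols)

    def nearest_channel(self, ml: float, ap: float) -> int:
        """Flat index of the electrode closest to a stereotaxic point."""
        d = np.linalg.norm(self.positions - np.array([ml, ap]), axis=1)
        return int(np.argmin(d))


@dataclass
class RawRecording:
    """Continuous multichannel recording (channels x time, microvolts)."""

    samples: np.ndarray
    sampling_rate: float
    channel_ids: list[str] | None = None
    geometry: GridGeometry | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = [str(i) for i in range(self.samples.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class TrialEnsemble:
    """Stimulus-aligned LFP epochs: (trials, channels, time).

    ``t_axis`` is peristimulus time in seconds with 0 at stimulus onset;
    epochs cover the half-open window [-pre_window, post_window).
    """

    lfp: np.ndarray
    sampling_rate: float
    t_axis: np.ndarray
    geometry: GridGeometry | None = None
    pre_window: float = 0.0
    post_window: float = 0.0
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        if self.lfp.ndim != 3:
            raise ValueError("lfp must be (trials, channels, time)")
        self.t_axis = np.asarray(self.t_axis, dtype=float)
        if self.t_axis.shape[0] != self.lfp.shape[2]:
            raise ValueError("t_axis length must match time dimension")
        if self.t_axis.size > 1 and not np.all(np.diff(self.t_axis) > 0):
            raise ValueError("t_axis must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[1]

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[2]

    @property
    def is_empty(self) -> bool:
        return self.n_trials == 0

    def time_mask(self, t_start: float, t_stop: float) -> np.ndarray:
        """Boolean mask over t_axis for the half-open window [t_start, t_stop)."""
        return (self.t_axis >= t_start) & (self.t_axis < t_stop)


@dataclass
class LaminarRecording:
    """Laminar-probe potential matrix: (depths, time), depth in um below surface."""

    phi: np.ndarray
    z_um: np.ndarray
    sampling_rate: float = 1000.0
    t_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.z_um = np.asarray(self.z_um, dtype=float)
        if self.z_um.shape[0] != self.phi.shape[0]:
            raise ValueError("z_um length must match the depth dimension")
        dz = np.diff(self.z_um)
        if np.any(dz <= 0):
            raise ValueError("z_um must be strictly increasing")
        if dz.size and not np.allclose(dz, dz[0], rtol=1e-6):
            raise ValueError("electrode spacing must be uniform")
        if self.t_axis is None:
            self.t_axis = np.arange(self.phi.shape[1]) / self.sampling_rate
        else:
            self.t_axis = np.asarray(self.t_axis, dtype=float)

    @property
    def dz_um(self) -> float:
        return float(self.z_um[1] - self.z_um[0])

    @property
    def n_channels(self) -> int:
        return self.phi.shape[0]


@dataclass
class SpikeTrain:
    """Sorted single-unit spike times.

    ``mean_rate`` below 0.5 spikes/s marks units excluded from coupling
    analyses (the standard inclusion rule for sorted units).
    """

    unit_id: str
    spike_times: np.ndarray
    depth_um: float = np.nan
    layer: str | None = None
    duration: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.size and (np.any(np.diff(t) < 0) or t[0] < 0):
            raise ValueError("spike times must be sorted and non-negative")
        self.spike_times = t

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def mean_rate(self) -> float:
        if self.duration is None or self.duration <= 0:
            return np.nan
        return self.n_spikes / self.duration

    @property
    def passes_rate_criterion(self) -> bool:
        return bool(self.mean_rate >= 0.5)
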