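"""Complex-SVD decomposition of analytic-signal ensembles and wave kinematics.

A single trial's band-filtered, Hilbert-transformed LFP forms a complex
n x t matrix ``A`` (n electrodes, t samples).  Its singular value
decomposition ``A = U diag(S) V*`` factorizes the trial into mutually
orthogonal spatiotemporal modes: column i of U carries the spatial
amplitude ``w_s = |U[:, i]| * s_i`` and spatial phase ``theta_s``;
row i of V* carries the temporal amplitude ``w_t`` and temporal phase
``theta_t``.  A coherent traveling wave concentrates in a single mode
whose spatial phase advances linearly across the grid; the conjugate
product of neighboring spatial loadings then yields the local phase
gradient, from which spatial wavelength (2*pi / |grad|) and propagation
velocity (temporal frequency / |grad|) follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GridGeometry

__all__ = [
    "ModeSet",
    "ModeSelection",
    "GradientField",
    "WaveKinematics",
    "complex_svd",
    "select_responsive_mode",
    "spatial_phase_offset",
    "phase_gradient",
    "wave_kinematics",
    "reconstruct_mode",
]


@dataclass
class ModeSet:
    """Economy-size complex SVD factors of one analytic ensemble.

    ``A = U @ diag(S) @ Vh`` with Vh the conjugate transpose of V.
    """

    U: np.ndarray
    S: np.ndarray
    Vh: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.S.size

    @property
    def variance_fractions(self) -> np.ndarray:
        """Fraction of total signal per mode: s_i / sum(s)."""
        return self.S / self.S.sum()

    def spatial_amplitude(self, i: int) -> np.ndarray:
        return np.abs(self.U[:, i]) * self.S[i]

    def spatial_phase(self, i: int) -> np.ndarray:
        return np.angle(self.U[:, i])

    def temporal_amplitude(self, i: int) -> np.ndarray:
        return np.abs(self.Vh[i, :]) * self.S[i]

    def temporal_phase(self, i: int) -> np.ndarray:
        # A[c, t] = sum_i U[c, i] s_i Vh[i, t]: the Vh row itself carries
        # the forward-rotating temporal phasor of the analytic signal, so a
        # positive-frequency oscillation has increasing angle(Vh[i, :])
        return np.angle(self.Vh[i, :])

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.S) @ self.Vh


def complex_svd(A: np.ndarray) -> ModeSet:
    """Singular value decomposition of a complex analytic ensemble."""
    A = np.asarray(A)
    if A.ndim != 2:
        raise ValueError("A must be a 2-D (channels x time) matrix")
    if not np.all(np.isfinite(A)):
        raise ValueError("A contains non-finite entries")
    U, S, Vh = np.linalg.svd(A, full_matrices=False)
    return ModeSet(U=U, S=S, Vh=Vh)


@dataclass
class ModeSelection:
    """Most visually responsive mode of a trial.

    ``w_z`` is the selected mode's temporal amplitude z-scored against its
    own pre-stimulus mean and SD; ``responsive`` is False when no candidate
    mode's post-window mean z reaches ``z_threshold`` (stationary-noise
    trials select unstably and are flagged rather than trusted).
    """

    index: int
    w_z: np.ndarray
    scores: np.ndarray
    responsive: bool
    skipped: list[int]


def select_responsive_mode(
    modes: ModeSet,
    t_axis: np.ndarray,
    pre_window: float = 0.4,
    post_window: float = 0.35,
    n_modes: int = 10,
    summary: str = "mean",
    z_threshold: float = 2.0,
) -> ModeSelection:
    """Pick the mode whose temporal amplitude rises most after the stimulus.

    For each of the first ``n_modes`` modes, the temporal amplitude w_t is
    z-scored against its pre-stimulus window ([-pre_window, 0)) and
    summarized over the post-stimulus window ([0, post_window)) by ``summary``
    ('mean' or 'max'); the argmax wins, ties to the lower index (larger
    singular value).  Modes with zero pre-stimulus SD are skipped.
    """
    t_axis = np.asarray(t_axis, dtype=float)
    pre = (t_axis >= -pre_window) & (t_axis < 0)
    post = (t_axis >= 0) & (t_axis < post_window)
    if not pre.any() or not post.any():
        raise ValueError("pre/post windows do not overlap the time axis")
    reduce = {"mean": np.mean, "max": np.max}[summary]
    n_cand = min(n_modes, modes.n_modes)
    scores = np.full(n_cand, -np.inf)
    skipped: list[int] = []
    w_z_all = []
    for i in range(n_cand):
        w_t = modes.temporal_amplitude(i)
        mu, sd = w_t[pre].mean(), w_t[pre].std(ddof=0)
        if sd == 0:
            skipped.append(i)
            w_z_all.append(np.full_like(w_t, np.nan))
            continue
        w_z = (w_t - mu) / sd
        w_z_all.append(w_z)
        scores[i] = reduce(w_z[post])
    if len(skipped) == n_cand:
        raise ValueError("all candidate modes have zero pre-stimulus variance")
    index = int(np.argmax(scores))  # argmax takes the first (lowest) index on ties
    return ModeSelection(
        index=index,
        w_z=w_z_all[index],
        scores=scores,
        responsive=bool(scores[index] >= z_threshold),
        skipped=skipped,
    )


def spatial_phase_offset(u_col: np.ndarray, reference_channel: int) -> np.ndarray:
    """Per-channel spatial phase relative to a reference electrode.

    offset[c] = wrapped angle of U[c] relative to U[reference]; the
    reference (typically the V1 electrode) is 0 by construction, and the
    result is invariant under a global phase rotation of the column.
    """
    u_col = np.asarray(u_col)
    if not 0 <= reference_channel < u_col.size:
        raise ValueError("reference channel out of range")
    offsets = np.angle(u_col * np.conj(u_col[reference_channel]))
    offsets[reference_channel] = 0.0  # exact by definition
    return offsets


@dataclass
class GradientField:
    """Per-electrode spatial phase-gradient vectors (rad/mm).

    ``grad[:, 0]`` is the mediolateral (ML) component, ``grad[:, 1]`` the
    anteroposterior (AP) component, in stereotaxic axes; NaN where a
    component is undefined (missing neighbor).  The gradient points in the
    propagation direction (increasing phase delay).
    """

    grad: np.ndarray
    geometry: GridGeometry

    @property
    def norm(self) -> np.ndarray:
        """Euclidean norm |grad| per electrode (rad/mm); NaN if any
        component is undefined."""
        return np.sqrt((self.grad**2).sum(axis=1))

    @property
    def direction(self) -> np.ndarray:
        """Gradient direction per electrode (rad, atan2(AP, ML))."""
        return np.arctan2(self.grad[:, 1], self.grad[:, 0])

    def mean_direction(self) -> float:
        """Circular mean of per-site gradient directions."""
        d = self.direction
        ok = np.isfinite(d)
        return float(np.angle(np.exp(1j * d[ok]).sum()))


def _axis_gradient(z_line: np.ndarray, step_mm: float) -> np.ndarray:
    """One-dimensional phase gradient along a lattice line.

    Conjugate product of each site with its next neighbor gives the angle
    advance per step; interior sites circularly average the two one-sided
    estimates, edges keep the single available one.  NaN-valued (missing)
    sites poison only their own neighborhood.
    """
    n = z_line.size
    fwd = np.full(n - 1, np.nan + 0j, dtype=complex)
    prod = z_line[:-1] * np.conj(z_line[1:])
    ok = np.isfinite(prod)
    fwd[ok] = prod[ok]
    est = np.full(n, np.nan)
    for i in range(n):
        parts = []
        if i < n - 1 and np.isfinite(fwd[i]):
            parts.append(np.exp(1j * np.angle(fwd[i])))
        if i > 0 and np.isfinite(fwd[i - 1]):
            parts.append(np.exp(1j * np.angle(fwd[i - 1])))
        if parts:
            est[i] = np.angle(np.sum(parts)) / step_mm
    return est


def phase_gradient(u_col: np.ndarray, geometry: GridGeometry) -> GradientField:
    """Spatial phase gradient of a mode column on a rectangular grid.

    The complex loading at each electrode is multiplied by the conjugate
    of its adjacent electrode's loading, iterating along the ML (columns)
    and AP (rows) lattice axes; the angle of the product divided by the
    pitch is the phase advance in rad/mm.  Row index increases toward
    negative AP, so the row-axis estimate is negated to express the AP
    component in stereotaxic +AP.
    """
    z = np.asarray(u_col, dtype=complex)
    if z.size != geometry.n_channels:
        raise ValueError("mode column length does not match geometry")
    zg = z.reshape(geometry.n_rows, geometry.n_cols)
    grad = np.full((geometry.n_channels, 2), np.nan)
    gg = grad.reshape(geometry.n_rows, geometry.n_cols, 2)
    for r in range(geometry.n_rows):
        gg[r, :, 0] = _axis_gradient(zg[r, :], geometry.pitch_mm)
    for c in range(geometry.n_cols):
        gg[:, c, 1] = -_axis_gradient(zg[:, c], geometry.pitch_mm)
    return GradientField(grad=grad, geometry=geometry)


@dataclass
class WaveKinematics:
    """Per-site wave kinematics derived from one trial's selected mode.

    wavelength_mm = 2*pi / |grad| (mm/cycle); velocity_mm_s = f_t / |grad|
    with f_t the temporal phase slope in rad/s; equivalently velocity =
    temporal frequency in cycles/s times wavelength.  NaN marks sites with
    an undefined (zero or missing) gradient.
    """

    f_t_rad_s: float
    grad_norm: np.ndarray
    wavelength_mm: np.ndarray
    velocity_mm_s: np.ndarray

    @property
    def f_t_hz(self) -> float:
        """Temporal frequency in cycles/s."""
        return self.f_t_rad_s / (2 * np.pi)


def wave_kinematics(
    gradient: GradientField,
    theta_t: np.ndarray,
    t_axis: np.ndarray,
    window: tuple[float, float] | None = None,
    edge_exclude: int = 0,
) -> WaveKinematics:
    """Spatial wavelength and velocity from gradient norm and phase slope.

    The temporal frequency is the least-squares slope of the unwrapped
    temporal phase over ``window`` (seconds, default: full axis), with
    ``edge_exclude`` samples dropped at each end of the selection to avoid
    analytic-signal edge artifacts.
    """
    t_axis = np.asarray(t_axis, dtype=float)
    theta_t = np.asarray(theta_t, dtype=float)
    mask = np.ones(t_axis.size, dtype=bool)
    if window is not None:
        mask &= (t_axis >= window[0]) & (t_axis < window[1])
    if edge_exclude:
        mask &= np.arange(t_axis.size) >= edge_exclude
        mask &= np.arange(t_axis.size) < t_axis.size - edge_exclude
    if mask.sum() < 2:
        raise ValueError("temporal-phase window too short")
    unwrapped = np.unwrap(theta_t[mask])
    f_t = float(np.polyfit(t_axis[mask], unwrapped, 1)[0])  # rad/s
    gn = gradient.norm
    with np.errstate(divide="ignore", invalid="ignore"):
        wavelength = np.where(gn > 1e-12, 2 * np.pi / gn, np.nan)
        velocity = np.where(gn > 1e-12, abs(f_t) / gn, np.nan)
    return WaveKinematics(
        f_t_rad_s=f_t,
        grad_norm=gn,
        wavelength_mm=wavelength,
        velocity_mm_s=velocity,
    )


def reconstruct_mode(modes: ModeSet, index: int) -> np.ndarray:
    """Real LFP contribution of one mode.

    The rank-1 analytic reconstruction is A_i = U[:, i] * s_i * Vh[i, :];
    its real part is the mode's contribution to the band-filtered LFP, and
    the sum over all modes recovers the real part of A.
    """
    if not 0 <= index < modes.n_modes:
        raise ValueError("mode index out of range")
    a_i = np.outer(modes.U[:, index] * modes.S[index], modes.Vh[index, :])
    return np.real(a_i)
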