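"""Electrode registration to stereotaxic coordinates and query-grid
averaging across animals.

Grid-local electrode positions are carried into the stereotaxic frame by
a rigid map (rotation + translation) anchored on the two laminar-probe
insertion sites, whose stereotaxic locations are known from histology.
Per-electrode quantities from multiple animals are then pooled on a fixed
query grid by Gaussian distance weighting with a hard support cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circstats import circular_mean_variance

__all__ = [
    "RigidRegistration",
    "fit_registration",
    "triangulate_electrodes",
    "QueryGrid",
    "gaussian_weights",
    "gaussian_query_average",
]


@dataclass(frozen=True)
class RigidRegistration:
    """Rigid grid-local -> stereotaxic map: p -> R(theta) @ p + translation."""

    theta: float
    translation: np.ndarray

    @property
    def R(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.R.T + np.asarray(self.translation, dtype=float)


def fit_registration(
    local_anchors: np.ndarray, stereo_anchors: np.ndarray
) -> RigidRegistration:
    """Fit the rigid map from two probe locations known in both frames.

    theta is the angle between the inter-anchor vectors in the two frames;
    the translation maps the first anchor exactly onto its stereotaxic
    target.  The second anchor maps exactly when the inter-anchor
    distances agree (rigid maps preserve distances).
    """
    la = np.asarray(local_anchors, dtype=float)
    sa = np.asarray(stereo_anchors, dtype=float)
    if la.shape != (2, 2) or sa.shape != (2, 2):
        raise ValueError("two anchors required in each frame")
    v_local = la[1] - la[0]
    v_st = sa[1] - sa[0]
    if np.linalg.norm(v_local) == 0 or np.linalg.norm(v_st) == 0:
        raise ValueError("anchors must not coincide")
    theta = float(
        np.arctan2(v_st[1], v_st[0]) - np.arctan2(v_local[1], v_local[0])
    )
    reg = RigidRegistration(theta=theta, translation=np.zeros(2))
    translation = sa[0] - reg.apply(la[0])[0]
    return RigidRegistration(theta=theta, translation=translation)


def triangulate_electrodes(
    reg: RigidRegistration, grid_local_positions: np.ndarray
) -> np.ndarray:
    """Stereotaxic (ML, AP) positions of grid electrodes (mm)."""
    return reg.apply(grid_local_positions)


@dataclass(frozen=True)
class QueryGrid:
    """Fixed stereotaxic query lattice with a truncated Gaussian kernel.

    Defaults: ML in [-3.5, 0], AP in [-5, 0] at 0.5 mm spacing; kernel
    sd 0.15 mm, support cut off at 0.3 mm.
    """

    ml_range: tuple[float, float] = (-3.5, 0.0)
    ap_range: tuple[float, float] = (-5.0, 0.0)
    spacing_mm: float = 0.5
    sigma_mm: float = 0.15
    cutoff_mm: float = 0.3

    @property
    def points(self) -> np.ndarray:
        ml = np.arange(self.ml_range[0], self.ml_range[1] + self.spacing_mm / 2,
                       self.spacing_mm)
        ap = np.arange(self.ap_range[0], self.ap_range[1] + self.spacing_mm / 2,
                       self.spacing_mm)
        mlg, apg = np.meshgrid(ml, ap)
        return np.column_stack([mlg.ravel(), apg.ravel()])

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def gaussian_weights(
    distances: np.ndarray, sigma_mm: float = 0.15, cutoff_mm: float = 0.3
) -> np.ndarray:
    """Truncated Gaussian kernel weights.

    W(d) = 1/(sigma*sqrt(2*pi)) * exp(-d^2 / (2*sigma^2)) for d <= cutoff,
    0 beyond.
    """
    d = np.asarray(distances, dtype=float)
    w = np.exp(-(d**2) / (2 * sigma_mm**2)) / (sigma_mm * np.sqrt(2 * np.pi))
    return np.where(d <= cutoff_mm, w, 0.0)


def gaussian_query_average(
    values: np.ndarray,
    electrode_positions: np.ndarray,
    grid: QueryGrid | None = None,
    circular: bool = False,
) -> np.ndarray:
    """Distance-weighted average of per-electrode values at each query point.

    Weights are renormalized over the contributing (within-cutoff)
    electrodes; queries with no electrode in support are NaN (undefined,
    not zero).  With ``circular=True`` the values are angles and are
    averaged as weighted resultant vectors.
    """
    if grid is None:
        grid = QueryGrid()
    values = np.asarray(values, dtype=float)
    pos = np.atleast_2d(np.asarray(electrode_positions, dtype=float))
    out = np.full(grid.n_points, np.nan)
    for qi, q in enumerate(grid.points):
        d = np.linalg.norm(pos - q, axis=1)
        w = gaussian_weights(d, grid.sigma_mm, grid.cutoff_mm)
        ok = (w > 0) & np.isfinite(values)
        if not ok.any():
            continue
        if circular:
            mean, _ = circular_mean_variance(values[ok], w[ok])
            out[qi] = mean
        else:
            out[qi] = np.sum(w[ok] * values[ok]) / np.sum(w[ok])
    return out
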