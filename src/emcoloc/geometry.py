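"""Planar geometry: study windows, distance bands, and boundary-effect weights.

Immunogold particle coordinates live in a rectangular observation window (an
electron-micrograph crop).  Colocalization is assessed inside a distance
annulus [r_lo, r_hi) around each particle; particles near the window edge have
part of that annulus outside the observed field, which biases density-type
statistics downward.  The ``annulus_fraction`` edge weight corrects this by the
fraction of the annulus area that falls inside the window, computed from the
exact circle-rectangle intersection (an angular quadrature is kept as an
independent cross-check).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StudyWindow",
    "DistanceBand",
    "EdgeWeightSpec",
    "edge_weight",
    "annulus_window_fraction",
    "annulus_window_fraction_quadrature",
]


@dataclass(frozen=True)
class StudyWindow:
    """Rectangular observation window, origin (0, 0), image-style axes.

    Parameters
    ----------
    width, height : float
        Side lengths in nanometres (canonical unit).  The y axis increases
        downward, matching image conventions; nothing downstream depends on
        the orientation, only on the rectangle geometry.
    """

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"window sides must be positive, got {self.width} x {self.height}"
            )

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of the (n, 2) coordinate array inside the window."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (pts[:, 0] >= 0.0)
            & (pts[:, 0] <= self.width)
            & (pts[:, 1] >= 0.0)
            & (pts[:, 1] <= self.height)
        )


@dataclass(frozen=True)
class DistanceBand:
    """Half-open colocalization annulus [r_lo, r_hi) in nanometres.

    A pair of opposite-type particles is a colocalizing pair iff their
    Euclidean distance d satisfies r_lo <= d < r_hi (strict at r_hi).
    """

    r_lo: float
    r_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.r_lo < self.r_hi):
            raise ValueError(
                f"need 0 <= r_lo < r_hi, got [{self.r_lo}, {self.r_hi})"
            )

    @property
    def annulus_area(self) -> float:
        return math.pi * (self.r_hi**2 - self.r_lo**2)

    def contains(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return (d >= self.r_lo) & (d < self.r_hi)


@dataclass(frozen=True)
class EdgeWeightSpec:
    """Boundary-correction choice.

    mode ``"none"`` (default) uses weight 1 for every particle; mode
    ``"annulus_fraction"`` weights by the fraction of the particle's distance
    annulus inside the window.  ``quadrature_points`` controls the angular
    resolution of the numeric cross-check only; the primary computation is the
    closed-form circle-rectangle intersection.
    """

    mode: str = "none"
    quadrature_points: int = 3600

    def __post_init__(self) -> None:
        if self.mode not in ("none", "annulus_fraction"):
            raise ValueError(f"unknown edge-weight mode {self.mode!r}")
        if self.quadrature_points < 4:
            raise ValueError("quadrature_points must be at least 4")


def _quarter_disc_area(a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    """Area of {x^2 + y^2 <= r^2} intersected with [0, a] x [0, b] (a, b >= 0)."""
    if r == 0.0:
        return np.zeros(np.broadcast(a, b).shape)
    a = np.minimum(np.asarray(a, dtype=float), r)
    b = np.minimum(np.asarray(b, dtype=float), r)
    # x-coordinate where the circle drops below height b
    c = np.sqrt(np.maximum(r * r - b * b, 0.0))
    m = np.minimum(a, c)

    def antider(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return 0.5 * (
            x * np.sqrt(np.maximum(r * r - x * x, 0.0))
            + r * r * np.arcsin(np.clip(x / r, -1.0, 1.0))
        )

    return b * m + antider(a) - antider(m)


def disc_window_area(points: np.ndarray, r: float, window: StudyWindow) -> np.ndarray:
    """Exact area of the disc of radius ``r`` around each point, clipped to the window.

    Points must lie inside the window; the disc decomposes into four quadrant
    pieces whose extents are the distances to the window sides.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not window.contains(pts).all():
        raise ValueError("all points must lie inside the window")
    dx0, dx1 = pts[:, 0], window.width - pts[:, 0]
    dy0, dy1 = pts[:, 1], window.height - pts[:, 1]
    return (
        _quarter_disc_area(dx0, dy0, r)
        + _quarter_disc_area(dx0, dy1, r)
        + _quarter_disc_area(dx1, dy0, r)
        + _quarter_disc_area(dx1, dy1, r)
    )


def annulus_window_fraction(
    points: np.ndarray, band: DistanceBand, window: StudyWindow
) -> np.ndarray:
    """Fraction of each point's annulus [r_lo, r_hi) area inside the window.

    This is the weight w(x) of the isotropic local edge correction: 1 for
    interior points, down to 0.25 exactly at a window corner (when the annulus
    fits inside the adjacent sides).
    """
    outer = disc_window_area(points, band.r_hi, window)
    inner = disc_window_area(points, band.r_lo, window)
    return (outer - inner) / band.annulus_area


def annulus_window_fraction_quadrature(
    points: np.ndarray,
    band: DistanceBand,
    window: StudyWindow,
    n_angles: int = 3600,
) -> np.ndarray:
    """Angular-quadrature estimate of the annulus-inside fraction.

    Deterministic midpoint rule over ``n_angles`` directions: along each ray the
    in-window radial extent is [r_lo, min(r_hi, t)] where t is the distance to
    the window boundary.  Serves as the numeric fallback and the cross-check of
    the closed form.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not window.contains(pts).all():
        raise ValueError("all points must lie inside the window")
    theta = (np.arange(n_angles) + 0.5) * (2.0 * math.pi / n_angles)
    c, s = np.cos(theta), np.sin(theta)
    with np.errstate(divide="ignore"):
        tx = np.where(
            c > 0,
            (window.width - pts[:, [0]]) / c,
            np.where(c < 0, -pts[:, [0]] / c, np.inf),
        )
        ty = np.where(
            s > 0,
            (window.height - pts[:, [1]]) / s,
            np.where(s < 0, -pts[:, [1]] / s, np.inf),
        )
    t = np.minimum(tx, ty)  # (n_points, n_angles) distance to boundary
    r_out = np.clip(t, band.r_lo, band.r_hi)
    area = 0.5 * (r_out**2 - band.r_lo**2) @ np.full(n_angles, 2.0 * math.pi / n_angles)
    return area / band.annulus_area


def edge_weight(
    point: np.ndarray,
    band: DistanceBand,
    window: StudyWindow,
    spec: EdgeWeightSpec = EdgeWeightSpec(),
) -> float:
    """Boundary-correction weight w(x) for one particle.

    Raises if the point lies outside the window.  Mode ``none`` returns 1.
    """
    pt = np.asarray(point, dtype=float).reshape(1, 2)
    if not window.contains(pt).all():
        raise ValueError(f"point {point!r} lies outside the window")
    if spec.mode == "none":
        return 1.0
    return float(annulus_window_fraction(pt, band, window)[0])


def edge_weights(
    points: np.ndarray,
    band: DistanceBand,
    window: StudyWindow,
    spec: EdgeWeightSpec = EdgeWeightSpec(),
) -> np.ndarray:
    """Vectorised :func:`edge_weight` over an (n, 2) coordinate array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        return np.ones(0)
    if spec.mode == "none":
        return np.ones(pts.shape[0])
    return annulus_window_fraction(pts, band, window)
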