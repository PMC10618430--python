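"""Closure-site geometry: cable line profile, ZP circle fit, hinge angles, zones.

All inputs here are manual annotations (the zippering point, rim points, hinge
ray points, zone bounds): the module fits and measures, it does not detect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from pnpmetrics.core_io import Annotation

__all__ = [
    "LineProfile",
    "CircleFit",
    "AngleMeasure",
    "cable_profile",
    "fit_circle",
    "dlhp_angle",
    "assign_zone",
    "point_distance_um",
]


@dataclass(frozen=True)
class LineProfile:
    """F-actin intensity along a fixed-length mediolateral line through the ZP.

    ``peak_mean_ratio`` (brightest point of the cable over the profile
    average) is the cable-enrichment statistic; it is 1.0 for a uniform
    image and invariant to rescaling the image by a positive constant.
    """

    positions_um: np.ndarray
    intensities: np.ndarray
    peak: float
    mean: float
    peak_mean_ratio: float


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle through annotated rim points at the ZP.

    Radius and curvature (1/radius) are both reported: a blunter, more
    'open' zippering point has a larger fitted radius.  Collinear input is
    flagged degenerate with curvature 0.
    """

    center_y_um: float
    center_x_um: float
    radius_um: float
    curvature_per_um: float
    rms_residual_um: float
    n_points: int
    degenerate: bool = False


@dataclass(frozen=True)
class AngleMeasure:
    """Dorsolateral hinge-point angles from a YZ reslice; mean of both sides."""

    left_deg: float
    right_deg: float
    mean_deg: float


def cable_profile(
    actin: np.ndarray,
    zp_px: tuple[float, float],
    pixel_size_um: float,
    length_um: float = 100.0,
    width_px: int = 3,
) -> LineProfile:
    """Width-averaged intensity profile of a mediolateral line through the ZP.

    The line has constant physical length (shared across embryos of one
    experiment), is centred on the ZP and sampled at pixel pitch; the peak is
    the maximum over the whole profile, wherever the cable sits on the line.
    """
    actin = np.asarray(actin, dtype=float)
    half_px = (length_um / pixel_size_um) / 2.0
    y0, x0 = zp_px
    n = int(round(2 * half_px)) + 1
    xs = np.linspace(x0 - half_px, x0 + half_px, n)

    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    rows = y0 + offsets
    if (
        xs.min() < 0
        or xs.max() > actin.shape[1] - 1
        or rows.min() < 0
        or rows.max() > actin.shape[0] - 1
    ):
        raise ValueError("profile line exits the image")

    samples = np.empty((width_px, n))
    for i, r in enumerate(rows):
        coords = np.vstack([np.full(n, r), xs])
        samples[i] = ndimage.map_coordinates(actin, coords, order=1, mode="nearest")
    intensities = samples.mean(axis=0)

    positions = (xs - x0) * pixel_size_um
    peak = float(intensities.max())
    mean = float(intensities.mean())
    return LineProfile(
        positions_um=positions,
        intensities=intensities,
        peak=peak,
        mean=mean,
        peak_mean_ratio=peak / mean if mean > 0 else float("nan"),
    )


def fit_circle(points_um: np.ndarray) -> CircleFit:
    """Algebraic (Kasa) least-squares circle through >= 3 (y, x) points.

    Solves the linear system for the circle ``x^2 + y^2 + D x + E y + F = 0``;
    exact for three non-collinear points (coincides with the circumcircle).
    Collinear points give a degenerate fit, reported as curvature 0.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit a circle")
    y, x = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    # collinearity check via the rank of centred coordinates
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        return CircleFit(
            center_y_um=float("nan"),
            center_x_um=float("nan"),
            radius_um=float("inf"),
            curvature_per_um=0.0,
            rms_residual_um=float("nan"),
            n_points=len(pts),
            degenerate=True,
        )
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    radius = float(np.sqrt(sol[2] + cx**2 + cy**2))
    residuals = np.hypot(x - cx, y - cy) - radius
    return CircleFit(
        center_y_um=float(cy),
        center_x_um=float(cx),
        radius_um=radius,
        curvature_per_um=1.0 / radius,
        rms_residual_um=float(np.sqrt(np.mean(residuals**2))),
        n_points=len(pts),
    )


def _ray_angle_deg(vertex: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1 = np.asarray(p1, dtype=float) - vertex
    v2 = np.asarray(p2, dtype=float) - vertex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length ray in hinge-angle triplet")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dlhp_angle(triplets: list[np.ndarray]) -> AngleMeasure:
    """Hinge angle on each side from (vertex, ray1, ray2) point triplets.

    Points come from a YZ reslice through the dorsolateral hinge points; the
    reported measure is the average of the left and right vertex angles.
    Scale-invariant by construction.
    """
    if len(triplets) != 2:
        raise ValueError("expected exactly two triplets (left and right hinge)")
    angles = []
    for t in triplets:
        t = np.asarray(t, dtype=float)
        if t.shape != (3, 2):
            raise ValueError("each triplet is (vertex, ray1, ray2) as (y, x) points")
        angles.append(_ray_angle_deg(t[0], t[1], t[2]))
    left, right = angles
    return AngleMeasure(left_deg=left, right_deg=right, mean_deg=(left + right) / 2.0)


def assign_zone(
    position_um: np.ndarray,
    annotation: Annotation,
) -> tuple[int | None, str]:
    """Zone and midline/lateral class of a (y, x) position.

    The zone is looked up from rostrocaudal ranges relative to the ZP
    (positive rostral); a position outside all configured zones is
    unassigned (zone None) and excluded from grouped statistics.  The
    midline class applies when the unsigned mediolateral distance is within
    the configured half-band.
    """
    pos = np.asarray(position_um, dtype=float)
    rc = float(annotation.rostrocaudal_um(pos[None])[0])
    ml = float(annotation.mediolateral_um(pos[None])[0])
    zone = None
    for z, (lo, hi) in annotation.zone_bounds.items():
        if lo <= rc <= hi:
            zone = int(z)
            break
    side = "midline" if ml <= annotation.midline_band_halfwidth_um else "lateral"
    return zone, side


def point_distance_um(p1: np.ndarray, p2: np.ndarray) -> float:
    """Euclidean distance between two (y, x) points (e.g. a neuropore length)."""
    return float(np.linalg.norm(np.asarray(p1, float) - np.asarray(p2, float)))
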