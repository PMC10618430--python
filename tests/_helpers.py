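"""Shared test helpers: rasterisation and closed-form oracles."""

import numpy as np


def rasterize_ellipse(major_px: float, minor_px: float, orientation_deg: float) -> np.ndarray:
    """Binary raster of an ellipse whose long axis is ``orientation_deg`` from the row axis."""
    n = int(2 * major_px) + 10
    yy, xx = np.mgrid[0:n, 0:n] - n // 2
    th = np.radians(orientation_deg)
    u = yy * np.cos(th) + xx * np.sin(th)
    v = -yy * np.sin(th) + xx * np.cos(th)
    return ((u / major_px) ** 2 + (v / minor_px) ** 2 <= 1).astype(np.int32)


def circumcircle_radius(p1, p2, p3) -> float:
    """Closed-form circumcircle radius: abc / (4 * area)."""
    a = np.linalg.norm(np.subtract(p2, p3))
    b = np.linalg.norm(np.subtract(p1, p3))
    c = np.linalg.norm(np.subtract(p1, p2))
    s = (a + b + c) / 2.0
    area = np.sqrt(s * (s - a) * (s - b) * (s - c))
    return a * b * c / (4.0 * area)
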