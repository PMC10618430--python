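"""Laser-ablation recoil analysis: landmark tracking, kymographs and PIV.

Cutting a single cell border releases the tension it carried; the immediate
increase in separation of two reference points flanking the cut ("recoil")
reads out that tension.  The acquisition protocol is two pre-ablation frames,
the cut, then post-ablation frames at a fixed interval; recoil is the change
in landmark distance between the pre-ablation mean and the first
post-ablation frame — later frames increasingly mix viscous relaxation into
the elastic response, so only the initial recoil is used as the tension
readout.

Cuts are classified by the angle of the ablated border from the rostrocaudal
axis: borders up to 45 degrees from rostrocaudal get a mediolaterally
oriented cut (measuring rostrocaudal recoil) and vice versa.

Landmarks are tracked by normalised cross-correlation of small templates with
subpixel parabolic peak refinement; the same matching engine drives the
block-matching PIV, applied after a difference-of-Gaussians bandpass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

__all__ = [
    "AblationSeries",
    "RecoilResult",
    "classify_orientation",
    "track_landmarks",
    "compute_recoil",
    "kymograph",
    "piv",
]

LOW_CONFIDENCE = 0.5


@dataclass
class AblationSeries:
    """One single-border ablation movie with its annotations.

    ``frames`` is time-ordered ``(T, Y, X)``; ``ablation_frame_index`` is the
    index of the first post-ablation frame (2 under the standard protocol of
    2 pre-frames + 18 post-frames at ~0.9 s/frame).  ``cut_line`` and
    ``landmark_pair`` are (y, x) point pairs in micrometres.
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    ablation_frame_index: int = 2
    cut_line: np.ndarray | None = None
    landmark_pair: np.ndarray | None = None
    orientation_class: str | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, Y, X)")
        if not (1 <= self.ablation_frame_index < self.frames.shape[0]):
            raise ValueError("need at least one pre- and one post-ablation frame")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if self.landmark_pair is not None:
            self.landmark_pair = np.asarray(self.landmark_pair, dtype=float)
            if np.allclose(self.landmark_pair[0], self.landmark_pair[1]):
                raise ValueError("landmark points must be distinct")
        if self.cut_line is not None:
            self.cut_line = np.asarray(self.cut_line, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass(frozen=True)
class RecoilResult:
    """Initial recoil of the landmark pair: pre-mean vs first post frame."""

    d_pre_um: float
    d_post_um: float
    recoil_um: float
    recoil_rate_um_s: float
    trace_um: np.ndarray
    quality_flags: tuple[str, ...] = ()

    @property
    def flagged(self) -> bool:
        return bool(self.quality_flags)


def classify_orientation(border_angle_deg: float) -> str:
    """Cut class from the ablated border's angle off the rostrocaudal axis.

    Borders within 45 degrees of the rostrocaudal axis (inclusive) are cut
    mediolaterally and measure rostrocaudal recoil; steeper borders are cut
    rostrocaudally and measure mediolateral recoil.  Angles outside [0, 90]
    are folded first.
    """
    a = float(border_angle_deg) % 180.0
    if a > 90.0:
        a = 180.0 - a
    return "rostrocaudal" if a <= 45.0 else "mediolateral"


def _parabolic_offset(c_minus: float, c0: float, c_plus: float) -> float:
    denom = c_minus - 2.0 * c0 + c_plus
    if denom >= 0:  # not a local maximum; skip refinement
        return 0.0
    off = 0.5 * (c_minus - c_plus) / denom
    return float(np.clip(off, -0.5, 0.5))


def _refine_peak(corr: np.ndarray) -> tuple[float, float, float]:
    """Subpixel (y, x) of the correlation peak and its value."""
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    dy = dx = 0.0
    if 0 < iy < corr.shape[0] - 1:
        dy = _parabolic_offset(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    if 0 < ix < corr.shape[1] - 1:
        dx = _parabolic_offset(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    return iy + dy, ix + dx, float(corr[iy, ix])


def track_landmarks(
    series: AblationSeries,
    template_radius_px: int = 9,
    search_radius_px: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Track both landmarks through every frame by template matching.

    The template for each landmark is cut from the mean of the pre-ablation
    frames.  Per frame, the landmark is relocated by normalised
    cross-correlation within a search window around its initial position,
    with parabolic subpixel refinement.  Returns positions in micrometres,
    shape ``(T, 2, 2)``, and peak-correlation confidences ``(T, 2)``;
    frames with confidence below 0.5 should be treated as unreliable.
    """
    if series.landmark_pair is None:
        raise ValueError("series has no landmark pair annotated")
    frames = series.frames
    px = series.pixel_size_um
    r, s = int(template_radius_px), int(search_radius_px)
    margin = r + s
    ny, nx = frames.shape[1:]

    init_px = series.landmark_pair / px
    for y0, x0 in init_px:
        if not (margin <= y0 <= ny - 1 - margin and margin <= x0 <= nx - 1 - margin):
            raise ValueError(
                f"landmark at ({y0:.1f}, {x0:.1f}) px too close to the image edge "
                f"for template radius {r} + search radius {s}"
            )

    pre = frames[: series.ablation_frame_index].mean(axis=0)
    positions = np.empty((series.n_frames, 2, 2))
    confidences = np.empty((series.n_frames, 2))
    for k, (y0, x0) in enumerate(init_px):
        yi, xi = int(round(y0)), int(round(x0))
        template = pre[yi - r : yi + r + 1, xi - r : xi + r + 1]
        for t in range(series.n_frames):
            window = frames[t, yi - margin : yi + margin + 1, xi - margin : xi + margin + 1]
            corr = match_template(window, template)
            py, pxl, conf = _refine_peak(corr)
            # corr index 0 puts the template corner at window corner
            positions[t, k] = ((yi - s) + py) * px, ((xi - s) + pxl) * px
            confidences[t, k] = conf
    return positions, confidences


def compute_recoil(
    positions_um: np.ndarray,
    series: AblationSeries,
    confidences: np.ndarray | None = None,
) -> RecoilResult:
    """Recoil of the landmark pair from tracked positions.

    ``d_pre`` is the mean separation over pre-ablation frames, ``d_post`` the
    separation at the first post-ablation frame; ``recoil = d_post - d_pre``
    and the rate divides by one frame interval.  Low-confidence tracking on
    any frame used, or a manual exclusion flag on the series, flags the
    result rather than silently dropping it.
    """
    positions_um = np.asarray(positions_um, dtype=float)
    trace = np.linalg.norm(positions_um[:, 0] - positions_um[:, 1], axis=1)
    pre_idx = series.ablation_frame_index
    d_pre = float(trace[:pre_idx].mean())
    d_post = float(trace[pre_idx])
    flags: list[str] = []
    if confidences is not None and (confidences[: pre_idx + 1] < LOW_CONFIDENCE).any():
        flags.append("low_confidence")
    if series.excluded:
        flags.append("excluded")
    recoil = d_post - d_pre
    return RecoilResult(
        d_pre_um=d_pre,
        d_post_um=d_post,
        recoil_um=recoil,
        recoil_rate_um_s=recoil / series.frame_interval_s,
        trace_um=trace,
        quality_flags=tuple(flags),
    )


def kymograph(
    frames: np.ndarray,
    line_px: np.ndarray,
    width_px: int = 3,
    samples: int | None = None,
) -> np.ndarray:
    """Space-time image of intensity along a line, one column per frame.

    The line is sampled at pixel pitch (or ``samples`` points) and averaged
    across ``width_px`` perpendicular offsets; rows are positions along the
    line, columns are frames.
    """
    frames = np.asarray(frames, dtype=float)
    (y0, x0), (y1, x1) = np.asarray(line_px, dtype=float)
    length = float(np.hypot(y1 - y0, x1 - x0))
    if samples is None:
        samples = max(2, int(round(length)) + 1)
    tpar = np.linspace(0.0, 1.0, samples)
    ys = y0 + tpar * (y1 - y0)
    xs = x0 + tpar * (x1 - x0)
    # unit normal for width averaging
    nyv, nxv = (x1 - x0) / length, -(y1 - y0) / length
    offsets = np.arange(width_px) - (width_px - 1) / 2.0

    out = np.empty((samples, frames.shape[0]))
    for t in range(frames.shape[0]):
        acc = np.zeros(samples)
        for off in offsets:
            coords = np.vstack([ys + off * nyv, xs + off * nxv])
            acc += ndimage.map_coordinates(frames[t], coords, order=1, mode="nearest")
        out[:, t] = acc / len(offsets)
    return out


def _bandpass(image: np.ndarray, low_sigma: float, high_sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(image, low_sigma) - ndimage.gaussian_filter(image, high_sigma)


def piv(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    bandpass: tuple[float, float] = (1.0, 8.0),
    window_px: int = 32,
    search_px: int = 8,
) -> dict[str, np.ndarray]:
    """Block-matching PIV between two frames.

    Both frames are bandpassed with a difference of Gaussians, then each
    non-overlapping ``window_px`` block of ``frame_a`` is relocated in
    ``frame_b`` within ``search_px`` by normalised cross-correlation with
    subpixel refinement.  Returns window-centre coordinates ``y``/``x`` (px),
    displacements ``u`` (x) and ``v`` (y) in px, and the peak correlation
    ``score`` per window, all on the window grid.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share shape")
    if window_px > min(frame_a.shape):
        raise ValueError("window larger than image")

    fa = _bandpass(frame_a, *bandpass)
    fb = _bandpass(frame_b, *bandpass)
    ny, nx = fa.shape
    s = int(search_px)

    # only windows whose full search region fits: a clipped search region
    # cannot represent displacements towards the missing side
    ys = np.arange(s, ny - window_px - s + 1, window_px)
    xs = np.arange(s, nx - window_px - s + 1, window_px)
    if len(ys) == 0 or len(xs) == 0:
        raise ValueError("image too small for this window and search size")
    shape = (len(ys), len(xs))
    y_c = np.empty(shape)
    x_c = np.empty(shape)
    u = np.empty(shape)
    v = np.empty(shape)
    score = np.empty(shape)
    for i, wy in enumerate(ys):
        for j, wx in enumerate(xs):
            template = fa[wy : wy + window_px, wx : wx + window_px]
            sy0, sy1 = max(0, wy - s), min(ny, wy + window_px + s)
            sx0, sx1 = max(0, wx - s), min(nx, wx + window_px + s)
            corr = match_template(fb[sy0:sy1, sx0:sx1], template)
            py, pxl, sc = _refine_peak(corr)
            v[i, j] = (sy0 + py) - wy
            u[i, j] = (sx0 + pxl) - wx
            score[i, j] = sc
            y_c[i, j] = wy + (window_px - 1) / 2.0
            x_c[i, j] = wx + (window_px - 1) / 2.0
    return {"y": y_c, "x": x_c, "u": u, "v": v, "score": score}
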