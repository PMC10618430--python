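"""Synthetic scenes with stored ground truth for every pipeline stage.

Nothing here aims at photorealism: the generators emulate exactly the image
features the measurement code depends on, so that each estimator can be
checked against known truth.

* :func:`make_sheet_scene` — a curved superficial epithelial sheet over a
  deeper confounding layer.  Cell borders come from a Voronoi tessellation of
  an anisotropic seed lattice (space is stretched, tessellated, unstretched),
  so midline cells realise a programmed aspect ratio along the rostrocaudal
  axis while lateral cells stay near-isotropic.  Each cell carries one
  nucleus with uniform DAPI and a YAP level following a programmable spatial
  gradient.  The superficial signal is painted at a smooth parametric depth
  ``z(x, y)``; the confounder is painted ``confounder_depth_offset_um``
  deeper.  Noise is applied last.
* :func:`make_nucleus_table` — the same YAP-gradient statistics without the
  imaging round-trip: nucleus records drawn directly from the programmed
  gradient plus noise, for estimator-level checks at large n.
* :func:`make_ablation_series` — a textured field cut along a line; the two
  halves separate rigidly following exponential recoil
  ``d(t) = d0 + A (1 - exp(-t / tau))`` after the cut, matching the
  acquisition protocol of 2 pre-frames + 18 post-frames at 0.9 s/frame.
* :func:`make_geometry_scene` — a V-shaped actin ridge meeting at the
  zippering point, rim points on a circle of known radius, and a YZ-reslice
  image with programmed hinge angles.

All generators are deterministic under a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from pnpmetrics.ablation import AblationSeries
from pnpmetrics.core_io import Annotation, ImageStack
from pnpmetrics.nuclei import NucleusRecord

__all__ = [
    "SceneParams",
    "SheetTruth",
    "NucleusTableTruth",
    "AblationTruth",
    "GeometryTruth",
    "make_sheet_scene",
    "make_nucleus_table",
    "make_ablation_series",
    "make_geometry_scene",
    "auto_place_hinge_points",
]


@dataclass(frozen=True)
class SceneParams:
    """All knobs of the synthetic scenes, with study-condition defaults.

    The ablation timing defaults (2 pre-frames, 18 post-frames, 0.9 s/frame)
    are the acquisition protocol; everything else is generator truth chosen
    to resemble E9.5 confocal data of the closing spinal neural tube
    (~0.5 um/px in-plane, cells of ~200 um^2, nuclei of ~30 um^2).
    """

    seed: int = 0
    # field geometry
    field_um: tuple[float, float] = (200.0, 200.0)
    pixel_size_um: float = 0.5
    z_step_um: float = 1.0
    psf_sigma_um: float = 0.5
    # cell sheet
    n_cells: int = 200
    midline_aspect: float = 2.5
    midline_orientation_deg: float = 0.0
    lateral_aspect: float = 1.2
    midline_halfwidth_um: float = 25.0
    membrane_amp: float = 200.0
    membrane_diffuse: float = 80.0
    # nuclei / YAP
    nucleus_radius_um: float = 3.0
    dapi_mean: float = 100.0
    yap_baseline: float = 200.0
    yap_slope_per_um: float = -1.0
    yap_axis: str = "mediolateral"
    yap_noise_sd: float = 5.0
    # ratio-table generator
    ratio_baseline: float = 2.0
    ratio_slope_per_um: float = -0.01
    ratio_noise_sd: float = 0.9
    # depth structure
    surface_base_um: float = 5.0
    surface_amp_um: float = 3.0
    surface_period_um: float = 20.0
    confounder_depth_offset_um: float = 15.0
    confounder_amp: float = 150.0
    z_spread_um: float = 1.5
    # noise
    noise_sigma: float = 20.0
    poisson_noise: bool = False
    # actin cable / geometry scene
    cable_amplitude: float = 150.0
    cable_background: float = 50.0
    cable_sigma_um: float = 2.0
    cable_v_angle_deg: float = 60.0
    circle_radius_um: float = 25.0
    n_rim_points: int = 20
    dlhp_angles_deg: tuple[float, float] = (70.0, 74.0)
    # ablation forward model
    recoil_d0_um: float = 10.0
    recoil_A_um: float = 2.0
    recoil_tau_s: float = 3.0
    frames_pre: int = 2
    frames_post: int = 18
    frame_interval_s: float = 0.9
    ablation_field_px: int = 128
    ablation_pixel_size_um: float = 0.25
    texture_amp: float = 200.0
    snr: float = 5.0

    def surface_depth_um(self, x_um: np.ndarray) -> np.ndarray:
        """Smooth parametric surface depth z(x) = base + amp * sin(x / period)."""
        return self.surface_base_um + self.surface_amp_um * np.sin(
            np.asarray(x_um, dtype=float) / self.surface_period_um
        )


# ---------------------------------------------------------------------------
# sheet scene
# ---------------------------------------------------------------------------


@dataclass
class SheetTruth:
    """Everything the generator knows about one sheet scene."""

    params: SceneParams
    labels: np.ndarray
    cell_table: pd.DataFrame
    nucleus_table: pd.DataFrame
    surface_z_um: np.ndarray
    se_stack: np.ndarray
    confounder_stack: np.ndarray
    annotation: Annotation
    channel_names: tuple[str, ...]


def _lattice_points(
    rng: np.random.Generator,
    y0: float,
    y1: float,
    x0: float,
    x1: float,
    dy: float,
    dx: float,
    jitter: float,
    rotation_deg: float = 0.0,
) -> np.ndarray:
    """Jittered rectangular lattice covering [y0,y1] x [x0,x1], optionally rotated."""
    cy, cx = (y0 + y1) / 2.0, (x0 + x1) / 2.0
    # generous cover so rotation leaves no gaps
    span = max(y1 - y0, x1 - x0) * 0.75
    gy = np.arange(cy - span, cy + span + dy, dy)
    gx = np.arange(cx - span, cx + span + dx, dx)
    yy, xx = np.meshgrid(gy, gx, indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    pts += rng.uniform(-jitter, jitter, pts.shape) * np.array([dy, dx])
    if rotation_deg:
        th = np.radians(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = (pts - [cy, cx]) @ rot.T + [cy, cx]
    keep = (pts[:, 0] >= y0) & (pts[:, 0] < y1) & (pts[:, 1] >= x0) & (pts[:, 1] < x1)
    return pts[keep]


def _moment_ellipse(mask: np.ndarray, pixel_size_um: float) -> tuple[float, float, float]:
    """(aspect, orientation_deg folded to [0,90], area_um2) by direct summation."""
    ys, xs = np.nonzero(mask)
    y = ys - ys.mean()
    x = xs - xs.mean()
    n = len(ys)
    cov = np.array(
        [
            [np.mean(y * y), np.mean(y * x)],
            [np.mean(y * x), np.mean(x * x)],
        ]
    )
    evals, evecs = np.linalg.eigh(cov)
    major = 4.0 * np.sqrt(evals[1])
    minor = 4.0 * np.sqrt(evals[0])
    vy, vx = evecs[:, 1]
    angle = np.degrees(np.arctan2(vx, vy)) % 180.0
    if angle > 90.0:
        angle = 180.0 - angle
    return major / max(minor, 1e-12), angle, n * pixel_size_um**2


def make_sheet_scene(params: SceneParams) -> tuple[ImageStack, SheetTruth]:
    """Render a 3D two-layer sheet scene and return it with its ground truth.

    Channels: ``membrane`` (bright borders plus diffuse cytoplasmic signal,
    used as the surface-detection reference), ``yap`` and ``dapi``.  The
    superficial layer is painted in a Gaussian z-band centred on the
    parametric surface; the confounder (a smooth random texture standing in
    for the bright underlying neuroepithelium) is painted deeper in all
    channels.  The separate noiseless layer renders are stored in the truth
    so projection fidelity can be measured exactly.
    """
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size_um
    h_um, w_um = params.field_um
    ny, nx = int(round(h_um / px)), int(round(w_um / px))
    cx_um = w_um / 2.0

    if params.nucleus_radius_um / px < 2:
        raise ValueError("cells too small for nuclei at this pixel size")

    # --- anisotropic Voronoi seed lattice -------------------------------
    cell_area = h_um * w_um / params.n_cells
    s = np.sqrt(cell_area)
    a_mid = params.midline_aspect
    mid_x0, mid_x1 = cx_um - params.midline_halfwidth_um, cx_um + params.midline_halfwidth_um
    mid_pts = _lattice_points(
        rng, 0, h_um, mid_x0, mid_x1,
        dy=s * np.sqrt(a_mid), dx=s / np.sqrt(a_mid),
        jitter=0.08, rotation_deg=params.midline_orientation_deg,
    )
    lat_jitter = 0.08 + 0.30 * (params.lateral_aspect - 1.0)
    lat_all = _lattice_points(rng, 0, h_um, 0, w_um, dy=s, dx=s, jitter=lat_jitter)
    lat_pts = lat_all[(lat_all[:, 1] < mid_x0) | (lat_all[:, 1] >= mid_x1)]
    seeds = np.vstack([mid_pts, lat_pts])
    is_midline_seed = np.concatenate(
        [np.ones(len(mid_pts), bool), np.zeros(len(lat_pts), bool)]
    )

    yy, xx = np.meshgrid(np.arange(ny) * px, np.arange(nx) * px, indexing="ij")
    _, idx = cKDTree(seeds).query(np.column_stack([yy.ravel(), xx.ravel()]))
    labels = (idx + 1).reshape(ny, nx).astype(np.int32)

    # --- 2D channel composites ------------------------------------------
    from skimage.segmentation import find_boundaries

    borders = find_boundaries(labels, mode="thick")
    membrane2d = params.membrane_diffuse + params.membrane_amp * borders.astype(float)

    yap2d = np.zeros((ny, nx))
    dapi2d = np.zeros((ny, nx))
    zp_y_um = h_um  # zippering point at the caudal edge; whole field is rostral
    nuc_rows = []
    cell_rows = []
    r_nuc_px = params.nucleus_radius_um / px
    for lab in range(1, len(seeds) + 1):
        mask = labels == lab
        n_px = int(mask.sum())
        if n_px == 0:
            continue
        ys, xs = np.nonzero(mask)
        cy_px, cx_px = ys.mean(), xs.mean()
        cy_um, cx_um_cell = cy_px * px, cx_px * px
        aspect, orient, area = _moment_ellipse(mask, px)
        group_mid = bool(is_midline_seed[lab - 1])
        cell_rows.append(
            {
                "label": lab,
                "centroid_y_um": cy_um,
                "centroid_x_um": cx_um_cell,
                "area_um2": area,
                "aspect_ratio": aspect,
                "orientation_deg": orient,
                "is_midline": group_mid,
                "programmed_aspect": a_mid if group_mid else params.lateral_aspect,
                "programmed_orientation_deg": (
                    params.midline_orientation_deg if group_mid else np.nan
                ),
                "touches_border": bool(
                    ys.min() == 0 or xs.min() == 0 or ys.max() == ny - 1 or xs.max() == nx - 1
                ),
            }
        )
        # one nucleus per interior cell
        if (
            cy_px - r_nuc_px < 1
            or cx_px - r_nuc_px < 1
            or cy_px + r_nuc_px > ny - 2
            or cx_px + r_nuc_px > nx - 2
        ):
            continue
        dyy, dxx = np.meshgrid(
            np.arange(ny) - cy_px, np.arange(nx) - cx_px, indexing="ij"
        )
        nuc_mask = dyy**2 + dxx**2 <= r_nuc_px**2
        ml_um = abs(cx_um_cell - w_um / 2.0)
        rc_um = zp_y_um - cy_um
        coord = ml_um if params.yap_axis == "mediolateral" else rc_um
        yap_clean = params.yap_baseline + params.yap_slope_per_um * coord
        yap_val = max(yap_clean + rng.normal(0.0, params.yap_noise_sd), 0.0)
        yap2d[nuc_mask] = yap_val
        dapi2d[nuc_mask] = params.dapi_mean
        nuc_rows.append(
            {
                "label": lab,
                "centroid_y_um": cy_um,
                "centroid_x_um": cx_um_cell,
                "mediolateral_um": ml_um,
                "rostrocaudal_um": rc_um,
                "yap_noiseless": yap_clean,
                "yap_rendered": yap_val,
                "dapi": params.dapi_mean,
                "ratio_noiseless": yap_clean / params.dapi_mean,
            }
        )

    psf_px = params.psf_sigma_um / px
    membrane2d = ndimage.gaussian_filter(membrane2d, psf_px)
    yap2d = ndimage.gaussian_filter(yap2d, psf_px)
    dapi2d = ndimage.gaussian_filter(dapi2d, psf_px)

    # --- 3D painting ------------------------------------------------------
    surface_z = params.surface_depth_um(xx)
    z_max = (
        params.surface_base_um
        + params.surface_amp_um
        + params.confounder_depth_offset_um
        + 3.0 * params.z_spread_um
    )
    nz = int(np.ceil(z_max / params.z_step_um)) + 1
    z_um = np.arange(nz) * params.z_step_um

    def paint(channel2d: np.ndarray, depth_um: np.ndarray) -> np.ndarray:
        w = np.exp(
            -((z_um[:, None, None] - depth_um[None]) ** 2)
            / (2.0 * params.z_spread_um**2)
        )
        return w * channel2d[None]

    conf2d = ndimage.gaussian_filter(rng.uniform(0, 1, (ny, nx)), 3.0)
    conf2d = params.confounder_amp * (conf2d - conf2d.min()) / max(np.ptp(conf2d), 1e-12)
    conf_depth = surface_z + params.confounder_depth_offset_um

    channel_names = ("membrane", "yap", "dapi")
    se_stack = np.stack(
        [paint(membrane2d, surface_z), paint(yap2d, surface_z), paint(dapi2d, surface_z)]
    )
    conf_chan = paint(conf2d, conf_depth)
    confounder_stack = np.stack(
        [0.7 * conf_chan, conf_chan, conf_chan]
    )  # dimmer in the membrane reference channel

    data = se_stack + confounder_stack
    if params.poisson_noise:
        data = rng.poisson(np.maximum(data, 0)).astype(float)
    if params.noise_sigma > 0:
        data = np.maximum(data + rng.normal(0.0, params.noise_sigma, data.shape), 0.0)

    annotation = Annotation(
        midline=np.array([[0.0, w_um / 2.0], [h_um, w_um / 2.0]]),
        zp_position=np.array([zp_y_um, w_um / 2.0]),
        zone_bounds={
            1: (0.0, h_um / 3.0 - 1.0),
            2: (h_um / 3.0, 2.0 * h_um / 3.0 - 1.0),
            3: (2.0 * h_um / 3.0, h_um),
        },
        midline_band_halfwidth_um=params.midline_halfwidth_um,
    )
    stack = ImageStack(
        data=data,
        channel_names=channel_names,
        pixel_size_um=px,
        z_step_um=params.z_step_um,
    )
    truth = SheetTruth(
        params=params,
        labels=labels,
        cell_table=pd.DataFrame(cell_rows),
        nucleus_table=pd.DataFrame(nuc_rows),
        surface_z_um=surface_z,
        se_stack=se_stack.astype(np.float32),
        confounder_stack=confounder_stack.astype(np.float32),
        annotation=annotation,
        channel_names=channel_names,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# direct nucleus-table generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucleusTableTruth:
    params: SceneParams
    slope_per_um: float
    population_r: float
    noiseless_ratios: np.ndarray


def make_nucleus_table(
    params: SceneParams,
    n_nuclei: int = 500,
    axis: str = "mediolateral",
) -> tuple[list[NucleusRecord], NucleusTableTruth]:
    """Draw nucleus records directly from the programmed ratio gradient.

    Positions are uniform on the reflected half-plane; the YAP/DAPI ratio is
    ``baseline + slope * coordinate + N(0, sd)``.  The implied population
    correlation ``slope * sd_x / sqrt(slope^2 sd_x^2 + sd^2)`` is stored in
    the truth, so sign-recovery claims can be conditioned on it.
    """
    rng = np.random.default_rng(params.seed)
    h_um, w_um = params.field_um
    ml = rng.uniform(0.0, w_um / 2.0, n_nuclei)
    rc = rng.uniform(0.0, h_um, n_nuclei)
    coord = ml if axis == "mediolateral" else rc
    clean = params.ratio_baseline + params.ratio_slope_per_um * coord
    ratios = clean + rng.normal(0.0, params.ratio_noise_sd, n_nuclei)

    sd_x = np.sqrt(((w_um / 2.0 if axis == "mediolateral" else h_um)) ** 2 / 12.0)
    signal = params.ratio_slope_per_um * sd_x
    pop_r = signal / np.sqrt(signal**2 + params.ratio_noise_sd**2)

    records = [
        NucleusRecord(
            label=i + 1,
            centroid_y_um=float(h_um - rc[i]),
            centroid_x_um=float(w_um / 2.0 + ml[i]),
            area_um2=30.0,
            perimeter_um=20.0,
            circularity=0.94,
            mean_yap=float(ratios[i] * params.dapi_mean),
            mean_dapi=params.dapi_mean,
            yap_dapi_ratio=float(ratios[i]),
            mediolateral_um=float(ml[i]),
            rostrocaudal_um=float(rc[i]),
        )
        for i in range(n_nuclei)
    ]
    truth = NucleusTableTruth(
        params=params,
        slope_per_um=params.ratio_slope_per_um,
        population_r=float(pop_r),
        noiseless_ratios=clean,
    )
    return records, truth


# ---------------------------------------------------------------------------
# ablation series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AblationTruth:
    params: SceneParams
    d_trace_um: np.ndarray
    positions_um: np.ndarray
    first_post_recoil_um: float
    cut_y_um: float


def _smooth_texture(rng: np.random.Generator, shape: tuple[int, int], amp: float) -> np.ndarray:
    t = ndimage.gaussian_filter(rng.uniform(0, 1, shape), 1.5)
    t = (t - t.min()) / max(np.ptp(t), 1e-12)
    return amp * t


def make_ablation_series(params: SceneParams) -> tuple[AblationSeries, AblationTruth]:
    """Forward-simulate a single-border ablation movie.

    A smooth random texture is cut along a mediolateral line through the
    centre; the two halves translate rigidly apart so that the landmark
    separation follows ``d(t) = d0`` pre-cut and
    ``d(t) = d0 + A (1 - exp(-t/tau))`` after, with the first post-ablation
    frame at ``t = frame_interval_s``.  The cut site is darkened in
    post-ablation frames.  Landmarks are placed with a random subpixel
    offset so raster phase never aligns across seeds.
    """
    rng = np.random.default_rng(params.seed)
    n = params.ablation_field_px
    px = params.ablation_pixel_size_um
    dt = params.frame_interval_s
    n_frames = params.frames_pre + params.frames_post

    texture = _smooth_texture(rng, (n, n), params.texture_amp)
    cut_y_px = n / 2.0 + rng.uniform(-0.5, 0.5)
    cx_px = n / 2.0 + rng.uniform(-0.5, 0.5)
    half_d_px = (params.recoil_d0_um / px) / 2.0

    # separation increase at each frame (0 pre-cut)
    d_extra = np.zeros(n_frames)
    for i in range(params.frames_post):
        t = (i + 1) * dt
        d_extra[params.frames_pre + i] = params.recoil_A_um * (
            1.0 - np.exp(-t / params.recoil_tau_s)
        )

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    above = yy < cut_y_px
    frames = np.empty((n_frames, n, n))
    positions = np.empty((n_frames, 2, 2))
    # SNR = texture contrast (std) over read-noise std
    noise_sd = float(texture.std()) / params.snr
    for f in range(n_frames):
        shift_px = (d_extra[f] / px) / 2.0
        src_y = np.where(above, yy + shift_px, yy - shift_px)
        frame = ndimage.map_coordinates(texture, [src_y, xx], order=3, mode="nearest")
        if f >= params.frames_pre:
            band = np.abs(yy - cut_y_px) < 1.5
            frame = np.where(band, 0.1 * frame, frame)
        if noise_sd > 0:
            frame = np.maximum(frame + rng.normal(0.0, noise_sd, frame.shape), 0.0)
        frames[f] = frame
        positions[f, 0] = ((cut_y_px - half_d_px - shift_px) * px, cx_px * px)
        positions[f, 1] = ((cut_y_px + half_d_px + shift_px) * px, cx_px * px)

    d_trace = np.linalg.norm(positions[:, 0] - positions[:, 1], axis=1)
    series = AblationSeries(
        frames=frames,
        frame_interval_s=dt,
        pixel_size_um=px,
        ablation_frame_index=params.frames_pre,
        cut_line=np.array([[cut_y_px * px, 0.0], [cut_y_px * px, (n - 1) * px]]),
        landmark_pair=positions[0].copy(),
        orientation_class="rostrocaudal",
    )
    truth = AblationTruth(
        params=params,
        d_trace_um=d_trace,
        positions_um=positions,
        first_post_recoil_um=float(
            params.recoil_A_um * (1.0 - np.exp(-dt / params.recoil_tau_s))
        ),
        cut_y_um=cut_y_px * px,
    )
    return series, truth


# ---------------------------------------------------------------------------
# geometry scene
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometryTruth:
    params: SceneParams
    zp_um: np.ndarray
    rim_points_um: np.ndarray
    circle_center_um: np.ndarray
    dlhp_triplets_px: list[np.ndarray]
    dlhp_mean_deg: float
    reslice: np.ndarray


def _segment_distance(yy, xx, p0, p1):
    """Distance of every pixel to the segment p0-p1 (all in px coordinates)."""
    d = np.array(p1) - np.array(p0)
    L2 = float(d @ d)
    t = ((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(yy - (p0[0] + t * d[0]), xx - (p0[1] + t * d[1]))


def make_geometry_scene(params: SceneParams) -> tuple[ImageStack, GeometryTruth]:
    """Render the closure-site geometry scene.

    The actin channel holds a V-shaped Gaussian ridge of programmed
    amplitude whose arms open caudally from the zippering point at the
    programmed V angle.  Rim points on a circle of ``circle_radius_um`` and
    a YZ-reslice with programmed hinge angles are stored in the truth.
    """
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size_um
    h_um, w_um = params.field_um
    ny, nx = int(round(h_um / px)), int(round(w_um / px))
    zp = np.array([ny / 2.0, nx / 2.0])  # px

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    half = np.radians(params.cable_v_angle_deg / 2.0)
    arm_len = ny / 2.0 - 2.0
    arms = []
    for sign in (-1.0, 1.0):
        direction = np.array([np.cos(half), sign * np.sin(half)])  # (dy, dx), caudal +y
        arms.append((zp, zp + arm_len * direction))
    dist = np.minimum(
        _segment_distance(yy, xx, *arms[0]), _segment_distance(yy, xx, *arms[1])
    )
    sigma_px = params.cable_sigma_um / px
    actin = params.cable_background + params.cable_amplitude * np.exp(
        -(dist**2) / (2.0 * sigma_px**2)
    )
    if params.noise_sigma > 0:
        actin = np.maximum(actin + rng.normal(0.0, params.noise_sigma, actin.shape), 0.0)

    # rim points on a circle touching the ZP from the rostral side
    center = zp * px - np.array([params.circle_radius_um, 0.0])
    theta = np.linspace(0, 2 * np.pi, params.n_rim_points, endpoint=False)
    rim = center + params.circle_radius_um * np.column_stack(
        [np.cos(theta), np.sin(theta)]
    )

    # YZ reslice with two hinges at programmed angles, bisector vertical
    res = np.full((ny, nx), 10.0)
    vds = []
    left_deg, right_deg = params.dlhp_angles_deg
    vx_left, vx_right = nx * 0.25, nx * 0.75
    vy = ny * 0.7
    triplets = []
    for vx, ang in ((vx_left, left_deg), (vx_right, right_deg)):
        half_a = np.radians(ang / 2.0)
        v = np.array([vy, vx])
        d1 = np.array([-np.cos(half_a), -np.sin(half_a)])  # up-left
        d2 = np.array([-np.cos(half_a), np.sin(half_a)])  # up-right
        L = ny * 0.25
        for d in (d1, d2):
            dseg = _segment_distance(yy, xx, v, v + L * d)
            res += 200.0 * np.exp(-(dseg**2) / (2.0 * 1.5**2))
        triplets.append(np.array([v, v + L * d1, v + L * d2]))
        vds.append(ang)
    if params.noise_sigma > 0:
        res = np.maximum(res + rng.normal(0.0, params.noise_sigma, res.shape), 0.0)

    stack = ImageStack(
        data=actin[None],
        channel_names=("actin",),
        pixel_size_um=px,
    )
    truth = GeometryTruth(
        params=params,
        zp_um=zp * px,
        rim_points_um=rim,
        circle_center_um=center,
        dlhp_triplets_px=triplets,
        dlhp_mean_deg=float(np.mean(vds)),
        reslice=res,
    )
    return stack, truth


def auto_place_hinge_points(
    reslice: np.ndarray,
    vertex_px: np.ndarray,
    radii_px: tuple[float, float] = (15.0, 30.0),
    n_angles: int = 720,
) -> np.ndarray:
    """Place ray points on the two rendered walls around a hinge vertex.

    For each radius, intensity is sampled on a circle around the vertex and
    the two brightest angular peaks (one per wall, separated by at least 20
    degrees) are taken; the wall direction is averaged over radii.  Returns
    a (vertex, ray1, ray2) triplet in pixel coordinates.
    """
    vertex = np.asarray(vertex_px, dtype=float)
    angles = np.linspace(-np.pi, np.pi, n_angles, endpoint=False)
    directions = []
    for r in radii_px:
        ys = vertex[0] + r * np.sin(angles)
        xs = vertex[1] + r * np.cos(angles)
        inside = (ys >= 0) & (ys <= reslice.shape[0] - 1) & (xs >= 0) & (xs <= reslice.shape[1] - 1)
        vals = np.full(n_angles, -np.inf)
        vals[inside] = ndimage.map_coordinates(
            reslice, [ys[inside], xs[inside]], order=1, mode="nearest"
        )
        first = int(np.argmax(vals))
        # suppress a window around the first peak to find the second wall
        sep = int(n_angles * 20.0 / 360.0)
        masked = vals.copy()
        for k in range(first - sep, first + sep + 1):
            masked[k % n_angles] = -np.inf
        second = int(np.argmax(masked))
        for peak in (first, second):
            directions.append((r, angles[peak]))
    # group directions into the two walls by angle proximity to the first radius's peaks
    base = [a for (r, a) in directions[:2]]
    walls: list[list[float]] = [[], []]
    for r, a in directions:
        diffs = [abs(np.angle(np.exp(1j * (a - b)))) for b in base]
        walls[int(np.argmin(diffs))].append(a)
    rays = []
    rmax = max(radii_px)
    for wall in walls:
        ang = np.angle(np.mean(np.exp(1j * np.array(wall))))
        rays.append(vertex + rmax * np.array([np.sin(ang), np.cos(ang)]))
    return np.array([vertex, rays[0], rays[1]])
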