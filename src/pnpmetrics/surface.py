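"""Superficial-layer extraction from z-stacks.

The surface ectoderm is a single cell layer sitting on top of the much
brighter, thicker neuroepithelium.  All downstream 2D analysis runs on a
"surface-subtracted" projection: for every (y, x) column we locate the depth
of the superficial layer in a reference channel, then max-project only a thin
band below that depth, discarding deeper confounding signal.

The surface is taken as the argmax of the Gaussian-smoothed (sigma = 1
z-step) column profile, and the resulting depth map is cleaned with a 2D
median filter.  Columns whose maximum intensity falls below an intensity
floor (default: Otsu threshold of the per-column maxima) carry no surface
signal and are marked invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from pnpmetrics.core_io import ImageStack

__all__ = ["DepthMap", "extract_surface", "project_band"]


@dataclass(frozen=True)
class DepthMap:
    """Per-column depth of the detected superficial layer.

    ``z_surface_um`` gives the depth in micrometres wherever ``valid_mask``
    is true; invalid columns are excluded from any projection.
    """

    z_surface_um: np.ndarray
    valid_mask: np.ndarray
    z_step_um: float

    def __post_init__(self) -> None:
        if self.z_surface_um.shape != self.valid_mask.shape:
            raise ValueError("z_surface_um and valid_mask must share shape")

    @property
    def z_index(self) -> np.ndarray:
        return np.rint(self.z_surface_um / self.z_step_um).astype(int)


def extract_surface(
    stack: ImageStack,
    reference_channel: str = "membrane",
    smoothing_radius_px: int = 5,
    intensity_floor: float | None = None,
) -> DepthMap:
    """Locate the superficial layer in every (y, x) column of a z-stack.

    Parameters
    ----------
    stack
        3D calibrated stack.
    reference_channel
        Channel used to detect the surface (typically the membrane stain).
    smoothing_radius_px
        Radius of the 2D median filter applied to the raw depth map.
    intensity_floor
        Columns whose maximum (smoothed) intensity is below this are invalid.
        Defaults to the Otsu threshold of the per-column maxima; blank stacks
        yield an all-invalid map.
    """
    if not stack.is_3d:
        raise ValueError("extract_surface requires a 3D stack")
    ref = np.asarray(stack.channel(reference_channel), dtype=float)

    smoothed = ndimage.gaussian_filter1d(ref, sigma=1.0, axis=0, mode="nearest")
    z_idx = np.argmax(smoothed, axis=0)
    col_max = smoothed.max(axis=0)

    if intensity_floor is None:
        if np.ptp(col_max) == 0:
            intensity_floor = np.inf if col_max.max() == 0 else -np.inf
        else:
            intensity_floor = threshold_otsu(col_max)
    valid = col_max >= intensity_floor

    if smoothing_radius_px > 0:
        size = 2 * int(smoothing_radius_px) + 1
        z_idx = ndimage.median_filter(z_idx, size=size, mode="nearest")

    return DepthMap(
        z_surface_um=z_idx.astype(float) * stack.z_step_um,
        valid_mask=valid,
        z_step_um=stack.z_step_um,
    )


def project_band(stack: ImageStack, depth: DepthMap, band_um: float = 10.0) -> ImageStack:
    """Max-project a band of thickness ``band_um`` below the detected surface.

    Every channel is projected over ``z in [z_surface, z_surface + band_um]``
    (depth increasing into the tissue).  Invalid columns are set to zero.
    A band thinner than one z-step falls back to the single nearest slice,
    with a warning.
    """
    if not band_um > 0:
        raise ValueError("band_um must be positive")
    if not stack.is_3d:
        raise ValueError("project_band requires a 3D stack")
    nz = stack.data.shape[1]
    z_step = stack.z_step_um
    if band_um < z_step:
        warnings.warn(
            f"band_um={band_um} is thinner than one z-step ({z_step} um); "
            "using the single nearest slice",
            stacklevel=2,
        )

    z0 = depth.z_index
    n_slices = max(1, int(np.floor(band_um / z_step)) + 1)
    zz = np.arange(nz)[:, None, None]
    in_band = (zz >= z0[None]) & (zz <= np.minimum(z0 + n_slices - 1, nz - 1)[None])

    out = np.empty((stack.n_channels,) + stack.frame_shape[1:], dtype=stack.data.dtype)
    for c in range(stack.n_channels):
        chan = stack.data[c]
        masked = np.where(in_band, chan, 0)
        proj = masked.max(axis=0)
        proj = np.where(depth.valid_mask, proj, 0)
        out[c] = proj
    return stack.with_data(out, z_step_um=None)
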