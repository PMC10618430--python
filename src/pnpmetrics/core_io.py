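"""Calibrated image I/O, annotation parsing and tabular output.

Conventions used throughout the package:

* Arrays are indexed ``(z, y, x)`` (3D) or ``(y, x)`` (2D) per channel, with a
  leading channel axis on multi-channel stacks.
* Coordinates are 0-based at pixel centres; a physical position is simply
  ``index * pixel_size_um``.
* The image y axis points caudally by default, so the rostrocaudal anatomical
  axis is the image row axis and angles "from the rostrocaudal axis" are
  measured against it.  Rostrocaudal positions are reported relative to the
  zippering point (ZP), positive rostrally (towards smaller y).
* Calibration is carried as metadata and never applied to voxel values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import LineString, Point

__all__ = [
    "ConfigurationError",
    "ImageStack",
    "Annotation",
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
    "load_annotation",
]


class ConfigurationError(ValueError):
    """Raised when required calibration or annotation entries are missing."""


_METADATA_KEY = "pnpmetrics"


@dataclass(frozen=True)
class ImageStack:
    """A calibrated multi-channel raster.

    Parameters
    ----------
    data
        Array of shape ``(C, Y, X)`` or ``(C, Z, Y, X)``.  A channel axis is
        always present, even for single-channel images.
    channel_names
        One name per channel (e.g. ``"membrane"``, ``"actin"``, ``"yap"``,
        ``"dapi"``).
    pixel_size_um
        In-plane pixel size in micrometres per pixel (isotropic in x/y).
    z_step_um
        Axial step in micrometres; required for 3D stacks.
    frame_interval_s
        Frame interval for time series, if applicable.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float
    z_step_um: float | None = None
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if data.ndim not in (3, 4):
            raise ValueError(f"expected (C, Y, X) or (C, Z, Y, X) data, got shape {data.shape}")
        if len(self.channel_names) != data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {data.shape[0]} channels"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.is_3d and (self.z_step_um is None or not self.z_step_um > 0):
            raise ConfigurationError("3D stacks require a positive z_step_um")
        if np.issubdtype(data.dtype, np.floating) and np.nanmin(data) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def is_3d(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the raster for a named channel (a view, not a copy)."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None
        return self.data[i]

    def with_data(self, data: np.ndarray, **overrides: Any) -> "ImageStack":
        kwargs: dict[str, Any] = dict(
            channel_names=self.channel_names,
            pixel_size_um=self.pixel_size_um,
            z_step_um=self.z_step_um,
            frame_interval_s=self.frame_interval_s,
        )
        kwargs.update(overrides)
        return ImageStack(data=data, **kwargs)


def read_stack(
    path: str | Path,
    *,
    channel_names: Sequence[str] | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    Calibration passed as keyword arguments takes precedence over any
    calibration embedded by :func:`write_stack`.  If neither source provides a
    pixel size, a :class:`ConfigurationError` is raised — voxel values are
    never silently assumed to be calibrated.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description or ""
    except (OSError, ValueError, IndexError, tifffile.TiffFileError) as exc:
        raise OSError(f"could not read TIFF {path}: {exc}") from exc

    meta: dict[str, Any] = {}
    if desc:
        try:
            loaded = json.loads(desc)
            if isinstance(loaded, dict):
                meta = loaded.get(_METADATA_KEY, {})
        except json.JSONDecodeError:
            pass

    if channel_names is None:
        channel_names = meta.get("channel_names")
    if pixel_size_um is None:
        pixel_size_um = meta.get("pixel_size_um")
    if z_step_um is None:
        z_step_um = meta.get("z_step_um")
    if frame_interval_s is None:
        frame_interval_s = meta.get("frame_interval_s")

    if pixel_size_um is None:
        raise ConfigurationError(f"{path}: no pixel size embedded and none supplied")

    data = np.asarray(data)
    if channel_names is None:
        channel_names = ["channel_0"] if data.ndim == 2 else None
    if data.ndim == 2:
        data = data[None]
    elif data.ndim == 3 and channel_names is not None and len(channel_names) == data.shape[0]:
        pass  # already (C, Y, X)
    elif data.ndim == 3 and (channel_names is None or len(channel_names) == 1):
        # single-channel z-stack stored as pages
        data = data[None]
        channel_names = channel_names or ["channel_0"]
    if channel_names is None:
        channel_names = [f"channel_{i}" for i in range(data.shape[0])]

    return ImageStack(
        data=data,
        channel_names=tuple(channel_names),
        pixel_size_um=float(pixel_size_um),
        z_step_um=None if z_step_um is None else float(z_step_um),
        frame_interval_s=None if frame_interval_s is None else float(frame_interval_s),
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` to TIFF with calibration embedded.

    Voxel values are written bit-exactly; integer rasters round-trip through
    :func:`read_stack` unchanged.
    """
    meta = {
        _METADATA_KEY: {
            "channel_names": list(stack.channel_names),
            "pixel_size_um": stack.pixel_size_um,
            "z_step_um": stack.z_step_um,
            "frame_interval_s": stack.frame_interval_s,
        }
    }
    tifffile.imwrite(
        Path(path), stack.data, description=json.dumps(meta), photometric="minisblack"
    )


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass
class Annotation:
    """Manual landmarks for one embryo, all lengths in micrometres.

    The midline is a polyline in image ``(y, x)`` coordinates; mediolateral
    positions are unsigned distances to it (left/right reflected together).
    Zone bounds are rostrocaudal ranges relative to the ZP, positive rostral.
    """

    midline: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    zp_position: np.ndarray | None = None
    zone_bounds: dict[int, tuple[float, float]] = field(default_factory=dict)
    midline_band_halfwidth_um: float = 25.0
    dlhp_triplets: list[np.ndarray] = field(default_factory=list)
    landmark_pairs: list[np.ndarray] = field(default_factory=list)
    exclusion_flags: list[dict[str, bool]] = field(default_factory=list)
    rostrocaudal_axis: str = "y"

    def __post_init__(self) -> None:
        self.midline = np.atleast_2d(np.asarray(self.midline, dtype=float))
        if self.zp_position is not None:
            self.zp_position = np.asarray(self.zp_position, dtype=float)
        self.dlhp_triplets = [np.asarray(t, dtype=float) for t in self.dlhp_triplets]
        self.landmark_pairs = [np.asarray(p, dtype=float) for p in self.landmark_pairs]
        self.validate()

    def validate(self) -> None:
        bounds = sorted(self.zone_bounds.values())
        for (lo0, hi0), (lo1, _hi1) in zip(bounds, bounds[1:]):
            if lo1 < hi0:
                raise ConfigurationError("zone ranges must be disjoint")
        for t in self.dlhp_triplets:
            if t.shape != (3, 2):
                raise ConfigurationError("each DLHP triplet is (vertex, ray1, ray2)")
            if np.allclose(t[0], t[1]) or np.allclose(t[0], t[2]):
                raise ConfigurationError("DLHP triplet vertex must be distinct from ray points")
        for p in self.landmark_pairs:
            if p.shape != (2, 2):
                raise ConfigurationError("landmark pairs are two (y, x) points")
            if np.allclose(p[0], p[1]):
                raise ConfigurationError("landmark pairs need non-zero initial separation")
        if not self.midline_band_halfwidth_um >= 0:
            raise ConfigurationError("midline_band_halfwidth_um must be non-negative")

    # -- derived coordinates ------------------------------------------------

    def mediolateral_um(self, points_um: np.ndarray) -> np.ndarray:
        """Unsigned distance from each ``(y, x)`` point to the midline polyline.

        Left and right sides are reflected onto one half-plane, assuming
        bilateral symmetry.
        """
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        if self.midline.shape[0] == 0:
            raise ConfigurationError("no midline annotated")
        if self.midline.shape[0] == 1:
            # vertical line through the single point (rostrocaudal axis = y)
            return np.abs(pts[:, 1] - self.midline[0, 1])
        line = LineString(self.midline[:, ::-1])  # shapely wants (x, y)
        return np.array([line.distance(Point(x, y)) for y, x in pts])

    def rostrocaudal_um(self, points_um: np.ndarray) -> np.ndarray:
        """Rostrocaudal position relative to the ZP, positive rostral."""
        if self.zp_position is None:
            raise ConfigurationError("no ZP position annotated")
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        return self.zp_position[0] - pts[:, 0]


def load_annotation(path: str | Path) -> Annotation:
    """Load an :class:`Annotation` from a per-embryo YAML config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict[str, Any] = {}
    if "midline" in raw:
        kwargs["midline"] = np.asarray(raw["midline"], dtype=float)
    if "zp_position" in raw:
        kwargs["zp_position"] = np.asarray(raw["zp_position"], dtype=float)
    if "zone_bounds" in raw:
        kwargs["zone_bounds"] = {
            int(k): (float(v[0]), float(v[1])) for k, v in raw["zone_bounds"].items()
        }
    for key in ("midline_band_halfwidth_um", "rostrocaudal_axis"):
        if key in raw:
            kwargs[key] = raw[key]
    if "dlhp_triplets" in raw:
        kwargs["dlhp_triplets"] = [np.asarray(t, dtype=float) for t in raw["dlhp_triplets"]]
    if "landmark_pairs" in raw:
        kwargs["landmark_pairs"] = [np.asarray(p, dtype=float) for p in raw["landmark_pairs"]]
    if "exclusion_flags" in raw:
        kwargs["exclusion_flags"] = list(raw["exclusion_flags"])
    return Annotation(**kwargs)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def _record_to_dict(record: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        return dataclasses.asdict(record)
    if isinstance(record, Mapping):
        return dict(record)
    raise TypeError(f"cannot tabulate record of type {type(record).__name__}")


def write_table(
    records: Iterable[Any],
    path: str | Path,
    *,
    units: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Write records (dataclasses or mappings) sharing one schema to CSV.

    Lengths are micrometres and angles degrees throughout the package; a
    ``units`` mapping is written as ``#`` comment lines above the header so
    the file is self-describing.  An empty record list writes a header-only
    file.  Returns the DataFrame that was written.
    """
    records = list(records)
    if records:
        rows = [_record_to_dict(r) for r in records]
        schema = list(rows[0])
        for row in rows[1:]:
            if list(row) != schema:
                raise ValueError("records do not share one schema")
        frame = pd.DataFrame(rows, columns=schema)
    else:
        frame = pd.DataFrame()
    with open(path, "w") as fh:
        for col, unit in (units or {}).items():
            fh.write(f"# {col}: {unit}\n")
        frame.to_csv(fh, index=False)
    return frame


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping unit comments."""
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
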