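"""Calibrated image-stack I/O, ROI placement, and tabular export.

Coordinate convention used throughout the package: 0-based pixel indices,
``(x, y) = (column, row)`` with the origin at the top-left pixel centre.
Physical quantities are micrometres, seconds and kilopascals.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__

#: 6.5 um sensor pitch behind a 40x objective.
DEFAULT_PIXEL_SIZE_UM = 0.1625


@dataclass(frozen=True)
class ImageStack:
    """Time-ordered pixel frames with physical calibration.

    Parameters
    ----------
    frames
        Array of shape ``(t, rows, cols)``; intensities are arbitrary units
        and are never rescaled by the reader.
    pixel_size
        Micrometres per pixel (isotropic).
    frame_interval
        Seconds per frame.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a (time, rows, cols) array with >= 1 frame")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not (self.frame_interval > 0):
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def fps(self) -> float:
        return 1.0 / self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class TissueGeometry:
    """Rectangular bundle footprint: centre (um), long-axis angle, size."""

    center: tuple[float, float]
    long_axis_angle: float  # degrees, in (-90, 90]
    length: float  # um, long axis
    width: float  # um, short axis

    def __post_init__(self):
        if not (self.length > self.width > 0):
            raise ValueError("require length > width > 0")
        if not (-90 < self.long_axis_angle <= 90):
            raise ValueError("long_axis_angle must lie in (-90, 90]")

    @property
    def axis_unit(self) -> np.ndarray:
        """Unit vector along the long axis in (x, y)."""
        a = np.deg2rad(self.long_axis_angle)
        return np.array([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class RoiSpec:
    """A square/rectangular tracking template, in pixel coordinates."""

    center: tuple[float, float]  # (x, y) px
    half_size: tuple[int, int]  # (hx, hy) px
    label: str  # "proximal" | "distal"
    tissue_id: str = "tissue0"

    def __post_init__(self):
        hx, hy = self.half_size
        if hx < 4 or hy < 4:
            raise ValueError("ROI half_size must be >= 4 px in each dimension")

    def bounds(self) -> tuple[int, int, int, int]:
        """Integer crop bounds (row0, row1, col0, col1), half-open."""
        cx, cy = self.center
        hx, hy = self.half_size
        r, c = int(round(cy)), int(round(cx))
        return r - hy, r + hy + 1, c - hx, c + hx + 1


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float = 0.02,
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Intensities are returned exactly as stored.  If *pixel_size* is omitted
    the 40x-objective default (0.1625 um/px) is assumed and a warning is
    emitted — calibration should normally come from the acquisition.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image stack: {path}")
    if pixel_size is None:
        warnings.warn(
            "pixel_size not supplied; assuming 0.1625 um/px (40x default)",
            stacklevel=2,
        )
        pixel_size = DEFAULT_PIXEL_SIZE_UM
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) != 1:
            raise ValueError(f"TIFF pages differ in shape: {sorted(shapes)}")
        frames = tf.asarray()
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames, pixel_size=pixel_size, frame_interval=frame_interval)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write frames as a multi-page TIFF (lossless, bit-exact round trip)."""
    tifffile.imwrite(Path(path), stack.frames, photometric="minisblack")


def place_rois_inner50(
    geometry: TissueGeometry,
    pixel_size: float,
    roi_half_size: int | tuple[int, int] = 10,
    frame_shape: tuple[int, int] | None = None,
    tissue_id: str = "tissue0",
) -> tuple[RoiSpec, RoiSpec]:
    """Place the proximal/distal tracking ROI pair at the inner 50% length.

    The two ROIs sit on the long axis at ``+/- length/4`` from the tissue
    centre, so their separation spans the inner half of the bundle — the
    placement that is least sensitive to end effects.  Returns
    ``(proximal, distal)`` where proximal is on the negative-axis side.
    """
    if isinstance(roi_half_size, int):
        roi_half_size = (roi_half_size, roi_half_size)
    half_sep_um = geometry.length / 4.0
    if min(roi_half_size) * pixel_size >= half_sep_um:
        raise ValueError("roi_half_size must be smaller than half the ROI separation")
    axis = geometry.axis_unit
    center = np.asarray(geometry.center, dtype=float)
    rois = []
    for label, sign in (("proximal", -1.0), ("distal", +1.0)):
        c_um = center + sign * half_sep_um * axis
        c_px = tuple(c_um / pixel_size)
        roi = RoiSpec(center=c_px, half_size=roi_half_size, label=label, tissue_id=tissue_id)
        if frame_shape is not None:
            r0, r1, c0, c1 = roi.bounds()
            if r0 < 0 or c0 < 0 or r1 > frame_shape[0] or c1 > frame_shape[1]:
                raise ValueError(
                    f"{label} ROI at {c_px} (px) falls outside frame {frame_shape}"
                )
        rois.append(roi)
    return rois[0], rois[1]


# ---------------------------------------------------------------------------
# tabular export

def _summary_row(rec) -> dict:
    from .kinetics import KineticsSummary  # local import, avoids cycle

    if isinstance(rec, KineticsSummary):
        return rec.as_dict()
    return dict(rec)


def write_kinetics_table(
    records: Sequence,
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write one row per tissue of kinetic parameters (and per-beat SDs) as CSV.

    A JSON sidecar ``<path>.json`` records the configuration, seed and
    software version so the table is self-describing.
    """
    path = Path(path)
    rows = [_summary_row(r) for r in records]
    df = pd.DataFrame(rows)
    if df.empty:
        # header-only table with the canonical column set
        from .kinetics import KINETICS_COLUMNS

        df = pd.DataFrame(columns=KINETICS_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = {
        "software": "mbkit",
        "version": __version__,
        "seed": seed,
        "config": config or {},
        "n_records": len(rows),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return df


def read_kinetics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def geometry_to_dict(g: TissueGeometry) -> dict:
    return dataclasses.asdict(g)


def geometry_from_dict(d: dict) -> TissueGeometry:
    return TissueGeometry(
        center=tuple(d["center"]),
        long_axis_angle=float(d["long_axis_angle"]),
        length=float(d["length"]),
        width=float(d["width"]),
    )
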