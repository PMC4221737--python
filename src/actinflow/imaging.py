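"""Image-stack, mask and vector-table I/O.

Coordinate convention (global, enforced everywhere in this package):
``x`` is the column index, ``y`` is the row index, the origin is the
*center* of the top-left pixel, and ``y`` increases downward.  Pixel
indexing is 0-based.  Velocities are stored in px/frame and converted to
µm/min only at reporting time (``px_per_frame_to_um_per_min``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("actinflow.imaging")

__all__ = [
    "ConfigurationError",
    "FormatError",
    "UnitsError",
    "ImageSequence",
    "CellMask",
    "NucleusSpec",
    "VelocityField",
    "read_sequence",
    "write_sequence",
    "mask_from_polygon",
    "mask_from_array",
    "write_vector_table",
    "read_vector_table",
    "px_per_frame_to_um_per_min",
]


class ConfigurationError(ValueError):
    """Missing or inconsistent user-supplied configuration."""


class FormatError(ValueError):
    """A file on disk does not have the expected layout."""


class UnitsError(ValueError):
    """Units recorded in a file disagree with the expected units."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class ImageSequence:
    """T ordered grayscale frames plus spatial/temporal calibration.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of nonnegative intensities, ``T >= 2``.
    pixel_size_um
        Physical pixel size in µm/px (> 0).
    frame_interval_s
        Time between consecutive frames in seconds (> 0).
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be a (T, H, W) stack, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise FormatError("at least two frames required")
        if not np.all(np.isfinite(self.frames)):
            raise FormatError("frame intensities must be finite")
        if not self.pixel_size_um > 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if not self.frame_interval_s > 0:
            raise ConfigurationError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:]


@dataclass
class CellMask:
    """Boolean raster marking the cell interior (the PIV region of interest)."""

    raster: np.ndarray
    source: str = "file"  # polygon | threshold | file

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.ndim != 2:
            raise ConfigurationError("mask raster must be 2-D")
        if not self.raster.any():
            raise ConfigurationError("mask contains no true pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape


@dataclass
class NucleusSpec:
    """Nuclear center plus the box used for the around-the-nucleus analysis.

    ``center`` is ``(x, y)`` in pixels; ``box`` is ``(x0, y0, x1, y1)`` with
    inclusive bounds in pixel coordinates.  The box must lie inside the image
    and overlap the cell mask.
    """

    center: tuple[float, float]
    box: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ConfigurationError("nucleus box must have positive extent")
        cx, cy = self.center
        if not (x0 <= cx <= x1 and y0 <= cy <= y1):
            raise ConfigurationError("nucleus center must lie inside its box")

    @classmethod
    def square(cls, center: tuple[float, float], side: float) -> "NucleusSpec":
        """Axis-aligned square box of a given side, centered on the nucleus."""
        cx, cy = center
        h = side / 2.0
        return cls(center=(cx, cy), box=(cx - h, cy - h, cx + h, cy + h))

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x0, y0, x1, y1 = self.box
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)

    def validate_against(self, mask: CellMask) -> None:
        cx, cy = self.center
        H, W = mask.shape
        ix, iy = int(round(cx)), int(round(cy))
        if not (0 <= ix < W and 0 <= iy < H):
            raise ConfigurationError("nucleus center outside image bounds")
        if not mask.raster[iy, ix]:
            raise ConfigurationError("nucleus center must lie inside the cell mask")


@dataclass
class VelocityField:
    """Per frame-pair grid of displacement vectors.

    ``x`` (nx,) and ``y`` (ny,) are window-center coordinates; ``u``, ``v``
    are ``(ny, nx)`` displacements in px/frame; ``valid`` flags usable
    vectors and ``interpolated`` flags vectors that were replaced by a
    neighbourhood median during validation.  Invalid, non-replaced vectors
    are NaN.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    frame_pair: tuple[int, int] = (0, 1)
    units: str = "px/frame"
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]
    window_size: int | None = None
    unreliable: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        shape = (self.y.size, self.x.size)
        for arr, nm in ((self.u, "u"), (self.v, "v"), (self.valid, "valid")):
            if arr.shape != shape:
                raise ConfigurationError(f"{nm} shape {arr.shape} != grid {shape}")
        if self.interpolated is None:
            self.interpolated = np.zeros(shape, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)

    @property
    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of node coordinates, each (ny, nx)."""
        return np.meshgrid(self.x, self.y)

    def speeds(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


def px_per_frame_to_um_per_min(
    value: float | np.ndarray, pixel_size_um: float, frame_interval_s: float
) -> float | np.ndarray:
    """Convert px/frame to µm/min using the acquisition calibration."""
    return value * pixel_size_um * (60.0 / frame_interval_s)


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def read_sequence(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_s: float,
    name: str | None = None,
) -> ImageSequence:
    """Read a multi-page grayscale TIFF stack.

    Calibration is taken from the arguments, never from embedded tags; if an
    embedded resolution tag is present and disagrees, a warning is logged and
    the argument wins.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        if xres is not None:
            num, den = xres.value
            if num:
                tag_um_per_px = den / num  # assumes tag resolution in px per unit
                if not np.isclose(tag_um_per_px, pixel_size_um, rtol=0.01):
                    logger.warning(
                        "embedded resolution tag (%g per px) conflicts with "
                        "configured pixel size %g um/px; using the configured value",
                        tag_um_per_px,
                        pixel_size_um,
                    )
    data = np.asarray(data)
    if data.ndim == 2:
        raise FormatError("at least two frames required (single-page TIFF)")
    if data.ndim != 3:
        raise FormatError(f"expected a grayscale (T, H, W) stack, got shape {data.shape}")
    if data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:-1]):
        raise FormatError("RGB(A) input not supported; provide a grayscale stack")
    return ImageSequence(
        frames=data.astype(np.float64),
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        name=name if name is not None else path.stem,
    )


def write_sequence(seq: ImageSequence, path: str | Path) -> None:
    """Write a sequence as a float32 multi-page TIFF (lossless round trip)."""
    tifffile.imwrite(
        Path(path), seq.frames.astype(np.float32), photometric="minisblack"
    )


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def mask_from_polygon(
    vertices: Sequence[tuple[float, float]], shape: tuple[int, int]
) -> CellMask:
    """Rasterize a polygon with the even-odd rule on pixel centers.

    A pixel is inside when its center lies inside the polygon.  Centers
    exactly on an edge are resolved by a deterministic top-left fill rule
    (the test point is nudged by +1e-9 in x and y), so the left/top edges of
    an axis-aligned box are inclusive and the right/bottom exclusive.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ConfigurationError("polygon needs at least three (x, y) vertices")
    x, y = verts[:, 0], verts[:, 1]
    # shoelace area; zero means degenerate
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area == 0:
        raise ConfigurationError("degenerate (zero-area) polygon")

    H, W = shape
    eps = 1e-9
    X, Y = np.meshgrid(np.arange(W, dtype=float) + eps, np.arange(H, dtype=float) + eps)
    inside = np.zeros((H, W), dtype=bool)
    n = verts.shape[0]
    for i in range(n):  # even-odd ray casting, one edge at a time
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if y1 == y2:
            continue
        crosses = (y1 > Y) != (y2 > Y)
        x_int = x1 + (Y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (X < x_int)
    if not inside.any():
        raise ConfigurationError("polygon covers no pixel centers")
    return CellMask(raster=inside, source="polygon")


def mask_from_array(raster: np.ndarray) -> CellMask:
    return CellMask(raster=raster, source="file")


# ---------------------------------------------------------------------------
# vector tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["frame_pair", "x_px", "y_px", "u", "v", "valid", "interpolated", "units"]


def vector_table(fields: Sequence[VelocityField]) -> pd.DataFrame:
    """Flatten velocity fields into one long-format table."""
    rows = []
    for f in fields:
        X, Y = f.grid
        rows.append(
            pd.DataFrame(
                {
                    "frame_pair": f.frame_pair[0],
                    "x_px": X.ravel(),
                    "y_px": Y.ravel(),
                    "u": f.u.ravel(),
                    "v": f.v.ravel(),
                    "valid": f.valid.ravel(),
                    "interpolated": f.interpolated.ravel(),
                    "units": f.units,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_vector_table(
    field_or_fields: VelocityField | Sequence[VelocityField], path: str | Path
) -> None:
    fields = (
        [field_or_fields]
        if isinstance(field_or_fields, VelocityField)
        else list(field_or_fields)
    )
    vector_table(fields).to_csv(Path(path), index=False, float_format="%.17g")


def read_vector_table(
    path: str | Path, expected_units: str | None = None
) -> list[VelocityField]:
    """Read a vector-table CSV back into one VelocityField per frame pair."""
    df = pd.read_csv(Path(path))
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"vector table missing columns: {missing}")
    units = df["units"].unique()
    if len(units) != 1:
        raise FormatError("vector table mixes units")
    units = str(units[0])
    if expected_units is not None and units != expected_units:
        raise UnitsError(
            f"vector table units {units!r} != expected {expected_units!r}; "
            "convert explicitly with px_per_frame_to_um_per_min"
        )
    out: list[VelocityField] = []
    for fp, grp in df.groupby("frame_pair", sort=True):
        xs = np.unique(grp["x_px"].to_numpy())
        ys = np.unique(grp["y_px"].to_numpy())
        shape = (ys.size, xs.size)
        ix = np.searchsorted(xs, grp["x_px"].to_numpy())
        iy = np.searchsorted(ys, grp["y_px"].to_numpy())
        u = np.full(shape, np.nan)
        v = np.full(shape, np.nan)
        valid = np.zeros(shape, dtype=bool)
        interp = np.zeros(shape, dtype=bool)
        u[iy, ix] = grp["u"].to_numpy()
        v[iy, ix] = grp["v"].to_numpy()
        valid[iy, ix] = grp["valid"].to_numpy().astype(bool)
        interp[iy, ix] = grp["interpolated"].to_numpy().astype(bool)
        out.append(
            VelocityField(
                x=xs, y=ys, u=u, v=v, valid=valid,
                interpolated=interp, frame_pair=(int(fp), int(fp) + 1), units=units,
            )
        )
    return out
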