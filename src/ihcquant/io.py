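"""Raster and tabular data model shared by every pipeline stage.

Images are 8-bit RGB rasters (TIFF or PNG); masks are single-channel 0/255
TIFF; regions of interest are either polygon vertex lists (JSON) or binary
masks; tables are CSV with a header row.  All pixel coordinates are 0-based,
row-major ``(row, col)``; boxes are half-open.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from PIL import Image
from shapely.geometry import Polygon

__all__ = [
    "RgbImage",
    "IntensityImage",
    "BinaryMask",
    "RoiSpec",
    "LabelTable",
    "FormatError",
    "UnsupportedImageError",
    "SchemaError",
    "read_image",
    "rasterize_roi",
    "read_mask",
    "write_mask",
    "read_table",
    "write_table",
]

#: scan resolution of a 20x objective, in micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 0.5


class FormatError(ValueError):
    """File could not be parsed in the declared format."""


class UnsupportedImageError(ValueError):
    """Image exists but is not 8-bit RGB."""


class SchemaError(ValueError):
    """Table columns do not match the declared schema."""


@dataclass
class RgbImage:
    """8-bit RGB raster with physical pixel size.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
    pixel_size_um : float
        Edge length of one pixel in micrometres (default 0.5, a 20x scan).
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise UnsupportedImageError(
                f"expected H x W x 3 array, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise UnsupportedImageError("channel values outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise UnsupportedImageError("empty image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class IntensityImage:
    """Real-valued single-channel image on a nominal [0, 255] scale."""

    values: np.ndarray
    range_hint: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("intensity image must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BinaryMask:
    """Boolean raster tagged with its role in the pipeline.

    ``role`` is one of ``{"roi", "stain", "epithelium"}``.
    """

    values: np.ndarray
    role: str = "roi"

    _ROLES = ("roi", "stain", "epithelium")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.role not in self._ROLES:
            raise ValueError(f"unknown mask role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def area_fraction(self) -> float:
        return float(self.values.mean())


@dataclass
class RoiSpec:
    """Region of interest: polygon vertex lists and/or a binary mask.

    Polygons use 0-based pixel units, vertices as ``(row, col)`` pairs.
    """

    polygons: list[np.ndarray] = field(default_factory=list)
    mask: BinaryMask | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSpec":
        with open(path) as fh:
            payload = json.load(fh)
        polys = [np.asarray(p, dtype=float) for p in payload["polygons"]]
        return cls(polygons=polys)

    def to_json(self, path: str | Path) -> None:
        payload = {"polygons": [np.asarray(p).tolist() for p in self.polygons]}
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class LabelTable:
    """Tabular fixture keyed by case identifier and marker name."""

    df: pd.DataFrame
    key_cols: tuple[str, ...] = ("marker", "case")

    def __post_init__(self) -> None:
        missing = [c for c in self.key_cols if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing key columns: {missing}")
        if self.df.duplicated(subset=list(self.key_cols)).any():
            raise SchemaError("duplicate (marker, case) keys")

    def __len__(self) -> int:
        return len(self.df)

    def lookup(self, marker: str, case: str) -> pd.Series:
        sel = self.df
        for col, val in zip(self.key_cols, (marker, case)):
            sel = sel[sel[col] == val]
        if len(sel) != 1:
            raise KeyError(f"({marker}, {case}) not found")
        return sel.iloc[0]


def read_image(path: str | Path) -> RgbImage:
    """Read an 8-bit RGB TIFF or PNG.

    For pyramidal TIFF only the first (highest-resolution) level is used.
    Pixel size is taken from TIFF resolution metadata when present,
    otherwise the 0.5 um default is recorded.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    pixel_size = DEFAULT_PIXEL_SIZE_UM
    if suffix in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tf:
                page = tf.pages[0]
                arr = page.asarray()
                res = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if res is not None and unit is not None:
                    num, den = res.value
                    if num > 0 and den > 0:
                        per_unit = num / den
                        unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit.value))
                        if unit_um:
                            pixel_size = unit_um / per_unit
        except (tifffile.TiffFileError, OSError) as exc:
            raise FormatError(f"unreadable TIFF {path}: {exc}") from exc
    elif suffix == ".png":
        try:
            arr = np.asarray(Image.open(path))
        except OSError as exc:
            raise FormatError(f"unreadable PNG {path}: {exc}") from exc
    else:
        raise FormatError(f"unsupported extension {suffix!r}")
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha if fully opaque
        if np.all(arr[:, :, 3] == 255):
            arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise UnsupportedImageError(
            f"{path}: expected 8-bit RGB, got dtype {arr.dtype}, shape {arr.shape}"
        )
    return RgbImage(pixels=arr, pixel_size_um=pixel_size)


def rasterize_roi(roi: RoiSpec, shape: tuple[int, int]) -> BinaryMask:
    """Rasterize an ROI to a boolean mask.

    A pixel belongs to the ROI iff its *center* lies within (or exactly on
    the boundary of) one of the polygons.  If the spec carries a mask it is
    returned as-is after a shape check.
    """
    h, w = shape
    if roi.mask is not None:
        if roi.mask.shape != (h, w):
            raise ValueError("ROI mask shape mismatch")
        return BinaryMask(roi.mask.values, role="roi")
    if not roi.polygons:
        warnings.warn("empty polygon list: ROI mask is empty", stacklevel=2)
        return BinaryMask(np.zeros(shape, dtype=bool), role="roi")
    out = np.zeros(shape, dtype=bool)
    rows, cols = np.mgrid[0:h, 0:w]
    points = shapely.points(cols.ravel() + 0.0, rows.ravel() + 0.0)
    for verts in roi.polygons:
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
            raise ValueError("polygon needs at least 3 (row, col) vertices")
        poly = Polygon([(c, r) for r, c in verts])  # shapely uses (x, y)
        if not poly.is_valid:
            raise ValueError("polygon is not simple (self-intersecting)")
        inside = shapely.covers(poly, points)  # covers: boundary counts in
        out |= inside.reshape(h, w)
    return BinaryMask(out, role="roi")


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as single-channel 8-bit TIFF with values 0/255."""
    tifffile.imwrite(Path(path), (mask.values.astype(np.uint8) * 255))


def read_mask(path: str | Path, role: str = "roi") -> BinaryMask:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise UnsupportedImageError("mask file must be single-channel")
    return BinaryMask(arr > 0, role=role)


def write_table(table: LabelTable, path: str | Path) -> None:
    table.df.to_csv(Path(path), index=False)


def read_table(
    path: str | Path,
    schema: list[str] | None = None,
    key_cols: tuple[str, ...] = ("marker", "case"),
) -> LabelTable:
    """Read a CSV table, optionally checking its column schema."""
    df = pd.read_csv(Path(path))
    if schema is not None and list(df.columns) != list(schema):
        raise SchemaError(f"expected columns {schema}, found {list(df.columns)}")
    return LabelTable(df=df, key_cols=key_cols)
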