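"""Hexagonal tiling and per-hexagon staining transmittance.

The ROI is partitioned by a pointy-top hexagonal lattice (pixel assigned to
the nearest hexagon center via cube-coordinate rounding, which is exact for
a hexagonal Voronoi partition).  Within each hexagon the transmittance

    T = sum over epithelium pixels of (255 - brown) / (N_epi * 255)

lies in [0, 1]: unstained pixels carry brown = 255 and contribute zero, a
fully stained black hexagon gives 1.  Hexagons with too few epithelium
pixels are flagged undefined and excluded from pooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BinaryMask, IntensityImage

__all__ = [
    "HexTiling",
    "HexRecord",
    "HexTransmittanceTable",
    "tile_hexagons",
    "transmittance",
    "hex_table",
    "pool_values",
    "DEFAULT_CIRCUMRADIUS",
    "DEFAULT_MIN_EPI_PIXELS",
]

#: ~50 um at the 0.5 um/px scan scale
DEFAULT_CIRCUMRADIUS = 100.0
DEFAULT_MIN_EPI_PIXELS = 50


@dataclass
class HexTiling:
    """Pixel-to-hexagon assignment over an ROI (pointy-top lattice)."""

    circumradius: float
    assignment: np.ndarray  # H x W int array, -1 outside the ROI
    centers: np.ndarray  # n_hex x 2 array of (row, col) centers

    @property
    def n_hexagons(self) -> int:
        return len(self.centers)


@dataclass
class HexRecord:
    hex_index: int
    epithelium_pixels: int
    transmittance: float | None  # None when too few epithelium pixels


@dataclass
class HexTransmittanceTable:
    case: str
    marker: str
    records: list[HexRecord]

    def defined_values(self) -> np.ndarray:
        return np.array(
            [r.transmittance for r in self.records if r.transmittance is not None]
        )

    def to_frame(self, tiling: HexTiling | None = None) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "case": self.case,
                "marker": self.marker,
                "hex_index": r.hex_index,
                "n_epi": r.epithelium_pixels,
                "transmittance": r.transmittance,
            }
            if tiling is not None:
                row["center_row"] = tiling.centers[r.hex_index][0]
                row["center_col"] = tiling.centers[r.hex_index][1]
            rows.append(row)
        return pd.DataFrame(rows)


def _cube_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Round fractional axial coordinates to the nearest hexagon (vectorized)."""
    sf = -qf - rf
    # floor(x + 1/2) rounding: unlike round-half-even it commutes with
    # integer lattice translations, so boundary tie-breaks are consistent
    rq = np.floor(qf + 0.5)
    rr = np.floor(rf + 0.5)
    rs = np.floor(sf + 0.5)
    dq = np.abs(rq - qf)
    dr = np.abs(rr - rf)
    ds = np.abs(rs - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    rq = np.where(fix_q, -rr - rs, rq)
    rr = np.where(fix_r, -rq - rs, rr)
    return rq.astype(np.int64), rr.astype(np.int64)


def tile_hexagons(roi: BinaryMask, circumradius: float = DEFAULT_CIRCUMRADIUS) -> HexTiling:
    """Assign every ROI pixel to exactly one hexagon of the lattice.

    Hexagon indices are ordered by (axial r, axial q), i.e. top-to-bottom,
    left-to-right; the cube-rounding rule is the deterministic tie-break on
    boundary pixels.
    """
    if circumradius < 2:
        raise ValueError("circumradius must be at least 2")
    h, w = roi.shape
    if circumradius > max(h, w):
        warnings.warn(
            "circumradius exceeds ROI extent; tiling collapses to ~1 hexagon",
            stacklevel=2,
        )
    rows, cols = np.nonzero(roi.values)
    assignment = np.full((h, w), -1, dtype=np.int64)
    if rows.size == 0:
        return HexTiling(
            circumradius=circumradius,
            assignment=assignment,
            centers=np.empty((0, 2)),
        )
    x = cols.astype(float)
    y = rows.astype(float)
    qf = (np.sqrt(3.0) / 3.0 * x - y / 3.0) / circumradius
    rf = (2.0 / 3.0 * y) / circumradius
    q, r = _cube_round(qf, rf)
    cells, inverse = np.unique(np.stack([r, q], axis=1), axis=0, return_inverse=True)
    assignment[rows, cols] = inverse
    cr = cells[:, 0].astype(float)
    cq = cells[:, 1].astype(float)
    centers = np.stack(
        [1.5 * circumradius * cr, np.sqrt(3.0) * circumradius * (cq + cr / 2.0)],
        axis=1,
    )
    return HexTiling(circumradius=circumradius, assignment=assignment, centers=centers)


def transmittance(
    hex_pixels: tuple[np.ndarray, np.ndarray],
    brown: IntensityImage,
    epithelium: BinaryMask,
    min_epi_pixels: int = DEFAULT_MIN_EPI_PIXELS,
) -> float | None:
    """Transmittance of one hexagon, or None when epithelium is too sparse."""
    if brown.shape != epithelium.shape:
        raise ValueError("shape mismatch between brown image and epithelium mask")
    rr, cc = hex_pixels
    epi = epithelium.values[rr, cc]
    n_epi = int(epi.sum())
    if n_epi < min_epi_pixels:
        return None
    vals = brown.values[rr, cc][epi]
    return float((255.0 - vals).sum() / (n_epi * 255.0))


def hex_table(
    case: str,
    marker: str,
    tiling: HexTiling,
    brown: IntensityImage,
    epithelium: BinaryMask,
    min_epi_pixels: int = DEFAULT_MIN_EPI_PIXELS,
) -> HexTransmittanceTable:
    """Per-hexagon transmittance for one case (vectorized over the tiling)."""
    if brown.shape != epithelium.shape or tiling.assignment.shape != brown.shape:
        raise ValueError("shape mismatch")
    n_hex = tiling.n_hexagons
    inside = tiling.assignment >= 0
    idx = tiling.assignment[inside]
    epi = epithelium.values[inside]
    absorb = (255.0 - brown.values[inside]) * epi
    n_epi = np.bincount(idx, weights=epi.astype(float), minlength=n_hex)
    total = np.bincount(idx, weights=absorb, minlength=n_hex)
    records = []
    for k in range(n_hex):
        nk = int(n_epi[k])
        t = total[k] / (nk * 255.0) if nk >= min_epi_pixels else None
        records.append(
            HexRecord(hex_index=k, epithelium_pixels=nk, transmittance=t)
        )
    return HexTransmittanceTable(case=case, marker=marker, records=records)


def pool_values(tables: list[HexTransmittanceTable]) -> np.ndarray:
    """Concatenate defined transmittances across cases for marker-level fitting."""
    vals = [t.defined_values() for t in tables]
    pooled = np.concatenate([v for v in vals if v.size]) if vals else np.array([])
    if pooled.size == 0:
        raise ValueError("no defined hexagon transmittances to pool")
    return pooled
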