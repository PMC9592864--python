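"""Epithelium segmentation by windowed-Fourier low-pass filtering.

Epithelium in hematoxylin-counterstained sections is nuclei-dense and
therefore darker, at a coarse spatial scale, than the surrounding stroma.
The segmenter low-pass filters the intensity image with a Gabor-style
sliding-window Fourier analysis (Gaussian apodization, raised-cosine
spectral rolloff, overlap-add recombination), binarizes the smoothed image
with Tsai's moment-preserving threshold, keeps the darker side, and removes
small residue with a morphological opening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import disk, opening

from .io import BinaryMask, IntensityImage, RgbImage
from .stain import ohta_transform

__all__ = [
    "GaborParams",
    "DegenerateHistogramError",
    "gabor_lowpass",
    "moment_threshold",
    "segment_epithelium",
]


class DegenerateHistogramError(ValueError):
    """Image histogram cannot support a bilevel threshold."""


@dataclass
class GaborParams:
    """Parameters of the low-pass segmentation pipeline.

    window_sigma : Gaussian apodization width in pixels.
    tile : analysis window edge in pixels (power of two); must be at least
        4 * window_sigma so the window decays inside the tile.
    cutoff : raised-cosine low-pass corner in cycles per window; response is
        1 below cutoff/2 and rolls off to 0 at cutoff.
    opening_radius : disk radius of the morphological opening, in pixels
        (10 px is ~5 um at the 0.5 um/px scan scale).
    """

    window_sigma: float = 64.0
    tile: int = 256
    cutoff: float = 16.0
    opening_radius: int = 10

    def __post_init__(self) -> None:
        if self.tile < 4 * self.window_sigma:
            raise ValueError("tile must be at least 4 * window_sigma")
        if not 0 < self.cutoff <= self.tile / 2:
            raise ValueError("cutoff must lie in (0, tile/2]")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be non-negative")


def _lowpass_response(tile: int, cutoff: float) -> np.ndarray:
    """Radial raised-cosine response on the FFT frequency grid (cycles/window)."""
    f = np.fft.fftfreq(tile) * tile
    rho = np.hypot(f[:, None], f[None, :])
    h = np.zeros_like(rho)
    inner = cutoff / 2.0
    h[rho < inner] = 1.0
    band = (rho >= inner) & (rho < cutoff)
    h[band] = 0.5 * (1.0 + np.cos(np.pi * (rho[band] - inner) / inner))
    return h


def gabor_lowpass(intensity: IntensityImage, params: GaborParams) -> IntensityImage:
    """Sliding-window Fourier low-pass with overlap-add recombination.

    Each tile is multiplied by a Gaussian window, transformed, multiplied by
    the radial raised-cosine response, inverse transformed, and re-weighted
    by the same window; tiles advance by half a tile and the accumulated
    output is normalized by the window times the filtered window
    (normalized convolution), which preserves constants exactly.
    """
    x = intensity.values
    h, w = x.shape
    t = params.tile
    if t > h or t > w:
        raise ValueError("tile larger than image")
    stride = t // 2

    ax = np.arange(t) - (t - 1) / 2.0
    win1d = np.exp(-0.5 * (ax / params.window_sigma) ** 2)
    win = win1d[:, None] * win1d[None, :]
    resp = _lowpass_response(t, params.cutoff)
    # normalized convolution: weight the output by the *filtered* window, so
    # a constant input reproduces exactly despite window truncation leakage
    filt_win = np.fft.ifft2(resp * np.fft.fft2(win)).real

    # reflect-pad so every output pixel gets full window coverage
    pad = t
    xp = np.pad(x, pad, mode="reflect")
    hp, wp = xp.shape
    acc = np.zeros_like(xp)
    wsum = np.zeros_like(xp)
    rows = list(range(0, hp - t + 1, stride))
    cols = list(range(0, wp - t + 1, stride))
    if rows[-1] != hp - t:
        rows.append(hp - t)
    if cols[-1] != wp - t:
        cols.append(wp - t)
    for r0 in rows:
        for c0 in cols:
            tilepx = xp[r0 : r0 + t, c0 : c0 + t]
            filt = np.fft.ifft2(resp * np.fft.fft2(win * tilepx)).real
            acc[r0 : r0 + t, c0 : c0 + t] += win * filt
            wsum[r0 : r0 + t, c0 : c0 + t] += win * filt_win
    out = acc / wsum
    return IntensityImage(values=out[pad : pad + h, pad : pad + w])


def moment_threshold(image: IntensityImage | np.ndarray) -> float:
    """Tsai's moment-preserving bilevel threshold.

    Chooses the cut so that a two-level image with levels z0 < z1 and dark
    fraction p0 preserves the first three sample moments of the input;
    returns the cut value (midway between the straddling order statistics,
    so for an exact two-level input the cut falls strictly between levels).
    """
    x = np.asarray(
        image.values if isinstance(image, IntensityImage) else image, dtype=float
    ).ravel()
    if x.size == 0 or np.unique(x).size < 2:
        raise DegenerateHistogramError("need at least two distinct values")
    m1 = x.mean()
    m2 = (x**2).mean()
    m3 = (x**3).mean()
    cd = m2 - m1 * m1
    if cd <= 0:
        raise DegenerateHistogramError("zero variance")
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise DegenerateHistogramError("moment system has no real levels")
    sq = np.sqrt(disc)
    z0 = (-c1 - sq) / 2.0
    z1 = (-c1 + sq) / 2.0
    p0 = (z1 - m1) / (z1 - z0)
    p0 = float(np.clip(p0, 0.0, 1.0))
    xs = np.sort(x)
    k = int(round(p0 * x.size))
    k = min(max(k, 1), x.size - 1)
    return float(0.5 * (xs[k - 1] + xs[k]))


def segment_epithelium(
    rgb: RgbImage,
    roi: BinaryMask,
    params: GaborParams | None = None,
    darker_is_foreground: bool = True,
) -> BinaryMask:
    """Segment epithelial territories inside the ROI.

    Pipeline: Ohta I1 intensity -> windowed-Fourier low-pass -> moment
    threshold over ROI pixels -> keep the darker (nuclei-dense) side ->
    binary opening with a disk -> intersect with the ROI.  A flat ROI
    (constant intensity) yields an empty mask.
    """
    params = params or GaborParams()
    if rgb.shape != roi.shape:
        raise ValueError("shape mismatch between image and ROI")
    intensity = IntensityImage(values=ohta_transform(rgb).I1)
    smooth = gabor_lowpass(intensity, params)
    vals = smooth.values[roi.values]
    if vals.size == 0:
        return BinaryMask(np.zeros(roi.shape, dtype=bool), role="epithelium")
    try:
        thr = moment_threshold(vals)
    except DegenerateHistogramError:
        return BinaryMask(np.zeros(roi.shape, dtype=bool), role="epithelium")
    if darker_is_foreground:
        fg = smooth.values <= thr
    else:
        fg = smooth.values > thr
    fg &= roi.values
    if params.opening_radius > 0:
        fg = opening(fg, disk(params.opening_radius))
    return BinaryMask(fg & roi.values, role="epithelium")
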