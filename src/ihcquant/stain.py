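"""DAB stain detection in the Ohta color space.

The Ohta features are a fixed linear transform of RGB; the second feature
I2 = (R - B) / 2 separates the brown DAB chromogen (red-dominant) from the
blue hematoxylin counterstain, so a one-dimensional two-component Gaussian
mixture on I2 within the region of interest yields a stained / unstained
pixel classification.  A scalar calibration shift on the decision threshold
is the hook tuned by the stereology quality-control loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import BinaryMask, IntensityImage, RgbImage
from .mixtures import DegenerateFitError, Gmm1D, _pair_intersection, fit_gmm_em

__all__ = [
    "OhtaImage",
    "StainModel",
    "ohta_transform",
    "fit_stain_model",
    "classify_stain",
    "brown_intensity",
]

DEFAULT_SUBSAMPLE_CAP = 200_000


@dataclass
class OhtaImage:
    """Ohta features I1 = (R+G+B)/3, I2 = (R-B)/2, I3 = (2G-R-B)/4."""

    I1: np.ndarray
    I2: np.ndarray
    I3: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.I1.shape


@dataclass
class StainModel:
    """Two-component I2 mixture and its decision threshold.

    The higher-mean component is the DAB class; ``decision_threshold`` is
    the crossing of the two component curves, and the effective threshold
    adds a scalar ``calibration_shift`` (default 0).
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    decision_threshold: float
    calibration_shift: float = 0.0

    @property
    def effective_threshold(self) -> float:
        return self.decision_threshold + self.calibration_shift

    def with_shift(self, shift: float) -> "StainModel":
        return StainModel(
            weights=self.weights,
            means=self.means,
            sds=self.sds,
            decision_threshold=self.decision_threshold,
            calibration_shift=shift,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": np.asarray(self.weights).tolist(),
            "means": np.asarray(self.means).tolist(),
            "sds": np.asarray(self.sds).tolist(),
            "decision_threshold": self.decision_threshold,
            "calibration_shift": self.calibration_shift,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "StainModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            weights=np.asarray(d["weights"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            decision_threshold=d["decision_threshold"],
            calibration_shift=d["calibration_shift"],
        )


def ohta_transform(rgb: RgbImage) -> OhtaImage:
    """Apply the Ohta color transform in real arithmetic."""
    px = rgb.pixels.astype(float)
    r, g, b = px[:, :, 0], px[:, :, 1], px[:, :, 2]
    return OhtaImage(
        I1=(r + g + b) / 3.0,
        I2=(r - b) / 2.0,
        I3=(2.0 * g - r - b) / 4.0,
    )


def fit_stain_model(
    i2_values: np.ndarray,
    subsample_cap: int = DEFAULT_SUBSAMPLE_CAP,
    seed: int = 0,
    K: int = 2,
) -> StainModel:
    """Fit the stained / unstained mixture on I2 values inside the ROI.

    Values beyond ``subsample_cap`` are subsampled without replacement with
    a seeded generator for EM tractability on large ROIs.  The decision
    threshold is the crossing of the two fitted component curves between
    their means.
    """
    x = np.asarray(i2_values, dtype=float).ravel()
    if x.size > subsample_cap:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=subsample_cap, replace=False)
    if x.size < 100:
        raise DegenerateFitError(f"need at least 100 I2 values, got {x.size}")
    model: Gmm1D = fit_gmm_em(x, K=K)
    w, m, s = model.weights, model.means, model.sds
    thr = _pair_intersection(w[-2], m[-2], s[-2], w[-1], m[-1], s[-1])
    return StainModel(
        weights=w, means=m, sds=s, decision_threshold=float(thr)
    )


def classify_stain(
    ohta: OhtaImage, model: StainModel, roi: BinaryMask
) -> BinaryMask:
    """Stained pixels: inside the ROI with I2 at or above the threshold."""
    if ohta.shape != roi.shape:
        raise ValueError("shape mismatch between image and ROI")
    stained = roi.values & (ohta.I2 >= model.effective_threshold)
    return BinaryMask(stained, role="stain")


def brown_intensity(rgb: RgbImage, stain: BinaryMask) -> IntensityImage:
    """Brown-intensity image: I1 at stained pixels, 255 elsewhere.

    Unstained pixels are treated as fully transmitting, so they contribute
    zero staining downstream.
    """
    if rgb.shape != stain.shape:
        raise ValueError("shape mismatch between image and stain mask")
    i1 = ohta_transform(rgb).I1
    out = np.full(rgb.shape, 255.0)
    out[stain.values] = i1[stain.values]
    return IntensityImage(values=out)
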