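"""Slide phantoms with known ground truth, and packaged fixture tables.

The phantom emulates a DAB-stained section: epithelium drawn as smoothed
random blobs on a near-white stromal background, a fine nuclei texture
darkening the epithelium, and DAB staining rendered by mixing epithelial
pixels toward a brown vector whose red-blue separation grows monotonically
with stain amount (so Ohta-I2 detection is well-posed).  Stain level
(low / medium / high) is assigned per hexagon of a lattice at the analysis
scale, giving exact per-hexagon class ground truth.

The fixture loader ships the printed study tables (hexagon class counts and
expert labels, per-case moments and composite scores, reader quality
factors) as package data for desk-scale reproduction tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .hexgrid import HexTiling, tile_hexagons
from .io import BinaryMask, LabelTable, RgbImage
from .stereology import LABELED, UNLABELED, CrossGrid, MarkSet

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "simulate_expert_marks",
    "load_study_fixture",
    "FIXTURE_NAMES",
]

# rendering palette: stroma is near-white, epithelium carries a bluish
# hematoxylin tint (R < B so I2 < 0), and the full-stain brown endpoint has
# strongly positive I2; mixing is linear so I2 is monotone in stain amount
STROMA_RGB = np.array([240.0, 235.0, 242.0])
EPITHELIUM_RGB = np.array([170.0, 162.0, 188.0])
STAIN_RGB = np.array([140.0, 60.0, 0.0])
CHANNEL_NOISE_SD = 3.0
#: minimum stain amount (on the 0-1 mixing scale) counted as truly stained
STAIN_MIN_AMOUNT = 0.1


@dataclass
class PhantomSpec:
    """Generation parameters of one slide phantom.

    stain_intensity_means are target brown intensities (darkness on the
    0-255 scale) of the three stain levels, strictly decreasing from low to
    high staining; a mean near 255 renders an effectively unstained level.
    """

    seed: int = 0
    height: int = 512
    width: int = 512
    epithelium_fraction_target: float = 0.4
    blob_scale: float = 32.0
    nuclei_texture_amplitude: float = 30.0
    stain_level_props: tuple[float, float, float] = (0.2, 0.5, 0.3)
    stain_intensity_means: tuple[float, float, float] = (200.0, 130.0, 55.0)
    stain_noise_sd: float = 8.0
    mark_error_rate: float = 0.0
    hex_circumradius: float = 48.0

    def __post_init__(self) -> None:
        if abs(sum(self.stain_level_props) - 1.0) > 1e-9:
            raise ValueError("stain_level_props must sum to 1")
        m = self.stain_intensity_means
        if not (m[0] > m[1] > m[2]):
            raise ValueError("stain_intensity_means must strictly decrease")
        if not 0.0 < self.epithelium_fraction_target < 1.0:
            raise ValueError("epithelium_fraction_target must lie in (0, 1)")
        if not 0.0 <= self.mark_error_rate < 1.0:
            raise ValueError("mark_error_rate must lie in [0, 1)")


@dataclass
class PhantomBundle:
    """Rendered phantom with every ground truth the pipeline can be scored on."""

    rgb: RgbImage
    true_epithelium: BinaryMask
    true_stain: BinaryMask
    true_hex_levels: np.ndarray  # level index per hexagon of the tiling
    hex_tiling: HexTiling
    true_stain_fraction: float
    achieved_epithelium_fraction: float
    spec: PhantomSpec = field(repr=False)


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render a phantom slide; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # epithelium: thresholded smoothed white noise at the target quantile
    noise = rng.standard_normal((h, w))
    smooth = gaussian_filter(noise, sigma=spec.blob_scale)
    cut = np.quantile(smooth, 1.0 - spec.epithelium_fraction_target)
    epithelium = smooth > cut
    achieved = float(epithelium.mean())
    if abs(achieved - spec.epithelium_fraction_target) > 0.05:
        warnings.warn(
            f"epithelium fraction target {spec.epithelium_fraction_target:.3f} "
            f"not reached at blob_scale {spec.blob_scale}: achieved {achieved:.3f}",
            stacklevel=2,
        )

    # stain level per hexagon of the analysis-scale lattice
    full = BinaryMask(np.ones((h, w), dtype=bool), role="roi")
    tiling = tile_hexagons(full, spec.hex_circumradius)
    levels = rng.choice(3, size=tiling.n_hexagons, p=spec.stain_level_props)
    level_img = levels[tiling.assignment]

    means = np.asarray(spec.stain_intensity_means, dtype=float)
    brown_target = means[level_img] + rng.normal(0.0, spec.stain_noise_sd, (h, w))
    amount = np.clip((255.0 - brown_target) / 255.0, 0.0, 1.0)
    amount[~epithelium] = 0.0  # DAB marks protein in tumor cells only

    img = np.empty((h, w, 3), dtype=float)
    img[:] = STROMA_RGB
    img[epithelium] = EPITHELIUM_RGB
    img += amount[:, :, None] * (STAIN_RGB - img)

    # fine nuclei texture inside epithelium: equal on all channels so the
    # red-blue separation used for stain detection is untouched
    texture = np.abs(gaussian_filter(rng.standard_normal((h, w)), sigma=1.5))
    texture /= max(texture.max(), 1e-12)
    img[epithelium] -= (spec.nuclei_texture_amplitude * texture[epithelium])[:, None]

    img += rng.normal(0.0, CHANNEL_NOISE_SD, (h, w, 3))
    rgb = RgbImage(pixels=np.clip(img, 0, 255).astype(np.uint8))

    # true stain: epithelial pixels whose noiseless level amount is material
    level_amount = (255.0 - means) / 255.0
    stained_levels = level_amount >= STAIN_MIN_AMOUNT
    true_stain = epithelium & stained_levels[level_img]

    return PhantomBundle(
        rgb=rgb,
        true_epithelium=BinaryMask(epithelium, role="epithelium"),
        true_stain=BinaryMask(true_stain, role="stain"),
        true_hex_levels=levels,
        hex_tiling=tiling,
        true_stain_fraction=float(true_stain.mean()),
        achieved_epithelium_fraction=achieved,
        spec=spec,
    )


def simulate_expert_marks(
    grid: CrossGrid,
    truth: BinaryMask,
    error_rate: float = 0.0,
    seed: int = 0,
) -> MarkSet:
    """Reader marks: truth at each cross, flipped independently at error_rate."""
    rng = np.random.default_rng(seed)
    labels = {}
    for p in grid.positions:
        val = bool(truth.values[p])
        if error_rate > 0 and rng.random() < error_rate:
            val = not val
        labels[p] = LABELED if val else UNLABELED
    return MarkSet(grid=grid, labels=labels)


FIXTURE_NAMES = (
    "table4_counts",
    "table4_expert",
    "table5_moments",
    "table5_cp1",
    "table5_loadings",
    "table2_sens_spec",
)


def _read_data(name: str) -> pd.DataFrame:
    path = resources.files("ihcquant").joinpath("data", name)
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def load_study_fixture(name: str) -> LabelTable:
    """Load one of the packaged study tables as a :class:`LabelTable`."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if name == "table4_counts":
        df = _read_data("table4.csv")[["marker", "case", "n0", "n1", "n2", "r50_pct", "ip_label"]]
    elif name == "table4_expert":
        df = _read_data("table4.csv")[["marker", "case", "expert_label"]]
    elif name == "table5_moments":
        df = _read_data("table5.csv")[["marker", "case", "i_moy", "i_sig", "i_skw"]]
    elif name == "table5_cp1":
        df = _read_data("table5.csv")[["marker", "case", "cp1"]]
    elif name == "table5_loadings":
        df = _read_data("table5_loadings.csv")
        return LabelTable(df=df, key_cols=("marker",))
    else:  # table2_sens_spec
        df = _read_data("table2.csv")
        return LabelTable(df=df, key_cols=("marker", "case", "comparison"))
    return LabelTable(df=df.reset_index(drop=True))
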