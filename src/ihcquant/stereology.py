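"""Stereological point counting, quality factors and detector calibration.

A regular grid of crosses with a uniformly random offset is laid over the
region of interest; readers (or an algorithm's mask sampled at the same
nodes) label each cross positive or negative, and the labeled fraction
estimates the area fraction of the compartment without bias.  Agreement
between readers, and between the consensus reader marks and the algorithm,
is summarized by two quality factors: the overlap of 95% confidence
intervals and the mean of sensitivity and specificity.  The second factor
drives an exhaustive grid-search calibration of detector parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io import BinaryMask

__all__ = [
    "CrossGrid",
    "MarkSet",
    "RatioEstimate",
    "QualityFactors",
    "EmptyGridError",
    "make_grid",
    "sample_mask_at",
    "estimate_ratio",
    "consensus_marks",
    "concordance_percent",
    "quality_factor_sens_spec",
    "quality_factor_ci",
    "calibrate",
]

LABELED = "labeled"
UNLABELED = "unlabeled"
EXCLUDED = "excluded"


class EmptyGridError(ValueError):
    """No grid node fell inside the region of interest."""


@dataclass
class CrossGrid:
    """Regular cross lattice with a seeded random offset, clipped to the ROI."""

    spacing: int
    offset: tuple[int, int]
    positions: list[tuple[int, int]]
    seed: int

    def __len__(self) -> int:
        return len(self.positions)

    def to_dict(self) -> dict:
        return {"spacing": self.spacing, "offset": list(self.offset), "seed": self.seed}


@dataclass
class MarkSet:
    """Reader (or virtual) labels at grid positions."""

    grid: CrossGrid
    labels: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = set(self.grid.positions)
        for p, lab in self.labels.items():
            if p not in pos:
                raise ValueError(f"mark at {p} is not a grid node")
            if lab not in (LABELED, UNLABELED, EXCLUDED):
                raise ValueError(f"unknown label {lab!r}")

    def counts(self) -> tuple[int, int, int]:
        vals = list(self.labels.values())
        return (
            vals.count(LABELED),
            vals.count(UNLABELED),
            vals.count(EXCLUDED),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"row": p[0], "col": p[1], "label": lab}
            for p, lab in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows, columns=["row", "col", "label"])


@dataclass
class RatioEstimate:
    """Surface-ratio estimate with a binomial (Wald) 95% CI, clipped to [0,1]."""

    p_hat: float
    n: int
    ci95: tuple[float, float]


@dataclass
class QualityFactors:
    qf_ci_overlap: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None

    @property
    def qf_sens_spec(self) -> float:
        if self.sensitivity is None or self.specificity is None:
            raise ValueError("sensitivity/specificity not set")
        return (self.sensitivity + self.specificity) / 2.0


def make_grid(roi: BinaryMask, spacing: int, seed: int) -> CrossGrid:
    """Place grid nodes at a seeded uniform offset, keeping in-ROI nodes."""
    if spacing < 2:
        raise ValueError("spacing must be at least 2")
    rng = np.random.default_rng(seed)
    dy, dx = rng.integers(0, spacing, size=2)
    h, w = roi.shape
    ys = np.arange(dy, h, spacing)
    xs = np.arange(dx, w, spacing)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    inside = roi.values[yy, xx]
    positions = [
        (int(r), int(c)) for r, c in zip(yy[inside].ravel(), xx[inside].ravel())
    ]
    if not positions:
        raise EmptyGridError("no grid node falls inside the ROI")
    return CrossGrid(
        spacing=spacing, offset=(int(dy), int(dx)), positions=positions, seed=seed
    )


def sample_mask_at(grid: CrossGrid, mask: BinaryMask) -> MarkSet:
    """Virtual marks: labeled iff the mask is true at the node pixel."""
    labels = {
        p: (LABELED if mask.values[p] else UNLABELED) for p in grid.positions
    }
    return MarkSet(grid=grid, labels=labels)


def estimate_ratio(marks: MarkSet) -> RatioEstimate:
    """Labeled fraction among non-excluded marks with a Wald 95% CI."""
    n_lab, n_unlab, _ = marks.counts()
    n = n_lab + n_unlab
    if n == 0:
        raise ValueError("no non-excluded marks")
    p = n_lab / n
    half = 1.96 * np.sqrt(p * (1.0 - p) / n)
    return RatioEstimate(
        p_hat=p, n=n, ci95=(max(0.0, p - half), min(1.0, p + half))
    )


def _check_same_grid(m1: MarkSet, m2: MarkSet) -> None:
    if m1.grid.positions != m2.grid.positions:
        raise ValueError("mark sets are on different grids")


def consensus_marks(m1: MarkSet, m2: MarkSet) -> MarkSet:
    """Keep marks the two readers agree on; disagreements become excluded."""
    _check_same_grid(m1, m2)
    labels = {}
    for p in m1.grid.positions:
        a, b = m1.labels.get(p), m2.labels.get(p)
        labels[p] = a if a == b else EXCLUDED
    return MarkSet(grid=m1.grid, labels=labels)


def concordance_percent(m1: MarkSet, m2: MarkSet) -> tuple[float, float, int]:
    """Per-label agreement percentages between two readers.

    The labeled percentage counts positions both readers call labeled over
    the positions *either* calls labeled (union base); analogously for the
    unlabeled percentage.  The total is the number of positions where
    neither reader excluded the mark.
    """
    _check_same_grid(m1, m2)
    both_lab = either_lab = both_unlab = either_unlab = total = 0
    for p in m1.grid.positions:
        a, b = m1.labels.get(p), m2.labels.get(p)
        if a == EXCLUDED or b == EXCLUDED or a is None or b is None:
            continue
        total += 1
        if a == LABELED or b == LABELED:
            either_lab += 1
            if a == b:
                both_lab += 1
        if a == UNLABELED or b == UNLABELED:
            either_unlab += 1
            if a == b:
                both_unlab += 1
    lab_pct = 100.0 * both_lab / either_lab if either_lab else 100.0
    unlab_pct = 100.0 * both_unlab / either_unlab if either_unlab else 100.0
    return lab_pct, unlab_pct, total


def quality_factor_sens_spec(reference: MarkSet, test: MarkSet) -> QualityFactors:
    """Sensitivity, specificity and their mean, against the reference reader.

    Positions excluded by either set are ignored.  The reference must carry
    both labeled and unlabeled marks for the metrics to be defined.
    """
    _check_same_grid(reference, test)
    tp = fn = tn = fp = 0
    for p in reference.grid.positions:
        a, b = reference.labels.get(p), test.labels.get(p)
        if a in (None, EXCLUDED) or b in (None, EXCLUDED):
            continue
        if a == LABELED:
            tp += b == LABELED
            fn += b == UNLABELED
        else:
            tn += b == UNLABELED
            fp += b == LABELED
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("reference marks are single-class; metrics undefined")
    return QualityFactors(
        sensitivity=tp / (tp + fn), specificity=tn / (tn + fp)
    )


def quality_factor_ci(e1: RatioEstimate, e2: RatioEstimate) -> float:
    """Overlap of two 95% CIs divided by the length of their union (0 if disjoint)."""
    lo1, hi1 = e1.ci95
    lo2, hi2 = e2.ci95
    inter = min(hi1, hi2) - max(lo1, lo2)
    union = max(hi1, hi2) - min(lo1, lo2)
    if inter <= 0:
        return 0.0
    if union == 0:  # two identical zero-length intervals
        return 1.0
    return inter / union


def calibrate(
    detector: Callable[[object], BinaryMask],
    param_grid: Sequence[object],
    marks: MarkSet,
    grid: CrossGrid | None = None,
) -> tuple[object, float]:
    """Exhaustive search for the detector parameters best matching reader marks.

    For each candidate the detector's mask is sampled at the mark grid and
    scored by the mean of sensitivity and specificity against ``marks``
    (the consensus reader set as reference).  Ties break to the first
    candidate in grid order.
    """
    if not param_grid:
        raise ValueError("empty parameter grid")
    grid = grid or marks.grid
    best_params, best_qf = None, -np.inf
    any_ok = False
    for params in param_grid:
        try:
            mask = detector(params)
            virtual = sample_mask_at(grid, mask)
            qf = quality_factor_sens_spec(marks, virtual).qf_sens_spec
        except (ValueError, RuntimeError):
            continue
        any_ok = True
        if qf > best_qf:
            best_params, best_qf = params, qf
    if not any_ok:
        raise RuntimeError("calibration failed: all candidates degenerate")
    return best_params, float(best_qf)
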