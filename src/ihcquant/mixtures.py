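"""1-D Gaussian mixture fitting and histogram thresholding.

The pipeline cuts a pooled transmittance histogram into low / medium / high
hexagon classes at the intersection points of the fitted Gaussian component
curves, and derives case-level binary calls from the resulting class counts.
EM initialization is fully deterministic (quantile means, equal weights) so
that marker-level thresholds are bit-reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "Gmm1D",
    "ThresholdPair",
    "ClassCounts",
    "CaseCall",
    "DegenerateFitError",
    "fit_gmm_em",
    "intersect_adjacent",
    "assign_classes",
    "call_case_main_class",
    "call_case_r50",
    "discordance",
]


class DegenerateFitError(RuntimeError):
    """EM collapsed a component or the data cannot support the fit."""


@dataclass
class Gmm1D:
    """Fitted K-component univariate Gaussian mixture, sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n_iter: int

    @property
    def K(self) -> int:
        return len(self.means)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(
            w * norm.pdf(x, m, s)
            for w, m, s in zip(self.weights, self.means, self.sds)
        )

    def component_pdf(self, k: int, x: np.ndarray) -> np.ndarray:
        return self.weights[k] * norm.pdf(x, self.means[k], self.sds[k])

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
        }


@dataclass
class ThresholdPair:
    """The two cuts separating low / medium / high classes (t1 < t2)."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError("thresholds must satisfy t1 < t2")


@dataclass
class ClassCounts:
    """Hexagon counts per class (low, middle, high) for one case."""

    n0: int
    n1: int
    n2: int

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2


@dataclass
class CaseCall:
    case: str
    marker: str
    ip_label: str
    expert_label: str
    r_pct: float | None = None

    @property
    def discordant(self) -> bool:
        return self.ip_label != self.expert_label


def fit_gmm_em(
    values: np.ndarray,
    K: int,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> Gmm1D:
    """Fit a K-component Gaussian mixture by deterministic EM.

    Initialization: component means at the (2k-1)/(2K) sample quantiles,
    equal weights, all standard deviations at sample sd / K.  Iterates until
    the log-likelihood gain drops below ``tol``.  Standard deviations are
    floored at 1e-4 of the data range; a component pinned to the floor for
    more than 10 consecutive iterations raises :class:`DegenerateFitError`.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 10 * K:
        raise DegenerateFitError(f"need at least {10 * K} values, got {n}")
    rng_x = float(x.max() - x.min())
    if rng_x == 0.0:
        raise DegenerateFitError("all values identical")
    sd_floor = 1e-4 * rng_x

    qs = (2 * np.arange(1, K + 1) - 1) / (2 * K)
    means = np.quantile(x, qs)
    sds = np.full(K, max(x.std(), sd_floor) / K)
    sds = np.maximum(sds, sd_floor)
    weights = np.full(K, 1.0 / K)

    loglik = -np.inf
    floored_runs = np.zeros(K, dtype=int)
    for it in range(1, max_iter + 1):
        # E step: responsibilities via log-sum-exp
        logp = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sds)[None, :]
            - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        new_loglik = float(lse.sum())
        resp = np.exp(logp - lse[:, None])

        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, sd_floor**2))

        at_floor = sds <= sd_floor * (1 + 1e-12)
        floored_runs = np.where(at_floor, floored_runs + 1, 0)
        if (floored_runs > 10).any():
            k_bad = int(np.argmax(floored_runs))
            raise DegenerateFitError(
                f"component {k_bad} collapsed (sd at floor for >10 iterations)"
            )
        if new_loglik - loglik < tol and np.isfinite(loglik):
            loglik = new_loglik
            break
        loglik = new_loglik

    order = np.argsort(means)
    return Gmm1D(
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        loglik=loglik,
        n_iter=it,
    )


def _pair_intersection(w1, m1, s1, w2, m2, s2) -> float:
    """Crossing of two weighted Gaussian curves located between their means.

    Solves w1 N(x; m1, s1) = w2 N(x; m2, s2), a quadratic in x.  If no real
    root falls strictly between the means (possible with very unequal
    weights), falls back to the equal-posterior point found by bisection —
    the posterior odds are monotone between the means, so a sign change is
    guaranteed there unless one curve dominates throughout, in which case
    the midpoint minimising the dominance gap is used.
    """
    if m1 > m2:
        (w1, m1, s1), (w2, m2, s2) = (w2, m2, s2), (w1, m1, s1)
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = -2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m1**2 / s1**2 - m2**2 / s2**2 - 2.0 * np.log((w1 * s2) / (w2 * s1))
    roots: list[float] = []
    if abs(a) < 1e-300:  # equal variances: linear equation
        if abs(b) > 0:
            roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = np.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    between = [r for r in roots if m1 < r < m2]
    if between:
        return float(min(between, key=lambda r: abs(r - 0.5 * (m1 + m2))))

    def gap(x):
        return (np.log(w1) + norm.logpdf(x, m1, s1)) - (
            np.log(w2) + norm.logpdf(x, m2, s2)
        )
    lo, hi = m1 + 1e-12 * (m2 - m1), m2 - 1e-12 * (m2 - m1)
    if gap(lo) * gap(hi) < 0:
        return float(brentq(gap, lo, hi, xtol=1e-12))
    grid = np.linspace(lo, hi, 1001)
    return float(grid[np.argmin(np.abs(gap(grid)))])


def intersect_adjacent(model: Gmm1D) -> ThresholdPair:
    """Thresholds at the crossings of adjacent component curves (K = 3)."""
    if model.K != 3:
        raise ValueError("threshold pair requires a 3-component mixture")
    w, m, s = model.weights, model.means, model.sds
    t1 = _pair_intersection(w[0], m[0], s[0], w[1], m[1], s[1])
    t2 = _pair_intersection(w[1], m[1], s[1], w[2], m[2], s[2])
    return ThresholdPair(t1=t1, t2=t2)


def assign_classes(values: np.ndarray, thresholds: ThresholdPair) -> ClassCounts:
    """Count values per class: v < t1 -> low, t1 <= v < t2 -> middle,
    v >= t2 -> high (boundary values go to the upper class)."""
    v = np.asarray(values, dtype=float)
    n0 = int((v < thresholds.t1).sum())
    n2 = int((v >= thresholds.t2).sum())
    n1 = int(v.size - n0 - n2)
    return ClassCounts(n0=n0, n1=n1, n2=n2)


def call_case_main_class(counts: ClassCounts) -> str:
    """Binary call by the dominant class (Bim / Mcl-1 rule).

    The class holding the most hexagons decides; the two upper classes are
    grouped as "high", so the case is "low" only when class 0 dominates.
    Ties break toward the lowest class index.
    """
    if counts.total == 0:
        raise ValueError("no hexagons to call")
    main = int(np.argmax([counts.n0, counts.n1, counts.n2]))
    return "low" if main == 0 else "high"


def call_case_r50(counts: ClassCounts) -> tuple[float, str]:
    """Binary call by the high-class share (P-ERK rule).

    R = 100 * n2 / total; the case is "high" only when the high class holds
    at least half of the hexagons, grouping the two lower classes as "low".
    """
    if counts.total == 0:
        raise ValueError("no hexagons to call")
    r_pct = 100.0 * counts.n2 / counts.total
    return r_pct, ("high" if r_pct >= 50.0 else "low")


def discordance(calls: list[CaseCall]) -> tuple[int, pd.DataFrame]:
    """Count calls disagreeing with the expert label; return them as a table."""
    for c in calls:
        if not c.expert_label:
            raise ValueError(f"case {c.case} has no expert label")
    rows = [
        {
            "case": c.case,
            "marker": c.marker,
            "ip_label": c.ip_label,
            "expert_label": c.expert_label,
            "r_pct": c.r_pct,
        }
        for c in calls
        if c.discordant
    ]
    table = pd.DataFrame(
        rows, columns=["case", "marker", "ip_label", "expert_label", "r_pct"]
    )
    return len(rows), table
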