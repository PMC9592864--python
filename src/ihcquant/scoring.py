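"""Composite heterogeneity score from per-case transmittance moments.

For each case the mean, standard deviation and skewness of the defined
hexagon transmittances summarize both level and heterogeneity of staining.
A standardized PCA across cases (correlation-matrix PCA: each moment column
centered and scaled by its sample SD) compresses the three moments into the
first principal component; the component is oriented so the loading on the
mean transmittance is positive, making higher scores mean stronger
staining.  Scores are min-max normalized to percent, shifted so a
mixture-derived (or supplied) threshold becomes the zero origin, and signed
scores yield the binary low / high call.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .mixtures import DegenerateFitError, fit_gmm_em, intersect_adjacent

__all__ = [
    "CaseMoments",
    "PcaModel",
    "ScoreRecord",
    "case_moments",
    "fit_pca",
    "score_cases",
    "minmax_percent",
    "auto_threshold",
    "shift_and_call",
]


@dataclass
class CaseMoments:
    """First three distribution moments of one case's hexagon transmittances."""

    i_moy: float  # mean
    i_sig: float  # population standard deviation
    i_skw: float  # population skewness g1 = m3 / m2^(3/2)


@dataclass
class PcaModel:
    """Standardized PCA of the 3 moment columns (first component only)."""

    col_means: np.ndarray
    col_sds: np.ndarray  # sample SD (ddof=1)
    loading: np.ndarray  # unit 3-vector, i_moy coefficient >= 0
    explained_var_ratio: float

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.col_means) / self.col_sds

    def to_dict(self) -> dict:
        return {
            "col_means": self.col_means.tolist(),
            "col_sds": self.col_sds.tolist(),
            "loading": self.loading.tolist(),
            "explained_var_ratio": self.explained_var_ratio,
        }


@dataclass
class ScoreRecord:
    case: str
    cp1: float
    pct: float
    shifted: float
    ip_label: str
    expert_label: str

    @property
    def discordant(self) -> bool:
        return self.ip_label != self.expert_label


def case_moments(values: np.ndarray) -> CaseMoments:
    """Mean, population SD and population skewness of one case's values."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 3:
        raise ValueError(f"need at least 3 values, got {v.size}")
    mean = float(v.mean())
    m2 = float(((v - mean) ** 2).mean())
    m3 = float(((v - mean) ** 3).mean())
    sd = float(np.sqrt(m2))
    if m2 == 0.0:
        warnings.warn("zero variance: skewness set to 0", stacklevel=2)
        skw = 0.0
    else:
        skw = m3 / m2**1.5
    return CaseMoments(i_moy=mean, i_sig=sd, i_skw=skw)


def _moment_matrix(moments: pd.DataFrame) -> np.ndarray:
    return moments[["i_moy", "i_sig", "i_skw"]].to_numpy(dtype=float)


def fit_pca(moments: pd.DataFrame) -> PcaModel:
    """Correlation-matrix PCA of the per-case moment table.

    Columns are standardized by their mean and sample SD; the loading is the
    leading eigenvector of the correlation matrix, sign-oriented so the
    i_moy coefficient is non-negative.
    """
    X = _moment_matrix(moments)
    if len(X) < 4:
        raise ValueError("need at least 4 cases")
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("constant moment column; PCA undefined")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    corr = np.corrcoef(X.T)
    eigval, eigvec = np.linalg.eigh(corr)
    loading = eigvec[:, -1]
    if loading[0] < 0:
        loading = -loading
    return PcaModel(
        col_means=means,
        col_sds=sds,
        loading=loading,
        explained_var_ratio=float(eigval[-1] / eigval.sum()),
    )


def score_cases(model: PcaModel, moments: pd.DataFrame) -> np.ndarray:
    """First-component score per case (zero mean over the fitted cases)."""
    Z = model.standardize(_moment_matrix(moments))
    return Z @ model.loading


def minmax_percent(scores: np.ndarray) -> np.ndarray:
    """Affine map of the scores onto [0, 100]."""
    s = np.asarray(scores, dtype=float)
    lo, hi = s.min(), s.max()
    if hi == lo:
        raise ValueError("all scores equal; normalization undefined")
    return 100.0 * (s - lo) / (hi - lo)


def auto_threshold(
    pct_values: np.ndarray,
    override: float | None = None,
) -> float:
    """Zero-origin threshold on the percent scale.

    Default: fit a 3-component mixture to the percent scores and return the
    higher of the two adjacent-curve intersections.  A manual ``override``
    (e.g. a study-fixed threshold) is returned verbatim when supplied.
    """
    if override is not None:
        if not 0.0 <= override <= 100.0:
            raise ValueError("override threshold must lie in [0, 100]")
        return float(override)
    p = np.asarray(pct_values, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 cases for the automatic threshold")
    model = fit_gmm_em(p, K=3)
    return float(intersect_adjacent(model).t2)


def score_barplot(records: list["ScoreRecord"], marker: str, ax=None):
    """Bar chart of signed scores per case; discordant cases drawn hollow."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    order = np.argsort([r.shifted for r in records])
    for i, k in enumerate(order):
        r = records[k]
        ax.bar(
            i,
            r.shifted,
            color="white" if r.discordant else ("tab:red" if r.shifted >= 0 else "tab:blue"),
            edgecolor="black",
        )
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xticks(range(len(records)))
    ax.set_xticklabels([records[k].case for k in order], rotation=90, fontsize=7)
    ax.set_ylabel("score (% − threshold)")
    ax.set_title(marker)
    return ax


def shift_and_call(
    pct: np.ndarray,
    threshold: float,
    expert: list[str],
    cases: list[str],
    cp1: np.ndarray | None = None,
) -> tuple[list[ScoreRecord], int]:
    """Signed scores and binary calls; count discordance with the expert."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must lie in [0, 100]")
    if len(expert) != len(pct) or len(cases) != len(pct):
        raise ValueError("pct, expert and cases must align")
    records = []
    for i, case in enumerate(cases):
        if not expert[i]:
            raise ValueError(f"case {case} has no expert label")
        shifted = float(pct[i] - threshold)
        records.append(
            ScoreRecord(
                case=case,
                cp1=float(cp1[i]) if cp1 is not None else float("nan"),
                pct=float(pct[i]),
                shifted=shifted,
                ip_label="high" if shifted >= 0 else "low",
                expert_label=expert[i],
            )
        )
    n_disc = sum(r.discordant for r in records)
    return records, n_disc
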