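"""Statistics layer: 1-D staging clusters, rank statistics and power.

The imaging-derived disease grade ("HSI stage") comes from agglomerative
hierarchical clustering of the per-measurement interlimb LWR differences
into k = 3 groups, relabeled low / mid / high by ascending cluster mean.
Group comparisons use the two-sided Mann-Whitney U test (exact
enumeration for small tie-free samples, tie-corrected normal
approximation otherwise); associations with clinical stage use
Spearman's rank correlation; distribution shape is checked with the
D'Agostino-Pearson omnibus normality test; and the minimum detectable
correlation for a given sample size follows from the Fisher
z transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "HsiStaging",
    "TestResult",
    "hsi_stage",
    "spearman",
    "mann_whitney_u",
    "normality_omnibus",
    "min_detectable_r",
]

STAGE_LABELS = ("low", "mid", "high")

#: Mann-Whitney exact-enumeration limit: exact when the smaller sample
#: has at most this many observations and there are no ties.
EXACT_LIMIT = 8


@dataclass
class HsiStaging:
    """k-cluster staging of 1-D values with ascending-mean label order."""

    values: np.ndarray
    labels: list[str]
    cluster_means: np.ndarray
    k: int

    def label_codes(self) -> np.ndarray:
        """Ordinal codes 0..k-1 matching ascending cluster means."""
        order = {lab: i for i, lab in enumerate(_stage_names(self.k))}
        return np.array([order[lab] for lab in self.labels])


@dataclass
class TestResult:
    """Statistic, two-sided p value, per-group sizes and a method tag."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value outside [0, 1]")


def _stage_names(k: int) -> list[str]:
    if k == 3:
        return list(STAGE_LABELS)
    return [f"stage_{i}" for i in range(k)]


def hsi_stage(values, k: int = 3, linkage: str = "ward") -> HsiStaging:
    """Agglomerative clustering of 1-D values cut at ``k`` clusters.

    Ward linkage on the Euclidean line by default (best mimics
    variance-based grouping of scalars; 'complete' and 'average' are
    accepted too). Clusters are relabeled by ascending mean, so for
    k = 3 the groups are named low / mid / high.
    """
    v = np.asarray(values, dtype=float).ravel()
    if np.unique(v).size < k:
        raise ValueError(f"need at least k={k} distinct values, got {np.unique(v).size}")
    if k == 1:
        raw = np.zeros(v.size, dtype=int)
    else:
        model = AgglomerativeClustering(n_clusters=k, linkage=linkage)
        raw = model.fit_predict(v.reshape(-1, 1))
    means = np.array([v[raw == c].mean() for c in range(k)])
    order = np.argsort(means)  # cluster id -> rank position
    rank_of = np.empty(k, dtype=int)
    rank_of[order] = np.arange(k)
    names = _stage_names(k)
    labels = [names[rank_of[c]] for c in raw]
    return HsiStaging(values=v, labels=labels, cluster_means=means[order], k=k)


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs two equal-length samples with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance: a sample is constant")
    r, _ = sps.spearmanr(x, y)
    return float(r)


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test between two independent samples.

    The p value is exact (full enumeration of the U null distribution)
    when the smaller sample has at most 8 observations and the pooled
    data are tie-free — the regime of small per-stage groups — and uses
    the tie-corrected normal approximation with continuity correction
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = min(a.size, b.size) <= EXACT_LIMIT and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=(int(a.size), int(b.size)),
        method="mann-whitney-u/" + ("exact" if exact else "asymptotic"),
    )


def normality_omnibus(values) -> TestResult:
    """D'Agostino-Pearson omnibus test of normality.

    Combines transformed sample skewness and kurtosis into a chi-square
    statistic with 2 df. Below n = 20 the kurtosis transform is
    unreliable; the result is still returned but carries a note.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError("omnibus normality test needs n >= 8")
    if np.unique(v).size < 2:
        raise ValueError("normality test on constant input")
    note = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.normaltest(v)
    if v.size < 20:
        note = f"n={v.size} < 20: omnibus test unreliable at this sample size"
    return TestResult(
        statistic=float(stat), p_value=float(p), n=(int(v.size),),
        method="dagostino-pearson", note=note,
    )


def min_detectable_r(n: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest correlation detectable at the given size, alpha and power.

    Based on the Fisher z transform: atanh(r) is approximately normal
    with standard error 1/sqrt(n - 3), so the detection bound is
    ``tanh((z_{1-alpha/2} + z_power) / sqrt(n - 3))``. With n = 58,
    alpha = 0.05 and power 0.80 this gives r = 0.36.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z_alpha = sps.norm.ppf(1.0 - alpha / 2.0)
    z_power = sps.norm.ppf(power)
    return float(np.tanh((z_alpha + z_power) / np.sqrt(n - 3)))
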