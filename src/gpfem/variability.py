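"""Intra-/inter-subject OI variability and group statistics.

Shape-and-distribution variability between two OI heatmaps is one minus
the zero-mean normalized cross-correlation coefficient (the single-offset
equivalent of template matching with a normalized correlation-coefficient
score): 0 means identical shape and distribution, values near 1 mean
maximally different.  Negative correlations are clamped to zero before the
subtraction so the score stays in [0, 1]; the raw coefficient is also
returned for reference.  Group contrasts use independent (pooled) or
paired t-tests and Levene's test (mean-centered), mirroring conventional
gait-lab reporting at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

ALPHA = 0.05


def _filled(hm) -> np.ndarray:
    """Heatmap grid with invalid cells filled by the map mean."""
    grid = np.asarray(hm.grid, float)
    mask = np.asarray(hm.valid_mask, bool)
    vals = grid[mask]
    if vals.size == 0:
        raise ValueError("heatmap has no valid cells")
    out = np.where(mask, grid, vals.mean())
    return out


def ncc(map_a, map_b) -> float:
    """Zero-mean normalized cross-correlation coefficient of two equal-size
    maps (invalid cells filled with each map's mean)."""
    a = _filled(map_a).ravel()
    b = _filled(map_b).ravel()
    if a.shape != b.shape:
        raise ValueError("heatmaps must have equal grid sizes")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance map: correlation undefined")
    return float(np.dot(a, b) / (na * nb))


def template_match_variability(map_a, map_b, return_raw: bool = False):
    """1 - clamped NCC: 0 for identical maps, up to 1 for anti-correlated."""
    r = ncc(map_a, map_b)
    score = 1.0 - min(max(r, 0.0), 1.0)
    if return_raw:
        return score, r
    return score


@dataclass
class VariabilityResult:
    shape_variability: float  # in [0, 1]
    mean_diff: float  # |mean_L - mean_R|, month^-1
    range_diff: float  # |range_L - range_R|, month^-1
    argmax_region_match: bool
    argmin_region_match: bool
    raw_ncc: float = float("nan")


def intra_subject(left_stats, right_stats, left_map, right_map) -> VariabilityResult:
    """Left-right within-subject comparison of OI maps and magnitudes."""
    score, r = template_match_variability(left_map, right_map, return_raw=True)
    return VariabilityResult(
        shape_variability=score,
        mean_diff=abs(left_stats.oi_mean - right_stats.oi_mean),
        range_diff=abs(left_stats.oi_range - right_stats.oi_range),
        argmax_region_match=left_stats.argmax_region == right_stats.argmax_region,
        argmin_region_match=left_stats.argmin_region == right_stats.argmin_region,
        raw_ncc=r,
    )


def inter_subject(group_maps: list) -> np.ndarray:
    """Per-femur mean template-matching variability against all other maps
    of the same group (self-comparisons excluded)."""
    n = len(group_maps)
    if n < 2:
        raise ValueError("need at least two maps in the group")
    out = np.zeros(n)
    pair = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair[i, j] = pair[j, i] = template_match_variability(
                group_maps[i], group_maps[j]
            )
    for i in range(n):
        out[i] = pair[i, np.arange(n) != i].mean()
    return out


@dataclass
class GroupComparison:
    metric: str
    test: str  # independent_t | dependent_t | levene
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int

    @property
    def significance_tier(self) -> str:
        if self.p_value < 0.001:
            return "p<0.001"
        if self.p_value < 0.01:
            return "p<0.01"
        if self.p_value < ALPHA:
            return "p<0.05"
        return "ns"


def group_compare(values_a, values_b, test: str = "independent_t",
                  metric: str = "", welch: bool = False,
                  levene_center: str = "mean") -> GroupComparison:
    """Two-sample comparison: pooled/Welch independent t, paired t, or
    Levene's variance test; two-sided p-values."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if test == "independent_t":
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("both samples have zero variance")
        res = stats.ttest_ind(a, b, equal_var=not welch)
    elif test == "dependent_t":
        if len(a) != len(b):
            raise ValueError("paired test requires equal sample sizes")
        if np.allclose(a, b):
            # identical pairs: zero differences, define t = 0, p = 1
            return GroupComparison(metric, test, 0.0, 1.0, a.mean(), b.mean(),
                                   a.std(ddof=1), b.std(ddof=1), len(a), len(b))
        res = stats.ttest_rel(a, b)
    elif test == "levene":
        res = stats.levene(a, b, center=levene_center)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        metric=metric,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=len(a),
        n_b=len(b),
    )
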