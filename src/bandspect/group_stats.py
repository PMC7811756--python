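"""Nonparametric voxel-wise inference and cohort statistics.

The imaging comparisons use pseudo-T statistics — two-sample (or
single-case) contrasts whose denominator uses a spatially smoothed
residual-variance map, stabilizing inference at low degrees of freedom —
with permutation-based cluster-level family-wise-error correction and an
optional threshold-free cluster enhancement (TFCE) variant. The scalar
cohort statistics cover covariate adjustment with estimated marginal
means, Mann-Whitney tests on the adjusted values, Cohen's d, a PCA-based
memory summary score, correlations, and median/IQR descriptives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from bandspect.preprocessing import fwhm_to_sigma_voxels

__all__ = [
    "DesignSpec",
    "ClusterResult",
    "relative_mask",
    "pseudo_t_map",
    "permutation_cluster_test",
    "tfce_map",
    "tfce_permutation_test",
    "adjust_covariate",
    "mann_whitney",
    "cohen_d",
    "cohen_d_from_data",
    "pca_summary",
    "correlate",
    "correlate_interictal",
    "describe",
]


@dataclass(frozen=True)
class DesignSpec:
    """Configuration of a voxel-wise group (or single-case) comparison."""

    n_permutations: int = 500
    primary_threshold: float = 2.5
    cluster_alpha: float = 0.05
    variance_smoothing_fwhm_mm: float = 8.0
    relative_mask_threshold: float = 0.8
    connectivity: int = 18
    direction: str = "greater"  # contrast: first group > second group
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least 1 permutation")
        if self.primary_threshold <= 0:
            raise ValueError("primary threshold must be positive")
        if not 0 < self.cluster_alpha < 1:
            raise ValueError("cluster_alpha must lie in (0, 1)")


@dataclass
class ClusterResult:
    """Observed clusters, the pseudo-T map, and the permutation null."""

    clusters: pd.DataFrame
    pseudo_t: np.ndarray
    null_max_cluster: np.ndarray
    n_null: int

    @property
    def min_attainable_p(self) -> float:
        return 1.0 / (1 + self.n_null)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.clusters[self.clusters["p_fwe"] < alpha]


def relative_mask(maps: list[np.ndarray], threshold: float = 0.8) -> np.ndarray:
    """Voxels where the grand-mean image exceeds ``threshold`` times the
    mean of the grand-mean image over its positive voxels."""
    if len(maps) == 0:
        raise ValueError("need at least one map")
    grand = np.mean(np.stack(maps), axis=0)
    positive = grand > 0
    if not positive.any():
        raise ValueError("grand-mean image has no positive voxels")
    cut = threshold * grand[positive].mean()
    mask = grand > cut
    if not mask.any():
        raise ValueError("relative mask is empty")
    return mask


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _pseudo_t(
    y: np.ndarray,
    group: np.ndarray,
    covariate: np.ndarray | None,
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float,
) -> np.ndarray:
    """Pseudo-T volume for value ~ intercept + group + covariate.

    ``y`` is (n_subjects, n_voxels) over the mask; the residual-variance
    map is Gaussian-smoothed within the mask before entering the
    denominator (fwhm_mm = 0 gives the ordinary ANCOVA t-map).
    """
    n = y.shape[0]
    cols = [np.ones(n), group.astype(float)]
    if covariate is not None:
        cols.append(np.asarray(covariate, float) - np.mean(covariate))
    x = np.column_stack(cols)
    p = x.shape[1]
    if n <= p:
        raise ValueError("design has no residual degrees of freedom")
    xtx_inv = np.linalg.inv(x.T @ x)
    if not np.all(np.isfinite(xtx_inv)):
        raise ValueError("rank-deficient design")
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - p)

    var_vol = np.zeros(mask.shape)
    var_vol[mask] = sigma2
    if fwhm_mm > 0:
        sig = fwhm_to_sigma_voxels(fwhm_mm, voxel_size_mm)
        num = ndimage.gaussian_filter(var_vol, sig)
        den = ndimage.gaussian_filter(mask.astype(float), sig)
        var_vol[mask] = num[mask] / den[mask]

    design_factor = xtx_inv[1, 1]
    tmap = np.zeros(mask.shape)
    se = np.sqrt(var_vol[mask] * design_factor)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta[1] / se
    tmap[mask] = np.where(np.isfinite(tvals), tvals, 0.0)
    return tmap


def pseudo_t_map(
    maps_a: list[np.ndarray],
    maps_b: list[np.ndarray],
    covariate: np.ndarray | None = None,
    fwhm_mm: float = 8.0,
    voxel_size_mm: float = 3.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Pseudo-T contrast map for group A (coded 1) versus group B."""
    if len(maps_a) < 1 or len(maps_b) < 2:
        raise ValueError("need n_A >= 1 and n_B >= 2")
    all_maps = list(maps_a) + list(maps_b)
    if mask is None:
        mask = relative_mask(all_maps)
    y = np.stack([m[mask] for m in all_maps])
    group = np.array([1] * len(maps_a) + [0] * len(maps_b))
    return _pseudo_t(y, group, covariate, mask, fwhm_mm, voxel_size_mm)


def _max_cluster_size(tmap: np.ndarray, threshold: float, structure: np.ndarray) -> int:
    lab, nlab = ndimage.label(tmap > threshold, structure=structure)
    if nlab == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def permutation_cluster_test(
    maps_a: list[np.ndarray],
    maps_b: list[np.ndarray],
    design: DesignSpec,
    covariate: np.ndarray | None = None,
    voxel_size_mm: float = 3.0,
    mask: np.ndarray | None = None,
) -> ClusterResult:
    """Permutation cluster-level inference on the pseudo-T map.

    Observed clusters are the connected components (default
    18-connectivity) of pseudo-T above the primary threshold. The null is
    the maximum cluster size under relabelings of the group column only —
    each subject's covariate value stays attached to their map. When the
    number of distinct relabelings does not exceed the requested
    permutation count, all of them are enumerated (e.g. 24 for a 1-vs-23
    single-case design); otherwise random relabelings are drawn. Corrected
    p-values use the (1 + exceedances) / (1 + n_null) estimator, which
    includes the identity relabeling and guarantees validity.
    """
    n_a, n_b = len(maps_a), len(maps_b)
    n = n_a + n_b
    all_maps = list(maps_a) + list(maps_b)
    if mask is None:
        mask = relative_mask(all_maps, design.relative_mask_threshold)
    sign = -1.0 if design.direction == "less" else 1.0
    y = np.stack([m[mask] for m in all_maps])
    group_obs = np.array([1] * n_a + [0] * n_b)
    fwhm = design.variance_smoothing_fwhm_mm
    structure = _connectivity_structure(design.connectivity)

    tmap = sign * _pseudo_t(y, group_obs, covariate, mask, fwhm, voxel_size_mm)
    lab, nlab = ndimage.label(tmap > design.primary_threshold, structure=structure)

    n_distinct = comb(n, n_a)
    if n_distinct < 20:
        warnings.warn(
            f"only {n_distinct} distinct relabelings; p-value granularity "
            f"{1.0 / n_distinct:.3f} exceeds 0.05",
            stacklevel=2,
        )
    rng = np.random.default_rng(design.seed)
    if n_distinct - 1 <= design.n_permutations:
        relabelings = [
            idx for idx in combinations(range(n), n_a)
            if idx != tuple(range(n_a))
        ]
    else:
        relabelings = []
        for _ in range(design.n_permutations):
            relabelings.append(tuple(rng.choice(n, size=n_a, replace=False)))

    null_max = np.empty(len(relabelings))
    group_perm = np.zeros(n)
    for i, idx in enumerate(relabelings):
        group_perm[:] = 0
        group_perm[list(idx)] = 1
        t_perm = sign * _pseudo_t(y, group_perm, covariate, mask, fwhm, voxel_size_mm)
        null_max[i] = _max_cluster_size(t_perm, design.primary_threshold, structure)

    rows = []
    voxel_mm3 = voxel_size_mm**3
    for c in range(1, nlab + 1):
        sel = lab == c
        size = int(sel.sum())
        peak_flat = np.argmax(np.where(sel, tmap, -np.inf))
        peak_ijk = np.unravel_index(peak_flat, tmap.shape)
        p_fwe = (1.0 + np.count_nonzero(null_max >= size)) / (1.0 + len(relabelings))
        rows.append(
            {
                "size_voxels": size,
                "size_mm3": size * voxel_mm3,
                "peak_pseudo_t": float(tmap[peak_ijk]),
                "peak_i": peak_ijk[0],
                "peak_j": peak_ijk[1],
                "peak_k": peak_ijk[2],
                "p_fwe": p_fwe,
            }
        )
    clusters = pd.DataFrame(
        rows,
        columns=["size_voxels", "size_mm3", "peak_pseudo_t",
                 "peak_i", "peak_j", "peak_k", "p_fwe"],
    ).sort_values("size_voxels", ascending=False, ignore_index=True)
    return ClusterResult(clusters, tmap, null_max, len(relabelings))


def tfce_map(
    stat_map: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float = 0.1,
    connectivity: int = 18,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a (positive-direction) map.

    TFCE(v) = sum over thresholds h of e(h, v)^E * h^H * dh, where
    e(h, v) is the extent of the supra-threshold cluster supporting voxel
    v at height h. Parameters default to the conventional E=0.5, H=2.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("statistic map must be finite")
    out = np.zeros_like(stat_map)
    top = float(stat_map.max())
    if top <= 0:
        return out
    structure = _connectivity_structure(connectivity)
    for h in np.arange(dh, top + dh / 2, dh):
        sup = stat_map >= h
        if not sup.any():
            break
        lab, nlab = ndimage.label(sup, structure=structure)
        sizes = np.bincount(lab.ravel())
        extent = sizes[lab]
        out[sup] += extent[sup] ** E * h**H * dh
    return out


def tfce_permutation_test(
    maps_a: list[np.ndarray],
    maps_b: list[np.ndarray],
    design: DesignSpec,
    covariate: np.ndarray | None = None,
    voxel_size_mm: float = 3.0,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """TFCE map with voxel-wise FWE-corrected p from the max-TFCE null."""
    n_a, n_b = len(maps_a), len(maps_b)
    n = n_a + n_b
    all_maps = list(maps_a) + list(maps_b)
    if mask is None:
        mask = relative_mask(all_maps, design.relative_mask_threshold)
    sign = -1.0 if design.direction == "less" else 1.0
    y = np.stack([m[mask] for m in all_maps])
    group_obs = np.array([1] * n_a + [0] * n_b)
    fwhm = design.variance_smoothing_fwhm_mm

    enhanced = tfce_map(
        sign * _pseudo_t(y, group_obs, covariate, mask, fwhm, voxel_size_mm),
        connectivity=design.connectivity,
    )
    rng = np.random.default_rng(design.seed)
    null_max = np.empty(design.n_permutations)
    group_perm = np.zeros(n)
    for i in range(design.n_permutations):
        group_perm[:] = 0
        group_perm[rng.choice(n, size=n_a, replace=False)] = 1
        t_perm = sign * _pseudo_t(y, group_perm, covariate, mask, fwhm, voxel_size_mm)
        null_max[i] = tfce_map(t_perm, connectivity=design.connectivity).max()
    p = np.ones_like(enhanced)
    p[mask] = (
        1.0 + (null_max[None, :] >= enhanced[mask][:, None]).sum(axis=1)
    ) / (1.0 + design.n_permutations)
    return enhanced, p


@dataclass
class CovariateAdjustment:
    """Covariate-adjusted values and estimated marginal means per group."""

    adjusted: np.ndarray  # values minus the pooled covariate effect
    emm: dict[str, float]
    emm_sd: dict[str, float]
    slope: float

    @property
    def residuals(self) -> np.ndarray:
        """Alias used for the rank tests (group structure retained)."""
        return self.adjusted


def adjust_covariate(
    values: np.ndarray, covariate: np.ndarray, groups: np.ndarray
) -> CovariateAdjustment:
    """ANCOVA-style adjustment with a pooled covariate slope.

    Fits value = b0 + slope * covariate + group offsets; the estimated
    marginal mean of each group is its prediction at the grand covariate
    mean, which equals the group mean of the covariate-adjusted values
    value - slope * (covariate - mean). Those adjusted values are what the
    rank tests compare.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    groups = np.asarray(groups)
    if values.size < 3:
        raise ValueError("need at least 3 observations")
    levels = list(pd.unique(groups))
    cov_c = covariate - covariate.mean()
    if np.allclose(cov_c, 0):
        slope = 0.0
    else:
        dummies = np.column_stack(
            [(groups == lv).astype(float) for lv in levels[1:]]
        ) if len(levels) > 1 else np.empty((values.size, 0))
        x = np.column_stack([np.ones(values.size), dummies, cov_c])
        beta, *_ = np.linalg.lstsq(x, values, rcond=None)
        slope = float(beta[-1])
    adjusted = values - slope * cov_c
    emm = {str(lv): float(adjusted[groups == lv].mean()) for lv in levels}
    emm_sd = {
        str(lv): float(adjusted[groups == lv].std(ddof=1))
        if (groups == lv).sum() > 1 else float("nan")
        for lv in levels
    }
    return CovariateAdjustment(adjusted, emm, emm_sd, slope)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) with a two-sided p-value.

    Exact enumeration when n_x + n_y <= 20 and there are no ties;
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohen_d(mean_a: float, mean_b: float, sd_common: float) -> float:
    """Standardized mean difference given a common SD."""
    if sd_common <= 0:
        raise ValueError("sd must be positive")
    return (mean_a - mean_b) / sd_common


def cohen_d_from_data(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    pooled_sd = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    return cohen_d(float(x.mean()), float(y.mean()), float(pooled_sd))


def pca_summary(
    subtest_scores: pd.DataFrame, age: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Single memory summary score from several age-regressed subtests.

    Each subtest is regressed on age over the pooled sample, the residuals
    are standardized, and the first principal component is extracted; the
    sign is fixed so the loadings are non-negative (higher = better
    performance on every subtest) and the scores are scaled to unit
    variance. Returns (scores, loadings).
    """
    scores = subtest_scores.to_numpy(dtype=float)
    n, k = scores.shape
    if n < 4:
        raise ValueError("need at least 4 subjects")
    age = np.asarray(age, dtype=float)
    x = np.column_stack([np.ones(n), age - age.mean()])
    beta, *_ = np.linalg.lstsq(x, scores, rcond=None)
    resid = scores - x @ beta
    sds = resid.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("a subtest column is constant after age regression")
    z = resid / sds
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[0]
    if loadings.sum() < 0:
        loadings = -loadings
    component = z @ loadings
    component = component / component.std(ddof=1)
    return component, loadings


def correlate(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def correlate_interictal(
    interictal_days: np.ndarray, values: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of ln(interictal interval) with a V measure."""
    intervals = np.asarray(interictal_days, dtype=float)
    if np.any(intervals <= 0):
        raise ValueError("interictal intervals must be positive")
    return correlate(np.log(intervals), values, method="pearson")


def describe(values: np.ndarray) -> tuple[float, float]:
    """Median and interquartile range.

    Quartiles use linear interpolation at position (n-1)p + 1 in the
    sorted sample (the numpy default), the rule consistent with the
    package's reference cohort tables.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 values")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q3 - q1)
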