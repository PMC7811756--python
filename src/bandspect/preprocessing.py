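"""Spatial operations between quantification and statistics.

Left-right flipping (so the epileptogenic side is consistently on one
side), Gaussian smoothing, fast:slow ratio maps, and atlas-region
summaries including the cluster-restricted "hippocampal area" extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt, log

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "AtlasLabels",
    "flip_lr",
    "random_control_flips",
    "smooth_gaussian",
    "fwhm_to_sigma_voxels",
    "ratio_map",
    "region_summary",
]

_FWHM_TO_SIGMA = 2.0 * sqrt(2.0 * log(2.0))  # ~2.3548


@dataclass
class AtlasLabels:
    """Integer label volume aligned to the parametric-map grid."""

    labels: np.ndarray
    names: dict[int, str]
    hemispheres: dict[int, str] = field(default_factory=dict)

    @classmethod
    def from_phantom(cls, phantom) -> "AtlasLabels":
        hemi = {
            code: ("left" if name.endswith("_left")
                   else "right" if name.endswith("_right") else "both")
            for code, name in phantom.region_names.items()
        }
        return cls(phantom.labels.copy(), dict(phantom.region_names), hemi)

    def codes_named(self, substring: str) -> list[int]:
        return [c for c, n in self.names.items() if substring in n]


def flip_lr(
    volume: np.ndarray, subject_lateralization: str, lr_axis: int | None = 0
) -> np.ndarray:
    """Mirror right-lateralized subjects along the left-right axis.

    Left-lateralized (or unlateralized) volumes are returned unchanged
    (as a copy). Applying the flip twice is the identity.
    """
    if lr_axis is None:
        raise ValueError("left-right axis is not annotated")
    if subject_lateralization == "right":
        return np.flip(volume, axis=lr_axis).copy()
    return np.asarray(volume).copy()


def random_control_flips(
    n_controls: int,
    n_flip: int | None = None,
    n_permutations: int = 10,
    seed: int | None = None,
    n_tle_flipped: int | None = None,
    n_tle: int | None = None,
) -> list[tuple[int, ...]]:
    """Seeded distinct subsets of controls to right-left flip.

    When ``n_flip`` is not given it mirrors the patient proportion:
    round(n_controls * n_tle_flipped / n_tle).
    """
    if n_flip is None:
        if n_tle_flipped is None or not n_tle:
            raise ValueError("give n_flip or the patient flip proportion")
        n_flip = round(n_controls * n_tle_flipped / n_tle)
    if n_flip > n_controls:
        raise ValueError("cannot flip more controls than exist")
    if n_flip == 0:
        return [()]
    total = comb(n_controls, n_flip)
    if n_permutations > total:
        raise ValueError(
            f"only {total} distinct subsets of size {n_flip} exist"
        )
    if total <= 10 * n_permutations:  # enumerate and sample without replacement
        all_subsets = list(combinations(range(n_controls), n_flip))
        rng = np.random.default_rng(seed)
        idx = rng.choice(total, size=n_permutations, replace=False)
        return [all_subsets[i] for i in sorted(idx)]
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    while len(out) < n_permutations:
        subset = tuple(sorted(rng.choice(n_controls, size=n_flip, replace=False)))
        if subset not in seen:
            seen.add(subset)
            out.append(subset)
    return out


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm: float) -> float:
    return fwhm_mm / (voxel_size_mm * _FWHM_TO_SIGMA)


def smooth_gaussian(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Isotropic Gaussian smoothing specified by FWHM in millimetres.

    With a mask, the result is renormalized by the smoothed mask so edge
    voxels are not attenuated toward zero; outside the mask the output is 0.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        out = volume.copy()
        if mask is not None:
            out = np.where(mask, out, 0.0)
        return out
    sigma = fwhm_to_sigma_voxels(fwhm_mm, voxel_size_mm)
    if mask is None:
        return ndimage.gaussian_filter(volume, sigma)
    mask = np.asarray(mask, dtype=float)
    num = ndimage.gaussian_filter(volume * mask, sigma)
    den = ndimage.gaussian_filter(mask, sigma)
    out = np.zeros_like(volume)
    inside = mask > 0
    out[inside] = num[inside] / den[inside]
    return out


def ratio_map(
    vf_map: np.ndarray, vs_map: np.ndarray, eps: float = 1e-6
) -> np.ndarray:
    """Voxel-wise V_F / V_S where V_S exceeds eps; 0 elsewhere."""
    vf_map = np.asarray(vf_map, dtype=float)
    vs_map = np.asarray(vs_map, dtype=float)
    if vf_map.shape != vs_map.shape:
        raise ValueError("maps must share a grid")
    out = np.zeros_like(vf_map)
    valid = vs_map > eps
    out[valid] = vf_map[valid] / vs_map[valid]
    return out


def region_summary(
    vs_map: np.ndarray,
    vf_map: np.ndarray,
    atlas: AtlasLabels,
    cluster_mask: np.ndarray | None = None,
    combine: str = "intersection",
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Per-region means of V_S / V_F (plus both ratio conventions).

    With a cluster mask, each region is restricted to its overlap with the
    mask (``combine='union'`` instead pools region and mask voxels); empty
    regions are dropped with a warning.
    """
    rows = []
    cluster = None if cluster_mask is None else np.asarray(cluster_mask, bool)
    for code, name in atlas.names.items():
        sel = atlas.labels == code
        if cluster is not None:
            sel = (sel | cluster) if combine == "union" else (sel & cluster)
        n_vox = int(np.count_nonzero(sel))
        if n_vox == 0:
            warnings.warn(f"region {name} has no voxels after masking", stacklevel=2)
            continue
        vs = vs_map[sel]
        vf = vf_map[sel]
        mean_vs = float(vs.mean())
        valid = vs > eps
        rows.append(
            {
                "region": name,
                "region_code": code,
                "n_voxels": n_vox,
                "mean_v_s": mean_vs,
                "mean_v_f": float(vf.mean()),
                "mean_v_t": float((vs + vf).mean()),
                "ratio_of_means_fs": float(vf.mean() / vs.mean()) if mean_vs > eps else np.nan,
                "mean_voxel_ratio_fs": float((vf[valid] / vs[valid]).mean()) if valid.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
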