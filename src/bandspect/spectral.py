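"""Bandpass spectral analysis of dynamic PET time-activity curves.

A tissue TAC is modelled as a non-negative sum of the parent plasma input
function convolved with exponentials exp(-beta_j t) on a fixed frequency
grid. The fitted spectrum is partitioned by frequency band: the slow band
(0.00063-0.00137 s^-1) captures slow-kinetic binding (V_S) and the fast
band (0.00137-0.1 s^-1) the fast-kinetic component (V_F); each band's
volume of distribution is the sum of alpha_j / beta_j over its grid points.
The default grid tiles exactly the union of the two bands, so
V_T = V_S + V_F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.optimize import nnls
from scipy.signal import fftconvolve

from bandspect.input_function import InputFunction
from bandspect.schedule import FrameSchedule

SLOW_BAND = (0.00063, 0.00137)
FAST_BAND = (0.00137, 0.1)

__all__ = [
    "SLOW_BAND",
    "FAST_BAND",
    "BetaGrid",
    "SpectralBasis",
    "SpectralFit",
    "VolumeComponents",
    "ParametricMaps",
    "summation_image",
    "brain_mask",
    "make_basis",
    "fit_tac",
    "band_volumes",
    "quantify_image",
    "global_value",
]


@dataclass(frozen=True)
class BetaGrid:
    """Log-spaced frequency grid with the slow/fast band partition.

    The boundary frequency 0.00137 s^-1 belongs to the fast band: the slow
    band is the half-open interval [0.00063, 0.00137).
    """

    betas: np.ndarray
    band_slow: tuple[float, float] = SLOW_BAND
    band_fast: tuple[float, float] = FAST_BAND

    def __post_init__(self) -> None:
        betas = np.asarray(self.betas, dtype=float)
        object.__setattr__(self, "betas", betas)
        if np.any(np.diff(betas) <= 0):
            raise ValueError("betas must be strictly increasing")
        if np.any(betas <= 0):
            raise ValueError("betas must be positive")

    @classmethod
    def default(cls, n: int = 120) -> "BetaGrid":
        """n log-spaced points spanning exactly [0.00063, 0.1] s^-1."""
        return cls(np.geomspace(SLOW_BAND[0], FAST_BAND[1], n))

    @property
    def slow_index(self) -> np.ndarray:
        lo, hi = self.band_slow
        return (self.betas >= lo) & (self.betas < hi)

    @property
    def fast_index(self) -> np.ndarray:
        lo, hi = self.band_fast
        return (self.betas >= lo) & (self.betas <= hi)


@dataclass
class SpectralBasis:
    """Frame-averaged convolution of the input function with each exp(-beta t)."""

    matrix: np.ndarray  # n_frames x n_betas
    grid: BetaGrid
    schedule: FrameSchedule


@dataclass
class SpectralFit:
    """Non-negative spectral coefficients for one TAC."""

    alphas: np.ndarray
    residual_rss: float
    fitted: np.ndarray
    weights: np.ndarray


@dataclass(frozen=True)
class VolumeComponents:
    """Band-partitioned volumes of distribution (mL/cm^3)."""

    v_t: float
    v_s: float
    v_f: float

    def ratio_fs(self, eps: float = 1e-9) -> float:
        """V_F / V_S, defined only where V_S exceeds eps."""
        return self.v_f / self.v_s if self.v_s > eps else float("nan")


@dataclass
class ParametricMaps:
    """Voxel-wise V_T / V_S / V_F volumes with mask and geometry."""

    v_t: np.ndarray
    v_s: np.ndarray
    v_f: np.ndarray
    mask: np.ndarray
    voxel_size_mm: float
    lr_axis: int = 0
    extra: dict = field(default_factory=dict)

    def save(self, directory: str | Path, prefix: str = "") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        for name, vol in [
            ("vt", self.v_t), ("vs", self.v_s), ("vf", self.v_f),
            ("mask", self.mask.astype(np.uint8)),
        ]:
            nib.save(
                nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine),
                str(directory / f"{prefix}{name}.nii.gz"),
            )


def summation_image(dynamic: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Duration-weighted sum of all frames (an 'add' image)."""
    dynamic = np.asarray(dynamic, dtype=float)
    if dynamic.shape[-1] != schedule.n_frames:
        raise ValueError("frame count does not match schedule")
    return np.tensordot(dynamic, schedule.duration_s, axes=([-1], [0]))


def brain_mask(sum_image: np.ndarray, percentile: float = 5.0) -> np.ndarray:
    """Binary mask omitting the lowest-signal voxels of a summation image.

    The threshold is the given percentile of the positive-valued voxel
    distribution; voxels strictly above it are retained. Tie rule: if the
    strict cut would omit more than the requested fraction (values tied at
    the threshold, e.g. a uniform image), the tied voxels are kept.
    """
    sum_image = np.asarray(sum_image, dtype=float)
    positive = sum_image > 0
    if not np.any(positive):
        raise ValueError("summation image has no positive voxels")
    vals = sum_image[positive]
    thr = np.percentile(vals, percentile)
    omitted = np.count_nonzero(vals <= thr)
    if omitted > percentile / 100.0 * vals.size:
        return sum_image >= thr
    return sum_image > thr


def make_basis(
    input_fn: InputFunction, schedule: FrameSchedule, grid: BetaGrid | None = None
) -> SpectralBasis:
    """Build the spectral basis matrix on the input function's 1 s grid.

    Column j holds the frame averages of the trapezoidal convolution of the
    parent plasma curve with exp(-beta_j t).
    """
    if grid is None:
        grid = BetaGrid.default()
    t = input_fn.time_s
    cp = input_fn.parent_plasma
    scan_end = float(schedule.end_s[-1])
    if t[-1] < scan_end - 1e-9:
        raise ValueError("input function does not cover the scan duration")
    dt = input_fn.dt
    n = t.size
    cols = []
    starts = np.rint(schedule.start_s / dt).astype(int)
    ends = np.rint(schedule.end_s / dt).astype(int)
    for beta in grid.betas:
        kernel = np.exp(-beta * (t - t[0]))
        conv = fftconvolve(cp, kernel)[:n] * dt
        # trapezoid endpoint correction for the discrete convolution sum
        conv -= 0.5 * dt * (cp[0] * kernel + cp * kernel[0])
        conv = np.clip(conv, 0.0, None)
        # frame averages via the cumulative trapezoid integral
        cum = np.concatenate([[0.0], np.cumsum((conv[1:] + conv[:-1]) * 0.5 * dt)])
        cols.append((cum[ends] - cum[starts]) / (schedule.duration_s))
    return SpectralBasis(np.column_stack(cols), grid, schedule)


def fit_tac(
    tac: np.ndarray, basis: SpectralBasis, weights: np.ndarray | None = None
) -> SpectralFit:
    """Weighted NNLS fit of one TAC onto the spectral basis.

    Default weights are the frame durations (approximate count-variance
    weighting for decay-corrected data).
    """
    tac = np.asarray(tac, dtype=float)
    if tac.size != basis.matrix.shape[0]:
        raise ValueError("TAC length does not match basis frame count")
    if np.any(~np.isfinite(tac)):
        raise ValueError("TAC contains non-finite values")
    if weights is None:
        weights = basis.schedule.duration_s
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    sw = np.sqrt(weights)
    alphas, rnorm = nnls(basis.matrix * sw[:, None], tac * sw)
    fitted = basis.matrix @ alphas
    return SpectralFit(alphas, float(rnorm**2), fitted, weights)


def band_volumes(fit: SpectralFit, grid: BetaGrid) -> VolumeComponents:
    """Partition a spectral fit into V_T / V_S / V_F via alpha_j / beta_j."""
    contrib = fit.alphas / grid.betas
    return VolumeComponents(
        v_t=float(contrib.sum()),
        v_s=float(contrib[grid.slow_index].sum()),
        v_f=float(contrib[grid.fast_index].sum()),
    )


def quantify_image(
    dynamic: np.ndarray,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    grid: BetaGrid | None = None,
    mask: np.ndarray | None = None,
    voxel_size_mm: float = 3.0,
    weights: np.ndarray | None = None,
) -> ParametricMaps:
    """Voxel-by-voxel spectral quantification of a 4D dynamic image."""
    dynamic = np.asarray(dynamic, dtype=float)
    if grid is None:
        grid = BetaGrid.default()
    if mask is None:
        mask = brain_mask(summation_image(dynamic, schedule))
    basis = make_basis(input_fn, schedule, grid)
    if weights is None:
        weights = schedule.duration_s
    shape = dynamic.shape[:-1]
    v_t = np.zeros(shape)
    v_s = np.zeros(shape)
    v_f = np.zeros(shape)
    inv_beta = 1.0 / grid.betas
    slow = grid.slow_index
    fast = grid.fast_index
    sw = np.sqrt(np.asarray(weights, float))
    bw = basis.matrix * sw[:, None]
    n_failures = 0
    idx = np.argwhere(mask)
    for i, j, k in idx:
        tac = dynamic[i, j, k]
        if not np.any(tac):
            continue
        try:
            alphas, _ = nnls(bw, tac * sw)
        except RuntimeError:  # pragma: no cover - NNLS non-convergence is rare
            n_failures += 1
            continue
        contrib = alphas * inv_beta
        v_t[i, j, k] = contrib.sum()
        v_s[i, j, k] = contrib[slow].sum()
        v_f[i, j, k] = contrib[fast].sum()
    if n_failures:
        warnings.warn(f"{n_failures} voxel fits failed to converge", stacklevel=2)
    return ParametricMaps(
        v_t, v_s, v_f, mask.astype(bool), voxel_size_mm,
        extra={"n_fit_failures": n_failures},
    )


def global_value(volume: np.ndarray, mask: np.ndarray) -> float:
    """Mean of a parametric map over a mask (e.g. the global total V_T)."""
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("mask is empty")
    return float(np.asarray(volume, dtype=float)[mask].mean())
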