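"""Metabolite-corrected parent plasma input functions from arterial blood data.

Continuous whole-blood monitoring covers the first 15 minutes; intermittent
discrete samples (whole blood, centrifuged plasma, and the chromatographic
parent fraction) cover the full scan. The plasma-over-blood ratio and the
parent-fraction curve are fitted to the discrete samples and applied to the
continuous segment; beyond it, the parent plasma curve is interpolated
through the discrete parent-plasma values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from bandspect._models import hill_parent_fraction, pob_model
from bandspect.schedule import FrameSchedule

__all__ = [
    "BloodData",
    "InputFunction",
    "fit_pob",
    "fit_parent_fraction",
    "build_input",
]


@dataclass
class BloodData:
    """Arterial blood measurements for one scan.

    ``continuous`` holds the detector whole-blood curve on a ~1 s grid
    (kBq/mL); ``discrete`` holds the manual samples with columns
    ``time_s``, ``whole_blood``, ``plasma``, ``parent_fraction`` (the
    baseline row has time_s < 0 and zero activity).
    """

    continuous_time_s: np.ndarray
    continuous_whole_blood: np.ndarray
    discrete: pd.DataFrame

    def __post_init__(self) -> None:
        t = np.asarray(self.continuous_time_s, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("continuous times must be strictly increasing")
        ts = self.discrete["time_s"].to_numpy(float)
        if np.any(np.diff(ts) <= 0):
            raise ValueError("discrete sample times must be strictly increasing")
        pf = self.discrete["parent_fraction"].to_numpy(float)
        ok = np.isfinite(pf)
        if np.any((pf[ok] < 0) | (pf[ok] > 1)):
            raise ValueError("parent fractions must lie in [0, 1]")

    @property
    def post_injection(self) -> pd.DataFrame:
        """Discrete samples taken after injection (time_s >= 0)."""
        return self.discrete[self.discrete["time_s"] >= 0]

    def to_csv(self, continuous_path: str | Path, discrete_path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.continuous_time_s,
                "activity_kBq_per_mL": self.continuous_whole_blood,
            }
        ).to_csv(continuous_path, index=False)
        self.discrete.to_csv(discrete_path, index=False)

    @classmethod
    def from_csv(
        cls, continuous_path: str | Path, discrete_path: str | Path
    ) -> "BloodData":
        cont = pd.read_csv(continuous_path)
        disc = pd.read_csv(discrete_path)
        return cls(
            cont["time_s"].to_numpy(float),
            cont["activity_kBq_per_mL"].to_numpy(float),
            disc,
        )


@dataclass
class InputFunction:
    """Metabolite-corrected parent plasma activity on a fine (1 s) time grid."""

    time_s: np.ndarray
    parent_plasma: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.parent_plasma = np.asarray(self.parent_plasma, dtype=float)
        if self.time_s.shape != self.parent_plasma.shape:
            raise ValueError("time and activity grids must match")
        if np.any(self.parent_plasma < 0):
            raise ValueError("parent plasma activity must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.time_s, self.parent_plasma, left=0.0, right=0.0)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time_s, "parent_plasma_activity": self.parent_plasma}
        ).to_csv(path, index=False)

    def write_fit_report(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "InputFunction":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(float), df["parent_plasma_activity"].to_numpy(float)
        )


def fit_pob(discrete: pd.DataFrame) -> tuple[dict, Callable[[np.ndarray], np.ndarray]]:
    """Fit the plasma-over-blood ratio curve to the discrete samples.

    Least-squares fit of ``pob0 + amp * (1 - exp(-rate t))`` to the
    plasma/whole-blood ratios of all post-injection samples with both
    activities positive. Returns the parameter record and an evaluator.
    """
    d = discrete[discrete["time_s"] >= 0]
    wb = d["whole_blood"].to_numpy(float)
    pl = d["plasma"].to_numpy(float)
    if np.any(wb <= 0) or np.any(pl <= 0):
        raise ValueError("plasma and whole-blood activities must be positive")
    t = d["time_s"].to_numpy(float)
    if t.size < 3:
        raise ValueError("need at least 3 discrete samples to fit the POB curve")
    ratio = pl / wb
    if np.allclose(ratio, ratio[0]):
        warnings.warn("all POB ratios equal; amplitude pinned to 0", stacklevel=2)
        params = {"pob0": float(ratio[0]), "amp": 0.0, "rate": 1e-3}
    else:
        p0 = (float(ratio[0]), float(ratio[-1] - ratio[0]), 1e-3)
        popt, _ = curve_fit(
            pob_model, t, ratio, p0=p0,
            bounds=([0.0, -2.0, 1e-7], [5.0, 5.0, 1.0]), maxfev=20000,
        )
        params = {"pob0": float(popt[0]), "amp": float(popt[1]), "rate": float(popt[2])}

    def evaluator(tt: np.ndarray) -> np.ndarray:
        return pob_model(tt, **params)

    return params, evaluator


def fit_parent_fraction(
    discrete: pd.DataFrame,
) -> tuple[dict, Callable[[np.ndarray], np.ndarray]]:
    """Fit the Hill-type parent-fraction curve to the chromatography samples.

    The evaluator is clipped to [0, 1] and is monotone non-increasing in
    time by construction of the Hill form.
    """
    d = discrete[(discrete["time_s"] >= 0) & discrete["parent_fraction"].notna()]
    t = d["time_s"].to_numpy(float)
    pf = d["parent_fraction"].to_numpy(float)
    if t.size < 4:
        raise ValueError("need at least 4 parent-fraction samples")
    if np.any((pf < 0) | (pf > 1)):
        raise ValueError("parent fractions must lie in [0, 1]")
    if np.allclose(pf, 1.0):
        params = {"floor": 1.0, "t50_s": 1e3, "hill": 1.0}
    else:
        p0 = (max(float(pf.min()) * 0.9, 1e-3), float(np.median(t)), 1.5)
        popt, _ = curve_fit(
            hill_parent_fraction, t, pf, p0=p0,
            bounds=([0.0, 1.0, 0.1], [1.0, 1e5, 10.0]), maxfev=20000,
        )
        params = {"floor": float(popt[0]), "t50_s": float(popt[1]), "hill": float(popt[2])}

    def evaluator(tt: np.ndarray) -> np.ndarray:
        return np.clip(hill_parent_fraction(tt, **params), 0.0, 1.0)

    return params, evaluator


def detect_bolus_arrival(time_s: np.ndarray, activity: np.ndarray) -> float:
    """First time the continuous curve exceeds 5% of its peak."""
    peak = float(np.max(activity))
    if peak <= 0:
        return float(time_s[0])
    idx = int(np.argmax(activity > 0.05 * peak))
    return float(time_s[idx])


def build_input(
    blood: BloodData,
    pob: Callable[[np.ndarray], np.ndarray],
    pf: Callable[[np.ndarray], np.ndarray],
    schedule: FrameSchedule,
    tail_interpolation: str = "log",
    pob_params: dict | None = None,
    pf_params: dict | None = None,
) -> InputFunction:
    """Assemble the parent plasma input function for the full scan.

    Over the continuously monitored segment, parent plasma is
    ``whole_blood(t) * POB(t) * pf(t)``. Beyond it, the curve is
    interpolated through the discrete parent-plasma values
    (plasma x parent_fraction), linearly in log-activity by default to
    avoid negative undershoot (set ``tail_interpolation='linear'`` for
    plain linear interpolation). The result is resampled to a 1 s grid
    covering the scan.
    """
    ct = np.asarray(blood.continuous_time_s, float)
    cwb = np.asarray(blood.continuous_whole_blood, float)
    scan_end = float(schedule.end_s[-1])
    cont_end = float(ct[-1])
    post = blood.post_injection
    late = post[post["time_s"] > cont_end]
    if np.all(cwb == 0):
        warnings.warn("all-zero whole-blood curve; input function is zero", stacklevel=2)
        grid = np.arange(0.0, scan_end + 1.0)
        return InputFunction(grid, np.zeros_like(grid))
    if len(late) < 2:
        raise ValueError("need at least 2 discrete samples after the continuous segment")

    grid = np.arange(0.0, scan_end + 1.0)

    # continuous segment: whole blood converted to parent plasma
    cont_pp = cwb * pob(ct) * pf(ct)

    # tail anchors: last continuous value + discrete parent plasma
    anchor_t = np.concatenate([[cont_end], late["time_s"].to_numpy(float)])
    anchor_v = np.concatenate(
        [
            [float(np.interp(cont_end, ct, cont_pp))],
            late["plasma"].to_numpy(float) * late["parent_fraction"].to_numpy(float),
        ]
    )

    early = grid <= cont_end
    values = np.empty_like(grid)
    values[early] = np.interp(grid[early], ct, cont_pp)
    tail_grid = grid[~early]
    if tail_interpolation == "log" and np.all(anchor_v > 0):
        values[~early] = np.exp(
            np.interp(tail_grid, anchor_t, np.log(anchor_v))
        )
    else:
        values[~early] = np.interp(tail_grid, anchor_t, anchor_v)

    if np.any(values < 0):
        warnings.warn("negative interpolated input values clipped to 0", stacklevel=2)
        values = np.clip(values, 0.0, None)

    provenance = {
        "pob": pob_params or {},
        "parent_fraction": pf_params or {},
        "tail_interpolation": tail_interpolation,
        "bolus_arrival_s": detect_bolus_arrival(ct, cwb),
        "continuous_end_s": cont_end,
    }
    return InputFunction(grid, values, provenance)


def build_input_from_blood(
    blood: BloodData, schedule: FrameSchedule, **kwargs
) -> InputFunction:
    """Convenience wrapper: fit POB and parent fraction, then build the input."""
    pob_params, pob = fit_pob(blood.discrete)
    pf_params, pf = fit_parent_fraction(blood.discrete)
    return build_input(
        blood, pob, pf, schedule, pob_params=pob_params, pf_params=pf_params, **kwargs
    )
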