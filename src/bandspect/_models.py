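"""Parametric curve forms shared by the blood-data generator and the fitters.

The plasma-over-blood (POB) ratio and parent-fraction forms are declared
stand-ins: the exact models used clinically for this tracer family live in
site-specific pipelines, so the generator and the input-function fitter use
the same forms here, making round-trip validation exact.
"""

from __future__ import annotations

import numpy as np


def pob_model(t: np.ndarray, pob0: float, amp: float, rate: float) -> np.ndarray:
    """Plasma-over-blood ratio: pob0 + amp * (1 - exp(-rate * t))."""
    t = np.asarray(t, dtype=float)
    return pob0 + amp * (1.0 - np.exp(-rate * np.clip(t, 0.0, None)))


def hill_parent_fraction(
    t: np.ndarray, floor: float, t50_s: float, hill: float
) -> np.ndarray:
    """Hill-type parent fraction: (1 - floor) / (1 + (t/t50)^h) + floor.

    Monotone non-increasing in t, equal to 1 at t = 0 and approaching
    ``floor`` as t -> inf; always within [floor, 1] for floor in [0, 1].
    """
    t = np.asarray(t, dtype=float)
    ratio = np.clip(t, 0.0, None) / float(t50_s)
    return (1.0 - floor) / (1.0 + ratio**hill) + floor


def whole_blood_model(
    t: np.ndarray,
    bolus_arrival_s: float,
    rise_s: float,
    amplitudes: np.ndarray,
    rates: np.ndarray,
) -> np.ndarray:
    """Whole-blood activity: linear rise from bolus arrival to the peak over
    ``rise_s`` seconds, then a multi-exponential washout.

    The peak equals the sum of the washout amplitudes so the curve is
    continuous at the rise/decay junction; activity is zero before arrival.
    """
    t = np.asarray(t, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    rates = np.asarray(rates, dtype=float)
    tp = t - bolus_arrival_s
    peak = amplitudes.sum()
    out = np.zeros_like(t)
    rising = (tp >= 0) & (tp < rise_s)
    out[rising] = peak * tp[rising] / rise_s
    decaying = tp >= rise_s
    td = tp[decaying] - rise_s
    out[decaying] = np.sum(
        amplitudes[:, None] * np.exp(-rates[:, None] * td[None, :]), axis=0
    )
    return out
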