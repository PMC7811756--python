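"""Synthetic dynamic PET, blood and cohort generators.

Everything downstream of the scanner is testable without real data: this
module emulates a 90-minute, 24-frame bolus acquisition — whole-blood,
plasma-over-blood and parent-fraction curves; voxel time-activity curves
that are sums of exponential components convolved with the input function;
and a patient/control cohort carrying the effect structure of interest
(hippocampal slow-band increase, fast-band decrease, memory deficit and a
negative log-interictal-interval association).

The TAC integrator here is deliberately independent of the spectral
module's basis builder (0.1 s recursive trapezoidal evaluation versus 1 s
FFT convolution), so recovery tests exercise two discretizations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from bandspect._models import hill_parent_fraction, pob_model, whole_blood_model
from bandspect.input_function import BloodData, InputFunction
from bandspect.schedule import FrameSchedule, default_frame_schedule
from bandspect.spectral import FAST_BAND, SLOW_BAND

__all__ = [
    "BloodModelParams",
    "BloodSim",
    "Phantom",
    "CohortSpec",
    "CohortData",
    "default_phantom",
    "simulate_blood",
    "simulate_tac",
    "simulate_dynamic_image",
    "simulate_cohort",
    "truth_maps",
]

# phantom region codes
BACKGROUND = 0
CORTEX = 1
WHITE_MATTER = 2
HIPPOCAMPUS_LEFT = 3
HIPPOCAMPUS_RIGHT = 4
TEMPORAL_LEFT = 5
TEMPORAL_RIGHT = 6
INSULA = 7

REGION_NAMES = {
    CORTEX: "cortex",
    WHITE_MATTER: "white_matter",
    HIPPOCAMPUS_LEFT: "hippocampus_left",
    HIPPOCAMPUS_RIGHT: "hippocampus_right",
    TEMPORAL_LEFT: "temporal_left",
    TEMPORAL_RIGHT: "temporal_right",
    INSULA: "insula",
}

HIPPOCAMPUS_LABELS = (HIPPOCAMPUS_LEFT, HIPPOCAMPUS_RIGHT)

# default discrete arterial sampling times (s); baseline drawn before injection
DEFAULT_SAMPLE_TIMES_S = (120.0, 300.0, 600.0, 900.0, 1500.0, 2100.0,
                          2700.0, 3600.0, 4500.0, 5400.0)
BASELINE_TIME_S = -60.0


@dataclass(frozen=True)
class BloodModelParams:
    """Ground-truth arterial model: linear rise to the peak after bolus
    arrival, triple-exponential whole-blood washout, saturating
    plasma-over-blood ratio and Hill-type parent-fraction decline."""

    bolus_arrival_s: float = 30.0
    rise_s: float = 30.0
    wb_amplitudes: tuple[float, ...] = (30.0, 8.0, 4.0)  # kBq/mL
    wb_rates: tuple[float, ...] = (0.01, 0.0008, 0.0001)  # s^-1
    pob0: float = 1.0
    pob_amp: float = 0.3
    pob_rate: float = 0.002  # s^-1
    pf_floor: float = 0.1
    pf_t50_s: float = 900.0
    pf_hill: float = 1.5

    def __post_init__(self) -> None:
        if self.bolus_arrival_s < 0:
            raise ValueError("bolus arrival must be >= 0")
        if any(r <= 0 for r in self.wb_rates) or self.pob_rate <= 0:
            raise ValueError("all rates must be positive")
        if not 0.0 <= self.pf_floor <= 1.0:
            raise ValueError("pf_floor must lie in [0, 1]")

    def whole_blood(self, t: np.ndarray) -> np.ndarray:
        return whole_blood_model(
            t, self.bolus_arrival_s, self.rise_s,
            np.asarray(self.wb_amplitudes), np.asarray(self.wb_rates),
        )

    def pob(self, t: np.ndarray) -> np.ndarray:
        return pob_model(t, self.pob0, self.pob_amp, self.pob_rate)

    def parent_fraction(self, t: np.ndarray) -> np.ndarray:
        return hill_parent_fraction(t, self.pf_floor, self.pf_t50_s, self.pf_hill)

    def parent_plasma(self, t: np.ndarray) -> np.ndarray:
        return self.whole_blood(t) * self.pob(t) * self.parent_fraction(t)


@dataclass
class BloodSim:
    """Noisy blood observations plus the retained noiseless truth."""

    blood: BloodData
    true_continuous: np.ndarray
    true_parent_plasma: InputFunction
    params: BloodModelParams


def simulate_blood(
    params: BloodModelParams,
    schedule: FrameSchedule,
    noise_sd: float = 0.0,
    seed: int | None = None,
    sample_times_s: tuple[float, ...] = DEFAULT_SAMPLE_TIMES_S,
) -> BloodSim:
    """Simulate continuous whole-blood monitoring (0-900 s, 1 s grid) and
    discrete samples, with fractional Gaussian noise of SD ``noise_sd``."""
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    scan_end = float(schedule.end_s[-1])

    cont_t = np.arange(0.0, 901.0)
    cont_true = params.whole_blood(cont_t)
    cont_obs = cont_true * (1.0 + noise_sd * rng.standard_normal(cont_t.size))
    cont_obs = np.clip(cont_obs, 0.0, None)

    st = np.asarray(sample_times_s, dtype=float)
    wb = params.whole_blood(st)
    plasma = wb * params.pob(st)
    pf = params.parent_fraction(st)
    wb_obs = np.clip(wb * (1 + noise_sd * rng.standard_normal(st.size)), 0, None)
    pl_obs = np.clip(plasma * (1 + noise_sd * rng.standard_normal(st.size)), 0, None)
    pf_obs = np.clip(pf * (1 + noise_sd * rng.standard_normal(st.size)), 0.0, 1.0)

    discrete = pd.DataFrame(
        {
            "time_s": np.concatenate([[BASELINE_TIME_S], st]),
            "whole_blood": np.concatenate([[0.0], wb_obs]),
            "plasma": np.concatenate([[0.0], pl_obs]),
            "parent_fraction": np.concatenate([[np.nan], pf_obs]),
        }
    )
    blood = BloodData(cont_t, cont_obs, discrete)

    truth_t = np.arange(0.0, scan_end + 1.0)
    truth = InputFunction(truth_t, params.parent_plasma(truth_t))
    return BloodSim(blood, cont_true, truth, params)


def _exp_conv_trapezoid(cp: np.ndarray, dt: float, beta: float) -> np.ndarray:
    """Trapezoidal-rule convolution of a sampled curve with exp(-beta t),
    evaluated recursively (exact trapezoid, O(n))."""
    a = math.exp(-beta * dt)
    return lfilter([dt / 2.0, dt / 2.0 * a], [1.0, -a], cp)


def simulate_tac(
    input_fn: InputFunction,
    components: list[tuple[float, float]],
    schedule: FrameSchedule,
    dt: float = 0.1,
) -> np.ndarray:
    """Noiseless frame-averaged TAC of sum_j alpha_j * (C_p (x) exp(-beta_j t)).

    Evaluated on a fine 0.1 s grid with trapezoidal integration, independent
    of the spectral basis builder.
    """
    scan_end = float(schedule.end_s[-1])
    t = np.arange(0.0, scan_end + dt / 2, dt)
    cp = input_fn(t)
    model = np.zeros_like(t)
    for alpha, beta in components:
        if beta <= 0:
            raise ValueError("beta must be positive")
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        model += alpha * _exp_conv_trapezoid(cp, dt, beta)
    cum = np.concatenate([[0.0], np.cumsum((model[1:] + model[:-1]) * 0.5 * dt)])
    starts = np.rint(schedule.start_s / dt).astype(int)
    ends = np.rint(schedule.end_s / dt).astype(int)
    return (cum[ends] - cum[starts]) / schedule.duration_s


@dataclass
class Phantom:
    """Digital brain phantom in a common (already 'normalized') space.

    ``kinetics`` maps each region code to its list of (alpha, beta)
    components; ground-truth band volumes follow as sum(alpha/beta) over
    components whose beta falls in each band.
    """

    labels: np.ndarray
    voxel_size_mm: float
    kinetics: dict[int, list[tuple[float, float]]]
    region_names: dict[int, str] = field(default_factory=lambda: dict(REGION_NAMES))
    lr_axis: int = 0  # lower index = left

    def region_voxels(self, code: int) -> np.ndarray:
        return self.labels == code

    @property
    def brain(self) -> np.ndarray:
        return self.labels > 0


DEFAULT_KINETICS: dict[int, list[tuple[float, float]]] = {
    # (alpha [s^-1-scaled amplitude], beta [s^-1]); V = alpha / beta
    CORTEX: [(0.0015, 0.001), (0.030, 0.01)],            # V_S 1.5, V_F 3.0
    WHITE_MATTER: [(0.0008, 0.001), (0.012, 0.01)],      # V_S 0.8, V_F 1.2
    HIPPOCAMPUS_LEFT: [(0.0050, 0.001), (0.017, 0.01)],  # V_S 5.0, V_F 1.7
    HIPPOCAMPUS_RIGHT: [(0.0050, 0.001), (0.017, 0.01)],
    TEMPORAL_LEFT: [(0.0025, 0.001), (0.028, 0.01)],
    TEMPORAL_RIGHT: [(0.0025, 0.001), (0.028, 0.01)],
    INSULA: [(0.0022, 0.001), (0.026, 0.01)],
}


def default_phantom(
    shape: tuple[int, int, int] = (40, 48, 40), voxel_size_mm: float = 3.0
) -> Phantom:
    """Geometric brain phantom: cortical ellipsoid, inner white matter, and
    bilateral hippocampal, temporal and insular regions."""
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        (np.arange(nx) - (nx - 1) / 2) / (nx / 2),
        (np.arange(ny) - (ny - 1) / 2) / (ny / 2),
        (np.arange(nz) - (nz - 1) / 2) / (nz / 2),
        indexing="ij",
    )
    labels = np.zeros(shape, dtype=np.int16)
    r2 = x**2 + y**2 + z**2
    labels[r2 <= 0.81] = CORTEX
    labels[(x**2 + y**2 + z**2) <= 0.30] = WHITE_MATTER

    def sphere(cx, cy, cz, radius):
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius**2

    hip_r = max(0.16, 2.0 / (nx / 2))  # at least ~2 voxels radius
    labels[sphere(-0.42, -0.10, -0.25, hip_r) & (labels > 0)] = HIPPOCAMPUS_LEFT
    labels[sphere(+0.42, -0.10, -0.25, hip_r) & (labels > 0)] = HIPPOCAMPUS_RIGHT

    temporal = (np.abs(x) > 0.55) & (z < -0.15) & (np.abs(y) < 0.45) & (labels == CORTEX)
    labels[temporal & (x < 0)] = TEMPORAL_LEFT
    labels[temporal & (x > 0)] = TEMPORAL_RIGHT

    insula = (np.abs(np.abs(x) - 0.30) < 0.08) & (np.abs(y) < 0.2) & (np.abs(z) < 0.15)
    labels[insula & (labels == CORTEX)] = INSULA

    return Phantom(labels, voxel_size_mm, {k: list(v) for k, v in DEFAULT_KINETICS.items()})


def _band_volume(components: list[tuple[float, float]], band: tuple[float, float],
                 closed_right: bool) -> float:
    lo, hi = band
    total = 0.0
    for alpha, beta in components:
        inside = lo <= beta < hi or (closed_right and beta == hi)
        if inside:
            total += alpha / beta
    return total


def truth_volumes(components: list[tuple[float, float]]) -> tuple[float, float, float]:
    """(V_T, V_S, V_F) of a component list under the printed band edges."""
    v_s = _band_volume(components, SLOW_BAND, closed_right=False)
    v_f = _band_volume(components, FAST_BAND, closed_right=True)
    v_t = sum(a / b for a, b in components)
    return v_t, v_s, v_f


def truth_maps(
    phantom: Phantom, kinetics: dict[int, list[tuple[float, float]]] | None = None
) -> dict[str, np.ndarray]:
    """Ground-truth V_T / V_S / V_F volumes from region kinetics."""
    kin = kinetics if kinetics is not None else phantom.kinetics
    out = {k: np.zeros(phantom.labels.shape) for k in ("v_t", "v_s", "v_f")}
    for code, comps in kin.items():
        sel = phantom.labels == code
        v_t, v_s, v_f = truth_volumes(comps)
        out["v_t"][sel] = v_t
        out["v_s"][sel] = v_s
        out["v_f"][sel] = v_f
    return out


def simulate_dynamic_image(
    phantom: Phantom,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    noise_scale: float = 0.0,
    seed: int | None = None,
    kinetics: dict[int, list[tuple[float, float]]] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """4D dynamic image with count-like Gaussian noise plus truth maps.

    Voxel noise is zero-mean Gaussian with
    SD = noise_scale * sqrt(max(TAC_i, eps) / duration_i), emulating the
    count-statistics scaling of decay-corrected reconstructions.
    """
    kin = kinetics if kinetics is not None else phantom.kinetics
    shape = phantom.labels.shape
    dyn = np.zeros(shape + (schedule.n_frames,))
    for code, comps in kin.items():
        sel = phantom.labels == code
        if not np.any(sel):
            continue
        dyn[sel] = simulate_tac(input_fn, comps, schedule)
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        sd = noise_scale * np.sqrt(
            np.maximum(dyn, 1e-12) / schedule.duration_s
        )
        sd[phantom.labels == BACKGROUND] = 0.0
        dyn = dyn + sd * rng.standard_normal(dyn.shape)
    return dyn, truth_maps(phantom, kin)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated patient/control cohort."""

    n_tle: int = 11
    n_control: int = 23
    hippocampal_vs_increase_ipsi: float = 0.24
    hippocampal_vs_increase_contra: float = 0.26
    vf_decrease_ipsi: float = 0.22
    memory_effect_d: float = 1.2
    r_interictal: float = -0.77
    global_scale_cv: float = 0.12
    regional_cv: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tle < 1 or self.n_control < 2:
            raise ValueError("need n_tle >= 1 and n_control >= 2")
        if min(self.hippocampal_vs_increase_ipsi,
               self.hippocampal_vs_increase_contra,
               -self.vf_decrease_ipsi) <= -1:
            raise ValueError("fractional effects must exceed -1")
        if abs(self.r_interictal) >= 1:
            raise ValueError("|r_interictal| must be < 1")


@dataclass
class CohortData:
    """Simulated cohort: covariate table, ground truth and (optional) maps."""

    table: pd.DataFrame
    truth_regional: pd.DataFrame
    subject_kinetics: dict[str, dict[int, list[tuple[float, float]]]]
    phantom: Phantom
    schedule: FrameSchedule
    vs_maps: dict[str, np.ndarray] = field(default_factory=dict)
    vf_maps: dict[str, np.ndarray] = field(default_factory=dict)
    truth_vs_maps: dict[str, np.ndarray] = field(default_factory=dict)
    truth_vf_maps: dict[str, np.ndarray] = field(default_factory=dict)
    regional_tacs: dict[str, pd.DataFrame] = field(default_factory=dict)


# memory subtests: (name, healthy mean, SD, max score)
MEMORY_SUBTESTS = [
    ("list_learning", 57.0, 9.3, 75.0),
    ("list_recall", 12.0, 2.9, 15.0),
    ("figure_learning", 39.0, 12.2, 45.0),
    ("figure_recall", 8.0, 2.9, 9.0),
]


def _exact_correlation_noise(z: np.ndarray, r: float, rng) -> np.ndarray:
    """Standard-normal-scale vector whose *sample* correlation with z is
    exactly r (Gram-Schmidt construction); needs len(z) >= 3."""
    zc = (z - z.mean()) / z.std()
    e = rng.standard_normal(z.size)
    e = e - e.mean()
    e = e - (e @ zc) / (zc @ zc) * zc  # orthogonal to z in sample
    e /= e.std()
    return r * zc + math.sqrt(1 - r**2) * e


def simulate_cohort(
    spec: CohortSpec,
    phantom: Phantom | None = None,
    schedule: FrameSchedule | None = None,
    mode: str = "maps",
    input_fn: InputFunction | None = None,
    map_noise_cv: float = 0.10,
) -> CohortData:
    """Simulate a TLE/control cohort with the configured effect structure.

    ``mode`` selects the imaging payload: ``"maps"`` synthesises noisy
    per-subject V_S / V_F maps directly from the ground-truth kinetics
    (desk-scale; used for group inference), ``"tacs"`` produces noiseless
    regional TACs (requires ``input_fn``), and ``"none"`` yields only the
    covariate table and ground truth.

    Patients' hippocampal slow-band amplitudes are scaled up ipsi- and
    contralaterally; ipsilateral fast-band amplitudes scaled down;
    right-lateralized patients have the effects mirrored. The interictal
    interval is generated so that ln(interval) has exactly the target
    sample correlation with the patients' ground-truth global V_S.
    """
    if phantom is None:
        phantom = default_phantom()
    if schedule is None:
        schedule = default_frame_schedule()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_tle + spec.n_control
    groups = ["tle"] * spec.n_tle + ["control"] * spec.n_control
    n_right = spec.n_tle // 2
    lateralization = (
        ["left"] * (spec.n_tle - n_right) + ["right"] * n_right + [""] * spec.n_control
    )
    ids = [f"TLE{i+1:02d}" for i in range(spec.n_tle)] + [
        f"CTRL{i+1:02d}" for i in range(spec.n_control)
    ]

    ages = np.concatenate(
        [
            np.clip(rng.normal(43.0, 8.0, spec.n_tle), 20, 70),
            np.clip(rng.normal(49.0, 9.0, spec.n_control), 20, 70),
        ]
    )
    sexes = ["M" if rng.random() > 4 / 11 else "F" for _ in range(spec.n_tle)] + [
        "M"
    ] * spec.n_control

    g = np.exp(rng.normal(0.0, spec.global_scale_cv, n))  # global kinetic scale

    region_codes = sorted(phantom.kinetics)
    subject_kinetics: dict[str, dict[int, list[tuple[float, float]]]] = {}
    rows = []
    for i, sid in enumerate(ids):
        kin: dict[int, list[tuple[float, float]]] = {}
        reg_scatter = np.exp(rng.normal(0.0, spec.regional_cv, len(region_codes)))
        if groups[i] == "tle":
            ipsi, contra = (
                (HIPPOCAMPUS_LEFT, HIPPOCAMPUS_RIGHT)
                if lateralization[i] == "left"
                else (HIPPOCAMPUS_RIGHT, HIPPOCAMPUS_LEFT)
            )
            slow_mult = {
                ipsi: 1.0 + spec.hippocampal_vs_increase_ipsi,
                contra: 1.0 + spec.hippocampal_vs_increase_contra,
            }
            fast_mult = {ipsi: 1.0 - spec.vf_decrease_ipsi}
        else:
            slow_mult, fast_mult = {}, {}
        for j, code in enumerate(region_codes):
            comps = []
            for alpha, beta in phantom.kinetics[code]:
                m = g[i] * reg_scatter[j]
                if beta < SLOW_BAND[1]:
                    m *= slow_mult.get(code, 1.0)
                else:
                    m *= fast_mult.get(code, 1.0)
                comps.append((alpha * m, beta))
            kin[code] = comps
        subject_kinetics[sid] = kin
        for code in region_codes:
            v_t, v_s, v_f = truth_volumes(kin[code])
            rows.append(
                {
                    "subject": sid,
                    "region": phantom.region_names.get(code, str(code)),
                    "region_code": code,
                    "v_t": v_t,
                    "v_s": v_s,
                    "v_f": v_f,
                }
            )
    truth_regional = pd.DataFrame(rows)

    # ground-truth global values (label-weighted over the brain)
    counts = {
        code: int(np.count_nonzero(phantom.labels == code)) for code in region_codes
    }
    total = sum(counts.values())
    glob = truth_regional.assign(
        w=lambda d: d["region_code"].map(counts) / total
    )
    global_vt = glob.groupby("subject").apply(
        lambda d: float((d["v_t"] * d["w"]).sum()), include_groups=False
    )
    global_vs = glob.groupby("subject").apply(
        lambda d: float((d["v_s"] * d["w"]).sum()), include_groups=False
    )

    # memory subtests: healthy mean minus d*SD for patients, small age slope
    mem = {}
    factor = rng.standard_normal(n)
    is_tle = np.array([grp == "tle" for grp in groups])
    for name, mu, sd, max_score in MEMORY_SUBTESTS:
        noise = rng.standard_normal(n)
        score = (
            mu
            - spec.memory_effect_d * sd * is_tle
            - 0.03 * sd * (ages - 45.0)
            + sd * (math.sqrt(0.5) * factor + math.sqrt(0.5) * noise)
        )
        mem[name] = np.clip(score, 0.0, max_score)

    # interictal interval: ln(days) anti-correlated with global V_S in patients
    interictal = np.full(n, np.nan)
    if spec.n_tle >= 3:
        z_vs = global_vs.loc[ids[: spec.n_tle]].to_numpy()
        ln_ii = 1.8 + 1.6 * _exact_correlation_noise(z_vs, spec.r_interictal, rng)
        interictal[: spec.n_tle] = np.exp(ln_ii)
    elif spec.n_tle >= 1:
        interictal[: spec.n_tle] = np.exp(rng.normal(1.8, 1.6, spec.n_tle))

    duration = np.full(n, np.nan)
    duration[: spec.n_tle] = np.exp(rng.normal(math.log(20.0), 0.6, spec.n_tle))

    hv_mu = np.where(is_tle, 2000.0, 1750.0)
    hv_left = rng.normal(hv_mu, 300.0)
    hv_right = rng.normal(hv_mu + 100.0, 300.0)

    table = pd.DataFrame(
        {
            "subject": ids,
            "group": groups,
            "age": ages,
            "sex": sexes,
            "lateralization": lateralization,
            "interictal_interval_days": interictal,
            "epilepsy_duration_years": duration,
            **mem,
            "hippocampal_volume_left_mm3": hv_left,
            "hippocampal_volume_right_mm3": hv_right,
            "global_total_vt": global_vt.loc[ids].to_numpy(),
            "global_vs_truth": global_vs.loc[ids].to_numpy(),
        }
    )

    data = CohortData(table, truth_regional, subject_kinetics, phantom, schedule)

    if mode == "maps":
        for sid in ids:
            tm = truth_maps(phantom, subject_kinetics[sid])
            data.truth_vs_maps[sid] = tm["v_s"]
            data.truth_vf_maps[sid] = tm["v_f"]
            for key, store in (("v_s", data.vs_maps), ("v_f", data.vf_maps)):
                noisy = tm[key] * (
                    1.0 + map_noise_cv * rng.standard_normal(tm[key].shape)
                )
                noisy[phantom.labels == BACKGROUND] = 0.0
                store[sid] = np.clip(noisy, 0.0, None)
    elif mode == "tacs":
        if input_fn is None:
            raise ValueError("mode='tacs' requires an input function")
        for sid in ids:
            recs = {
                phantom.region_names.get(code, str(code)): simulate_tac(
                    input_fn, subject_kinetics[sid][code], schedule
                )
                for code in region_codes
            }
            data.regional_tacs[sid] = pd.DataFrame(recs)
    elif mode != "none":
        raise ValueError(f"unknown mode {mode!r}")
    return data
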