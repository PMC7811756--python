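# Methods

This note documents the models implemented in `bandspect`, their
assumptions, the parameter defaults (with units), and the numerical
choices. Nothing here is an empirical claim beyond what the package
itself computes.

## 1. Frame schedule

A `FrameSchedule` is a contiguous sequence of frames given by start times
and durations in seconds. The default schedule has 24 frames over 5400 s
(90 min): 4 × 30 s, 4 × 60 s, 4 × 120 s, 6 × 300 s, 6 × 460 s. Frame mid-
times are `start + duration/2`.

## 2. Input function

The metabolite-corrected parent plasma input function is assembled from
two blood data streams:

- a **continuous** whole-blood curve sampled at 1 Hz over the first
  900 s, and
- **discrete** samples (default times 120–5400 s, plus a pre-injection
  baseline at −60 s) with whole-blood activity, plasma activity and
  measured parent fraction.

Three sub-models are fitted to the discrete samples:

- **Plasma-over-blood ratio** `POB(t) = pob0 + amp·(1 − exp(−rate·t))`
  (dimensionless; rate in s⁻¹), fitted by least squares to the
  plasma/whole-blood ratios; requires ≥ 3 usable samples. If all ratios
  are equal the amplitude is pinned to 0 with a warning.
- **Parent fraction** `pf(t) = (1 − floor)/(1 + (t/t50)^h) + floor`
  (Hill function; t50 in s), fitted to the measured fractions; requires
  ≥ 4 samples; the evaluator is clipped to [0, 1].
- **Bolus arrival** is detected as the first continuous sample exceeding
  5% of the continuous peak.

The continuous segment of the input function is
`whole_blood(t) · POB(t) · pf(t)` on the 1 s grid over 0–900 s. Beyond
900 s the curve passes through the discrete parent-plasma values
(`plasma · pf`) with **log-linear interpolation** between anchors (PET
plasma curves decay near-exponentially, so interpolation is linear in
log-activity); at least two post-continuous discrete samples are
required. The assembled curve is resampled to a uniform 1 s grid over
the full scan.

## 3. Bandpass spectral analysis

### Model

`TAC(t) = Σⱼ αⱼ (C_p ⊗ e^(−βⱼ t))(t)` with αⱼ ≥ 0. The β grid is fixed:
default 120 logarithmically spaced points spanning **[0.00063, 0.1] s⁻¹**
inclusive. Bands:

- slow: β ∈ [0.00063, 0.00137) s⁻¹ → V_S = Σ αⱼ/βⱼ over slow j,
- fast: β ∈ [0.00137, 0.1] s⁻¹ → V_F likewise; the boundary value
  0.00137 belongs to the fast band.

Because the two bands tile the grid, V_T = V_S + V_F identically.

### Numerics

- Basis columns are built by FFT convolution of the 1 s input grid with
  `e^(−βt)`, with trapezoid endpoint correction, clipped at 0, then
  averaged over frames via a cumulative trapezoid integral.
- Fitting uses `scipy.optimize.nnls` on basis and TAC rows weighted by
  `sqrt(frame duration)` (longer frames carry proportionally more
  information under count-limited noise).
- The voxel loop (`quantify_image`) restricts to a brain mask. The
  default mask keeps voxels above the 5th percentile of the positive
  summation-image voxels using a strict `>` cut; if many identical
  values straddle the percentile so that `>` would omit more than the
  requested fraction, `>=` is used instead (tie rule — relevant when a
  large region is exactly uniform).

### Independence of generator and fitter

The synthetic generator integrates the same convolution model with a
**different integrator** (recursive trapezoidal exponential convolution
via `scipy.signal.lfilter` on a 0.1 s grid) so that recovery tests are
not self-fulfilling. Both are checked against a closed-form piecewise-
linear convolution oracle.

## 4. Synthetic data generator

### Blood

Whole blood is a linear rise over 30 s from bolus arrival (default 30 s
post-injection) followed by a triple exponential (default amplitudes
30, 8, 4 kBq/mL; rates 0.01, 0.0008, 0.0001 s⁻¹). POB and parent-
fraction truths use the same functional forms the fitters assume
(defaults: pob0 = 1.0, amp = 0.3, rate = 0.002 s⁻¹; floor = 0.1,
t50 = 900 s, h = 1.5), so round-trip tests measure estimation error
only. Optional multiplicative Gaussian noise (fractional SD) can be
applied to the sampled curves.

### Phantom

A geometric brain phantom (default 40×48×40 voxels, 3 mm isotropic):
cortical ellipsoid, inner white matter, bilateral hippocampal spheres,
temporal poles, insular ribbon. Default kinetics per region are
two-component (slow β = 0.001, fast β = 0.01 s⁻¹) with e.g. hippocampus
V_S = 5.0, V_F = 1.7 and cortex V_S = 1.5, V_F = 3.0. Dynamic images add
count-like frame noise with SD `noise_scale · sqrt(TAC/duration)`;
`noise_scale = 6` gives ≈ 10% median frame CV in cortex.

### Cohort

`simulate_cohort` generates 11 patients and 23 controls (configurable).
Patients receive a +24% ipsilateral and +26% contralateral hippocampal
V_S increase and a −22% ipsilateral V_F decrease (mirrored for
right-lateralized patients, n = n_tle // 2). Subject variability has two
levels: a global lognormal scale (CV 0.12) and per-region scatter
(CV 0.08). The regional scatter is deliberate: without it, adjusting for
global V_T would leave near-zero residual variance and the inference
problems would be degenerate. Interictal intervals are constructed so
that the **in-sample** Pearson correlation of ln(interval) with global
V_S is exactly the target (default −0.77) via a Gram–Schmidt step; an
in-expectation construction would be biased ~0.015 toward zero at
n = 11, making round-trip tests ambiguous. Memory subtests get a group
shift of d = 1.2 plus an age slope. The default "maps" mode synthesises
per-subject V_S/V_F maps from ground-truth kinetics with multiplicative
voxel noise (CV 0.10) instead of running 34 full dynamic simulations.

## 5. Preprocessing

- Right-lateralized subjects are mirrored along the left–right axis so
  all "ipsilateral" sides align; a matching utility flips a seeded
  random subset of controls (proportional to the flipped-patient
  fraction, e.g. 10 of 23).
- Gaussian smoothing converts FWHM (mm) to σ (voxels) as
  `FWHM / (voxel · 2.3548)`; masked smoothing renormalizes by the
  smoothed mask so means inside the mask are preserved.
- `ratio_map` computes V_F/V_S where V_S exceeds a small epsilon, else 0.
- `region_summary` tabulates per-region means; a cluster mask restricts
  each region to its **intersection** with the cluster (a union would
  admit non-hippocampal voxels into a "hippocampal area"); empty
  intersections are dropped with a warning.

## 6. Inference

### Pseudo-T

Per voxel, OLS of value on [1, group, centered covariate]. The residual
variance map is Gaussian-smoothed **within the analysis mask** (default
8 mm FWHM) before entering the denominator; with FWHM = 0 this reduces
exactly to the classic ANCOVA t statistic. Variance smoothing
stabilizes the denominator at low degrees of freedom and is what makes
single-case (1-vs-23) contrasts usable.

### Permutation cluster test

Clusters are connected components (default 18-connectivity) of the
pseudo-T map above a primary threshold (default 2.5). The null
distribution is the maximum cluster size under relabelings of the group
column only — each subject's covariate value stays attached to their
map. All `C(n, n_A) − 1` distinct non-identity relabelings are
enumerated when they do not exceed the requested permutation count
(e.g. 23 for a 1-vs-23 design, so the minimum attainable corrected p is
1/24); otherwise random relabelings are drawn. Corrected p-values use
`(1 + exceedances)/(1 + n_null)`, which includes the identity and is
valid by construction. A warning is raised when fewer than 20 distinct
relabelings exist.

### TFCE

`TFCE(v) = Σ_h e(h, v)^E · h^H · dh` with E = 0.5, H = 2, dh = 0.1,
computed over positive heights; inference uses the max-TFCE permutation
null.

### Scalar statistics

- Covariate adjustment uses a pooled slope (ANCOVA with group dummies);
  estimated marginal means are group means of
  `value − slope·(covariate − mean)`, and the rank tests compare those
  adjusted values.
- Mann–Whitney U uses exact enumeration for n ≤ 20 without ties, else
  the tie-corrected normal approximation (scipy).
- Cohen's d is available from marginal means with a common SD and from
  raw samples with the pooled SD.
- The memory summary is the first principal component of the
  age-regressed, standardized subtest scores, sign-fixed to
  non-negative loadings and scaled to unit variance.
- Median/IQR descriptives use linearly interpolated quartiles at sorted
  position `(n−1)p + 1` (the numpy default), the rule consistent with
  the package's reference cohort table.

## 7. Limitations

- The generator and the phantom are geometric idealizations; recovery
  and calibration results on them do not certify performance on real
  scanner data (no attenuation, scatter, motion, or partial-volume
  model beyond optional Gaussian smoothing).
- The input-function tail relies on log-linear interpolation through
  discrete samples; sparse or noisy late samples propagate directly
  into V_S.
- The slow band's lower edge (0.00063 s⁻¹) is close to the inverse scan
  duration; amplitudes at slower rates alias into the slow band.
- Permutation inference assumes exchangeability of subjects under the
  null after covariate centering; strong covariate-group confounding
  violates this.
- The acceptance-scale inference problems use 20³ grids and 500
  permutations — calibration at full resolution with many more
  permutations is not re-verified here.
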