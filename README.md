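# bandspect

Dual-band spectral quantification and nonparametric inference for dynamic
PET.

## Scientific problem

Some PET radiotracers are trapped in (or cleared extremely slowly from) a
tissue compartment of interest, while the rest of the signal reflects
faster exchanging compartments and nonspecific uptake. Conventional
single-number quantification (a total volume of distribution, V_T)
confounds the two. `bandspect` implements *bandpass spectral analysis*:
each tissue time-activity curve (TAC) is decomposed against a metabolite-
corrected arterial parent-plasma input function as a non-negative sum of
convolved exponential basis functions, and the fitted spectrum is
partitioned into a **slow band** (clearance rate β in [0.00063, 0.00137)
s⁻¹, volume of distribution **V_S**) capturing near-irreversible binding,
and a **fast band** (β in [0.00137, 0.1] s⁻¹, **V_F**) capturing the
rapidly exchanging signal. By construction V_T = V_S + V_F.

On top of voxel-wise V_S / V_F maps, the package provides the matching
inference machinery for small clinical cohorts: pseudo-T statistics with
spatially smoothed residual variance, permutation-based cluster-level
family-wise-error correction (including a single-case mode that enumerates
all relabelings), threshold-free cluster enhancement, covariate-adjusted
rank tests, and a PCA memory-summary score. A synthetic-data module
generates blood curves, dynamic phantom images and full patient/control
cohorts with known ground truth, so every stage of the pipeline can be
validated end to end.

## Core model

A TAC is modeled as

```
TAC(t) = Σⱼ αⱼ · (C_p ⊗ exp(−βⱼ t))(t),   αⱼ ≥ 0,
```

where C_p is the parent plasma input function and the βⱼ lie on a fixed
logarithmic grid (default 120 points tiling [0.00063, 0.1] s⁻¹). The
amplitudes are fitted by frame-duration-weighted non-negative least
squares, and each band's volume of distribution is Σ αⱼ/βⱼ over the βⱼ in
that band. The input function itself is assembled from a continuously
sampled whole-blood curve corrected by fitted plasma-over-blood and
Hill-type parent-fraction models, continued through the late discrete
samples by log-linear interpolation.

## Worked example

Simulate noiseless blood data, build the input function from the observed
(not ground-truth) curves, and quantify a hippocampal TAC whose true
volumes are V_S = 5.0 and V_F = 1.7:

```python
import bandspect.synthetic as syn
from bandspect.schedule import default_frame_schedule
from bandspect.input_function import build_input_from_blood
from bandspect.spectral import BetaGrid, make_basis, fit_tac, band_volumes

schedule = default_frame_schedule()                    # 24 frames, 90 min
blood = syn.simulate_blood(syn.BloodModelParams(), schedule,
                           noise_sd=0.0, seed=0)
inp = build_input_from_blood(blood.blood, schedule)    # fit POB + parent fraction
tac = syn.simulate_tac(blood.true_parent_plasma,
                       syn.DEFAULT_KINETICS[syn.HIPPOCAMPUS_LEFT], schedule)
grid = BetaGrid.default()
vols = band_volumes(fit_tac(tac, make_basis(inp, schedule, grid)), grid)
print(vols.v_s, vols.v_f, vols.v_t)
```

This prints `V_S = 4.944`, `V_F = 1.732`, `V_T = 6.675` — within ~1–2% of
the ground truth, the residual error coming from fitting the input
function rather than using the generator's curve.

The same pipeline is available from the command line:

```sh
bandspect simulate --out data/ --seed 7         # synthetic cohort dataset
bandspect build-input --continuous data/blood_continuous.csv \
    --discrete data/blood_discrete.csv --out data/input.csv
bandspect compare-groups --dataset data/ --out clusters.csv
bandspect report --dataset data/ --out report.json
```

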