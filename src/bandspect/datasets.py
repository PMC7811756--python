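"""Reference clinical data for the worked examples.

A cohort of 11 individuals with MRI-negative temporal lobe epilepsy
(and summary values for 23 healthy controls) scanned with a GABA-A
alpha5-preferring benzodiazepine-site radioligand: per-patient clinical
covariates, group-level memory-battery marginal means, and hippocampal-area
volume-of-distribution summaries. These numbers anchor the package's
descriptive-statistics and effect-size worked examples.
"""

from __future__ import annotations

import io

import pandas as pd

_TLE_CSV = """\
subject,age,sex,handedness,lateralization,onset_years,duration_years,interictal_interval_days,seizure_per_month,amipb_summary,hippocampal_volume_left_mm3,hippocampal_volume_right_mm3,global_total_vt
LTLE1,39,M,L,left,19,20,2,1.5,0.70,1672,1840,3.24
LTLE2,40,M,R,left,26,14,16,9,-2.02,2207,2472,2.98
LTLE3,40,M,R,left,18,22,2,15.5,-1.54,2262,2351,2.84
LTLE4,48,F,L,left,17,31,115,0.2,0.45,1348,1485,2.40
LTLE5,64,M,R,left,21,43,6,6.5,-1.60,1817,2213,3.16
LTLE6,40,M,R,left,37,3,30,1,0.11,2059,2012,3.23
RTLE1,46,F,R,right,15,31,2,3,0.02,2270,2288,2.88
RTLE2,32,F,R,right,21,11,5,6.5,0.29,2187,1998,3.36
RTLE3,42,M,R,right,36,6,304,0.2,0.25,1926,2037,2.62
RTLE4,39,M,R,right,27,12,1,4.5,1.00,2010,2353,2.98
RTLE5,54,M,R,right,22,32,24,2.5,-1.27,1838,1885,2.72
"""


def load_tle_cohort() -> pd.DataFrame:
    """Per-patient clinical covariates for the 11-patient reference cohort."""
    return pd.read_csv(io.StringIO(_TLE_CSV))


# memory battery: estimated marginal means after age regression
# (tle_mean, control_mean, common_sd)
MEMORY_MARGINALS = {
    "list_learning": (44.5, 57.3, 9.3),
    "list_recall": (8.3, 12.1, 2.9),
    "figure_learning": (29.9, 38.9, 12.2),
    "figure_recall": (6.9, 8.5, 2.9),
    "summary": (-0.4, 0.7, 1.0),
}

# hippocampal-area volumes of distribution, estimated marginal means after
# regression of global total V_T: {measure: (tle_mean, control_mean)}
HIPPOCAMPAL_AREA_MEANS = {
    "v_s_ipsilateral": (6.21, 5.02),
    "v_s_contralateral": (6.57, 5.21),
    "v_f_ipsilateral": (1.35, 1.72),
    "v_f_contralateral": (1.39, 1.67),
}

# control-group descriptives (median, iqr) for columns without per-subject data
CONTROL_SUMMARIES = {
    "age": (49.0, 13.0),
    "global_total_vt": (2.86, 0.37),
    "hippocampal_volume_left_mm3": (1657.0, 481.0),
    "hippocampal_volume_right_mm3": (1940.0, 484.0),
}
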