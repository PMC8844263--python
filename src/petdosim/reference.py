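"""Published reference values from the first-in-humans 18F-rhPSMA-7.3 study.

Cohort summary statistics printed in the study report: initial organ uptake
fractions, cumulative urinary excretion, and the mean organ absorbed doses /
effective dose computed with OLINDA/EXM 1.0 on the Cristy–Eckerman adult
phantom.  The synthetic cohort generator is calibrated to these values and
the dose engine is cross-checked against them.
"""
from __future__ import annotations

#: Target administered activity (MBq) and tolerance; the realised cohort mean
#: was 220 MBq (range 210–228).
INJECTED_TARGET_MBQ: float = 225.0
INJECTED_TOLERANCE: float = 0.10
INJECTED_RANGE_MBQ: tuple[float, float] = (210.0, 228.0)

#: Mean fraction of injected activity measured 1 min after injection in the
#: organs with quantifiable early uptake, with the printed subject ranges.
INITIAL_UPTAKE_1MIN: dict[str, float] = {
    "liver": 0.158,
    "muscle": 0.243,
    "heart_content": 0.074,
    "cortical_bone": 0.035,
    "brain": 0.008,
    "pancreas": 0.006,
}

INITIAL_UPTAKE_RANGES: dict[str, tuple[float, float]] = {
    "liver": (0.139, 0.170),
    "muscle": (0.192, 0.293),
    "heart_content": (0.065, 0.092),
    "cortical_bone": (0.030, 0.044),
    "brain": (0.006, 0.011),
    "pancreas": (0.004, 0.009),
}

#: Cumulative decay-corrected fraction of injected activity excreted in urine
#: by the end of each scanning session (collection/void times in minutes).
URINE_CUMULATIVE: tuple[tuple[float, float], ...] = (
    (111.0, 0.072),
    (194.0, 0.114),
    (263.0, 0.148),
)

#: Session-1 urinary excretion subject range (fraction of injected activity).
URINE_SESSION1_RANGE: tuple[float, float] = (0.044, 0.090)

#: Mean organ absorbed doses (mGy/MBq) over the six subjects, 3.5-h voiding
#: interval, as reported from OLINDA/EXM 1.0.
ORGAN_DOSES_35H_MGY_PER_MBQ: dict[str, float] = {
    "adrenals": 0.184,
    "kidneys": 0.172,
    "submandibular_glands": 0.148,
    "parotid_glands": 0.114,
    "spleen": 0.083,
    "lacrimal_glands": 0.080,
    "sublingual_glands": 0.065,
    "liver": 0.062,
    "pancreas": 0.028,
    "heart_wall": 0.020,
    "gallbladder_wall": 0.017,
    "urinary_bladder_wall": 0.012,
    "stomach_wall": 0.012,
    "small_intestine": 0.012,
    "osteogenic_cells": 0.012,
    "uterus": 0.011,
    "thymus": 0.010,
    "uli_wall": 0.010,
    "lungs": 0.010,
    "red_marrow": 0.010,
    "thyroid": 0.010,
    "lli_wall": 0.007,
    "muscle": 0.006,
    "testes": 0.005,
    "ovaries": 0.005,
    "breasts": 0.004,
    "skin": 0.002,
    "brain": 0.002,
}

#: Urinary bladder wall mean absorbed dose with a 1-h voiding interval.
BLADDER_WALL_DOSE_1H_MGY_PER_MBQ: float = 0.006

#: Reported mean effective doses (mSv/MBq).
EFFECTIVE_DOSE_1H_MSV_PER_MBQ: float = 0.0138
EFFECTIVE_DOSE_35H_MSV_PER_MBQ: float = 0.0141
EFFECTIVE_DOSE_TABLE_MSV_PER_MBQ: float = 0.014  # value printed in the dose table
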