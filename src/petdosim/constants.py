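"""Physical constants and reference-phantom data.

Nuclear data for fluorine-18 and the organ masses of the Cristy–Eckerman
hermaphroditic 70-kg adult phantom, plus the ICRP Publication 60 tissue
weighting factors. These are standard fixture constants of the field, not
quantities estimated by this package.
"""
from __future__ import annotations

import math

# ---------------------------------------------------------------------------
# Fluorine-18 decay data (ICRP-107 / standard decay tables)
# ---------------------------------------------------------------------------

#: Physical half-life of F-18 in minutes.
F18_HALF_LIFE_MIN: float = 109.77

#: Physical decay constant of F-18, per hour.
LAMBDA_P_PER_H: float = math.log(2.0) / (F18_HALF_LIFE_MIN / 60.0)

#: Mean life of F-18 in hours (= 1 / lambda_p ≈ 2.640 h).  Upper bound on any
#: residence time per unit injected activity.
F18_MEAN_LIFE_H: float = 1.0 / LAMBDA_P_PER_H

#: Mean positron energy per beta+ decay (MeV) and positron branching ratio.
F18_MEAN_BETA_ENERGY_MEV: float = 0.2498
F18_POSITRON_YIELD: float = 0.9673

_J_PER_MEV = 1.602176634e-13
_DECAYS_PER_MBQ_H = 3.6e9

#: Mean NONPENETRATING energy deposited locally per decay (positrons; Auger
#: and conversion electrons are negligible for F-18), expressed as an
#: equilibrium dose constant: mGy·g per MBq·h of cumulated activity.
DELTA_NP_MGY_G_PER_MBQ_H: float = (
    F18_MEAN_BETA_ENERGY_MEV * F18_POSITRON_YIELD * _J_PER_MEV * _DECAYS_PER_MBQ_H * 1.0e6
)

#: Mean PENETRATING energy per decay (two 511-keV annihilation photons per
#: positron), same units.  Used only by the synthetic S-value table.
DELTA_PEN_MGY_G_PER_MBQ_H: float = (
    2.0 * 0.510999 * F18_POSITRON_YIELD * _J_PER_MEV * _DECAYS_PER_MBQ_H * 1.0e6
)

# ---------------------------------------------------------------------------
# Cristy–Eckerman adult phantom organ masses (g)
# ---------------------------------------------------------------------------
# The phantom is hermaphroditic: it carries both testes and ovaries/uterus/
# breasts.  The four glands at the end were not part of the original phantom;
# they are added as unit-density spheres with the masses used when salivary
# and lacrimal glands are treated as explicit PSMA-avid source organs.

ADULT_PHANTOM_MASSES_G: dict[str, float] = {
    "adrenals": 16.3,
    "brain": 1420.0,
    "breasts": 351.0,
    "gallbladder_wall": 10.5,
    "gallbladder_content": 55.7,
    "lli_wall": 167.0,
    "lli_content": 75.0,
    "small_intestine": 677.0,
    "stomach_wall": 158.0,
    "stomach_content": 260.0,
    "uli_wall": 220.0,
    "uli_content": 135.0,
    "heart_wall": 316.0,
    "heart_content": 454.0,
    "kidneys": 299.0,
    "liver": 1910.0,
    "lungs": 1000.0,
    "muscle": 28000.0,
    "ovaries": 8.71,
    "pancreas": 94.3,
    "red_marrow": 1120.0,
    "cortical_bone": 4000.0,
    "trabecular_bone": 1000.0,
    "osteogenic_cells": 120.0,
    "skin": 3010.0,
    "spleen": 183.0,
    "testes": 39.1,
    "thymus": 20.9,
    "thyroid": 20.7,
    "urinary_bladder_wall": 47.6,
    "urinary_bladder_content": 211.0,
    "uterus": 79.0,
    # added PSMA-avid glands (unit-density spheres)
    "parotid_glands": 25.0,
    "submandibular_glands": 12.5,
    "sublingual_glands": 12.5,
    "lacrimal_glands": 5.0,
    "total_body": 73700.0,
}

#: The four glands added on top of the standard phantom, with their sphere
#: masses.  They have no geometry in the phantom S-value tables: self-dose is
#: computed with the nonpenetrating sphere model and their cumulated activity
#: is routed to the remainder for all other targets.
ADDED_GLANDS_G: dict[str, float] = {
    "parotid_glands": 25.0,
    "submandibular_glands": 12.5,
    "sublingual_glands": 12.5,
    "lacrimal_glands": 5.0,
}

# ---------------------------------------------------------------------------
# ICRP Publication 60 tissue weighting factors
# ---------------------------------------------------------------------------

#: w_T per ICRP-60.  "remainder" carries 0.05 spread over the remainder organ
#: list below.  The weights sum to exactly 1.
ICRP60_WEIGHTS: dict[str, float] = {
    "gonads": 0.20,
    "red_marrow": 0.12,
    "colon": 0.12,
    "lungs": 0.12,
    "stomach_wall": 0.12,
    "urinary_bladder_wall": 0.05,
    "breasts": 0.05,
    "liver": 0.05,
    "esophagus": 0.05,
    "thyroid": 0.05,
    "skin": 0.01,
    "bone_surface": 0.01,
    "remainder": 0.05,
}

#: Remainder organs (ICRP-60 as amended by Publication 67: the upper large
#: intestine moved into the colon, leaving nine tissues).
ICRP60_REMAINDER_ORGANS: tuple[str, ...] = (
    "adrenals",
    "brain",
    "small_intestine",
    "kidneys",
    "muscle",
    "pancreas",
    "spleen",
    "thymus",
    "uterus",
)

#: Dose surrogates for weighted tissues that are not direct dose-report rows:
#: the colon is the mass-weighted mean of the two large-intestine walls, the
#: esophagus is approximated by the thymus, and "bone surface" is the
#: osteogenic-cells row.  Gonads are the mean of testes and ovaries doses
#: (the phantom is hermaphroditic; a sex-averaged effective dose is reported).
SURROGATE_TISSUES: dict[str, tuple[str, ...]] = {
    "gonads": ("testes", "ovaries"),
    "colon": ("uli_wall", "lli_wall"),
    "esophagus": ("thymus",),
    "bone_surface": ("osteogenic_cells",),
}
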