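"""Reference summary statistics from two ICU cohort-selection case studies.

These are printed cohort summaries (counts, means/SDs, category
percentages) at each exclusion step of two published ICU analyses —
one eICU-based sepsis/troponin study with four cohort states, one
MIMIC-IV-based creatinine/mortality study with three. The underlying
patient-level data are credentialed and cannot ship here; the printed
summaries alone are enough to exercise every drift formula, so they
serve as numeric fixtures.

Structure: each step is a dict with ``n``, continuous variables as
(mean, sd), and categorical variables as ordered {label: count} maps.
"""

from __future__ import annotations

# eICU-like sepsis/troponin case study: 4 cohort states.
# Steps: all ICU stays -> no known heart disease -> sepsis -> troponin measured.
EICU_STEPS = [
    {
        "n": 126_750,
        "age": (62.8, 16.2),
        "apache_iv": (57.3, 25.8),
        "ethnicity": {
            "Caucasian": 98_333,
            "African American": 14_705,
            "Other or Unknown": 5_979,
            "Hispanic": 4_714,
            "Asian": 2_152,
            "Native American": 867,
        },
        "sex": {"Female": 57_373, "Male": 69_376},
    },
    {
        "n": 117_489,
        "age": (62.5, 16.3),
        "apache_iv": (56.2, 24.6),
        "ethnicity": {
            "Caucasian": 91_642,
            "African American": 13_216,
            "Other or Unknown": 5_497,
            "Hispanic": 4_327,
            "Asian": 1_988,
            "Native American": 819,
        },
        "sex": {"Female": 55_564, "Male": 66_655},
    },
    {
        "n": 17_161,
        "age": (64.6, 15.5),
        "apache_iv": (69.0, 26.2),
        "ethnicity": {
            "Caucasian": 13_387,
            "African American": 1_810,
            "Other or Unknown": 822,
            "Hispanic": 666,
            "Asian": 333,
            "Native American": 143,
        },
        "sex": {"Female": 8_357, "Male": 8_804},
    },
    {
        "n": 1_094,
        "age": (69.1, 13.2),
        "apache_iv": (76.3, 25.6),
        "ethnicity": {
            "Caucasian": 933,
            "African American": 102,
            "Other or Unknown": 33,
            "Hispanic": 11,
            "Asian": 10,
            "Native American": 5,
        },
        "sex": {"Female": 511, "Male": 583},
    },
]

# MIMIC-IV-like creatinine/mortality case study: 3 cohort states.
# Steps: all ICU stays -> first ICU stay only -> complete creatinine
# and stay >= 12 h.
MIMIC_STEPS = [
    {
        "n": 94_458,
        "age": (64.78, 16.74),
        "sex": {"Male": 52_875, "Female": 41_583},
        "insurance": {
            "Medicare": 51_819,
            "Private": 24_540,
            "Medicaid": 14_240,
            "Other": 2_328,
            "No charge": 8,
            "Missing": 1_523,
        },
        "icu_mortality": {"No Mortality": 86_930, "Mortality": 7_528},
    },
    {
        "n": 65_366,
        "age": (64.53, 17.13),
        "sex": {"Male": 36_720, "Female": 28_646},
        "insurance": {
            "Medicare": 34_464,
            "Private": 18_447,
            "Medicaid": 9_353,
            "Other": 1_733,
            "No charge": 7,
            "Missing": 1_362,
        },
        "icu_mortality": {"No Mortality": 60_485, "Mortality": 4_881},
    },
    {
        "n": 61_360,
        "age": (64.63, 16.93),
        "sex": {"Male": 34_608, "Female": 26_739},
        "insurance": {
            "Medicare": 32_457,
            "Private": 17_383,
            "Medicaid": 8_733,
            "Other": 1_633,
            "No charge": 7,
            "Missing": 1_147,
        },
        "icu_mortality": {"No Mortality": 57_209, "Mortality": 4_138},
    },
]
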