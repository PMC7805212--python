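"""Published per-group summary statistics used to parameterize synthetic cohorts.

Medians with inter-quartile ranges (IQR) per group for every quantitative
measure of the training cohort comparison table, plus per-group ICV and
demographics from the cohort characteristics table.  Relative volumes are in
percent of ICV, atrophy ratios on the x100 CSF/parenchyma scale, QMTA and
AD-RAI unitless.
"""

# measure -> group -> (median, iqr)
TABLE_MEASURES = {
    "hippocampus": {"NC": (0.45, 0.05), "AD": (0.39, 0.09), "FTD": (0.42, 0.07)},
    "caudate_left": {"NC": (0.23, 0.02), "AD": (0.23, 0.04), "FTD": (0.21, 0.04)},
    "frontal_left_atrophy": {"NC": (42.50, 14.40), "AD": (42.30, 13.30), "FTD": (51.30, 14.10)},
    "frontal_right_atrophy": {"NC": (40.70, 14.80), "AD": (43.40, 12.80), "FTD": (51.50, 15.30)},
    "occipital_right_atrophy": {"NC": (9.11, 4.82), "AD": (12.70, 5.90), "FTD": (10.00, 5.46)},
    "frontal_left": {"NC": (5.56, 0.67), "AD": (5.50, 0.51), "FTD": (5.22, 0.65)},
    "occipital_right": {"NC": (2.26, 0.31), "AD": (2.13, 0.52), "FTD": (2.36, 0.34)},
    "temporal_left": {"NC": (3.71, 0.32), "AD": (3.30, 0.40), "FTD": (3.06, 0.76)},
    "temporal_right": {"NC": (3.68, 0.37), "AD": (3.30, 0.55), "FTD": (3.20, 0.71)},
    "parietal_left": {"NC": (2.63, 0.31), "AD": (2.42, 0.38), "FTD": (2.63, 0.38)},
    "parietal_right": {"NC": (2.81, 0.42), "AD": (2.50, 0.37), "FTD": (2.86, 0.40)},
    "insular_left": {"NC": (0.47, 0.05), "AD": (0.42, 0.05), "FTD": (0.36, 0.07)},
    "insular_right": {"NC": (0.48, 0.05), "AD": (0.46, 0.05), "FTD": (0.42, 0.09)},
    "qmta": {"NC": (0.33, 0.07), "AD": (0.55, 0.32), "FTD": (0.52, 0.38)},
}

ADRAI = {"NC": (0.12, 0.20), "AD": (0.94, 0.51), "FTD": (0.97, 0.23)}

# visual rating, carried as metadata only
MTA = {"NC": (0.25, 1.00), "AD": (1.50, 1.50), "FTD": (1.50, 1.50)}

# group -> (mean, sd), mL — training cohort
ICV_TRAIN = {"NC": (1505.12, 145.51), "AD": (1526.37, 170.79), "FTD": (1472.14, 155.82)}

# validation cohort ICV (AD from one database, FTD from another)
ICV_VALIDATION = {"AD": (1456.48, 158.80), "FTD": (1521.82, 131.45)}

DEMOGRAPHICS_TRAIN = {
    "age_mean": 64.55,
    "age_sd": 10.15,
    "education_mean": 15.45,
    "education_sd": 2.98,
    "male_fraction": 25 / 47,
}

DEMOGRAPHICS_VALIDATION = {
    "age_mean": 64.43,
    "age_sd": 7.34,
    "education_mean": 16.00,
    "education_sd": 3.07,
    "male_fraction": 0.50,
}

# Measures whose printed AD-vs-FTD difference was significant, split by which
# disease group has the larger values.  Used by tests and examples as the
# expected dominant sets.
EXPECTED_FTD_DOMINANT = (
    "frontal_left_atrophy",
    "frontal_right_atrophy",
    "hippocampus",
    "parietal_left",
    "parietal_right",
    "occipital_right",
)
EXPECTED_AD_DOMINANT = (
    "occipital_right_atrophy",
    "frontal_left",
    "insular_left",
    "insular_right",
    "caudate_left",
)

# Nominal relative volumes (% ICV) for lobes/structures without a printed row;
# they complete the raw volumetry report but never enter the analysis panel.
NOMINAL_LOBE_REL = {
    ("frontal", "right"): 5.50,
    ("occipital", "left"): 2.30,
    ("cingulate", "left"): 0.95,
    ("cingulate", "right"): 0.95,
}
NOMINAL_LOBE_ATROPHY = {
    ("temporal", "left"): 28.0,
    ("temporal", "right"): 28.0,
    ("parietal", "left"): 30.0,
    ("parietal", "right"): 30.0,
    ("occipital", "left"): 10.0,
    ("insular", "left"): 35.0,
    ("insular", "right"): 35.0,
    ("cingulate", "left"): 30.0,
    ("cingulate", "right"): 30.0,
}
NOMINAL_STRUCTURE_REL = {
    "brain_parenchyma": 78.0,
    "ventricular_system": 2.4,
    "lateral_ventricle": 1.8,
    "amygdala_left": 0.10,
    "amygdala_right": 0.10,
}
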