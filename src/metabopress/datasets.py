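"""Bundled reference data.

``ckd_bp_metabolite_table`` returns the published association table from a
large two-cohort serum-metabolomics study of blood pressure in chronic kidney
disease (discovery n = 824, validation n = 552): the 31 LC-MS features that
were significantly associated with the 5-level blood-pressure code in both
cohorts, with per-cohort and pooled linear-regression estimates and p-values
and the published Benjamini-Hochberg adjusted p-values (m = 31). The table is
used as a worked example and as a fixed input for exercising ``bh_adjust``
and the replication-counting logic against published numbers.

``stratum_sizes`` returns the per-CKD-stage sample counts of the same study's
cohorts, and ``covariate_reference`` the per-stage means and SDs of the
clinical covariates, which parameterize the synthetic-data generator.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ckd_bp_metabolite_table", "stratum_sizes", "covariate_reference", "STRATA"]

STRATA = ["control", "ckd1", "ckd2", "ckd3", "ckd4", "ckd5"]

# metabolite, m/z, retention time (min),
# discovery estimate, discovery p, validation estimate, validation p,
# combined estimate, combined p, published BH-adjusted p
_ASSOC_ROWS = [
    ("Aspartylglycosamine", 412.0567, 4.53, 0.0015, 1.44e-2, 0.002, 5.63e-3, 0.0007, 4.58e-5, 1.42e-3),
    ("Fructose-1,6-diphosphate", 447.9958, 2.89, 0.0008, 3.61e-2, 0.001, 4.48e-2, 0.0004, 1.19e-4, 1.84e-3),
    ("L-Glutamic acid", 226.0740, 0.98, 0.0004, 1.36e-3, 0.0003, 4.27e-2, 0.0001, 3.27e-4, 3.38e-3),
    ("Niacinamide", 283.0602, 3.44, 0.0028, 1.32e-2, 0.0077, 1.09e-4, 0.0017, 5.30e-4, 4.11e-3),
    ("3-Dehydrocarnitine", 236.0078, 3.57, 0.0011, 2.17e-2, 0.0014, 1.84e-2, 0.0004, 1.27e-3, 7.87e-3),
    ("Phosphocreatine", 294.0924, 5.14, -0.0012, 4.44e-2, -0.0015, 1.24e-2, -0.0006, 6.39e-3, 3.30e-2),
    ("Dodecanedioic acid", 269.1144, 3.47, -0.0035, 1.79e-2, -0.0046, 2.64e-2, -0.0011, 1.38e-2, 6.11e-2),
    ("2-Hydroxyestrone sulfate", 408.1494, 3.01, -0.0006, 4.72e-2, -0.001, 2.20e-2, -0.0003, 2.07e-2, 8.02e-2),
    ("Xanthine", 368.0554, 3.86, 0.0013, 2.51e-2, 0.0016, 3.19e-2, 0.0003, 4.01e-2, 1.38e-1),
    ("Phosphate", 181.0374, 0.87, -0.0003, 1.03e-2, -0.0003, 4.94e-2, -0.0001, 4.56e-2, 1.41e-1),
    ("NADP+", 391.0605, 4.09, 0.0004, 5.68e-3, 0.0003, 2.39e-2, 0.0, 8.34e-2, 2.24e-1),
    ("Coenzyme A", 393.0802, 4.33, 0.0002, 2.99e-2, 0.0002, 7.57e-3, 0.0, 8.69e-2, 2.24e-1),
    ("Nicotine glucuronide", 415.0683, 0.87, 0.0005, 1.40e-2, -0.0005, 2.10e-2, -0.0001, 1.12e-1, 2.55e-1),
    ("Dihydroasparagusic acid", 305.0033, 1.34, 0.0029, 2.08e-4, 0.0036, 1.67e-4, 0.0003, 1.15e-1, 2.55e-1),
    ("N2-Methylguanine", 210.0359, 5.48, 0.0061, 1.78e-4, 0.0048, 1.29e-2, 0.0003, 1.25e-1, 2.58e-1),
    ("Butyl acetate", 81.0702, 4.96, 0.0131, 3.78e-2, -0.0088, 4.61e-2, -0.0026, 1.51e-1, 2.93e-1),
    ("Kynuramine", 392.2132, 3.80, -0.0004, 3.72e-2, -0.0005, 3.93e-2, -0.0001, 1.75e-1, 3.19e-1),
    ("N-Myristoyl Alanine", 306.2628, 4.67, 0.007, 4.45e-2, 0.0091, 2.23e-2, -0.0002, 2.09e-1, 3.60e-1),
    ("N-Acetylputrescine", 207.0297, 0.85, 0.0047, 2.64e-3, 0.0052, 1.26e-2, 0.0003, 2.65e-1, 4.32e-1),
    ("Undecanedioic acid", 199.1360, 4.75, 0.0028, 8.12e-3, 0.0034, 2.63e-2, 0.0004, 3.28e-1, 5.00e-1),
    ("dUDP", 206.0009, 4.65, 0.0029, 3.64e-2, -0.0045, 1.98e-2, 0.0005, 3.39e-1, 5.00e-1),
    ("5-Hydroxytryptamine", 177.1022, 3.18, 0.0, 1.63e-2, 0.0, 1.76e-2, 0.0, 4.39e-1, 6.00e-1),
    ("Methionine sulfoxide", 244.0650, 2.42, 0.0103, 2.80e-3, 0.0131, 1.04e-3, 0.0, 4.45e-1, 6.00e-1),
    ("Selenocysteine", 355.9162, 2.93, -0.0018, 2.56e-2, -0.0028, 1.38e-2, -0.0002, 5.33e-1, 6.88e-1),
    ("N-Acetylneuraminic acid", 332.0959, 0.98, -0.0285, 4.95e-2, -0.0483, 4.48e-2, 0.0, 5.90e-1, 7.00e-1),
    ("N-Acetylgalactosamine 6-sulfate", 365.0669, 2.73, 0.0085, 1.47e-2, 0.0088, 3.97e-2, 0.0001, 6.04e-1, 7.00e-1),
    ("3-Methyladenine", 172.0588, 2.89, 0.0016, 9.56e-3, 0.0018, 2.67e-2, 0.0, 6.10e-1, 7.00e-1),
    ("N-Acetylaspartylglutamic acid", 322.1209, 4.21, -0.0004, 1.90e-2, 0.0005, 4.01e-2, 0.0, 7.17e-1, 7.71e-1),
    ("Sphingosine-1-phosphate", 356.1989, 5.44, -0.0015, 3.84e-2, 0.0019, 2.80e-2, 0.0001, 7.21e-1, 7.71e-1),
    ("Oxodecanoylcarnitine", 271.1503, 4.52, 0.0004, 3.69e-2, -0.0006, 4.41e-2, 0.0, 8.79e-1, 8.88e-1),
    ("2-Methylguanosine", 342.0801, 3.26, -0.0004, 2.41e-2, 0.0002, 4.79e-2, 0.0, 8.88e-1, 8.88e-1),
]

_ASSOC_COLUMNS = [
    "metabolite", "mz", "rt",
    "estimate_discovery", "p_discovery",
    "estimate_validation", "p_validation",
    "estimate_combined", "p_combined",
    "p_adjusted_published",
]

# per-CKD-stage sample sizes; the study's methods text disagrees with its
# summary table for two cells (discovery control 114 vs 144, validation CKD5
# 196 vs 96) and only the table's counts sum to the stated cohort totals
# (824 / 552), so "table" is the default preset
_STRATUM_SIZES = {
    "table": {
        "discovery": (144, 125, 133, 131, 150, 141),
        "validation": (96, 97, 76, 94, 93, 96),
    },
    "text": {
        "discovery": (114, 125, 133, 131, 150, 141),
        "validation": (96, 97, 76, 94, 93, 196),
    },
}

# (mean, sd) per stratum, discovery cohort then validation cohort;
# men_frac is a proportion, age in years, eGFR in mL/min/1.73m^2,
# weight in kg, BMI in kg/m^2
_COVARIATE_REFERENCE = {
    "discovery": {
        "men_frac": (0.625, 0.456, 0.571, 0.588, 0.547, 0.489),
        "age": ((57.28, 17.66), (54.65, 8.54), (56.41, 10.2), (55.36, 15.44), (59.51, 14.27), (59.86, 16.41)),
        "egfr": ((107.03, 15.73), (109.75, 16.48), (78.95, 12.32), (44.53, 11.75), (21.7, 4.95), (8.18, 3.07)),
        "weight": ((70.36, 11.9), (69.18, 12.83), (73.13, 11.13), (74.08, 12.08), (73.07, 13.29), (72.41, 13.1)),
        "bmi": ((24.34, 3.36), (24.39, 3.49), (23.78, 3.08), (24.09, 3.39), (24.68, 3.11), (25.58, 3.28)),
    },
    "validation": {
        "men_frac": (0.615, 0.526, 0.566, 0.617, 0.548, 0.521),
        "age": ((57.74, 15.69), (55.94, 7.79), (52.78, 9.18), (57.62, 14.64), (59.05, 14.45), (58.56, 14.5)),
        "egfr": ((106.06, 11.64), (106.39, 11.53), (78.54, 10.72), (44.48, 13.26), (21.55, 4.54), (8.77, 3.0)),
        "weight": ((69.79, 11.41), (71.21, 13.14), (73.53, 11.95), (71.9, 12.76), (72.48, 11.56), (72.54, 12.61)),
        "bmi": ((24.18, 3.19), (24.68, 3.25), (23.6, 3.11), (24.8, 3.5), (25.27, 3.63), (25.76, 3.47)),
    },
}


def ckd_bp_metabolite_table() -> pd.DataFrame:
    """The 31-metabolite two-cohort replication table (see module docstring)."""
    return pd.DataFrame(_ASSOC_ROWS, columns=_ASSOC_COLUMNS)


def stratum_sizes(cohort: str, preset: str = "table") -> tuple[int, ...]:
    """Per-stage sample counts (control, CKD1..CKD5) for one cohort."""
    try:
        return _STRATUM_SIZES[preset][cohort]
    except KeyError:
        raise ValueError(
            f"unknown preset/cohort {preset!r}/{cohort!r}; presets: "
            f"{sorted(_STRATUM_SIZES)}, cohorts: discovery, validation"
        ) from None


def covariate_reference(cohort: str) -> dict:
    """Per-stage covariate summary statistics for one cohort."""
    if cohort not in _COVARIATE_REFERENCE:
        raise ValueError(f"unknown cohort {cohort!r}")
    return _COVARIATE_REFERENCE[cohort]
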