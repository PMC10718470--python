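"""Published summary statistics of the 555-patient reference cohort.

These are the printed per-level results of the CT morphometry study the
package models: mean +/- SD canal areas for the manual measurement and
the three shape approximations, mean differences of each approximation
against the manual area, approximation-vs-manual Pearson correlations,
signed percent errors, and the cohort demographics.  They serve two
roles: calibration targets for the synthetic cohort generator and frozen
expected values for the exact table-arithmetic checks.

Keys are level strings ("L1".."L5") and shape strings ("ellipse",
"triangle", "rectangle"); all areas in mm^2.
"""

from __future__ import annotations

__all__ = [
    "LEVEL_MEANS",
    "MEAN_DIFFERENCES",
    "CORRELATIONS",
    "PERCENT_ERRORS",
    "DEMOGRAPHICS",
    "N_PATIENTS",
]

N_PATIENTS = 555

#: Per-level (mean, SD) of the manual area and the three shape estimates.
LEVEL_MEANS: dict[str, dict[str, tuple[float, float]]] = {
    "L1": {
        "manual": (281.78, 48.89),
        "ellipse": (305.56, 56.50),
        "triangle": (194.53, 35.97),
        "rectangle": (389.06, 71.93),
    },
    "L2": {
        "manual": (262.25, 49.79),
        "ellipse": (285.35, 57.05),
        "triangle": (181.66, 36.32),
        "rectangle": (363.32, 72.64),
    },
    "L3": {
        "manual": (253.28, 49.93),
        "ellipse": (277.85, 58.15),
        "triangle": (176.88, 37.02),
        "rectangle": (353.76, 74.04),
    },
    "L4": {
        "manual": (266.16, 64.16),
        "ellipse": (302.24, 75.08),
        "triangle": (192.41, 47.80),
        "rectangle": (384.82, 95.60),
    },
    "L5": {
        "manual": (318.50, 90.23),
        "ellipse": (367.91, 100.59),
        "triangle": (234.22, 64.03),
        "rectangle": (468.43, 128.07),
    },
}

#: (mean difference, SD of differences) per (level, shape); estimate - manual.
MEAN_DIFFERENCES: dict[tuple[str, str], tuple[float, float]] = {
    ("L1", "ellipse"): (23.78, 23.93),
    ("L1", "triangle"): (-87.25, 22.24),
    ("L1", "rectangle"): (107.28, 34.45),
    ("L2", "ellipse"): (23.10, 20.64),
    ("L2", "triangle"): (-80.59, 20.47),
    ("L2", "rectangle"): (101.07, 31.58),
    ("L3", "ellipse"): (24.57, 24.47),
    ("L3", "triangle"): (-76.40, 22.47),
    ("L3", "rectangle"): (100.48, 35.47),
    ("L4", "ellipse"): (36.08, 32.15),
    ("L4", "triangle"): (-73.75, 29.15),
    ("L4", "rectangle"): (118.66, 46.40),
    ("L5", "ellipse"): (49.41, 36.88),
    ("L5", "triangle"): (-84.28, 38.53),
    ("L5", "rectangle"): (149.93, 55.02),
}

#: Pearson r between any shape estimate and the manual area, per level.
#: One value per level: all three shapes are scalar multiples of IPD*AP,
#: so their correlations with any reference coincide.
CORRELATIONS: dict[str, float] = {
    "L1": 0.907,
    "L2": 0.934,
    "L3": 0.909,
    "L4": 0.905,
    "L5": 0.931,
}

#: Signed aggregate percent error per (level, shape), in %.
PERCENT_ERRORS: dict[tuple[str, str], float] = {
    ("L1", "ellipse"): 8.44,
    ("L1", "triangle"): -30.96,
    ("L1", "rectangle"): 38.07,
    ("L2", "ellipse"): 8.81,
    ("L2", "triangle"): -30.73,
    ("L2", "rectangle"): 38.54,
    ("L3", "ellipse"): 9.70,
    ("L3", "triangle"): -30.16,
    ("L3", "rectangle"): 39.67,
    ("L4", "ellipse"): 13.56,
    ("L4", "triangle"): -27.71,
    ("L4", "rectangle"): 44.58,
    ("L5", "ellipse"): 15.51,
    ("L5", "triangle"): -26.46,
    ("L5", "rectangle"): 47.07,
}

#: Cohort demographics (used only for optional realism columns).
DEMOGRAPHICS: dict[str, float | tuple[float, float]] = {
    "n_male": 231,
    "n_female": 324,
    "age_mean": 27.2,
    "age_range": (18.0, 35.0),
    "height_mean_m": 1.54,
    "height_sd_m": 0.09,
    "weight_mean_kg": 80.44,
    "weight_sd_kg": 23.42,
    "bmi_mean": 28.27,
    "bmi_sd": 7.2,
}
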