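"""Published summary tables from the original nine-rater clinical
accuracy study.

The original study evaluated the quantitative report with nine human
raters (three consultants, three registrars, three non-clinical image
analysts) on 45 scans (15 controls, 16 AD, 14 FTD).  Raw episode data
are not redistributable, but the published per-group and per-rater
summaries are self-consistent aggregates that this package can recompute
from their printed components; they are stored here as inputs for those
re-computations (see ``scripts/acceptance.py``).

Percentages are as printed (e.g. 71.5 means 71.5%); kappas are plain
values.  A dash in the source table is represented as ``None``.
"""

from __future__ import annotations

EXPERIENCE_LEVELS = ("consultant", "registrar", "analyst")

#: Test-cohort demographics: group -> (n, age mean, age SD).
TEST_COHORT_DEMOGRAPHICS = {
    "control": {"n": 15, "age_mean": 60.0, "age_sd": 8.7, "male": 4, "female": 11,
                "mmse_mean": 26.9, "mmse_sd": 4.0, "duration_mean": None,
                "duration_sd": None},
    "AD": {"n": 16, "age_mean": 61.7, "age_sd": 6.6, "male": 9, "female": 7,
           "mmse_mean": 20.5, "mmse_sd": 6.4, "duration_mean": 2.7,
           "duration_sd": 1.6},
    "FTD": {"n": 14, "age_mean": 59.9, "age_sd": 7.3, "male": 11, "female": 3,
            "mmse_mean": 22.0, "mmse_sd": 9.1, "duration_mean": 3.5,
            "duration_sd": 2.4},
}

#: Printed total-column age summary for the 45-scan cohort.
TEST_COHORT_TOTAL_AGE = {"mean": 60.6, "sd": 7.4}

#: Normative reference cohort demographics.
NORMATIVE_REFERENCE = {"n": 461, "age_mean": 70.09, "age_sd": 12.05,
                       "percent_female": 51.4}

#: Volume-loss (normal vs abnormal) metric table:
#: metric -> level -> dict(without/with mean & SD, printed p and d).
#: The 'combined' rows are the printed all-groups-combined values.
VOLUME_LOSS_METRICS = {
    "sensitivity": {
        "consultant": {"without": (68.9, 5.0), "with": (80.0, 10.0),
                       "p": 0.13, "d": 1.4},
        "registrar": {"without": (75.5, 8.4), "with": (81.1, 1.9),
                      "p": 0.3, "d": 0.8},
        "analyst": {"without": (70.0, 25.1), "with": (85.5, 10.1),
                    "p": 0.23, "d": 0.9},
        "combined": {"without": (71.5, 13.8), "with": (82.2, 7.6),
                     "p": 0.015, "d": 1.03},
    },
    "specificity": {
        "consultant": {"without": (75.6, 3.8), "with": (80.0, 13.3),
                       "p": 0.52, "d": 0.43},
        "registrar": {"without": (82.2, 10.1), "with": (68.8, 25.2),
                      "p": 0.37, "d": -0.6},
        "analyst": {"without": (77.7, 3.8), "with": (68.9, 13.8),
                    "p": 0.45, "d": -0.52},
        "combined": {"without": (78.5, 6.4), "with": (72.3, 16.8),
                     "p": 0.3, "d": -0.37},
    },
    "accuracy": {
        "consultant": {"without": (71.1, 2.2), "with": (80.0, 2.2),
                       "p": 0.02, "d": 4.0},
        "registrar": {"without": (77.7, 3.8), "with": (77.0, 9.2),
                      "p": 0.87, "d": -0.1},
        "analyst": {"without": (72.6, 17.9), "with": (80.0, 2.2),
                    "p": 0.5, "d": 0.46},
        "combined": {"without": (73.8, 9.5), "with": (79.0, 5.1),
                     "p": 0.15, "d": 0.53},
    },
}

#: Per-rater kappas for the binary volume-loss call.
#: rater -> (experience, kappa without, kappa with, printed net change as a
#: string preserving the printed precision).  Only the first rater of each
#: group carries the printed group p value.
KAPPA_VOLUME_LOSS = {
    "A1": ("consultant", 0.400, 0.586, "0.186", 0.038),
    "A2": ("consultant", 0.469, 0.571, "0.102", None),
    "A3": ("consultant", 0.381, 0.492, "0.111", None),
    "B1": ("registrar", 0.455, 0.211, "-0.244", 0.68),
    "B2": ("registrar", 0.522, 0.571, "0.05", None),
    "B3": ("registrar", 0.613, 0.667, "0.054", None),
    "C1": ("analyst", 0.169, 0.531, "0.362", 0.66),
    "C2": ("analyst", 0.746, 0.556, "-0.19", None),
    "C3": ("analyst", 0.492, 0.557, "0.065", None),
}

#: Printed overall row of the volume-loss kappa table.  Note: these do not
#: equal the mean of the printed per-rater kappas (0.472 / 0.527),
#: indicating they were computed from unrounded inputs; they are stored
#: for reference but are not recomputable from the printed rows.
KAPPA_VOLUME_LOSS_OVERALL = {"mean_without": 0.48, "sd_without": 0.17,
                             "mean_with": 0.52, "sd_with": 0.13,
                             "net_change": 0.04}

#: Per-rater kappas for the three-class diagnosis agreement.
KAPPA_DIAGNOSIS = {
    "A1": ("consultant", 0.432, 0.531, "0.099", 0.04),
    "A2": ("consultant", 0.450, 0.498, "0.048", None),
    "A3": ("consultant", 0.335, 0.434, "0.099", None),
    "B1": ("registrar", 0.381, 0.220, "-0.161", 0.56),
    "B2": ("registrar", 0.326, 0.428, "0.102", None),
    "B3": ("registrar", 0.494, 0.391, "-0.103", None),
    "C1": ("analyst", 0.020, 0.176, "0.156", 0.28),
    "C2": ("analyst", 0.529, 0.496, "-0.033", None),
    "C3": ("analyst", 0.396, 0.529, "0.133", None),
}

#: Printed overall row of the diagnosis kappa table (self-consistent with
#: its per-rater rows to within one unit in the last printed digit).
KAPPA_DIAGNOSIS_OVERALL = {"mean_without": 0.37, "sd_without": 0.15,
                           "mean_with": 0.41, "sd_with": 0.13,
                           "net_change": 0.037}

#: Cross-rater reliability for the volume-loss call.
RELIABILITY = {
    "without_report": {"cronbach_alpha": 0.886, "icc_single": 0.454,
                       "icc_average": 0.882},
    "with_report": {"cronbach_alpha": 0.925, "icc_single": 0.563,
                    "icc_average": 0.921},
}

#: Published sample-size guidance for future paired studies: target power
#: -> raters required (rounded to multiples of 5 in the source).
POWER_SAMPLE_SIZES = {0.80: 30, 0.90: 40, 0.95: 45}
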