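"""Published reference values for the C-IGDC development study.

The C-IGDC (Chinese Internet Gaming Disorder Checklist) is a 34-item
screening instrument for Internet gaming disorder, organised as nine
first-order subconstructs (one per DSM-5 IGD criterion) under a single
second-order factor.  The constants below are the published standardized
factor loadings of the 34-item model, the published second-order loadings,
and the published screening-efficacy rows of the cutoff analysis against
the DSM-5 diagnostic reference (N = 464, 60 reference positives).

They serve two purposes: as default parameters for the synthetic-data
generator, and as inputs to the item-reduction and cutoff-selection
reproductions.
"""

from __future__ import annotations

# Nine subconstructs -> item labels, in questionnaire order.
FACTOR_MAP: dict[str, list[str]] = {
    "F1": ["F1_1", "F1_2", "F1_3", "F1_4"],          # preoccupation
    "F2": ["F2_1", "F2_2", "F2_3", "F2_4"],          # withdrawal
    "F3": ["F3_1", "F3_2", "F3_3"],                  # tolerance
    "F4": ["F4_1", "F4_2", "F4_3", "F4_4"],          # unsuccessful control
    "F5": ["F5_1", "F5_2", "F5_3", "F5_4"],          # loss of interests
    "F6": ["F6_1", "F6_2", "F6_3", "F6_4"],          # continued gaming
    "F7": ["F7_1", "F7_2", "F7_3"],                  # deception
    "F8": ["F8_1", "F8_2", "F8_3"],                  # escape / relief
    "F9": ["F9_1", "F9_2", "F9_3", "F9_4", "F9_5"],  # problems
}

FACTOR_NAMES: dict[str, str] = {
    "F1": "Preoccupation",
    "F2": "Withdrawal",
    "F3": "Tolerance",
    "F4": "Unsuccessful to control",
    "F5": "Loss of interests",
    "F6": "Continued gaming despite psychosocial problems",
    "F7": "Deception",
    "F8": "Escape/Relief",
    "F9": "Problems",
}

# Published standardized first-order loadings of the 34-item model.
LOADINGS_34: dict[str, float] = {
    "F1_1": 0.88, "F1_2": 0.83, "F1_3": 0.82, "F1_4": 0.81,
    "F2_1": 0.75, "F2_2": 0.80, "F2_3": 0.62, "F2_4": 0.90,
    "F3_1": 0.83, "F3_2": 0.86, "F3_3": 0.65,
    "F4_1": 0.78, "F4_2": 0.73, "F4_3": 0.68, "F4_4": 0.73,
    "F5_1": 0.83, "F5_2": 0.83, "F5_3": 0.73, "F5_4": 0.76,
    "F6_1": 0.76, "F6_2": 0.62, "F6_3": 0.79, "F6_4": 0.74,
    "F7_1": 0.80, "F7_2": 0.95, "F7_3": 0.79,
    "F8_1": 0.81, "F8_2": 0.93, "F8_3": 0.89,
    "F9_1": 0.73, "F9_2": 0.76, "F9_3": 0.77, "F9_4": 0.90, "F9_5": 0.71,
}

# Published standardized second-order loadings (subconstruct on the
# general IGD factor), 34-item model.
SECOND_ORDER_34: dict[str, float] = {
    "F1": 0.75, "F2": 0.90, "F3": 0.91, "F4": 0.93, "F5": 0.86,
    "F6": 0.84, "F7": 0.71, "F8": 0.67, "F9": 0.84,
}

# Published screening-efficacy rows for integer cutoffs 16-22 of the
# 27-item sum score against the DSM-5 reference (>=5 of 9 criteria).
# Percentages are printed at 1 dp, kappa/Youden at 2 dp.
PUBLISHED_CUTOFF_ROWS: dict[int, dict[str, float]] = {
    16: {"sensitivity": 91.7, "specificity": 73.0, "ppr": 33.5, "npr": 98.3,
         "kappa": 0.37, "youden": 0.65, "dor": 30.91},
    17: {"sensitivity": 90.0, "specificity": 78.5, "ppr": 38.3, "npr": 98.1,
         "kappa": 0.43, "youden": 0.69, "dor": 32.15},
    18: {"sensitivity": 90.0, "specificity": 80.4, "ppr": 40.6, "npr": 98.2,
         "kappa": 0.46, "youden": 0.70, "dor": 38.33},
    19: {"sensitivity": 86.7, "specificity": 82.7, "ppr": 42.6, "npr": 97.7,
         "kappa": 0.48, "youden": 0.69, "dor": 31.25},
    20: {"sensitivity": 81.7, "specificity": 85.4, "ppr": 45.4, "npr": 96.9,
         "kappa": 0.50, "youden": 0.67, "dor": 26.62},
    21: {"sensitivity": 76.7, "specificity": 87.1, "ppr": 46.9, "npr": 96.2,
         "kappa": 0.50, "youden": 0.64, "dor": 22.07},
    22: {"sensitivity": 68.3, "specificity": 90.3, "ppr": 51.3, "npr": 95.1,
         "kappa": 0.51, "youden": 0.59, "dor": 20.23},
}

#: study sample size and DSM-5 reference margin (12.9% of 464 -> 60 positives)
STUDY_N = 464
REFERENCE_POSITIVES = 60
REFERENCE_NEGATIVES = STUDY_N - REFERENCE_POSITIVES
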