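"""Shared covariate binning rules.

The bins mirror the published cluster-profile row labels: four age groups,
three BMI classes (WHO cut-offs), and four bins for the 0-10 pain and sleep
interference scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AGE_EDGES = [0.0, 45.0, 65.0, 75.0, np.inf]
AGE_LABELS = ["0-44", "45-64", "65-74", "75+"]

BMI_EDGES = [0.0, 25.0, 30.0, np.inf]
BMI_LABELS = ["normal", "overweight", "obese"]

# continuous 0-10 scores binned to the integer groups 0-3 / 4-5 / 6-7 / 8-10
SCORE_EDGES = [-0.5, 3.5, 5.5, 7.5, 10.0]
SCORE_LABELS = ["0-3", "4-5", "6-7", "8-10"]


def age_group(age) -> pd.Series:
    """Age in years -> one of 0-44 / 45-64 / 65-74 / 75+ (left-closed bins)."""
    out = pd.cut(np.asarray(age, dtype=float), bins=AGE_EDGES,
                 labels=AGE_LABELS, right=False, include_lowest=True)
    return pd.Series(out).astype(object)


def age_cohort_code(age) -> np.ndarray:
    """Numeric age-cohort coding 0..3 used as ARX input x10."""
    return np.searchsorted(AGE_EDGES[1:-1], np.asarray(age, float),
                           side="right")


def bmi_class(bmi) -> pd.Series:
    """BMI in kg/m^2 -> normal (<25) / overweight (25-30) / obese (>=30)."""
    out = pd.cut(np.asarray(bmi, dtype=float), bins=BMI_EDGES,
                 labels=BMI_LABELS, right=False, include_lowest=True)
    return pd.Series(out).astype(object)


def score_bin(score) -> pd.Series:
    """0-10 score -> 0-3 / 4-5 / 6-7 / 8-10 (nearest-integer grouping)."""
    out = pd.cut(np.asarray(score, dtype=float), bins=SCORE_EDGES,
                 labels=SCORE_LABELS, right=True, include_lowest=True)
    return pd.Series(out).astype(object)
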