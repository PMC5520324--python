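"""Reference per-cluster ARX equations for weekly pain score.

Weekly pain in a given cluster is modelled as a linear lagged regression

    pain(t) = c + a1*pain(t-1) + a2*pain(t-2) + b*sleep(t-1)
              + d0*dose(t) + d1*dose(t-1) + d2*dose(t-2)
              + exogenous patient terms + e(t),    e(t) ~ N(0, sigma^2)

with inputs named ``x1`` .. ``x13``:

====  ==========================================  ====================
name  meaning                                     units / coding
====  ==========================================  ====================
x1    pain score, lag 1                           0-10
x2    pain score, lag 2                           0-10
x3    sleep interference score, lag 1             0-10
x4    pregabalin dose, lag 0 (same week)          mg
x5    pregabalin dose, lag 1                      mg
x6    pregabalin dose, lag 2                      mg
x7    insulin use                                 0/1
x8    pregabalin monotherapy                      0/1
x9    gender                                      female=1, male=0
x10   age cohort                                  0: 0-44, 1: 45-64,
                                                  2: 65-74, 3: 75+
x11   pDPN duration                               years
x12   feeling calm and relaxed, lag 1             1=always .. 6=never
x13   feeling full of energy, lag 1               1=always .. 6=never
====  ==========================================  ====================

``CLUSTER_EQUATIONS`` holds the six published calibration equations used as
the generative truth by the synthetic-cohort module and as recovery targets
in the tests; ``CLUSTER_NOISE_SD`` holds the matching residual scales
(the published per-cluster root mean square errors).
"""

from __future__ import annotations

from .errors import SpecificationError

#: all recognised input names, in canonical order
TERM_ORDER = tuple(f"x{i}" for i in range(1, 14))

#: term name -> (panel variable, lag) for time-varying inputs
LAGGED_TERMS = {
    "x1": ("pain", 1),
    "x2": ("pain", 2),
    "x3": ("sleep", 1),
    "x4": ("dose_mg", 0),
    "x5": ("dose_mg", 1),
    "x6": ("dose_mg", 2),
    "x12": ("feeling_calm", 1),
    "x13": ("feeling_energy", 1),
}

#: term name -> cohort column for patient-level exogenous inputs
EXOGENOUS_TERMS = {
    "x7": "insulin",
    "x8": "monotherapy",
    "x9": "gender_code",
    "x10": "age_cohort_code",
    "x11": "pdpn_duration",
}

CLUSTER_EQUATIONS = {
    1: {"const": -0.0409, "x1": 0.7180, "x2": 0.0436, "x3": 0.0949,
        "x5": -0.0012, "x6": 0.0015, "x11": 0.0179},
    2: {"const": -0.1447, "x1": 0.8749, "x2": 0.0196, "x4": -0.0006,
        "x5": -0.0007, "x6": 0.0015, "x13": 0.0250},
    3: {"const": -0.0604, "x1": 0.7865, "x2": 0.0164, "x3": 0.0374,
        "x5": -0.0009, "x6": 0.0012, "x13": 0.0425},
    4: {"const": -0.0826, "x1": 0.8341, "x2": 0.0451, "x5": -0.0012,
        "x6": 0.0017, "x12": -0.0109},
    5: {"const": 0.0789, "x1": 0.9011, "x2": 0.0107, "x4": -0.0011,
        "x6": 0.0012, "x8": -0.1107, "x9": -0.0496, "x10": 0.0465},
    6: {"const": -0.2732, "x1": 0.8919, "x2": -0.0103, "x5": -0.0004,
        "x6": 0.0007, "x7": 0.0276, "x12": 0.0655},
}

#: residual standard deviation per cluster (pain-score units)
CLUSTER_NOISE_SD = {1: 0.54, 2: 0.55, 3: 0.55, 4: 0.53, 5: 0.53, 6: 0.57}


def validate_coeffs(coeffs: dict) -> None:
    """Raise :class:`SpecificationError` on unknown coefficient names."""
    known = set(TERM_ORDER) | {"const"}
    unknown = set(coeffs) - known
    if unknown:
        raise SpecificationError(
            f"unknown coefficient name(s): {sorted(unknown)}; "
            f"expected 'const' or x1..x13"
        )


def linear_predictor(coeffs: dict, inputs: dict) -> float:
    """Evaluate ``const + sum coeff * input`` for one target week.

    ``inputs`` maps term names (x1..x13) to values; terms absent from
    ``coeffs`` are ignored, terms present in ``coeffs`` but missing from
    ``inputs`` raise :class:`SpecificationError`.
    """
    validate_coeffs(coeffs)
    y = float(coeffs.get("const", 0.0))
    for name, beta in coeffs.items():
        if name == "const":
            continue
        if name not in inputs:
            raise SpecificationError(f"input {name!r} required by the equation "
                                     "but not supplied")
        y += float(beta) * float(inputs[name])
    return y
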