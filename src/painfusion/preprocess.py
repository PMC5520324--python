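"""Interpolation of missing weekly scores and responder outcomes.

Missing interior weeks are filled by local second-order (piecewise
quadratic) interpolation through the three nearest observed points, the
same order of interpolation used by time-series EXPAND-style procedures;
boundary gaps are filled by quadratic extrapolation from the last three
observed points and flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InterpolationError

INTERPOLATABLE = ("pain", "sleep", "feeling_energy", "feeling_calm",
                  "feeling_discouraged")


def _quad_eval(xs, ys, x):
    """Lagrange quadratic through three (xs, ys) points, evaluated at x."""
    (x0, x1, x2), (y0, y1, y2) = xs, ys
    return (y0 * (x - x1) * (x - x2) / ((x0 - x1) * (x0 - x2))
            + y1 * (x - x0) * (x - x2) / ((x1 - x0) * (x1 - x2))
            + y2 * (x - x0) * (x - x1) / ((x2 - x0) * (x2 - x1)))


def interpolate_second_order(weeks, values, *, lo=0.0, hi=10.0,
                             patient_id=None):
    """Fill missing entries of a weekly series by piecewise quadratics.

    ``values`` may contain NaN for missing weeks.  Each missing week is
    interpolated through the three observed weeks nearest to it (ties going
    to the earlier week), which reproduces any quadratic trend exactly and
    extrapolates boundary gaps from the nearest three points.  Observed
    values are returned unchanged; filled values are clipped to [lo, hi].

    Returns
    -------
    (filled, interpolated_mask) : pair of ndarrays
    """
    weeks = np.asarray(weeks, dtype=float)
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    if obs.sum() < 3:
        who = f" for patient {patient_id!r}" if patient_id is not None else ""
        raise InterpolationError(
            f"need >=3 observed points to interpolate{who} "
            f"(got {int(obs.sum())})")
    filled = values.copy()
    interp = np.zeros(len(values), dtype=bool)
    ow, ov = weeks[obs], values[obs]
    for i in np.flatnonzero(~obs):
        order = np.argsort(np.abs(ow - weeks[i]), kind="stable")[:3]
        filled[i] = float(np.clip(_quad_eval(ow[order], ov[order], weeks[i]),
                                  lo, hi))
        interp[i] = True
    return filled, interp


def interpolate_panel(panel: pd.DataFrame,
                      variables=("pain", "sleep")) -> pd.DataFrame:
    """Interpolate the requested weekly variables for every patient.

    Adds an ``interpolated`` flag column (True on weeks whose values were
    filled).  Patients with fewer than three observed weeks raise
    :class:`InterpolationError` naming the patient.
    """
    panel = panel.sort_values(["patient_id", "week"], kind="stable").copy()
    panel["interpolated"] = False
    for pid, grp in panel.groupby("patient_id", sort=False):
        idx = grp.index
        any_interp = np.zeros(len(idx), dtype=bool)
        for var in variables:
            vals = grp[var].to_numpy(dtype=float)
            if not np.isnan(vals).any():
                continue
            filled, mask = interpolate_second_order(
                grp["week"].to_numpy(), vals, patient_id=pid)
            panel.loc[idx, var] = filled
            any_interp |= mask
        panel.loc[idx[any_interp], "interpolated"] = True
    return panel


def responder_level(pain_baseline, pain_t):
    """Fractional pain reduction (baseline - pain_t) / baseline.

    Positive values are improvement; a worsening gives a negative level.
    Undefined (error) at zero baseline.
    """
    pain_baseline = np.asarray(pain_baseline, dtype=float)
    if np.any(pain_baseline <= 0):
        raise DegenerateInputError(
            "responder level undefined for baseline pain <= 0")
    return (pain_baseline - np.asarray(pain_t, dtype=float)) / pain_baseline


def classify_responder(level, threshold=0.50):
    """Responder flag: level >= threshold (inclusive). Threshold in (0, 1]."""
    if not 0 < threshold <= 1:
        raise DegenerateInputError("threshold must lie in (0, 1]")
    return np.asarray(level, dtype=float) >= threshold
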