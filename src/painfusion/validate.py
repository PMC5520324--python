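"""Validation of the calibrated models on patients never matched to the RCT.

Two checks mirror the source design: (i) two-sample t-tests of observed
versus model-predicted pain outcomes, per cluster, on the validation set
(observational patients with no coarsened exact match); (ii) a before/after
comparison of the log-likelihood of a multinomial logit of binned baseline
pain on the matching variables, quantifying how much the matched sample
improves the explanatory grip of those variables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import binning
from .errors import DegenerateInputError
from .preprocess import classify_responder, responder_level

LOGIT_VARS = ("gender_code", "age", "bmi", "baseline_sleep")


def ttest_obs_vs_pred(observed, predicted, paired: bool = False):
    """Student's t-test of observed vs predicted values.

    Two-sample with pooled variance by default (``paired=True`` switches to
    the paired test).  Returns ``(t, p)`` with a two-sided p-value.
    """
    a = np.asarray(observed, dtype=float)
    b = np.asarray(predicted, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("both samples need >= 2 values")
    if paired:
        if len(a) != len(b):
            raise DegenerateInputError("paired test needs equal lengths")
        d = a - b
        if np.allclose(d.std(ddof=1), 0):
            if np.allclose(d, 0):
                return 0.0, 1.0
            raise DegenerateInputError("zero variance of paired differences")
        t, p = stats.ttest_rel(a, b)
        return float(t), float(p)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DegenerateInputError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def _final_levels(fit, cohort_row_by_id, panel, patient_ids, final_week):
    """Observed and predicted responder levels at the final week."""
    obs_lv, pred_lv, used = [], [], []
    by_pid = {pid: grp for pid, grp in panel.groupby("patient_id")}
    for pid in patient_ids:
        grp = by_pid.get(pid)
        if grp is None:
            continue
        g = grp.set_index("week")
        if final_week not in g.index or pd.isna(g.loc[final_week, "pain"]):
            continue
        patient = cohort_row_by_id.loc[pid]
        base = float(g.loc[0, "pain"]) if 0 in g.index else float(
            patient["baseline_pain"])
        if base <= 0:
            continue
        pred = fit.predict_trajectory(patient, grp, dynamic=True)
        obs_lv.append(float(responder_level(base, g.loc[final_week, "pain"])))
        pred_lv.append(float(responder_level(base, pred.loc[final_week])))
        used.append(pid)
    return np.array(obs_lv), np.array(pred_lv), used


def validate_unmatched(fits: dict, cohort: pd.DataFrame, matched_ids,
                       panel: pd.DataFrame, assignment: pd.Series,
                       thresholds=(0.50, 0.30), final_week: int = 6,
                       condition_on: str = "observed") -> pd.DataFrame:
    """Observed-vs-predicted report on the validation (unmatched) patients.

    For each cluster: t-test p-values comparing observed and predicted
    final-week pain among responders (at each threshold), and comparing
    observed and predicted responder-status indicators.  ``condition_on``
    chooses whether "responders" means observed or predicted responders.
    Clusters with no unmatched patients yield a row of NaNs.
    """
    matched_ids = set(matched_ids)
    cov = cohort.set_index("patient_id")
    rows = []
    for c, fit in sorted(fits.items()):
        members = assignment.index[assignment == c]
        unmatched = [pid for pid in members if pid not in matched_ids]
        row = {"cluster": c, "n_validation": len(unmatched)}
        if not unmatched:
            warnings.warn(f"cluster {c}: no unmatched patients")
            rows.append(row)
            continue
        obs_lv, pred_lv, used = _final_levels(fit, cov, panel, unmatched,
                                              final_week)
        row["n_validation"] = len(used)
        if len(used) < 2:
            rows.append(row)
            continue
        base = cov.loc[used, "baseline_pain"].to_numpy(dtype=float)
        obs_pain = base * (1 - obs_lv)
        pred_pain = base * (1 - pred_lv)
        for thr in thresholds:
            key = f"{int(round(thr * 100))}"
            sel = (classify_responder(obs_lv, thr) if condition_on == "observed"
                   else classify_responder(pred_lv, thr))
            if sel.sum() >= 2:
                _, p = ttest_obs_vs_pred(obs_pain[sel], pred_pain[sel])
                row[f"p_pain_resp{key}"] = p
            _, p = ttest_obs_vs_pred(
                classify_responder(obs_lv, thr).astype(float),
                classify_responder(pred_lv, thr).astype(float))
            row[f"p_status{key}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def _mnlogit_llf(df: pd.DataFrame, outcome_col: str, xvars) -> float:
    import statsmodels.api as sm

    cats = sorted(df[outcome_col].dropna().unique())
    if len(cats) < 2:
        raise DegenerateInputError("outcome has a single category")
    y = df[outcome_col].map({c: i for i, c in enumerate(cats)}).to_numpy()
    X = sm.add_constant(df[list(xvars)].to_numpy(dtype=float),
                        has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(y, X).fit(disp=0, maxiter=200)
    return float(res.llf)


def loglik_before_after(cohort: pd.DataFrame, before_ids, after_ids,
                        matching_vars=LOGIT_VARS):
    """Multinomial-logit log-likelihood of binned baseline pain, before vs
    after matching.

    Baseline pain is binned to the published score groups (0-3/4-5/6-7/8-10)
    and regressed on the matching variables in both samples.  Sparse outcome
    bins (fewer than 2 patients) are collapsed into the adjacent bin with a
    warning.  Returns ``(llf_before, llf_after, chi2_p)`` where the p-value
    is from a chi-square comparison of the two log-likelihoods on the model's
    degrees of freedom.
    """
    cov = cohort.set_index("patient_id")

    def prep(ids):
        df = cov.loc[list(ids), list(matching_vars) + ["baseline_pain"]].copy()
        df["pain_bin"] = binning.score_bin(df["baseline_pain"]).to_numpy()
        counts = df["pain_bin"].value_counts()
        order = [b for b in binning.SCORE_LABELS if b in counts.index]
        for i, b in enumerate(order):
            if counts[b] < 2 and len(order) > 1:
                tgt = order[i + 1] if i + 1 < len(order) else order[i - 1]
                warnings.warn(f"collapsing sparse pain bin {b!r} into {tgt!r}")
                df.loc[df["pain_bin"] == b, "pain_bin"] = tgt
        return df

    llf_before = _mnlogit_llf(prep(before_ids), "pain_bin", matching_vars)
    llf_after = _mnlogit_llf(prep(after_ids), "pain_bin", matching_vars)
    df_model = (len(matching_vars) + 1) * (len(binning.SCORE_LABELS) - 1)
    stat = 2.0 * abs(llf_after - llf_before)
    p = float(stats.chi2.sf(stat, df_model))
    return llf_before, llf_after, p
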