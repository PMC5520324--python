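"""Per-cluster ARX calibration of weekly pain scores.

The model is a linear lagged regression of pain on its own lags, lagged
sleep interference, current and lagged pregabalin dose, lagged feeling
items and patient-level exogenous covariates, fit by Gaussian maximum
likelihood (equivalently ordinary least squares).  The published equations
carry no moving-average error terms, so despite the ARMAX name the model
family implemented here is ARX.

Organisation follows the statsmodels idiom: build a
:class:`PainARXModel` from a completed weekly panel (``from_panel``), call
``fit()`` and work with the returned :class:`PainARXResults` (coefficients,
standard errors, log-likelihood, R^2, RMSE, likelihood-ratio test,
``summary()``, trajectory prediction).  ``stepwise_select`` wraps the
forward/backward partial-F search used to pick each cluster's terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .equations import (EXOGENOUS_TERMS, LAGGED_TERMS, TERM_ORDER,
                        linear_predictor)
from .errors import (DegenerateInputError, PredictionError, SingularFitError,
                     SpecificationError)
from .preprocess import responder_level


@dataclass(frozen=True)
class ARXSpec:
    """Candidate term set for one cluster's model (subset of x1..x13)."""

    terms: tuple

    def __post_init__(self):
        unknown = set(self.terms) - set(TERM_ORDER)
        if unknown:
            raise SpecificationError(f"unknown terms: {sorted(unknown)}")
        ordered = tuple(t for t in TERM_ORDER if t in self.terms)
        object.__setattr__(self, "terms", ordered)

    @property
    def max_lag(self) -> int:
        lags = [LAGGED_TERMS[t][1] for t in self.terms if t in LAGGED_TERMS]
        return max(lags, default=0)


DEFAULT_SPEC = ARXSpec(TERM_ORDER)


def build_design(panel: pd.DataFrame, cohort: pd.DataFrame, spec: ARXSpec,
                 patients=None) -> pd.DataFrame:
    """Stack one regression row per patient-week with all lags available.

    Target weeks run from ``max(1, max lag)`` of the spec through the last
    panel week; rows with any required input missing are dropped (count
    emitted as a warning).  Output is ordered by (patient, week) with the
    response in column ``y``.
    """
    if patients is not None:
        panel = panel[panel["patient_id"].isin(set(patients))]
    exo_cols = {t: EXOGENOUS_TERMS[t] for t in spec.terms
                if t in EXOGENOUS_TERMS}
    cov = cohort.set_index("patient_id")

    wide = {}
    for var in {"pain"} | {LAGGED_TERMS[t][0] for t in spec.terms
                           if t in LAGGED_TERMS}:
        wide[var] = panel.pivot(index="patient_id", columns="week",
                                values=var)
    weeks = sorted(wide["pain"].columns)
    t0 = max(1, spec.max_lag)
    targets = [w for w in weeks if w >= t0]

    blocks = []
    for w in targets:
        block = pd.DataFrame(index=wide["pain"].index)
        block["y"] = wide["pain"][w]
        for t in spec.terms:
            if t in LAGGED_TERMS:
                var, lag = LAGGED_TERMS[t]
                wl = w - lag
                block[t] = wide[var][wl] if wl in wide[var].columns else np.nan
            else:
                block[t] = cov.loc[block.index, exo_cols[t]].to_numpy(dtype=float)
        block["week"] = w
        blocks.append(block)
    design = pd.concat(blocks)
    design = design.reset_index().sort_values(["patient_id", "week"],
                                              kind="stable")
    design = design.set_index(["patient_id", "week"])
    n0 = len(design)
    design = design.dropna()
    dropped = n0 - len(design)
    if dropped:
        warnings.warn(f"build_design: dropped {dropped} rows with missing lags")
    return design[["y", *spec.terms]]


class PainARXModel:
    """Gaussian ARX model of weekly pain on a stacked design.

    Parameters
    ----------
    design
        Frame from :func:`build_design` (column ``y`` plus term columns).
    spec
        The term set; defaults to the design's columns.
    cluster_id
        Optional label carried through to results.
    """

    def __init__(self, design: pd.DataFrame, spec: ARXSpec | None = None,
                 cluster_id=None):
        self.design = design
        self.spec = spec if spec is not None else ARXSpec(
            tuple(c for c in design.columns if c != "y"))
        self.cluster_id = cluster_id
        self.endog = design["y"].to_numpy(dtype=float)
        self.exog = design[list(self.spec.terms)].to_numpy(dtype=float)

    @classmethod
    def from_panel(cls, panel, cohort, spec=DEFAULT_SPEC, patients=None,
                   cluster_id=None) -> "PainARXModel":
        design = build_design(panel, cohort, spec, patients)
        return cls(design, spec, cluster_id)

    def _check_rank(self, X):
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # point at the terms loading on the null space
            _, s, vt = np.linalg.svd(X, full_matrices=False)
            null = np.abs(vt[-1]) > 1e-6
            names = ["const", *self.spec.terms]
            bad = [names[i] for i in np.flatnonzero(null)]
            raise SingularFitError(f"design is rank deficient; collinear "
                                   f"terms: {bad}")

    def fit(self) -> "PainARXResults":
        """Gaussian maximum-likelihood fit (identical to least squares)."""
        n, p = self.exog.shape
        if n < p + 1:
            raise DegenerateInputError(
                f"need at least terms+1 rows ({p + 1}), got {n}")
        X = sm.add_constant(self.exog, has_constant="add")
        self._check_rank(X)
        res = sm.OLS(self.endog, X).fit()
        return PainARXResults(self, res)


class PainARXResults:
    """Fitted ARX model: estimates, uncertainties, fit metrics, prediction."""

    def __init__(self, model: PainARXModel, smres):
        self.model = model
        self._smres = smres
        names = ["const", *model.spec.terms]
        self.params = pd.Series(smres.params, index=names)
        self.bse = pd.Series(smres.bse, index=names)
        self.nobs = int(smres.nobs)
        self.resid = np.asarray(smres.resid)
        sse = float(self.resid @ self.resid)
        self.rmse = float(np.sqrt(sse / self.nobs))
        self.noise_sd = self.rmse          # ML residual scale
        self.llf = float(smres.llf)
        self.rsquared = float(smres.rsquared)

    @property
    def cluster_id(self):
        return self.model.cluster_id

    def coeffs(self) -> dict:
        """Coefficient mapping usable by the trajectory simulator."""
        return self.params.to_dict()

    def loglik_null(self) -> float:
        y = self.model.endog
        sse0 = float(((y - y.mean()) ** 2).sum())
        n = self.nobs
        return -n / 2 * (np.log(2 * np.pi * sse0 / n) + 1)

    def lr_test(self):
        """Likelihood-ratio test of the model against intercept-only."""
        stat = 2 * (self.llf - self.loglik_null())
        df = len(self.model.spec.terms)
        return stat, df, float(stats.chi2.sf(stat, df)) if df else 1.0

    @property
    def lr_pvalue(self) -> float:
        return self.lr_test()[2]

    def summary(self):
        return self._smres.summary(
            yname="pain", xname=["const", *self.model.spec.terms])

    def to_dict(self) -> dict:
        stat, df, p = self.lr_test()
        return {"cluster": self.cluster_id,
                "terms": list(self.model.spec.terms),
                "coefficients": {k: float(v) for k, v in self.params.items()},
                "bse": {k: float(v) for k, v in self.bse.items()},
                "noise_sd": self.noise_sd, "log_likelihood": self.llf,
                "r2": self.rsquared, "rmse": self.rmse, "n_obs_used": self.nobs,
                "lr_pvalue": p}

    def predict_trajectory(self, patient, patient_panel: pd.DataFrame,
                           weeks=None, dynamic: bool = True) -> pd.Series:
        """Roll the fitted equation forward for one patient.

        ``patient_panel`` supplies the patient's weekly inputs (sleep, dose,
        feelings, and observed pain).  With ``dynamic=True`` predicted pain
        feeds the pain lags beyond the first step; with ``dynamic=False``
        observed pain lags are used (one-step-ahead mode, the basis of the
        fit metrics).  Predictions are clipped to [0, 10].
        """
        return predict_trajectory(self.coeffs(), patient, patient_panel,
                                  weeks=weeks, dynamic=dynamic)


def predict_trajectory(coeffs: dict, patient, patient_panel: pd.DataFrame,
                       weeks=None, dynamic: bool = True) -> pd.Series:
    """Iterated one-step prediction of weekly pain from a coefficient map."""
    pp = patient_panel.sort_values("week").set_index("week")
    have_weeks = list(pp.index)
    if weeks is None:
        weeks = [w for w in have_weeks if w >= 1]
    base = float(pp.loc[0, "pain"]) if 0 in pp.index else float(
        patient["baseline_pain"])

    exo = {}
    for name, col in EXOGENOUS_TERMS.items():
        if name in coeffs:
            if col not in patient or pd.isna(patient[col]):
                raise PredictionError(f"missing exogenous input {col!r} ({name})")
            exo[name] = float(patient[col])

    def panel_val(var, w, term):
        if w < 0:
            return 0.0 if var == "dose_mg" else base
        if w not in pp.index or pd.isna(pp.loc[w, var]):
            raise PredictionError(f"missing {var!r} at week {w} ({term})")
        return float(pp.loc[w, var])

    pain_hat = {0: base, -1: base}
    preds = {}
    for t in sorted(weeks):
        inputs = dict(exo)
        for term in ("x1", "x2"):
            if term not in coeffs:
                continue
            lag = LAGGED_TERMS[term][1]
            w = t - lag
            if dynamic and w in preds:
                inputs[term] = preds[w]
            elif w <= 0:
                inputs[term] = pain_hat.get(w, base)
            else:
                inputs[term] = panel_val("pain", w, term)
        for term in ("x3", "x4", "x5", "x6", "x12", "x13"):
            if term in coeffs:
                var, lag = LAGGED_TERMS[term]
                inputs[term] = panel_val(var, t - lag, term)
        preds[t] = float(np.clip(linear_predictor(coeffs, inputs), 0.0, 10.0))
    return pd.Series(preds, name="pain_pred").sort_index()


def cross_correlation_screen(panel: pd.DataFrame, target: str = "pain",
                             candidates=("sleep", "dose_mg", "feeling_energy",
                                         "feeling_calm", "feeling_discouraged"),
                             lags=(-2, -1, 0, 1, 2),
                             min_pairs: int = 3) -> pd.DataFrame:
    """Pearson cross-correlations between pain(t) and candidate(t+lag).

    Pairs are pooled across patients.  Variables with zero variance (or too
    few pairs) get NaN.  Use :func:`format_correlation_report` for the
    reporting convention that suppresses values below 0.70.
    """
    wide = {v: panel.pivot(index="patient_id", columns="week", values=v)
            for v in {target, *candidates}}
    weeks = sorted(wide[target].columns)
    out = pd.DataFrame(index=list(candidates), columns=list(lags), dtype=float)
    for var in candidates:
        for lag in lags:
            xs, ys = [], []
            for w in weeks:
                if w + lag not in wide[var].columns:
                    continue
                a = wide[target][w].to_numpy(dtype=float)
                b = wide[var][w + lag].to_numpy(dtype=float)
                ok = ~(np.isnan(a) | np.isnan(b))
                xs.append(a[ok])
                ys.append(b[ok])
            if not xs:
                continue
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            if len(x) < min_pairs or x.std() == 0 or y.std() == 0:
                continue
            out.loc[var, lag] = float(np.corrcoef(x, y)[0, 1])
    out.index.name = "variable"
    out.columns.name = "lag"
    return out


def format_correlation_report(corr: pd.DataFrame,
                              threshold: float = 0.70) -> pd.DataFrame:
    """Reporting view: only cross-correlations >= threshold are shown."""
    return corr.where(corr >= threshold)


def stepwise_select(model: PainARXModel, alpha: float = 0.05):
    """Forward-then-backward term selection by partial-F tests.

    Forward: repeatedly add the candidate with the largest partial F whose
    p-value is below ``alpha`` (ties broken by the canonical x1..x13
    order).  Backward: repeatedly drop the included term with the smallest
    partial F whose p-value is at or above ``alpha``.  Returns the fitted
    :class:`PainARXResults` of the final model (intercept-only, with a
    warning, when nothing enters).
    """
    y = model.endog
    n = len(y)
    candidates = list(model.spec.terms)
    cols = {t: model.design[t].to_numpy(dtype=float) for t in candidates}

    def sse_of(terms):
        X = np.column_stack([np.ones(n)] + [cols[t] for t in terms])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    def partial_f(terms_small, terms_big):
        sse_r, sse_f = sse_of(terms_small), sse_of(terms_big)
        df2 = n - (len(terms_big) + 1)
        if df2 <= 0 or sse_f <= 0:
            return np.inf, 0.0
        f = (sse_r - sse_f) / (sse_f / df2)
        return f, float(stats.f.sf(f, 1, df2))

    included: list = []
    while True:
        best = None
        for t in candidates:
            if t in included:
                continue
            f, p = partial_f(included, included + [t])
            if p < alpha and (best is None or f > best[1] + 1e-12):
                best = (t, f)
        if best is None:
            break
        included.append(best[0])
    while included:
        worst = None
        for t in included:
            rest = [u for u in included if u != t]
            f, p = partial_f(rest, included)
            if p >= alpha and (worst is None or f < worst[1] - 1e-12):
                worst = (t, f)
        if worst is None:
            break
        included.remove(worst[0])

    included = [t for t in TERM_ORDER if t in included]
    if not included:
        warnings.warn("stepwise_select: no term passed entry; "
                      "returning intercept-only model")
    sub = model.design[["y", *included]]
    return PainARXModel(sub, ARXSpec(tuple(included)) if included else
                        ARXSpec(()), model.cluster_id).fit()


def roc_responder(observed_levels, predicted_levels, threshold: float = 0.50):
    """ROC of predicted responder level against observed responder status.

    Observed status is ``observed_level >= threshold``; the ROC sweeps
    cutoffs of the predicted level, with trapezoidal AUC.  Returns a dict
    with ``fpr``, ``tpr``, ``cutoffs`` and ``auc`` (None when the observed
    labels are single-class).
    """
    from sklearn.metrics import auc as _auc
    from sklearn.metrics import roc_curve

    obs = np.asarray(observed_levels, dtype=float)
    pred = np.asarray(predicted_levels, dtype=float)
    labels = obs >= threshold
    if labels.all() or not labels.any():
        return {"fpr": None, "tpr": None, "cutoffs": None, "auc": None}
    fpr, tpr, cut = roc_curve(labels.astype(int), pred)
    return {"fpr": fpr, "tpr": tpr, "cutoffs": cut,
            "auc": float(_auc(fpr, tpr))}
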