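"""Synthetic pDPN cohort generator.

Emulates the structure of the source datasets this pipeline was designed
for: a large observational cohort with weekly pain/sleep scores observed at
weeks 0, 1, 3 and 6 (weeks 2, 4, 5 missing), and a smaller fixed-dose RCT
cohort observed every week.  Patients are drawn from a six-component mixture
of cluster profiles (see ``data/cluster_params.yaml``); weekly pain follows
the per-cluster reference ARX equations plus Gaussian noise, sleep
interference tracks pain, pregabalin dose follows a 75 -> 150 -> terminal
titration ladder (fixed dose in the RCT arm), and the three general-feeling
items evolve as sticky six-state chains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import binning
from .config import CohortConfig, DEFAULT_WEEKS, load_cluster_params
from .equations import CLUSTER_EQUATIONS, CLUSTER_NOISE_SD, linear_predictor
from .errors import ConfigurationError

PANEL_COLUMNS = ["patient_id", "week", "pain", "sleep", "dose_mg",
                 "feeling_energy", "feeling_calm", "feeling_discouraged",
                 "observed"]

COHORT_COLUMNS = ["patient_id", "arm", "gender", "gender_code", "age",
                  "age_group", "age_cohort_code", "bmi", "bmi_class",
                  "pdpn_duration", "depression_history", "monotherapy",
                  "prior_gabapentin", "insulin", "baseline_pain",
                  "baseline_sleep", "true_cluster"]

#: non-ladder doses used for the residual "other" dose category (mg)
_OTHER_DOSES = np.array([50, 100, 200, 250, 400, 450, 500], dtype=float)
_LADDER = np.array([75.0, 150.0, 300.0, 600.0])

_MEASURED_VARS = ("pain", "sleep", "feeling_energy", "feeling_calm",
                  "feeling_discouraged")


def _tnorm(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_cluster_covariates(n, cluster, params, rng):
    """Draw n patients' baseline covariates from one cluster profile."""
    p = params["clusters"][cluster]
    female = rng.random(n) < p["female_pct"] / 100.0
    age = _tnorm(rng, p["age"]["mean"], p["age"]["sd"], 18, 95, n)
    bmi = _tnorm(rng, p["bmi"]["mean"], p["bmi"]["sd"], 15, 60, n)
    dur = _tnorm(rng, p["pdpn_duration"]["mean"], p["pdpn_duration"]["sd"],
                 0, 40, n)
    pain0 = _tnorm(rng, p["baseline_pain"]["mean"], p["baseline_pain"]["sd"],
                   0, 10, n)
    sleep0 = _tnorm(rng, p["baseline_sleep"]["mean"],
                    p["baseline_sleep"]["sd"], 0, 10, n)
    return pd.DataFrame({
        "gender": np.where(female, "female", "male"),
        "gender_code": female.astype(int),
        "age": age,
        "age_group": binning.age_group(age).to_numpy(),
        "age_cohort_code": binning.age_cohort_code(age),
        "bmi": bmi,
        "bmi_class": binning.bmi_class(bmi).to_numpy(),
        "pdpn_duration": dur,
        "depression_history": (rng.random(n) < p["depression_pct"] / 100).astype(int),
        "monotherapy": (rng.random(n) < p["monotherapy_pct"] / 100).astype(int),
        "prior_gabapentin": (rng.random(n) < p["prior_gabapentin_pct"] / 100).astype(int),
        "insulin": (rng.random(n) < p["insulin_pct"] / 100).astype(int),
        "baseline_pain": pain0,
        "baseline_sleep": sleep0,
        "true_cluster": cluster,
    })


def _sample_terminal_dose(cluster, params, rng) -> float:
    p = params["clusters"][cluster]["dose_pct"]
    cats = [75, 150, 300, 600, "other"]
    w = np.array([p[c] for c in cats], dtype=float)
    pick = cats[rng.choice(len(cats), p=w / w.sum())]
    if pick == "other":
        return float(rng.choice(_OTHER_DOSES))
    return float(pick)


def _dose_schedule(terminal, weeks, arm):
    """Titration ladder 75 -> 150 -> terminal; RCT doses are fixed."""
    if arm == "rct":
        return {w: terminal for w in weeks}
    sched = {}
    for w in weeks:
        if w == 0:
            sched[w] = min(75.0, terminal)
        elif w == 1:
            sched[w] = min(150.0, terminal)
        else:
            sched[w] = terminal
    return sched


def _sample_feeling(freqs, rng) -> int:
    w = np.asarray(freqs, dtype=float)
    return int(rng.choice(6, p=w / w.sum())) + 1


def _step_feeling(state, stay_prob, rng) -> int:
    if rng.random() < stay_prob:
        return state
    if state == 1:
        return 2
    if state == 6:
        return 5
    return state + 1 if rng.random() < 0.5 else state - 1


def simulate_trajectory(patient, coeffs, noise_sd, rng, *, params=None,
                        weeks=DEFAULT_WEEKS, arm="observational",
                        terminal_dose=None) -> pd.DataFrame:
    """Simulate one patient's weekly panel rows from an ARX equation.

    Parameters
    ----------
    patient
        Mapping / Series with the baseline covariates (at least
        ``baseline_pain``; exogenous codes and ``true_cluster`` as needed by
        the equation and the auxiliary processes).
    coeffs
        Coefficient mapping over ``const`` and x1..x13, e.g. one of
        :data:`painfusion.equations.CLUSTER_EQUATIONS`.
    noise_sd
        Residual SD of the pain process (>= 0).
    rng
        Integer seed or :class:`numpy.random.Generator`.

    Notes
    -----
    Lags reaching below week 0 use a baseline-carry convention: lagged pain
    is the baseline pain score and lagged dose is 0.  Pain and sleep are
    clipped to the 0-10 scale after noise.
    """
    rng = np.random.default_rng(rng) if not hasattr(rng, "normal") else rng
    if params is None:
        params = load_cluster_params()
    cluster = int(patient.get("true_cluster", 1)) if hasattr(patient, "get") \
        else int(patient["true_cluster"])
    cp = params["clusters"][cluster]
    aux = params["aux"]

    weeks = tuple(weeks)
    horizon = range(0, (max(weeks) + 1) if weeks else 0)
    if terminal_dose is None:
        terminal_dose = _sample_terminal_dose(cluster, params, rng)
    dose = _dose_schedule(terminal_dose, list(horizon), arm)

    pain0 = float(patient["baseline_pain"])
    sleep0 = float(patient.get("baseline_sleep", pain0))
    sleep_alpha = (cp["baseline_sleep"]["mean"]
                   - aux["sleep_slope"] * cp["baseline_pain"]["mean"])

    pain = {0: pain0, -1: pain0}
    sleep = {0: sleep0}
    feel = {0: {k: _sample_feeling(cp["feelings"][k], rng)
                for k in ("energy", "calm", "discouraged")}}

    exo = {}
    for name, col in (("x7", "insulin"), ("x8", "monotherapy"),
                      ("x9", "gender_code"), ("x10", "age_cohort_code"),
                      ("x11", "pdpn_duration")):
        if name in coeffs:
            exo[name] = float(patient[col])

    for t in horizon:
        if t == 0:
            continue
        inputs = dict(exo)
        inputs["x1"] = pain[t - 1]
        inputs["x2"] = pain[t - 2] if t >= 2 else pain[-1]
        inputs["x3"] = sleep[t - 1]
        inputs["x4"] = dose[t]
        inputs["x5"] = dose.get(t - 1, 0.0)
        inputs["x6"] = dose.get(t - 2, 0.0)
        inputs["x12"] = feel[t - 1]["calm"]
        inputs["x13"] = feel[t - 1]["energy"]
        y = linear_predictor(coeffs, inputs)
        if noise_sd > 0:
            y += rng.normal(0.0, noise_sd)
        pain[t] = float(np.clip(y, 0.0, 10.0))
        s = sleep_alpha + aux["sleep_slope"] * pain[t]
        s += rng.normal(0.0, aux["sleep_noise_sd"])
        sleep[t] = float(np.clip(s, 0.0, 10.0))
        feel[t] = {k: _step_feeling(feel[t - 1][k], aux["feeling_stay_prob"], rng)
                   for k in ("energy", "calm", "discouraged")}

    pid = patient["patient_id"] if "patient_id" in patient else ""
    rows = [{
        "patient_id": pid, "week": w, "pain": pain[w], "sleep": sleep[w],
        "dose_mg": dose[w], "feeling_energy": feel[w]["energy"],
        "feeling_calm": feel[w]["calm"],
        "feeling_discouraged": feel[w]["discouraged"], "observed": True,
    } for w in weeks]
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def inject_missingness(panel: pd.DataFrame, missing_weeks,
                       obs_patients) -> pd.DataFrame:
    """Mask measured variables at ``missing_weeks`` for observational patients.

    Pain, sleep and the feeling items are set to NaN and ``observed`` to
    False; the prescribed dose is left in place.  RCT patients (those not in
    ``obs_patients``) are untouched.  Returns a new frame.
    """
    missing_weeks = set(missing_weeks)
    panel = panel.copy()
    if not missing_weeks or panel.empty:
        return panel
    bad = missing_weeks - set(panel["week"].unique())
    if bad:
        raise ConfigurationError(f"weeks {sorted(bad)} not present in panel")
    obs_patients = set(obs_patients)
    mask = panel["week"].isin(missing_weeks) & panel["patient_id"].isin(obs_patients)
    panel.loc[mask, list(_MEASURED_VARS)] = np.nan
    panel.loc[mask, "observed"] = False
    return panel


def generate_cohort(config: CohortConfig, trajectories: bool = True):
    """Generate the full synthetic cohort.

    Returns ``(cohort, panel)``: one row per patient with baseline
    covariates and the latent ``true_cluster`` label, and the long weekly
    panel (observational-arm weeks in ``config.missing_weeks_obs`` already
    masked).  Deterministic given ``config.seed``.  With
    ``trajectories=False`` only the covariate table is populated and the
    panel comes back empty (useful when only baseline structure is needed).
    """
    params = load_cluster_params(config.params_path)
    mix = np.asarray(config.cluster_mix if config.cluster_mix is not None
                     else params["cluster_mix"], dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ConfigurationError("cluster_mix must sum to 1")

    ss = np.random.SeedSequence(config.seed)
    cov_rng, traj_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    frames = []
    for arm, n in (("observational", config.n_obs), ("rct", config.n_rct)):
        if n == 0:
            continue
        labels = cov_rng.choice(6, size=n, p=mix) + 1
        parts = []
        for c in range(1, 7):
            nc = int((labels == c).sum())
            if nc:
                parts.append(_sample_cluster_covariates(nc, c, params, cov_rng))
        block = pd.concat(parts, ignore_index=True)
        prefix = "OBS" if arm == "observational" else "RCT"
        block.insert(0, "arm", arm)
        block.insert(0, "patient_id",
                     [f"{prefix}-{i:05d}" for i in range(1, len(block) + 1)])
        frames.append(block)

    if not frames:
        cohort = pd.DataFrame(columns=COHORT_COLUMNS)
        panel = pd.DataFrame(columns=PANEL_COLUMNS)
        return cohort, panel

    cohort = pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]
    if not trajectories:
        return cohort, pd.DataFrame(columns=PANEL_COLUMNS)

    panels = []
    for _, patient in cohort.iterrows():
        c = int(patient["true_cluster"])
        noise = (config.noise_sd if config.noise_sd is not None
                 else params["clusters"][c].get("noise_sd", CLUSTER_NOISE_SD[c]))
        panels.append(simulate_trajectory(
            patient, CLUSTER_EQUATIONS[c], noise, traj_rng, params=params,
            weeks=config.week_grid, arm=patient["arm"]))
    panel = pd.concat(panels, ignore_index=True)

    obs_ids = cohort.loc[cohort["arm"] == "observational", "patient_id"]
    panel = inject_missingness(panel, config.missing_weeks_obs, obs_ids)
    return cohort, panel


def write_cohort_csv(cohort: pd.DataFrame, path, seed=None) -> None:
    """Write cohort.csv, one row per patient, seed recorded in a header comment."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# painfusion cohort, seed={seed}\n")
        cohort.to_csv(fh, index=False)


def write_panel_csv(panel: pd.DataFrame, path, seed=None) -> None:
    """Write panel.csv in long format: patient_id, week, variable, value, observed."""
    long = panel.melt(
        id_vars=["patient_id", "week", "observed"],
        value_vars=[c for c in PANEL_COLUMNS
                    if c not in ("patient_id", "week", "observed")],
        var_name="variable", value_name="value")
    long = long.sort_values(["patient_id", "week", "variable"],
                            kind="stable").reset_index(drop=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# painfusion panel, seed={seed}\n")
        long.to_csv(fh, index=False)


def read_panel_csv(path) -> pd.DataFrame:
    """Read a long-format panel.csv back into the wide in-memory layout."""
    long = pd.read_csv(path, comment="#")
    wide = long.pivot(index=["patient_id", "week"], columns="variable",
                      values="value")
    wide["observed"] = long.groupby(["patient_id", "week"])["observed"].first()
    wide = wide.reset_index()
    wide.columns.name = None
    cols = [c for c in PANEL_COLUMNS if c in wide.columns]
    return wide[cols]
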