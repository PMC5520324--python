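"""End-to-end orchestration: synth -> preprocess -> cluster -> CEM -> ARX ->
validation, with a JSON manifest recording seeds, parameters and patient
accounting at every stage."""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arx import DEFAULT_SPEC, PainARXModel, roc_responder, stepwise_select
from .cem import default_scheme, imbalance_report, match_cluster
from .cluster import (cut_by_spr2, encode_features, profile_clusters,
                      semipartial_r2, ward_cluster)
from .config import CohortConfig
from .errors import ConfigurationError, PainfusionError
from .preprocess import interpolate_panel, responder_level
from .synth import generate_cohort, write_cohort_csv, write_panel_csv

_DEFAULT_CONFIG = {
    "synth": {"n_obs": 3159, "n_rct": 398, "seed": 0, "noise_sd": None,
              "missing_weeks": [2, 4, 5]},
    "cluster": {"spr2_threshold": 0.05},
    "cem": {},
    "armax": {"alpha": 0.05, "stepwise": True},
    "validate": {"thresholds": [0.50, 0.30]},
}

_REQUIRED_SYNTH_KEYS = ("n_obs", "n_rct", "seed")


def load_config(path_or_dict) -> dict:
    """Parse and validate a pipeline configuration (YAML path or dict)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(path_or_dict)
    unknown = set(cfg) - set(_DEFAULT_CONFIG)
    if unknown:
        raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
    if "synth" not in cfg:
        raise ConfigurationError("missing config key: 'synth'")
    for key in _REQUIRED_SYNTH_KEYS:
        if key not in cfg["synth"]:
            raise ConfigurationError(f"missing config key: 'synth.{key}'")
    merged = {}
    for section, defaults in _DEFAULT_CONFIG.items():
        merged[section] = {**defaults, **cfg.get(section, {})}
        unknown = set(merged[section]) - set(defaults)
        if unknown:
            raise ConfigurationError(
                f"unknown key(s) in '{section}': {sorted(unknown)}")
    return merged


def run_pipeline(config, out_dir) -> dict:
    """Run all stages; artifacts and manifest.json land in ``out_dir``.

    Returns the manifest dict.  A stage failure aborts with the stage name
    and the patient counts accumulated so far.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["synth"]["seed"])
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(("synth",),
                                      np.random.SeedSequence(seed).spawn(1))}
    manifest = {"package_version": __version__, "seed": seed,
                "stage_seeds": stage_seeds, "config": _jsonable(cfg),
                "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "counts": {}, "stages": []}
    state = {}
    stages = [("synth", _stage_synth), ("preprocess", _stage_preprocess),
              ("cluster", _stage_cluster), ("cem", _stage_cem),
              ("armax", _stage_armax), ("validate", _stage_validate)]
    for name, fn in stages:
        try:
            fn(cfg, state, out, manifest)
            manifest["stages"].append(name)
        except Exception as exc:
            raise PainfusionError(
                f"stage {name!r} failed ({exc}); counts so far: "
                f"{manifest['counts']}") from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))


def _stage_synth(cfg, state, out, manifest):
    s = cfg["synth"]
    config = CohortConfig(n_obs=int(s["n_obs"]), n_rct=int(s["n_rct"]),
                          seed=int(stage_seed(manifest, "synth")),
                          noise_sd=s["noise_sd"],
                          missing_weeks_obs=frozenset(s["missing_weeks"]))
    cohort, panel = generate_cohort(config)
    state["cohort"], state["panel"] = cohort, panel
    write_cohort_csv(cohort, out / "cohort.csv", seed=config.seed)
    write_panel_csv(panel, out / "panel.csv", seed=config.seed)
    manifest["counts"]["synth"] = {
        "patients": len(cohort),
        "observational": int((cohort["arm"] == "observational").sum()),
        "rct": int((cohort["arm"] == "rct").sum())}


def stage_seed(manifest, name):
    return manifest["stage_seeds"].get(name, manifest["seed"])


def _stage_preprocess(cfg, state, out, manifest):
    panel = state["panel"]
    filled = interpolate_panel(
        panel, variables=("pain", "sleep", "feeling_energy", "feeling_calm",
                          "feeling_discouraged"))
    complete = (filled.groupby("patient_id")["pain"]
                .apply(lambda s: s.notna().all()))
    excluded = sorted(complete.index[~complete])
    state["panel_interp"] = filled[~filled["patient_id"].isin(excluded)]
    state["excluded_incomplete"] = excluded
    filled.to_csv(out / "panel_interp.csv", index=False)
    manifest["counts"]["preprocess"] = {
        "input": int(panel["patient_id"].nunique()),
        "retained": int(state["panel_interp"]["patient_id"].nunique()),
        "excluded_incomplete": len(excluded)}


def _stage_cluster(cfg, state, out, manifest):
    cohort = state["cohort"]
    obs = cohort[cohort["arm"] == "observational"].reset_index(drop=True)
    features = encode_features(obs)
    solution = ward_cluster(features)
    semipartial_r2(solution)
    cut_by_spr2(solution, threshold=float(cfg["cluster"]["spr2_threshold"]))
    state["solution"] = solution
    state["assignment"] = solution.assignment
    solution.assignment.rename("cluster").to_csv(out / "clusters.csv",
                                                 index_label="patient_id")
    pd.DataFrame(solution.merge_history,
                 columns=["node_a", "node_b", "height", "merged_size"]
                 ).to_csv(out / "merge_history.csv", index_label="merge")
    pd.Series(solution.spr2, name="spr2").to_csv(out / "spr2.csv",
                                                 index_label="merge")
    profile = profile_clusters(cohort, solution.assignment,
                               panel=state["panel_interp"])
    profile.to_csv(out / "cluster_profiles.csv", index=False)
    manifest["counts"]["cluster"] = {
        "observational": len(obs), "k": int(solution.k),
        "cluster_sizes": solution.assignment.value_counts().sort_index()
                                 .to_dict()}


def _stage_cem(cfg, state, out, manifest):
    cohort, assignment = state["cohort"], state["assignment"]
    scheme = default_scheme()
    rct = cohort[cohort["arm"] == "rct"]
    matched_rows, imb_rows = [], []
    state["matched"] = {}
    for c in sorted(assignment.unique()):
        members = assignment.index[assignment == c]
        obs_c = cohort[cohort["patient_id"].isin(members)]
        md = match_cluster(obs_c, rct, scheme, cluster_id=int(c))
        state["matched"][int(c)] = md
        obs_m = obs_c[obs_c["patient_id"].isin(md.matched_ids)]
        rct_m = rct[rct["patient_id"].isin(md.matched_ids)]
        rep = imbalance_report(int(c), obs_c, rct, obs_m, rct_m, scheme)
        imb_rows.append({**rep.as_row(), "obs_before": md.obs_before,
                         "obs_after": md.obs_after,
                         "rct_matched": md.rct_matched})
        for pid in md.matched.index:
            matched_rows.append({
                "patient_id": pid, "cluster": int(c),
                "matched": bool(md.matched.loc[pid]),
                "weight": float(md.weights.loc[pid])})
    pd.DataFrame(matched_rows).to_csv(out / "matched.csv", index=False)
    pd.DataFrame(imb_rows).to_csv(out / "imbalance.csv", index=False)
    obs_matched = set()
    for md in state["matched"].values():
        obs_matched |= set(md.matched_ids) & set(assignment.index)
    state["obs_matched_ids"] = obs_matched
    manifest["counts"]["cem"] = {
        "obs_matched_unique": len(obs_matched),
        "rct_matched_unique": len(set().union(*(
            set(md.matched_ids) - set(assignment.index)
            for md in state["matched"].values()))) if state["matched"] else 0,
        "per_cluster": {int(r["cluster"]): {"obs_after": r["obs_after"],
                                            "rct_matched": r["rct_matched"]}
                        for r in imb_rows}}


def _stage_armax(cfg, state, out, manifest):
    cohort, panel = state["cohort"], state["panel_interp"]
    assignment = state["assignment"]
    alpha = float(cfg["armax"]["alpha"])
    fits, fit_rows, roc_rows, pred_rows = {}, [], [], []
    have_panel = set(panel["patient_id"].unique())
    for c, md in state["matched"].items():
        calib = [pid for pid in md.matched_ids if pid in have_panel]
        if len(calib) < 20:
            warnings.warn(f"cluster {c}: too few calibration patients "
                          f"({len(calib)}); skipping fit")
            continue
        model = PainARXModel.from_panel(panel, cohort, DEFAULT_SPEC,
                                        patients=calib, cluster_id=c)
        res = (stepwise_select(model, alpha=alpha)
               if cfg["armax"]["stepwise"] else model.fit())
        fits[c] = res
        fit_rows.append(res.to_dict())
        preds = _cluster_predictions(res, cohort, panel, calib, cluster=c)
        pred_rows.append(preds)
        roc = _roc_from_predictions(res, cohort, panel, preds)
        if roc is not None:
            for fpr, tpr, cut in zip(roc["fpr"], roc["tpr"], roc["cutoffs"]):
                roc_rows.append({"cluster": c, "auc": roc["auc"],
                                 "cutoff": cut, "fpr": fpr, "tpr": tpr})
    state["fits"] = fits
    with open(out / "armax_fits.json", "w") as fh:
        json.dump(fit_rows, fh, indent=2)
    if pred_rows:
        pd.concat(pred_rows, ignore_index=True).to_csv(
            out / "predictions.csv", index=False)
    pd.DataFrame(roc_rows).to_csv(out / "roc.csv", index=False)
    manifest["counts"]["armax"] = {
        int(c): {"n_rows": fits[c].nobs, "r2": fits[c].rsquared,
                 "rmse": fits[c].rmse} for c in fits}


def _cluster_predictions(res, cohort, panel, patients, cluster):
    """Dynamic weekly pain predictions for a set of patients (long format)."""
    cov = cohort.set_index("patient_id")
    rows = []
    for pid, grp in panel[panel["patient_id"].isin(set(patients))].groupby(
            "patient_id"):
        try:
            pred = res.predict_trajectory(cov.loc[pid], grp, dynamic=True)
        except Exception:
            continue
        for w, v in pred.items():
            rows.append({"patient_id": pid, "cluster": cluster, "week": w,
                         "pain_pred": v})
    return pd.DataFrame(rows)


def _roc_from_predictions(res, cohort, panel, preds, final_week=6,
                          threshold=0.50):
    if preds.empty:
        return None
    cov = cohort.set_index("patient_id")
    final = preds[preds["week"] == final_week].set_index("patient_id")
    obs = panel[panel["week"] == final_week].set_index("patient_id")["pain"]
    obs_lv, pred_lv = [], []
    for pid, row in final.iterrows():
        base = float(cov.loc[pid, "baseline_pain"])
        if base <= 0 or pid not in obs.index or pd.isna(obs.loc[pid]):
            continue
        obs_lv.append((base - float(obs.loc[pid])) / base)
        pred_lv.append((base - float(row["pain_pred"])) / base)
    if len(obs_lv) < 4:
        return None
    return roc_responder(np.asarray(obs_lv), np.asarray(pred_lv), threshold)


def _stage_validate(cfg, state, out, manifest):
    from .validate import loglik_before_after, validate_unmatched
    cohort, panel = state["cohort"], state["panel_interp"]
    assignment = state["assignment"]
    report = validate_unmatched(
        state["fits"], cohort, state["obs_matched_ids"], panel, assignment,
        thresholds=tuple(cfg["validate"]["thresholds"]))
    report.to_csv(out / "validation.csv", index=False)
    _validation_histograms(state, out)
    ll_rows = []
    for c, md in state["matched"].items():
        before = list(assignment.index[assignment == c])
        after = list(md.matched_ids)
        if len(after) < 30:
            continue
        try:
            lb, la, p = loglik_before_after(cohort, before, after)
        except Exception as exc:   # degenerate small clusters
            warnings.warn(f"cluster {c}: loglik comparison failed ({exc})")
            continue
        ll_rows.append({"cluster": c, "loglik_before": lb,
                        "loglik_after": la, "chi2_p": p})
    pd.DataFrame(ll_rows).to_csv(out / "loglik.csv", index=False)
    n_val = int(report["n_validation"].fillna(0).sum()) \
        if "n_validation" in report else 0
    manifest["counts"]["validate"] = {"validation_patients": n_val}


def _validation_histograms(state, out):
    """Observed-vs-predicted final-pain histograms per cluster (unmatched)."""
    from .plots import plot_obs_vs_pred_hist
    cohort, panel = state["cohort"], state["panel_interp"]
    assignment = state["assignment"]
    matched = state["obs_matched_ids"]
    cov = cohort.set_index("patient_id")
    final = panel[panel["week"] == 6].set_index("patient_id")["pain"]
    for c, res in state["fits"].items():
        members = [pid for pid in assignment.index[assignment == c]
                   if pid not in matched]
        obs_vals, pred_vals = [], []
        for pid, grp in panel[panel["patient_id"].isin(members)].groupby(
                "patient_id"):
            if pid not in final.index or pd.isna(final.loc[pid]):
                continue
            try:
                pred = res.predict_trajectory(cov.loc[pid], grp, dynamic=True)
            except Exception:
                continue
            obs_vals.append(float(final.loc[pid]))
            pred_vals.append(float(pred.loc[6]))
        if len(obs_vals) >= 4:
            plot_obs_vs_pred_hist(obs_vals, pred_vals,
                                  out / f"validation_hist_cluster{c}.png",
                                  label=f"cluster {c}: final-week pain")
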