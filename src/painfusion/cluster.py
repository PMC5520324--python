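"""Ward minimum-variance clustering of the observational cohort.

The nine clustering variables (gender, age, pDPN duration, BMI, depression
history, pregabalin monotherapy, prior gabapentin, baseline pain, baseline
sleep interference) are encoded numerically, standardized to unit variance,
and clustered agglomeratively under Ward's criterion.  The cluster count is
selected from the semipartial R-squared of each merge: the first cluster
count (scanning from the top of the tree) whose forming merge absorbs less
than a threshold fraction (default 5%) of the total sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage

from . import binning
from .errors import DegenerateInputError, SpecificationError
from .preprocess import classify_responder, responder_level

CLUSTERING_VARIABLES = ("gender_code", "age", "pdpn_duration", "bmi",
                        "depression_history", "monotherapy",
                        "prior_gabapentin", "baseline_pain", "baseline_sleep")


@dataclass
class FeatureMatrix:
    """Standardized clustering features plus invertible scaling metadata."""

    values: np.ndarray
    columns: tuple
    center: np.ndarray
    scale: np.ndarray
    patient_ids: np.ndarray

    def unscale(self) -> np.ndarray:
        return self.values * self.scale + self.center


@dataclass
class ClusterSolution:
    """Full Ward merge history with semipartial R-squared bookkeeping."""

    merge_history: np.ndarray       # scipy linkage matrix (n-1, 4)
    heights: np.ndarray
    total_ss: float
    patient_ids: np.ndarray
    spr2: np.ndarray | None = None  # per merge, in merge order
    k: int | None = None
    assignment: pd.Series | None = None  # patient_id -> 1..k
    threshold: float | None = None

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def cut(self, k: int) -> pd.Series:
        """Partition into k clusters; labels 1..k in order of first appearance."""
        raw = cut_tree(self.merge_history, n_clusters=k).ravel()
        relabel, nxt = {}, 1
        out = np.empty(len(raw), dtype=int)
        for i, g in enumerate(raw):
            if g not in relabel:
                relabel[g] = nxt
                nxt += 1
            out[i] = relabel[g]
        return pd.Series(out, index=self.patient_ids, name="cluster")


def encode_features(cohort: pd.DataFrame,
                    variables=CLUSTERING_VARIABLES) -> FeatureMatrix:
    """Numeric encoding of the clustering variables, all columns standardized.

    Binary flags are 0/1 and continuous variables raw before a common
    z-scaling; standardizing every column keeps a flag flip comparable to a
    continuous shift of a few SDs instead of letting the wide continuous
    scales dominate.  The scaling is recorded and invertible.
    """
    X = np.empty((len(cohort), len(variables)), dtype=float)
    for j, var in enumerate(variables):
        col = cohort[var]
        if not pd.api.types.is_numeric_dtype(col):
            raise SpecificationError(f"clustering column {var!r} is not numeric")
        X[:, j] = col.to_numpy(dtype=float)
    center = X.mean(axis=0) if len(X) else np.zeros(len(variables))
    scale = X.std(axis=0) if len(X) else np.ones(len(variables))
    scale = np.where(scale > 0, scale, 1.0)
    return FeatureMatrix((X - center) / scale, tuple(variables), center,
                         scale, cohort["patient_id"].to_numpy())


def ward_cluster(features: FeatureMatrix) -> ClusterSolution:
    """Full agglomerative Ward tree (Lance-Williams update, scipy backend).

    Merge heights are the Ward distances; the within-cluster sum-of-squares
    increase of merge m is ``height[m]**2 / 2``.  Deterministic given input
    order.
    """
    X = features.values
    if len(X) < 2:
        raise DegenerateInputError("clustering needs at least 2 patients")
    Z = linkage(X, method="ward")
    heights = Z[:, 2].copy()
    if np.any(np.diff(heights) < -1e-9):
        raise AssertionError("Ward merge heights must be nondecreasing")
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    return ClusterSolution(merge_history=Z, heights=heights, total_ss=tss,
                           patient_ids=features.patient_ids)


def semipartial_r2(solution: ClusterSolution) -> np.ndarray:
    """Semipartial R^2 of each merge: Delta within-SS / total SS.

    The sequence is in merge order and sums to 1.
    """
    if solution.total_ss <= 0:
        raise DegenerateInputError(
            "total sum of squares is zero (all points identical)")
    spr2 = solution.heights ** 2 / 2.0 / solution.total_ss
    solution.spr2 = spr2
    return spr2


def cut_by_spr2(solution: ClusterSolution, threshold: float = 0.05) -> ClusterSolution:
    """Choose the cluster count from the semipartial R^2 profile.

    Scanning from the top of the tree (k = 1, 2, ...), k is the first
    cluster count whose forming merge (k+1 -> k clusters) has semipartial
    R^2 below ``threshold``; if no merge qualifies, every point is its own
    cluster.  Sets ``k`` and ``assignment`` on the solution and returns it.
    """
    if not 0 < threshold < 1:
        raise DegenerateInputError("spr2 threshold must lie in (0, 1)")
    spr2 = solution.spr2 if solution.spr2 is not None else semipartial_r2(solution)
    n = solution.n
    k = n
    for kk in range(1, n):
        # merge producing kk clusters is merge index n-1-kk (0-based)
        if spr2[n - 1 - kk] < threshold:
            k = kk
            break
    solution.k = k
    solution.threshold = threshold
    solution.assignment = solution.cut(k) if k < n else pd.Series(
        np.arange(1, n + 1), index=solution.patient_ids, name="cluster")
    return solution


def profile_clusters(cohort: pd.DataFrame, assignment: pd.Series,
                     panel: pd.DataFrame | None = None,
                     final_week: int = 6) -> pd.DataFrame:
    """Per-cluster descriptive profile in the published table layout.

    One row per cluster: n, % female, age mean/SD, BMI class %, baseline
    pain/sleep means and bin %, therapy-flag %, and (when a complete panel
    is supplied) the 50%-threshold responder share at ``final_week``.
    Clusters present in ``assignment`` but empty after joining are omitted
    with a warning.
    """
    import warnings

    df = cohort.set_index("patient_id").join(assignment.rename("cluster"),
                                             how="inner")
    resp = None
    if panel is not None:
        final = panel[panel["week"] == final_week].set_index("patient_id")
        joined = df.join(final["pain"].rename("final_pain"), how="left")
        ok = joined["final_pain"].notna() & (joined["baseline_pain"] > 0)
        lv = responder_level(joined.loc[ok, "baseline_pain"],
                             joined.loc[ok, "final_pain"])
        flags = pd.Series(classify_responder(lv, 0.50),
                          index=joined.index[ok])
        resp = flags.groupby(joined.loc[ok, "cluster"]).mean() * 100

    rows = []
    for c in sorted(pd.unique(assignment.dropna())):
        sub = df[df["cluster"] == c]
        if sub.empty:
            warnings.warn(f"cluster {c} is empty; row omitted")
            continue
        row = {"cluster": c, "n": len(sub),
               "female_pct": 100 * (sub["gender_code"] == 1).mean(),
               "age_mean": sub["age"].mean(), "age_sd": sub["age"].std(),
               "bmi_mean": sub["bmi"].mean(), "bmi_sd": sub["bmi"].std(),
               "baseline_pain_mean": sub["baseline_pain"].mean(),
               "baseline_pain_sd": sub["baseline_pain"].std(),
               "baseline_sleep_mean": sub["baseline_sleep"].mean(),
               "baseline_sleep_sd": sub["baseline_sleep"].std(),
               "depression_pct": 100 * sub["depression_history"].mean(),
               "monotherapy_pct": 100 * sub["monotherapy"].mean(),
               "prior_gabapentin_pct": 100 * sub["prior_gabapentin"].mean(),
               "insulin_pct": 100 * sub["insulin"].mean()}
        for lab, share in binning.bmi_class(sub["bmi"]).value_counts(
                normalize=True).items():
            row[f"bmi_{lab}_pct"] = 100 * share
        for col, pref in (("baseline_pain", "pain"), ("baseline_sleep", "sleep")):
            shares = binning.score_bin(sub[col]).value_counts(normalize=True)
            for lab in binning.SCORE_LABELS:
                row[f"{pref}_{lab}_pct"] = 100 * shares.get(lab, 0.0)
        for lab in binning.AGE_LABELS:
            row[f"age_{lab}_pct"] = 100 * (sub["age_group"] == lab).mean()
        if resp is not None:
            row["responder50_pct"] = resp.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
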