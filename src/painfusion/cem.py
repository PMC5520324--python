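"""Coarsened exact matching (CEM) of RCT patients into observational clusters.

Matching variables are temporarily coarsened into substantively meaningful
bins, patients are stratified on the joint bin signature, and only strata
containing members of both groups are kept.  Covariate balance is measured
by the multivariate L1 imbalance: half the sum of absolute differences
between the two groups' relative frequencies over the joint histogram cells
(0 = identical empirical distributions, 1 = disjoint support).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import binning
from .errors import DegenerateInputError, SpecificationError

#: default matching variables: sex plus coarsened age, BMI and the two
#: baseline 0-10 scores
DEFAULT_MATCH_VARS = ("gender", "age_group", "bmi_class", "pain_bin",
                      "sleep_bin")


@dataclass
class CoarseningScheme:
    """Per-variable binning rules.

    ``rules`` maps a matching-variable name to either ``None`` (categorical
    passthrough of an existing column) or ``(source_column, edges, labels)``
    with strictly increasing cut-points covering the variable's range; an
    optional fourth element gives the ``right`` closure of the bins
    (default True, i.e. right-closed intervals).
    """

    rules: dict = field(default_factory=dict)

    def __post_init__(self):
        for var, rule in self.rules.items():
            if rule is None:
                continue
            _, edges, labels = rule[:3]
            edges = list(edges)
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise SpecificationError(
                    f"cut-points for {var!r} must be strictly increasing")
            if len(labels) != len(edges) - 1:
                raise SpecificationError(
                    f"{var!r}: need one label per bin")

    @property
    def variables(self):
        return tuple(self.rules)


def default_scheme() -> CoarseningScheme:
    """Published-table bins: 4 age groups, 3 BMI classes, 4 score bins."""
    return CoarseningScheme({
        "gender": None,
        "age_group": ("age", binning.AGE_EDGES, binning.AGE_LABELS, False),
        "bmi_class": ("bmi", binning.BMI_EDGES, binning.BMI_LABELS, False),
        "pain_bin": ("baseline_pain", binning.SCORE_EDGES, binning.SCORE_LABELS),
        "sleep_bin": ("baseline_sleep", binning.SCORE_EDGES, binning.SCORE_LABELS),
    })


def coarsen(cohort: pd.DataFrame, scheme: CoarseningScheme) -> pd.DataFrame:
    """Map each patient to a tuple of bin labels (original values untouched).

    Returns a frame indexed like ``cohort`` with one column per matching
    variable plus a ``signature`` column holding the joint label tuple.
    """
    out = pd.DataFrame(index=cohort.index)
    for var, rule in scheme.rules.items():
        if rule is None:
            out[var] = cohort[var].astype(str).to_numpy()
        else:
            src, edges, labels = rule[:3]
            right = rule[3] if len(rule) > 3 else True
            binned = pd.cut(cohort[src].to_numpy(dtype=float), bins=edges,
                            labels=labels, right=right, include_lowest=True)
            binned = pd.Series(binned, index=cohort.index).astype(object)
            if binned.isna().any():
                val = cohort.loc[binned.isna(), src].iloc[0]
                raise SpecificationError(
                    f"value {val!r} of {src!r} falls outside every bin")
            out[var] = binned
    out["signature"] = list(map(tuple, out[list(scheme.rules)].to_numpy()))
    return out


@dataclass
class MatchedDataset:
    """Result of matching one observational cluster against the RCT pool."""

    cluster_id: int
    strata: dict                    # signature -> (obs ids, rct ids)
    matched: pd.Series              # patient_id -> bool
    weights: pd.Series              # patient_id -> CEM weight
    obs_before: int
    obs_after: int
    rct_matched: int

    @property
    def matched_ids(self):
        return self.matched.index[self.matched]


def match_cluster(obs_patients: pd.DataFrame, rct_patients: pd.DataFrame,
                  scheme: CoarseningScheme | None = None,
                  cluster_id: int = 0) -> MatchedDataset:
    """CEM between one cluster's observational patients and all RCT patients.

    A stratum (joint coarsened signature) is matched iff it contains at
    least one patient from each group.  Matched RCT patients get weight 1;
    matched observational patients get the standard CEM reweighting toward
    the RCT stratum distribution; unmatched patients get weight 0.
    """
    if scheme is None:
        scheme = default_scheme()
    if obs_patients.empty or rct_patients.empty:
        raise DegenerateInputError("both matching groups must be non-empty")

    obs_sig = coarsen(obs_patients, scheme)["signature"]
    rct_sig = coarsen(rct_patients, scheme)["signature"]
    obs_ids = obs_patients["patient_id"].to_numpy()
    rct_ids = rct_patients["patient_id"].to_numpy()

    obs_by_sig = pd.Series(obs_ids).groupby(obs_sig.to_numpy()).apply(list)
    rct_by_sig = pd.Series(rct_ids).groupby(rct_sig.to_numpy()).apply(list)
    common = sorted(set(obs_by_sig.index) & set(rct_by_sig.index))

    strata = {sig: (obs_by_sig[sig], rct_by_sig[sig]) for sig in common}
    matched = pd.Series(False, index=np.concatenate([obs_ids, rct_ids]))
    weights = pd.Series(0.0, index=matched.index)

    m_obs = sum(len(o) for o, _ in strata.values())
    m_rct = sum(len(r) for _, r in strata.values())
    for sig, (o, r) in strata.items():
        matched.loc[o] = True
        matched.loc[r] = True
        weights.loc[r] = 1.0
        # reweight matched observational strata toward the RCT distribution
        weights.loc[o] = (len(r) / len(o)) * (m_obs / m_rct)

    if not strata:
        warnings.warn(f"cluster {cluster_id}: no matched strata")
    return MatchedDataset(cluster_id=cluster_id, strata=strata,
                          matched=matched, weights=weights,
                          obs_before=len(obs_ids),
                          obs_after=int(matched.loc[obs_ids].sum()),
                          rct_matched=int(matched.loc[rct_ids].sum()))


def l1_imbalance(group_a: pd.DataFrame, group_b: pd.DataFrame,
                 scheme: CoarseningScheme | None = None) -> float:
    """Multivariate L1 imbalance between two groups on the joint bins.

    ``0.5 * sum_cells |f_cell - g_cell|`` over the joint histogram of the
    coarsened matching variables, where f and g are relative frequencies.
    """
    if scheme is None:
        scheme = default_scheme()
    if group_a.empty or group_b.empty:
        raise DegenerateInputError("L1 imbalance undefined for an empty group")
    fa = pd.Series(coarsen(group_a, scheme)["signature"]).value_counts(normalize=True)
    fb = pd.Series(coarsen(group_b, scheme)["signature"]).value_counts(normalize=True)
    cells = fa.index.union(fb.index)
    return float(0.5 * np.abs(fa.reindex(cells, fill_value=0.0).to_numpy()
                              - fb.reindex(cells, fill_value=0.0).to_numpy()).sum())


@dataclass
class ImbalanceReport:
    cluster_id: int
    l1_before: float
    l1_after: float
    reduction_pct: float | None

    def as_row(self) -> dict:
        return {"cluster": self.cluster_id, "l1_before": self.l1_before,
                "l1_after": self.l1_after, "reduction_pct": self.reduction_pct}


def imbalance_report(cluster_id, obs_before, rct_before, obs_after, rct_after,
                     scheme: CoarseningScheme | None = None) -> ImbalanceReport:
    """Global L1 imbalance before vs after matching and the percent reduction.

    ``reduction_pct`` is ``100 * (L1_before - L1_after) / L1_before``; when
    the groups start perfectly balanced it is undefined and reported as None.
    """
    before = l1_imbalance(obs_before, rct_before, scheme)
    after = l1_imbalance(obs_after, rct_after, scheme)
    red = 100.0 * (before - after) / before if before > 0 else None
    return ImbalanceReport(cluster_id, before, after, red)
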