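import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import painfusion as pf
from painfusion.cem import CoarseningScheme, default_scheme
from painfusion.errors import DegenerateInputError, SpecificationError

from _oracles import l1_by_hand


def mini_cohort(rows):
    """Patients from (id, gender, age, bmi, pain, sleep) tuples."""
    return pd.DataFrame([{
        "patient_id": pid, "gender": g, "age": age, "bmi": bmi,
        "baseline_pain": pain, "baseline_sleep": sleep}
        for pid, g, age, bmi, pain, sleep in rows])


GENDER_ONLY = CoarseningScheme({"gender": None})


class TestCoarsen:
    def test_published_bins(self):
        cohort = mini_cohort([("A", "male", 50, 27, 8, 3)])
        sig = pf.coarsen(cohort, default_scheme())
        assert sig.loc[0, "age_group"] == "45-64"
        assert sig.loc[0, "bmi_class"] == "overweight"
        assert sig.loc[0, "pain_bin"] == "8-10"
        assert sig.loc[0, "sleep_bin"] == "0-3"

    def test_empty_cohort(self):
        cohort = mini_cohort([])
        out = pf.coarsen(cohort.reindex(columns=["patient_id", "gender",
                                                 "age", "bmi",
                                                 "baseline_pain",
                                                 "baseline_sleep"]),
                         default_scheme())
        assert out.empty

    def test_out_of_range_value_rejected(self):
        cohort = mini_cohort([("A", "male", 50, 27, 14, 3)])
        with pytest.raises(SpecificationError):
            pf.coarsen(cohort, default_scheme())

    def test_bad_cutpoints_rejected(self):
        with pytest.raises(SpecificationError):
            CoarseningScheme({"x": ("age", [0, 10, 5], ["a", "b"])})


class TestMatchCluster:
    def test_identical_pair_matches_with_unit_weights(self):
        obs = mini_cohort([("O1", "male", 50, 27, 6, 5)])
        rct = mini_cohort([("R1", "male", 52, 28, 6, 5)])
        md = pf.match_cluster(obs, rct, default_scheme(), cluster_id=1)
        assert len(md.strata) == 1
        assert md.matched.all()
        assert md.weights.loc["O1"] == pytest.approx(1.0)
        assert md.weights.loc["R1"] == pytest.approx(1.0)

    def test_disjoint_signatures_warns_empty(self):
        obs = mini_cohort([("O1", "male", 30, 20, 2, 2)])
        rct = mini_cohort([("R1", "female", 80, 45, 9, 9)])
        with pytest.warns(UserWarning, match="no matched strata"):
            md = pf.match_cluster(obs, rct, default_scheme())
        assert not md.matched.any()
        assert (md.weights == 0).all()

    def test_counts_match_bruteforce_stratum_enumeration(self):
        rng = np.random.default_rng(8)
        genders = ["male", "female"]
        obs = mini_cohort([(f"O{i}", genders[rng.integers(2)],
                            rng.uniform(30, 80), rng.uniform(18, 40),
                            rng.uniform(1, 10), rng.uniform(1, 10))
                           for i in range(10)])
        rct = mini_cohort([(f"R{i}", genders[rng.integers(2)],
                            rng.uniform(30, 80), rng.uniform(18, 40),
                            rng.uniform(1, 10), rng.uniform(1, 10))
                           for i in range(10)])
        scheme = default_scheme()
        md = pf.match_cluster(obs, rct, scheme)
        # independent enumeration from raw signatures
        osig = list(pf.coarsen(obs, scheme)["signature"])
        rsig = list(pf.coarsen(rct, scheme)["signature"])
        common = set(osig) & set(rsig)
        exp_obs = sum(s in common for s in osig)
        exp_rct = sum(s in common for s in rsig)
        assert md.obs_after == exp_obs
        assert md.rct_matched == exp_rct
        assert set(md.strata) == common

    def test_union_of_matched_and_unmatched_is_input(self):
        obs = mini_cohort([(f"O{i}", "male", 40 + i, 25, 5, 5)
                           for i in range(6)])
        rct = mini_cohort([(f"R{i}", "male", 40 + 5 * i, 25, 5, 5)
                           for i in range(4)])
        md = pf.match_cluster(obs, rct, default_scheme())
        assert set(md.matched.index) == {f"O{i}" for i in range(6)} | \
            {f"R{i}" for i in range(4)}
        assert not md.matched.index.has_duplicates

    def test_empty_group_rejected(self):
        obs = mini_cohort([("O1", "male", 50, 27, 6, 5)])
        with pytest.raises(DegenerateInputError):
            pf.match_cluster(obs, obs.iloc[:0], default_scheme())


class TestL1Imbalance:
    def test_identical_groups_zero(self):
        g = mini_cohort([("A", "male", 50, 27, 6, 5),
                         ("B", "female", 70, 32, 8, 8)])
        assert pf.l1_imbalance(g, g.copy()) == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        a = mini_cohort([("A", "male", 30, 20, 2, 2)])
        b = mini_cohort([("B", "female", 80, 45, 9, 9)])
        assert pf.l1_imbalance(a, b) == pytest.approx(1.0)

    def test_hand_computed_quarter(self):
        """A = 2+2 over two cells, B = 3+1: L1 = (|.5-.75|+|.5-.25|)/2."""
        a = mini_cohort([("A1", "male", 50, 27, 6, 5),
                         ("A2", "male", 50, 27, 6, 5),
                         ("A3", "female", 50, 27, 6, 5),
                         ("A4", "female", 50, 27, 6, 5)])
        b = mini_cohort([("B1", "male", 50, 27, 6, 5),
                         ("B2", "male", 50, 27, 6, 5),
                         ("B3", "male", 50, 27, 6, 5),
                         ("B4", "female", 50, 27, 6, 5)])
        assert pf.l1_imbalance(a, b, GENDER_ONLY) == pytest.approx(0.25)

    @settings(deadline=None, max_examples=30)
    @given(a=st.lists(st.integers(0, 3), min_size=1, max_size=12),
           b=st.lists(st.integers(0, 3), min_size=1, max_size=12))
    def test_properties_bounds_symmetry_duplication(self, a, b):
        ages = [30.0, 50.0, 70.0, 80.0]
        ga = mini_cohort([(f"A{i}", "male", ages[v], 25, 5, 5)
                          for i, v in enumerate(a)])
        gb = mini_cohort([(f"B{i}", "male", ages[v], 25, 5, 5)
                          for i, v in enumerate(b)])
        scheme = default_scheme()
        l1 = pf.l1_imbalance(ga, gb, scheme)
        assert 0.0 <= l1 <= 1.0
        assert pf.l1_imbalance(gb, ga, scheme) == pytest.approx(l1)
        ga2 = pd.concat([ga, ga]).reset_index(drop=True)
        gb2 = pd.concat([gb, gb]).reset_index(drop=True)
        assert pf.l1_imbalance(ga2, gb2, scheme) == pytest.approx(l1)
        assert l1 == pytest.approx(
            l1_by_hand([ages[v] for v in a], [ages[v] for v in b]))

    def test_empty_group_undefined(self):
        g = mini_cohort([("A", "male", 50, 27, 6, 5)])
        with pytest.raises(DegenerateInputError):
            pf.l1_imbalance(g, g.iloc[:0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matching_never_increases_imbalance(self, seed):
        """On the coarsening bins, L1 after CEM <= L1 before."""
        cfg = pf.CohortConfig(n_obs=220, n_rct=80, seed=seed,
                              missing_weeks_obs=frozenset())
        cohort, _ = pf.generate_cohort(cfg)
        obs = cohort[cohort["arm"] == "observational"]
        rct = cohort[cohort["arm"] == "rct"]
        scheme = default_scheme()
        for c in (1, 2, 6):
            obs_c = obs[obs["true_cluster"] == c]
            md = pf.match_cluster(obs_c, rct, scheme, cluster_id=c)
            if not md.strata:
                continue
            obs_m = obs_c[obs_c["patient_id"].isin(md.matched_ids)]
            rct_m = rct[rct["patient_id"].isin(md.matched_ids)]
            before = pf.l1_imbalance(obs_c, rct, scheme)
            after = pf.l1_imbalance(obs_m, rct_m, scheme)
            assert after <= before + 1e-12


class TestImbalanceReport:
    def test_percent_reduction_examples(self):
        """Reduction rounds to the published 63% and 6% rows."""
        assert round(100 * (0.70 - 0.26) / 0.70) == 63
        rep = pf.imbalance_report  # exercised via L1 below
        a = mini_cohort([("A1", "male", 50, 27, 6, 5),
                         ("A2", "female", 50, 27, 6, 5)])
        b = mini_cohort([("B1", "male", 50, 27, 6, 5),
                         ("B2", "female", 50, 27, 6, 5)])
        out = rep(1, a, b, a, b, GENDER_ONLY)
        assert out.l1_before == pytest.approx(0.0)
        assert out.reduction_pct is None

    def test_equal_before_after_zero_reduction(self):
        a = mini_cohort([("A1", "male", 50, 27, 6, 5)])
        b = mini_cohort([("B1", "female", 50, 27, 6, 5),
                         ("B2", "male", 50, 27, 6, 5)])
        out = pf.imbalance_report(1, a, b, a, b, GENDER_ONLY)
        assert out.l1_before == pytest.approx(0.5)
        assert out.reduction_pct == pytest.approx(0.0)

    def test_reduction_formula(self):
        a = mini_cohort([("A%d" % i, "male", 50, 27, 6, 5)
                         for i in range(4)])
        b = mini_cohort([("B1", "female", 50, 27, 6, 5),
                         ("B2", "male", 50, 27, 6, 5)])
        after_a = mini_cohort([("A1", "male", 50, 27, 6, 5)])
        after_b = mini_cohort([("B2", "male", 50, 27, 6, 5)])
        out = pf.imbalance_report(1, a, b, after_a, after_b, GENDER_ONLY)
        assert out.l1_before == pytest.approx(0.5)
        assert out.l1_after == pytest.approx(0.0)
        assert out.reduction_pct == pytest.approx(100.0)
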