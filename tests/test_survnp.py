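"""Kaplan-Meier and stratified Gehan-Breslow: hand oracles, lifelines, permutation."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

import flymort as fm
from flymort.survnp import gehan_scores
from conftest import make_records


class TestKaplanMeier:
    def test_all_censored_survival_is_one(self):
        recs = make_records([2.0, 4.0, 5.0, 7.0, 9.0], ["censored"] * 5)
        km = fm.km_fit(recs)["all"]
        assert km.times.size == 0
        assert np.all(km.evaluate(np.array([0.0, 5.0, 100.0])) == 1.0)

    def test_hand_computed_product_limit(self):
        # death at t=2 with 5 at risk, two deaths at t=3 with 4 at risk
        recs = make_records([2.0, 3.0, 3.0, 4.0, 5.0],
                            ["death", "death", "death", "censored", "censored"])
        km = fm.km_fit(recs)["all"]
        assert km.evaluate(np.array([2.0]))[0] == pytest.approx(0.8)
        assert km.evaluate(np.array([3.0]))[0] == pytest.approx(0.8 * (2 / 4))

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        ages = np.ceil(rng.exponential(10, 200) + 0.5)
        recs = make_records(ages, ["death"] * 200)
        km = fm.km_fit(recs)["all"]
        t = np.unique(ages)
        ecdf = np.array([(ages <= ti).mean() for ti in t])
        assert np.allclose(km.evaluate(t), 1 - ecdf)

    def test_duplication_invariance(self):
        recs = make_records([2.0, 3.0, 3.0, 4.0], ["death", "death", "censored", "death"])
        km1 = fm.km_fit(recs)["all"]
        km3 = fm.km_fit(pd.concat([recs] * 3, ignore_index=True))["all"]
        assert np.allclose(km1.survival, km3.survival)
        assert np.allclose(km1.times, km3.times)

    def test_matches_lifelines(self, study_cohort):
        df = study_cohort.to_frame()
        sub = df[(df.sex == "male") & (df.treatment == "rapamycin")]
        km = fm.km_fit(sub)["all"]
        kmf = KaplanMeierFitter().fit(
            sub.observed_age, event_observed=(sub.event == "death")
        )
        theirs = kmf.survival_function_at_times(km.times).to_numpy()
        assert np.allclose(km.survival, theirs, atol=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fm.km_fit(make_records([], []))


class TestGehanBreslow:
    def test_scores_sum_to_zero_and_match_hand_values(self):
        ages = np.array([1.0, 2.0, 3.0, 4.0])
        death = np.ones(4, dtype=bool)
        u = gehan_scores(ages, death)
        assert np.allclose(u, [-3, -1, 1, 3])
        rng = np.random.default_rng(1)
        ages = np.round(rng.exponential(9, 50) + 1)
        death = rng.random(50) > 0.3
        assert gehan_scores(ages, death).sum() == pytest.approx(0.0)

    def test_identical_death_multisets_symmetric(self):
        recs = make_records(
            [1.0, 2.0, 1.0, 2.0], ["death"] * 4,
            treatment=["control", "control", "rapamycin", "rapamycin"],
        )
        res = fm.gehan_breslow_stratified(recs, "treatment", method="exact")
        assert res.raw_statistic == 0.0
        assert res.p_value == 1.0

    def test_exhaustive_enumeration_oracle(self):
        # A deaths {1,2}, B deaths {3,4}: 6 arrangements, |W| maximal, p = 2/6
        recs = make_records(
            [1.0, 2.0, 3.0, 4.0], ["death"] * 4,
            treatment=["control", "control", "rapamycin", "rapamycin"],
        )
        res = fm.gehan_breslow_stratified(recs, "treatment", method="exact")
        assert res.method == "exact"
        assert res.n_permutations == 6
        assert res.p_value == pytest.approx(2 / 6)

    def test_label_swap_flips_sign_not_p(self):
        rng = np.random.default_rng(2)
        ages = np.round(rng.exponential(8, 30) + 1)
        trt = ["control"] * 15 + ["rapamycin"] * 15
        ev = np.where(rng.random(30) > 0.2, "death", "censored")
        recs = make_records(ages, ev, treatment=trt)
        swapped = recs.copy()
        swapped["treatment"] = swapped.treatment.map(
            {"control": "rapamycin", "rapamycin": "control"}
        )
        a = fm.gehan_breslow_stratified(recs, "treatment", method="asymptotic")
        b = fm.gehan_breslow_stratified(swapped, "treatment", method="asymptotic")
        assert a.raw_statistic == pytest.approx(-b.raw_statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_single_stratum_equals_unstratified(self):
        rng = np.random.default_rng(3)
        ages = np.round(rng.exponential(8, 40) + 1)
        trt = ["control"] * 20 + ["rapamycin"] * 20
        ev = np.where(rng.random(40) > 0.2, "death", "censored")
        recs = make_records(ages, ev, treatment=trt)  # sex constant -> 1 stratum
        a = fm.gehan_breslow_stratified(recs, "treatment", strata="sex")
        b = fm.gehan_breslow_stratified(recs, "treatment")
        assert a.raw_statistic == pytest.approx(b.raw_statistic)
        assert a.statistic == pytest.approx(b.statistic)

    def test_asymptotic_close_to_lifelines_wilcoxon(self):
        rng = np.random.default_rng(5)
        t_a, t_b = rng.exponential(10, 40), rng.exponential(14, 40)
        e_a, e_b = rng.random(40) > 0.2, rng.random(40) > 0.2
        recs = make_records(
            np.r_[t_a, t_b],
            np.where(np.r_[e_a, e_b], "death", "censored"),
            treatment=["control"] * 40 + ["rapamycin"] * 40,
        )
        ours = fm.gehan_breslow_stratified(recs, "treatment", method="asymptotic")
        theirs = logrank_test(t_a, t_b, e_a, e_b, weightings="wilcoxon")
        # variance conventions differ slightly (permutation vs hypergeometric)
        assert ours.p_value == pytest.approx(theirs.p_value, abs=0.01)

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(7)
        ages = np.round(rng.exponential(8, 12) + 1)
        ev = np.where(rng.random(12) > 0.25, "death", "censored")
        trt = ["control"] * 6 + ["rapamycin"] * 6
        sex = (["female"] * 3 + ["male"] * 3) * 2
        recs = make_records(ages, ev, treatment=trt, sex=sex)
        exact = fm.gehan_breslow_stratified(recs, "treatment", strata="sex", method="exact")
        mc = fm.gehan_breslow_stratified(
            recs, "treatment", strata="sex", method="mc",
            n_permutations=100_000, seed=11,
        )
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 100_000)
        assert abs(mc.p_value - exact.p_value) < 3 * se + 2e-5

    def test_errors(self):
        recs = make_records([1.0, 2.0], ["death", "death"])
        with pytest.raises(ValueError, match="exactly 2"):
            fm.gehan_breslow_stratified(recs, "treatment")
        recs2 = make_records(
            [1.0, 2.0, 3.0, 4.0], ["death"] * 4,
            treatment=["control", "control", "rapamycin", "rapamycin"],
            sex=["female", "female", "male", "male"],
        )
        with pytest.raises(ValueError, match="stratum"):
            fm.gehan_breslow_stratified(recs2, "treatment", strata="sex")
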