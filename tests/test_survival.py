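import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tilprog as tp
from tilprog.survival import (
    KMCurve,
    classification_overlap,
    km_estimate,
    logrank_test,
    parse_stage,
    stage_composition,
    stratified_survival,
)

from conftest import logrank_oracle


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(5.0) == 1.0

    def test_censoring_removes_subject_from_risk_set(self):
        # times (1, 2+, 3): S(1) = 2/3; at t=3 one subject at risk and it
        # dies, so the product-limit gives S(3) = 0
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)
        assert np.array_equal(curve.at_risk, [3, 1])

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])

    def test_random_no_censoring_datasets_equal_empirical(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            times = rng.integers(1, 20, size=rng.integers(2, 30)).astype(float)
            curve = km_estimate(times, np.ones_like(times))
            for t in curve.times:
                assert curve.survival_at(t) == pytest.approx((times > t).mean(),
                                                             abs=1e-12)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t, e = [1, 3, 5, 7], [1, 1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.chisq == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_toy_example(self):
        # G1 events at (1,2), G2 events at (3,4): O-E over the pooled risk
        # sets gives chi-square 2.882
        res = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert res.chisq == pytest.approx(2.882, abs=1e-3)
        assert res.chisq == pytest.approx(logrank_oracle([1, 2], [1, 1],
                                                         [3, 4], [1, 1]), abs=1e-10)

    def test_agrees_with_oracle_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            ta = rng.exponential(10, size=12)
            tb = rng.exponential(5, size=15)
            ea = (rng.random(12) > 0.3).astype(int)
            eb = (rng.random(15) > 0.3).astype(int)
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank_test(ta, ea, tb, eb)
            assert res.chisq == pytest.approx(logrank_oracle(ta, ea, tb, eb),
                                              abs=1e-8)

    def test_symmetric_in_group_order_and_time_rescaling(self):
        ta, ea = [1.0, 4.0, 6.0], [1, 1, 0]
        tb, eb = [2.0, 3.0, 9.0], [1, 0, 1]
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        r3 = logrank_test(np.multiply(ta, 12.0), ea, np.multiply(tb, 12.0), eb)
        assert r1.chisq == pytest.approx(r2.chisq, abs=1e-12)
        assert r1.chisq == pytest.approx(r3.chisq, abs=1e-12)

    def test_no_events_flagged(self):
        res = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert res.flagged and res.p == 1.0

    def test_small_sample_rank_agreement_with_exact_permutation(self):
        # asymptotic p must order the permutation distribution consistently
        rng = np.random.default_rng(2)
        times = rng.exponential(5, size=8)
        events = np.ones(8, dtype=int)
        chisqs = []
        for assign in itertools.combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(assign)] = True
            chisqs.append(logrank_oracle(times[mask], events[mask],
                                         times[~mask], events[~mask]))
        chisqs = np.array(chisqs)
        perm_p = np.array([(chisqs >= c).mean() for c in chisqs])
        asym_p = sps.chi2.sf(chisqs, df=1)
        rho = sps.spearmanr(perm_p, asym_p).statistic
        assert rho > 0.9999

    def test_power_against_planted_hazard_ratio(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            ta = rng.exponential(1.0, size=100)      # hazard 1
            tb = rng.exponential(1 / 3, size=100)    # hazard 3
            res = logrank_test(ta, np.ones(100), tb, np.ones(100))
            rejections += res.p < 0.01
        assert rejections >= 19  # >= 95% of replicates at n=200, HR=3


class TestStratified:
    def _cohort(self, seed=3, n=200):
        rng = np.random.default_rng(seed)
        labels = pd.Series(rng.choice(["enriched", "depleted", "neither"], size=n,
                                      p=[0.4, 0.4, 0.2]),
                           index=[f"pt{i}" for i in range(n)])
        hazard = np.where(labels == "depleted", 0.05, 0.01)
        clinical = pd.DataFrame({
            "os_months": rng.exponential(1 / hazard),
            "os_event": 1,
            "stage": rng.choice(["Stage I", "Stage IIA", "Stage IIIB", "Stage IV"],
                                size=n),
        }, index=labels.index)
        return clinical, labels

    def test_all_stage_subset_equals_unstratified(self):
        clinical, labels = self._cohort()
        full = stratified_survival(clinical, labels)
        subset = stratified_survival(clinical, labels, ["I", "II", "III", "IV"])
        assert full.test.chisq == pytest.approx(subset.test.chisq, abs=1e-12)

    def test_neither_patients_are_excluded(self):
        clinical, labels = self._cohort()
        res = stratified_survival(clinical, labels)
        n_used = sum(c.n for c in res.curves.values())
        assert n_used == (labels != "neither").sum()

    def test_empty_class_after_restriction_flagged(self):
        clinical, labels = self._cohort()
        labels[clinical["stage"].str.contains("IV")] = "neither"
        labels[labels == "depleted"] = "neither"
        res = stratified_survival(clinical, labels, ["IV"])
        assert res.flagged and res.test is None

    def test_stage_confined_signal_detected_in_its_stages(self):
        # class hazard differs only within stages II-III
        rng = np.random.default_rng(4)
        n = 400
        labels = pd.Series(np.where(np.arange(n) % 2 == 0, "enriched", "depleted"),
                           index=[f"pt{i}" for i in range(n)])
        stage = rng.choice(["Stage I", "Stage II", "Stage III"], size=n)
        in_sig = np.isin(stage, ["Stage II", "Stage III"]) & (labels == "depleted")
        hazard = np.where(in_sig, 0.06, 0.01)
        clinical = pd.DataFrame({
            "os_months": rng.exponential(1 / hazard), "os_event": 1, "stage": stage,
        }, index=labels.index)
        p_23 = stratified_survival(clinical, labels, ["II", "III"]).test.p
        p_1 = stratified_survival(clinical, labels, ["I"]).test.p
        assert p_23 < p_1
        assert p_23 < 1e-6


class TestStageAndOverlap:
    @pytest.mark.parametrize("raw,expected", [
        ("Stage IIA", "II"), ("Stage IV", "IV"), ("stage iiic", "III"),
        ("I", "I"), ("unknown", None),
    ])
    def test_stage_parsing(self, raw, expected):
        assert parse_stage(raw) == expected

    def test_single_stage_class(self):
        classes = pd.Series(["enriched"] * 4, index=list("abcd"))
        stages = pd.Series(["Stage II"] * 4, index=list("abcd"))
        prop, mean = stage_composition(classes, stages)
        assert np.allclose(prop.loc["enriched"], [0, 1, 0, 0])
        assert mean["enriched"] == pytest.approx(2.0)

    def test_balanced_stages_mean(self):
        classes = pd.Series(["enriched"] * 4, index=list("abcd"))
        stages = pd.Series(["I", "II", "III", "IV"], index=list("abcd"))
        _, mean = stage_composition(classes, stages)
        assert mean["enriched"] == pytest.approx(2.5)

    def test_stage_skew_recovered_from_simulation(self):
        rng = np.random.default_rng(5)
        n = 1000
        probs = {"enriched": [0.4, 0.4, 0.1, 0.1], "depleted": [0.1, 0.1, 0.4, 0.4]}
        classes = pd.Series(rng.choice(["enriched", "depleted"], size=n),
                            index=range(n))
        stages = pd.Series([
            rng.choice(["I", "II", "III", "IV"], p=probs[c]) for c in classes],
            index=classes.index)
        prop, _ = stage_composition(classes, stages)
        for cls, expected in probs.items():
            se = np.sqrt(np.multiply(expected, np.subtract(1.0, expected))
                         / (classes == cls).sum())
            assert np.all(np.abs(prop.loc[cls] - expected) < 5 * se + 0.01)

    def test_overlap_from_printed_counts(self):
        # 25 shared of 33 enriched -> 76%
        idx = range(100)
        a = pd.Series(["neither"] * 100, index=idx)
        b = pd.Series(["neither"] * 100, index=idx)
        a.iloc[:33] = "enriched"
        b.iloc[8:33] = "enriched"
        res = classification_overlap(a, b)
        assert (res.n_both, res.n_a) == (25, 33)
        assert res.percent == 76

    def test_identical_and_disjoint_overlap(self):
        idx = range(10)
        a = pd.Series(["enriched"] * 5 + ["neither"] * 5, index=idx)
        assert classification_overlap(a, a).percent == 100
        b = pd.Series(["neither"] * 5 + ["enriched"] * 5, index=idx)
        assert classification_overlap(a, b).percent == 0

    def test_mismatched_universes_rejected(self):
        a = pd.Series(["enriched"], index=["p1"])
        b = pd.Series(["enriched"], index=["p2"])
        with pytest.raises(ValueError):
            classification_overlap(a, b)
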