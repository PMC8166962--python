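"""Kaplan-Meier curves and the two-arm log-rank comparison."""

import itertools

import numpy as np
import pytest

from srspv import (
    LatencySet,
    OnsetComparison,
    compare_onset_profiles,
    km_estimate,
    logrank_test,
)

from conftest import FOCAL_PT, make_dataset


def mantel_cox_chi2(x1, x2):
    """Independently coded Mantel-Cox statistic (ties pooled)."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    times = np.unique(np.concatenate([x1, x2]))
    O1 = E1 = V = 0.0
    for t in times:
        n1 = (x1 >= t).sum()
        n2 = (x2 >= t).sum()
        d1 = (x1 == t).sum()
        d2 = (x2 == t).sum()
        n, d = n1 + n2, d1 + d2
        if n < 2:
            O1 += d1 - d * n1 / n if n else 0.0
            continue
        O1 += d1
        E1 += d * n1 / n
        V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


class TestKMEstimate:
    def test_hand_computed_steps(self):
        km = km_estimate([1.0, 2.0, 3.0])
        assert list(km.event_times) == [1.0, 2.0, 3.0]
        assert km.survival_probs == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert list(km.n_at_risk) == [3, 2, 1]

    def test_all_equal_single_step(self):
        km = km_estimate([7.0, 7.0, 7.0])
        assert list(km.event_times) == [7.0]
        assert km.survival_probs == pytest.approx([0.0])

    def test_km_equals_one_minus_ecdf(self):
        """With no censoring the product-limit estimate is 1 - ECDF."""
        rng = np.random.default_rng(8)
        x = np.round(30 * rng.weibull(0.9, 500))
        km = km_estimate(x)
        for t, s in zip(km.event_times, km.survival_probs):
            assert s == pytest.approx(np.mean(x > t), abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestLogRank:
    def test_identical_groups_null(self):
        res = logrank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(9)
        x1, x2 = 20 * rng.weibull(1.0, 25), 35 * rng.weibull(1.0, 30)
        r12, r21 = logrank_test(x1, x2), logrank_test(x2, x1)
        assert r12.chi_square == pytest.approx(r21.chi_square, rel=1e-10)
        assert r12.p_value == pytest.approx(r21.p_value, rel=1e-10)

    def test_matches_independent_statistic(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            x1 = np.round(30 * rng.weibull(0.8, 15))
            x2 = np.round(50 * rng.weibull(1.2, 20))
            res = logrank_test(x1, x2)
            assert res.chi_square == pytest.approx(mantel_cox_chi2(x1, x2), rel=1e-8)

    def test_exhaustive_permutation_oracle(self):
        """Asymptotic p agrees with the all-permutations p within its resolution."""
        group1, group2 = [2.0, 4.0, 6.0], [20.0, 40.0, 60.0]
        observed = mantel_cox_chi2(group1, group2)
        pooled = group1 + group2
        stats_all = [
            mantel_cox_chi2([pooled[i] for i in idx],
                            [pooled[i] for i in range(6) if i not in idx])
            for idx in itertools.combinations(range(6), 3)
        ]
        p_perm = np.mean([s >= observed - 1e-12 for s in stats_all])
        p_asym = logrank_test(group1, group2).p_value
        assert logrank_test(group1, group2).chi_square == pytest.approx(observed, rel=1e-8)
        assert abs(p_asym - p_perm) <= 2 / len(stats_all)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            logrank_test([], [1.0])


class TestCompareOnsetProfiles:
    def make_two_arm_records(self, lat1, lat2):
        from srspv import DrugVocabulary, assemble_analysis_set
        import datetime

        rows_demo, rows_drug, rows_reac = [], [], []
        start = datetime.date(2019, 1, 1)
        for j, (drug, lats) in enumerate([("sbp", lat1), ("nabp", lat2)]):
            for i, d in enumerate(lats):
                cid = f"{drug}{i}"
                onset = start + datetime.timedelta(days=int(d))
                rows_demo.append((cid, "female", "60-69", "2019"))
                rows_drug.append((cid, 1, drug, "suspected", "20190101", ""))
                rows_reac.append(
                    (cid, FOCAL_PT, "peripheral neuropathy", onset.strftime("%Y%m%d"), "improved")
                )
        ds = make_dataset(rows_demo, rows_drug, rows_reac)
        vocab = DrugVocabulary({"sbp": ("sbp", "L01CD01"), "nabp": ("nabp", "L01CD01")})
        return assemble_analysis_set(ds, vocab, {FOCAL_PT})

    def test_identical_arms_not_significant(self):
        lats = list(range(1, 21))
        records = self.make_two_arm_records(lats, lats)
        comp = compare_onset_profiles(records, "sbp", "nabp")
        assert not comp.significant and comp.logrank.p_value == pytest.approx(1.0)

    def test_separated_arms_detected(self):
        """Arms mimicking the sb-/nab-paclitaxel contrast (alpha 56 vs 13)."""
        rng = np.random.default_rng(12)
        lat1 = np.round(np.minimum(56 * rng.weibull(0.78, 67), 365))
        lat2 = np.round(np.minimum(13 * rng.weibull(0.74, 12), 365))
        records = self.make_two_arm_records(lat1, lat2)
        comp = compare_onset_profiles(records, "sbp", "nabp")
        assert comp.median1_days > comp.median2_days
        assert comp.n1 == 67 and comp.n2 == 12

    def test_small_arm_warns_but_runs(self):
        records = self.make_two_arm_records(list(range(1, 21)), [3.0, 5.0, 9.0])
        comp = compare_onset_profiles(records, "sbp", "nabp")
        assert comp.warnings and "descriptive" in comp.warnings[0]

    def test_monotone_power_in_separation(self):
        """Widening the scale gap does not reduce the rejection rate."""
        rng = np.random.default_rng(13)
        rates = []
        for alpha2 in (50.0, 25.0, 8.0):
            rejections = 0
            for _ in range(30):
                x1 = 50 * rng.weibull(0.8, 40)
                x2 = alpha2 * rng.weibull(0.8, 40)
                g1 = LatencySet("a", np.minimum(x1, 365))
                g2 = LatencySet("b", np.minimum(x2, 365))
                rejections += OnsetComparison(g1, g2).fit().significant
            rates.append(rejections / 30)
        assert rates[0] <= rates[1] + 0.1 and rates[1] <= rates[2] + 0.1
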