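"""Latency derivation rules, quantile summaries, Weibull MLE and hazard classes."""

import numpy as np
import pytest
from scipy import stats

from srspv import (
    HazardClass,
    LatencySet,
    WeibullTimeToOnset,
    assemble_analysis_set,
    classify_hazard,
    compute_latencies,
    fit_weibull,
    summarize_latency,
    tto_table,
)
from srspv.time_to_onset import FitError, _negative_log_likelihood

from conftest import FOCAL_PT, make_dataset


def records_for(rows, vocab):
    """rows: (case_id, start, onset) triples for one oxaliplatin case each."""
    ds = make_dataset(
        demo_rows=[(cid, "male", "60-69", "2019") for cid, _, _ in rows],
        drug_rows=[(cid, 1, "oxaliplatin", "suspected", start, "") for cid, start, _ in rows],
        reac_rows=[
            (cid, FOCAL_PT, "peripheral neuropathy", onset, "recovered")
            for cid, _, onset in rows
        ],
    )
    return assemble_analysis_set(ds, vocab, {FOCAL_PT})


class TestComputeLatencies:
    def test_day_arithmetic_and_exclusions(self, vocab):
        records = records_for(
            [
                ("C1", "20200101", "20200115"),  # 14 days, retained
                ("C2", "202001", "20200120"),  # partial start -> excluded
                ("C3", "20200101", "202003"),  # partial onset -> excluded
                ("C4", "20200301", "20200201"),  # negative -> excluded
                ("C5", "20190101", "20200301"),  # 425 days -> outside window
                ("C6", "20200101", "20200101"),  # day 0, retained
            ],
            vocab,
        )
        lat = compute_latencies(records, "oxaliplatin")
        assert sorted(lat.latencies_days) == [0.0, 14.0]
        assert lat.n_excluded_incomplete == 2
        assert lat.n_excluded_negative == 1
        assert lat.n_excluded_window == 1
        # accounting conserves candidates
        assert lat.n + lat.n_excluded_incomplete + lat.n_excluded_negative + lat.n_excluded_window == 6

    def test_duplicate_accounting(self, small_dataset, vocab):
        records = assemble_analysis_set(small_dataset, vocab, {FOCAL_PT})
        lat = compute_latencies(records, "oxaliplatin")
        assert lat.n_excluded_duplicate == 1  # two Rx rows collapsed to one record

    def test_window_is_inclusive(self, vocab):
        records = records_for([("C1", "20190101", "20200101")], vocab)  # exactly 365
        assert compute_latencies(records, "oxaliplatin").n == 1


class TestSummarize:
    def test_singleton(self):
        s = summarize_latency(LatencySet("x", [5.0]))
        assert (s.median_days, s.q1_days, s.q3_days) == (5.0, 5.0, 5.0)

    def test_np1_convention(self):
        s = summarize_latency(LatencySet("x", [1.0, 2.0, 3.0, 4.0]))
        assert (s.q1_days, s.median_days, s.q3_days) == (1.25, 2.5, 3.75)

    def test_exponential_median(self):
        rng = np.random.default_rng(0)
        x = np.minimum(50 * rng.weibull(1.0, 10_000), 365.0)
        s = summarize_latency(LatencySet("x", x))
        assert s.median_days == pytest.approx(50 * np.log(2), rel=0.05)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_latency(LatencySet("x", []))


class TestWeibullFit:
    def test_exponential_limit(self):
        """With shape 1 data, the MLE scale tracks the sample mean."""
        rng = np.random.default_rng(1)
        x = 30 * rng.weibull(1.0, 2_000)
        fit = WeibullTimeToOnset(x).fit()
        assert fit.beta == pytest.approx(1.0, abs=0.05)
        assert fit.alpha_days == pytest.approx(x.mean(), rel=0.05)

    def test_matches_scipy_mle(self):
        rng = np.random.default_rng(2)
        x = 50 * rng.weibull(0.8, 500)
        fit = WeibullTimeToOnset(x).fit()
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        assert fit.beta == pytest.approx(c, rel=1e-4)
        assert fit.alpha_days == pytest.approx(scale, rel=1e-4)

    def test_optimum_beats_perturbed_grid(self):
        rng = np.random.default_rng(3)
        x = 50 * rng.weibull(0.8, 300)
        fit = WeibullTimeToOnset(x).fit()
        log_t = np.log(x)
        nll_hat = _negative_log_likelihood(
            np.array([np.log(fit.alpha_days), np.log(fit.beta)]), x, log_t
        )
        for da in np.linspace(-0.2, 0.2, 10):
            for db in np.linspace(-0.2, 0.2, 10):
                if da == 0 and db == 0:
                    continue
                theta = np.array([np.log(fit.alpha_days) + da, np.log(fit.beta) + db])
                assert _negative_log_likelihood(theta, x, log_t) >= nll_hat - 1e-9

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        x = 20 * rng.weibull(1.3, 400)
        f1 = WeibullTimeToOnset(x).fit()
        f3 = WeibullTimeToOnset(3.0 * x).fit()
        assert f3.alpha_days == pytest.approx(3.0 * f1.alpha_days, rel=1e-5)
        assert f3.beta == pytest.approx(f1.beta, rel=1e-5)

    def test_median_identity_on_large_sample(self):
        rng = np.random.default_rng(5)
        x = 40 * rng.weibull(0.9, 20_000)
        fit = WeibullTimeToOnset(x).fit()
        implied = fit.alpha_days * np.log(2) ** (1 / fit.beta)
        assert implied == pytest.approx(np.median(x), rel=0.03)

    def test_zero_latencies_shifted_for_fit_only(self):
        x = np.array([0.0, 0.0, 1, 2, 3, 5, 8, 13, 21, 34, 55, 89])
        fit = WeibullTimeToOnset(x).fit()
        assert np.isfinite(fit.log_likelihood)
        s = summarize_latency(LatencySet("x", x))
        # zeros retained in the summary: (n+1)p positions over the raw values
        assert s.q1_days == pytest.approx(1.25)
        assert s.median_days == pytest.approx(6.5)

    def test_minimum_n_refusal(self):
        with pytest.raises(FitError, match="below the minimum"):
            fit_weibull([1.0] * 9)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(6)
        x = 50 * rng.weibull(0.8, 200)
        fit = WeibullTimeToOnset(x).fit()
        assert fit.alpha_ci[0] < fit.alpha_days < fit.alpha_ci[1]
        assert fit.beta_ci[0] < fit.beta < fit.beta_ci[1]
        assert fit.alpha_ci[0] > 0 and fit.beta_ci[0] > 0


class TestClassifyHazard:
    @pytest.mark.parametrize(
        "ci, expected",
        [
            ((0.64, 0.89), HazardClass.INITIAL_FAILURE),  # printed taxane-style CI
            ((0.85, 1.05), HazardClass.RANDOM_FAILURE),  # platinum-style CI spans 1
            ((1.10, 1.50), HazardClass.WEAR_OUT_FAILURE),
            ((0.90, 1.00), HazardClass.RANDOM_FAILURE),  # boundary is not initial
            ((1.00, 1.20), HazardClass.RANDOM_FAILURE),  # boundary is not wear-out
        ],
    )
    def test_rule(self, ci, expected):
        assert classify_hazard(ci) == expected


class TestTtoTable:
    def test_small_class_keeps_summary_row(self, vocab):
        rows = [(f"C{i}", "20200101", f"202001{10+i:02d}") for i in range(5)]
        records = records_for(rows, vocab)
        out = tto_table(records, ["oxaliplatin"])
        assert out.iloc[0]["n"] == 5
        assert "alpha" not in out.columns or np.isnan(out.iloc[0].get("alpha", np.nan))
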