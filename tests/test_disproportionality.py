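"""ROR estimation, Woolf intervals, and the signal rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srspv import (
    ContingencyTable,
    ReportingOddsRatio,
    assemble_analysis_set,
    build_contingency,
    compute_ror,
    detect_signal,
    flag_cases,
    run_signal_screen,
)
from srspv.casedef import DrugVocabulary
from srspv.disproportionality import SignalResult

from conftest import FOCAL_PT

cells = st.integers(min_value=1, max_value=100_000)


def woolf_oracle(a, b, c, d, z=1.959963984540054):
    """Independent log-odds computation for cross-checking."""
    log_or = math.log(a) + math.log(d) - math.log(b) - math.log(c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or), math.exp(log_or - z * se), math.exp(log_or + z * se)


class TestComputeRor:
    def test_vinblastine_printed_row(self):
        result = compute_ror(ContingencyTable(17, 277, 1866, 620129))
        assert result.rounded() == (20.4, 12.5, 33.4)

    def test_symmetric_table(self):
        result = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert result.ror == pytest.approx(1.0)
        assert result.ci_low * result.ci_high == pytest.approx(1.0)  # log-symmetric

    def test_undefined_when_few_cases_or_zero_cells(self):
        assert not compute_ror(ContingencyTable(1, 50, 100, 1000)).evaluable
        assert not compute_ror(ContingencyTable(5, 0, 100, 1000)).evaluable
        assert compute_ror(ContingencyTable(5, 0, 100, 1000)).ror is None

    def test_haldane_mode_rescues_zero_cells(self):
        result = compute_ror(ContingencyTable(5, 0, 100, 1000), zero_cell_correction=True)
        assert result.evaluable and result.ror > 1

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_exchange_symmetry(self, a, b, c, d):
        """Swapping (a<->c, b<->d) inverts the ROR exactly."""
        r1 = compute_ror(ContingencyTable(a, b, c, d))
        r2 = compute_ror(ContingencyTable(c, d, a, b))
        if r1.evaluable and r2.evaluable:
            assert r1.ror * r2.ror == pytest.approx(1.0, rel=1e-12)

    @given(a=st.integers(min_value=2, max_value=100_000), b=cells, c=cells, d=cells,
           k=st.integers(min_value=2, max_value=50))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_scaling_fixes_ror_and_narrows_ci(self, a, b, c, d, k):
        r1 = compute_ror(ContingencyTable(a, b, c, d))
        rk = compute_ror(ContingencyTable(k * a, k * b, k * c, k * d))
        assert rk.ror == pytest.approx(r1.ror, rel=1e-12)
        assert rk.ci_high - rk.ci_low < r1.ci_high - r1.ci_low

    def test_oracle_equivalence_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            a, b, c, d = rng.integers(2, 10_000, size=4)
            result = compute_ror(ContingencyTable(int(a), int(b), int(c), int(d)))
            ror, lo, hi = woolf_oracle(a, b, c, d)
            assert abs(math.log(result.ror) - math.log(ror)) < 1e-12
            assert abs(math.log(result.ci_low) - math.log(lo)) < 1e-10
            assert abs(math.log(result.ci_high) - math.log(hi)) < 1e-10


class TestDetectSignal:
    def test_strong_signal(self):
        result = compute_ror(ContingencyTable(491, 8246, 1392, 612160))
        assert result.is_signal

    def test_single_case_never_signals(self):
        result = SignalResult("x", 1, 50.0, 20.0, 100.0, evaluable=True)
        assert not detect_signal(result).is_signal

    def test_ci_low_at_boundary(self):
        result = SignalResult("x", 10, 3.0, 0.99, 9.0, evaluable=True)
        assert not detect_signal(result).is_signal
        assert detect_signal(SignalResult("x", 10, 3.0, 1.01, 9.0, evaluable=True)).is_signal


class TestBuildContingency:
    def test_printed_oxaliplatin_construction(self):
        """a=491 exposed cases of 8,737 exposed reports; denominators 622,289 / 1,883."""
        table = ContingencyTable(a=491, b=8737 - 491, c=1883 - 491, d=622_289 - 8737 - 1392)
        assert (table.a, table.b, table.c, table.d) == (491, 8246, 1392, 612160)
        assert compute_ror(table).rounded() == (26.2, 23.6, 29.1)

    def test_zero_exposure(self, small_dataset, vocab):
        records = assemble_analysis_set(small_dataset, vocab, {FOCAL_PT})
        total_cases = int(flag_cases(small_dataset, {FOCAL_PT}).sum())
        table = build_contingency(records, "nosuchdrug", 3, total_cases)
        assert (table.a, table.b, table.c, table.d) == (0, 0, 2, 1)

    def test_negative_cell_raises(self, small_dataset, vocab):
        records = assemble_analysis_set(small_dataset, vocab, {FOCAL_PT})
        with pytest.raises(ValueError):
            # zero database cases while an exposed case exists -> c < 0
            build_contingency(records, "oxaliplatin", 3, 0)


class TestScreen:
    def test_screen_rows_and_order(self, small_dataset, vocab):
        records = assemble_analysis_set(small_dataset, vocab, {FOCAL_PT})
        out = run_signal_screen(records, ["sb-paclitaxel", "oxaliplatin"], 3, 2)
        assert list(out["drug_or_class"]) == ["sb-paclitaxel", "oxaliplatin"]  # ATC order
        assert (out["total_reports"] == 3).all()

    def test_unknown_target_non_evaluable(self, small_dataset, vocab):
        records = assemble_analysis_set(small_dataset, vocab, {FOCAL_PT})
        out = run_signal_screen(records, ["ghost"], 3, 2)
        assert not out.iloc[0]["evaluable"]

    def test_empty_records_all_non_evaluable(self):
        import pandas as pd

        from srspv.casedef import ANALYSIS_COLUMNS

        records = pd.DataFrame(columns=ANALYSIS_COLUMNS)
        out = run_signal_screen(records, ["a", "b"], 0, 0)
        assert not out["evaluable"].any()
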