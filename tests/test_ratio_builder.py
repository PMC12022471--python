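"""Ratio construction from result tables: filtering, pairing, sufficiency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratiocv import (
    ResultRecord,
    build_consecutive_ratios,
    filter_records,
    sufficiency_check,
)
from ratiocv.ratio_builder import RatioSample


def _rec(pid, value, ts, analyte="crea", sex=None, age=50.0):
    return ResultRecord(patient_id=pid, analyte=analyte,
                        timestamp=pd.Timestamp(ts), value=value, sex=sex, age=age)


def _series(pid, values, analyte="crea", start="2020-01-01", **kw):
    return [_rec(pid, v, pd.Timestamp(start) + pd.Timedelta(days=i), analyte, **kw)
            for i, v in enumerate(values)]


class TestBuildConsecutiveRatios:
    def test_adjacent_pairs_later_over_earlier(self):
        sample = build_consecutive_ratios(_series("p1", [2.0, 3.0, 1.5]))
        np.testing.assert_allclose(sorted(sample.ratios), [0.5, 1.5])

    def test_single_result_patients_contribute_nothing(self):
        recs = _series("p1", [5.0])[:1] + _series("p2", [7.0])[:1]
        sample = build_consecutive_ratios(recs)
        assert sample.n_ratios == 0

    def test_k_results_give_k_minus_one_ratios(self):
        recs = []
        for p in range(10):
            recs += _series(f"p{p}", [1.0, 2.0, 3.0])
        sample = build_consecutive_ratios(recs)
        assert sample.n_ratios == 20
        assert sample.n_patients == 10

    def test_input_order_is_irrelevant(self):
        recs = _series("p1", [2.0, 3.0, 1.5]) + _series("p2", [1.0, 4.0])
        shuffled = [recs[i] for i in [4, 1, 3, 0, 2]]
        a = build_consecutive_ratios(recs)
        b = build_consecutive_ratios(shuffled)
        assert sorted(a.ratios) == sorted(b.ratios)

    def test_duplicate_timestamps_tie_break_by_value(self):
        t = pd.Timestamp("2020-01-01")
        recs = [_rec("p1", 4.0, t), _rec("p1", 2.0, t),
                _rec("p1", 3.0, t + pd.Timedelta(days=1))]
        sample = build_consecutive_ratios(recs)
        # ties sorted value-ascending: 2, 4, 3
        np.testing.assert_allclose(sorted(sample.ratios), [0.75, 2.0])

    def test_gap_filters(self):
        recs = _series("p1", [1.0, 2.0]) \
            + _series("p2", [1.0, 2.0], start="2021-01-01")
        # p2's second result pushed 400 days after its first
        recs[3] = _rec("p2", 2.0, pd.Timestamp("2021-01-01") + pd.Timedelta(days=400))
        sample = build_consecutive_ratios(recs, max_gap=pd.Timedelta(days=30))
        assert sample.n_ratios == 1
        sample = build_consecutive_ratios(recs, min_gap=pd.Timedelta(days=100))
        assert sample.n_ratios == 1

    def test_disjoint_pairs_use_each_result_once(self):
        recs = _series("p1", [1.0, 2.0, 4.0]) + _series("p2", [1.0, 2.0, 4.0, 8.0, 16.0])
        sample = build_consecutive_ratios(recs, disjoint_pairs=True)
        # k=3 -> 1 pair, k=5 -> 2 pairs
        assert sample.n_ratios == 3
        np.testing.assert_allclose(sorted(sample.ratios), [2.0, 2.0, 2.0])

    def test_mixed_analytes_rejected(self):
        recs = _series("p1", [1.0, 2.0]) + _series("p2", [1.0], analyte="alb")
        with pytest.raises(ValueError, match="one analyte"):
            build_consecutive_ratios(recs)

    @given(st.lists(st.tuples(st.integers(0, 4), st.floats(0.1, 10.0)),
                    min_size=0, max_size=30))
    @settings(derandomize=True, max_examples=60)
    def test_count_conservation_against_brute_force(self, rows):
        recs = []
        per_patient: dict[int, int] = {}
        for i, (pid, value) in enumerate(rows):
            per_patient[pid] = per_patient.get(pid, 0) + 1
            recs.append(_rec(f"p{pid}", value,
                             pd.Timestamp("2020-01-01") + pd.Timedelta(hours=i)))
        expected = sum(max(0, k - 1) for k in per_patient.values())
        sample = build_consecutive_ratios(recs)
        assert sample.n_ratios == expected
        assert np.all(sample.ratios > 0)
        assert np.all(np.isfinite(np.log(sample.ratios)))


class TestFilterRecords:
    @pytest.fixture()
    def records(self):
        return (
            _series("p1", [1.0, 2.0], analyte="crea", sex="M", age=40)
            + _series("p2", [1.0, 2.0], analyte="crea", sex="F", age=70)
            + _series("p3", [1.0, 2.0], analyte="alb", sex="F", age=30)
            + _series("p4", [1.0], analyte="crea", sex="M", age=15)
        )

    def test_analyte_selection(self, records):
        out = filter_records(records, "crea")
        assert set(out["analyte"]) == {"crea"}
        assert len(out) == 4

    def test_sex_filter(self, records):
        out = filter_records(records, "crea", sex="M")
        assert set(out["patient_id"]) == {"p1"}

    def test_default_age_range_excludes_minors(self, records):
        out = filter_records(records, "crea")
        assert "p4" not in set(out["patient_id"])

    def test_age_bounds_inclusive(self):
        recs = [_rec("a", 1.0, "2020-01-01", age=18.0),
                _rec("b", 1.0, "2020-01-01", age=110.0),
                _rec("c", 1.0, "2020-01-01", age=17.9)]
        out = filter_records(recs, "crea")
        assert set(out["patient_id"]) == {"a", "b"}

    def test_unknown_analyte_warns_not_raises(self, records, caplog):
        with caplog.at_level("WARNING"):
            out = filter_records(records, "nope")
        assert out.empty
        assert any("nope" in m for m in caplog.messages)


class TestSufficiencyCheck:
    def _sample(self, n):
        return RatioSample(analyte="x", subgroup="All",
                           ratios=np.ones(n) + 0.01, n_patients=n, n_ratios=n)

    def test_low_count_warns(self):
        warnings = sufficiency_check(self._sample(4999))
        assert len(warnings) == 1 and "5000" in warnings[0]

    def test_adequate_sample_is_silent(self):
        assert sufficiency_check(self._sample(6882), 0.1) == []

    def test_high_pathological_fraction_warns(self):
        warnings = sufficiency_check(self._sample(10_000), 0.35)
        assert len(warnings) == 1 and "pathological" in warnings[0]
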