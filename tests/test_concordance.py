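"""Concordance classification, time-course reclassification, and table cells."""

import itertools

import pydantic
import pytest

from neutralqol import (
    ComparisonRecord,
    StudyResult,
    TimepointPair,
    aggregate,
    aggregate_timecourse,
    classify,
    classify_record,
    load_study_results,
    save_study_results,
)

DIRECTIONS = ("improved", "worsened", "no_change")


def _res(direction, significant):
    # bypass validation so the truth table covers all 6 direction/sig states
    return StudyResult.model_construct(direction=direction, significant=significant)


def _record(study_id, patterns, stratum="non_rare", generic_id="SF-36", **kw):
    pairs = [
        TimepointPair(timepoint=f"t{k + 1}", specific=s, generic=g)
        for k, (s, g) in enumerate(patterns)
    ]
    return ComparisonRecord(
        study_id=study_id, stratum=stratum, generic_id=generic_id, pairs=pairs, **kw
    )


SIG_IMPROVED = StudyResult(direction="improved", significant=True)
SIG_WORSENED = StudyResult(direction="worsened", significant=True)
NS_IMPROVED = StudyResult(direction="improved", significant=False)
NS_WORSENED = StudyResult(direction="worsened", significant=False)
NO_CHANGE = StudyResult(direction="no_change", significant=False)


class TestClassify:
    def test_no_change_cannot_be_significant(self):
        with pytest.raises(pydantic.ValidationError):
            StudyResult(direction="no_change", significant=True)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            # fully aligned
            (SIG_IMPROVED, SIG_IMPROVED, "strong"),
            (SIG_WORSENED, SIG_WORSENED, "strong"),
            (NO_CHANGE, NO_CHANGE, "strong"),
            (NS_IMPROVED, NS_IMPROVED, "strong"),
            # both non-significant reads as "no change" for alignment,
            # whatever directions were recorded
            (NS_IMPROVED, NS_WORSENED, "strong"),
            (NS_IMPROVED, NO_CHANGE, "strong"),
            # same direction, significant with only one instrument
            (SIG_IMPROVED, NS_IMPROVED, "moderate"),
            (SIG_WORSENED, NS_WORSENED, "moderate"),
            # significant effect vs no change, or significant opposites
            (SIG_IMPROVED, SIG_WORSENED, "none"),
            (SIG_IMPROVED, NO_CHANGE, "none"),
            (SIG_IMPROVED, NS_WORSENED, "none"),
            (SIG_WORSENED, NS_IMPROVED, "none"),
        ],
    )
    def test_rules(self, a, b, expected):
        assert classify(a, b) == expected

    def test_total_and_symmetric_over_full_truth_table(self):
        """Every direction × significance combination (6 × 6 states) maps to
        exactly one level, symmetrically."""
        states = [
            _res(d, s) for d, s in itertools.product(DIRECTIONS, (True, False))
        ]
        seen = 0
        for a, b in itertools.product(states, states):
            level = classify(a, b)
            assert level in ("none", "moderate", "strong")
            assert level == classify(b, a)
            seen += 1
        assert seen == 36


class TestClassifyRecord:
    def test_uniform_record_not_reclassified(self):
        rec = _record("s1", [(SIG_IMPROVED, SIG_IMPROVED)] * 3)
        c = classify_record(rec)
        assert c.levels == ("strong",) * 3
        assert c.headline == "strong"
        assert not c.reclassified

    def test_level_change_flags_reclassification(self):
        rec = _record(
            "s2", [(SIG_IMPROVED, SIG_IMPROVED), (SIG_IMPROVED, NS_IMPROVED)]
        )
        c = classify_record(rec)
        assert c.levels == ("strong", "moderate")
        assert c.headline == "strong"  # anchored at the first time point
        assert c.reclassified

    def test_duplicate_timepoints_rejected(self):
        with pytest.raises(pydantic.ValidationError, match="duplicate"):
            ComparisonRecord(
                study_id="s", stratum="rare", generic_id="SF-36",
                pairs=[
                    TimepointPair(
                        timepoint="t1", specific=NO_CHANGE, generic=NO_CHANGE
                    ),
                    TimepointPair(
                        timepoint="t1", specific=NO_CHANGE, generic=NO_CHANGE
                    ),
                ],
            )


def _records_with_levels(n_none, n_moderate, n_strong, **kw):
    patterns = {
        "none": (SIG_IMPROVED, NO_CHANGE),
        "moderate": (SIG_IMPROVED, NS_IMPROVED),
        "strong": (SIG_IMPROVED, SIG_IMPROVED),
    }
    records = []
    k = 0
    for level, count in (
        ("none", n_none), ("moderate", n_moderate), ("strong", n_strong)
    ):
        for _ in range(count):
            records.append(_record(f"s{k}", [patterns[level]], **kw))
            k += 1
    return records


class TestAggregate:
    def test_counts_and_half_up_percentages(self):
        """An 11-study cell with 2/6/3 studies per level prints 18/55/27."""
        cell = aggregate(_records_with_levels(2, 6, 3), "non_rare", "SF-36")
        assert cell.n == 11
        assert cell.counts == {"none": 2, "moderate": 6, "strong": 3}
        assert cell.percentages == {"none": 18, "moderate": 55, "strong": 27}

    def test_31_study_cell(self):
        cell = aggregate(_records_with_levels(5, 17, 9), "non_rare", "SF-36")
        assert cell.percentages == {"none": 16, "moderate": 55, "strong": 29}

    def test_singleton_cell(self):
        cell = aggregate(_records_with_levels(0, 0, 1), "non_rare", "SF-36")
        assert cell.percentages == {"none": 0, "moderate": 0, "strong": 100}

    def test_empty_cell_marker(self):
        cell = aggregate(_records_with_levels(1, 1, 1), "rare", "EQ-5D")
        assert cell.empty and cell.n == 0

    def test_conservation(self):
        cell = aggregate(_records_with_levels(3, 4, 5), "non_rare", "SF-36")
        assert sum(cell.counts.values()) == cell.n
        assert abs(sum(cell.percentages.values()) - 100) <= 1


class TestAggregateTimecourse:
    def _multi(self, n_total, n_reclassified, **kw):
        records = []
        for k in range(n_total):
            if k < n_reclassified:
                patterns = [(SIG_IMPROVED, SIG_IMPROVED), (SIG_IMPROVED, NO_CHANGE)]
            else:
                patterns = [(SIG_IMPROVED, SIG_IMPROVED)] * 2
            records.append(_record(f"m{k}", patterns, **kw))
        return records

    def test_no_multi_timepoint_records(self):
        single = _records_with_levels(1, 1, 1)
        tc = aggregate_timecourse(single, "non_rare", "SF-36")
        assert tc.empty and tc.n_multi_timepoint == 0

    @pytest.mark.parametrize(
        "n,n_re,pct", [(36, 7, 19), (23, 2, 9), (2, 0, 0)]
    )
    def test_reclassification_percentages(self, n, n_re, pct):
        tc = aggregate_timecourse(self._multi(n, n_re), "non_rare", "SF-36")
        assert tc.n_multi_timepoint == n
        assert tc.n_reclassified == n_re
        assert tc.pct_reclassified == pct

    def test_single_timepoint_records_excluded(self):
        records = self._multi(4, 1) + _records_with_levels(5, 0, 0)
        tc = aggregate_timecourse(records, "non_rare", "SF-36")
        assert tc.n_multi_timepoint == 4

    def test_qol_change_detection(self):
        changed = _record(
            "c1", [(SIG_IMPROVED, SIG_IMPROVED), (NS_IMPROVED, SIG_IMPROVED)]
        )
        static = _record("c2", [(SIG_IMPROVED, SIG_IMPROVED)] * 2)
        tc = aggregate_timecourse([changed, static], "non_rare", "SF-36")
        assert tc.n_qol_change == 1
        assert tc.pct_qol_change == 50


class TestStudyResultsIO:
    def test_roundtrip(self, tmp_path):
        records = _records_with_levels(2, 1, 1) + [
            _record(
                "multi",
                [(SIG_IMPROVED, NS_IMPROVED), (SIG_WORSENED, SIG_WORSENED)],
                stratum="rare",
                is_clinical_trial=True,
            )
        ]
        path = save_study_results(records, tmp_path / "studies.csv")
        loaded = load_study_results(path)
        assert sorted(r.study_id for r in loaded) == sorted(
            r.study_id for r in records
        )
        by_id = {r.study_id: r for r in loaded}
        assert by_id["multi"] == records[-1]
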