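"""Trio validation by class-aware coverage overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvbench.core import CNClass, CallSet, Pedigree, Trio
from cnvbench.family_validation import (
    coverage_fraction,
    stratify_by_size,
    summarize_validation,
    validate_dataset,
    validate_extended,
    validate_trio,
)
from conftest import brute_force_coverage, seg

interval = st.tuples(st.integers(0, 9_900), st.integers(1, 400), st.sampled_from(["loss", "gain"]))


class TestCoverageFraction:
    def test_derived_partial_coverage(self):
        target = seg(1, 100, 200, "loss")
        others = [seg(1, 90, 150, "loss"), seg(1, 150, 195, "loss")]
        assert coverage_fraction(target, others) == pytest.approx(0.95)

    def test_empty_others_zero(self):
        assert coverage_fraction(seg(1, 0, 10, "loss"), []) == 0.0

    def test_self_coverage_one(self):
        s = seg(1, 0, 10, "loss")
        assert coverage_fraction(s, [s]) == 1.0

    def test_class_mismatch_ignored(self):
        assert coverage_fraction(seg(1, 0, 10, "loss"), [seg(1, 0, 10, "gain")]) == 0.0

    def test_class_blind_pools_classes(self):
        target = seg(1, 0, 100, "loss")
        others = [seg(1, 0, 60, "gain"), seg(1, 40, 100, "loss")]
        assert coverage_fraction(target, others, same_class=False) == 1.0

    def test_other_chromosome_ignored(self):
        assert coverage_fraction(seg(1, 0, 10, "loss"), [seg(2, 0, 10, "loss")]) == 0.0

    @settings(max_examples=300, deadline=None)
    @given(target=interval, others=st.lists(interval, max_size=12))
    def test_matches_per_base_oracle_exactly(self, target, others):
        t = seg(1, target[0], target[0] + target[1], target[2])
        other_segs = [seg(1, a, a + l, c) for a, l, c in others]
        for same_class in (True, False):
            assert coverage_fraction(t, other_segs, same_class) == pytest.approx(
                brute_force_coverage(t, other_segs, same_class), abs=0
            )


def trio_sets(off_segs, fa_segs, mo_segs, tool="t"):
    return (
        CallSet("c", tool, off_segs),
        CallSet("f", tool, fa_segs),
        CallSet("m", tool, mo_segs),
    )


class TestValidateTrio:
    def test_identical_paternal_cnv_validates(self):
        s = seg(1, 100, 200, "loss")
        (r,) = validate_trio(*trio_sets([s], [s], []))
        assert r.validated and r.coverage_father == 1.0

    def test_class_mismatch_never_validates(self):
        (r,) = validate_trio(
            *trio_sets([seg(1, 100, 200, "loss")], [], [seg(1, 95, 200, "gain")])
        )
        assert not r.validated and r.coverage_mother == 0.0

    def test_exact_threshold_fails_strict_comparison(self):
        # coverage exactly 0.90 is NOT > 0.90
        (r,) = validate_trio(
            *trio_sets([seg(1, 0, 100, "loss")], [seg(1, 0, 90, "loss")], [])
        )
        assert r.coverage_father == pytest.approx(0.9) and not r.validated

    def test_parents_not_pooled_into_one_union(self):
        # each parent alone covers 50%; pooling would cover 100%
        (r,) = validate_trio(
            *trio_sets(
                [seg(1, 0, 100, "loss")],
                [seg(1, 0, 50, "loss")],
                [seg(1, 50, 100, "loss")],
            )
        )
        assert not r.validated

    def test_fragmented_parent_union_counts(self):
        (r,) = validate_trio(
            *trio_sets(
                [seg(1, 0, 100, "loss")],
                [seg(1, 0, 60, "loss"), seg(1, 62, 100, "loss")],
                [],
            )
        )
        assert r.coverage_father == pytest.approx(0.98) and r.validated

    def test_cross_tool_callsets_rejected(self):
        with pytest.raises(ValueError):
            validate_trio(
                CallSet("c", "t1", []), CallSet("f", "t2", []), CallSet("m", "t1", [])
            )

    def test_threshold_monotonicity(self):
        off = [seg(1, 0, 100, "loss"), seg(1, 200, 300, "loss"), seg(2, 0, 50, "gain")]
        fa = [seg(1, 0, 80, "loss"), seg(1, 200, 300, "loss")]
        mo = [seg(2, 0, 30, "gain")]
        validated_sets = []
        for thr in (0.5, 0.7, 0.9, 0.99):
            recs = validate_trio(*trio_sets(off, fa, mo), threshold=thr)
            validated_sets.append({r.segment.sort_key() for r in recs if r.validated})
        for lo, hi in zip(validated_sets, validated_sets[1:]):
            assert hi <= lo


class TestValidateExtended:
    def test_other_tool_rescues_validation(self):
        s = seg(1, 100, 200, "loss")
        off = CallSet("c", "t1", [s])
        parental = [CallSet("f", "t2", [s])]
        same_tool = validate_trio(off, CallSet("f", "t1", []), CallSet("m", "t1", []))
        extended = validate_extended(off, parental, "f", "m")
        assert not same_tool[0].validated and extended[0].validated

    def test_no_parental_calls_not_validated(self):
        (r,) = validate_extended(CallSet("c", "t1", [seg(1, 0, 10, "loss")]), [], "f", "m")
        assert not r.validated

    def test_extended_comparison_accepts_exact_threshold(self):
        # extended mode uses >=, so exactly 90% passes
        off = CallSet("c", "t1", [seg(1, 0, 100, "loss")])
        parental = [CallSet("f", "t2", [seg(1, 0, 90, "loss")])]
        (r,) = validate_extended(off, parental, "f", "m", threshold=0.9)
        assert r.validated

    def test_superset_of_same_tool_validation(self):
        off = CallSet("c", "t1", [seg(1, 0, 100, "loss"), seg(2, 0, 60, "gain")])
        fa_t1 = CallSet("f", "t1", [seg(1, 0, 100, "loss")])
        parental = [fa_t1, CallSet("m", "t2", [seg(2, 0, 60, "gain")])]
        same = validate_trio(off, fa_t1, CallSet("m", "t1", []), strict=False)
        ext = validate_extended(off, parental, "f", "m", strict=False)
        for rs, re in zip(same, ext):
            assert re.validated or not rs.validated


class TestSummaries:
    def _records(self):
        dels = [seg(1, i * 1000, i * 1000 + 100, "loss") for i in range(4)]
        dups = [seg(2, i * 1000, i * 1000 + 200, "gain") for i in range(2)]
        off = CallSet("c", "t", dels + dups)
        fa = CallSet("f", "t", dels[:3] + dups[:1])
        return validate_trio(off, fa, CallSet("m", "t", []))

    def test_hand_counted_percentages(self):
        summary = summarize_validation(self._records())
        assert summary["pct_validated"] == pytest.approx(100 * 4 / 6, abs=0.01)
        assert summary["pct_validated_deletions"] == pytest.approx(75.0)
        assert summary["pct_validated_duplications"] == pytest.approx(50.0)
        assert summary["ddr_validated"] == pytest.approx(3.0)

    def test_validated_sequence_per_base(self):
        summary = summarize_validation(self._records())
        # validated bp = 3*100 + 1*200 = 500 of total 4*100 + 2*200 = 800
        assert summary["pct_validated_sequence"] == pytest.approx(100 * 500 / 800)

    def test_all_validated_gives_100(self):
        s = seg(1, 0, 100, "loss")
        records = validate_trio(*trio_sets([s], [s], []))
        summary = summarize_validation(records)
        assert summary["pct_validated"] == 100.0
        assert summary["pct_validated_sequence"] == 100.0

    def test_empty_records_absent(self):
        assert summarize_validation([]) is None


class TestStratifyBySize:
    def test_single_bin_reproduces_overall_rate(self):
        records = TestSummaries()._records()
        out = stratify_by_size(records, [])
        assert len(out) == 1
        assert out.iloc[0]["pct_validated"] == pytest.approx(100 * 4 / 6, abs=0.01)

    def test_two_bins_match_hand_counts(self):
        records = TestSummaries()._records()
        out = stratify_by_size(records, [150])
        small = out[out["bin_high"] == 150].iloc[0]  # the four 100-bp deletions
        large = out[out["bin_low"] == 150].iloc[0]  # the two 200-bp duplications
        assert (small["n_cnvs"], small["n_validated"]) == (4, 3)
        assert (large["n_cnvs"], large["n_validated"]) == (2, 1)

    def test_empty_bin_rate_undefined(self):
        records = TestSummaries()._records()
        out = stratify_by_size(records, [1, 2])
        empty = out[(out["bin_low"] == 1) & (out["bin_high"] == 2)].iloc[0]
        assert empty["n_cnvs"] == 0 and np.isnan(empty["pct_validated"])

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_size([], [10, 10])


class TestValidateDataset:
    def test_missing_parent_counts_as_empty(self):
        calls = {
            ("c", "t"): CallSet("c", "t", [seg(1, 0, 100, "loss")]),
            ("f", "t"): CallSet("f", "t", [seg(1, 0, 100, "loss")]),
        }
        ped = Pedigree([Trio("c", "f", "m", "CEU")])
        records, summary = validate_dataset(calls, ped)
        assert records[("c", "t")][0].validated
        assert summary.iloc[0]["population"] == "CEU"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            validate_dataset({}, Pedigree([]), mode="sideways")
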