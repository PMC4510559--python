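"""Call-set, pedigree and marker-map I/O plus standardization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvbench.call_io import (
    CallFileError,
    markers_to_segments,
    read_call_file,
    read_marker_map,
    read_pedigree,
    standardize,
    write_call_file,
    write_marker_map,
    write_pedigree,
)
from cnvbench.core import (
    CNClass,
    CallSet,
    GenomicSegment,
    MarkerMap,
    Pedigree,
    Trio,
    collapse_genotype_to_class,
    merge_intervals,
)
from conftest import seg


class TestGenotypeCollapse:
    @pytest.mark.parametrize(
        "genotype,expected",
        [
            (0, CNClass.LOSS),
            (1, CNClass.LOSS),
            (2, CNClass.NORMAL),
            (3, CNClass.GAIN),
            (4, CNClass.GAIN),
            (6, CNClass.GAIN),
        ],
    )
    def test_mapping(self, genotype, expected):
        assert collapse_genotype_to_class(genotype) is expected

    @pytest.mark.parametrize("bad", [-1, 7, 2.5, "x"])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            collapse_genotype_to_class(bad)


class TestSegmentInvariants:
    def test_requires_positive_length(self):
        with pytest.raises(ValueError):
            seg(start=100, end=100)

    def test_requires_autosome(self):
        with pytest.raises(ValueError):
            seg(chrom=23)

    def test_genotype_class_consistency_enforced(self):
        with pytest.raises(ValueError):
            GenomicSegment(chrom=1, start=0, end=10, cn_class=CNClass.GAIN, cn_genotype=1)


class TestCallFileRoundTrip:
    def test_three_row_identity_read_back(self, tmp_path):
        cs = CallSet(
            "S1",
            "toolA",
            [
                seg(1, 100, 200, "loss", n_markers=5),
                seg(2, 50, 500, "gain"),
                seg(1, 1000, 2000, "loss"),
            ],
        )
        path = tmp_path / "calls.tsv"
        write_call_file([cs], path)
        (back,) = read_call_file(path)
        assert len(back) == 3
        assert back == CallSet("S1", "toolA", cs.segments)

    def test_round_trip_is_identity_on_standardized_sets(self, tmp_path):
        cs = standardize(
            CallSet("S1", "t", [seg(1, 0, 10, "loss"), seg(1, 5, 30, "loss"), seg(3, 9, 12, "gain")])
        )
        path = tmp_path / "rt.tsv"
        write_call_file([cs], path)
        (back,) = read_call_file(path)
        write_call_file([back], tmp_path / "rt2.tsv")
        assert (tmp_path / "rt2.tsv").read_bytes() == path.read_bytes()
        assert back == cs

    def test_chrx_rows_dropped(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text(
            "sample_id\ttool_id\tchrom\tstart\tend\tcn\n"
            "S1\tt\t1\t0\t10\tloss\n"
            "S1\tt\tchrX\t0\t10\tloss\n"
        )
        (cs,) = read_call_file(path)
        assert len(cs) == 1 and cs.segments[0].chrom == 1

    def test_genotype_coded_cn_parsed(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text(
            "sample_id\ttool_id\tchrom\tstart\tend\tcn\nS1\tt\t1\t0\t10\t1\nS1\tt\t1\t20\t30\t4\n"
        )
        (cs,) = read_call_file(path)
        assert [s.cn_class for s in cs] == [CNClass.LOSS, CNClass.GAIN]
        assert [s.cn_genotype for s in cs] == [1, 4]

    def test_unknown_cn_code_names_the_code(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text("sample_id\ttool_id\tchrom\tstart\tend\tcn\nS1\tt\t1\t0\t10\tweird\n")
        with pytest.raises(CallFileError, match="weird"):
            read_call_file(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text("sample_id\ttool_id\tchrom\tstart\tend\tcn\nS1\tt\t1\tzero\t10\tloss\n")
        with pytest.raises(CallFileError, match="line 2"):
            read_call_file(path)

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_call_file(tmp_path / "x.tsv", dialect="nope")


@pytest.fixture
def toy_map():
    return MarkerMap(
        [("m1", 1, 100), ("m2", 1, 200), ("m3", 1, 300), ("m4", 2, 50), ("m5", 2, 60)]
    )


class TestMarkersToSegments:
    def test_single_run(self, toy_map):
        segs = markers_to_segments([("m1", "loss"), ("m2", "loss"), ("m3", "loss")], toy_map)
        assert segs == [
            GenomicSegment(chrom=1, start=100, end=301, cn_class=CNClass.LOSS, n_markers=3)
        ]

    def test_normal_marker_splits_run(self, toy_map):
        segs = markers_to_segments(
            [("m1", "loss"), ("m2", "normal"), ("m3", "loss")], toy_map
        )
        assert [(s.start, s.end, s.n_markers) for s in segs] == [(100, 101, 1), (300, 301, 1)]

    def test_unlisted_map_marker_breaks_run(self, toy_map):
        segs = markers_to_segments([("m1", "loss"), ("m3", "loss")], toy_map)
        assert [(s.start, s.end) for s in segs] == [(100, 101), (300, 301)]

    def test_chromosome_boundary_splits_run(self, toy_map):
        segs = markers_to_segments(
            [("m3", "gain"), ("m4", "gain"), ("m5", "gain")], toy_map
        )
        assert [(s.chrom, s.start, s.end, s.n_markers) for s in segs] == [
            (1, 300, 301, 1),
            (2, 50, 61, 2),
        ]

    def test_unknown_marker_rejected(self, toy_map):
        with pytest.raises(KeyError, match="m99"):
            markers_to_segments([("m99", "loss")], toy_map)

    def test_genotype_states_accepted(self, toy_map):
        segs = markers_to_segments([("m1", 1), ("m2", 1)], toy_map)
        assert segs[0].cn_class is CNClass.LOSS

    @settings(max_examples=100, deadline=None)
    @given(
        states=st.lists(
            st.sampled_from(["loss", "normal", "gain", None]), min_size=1, max_size=30
        )
    )
    def test_reexpansion_reproduces_input_states(self, states):
        """Expanding output segments against the map recovers exactly the
        variant-state markers of the input (brute-force oracle)."""
        marker_map = MarkerMap([(f"m{i}", 1, 10 * i + 5) for i in range(len(states))])
        marker_states = [
            (f"m{i}", s) for i, s in enumerate(states) if s is not None
        ]
        segs = markers_to_segments(marker_states, marker_map)
        expanded = {}
        for s in segs:
            ids = [
                m
                for m, (c, p) in ((m, marker_map.location(m)) for m, _, _ in marker_map.iter_entries())
                if c == s.chrom and s.start <= p < s.end
            ]
            assert len(ids) == s.n_markers
            for m in ids:
                expanded[m] = s.cn_class.value
        expected = {m: s for m, s in marker_states if s in ("loss", "gain")}
        assert expanded == expected


class TestStandardize:
    def test_overlapping_same_class_merged(self, make_callset):
        cs = standardize(make_callset([seg(1, 100, 200, "loss"), seg(1, 150, 250, "loss")]))
        assert [(s.start, s.end) for s in cs] == [(100, 250)]

    def test_book_ended_same_class_merged(self, make_callset):
        cs = standardize(make_callset([seg(1, 100, 200, "loss"), seg(1, 200, 250, "loss")]))
        assert [(s.start, s.end) for s in cs] == [(100, 250)]

    def test_classes_never_merged_across(self, make_callset):
        cs = standardize(make_callset([seg(1, 100, 200, "loss"), seg(1, 150, 250, "gain")]))
        assert len(cs) == 2
        assert {s.cn_class for s in cs} == {CNClass.LOSS, CNClass.GAIN}

    def test_normal_segments_dropped(self, make_callset):
        cs = standardize(
            make_callset([seg(1, 0, 10, "normal", cn_genotype=2), seg(1, 20, 30, "loss")])
        )
        assert [s.cn_class for s in cs] == [CNClass.LOSS]

    def test_sub_kb_outliers_retained(self, make_callset):
        cs = standardize(make_callset([seg(1, 100, 600, "loss")]))
        assert len(cs) == 1 and cs.segments[0].length == 500

    @settings(max_examples=100, deadline=None)
    @given(
        intervals=st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80), st.sampled_from(["loss", "gain"])),
            min_size=0,
            max_size=15,
        )
    )
    def test_idempotent_and_length_non_increasing(self, intervals):
        cs = CallSet("S", "t", [seg(1, a, a + l, c) for a, l, c in intervals])
        once = standardize(cs)
        twice = standardize(once)
        assert once == twice
        # merging only: covered bases per class conserved, raw sum never grows
        for cls in (CNClass.LOSS, CNClass.GAIN):
            raw = [(s.start, s.end) for s in cs if s.cn_class is cls]
            merged_len = sum(e - s for s, e in merge_intervals(raw))
            assert sum(s.length for s in once.by_class(cls)) == merged_len
            assert merged_len <= sum(e - s for s, e in raw)


class TestPedigreeIO:
    def test_round_trip(self, tmp_path):
        ped = Pedigree(
            [
                Trio("c1", "f1", "m1", "CEU"),
                Trio("c2", "f2", "m2", "YRI"),
            ]
        )
        path = tmp_path / "trios.ped"
        write_pedigree(ped, path)
        assert read_pedigree(path) == ped

    def test_duplicate_offspring_rejected(self):
        with pytest.raises(ValueError):
            Pedigree([Trio("c1", "f1", "m1"), Trio("c1", "f2", "m2")])

    def test_trio_ids_must_differ(self):
        with pytest.raises(ValueError):
            Trio("a", "a", "m")


class TestMarkerMapIO:
    def test_round_trip(self, tmp_path, toy_map):
        path = tmp_path / "map.tsv"
        write_marker_map(toy_map, path)
        back = read_marker_map(path)
        assert list(back.iter_entries()) == list(toy_map.iter_entries())

    def test_duplicate_marker_rejected(self):
        with pytest.raises(ValueError):
            MarkerMap([("m1", 1, 10), ("m1", 2, 20)])

    def test_count_in_half_open(self, toy_map):
        assert toy_map.count_in(1, 100, 300) == 2
        assert toy_map.count_in(1, 100, 301) == 3
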