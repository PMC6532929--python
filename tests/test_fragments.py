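"""Fragment IO: BAM/SAM pair reconstruction, BED round trips, repeat collapse."""

import numpy as np
import pysam
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rdnafoot.errors import BedParseError
from rdnafoot.fragments import (
    Fragment,
    FragmentFilter,
    Fragments,
    collapse_fragments,
    collapse_to_unit,
    read_fragments_bam,
    read_fragments_bed,
    write_fragments_bed,
)
from rdnafoot.regions import GenomicInterval

CHROM = "chrXII"
CHROM_LEN = 1_078_177


def _make_pairs(rng, n):
    """(start, length, mapq) triples for synthetic proper pairs."""
    starts = rng.integers(458_000, 460_000, n)
    lengths = rng.integers(30, 300, n)
    mapqs = rng.integers(0, 60, n)
    return sorted(zip(starts.tolist(), lengths.tolist(), mapqs.tolist()))


def _write_alignments(path, pairs, bam=True):
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": CHROM, "LN": CHROM_LEN}]}
    mode = "wb" if bam else "w"
    read_len = 20
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for i, (start, length, mapq) in enumerate(pairs):
            for is_r1 in (True, False):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"pair{i}"
                a.reference_id = 0
                a.next_reference_id = 0
                a.mapping_quality = mapq
                a.query_sequence = "A" * read_len
                a.cigarstring = f"{read_len}M"
                if is_r1:
                    a.flag = 99
                    a.reference_start = start
                    a.next_reference_start = start + length - read_len
                    a.template_length = length
                else:
                    a.flag = 147
                    a.reference_start = start + length - read_len
                    a.next_reference_start = start
                    a.template_length = -length
                out.write(a)
    if bam:
        pysam.sort("-o", str(path), str(path))
        pysam.index(str(path))


@pytest.fixture(scope="module")
def pair_table():
    return _make_pairs(np.random.default_rng(7), 1000)


@pytest.fixture(scope="module")
def bam_path(tmp_path_factory, pair_table):
    path = tmp_path_factory.mktemp("aln") / "pairs.bam"
    _write_alignments(path, pair_table, bam=True)
    return path


class TestBamReading:
    def test_fragment_is_outer_template_span(self, tmp_path):
        path = tmp_path / "one.bam"
        _write_alignments(path, [(100, 75, 60)])
        frags = list(read_fragments_bam(path))
        assert frags == [Fragment(CHROM, 100, 175)]
        assert frags[0].length == 75

    def test_default_filter_drops_sub50bp_fragments(self, tmp_path):
        path = tmp_path / "short.bam"
        _write_alignments(path, [(100, 40, 60), (300, 50, 60)])
        frags = list(read_fragments_bam(path))
        assert [f.length for f in frags] == [50]

    @pytest.mark.parametrize(
        "filt",
        [
            FragmentFilter(),
            FragmentFilter(min_length=60, max_length=180),
            FragmentFilter(min_mapq=30),
            FragmentFilter(region=GenomicInterval(CHROM, 458_500, 459_000)),
        ],
    )
    def test_matches_bruteforce_count(self, bam_path, pair_table, filt):
        expected = [
            (s, s + ln)
            for s, ln, mq in pair_table
            if filt.passes(Fragment(CHROM, s, s + ln), mq)
        ]
        got = read_fragments_bam(bam_path, filt)
        assert sorted(zip(got.starts.tolist(), got.ends.tolist())) == sorted(expected)

    def test_sam_without_index_streams_whole_file(self, tmp_path, pair_table):
        path = tmp_path / "pairs.sam"
        _write_alignments(path, pair_table, bam=False)
        filt = FragmentFilter(region=GenomicInterval(CHROM, 458_500, 459_000))
        expected = sum(
            filt.passes(Fragment(CHROM, s, s + ln), mq) for s, ln, mq in pair_table
        )
        assert len(read_fragments_bam(path, filt)) == expected

    def test_dedup_collapses_identical_fragments(self, tmp_path):
        path = tmp_path / "dup.bam"
        _write_alignments(path, [(100, 75, 60), (100, 75, 60), (300, 80, 60)])
        assert len(read_fragments_bam(path)) == 3
        assert len(read_fragments_bam(path, dedup=True)) == 2


fragment_lists = st.lists(
    st.tuples(
        st.sampled_from(["chrXII", "chrIV"]),
        st.integers(min_value=0, max_value=100_000),
        st.integers(min_value=1, max_value=400),
    ).map(lambda t: Fragment(t[0], t[1], t[1] + t[2])),
    max_size=60,
)


class TestBed:
    @given(frags=fragment_lists)
    def test_round_trip_preserves_multiset(self, tmp_path_factory, frags):
        path = tmp_path_factory.mktemp("bed") / "rt.bed"
        write_fragments_bed(frags, path)
        back = read_fragments_bed(path)
        assert back.multiset() == Fragments.from_records(frags).multiset()

    def test_plain_line_parses(self, tmp_path):
        path = tmp_path / "one.bed"
        path.write_text("chrXII\t458900\t458975\n")
        (frag,) = read_fragments_bed(path)
        assert frag == Fragment("chrXII", 458900, 458975)
        assert frag.length == 75

    def test_empty_file_gives_empty_stream(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert len(read_fragments_bed(path)) == 0

    @pytest.mark.parametrize(
        "content,lineno",
        [
            ("chrXII\t100\t200\nchrXII\tabc\t300\n", 2),
            ("chrXII\t500\t400\n", 1),
        ],
    )
    def test_malformed_line_reports_line_number(self, tmp_path, content, lineno):
        path = tmp_path / "bad.bed"
        path.write_text(content)
        with pytest.raises(BedParseError, match=f"line {lineno}"):
            read_fragments_bed(path)


class TestFilterProperties:
    @given(frags=fragment_lists)
    def test_filtering_is_idempotent(self, frags):
        filt = FragmentFilter(min_length=50, max_length=250)
        fs = Fragments.from_records(frags)
        once = filt.apply(fs)
        twice = filt.apply(once)
        assert once.multiset() == twice.multiset()

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            FragmentFilter(min_length=200, max_length=100)


class TestCollapse:
    def test_one_unit_downstream_maps_to_same_offset(self, lm):
        inside = Fragment(lm.chrom, lm.rars - 30, lm.rars + 45)
        shifted = Fragment(lm.chrom, inside.start + lm.unit_length,
                           inside.end + lm.unit_length)
        collapsed, flag = collapse_to_unit(shifted, lm)
        assert flag and collapsed == inside

    def test_fragment_inside_unit_unchanged(self, lm):
        frag = Fragment(lm.chrom, lm.rars - 30, lm.rars + 45)
        collapsed, flag = collapse_to_unit(frag, lm)
        assert flag and collapsed == frag

    def test_fragment_outside_rdna_flagged_unchanged(self, lm):
        frag = Fragment("chrIV", 1000, 1100)
        collapsed, flag = collapse_to_unit(frag, lm)
        assert not flag and collapsed == frag

    def test_length_invariant_under_collapse(self, lm):
        rng = np.random.default_rng(5)
        starts = rng.integers(lm.repeat_unit.start, lm.repeat_unit.end + 2 * lm.unit_length, 500)
        lengths = rng.integers(50, 250, 500)
        frags = Fragments(np.full(500, lm.chrom, dtype=object), starts, starts + lengths)
        collapsed, _ = collapse_fragments(frags, lm)
        np.testing.assert_array_equal(collapsed.lengths, frags.lengths)

    def test_tiled_copies_collapse_onto_source_distribution(self, lm):
        """Fragments copied across 3 concatenated units collapse back onto
        the single-unit source histogram exactly."""
        rng = np.random.default_rng(11)
        n = 10_000
        src_starts = rng.integers(lm.repeat_unit.start, lm.repeat_unit.end - 200, n)
        lengths = rng.integers(50, 200, n)
        unit_offsets = rng.integers(0, 3, n) * lm.unit_length
        tiled = Fragments(
            np.full(n, lm.chrom, dtype=object),
            src_starts + unit_offsets,
            src_starts + unit_offsets + lengths,
        )
        collapsed, flags = collapse_fragments(tiled, lm)
        assert flags.all()
        edges = np.arange(lm.repeat_unit.start, lm.repeat_unit.end + 50, 50)
        hist_src, _ = np.histogram(src_starts, bins=edges)
        hist_col, _ = np.histogram(collapsed.starts, bins=edges)
        np.testing.assert_array_equal(hist_col, hist_src)
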