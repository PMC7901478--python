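"""GFF3 parsing and unique-region index construction."""

import numpy as np
import pytest

from proquant.annotation import FeatureRecord, build_unique_index, parse_features
from proquant.errors import AnnotationError


def feat(fid, strand, *intervals, contig="chr1"):
    return FeatureRecord(
        feature_id=fid, contig=contig, strand=strand,
        intervals=tuple(intervals), feature_type="gene",
    )


class TestParseFeatures:
    def test_coordinates_convert_to_half_open(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text("chr1\t.\tgene\t101\t200\t.\t+\t.\tID=gA\n")
        (rec,) = parse_features(path)
        assert (rec.feature_id, rec.contig, rec.strand) == ("gA", "chr1", "+")
        assert rec.intervals == ((100, 200),)

    def test_rows_sharing_an_id_merge_into_one_feature(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(
            "chr1\t.\tCDS\t1\t50\t.\t+\t.\tID=gB\n"
            "chr1\t.\tCDS\t61\t90\t.\t+\t.\tID=gB\n"
        )
        (rec,) = parse_features(path, feature_type="CDS")
        assert rec.intervals == ((0, 50), (60, 90))

    def test_missing_attribute_names_the_row(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text("chr1\t.\tgene\t1\t50\t.\t+\t.\tName=gC\n")
        with pytest.raises(AnnotationError, match="line 1"):
            parse_features(path)

    def test_duplicate_id_on_different_strand_is_ambiguous(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(
            "chr1\t.\tgene\t1\t50\t.\t+\t.\tID=gD\n"
            "chr1\t.\tgene\t100\t150\t.\t-\t.\tID=gD\n"
        )
        with pytest.raises(AnnotationError, match="gD"):
            parse_features(path)

    def test_malformed_row_names_the_line(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text("chr1\t.\tgene\t1\t50\n")
        with pytest.raises(AnnotationError, match="line 1"):
            parse_features(path)

    def test_comments_and_fasta_trailer_ignored(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t1\t50\t.\t+\t.\tID=gA\n"
            "##FASTA\n"
            ">chr1\nACGT\n"
        )
        assert [r.feature_id for r in parse_features(path)] == ["gA"]

    def test_other_feature_types_skipped(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(
            "chr1\t.\tmRNA\t1\t50\t.\t+\t.\tID=t1\n"
            "chr1\t.\tgene\t1\t50\t.\t+\t.\tID=gA\n"
        )
        assert [r.feature_id for r in parse_features(path)] == ["gA"]


def brute_force_unique(features, strand_aware):
    """Per-position oracle: a base belongs to a feature iff it alone covers it."""
    lanes = {}
    for f in features:
        lane = (f.contig, f.strand if strand_aware else ".")
        lane_map = lanes.setdefault(lane, {})
        covered = set()
        for s, e in f.intervals:
            covered.update(range(s, e))
        for pos in covered:
            lane_map[pos] = None if pos in lane_map else f.feature_id
    lengths = {f.feature_id: 0 for f in features}
    sets = {f.feature_id: set() for f in features}
    for lane_map in lanes.values():
        for pos, fid in lane_map.items():
            if fid is not None:
                lengths[fid] += 1
                sets[fid].add(pos)
    return sets, lengths


class TestUniqueIndex:
    def test_disjoint_features_keep_full_lengths(self):
        idx = build_unique_index([feat("gA", "+", (0, 100)), feat("gB", "+", (200, 300))], False)
        assert idx.unique_intervals["gA"] == [(0, 100)]
        assert idx.unique_intervals["gB"] == [(200, 300)]
        assert idx.unique_length == {"gA": 100, "gB": 100}

    def test_shared_region_belongs_to_neither(self):
        idx = build_unique_index([feat("gA", "+", (0, 100)), feat("gB", "+", (50, 150))], False)
        assert idx.unique_intervals["gA"] == [(0, 50)]
        assert idx.unique_intervals["gB"] == [(100, 150)]
        assert idx.unique_length == {"gA": 50, "gB": 50}

    @pytest.mark.parametrize(
        "strand_aware,expected", [(True, {"gA": 100, "gB": 100}), (False, {"gA": 50, "gB": 50})]
    )
    def test_opposite_strands_interact_only_when_agnostic(self, strand_aware, expected):
        feats = [feat("gA", "+", (0, 100)), feat("gB", "-", (50, 150))]
        assert build_unique_index(feats, strand_aware).unique_length == expected
        _, oracle_len = brute_force_unique(feats, strand_aware)
        assert oracle_len == expected

    def test_fully_shadowed_feature_gets_zero_length(self):
        idx = build_unique_index([feat("gA", "+", (0, 300)), feat("gB", "+", (100, 200))], False)
        assert idx.unique_length["gB"] == 0
        assert idx.unique_intervals["gA"] == [(0, 100), (200, 300)]

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("strand_aware", [True, False])
    def test_matches_per_position_oracle_on_random_annotations(self, seed, strand_aware):
        rng = np.random.default_rng(seed)
        feats = []
        for i in range(int(rng.integers(1, 31))):
            n_iv = int(rng.integers(1, 4))
            ivs = []
            for _ in range(n_iv):
                s = int(rng.integers(0, 4800))
                ivs.append((s, s + int(rng.integers(1, 200))))
            # merge a feature's own intervals so self-overlap cannot shadow it
            merged = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            strand = "+" if rng.random() < 0.6 else "-"
            feats.append(feat(f"f{i}", strand, *merged))
        idx = build_unique_index(feats, strand_aware)
        oracle_sets, oracle_len = brute_force_unique(feats, strand_aware)
        assert idx.unique_length == oracle_len
        for f in feats:
            got = set()
            for s, e in idx.unique_intervals[f.feature_id]:
                got.update(range(s, e))
            assert got == oracle_sets[f.feature_id]

    def test_unique_plus_ambiguous_positions_cover_everything(self):
        rng = np.random.default_rng(42)
        feats = []
        for i in range(25):
            s = int(rng.integers(0, 3000))
            feats.append(feat(f"f{i}", "+", (s, s + int(rng.integers(10, 400)))))
        idx = build_unique_index(feats, False)
        coverage = {}
        for f in feats:
            for pos in range(f.start, f.end):
                coverage[pos] = coverage.get(pos, 0) + 1
        covered_once = sum(1 for c in coverage.values() if c == 1)
        assert sum(idx.unique_length.values()) == covered_once

    def test_input_order_does_not_matter(self):
        rng = np.random.default_rng(7)
        feats = [feat(f"f{i}", "+", (int(s), int(s) + 150))
                 for i, s in enumerate(rng.integers(0, 2000, size=15))]
        a = build_unique_index(feats, False)
        b = build_unique_index(list(reversed(feats)), False)
        assert a.unique_intervals == b.unique_intervals
        assert a.unique_length == b.unique_length

    def test_unique_intervals_stay_inside_feature_span(self):
        feats = [feat("gA", "+", (10, 200)), feat("gB", "+", (150, 400))]
        idx = build_unique_index(feats, False)
        for f in feats:
            for s, e in idx.unique_intervals[f.feature_id]:
                assert f.start <= s < e <= f.end


from hypothesis import given, settings, strategies as st

interval_lists = st.lists(
    st.tuples(st.integers(0, 2000), st.integers(1, 300)).map(lambda t: (t[0], t[0] + t[1])),
    min_size=1, max_size=25,
)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(interval_lists)
def test_unique_length_accounting_holds_for_arbitrary_layouts(intervals):
    """Unique bases plus multiply-covered bases equal all covered bases."""
    feats = [feat(f"f{i}", "+", iv) for i, iv in enumerate(intervals)]
    idx = build_unique_index(feats, False)
    coverage = {}
    for s, e in intervals:
        for pos in range(s, e):
            coverage[pos] = coverage.get(pos, 0) + 1
    covered_once = sum(1 for c in coverage.values() if c == 1)
    multi = sum(1 for c in coverage.values() if c >= 2)
    assert sum(idx.unique_length.values()) == covered_once
    assert covered_once + multi == len(coverage)
    for f in feats:
        assert 0 <= idx.unique_length[f.feature_id] <= f.end - f.start
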