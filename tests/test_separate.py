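import numpy as np
import pandas as pd
import pytest

from xenofrag.genome import InvalidSpecError
from xenofrag.separate import (
    Blacklist,
    build_blacklist,
    downsample,
    filter_alignments,
    fragments_to_read_pairs,
    infer_fragments,
    merge_human_calls,
    merge_intervals,
    pool_replicates,
)
from conftest import toy_fragments


def regions(*ivals, chrom="c1"):
    return pd.DataFrame([(chrom, s, e) for s, e in ivals], columns=["chrom", "start", "end"])


def brute_force_blacklist(control_regions, genome_len=100_000, chrom="c1"):
    """Independent per-base oracle for the support rule."""
    keys = list(control_regions)
    cover = {k: np.zeros(genome_len, dtype=bool) for k in keys}
    for k, df in control_regions.items():
        for _, r in df.iterrows():
            cover[k][r["start"] : r["end"]] = True
    samples = sorted({k[0] for k in keys})
    methods = sorted({k[1] for k in keys})
    n_samp = np.zeros(genome_len, dtype=int)
    for s in samples:
        any_cov = np.zeros(genome_len, dtype=bool)
        for k in keys:
            if k[0] == s:
                any_cov |= cover[k]
        n_samp += any_cov
    n_meth = np.zeros(genome_len, dtype=int)
    for m in methods:
        any_cov = np.zeros(genome_len, dtype=bool)
        for k in keys:
            if k[1] == m:
                any_cov |= cover[k]
        n_meth += any_cov
    mask = (n_samp >= 2) | (n_meth >= 2)
    # mask -> interval list
    diff = np.diff(mask.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


class TestBlacklist:
    def test_two_samples_one_method_blacklisted(self):
        bl = build_blacklist(
            {("s1", "A"): regions((100, 200)), ("s2", "A"): regions((150, 250))}
        )
        assert bl.intervals["c1"].tolist() == [[150, 200]]

    def test_one_sample_two_methods_blacklisted(self):
        bl = build_blacklist(
            {("s1", "A"): regions((100, 200)), ("s1", "B"): regions((100, 200))}
        )
        assert bl.intervals["c1"].tolist() == [[100, 200]]

    def test_single_support_not_blacklisted(self):
        bl = build_blacklist(
            {("s1", "A"): regions((100, 200)), ("s2", "A"): regions((300, 400))}
        )
        assert "c1" not in bl.intervals or len(bl.intervals["c1"]) == 0

    def test_matches_per_base_brute_force_on_random_toys(self):
        rng = np.random.default_rng(11)
        for rep in range(8):
            ctrl = {}
            for s in ("s1", "s2", "s3"):
                for m in ("A", "B"):
                    n = rng.integers(3, 15)
                    starts = rng.integers(0, 9_500, size=n)
                    lens = rng.integers(50, 500, size=n)
                    ctrl[(s, m)] = regions(*zip(starts.tolist(), (starts + lens).tolist()))
            bl = build_blacklist(ctrl)
            got = bl.intervals.get("c1", np.empty((0, 2))).tolist()
            expected = [list(t) for t in brute_force_blacklist(ctrl, genome_len=10_000)]
            assert got == expected

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(InvalidSpecError, match="chrZ"):
            build_blacklist(
                {("s1", "A"): regions((0, 10), chrom="chrZ")}, known_chroms=["c1"]
            )

    def test_provenance_records_supporting_pairs(self):
        bl = build_blacklist(
            {("s1", "A"): regions((100, 200)), ("s2", "A"): regions((150, 250))}
        )
        assert bl.provenance["c1"][0] == {("s1", "A"), ("s2", "A")}


class TestMergeHumanCalls:
    def verdicts(self, rows):
        return pd.DataFrame(rows, columns=["read_id", "method", "call"])

    def test_either_method_retains(self):
        ids = merge_human_calls(
            self.verdicts([(1, "A", "human"), (1, "B", "mouse"), (2, "A", "mouse")])
        )
        assert ids.tolist() == [1]

    def test_union_is_idempotent(self):
        ids = merge_human_calls(self.verdicts([(1, "A", "human"), (1, "B", "human")]))
        assert ids.tolist() == [1]

    def test_neither_absent(self):
        ids = merge_human_calls(self.verdicts([(1, "A", "neither"), (1, "B", "mouse")]))
        assert ids.size == 0

    def test_conflicting_duplicates_rejected(self):
        with pytest.raises(InvalidSpecError):
            merge_human_calls(self.verdicts([(1, "A", "human"), (1, "A", "mouse")]))


class TestFilters:
    def reads(self, rows):
        return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "mapq"])

    def test_mapq_threshold_is_inclusive(self):
        reads = self.reads([(1, "c1", 0, 100, 29), (2, "c1", 0, 100, 30)])
        kept = filter_alignments(reads, None, min_mapq=30)
        assert kept["read_id"].tolist() == [2]

    def test_single_base_overlap_removed(self):
        bl = Blacklist(intervals={"c1": np.array([[100, 200]])}, provenance={"c1": [set()]})
        reads = self.reads(
            [(1, "c1", 50, 101, 60), (2, "c1", 199, 300, 60), (3, "c1", 200, 300, 60)]
        )
        kept = filter_alignments(reads, bl)
        assert kept["read_id"].tolist() == [3]

    def test_empty_blacklist_leaves_only_mapq_rule(self):
        reads = self.reads([(1, "c1", 0, 100, 60), (2, "c1", 0, 100, 10)])
        kept = filter_alignments(reads, Blacklist())
        assert kept["read_id"].tolist() == [1]

    def test_enlarging_blacklist_never_grows_retained_set(self):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 10_000, 300)
        reads = self.reads(
            [(i, "c1", int(s), int(s + 150), 60) for i, s in enumerate(starts)]
        )
        small = Blacklist(intervals={"c1": np.array([[2000, 2500]])}, provenance={"c1": [set()]})
        big = Blacklist(
            intervals={"c1": np.array([[2000, 2500], [7000, 8000]])},
            provenance={"c1": [set(), set()]},
        )
        kept_small = set(filter_alignments(reads, small)["read_id"])
        kept_big = set(filter_alignments(reads, big)["read_id"])
        assert kept_big <= kept_small


class TestInferFragments:
    def pairs(self, rows):
        return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "mapq"])

    def test_outer_span_of_pair(self):
        frags = infer_fragments(
            self.pairs([(1, "c1", 1000, 1075, 60), (1, "c1", 1092, 1167, 60)])
        )
        assert frags.iloc[0][["start", "end", "length"]].tolist() == [1000, 1167, 167]

    def test_length_bounds_inclusive(self):
        rows = []
        for rid, span in [(1, 49), (2, 50), (3, 1000), (4, 1001)]:
            rows += [(rid, "c1", 0, 30, 60), (rid, "c1", span - 30, span, 60)]
        frags = infer_fragments(self.pairs(rows))
        assert sorted(frags["read_id"]) == [2, 3]
        assert frags.attrs["n_length_dropped"] == 2

    def test_discordant_and_orphans_skipped(self):
        frags = infer_fragments(
            self.pairs(
                [
                    (1, "c1", 0, 75, 60),
                    (1, "c2", 100, 175, 60),  # discordant pair
                    (2, "c1", 0, 75, 60),  # orphan
                    (3, "c1", 0, 75, 60),
                    (3, "c1", 92, 167, 60),
                ]
            )
        )
        assert frags["read_id"].tolist() == [3]
        assert frags.attrs["n_orphans"] == 1
        assert frags.attrs["n_discordant"] == 1

    def test_round_trip_through_read_pairs(self):
        frags = toy_fragments([167, 143, 60], start=5000)
        pairs = fragments_to_read_pairs(frags, read_len=75)
        back = infer_fragments(pairs)
        assert back["length"].tolist() == [167, 143, 60]
        assert back["start"].tolist() == [5000, 5000, 5000]


class TestPoolingAndDownsampling:
    def test_pooling_is_additive(self):
        a = toy_fragments([100] * 7)
        b = toy_fragments([150] * 5)
        pooled = pool_replicates({"s1": a, "s2": b, "s3": a}, {"s1": "g", "s2": "g", "s3": "h"})
        assert len(pooled["g"]) == 12
        assert len(pooled["h"]) == 7

    def test_default_cohort_pools_to_four_groups(self, small_cohort):
        cdx = small_cohort.cdx_sheet
        groups = {
            r["sample"]: f"{r['cell_line']}|{r['site']}" for _, r in cdx.iterrows()
        }
        tables = {name: small_cohort.samples[name].frags for name in groups}
        pooled = pool_replicates(tables, groups)
        assert len(pooled) == 4
        assert sum(len(v) for v in pooled.values()) == sum(len(v) for v in tables.values())

    def test_unmapped_sample_rejected(self):
        with pytest.raises(InvalidSpecError):
            pool_replicates({"s1": toy_fragments([100])}, {})

    def test_downsample_exact_and_reproducible(self):
        frags = toy_fragments(np.arange(50, 1050))
        sub1 = downsample(frags, 100, seed=3)
        sub2 = downsample(frags, 100, seed=3)
        assert len(sub1) == 100
        assert sub1["read_id"].is_unique
        pd.testing.assert_frame_equal(sub1, sub2)

    def test_downsample_overshoot_warns_and_returns_all(self):
        frags = toy_fragments([100] * 10)
        with pytest.warns(UserWarning, match="exceeds available"):
            out = downsample(frags, 10_000, seed=1)
        assert len(out) == 10


def test_merge_intervals_merges_touching_and_overlapping():
    out = merge_intervals(np.array([[10, 20], [15, 30], [30, 40], [50, 60]]))
    assert out.tolist() == [[10, 40], [50, 60]]
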