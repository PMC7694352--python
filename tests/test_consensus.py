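import numpy as np
import pytest

from cnvpop.callsets import CnvCall, RdCnvr
from cnvpop.consensus import (
    Cnvr,
    build_cnvrs,
    classify_cnvr,
    intersect_callsets,
    summarize,
    unify_with_read_depth,
)
from cnvpop.intervals import GenomicInterval, overlap_fraction, overlap_length

from conftest import random_intervals


def call(start, end, svtype="DEL", caller="delly", sample="S1", chrom="chr1"):
    kwargs = {"vaf": 0.5, "support_reads": 10} if caller == "pindel" else {}
    return CnvCall(sample, GenomicInterval(chrom, start, end), svtype, caller,
                   "PASS", **kwargs)


class TestIntersectCallsets:
    def test_boundary_of_reciprocal_rule(self):
        # overlap 500 = 50% of the smaller call: exactly at threshold, kept
        out = intersect_callsets([call(1000, 2000)], [call(1500, 2600, caller="pindel")])
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (1500, 2000)

    def test_below_threshold_dropped(self):
        out = intersect_callsets([call(1000, 2000)], [call(1501, 2600, caller="pindel")])
        assert out == []

    def test_svtype_mismatch(self):
        out = intersect_callsets([call(1000, 2000, "DEL")],
                                 [call(1000, 2000, "DUP", caller="pindel")])
        assert out == []

    def test_multiple_samples_rejected(self):
        with pytest.raises(ValueError):
            intersect_callsets([call(0, 100, sample="S1")],
                               [call(0, 100, caller="pindel", sample="S2")])

    def test_consensus_contained_in_both_sources(self, rng):
        delly = [call(int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 5000, 30), rng.integers(60, 400, 30))]
        pindel = [call(int(s), int(s) + int(l), caller="pindel")
                  for s, l in zip(rng.integers(0, 5000, 30), rng.integers(60, 400, 30))]
        for cc in intersect_callsets(delly, pindel):
            d, p = cc.source_pair
            assert overlap_length(cc.interval, d.interval) == cc.interval.length
            assert overlap_length(cc.interval, p.interval) == cc.interval.length

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_greedy_matching_oracle(self, seed):
        rng = np.random.default_rng(seed)
        truth = random_intervals(rng, 25, n_chroms=2, span=20_000, max_len=400)
        delly, pindel = [], []
        for iv in truth:  # jittered pair per true event
            for lst, caller in ((delly, "delly"), (pindel, "pindel")):
                s = iv.start + int(rng.normal(0, 30))
                e = iv.end + int(rng.normal(0, 30))
                if e > s:
                    lst.append(call(max(0, s), e, caller=caller, chrom=iv.chrom))
        got = intersect_callsets(delly, pindel)
        exp = oracle_matching(delly, pindel)
        assert [(c.interval, c.svtype) for c in got] == exp

    def test_each_call_used_at_most_once(self):
        # one delly call overlapping two pindel partners joins only the best
        d = [call(1000, 2000)]
        p = [call(900, 1900, caller="pindel"), call(1200, 2100, caller="pindel")]
        out = intersect_callsets(d, p)
        assert len(out) == 1
        assert out[0].source_pair[1].interval.start == 900  # larger overlap


def oracle_matching(delly, pindel, min_frac=0.5):
    """Repeated global-best selection over all remaining pairs."""
    pairs = []
    for i, d in enumerate(delly):
        for j, p in enumerate(pindel):
            if d.svtype != p.svtype or d.interval.chrom != p.interval.chrom:
                continue
            ov = overlap_length(d.interval, p.interval)
            if ov > 0 and overlap_fraction(d.interval, p.interval, "smaller") >= min_frac:
                pairs.append((ov, d.interval, p.interval, i, j))
    taken_d, taken_p, chosen = set(), set(), []
    while True:
        avail = [t for t in pairs if t[3] not in taken_d and t[4] not in taken_p]
        if not avail:
            break
        best = min(avail, key=lambda t: (-t[0], t[1], t[2]))
        taken_d.add(best[3])
        taken_p.add(best[4])
        iv = GenomicInterval(best[1].chrom, max(best[1].start, best[2].start),
                             min(best[1].end, best[2].end))
        chosen.append((iv, delly[best[3]].svtype))
    chosen.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    return chosen


def consensus_of(start, end, sample="S1", svtype="DEL", chrom="chr1"):
    d = call(start, end, svtype, "delly", sample, chrom)
    p = call(start, end, svtype, "pindel", sample, chrom)
    out = intersect_callsets([d], [p])
    assert len(out) == 1
    return out[0]


POPS = {"S1": "P1", "S2": "P2", "S3": "P1", "S4": "P2"}


class TestBuildCnvrs:
    def test_merge_and_singleton_removal(self):
        cons = [
            consensus_of(100, 200, "S1"),
            consensus_of(150, 260, "S2"),
            consensus_of(400, 500, "S3"),
        ]
        cnvrs = build_cnvrs(cons, POPS, level="meta")
        assert len(cnvrs) == 1
        assert (cnvrs[0].interval.start, cnvrs[0].interval.end) == (100, 260)
        assert cnvrs[0].n_members == 2

    def test_population_level_splits_singletons(self):
        # same region, but the two carriers sit in different populations
        cons = [consensus_of(100, 200, "S1"), consensus_of(150, 260, "S2")]
        assert build_cnvrs(cons, POPS, level="population") == []
        assert len(build_cnvrs(cons, POPS, level="meta")) == 1

    def test_unmapped_sample_is_error(self):
        with pytest.raises(ValueError, match="SX"):
            build_cnvrs([consensus_of(0, 100, "SX")], POPS)

    def test_mixed_types_make_complex(self):
        cons = [consensus_of(100, 300, "S1", "DEL"), consensus_of(200, 400, "S2", "DUP")]
        (cnvr,) = build_cnvrs(cons, POPS, level="meta")
        assert cnvr.cnvr_class == "complex"

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_cluster_and_filter_oracle(self, seed):
        rng = np.random.default_rng(seed)
        samples = ["S1", "S2", "S3", "S4"]
        cons = []
        for _ in range(40):
            s = int(rng.integers(0, 5000))
            length = int(rng.integers(60, 600))
            cons.append(consensus_of(s, s + length, samples[rng.integers(4)]))
        got = build_cnvrs(cons, POPS, level="meta")
        # oracle: all-pairs clustering of member intervals, then size filter
        parent = list(range(len(cons)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(cons)):
            for j in range(i + 1, len(cons)):
                if overlap_length(cons[i].interval, cons[j].interval) >= 1:
                    parent[find(j)] = find(i)
        groups = {}
        for i in range(len(cons)):
            groups.setdefault(find(i), []).append(cons[i])
        exp = sorted(
            (min(c.interval.start for c in g), max(c.interval.end for c in g), len(g))
            for g in groups.values() if len(g) >= 2
        )
        assert [(r.interval.start, r.interval.end, r.n_members) for r in got] == exp


class TestClassify:
    @pytest.mark.parametrize(
        "types, expected",
        [
            (["DEL", "DEL", "DEL"], "deletion"),
            (["DUP"], "duplication"),
            (["DEL", "DUP"], "complex"),
        ],
    )
    def test_examples(self, types, expected):
        assert classify_cnvr(types) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_cnvr([])


def make_cnvr(start, end, chrom="chr1"):
    return Cnvr(GenomicInterval(chrom, start, end),
                members=(consensus_of(start, end), consensus_of(start, end, "S2")),
                approaches=frozenset({"pairedend_splitread"}),
                cnvr_class="deletion", level="meta")


class TestUnifyWithReadDepth:
    def test_qualifying_partner_extends_envelope(self):
        out = unify_with_read_depth([make_cnvr(100, 260)],
                                    [RdCnvr(GenomicInterval("chr1", 120, 250))])
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (100, 260)
        assert out[0].approaches == {"pairedend_splitread", "read_depth"}

    def test_below_half_of_shortest_drops_both(self):
        out = unify_with_read_depth([make_cnvr(100, 260)],
                                    [RdCnvr(GenomicInterval("chr1", 200, 400))])
        assert out == []

    def test_rd_extending_past_cnvr_grows_union_envelope(self):
        out = unify_with_read_depth([make_cnvr(100, 260)],
                                    [RdCnvr(GenomicInterval("chr1", 150, 320))])
        assert (out[0].interval.start, out[0].interval.end) == (100, 320)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cnvrs = [make_cnvr(int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 8000, 20), rng.integers(60, 500, 20))]
        rd = [RdCnvr(iv) for iv in random_intervals(rng, 20, n_chroms=1, span=8000)]
        got = unify_with_read_depth(cnvrs, rd)
        exp = []
        for r in cnvrs:
            partners = [x.interval for x in rd
                        if overlap_length(r.interval, x.interval) > 0
                        and overlap_fraction(r.interval, x.interval, "shortest") >= 0.5]
            if partners:
                exp.append((min([r.interval.start] + [p.start for p in partners]),
                            max([r.interval.end] + [p.end for p in partners])))
        exp.sort()
        assert sorted((r.interval.start, r.interval.end) for r in got) == exp

    def test_all_outputs_have_both_approaches(self, rng):
        cnvrs = [make_cnvr(i * 300, i * 300 + 200) for i in range(10)]
        rd = [RdCnvr(GenomicInterval("chr1", i * 300 + 20, i * 300 + 180))
              for i in range(0, 10, 2)]
        for r in unify_with_read_depth(cnvrs, rd):
            assert r.approaches == {"pairedend_splitread", "read_depth"}


class TestSummarize:
    def test_printed_coverage_arithmetic(self):
        # 266.71 Mb of CNVRs on a 2.47 Gb genome -> 10.80% at 2 d.p.
        cnvr = make_cnvr(0, 266_710_000)
        s = summarize([cnvr], 2_470_000_000)
        assert round(s.coverage_percent, 2) == 10.80

    def test_whole_genome_is_100_percent(self):
        s = summarize([make_cnvr(0, 10_000)], 10_000)
        assert s.coverage_percent == 100.0

    def test_union_not_double_counted(self, rng):
        cnvrs = [make_cnvr(0, 1000), make_cnvr(500, 1500)]
        s = summarize(cnvrs, 10_000)
        assert s.union_span_bp == 1500
        assert s.total_length_bp == 2000

    def test_class_counts_partition_total(self):
        cnvrs = [make_cnvr(i * 2000, i * 2000 + 100) for i in range(5)]
        s = summarize(cnvrs, 100_000)
        assert sum(s.counts_by_class.values()) == s.n_total == 5

    def test_per_sample_stats_for_raw_calls(self):
        calls = [call(0, 100, sample="S1"), call(500, 800, sample="S1"),
                 call(0, 100, sample="S2")]
        s = summarize(calls, 10_000)
        assert s.counts_by_sample == {"S1": 2, "S2": 1}
        assert s.span_by_sample == {"S1": 400, "S2": 100}

    def test_invalid_genome_length(self):
        with pytest.raises(ValueError):
            summarize([], 0)
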