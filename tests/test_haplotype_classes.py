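from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import haplomosaic as hm
from haplomosaic.config import AnalysisConfig
from haplomosaic.haplotype_classes import (
    AllStatusesUnknownError,
    classify_segment,
    segment_summary,
)

bitstrings = st.integers(0, 2**20 - 1).map(lambda v: format(v, "020b"))


class TestHamming:
    def test_identity_and_complement(self):
        s = "01" * 25
        assert hm.hamming(s, s) == 0
        assert hm.hamming("0" * 50, "1" * 50) == 50

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            hm.hamming("01", "011")

    @given(bitstrings, bitstrings)
    @settings(deadline=None)
    def test_matches_positionwise_recount(self, a, b):
        assert hm.hamming(a, b) == sum(x != y for x, y in zip(a, b))


def _reference_grouping(haps, max_diff):
    """Independent re-implementation of the grouping contract."""
    counter = Counter(haps)
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    groups = []  # (representative, members dict)
    for h, c in ordered:
        for rep, members in groups:
            if sum(x != y for x, y in zip(h, rep)) <= max_diff:
                members[h] = c
                break
        else:
            groups.append((h, {h: c}))
    return sorted(
        [(rep, members) for rep, members in groups],
        key=lambda g: (-sum(g[1].values()), g[0]),
    )


class TestGrouping:
    def test_absorption_of_near_identical_strings(self):
        a = "0" * 50
        a1 = "1" + "0" * 49
        b = "1" * 50
        haps = [a] * 300 + [a1] * 5 + [b] * 120
        chset = hm.group_haplotypes(haps)
        assert [g.count for g in chset.groups] == [305, 120]
        assert chset.groups[0].representative == a
        assert chset.groups[0].members == {a: 300, a1: 5}

    def test_equidistant_string_joins_more_frequent_group(self):
        a = "0" * 50
        b = "0" * 46 + "1111"  # Hamming(a, b) = 4: distinct groups
        mid = "0" * 48 + "11"  # distance 2 from both
        haps = [a] * 200 + [b] * 100 + [mid] * 3
        chset = hm.group_haplotypes(haps)
        assert chset.groups[0].count == 203
        assert mid in chset.groups[0].members

    def test_empty_input_gives_empty_chset(self):
        chset = hm.group_haplotypes([])
        assert len(chset) == 0

    def test_continent_counts_follow_labels(self):
        haps = ["0" * 10, "0" * 10, "1" * 10, "0" * 10]
        conts = ["AFR", "AFR", "EUR", "ASN"]
        chset = hm.group_haplotypes(haps, continents=conts)
        top = chset.groups[0]
        assert top.continent_counts == {"AFR": 2, "ASN": 1}
        assert chset.groups[1].continent_counts == {"EUR": 1}

    @given(st.lists(st.integers(0, 2**10 - 1).map(lambda v: format(v, "010b")),
                    min_size=0, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_matches_reference_partition_and_conserves_counts(self, haps):
        chset = hm.group_haplotypes(haps, max_intra_diff=2)
        assert sum(g.count for g in chset.groups) == len(haps)
        ref = _reference_grouping(haps, 2)
        assert [(g.representative, g.members) for g in chset.groups] == ref


class TestCommonHaplotypes:
    def test_absolute_count_threshold(self):
        haps = ["0" * 50] * 305 + ["1" * 50] * 120 + [("01" * 25)] * 80
        chset = hm.group_haplotypes(haps)
        chs = hm.common_haplotypes(chset, min_count=100)
        assert [g.count for g in chs] == [305, 120]

    def test_frequency_threshold_equivalent_to_count(self):
        rng = np.random.default_rng(0)
        pool = ["0" * 50, "1" * 50, "01" * 25, "10" * 25]
        haps = [pool[i] for i in rng.integers(0, 4, 2184)]
        chset = hm.group_haplotypes(haps)
        by_freq = hm.common_haplotypes(chset, min_freq=0.05)
        by_count = hm.common_haplotypes(chset, min_count=110)  # 0.05 * 2184
        assert [g.representative for g in by_freq] == [
            g.representative for g in by_count
        ]

    def test_both_or_neither_threshold_is_error(self):
        chset = hm.group_haplotypes(["01"])
        with pytest.raises(ValueError):
            hm.common_haplotypes(chset, min_count=100, min_freq=0.05)
        with pytest.raises(ValueError):
            hm.common_haplotypes(chset)

    def test_empty_chset_gives_empty(self):
        assert hm.common_haplotypes(hm.group_haplotypes([]), min_count=1) == []


def _group(rep, count):
    g = hm.HaplotypeGroup(representative=rep)
    g.members[rep] = count
    return g


class TestYinYang:
    def test_single_complementary_pair(self):
        a = _group("0" * 50, 800)
        ab = _group("1" * 50, 400)
        pairs = hm.find_yinyang([a, ab])
        assert len(pairs) == 1
        assert pairs[0].yin is a and pairs[0].yang is ab
        assert pairs[0].n_diff == 50

    def test_greedy_trace_leaves_third_ch_unpaired(self):
        A = "0" * 50
        Abar = "1" * 50
        B = "0" * 46 + "1111"  # Hamming(A, B) = 4; Hamming(B, Abar) = 46
        chs = [_group(A, 800), _group(B, 700), _group(Abar, 400)]
        pairs = hm.find_yinyang(chs, min_diff=46)
        # A pairs with its complement first (highest-rank scan), not with B
        assert len(pairs) == 1
        assert pairs[0].yin.representative == A
        assert pairs[0].yang.representative == Abar

    def test_two_pairs_in_one_segment(self):
        A = "0" * 50
        B = "0" * 3 + "1" * 47
        chs = [
            _group(A, 800),
            _group("1" * 50, 700),
            _group(B, 600),
            _group("1" * 3 + "0" * 47, 500),
        ]
        pairs = hm.find_yinyang(chs, min_diff=47)
        assert len(pairs) == 2
        # segment-level Yin/Yang CH count matches the even counts convention
        assert 2 * len(pairs) == 4

    def test_raising_min_diff_never_creates_pairs(self):
        rng = np.random.default_rng(5)
        chs = [
            _group("".join(map(str, rng.integers(0, 2, 50))), int(c))
            for c in rng.integers(100, 900, 8)
        ]
        chs.append(_group("".join("1" if ch == "0" else "0"
                                  for ch in chs[0].representative), 150))
        n47 = len(hm.find_yinyang(chs, min_diff=47))
        n50 = len(hm.find_yinyang(chs, min_diff=50))
        assert n50 <= n47


class TestDerivedFraction:
    def test_all_ancestral_is_zero(self):
        assert hm.derived_fraction("0" * 10, ["R"] * 10) == 0.0

    def test_all_derived_is_one(self):
        assert hm.derived_fraction("1" * 10, ["R"] * 10) == 1.0

    def test_hand_counted_fixture(self):
        # 12 derived among 50 known positions -> 0.24
        h = "1" * 12 + "0" * 38 + "1" * 5
        statuses = ["R"] * 50 + ["X"] * 5
        assert hm.derived_fraction(h, statuses) == pytest.approx(0.24)

    def test_m_status_inverts_polarity(self):
        assert hm.derived_fraction("00", ["M", "M"]) == 1.0

    def test_all_unknown_raises_distinct_error(self):
        with pytest.raises(AllStatusesUnknownError):
            hm.derived_fraction("01", ["X", "X"])


class TestMosaicSourceSplit:
    def test_mosaic_equal_to_yin_credits_yin_only(self):
        yin = "1" * 20 + "0" * 30
        yang = "".join("1" if c == "0" else "0" for c in yin)
        statuses = ["R"] * 50
        n_yin, n_yang, n_other = hm.mosaic_source_split(yin, yin, yang, statuses)
        assert (n_yin, n_yang, n_other) == (20, 0, 0)

    def test_positions_where_pair_agrees_go_to_other(self):
        yin = "110"
        yang = "011"  # agree at position 1
        mosaic = "010"
        statuses = ["R", "R", "R"]
        assert hm.mosaic_source_split(mosaic, yin, yang, statuses) == (0, 0, 1)

    def test_planted_ten_two_split(self, default_synth):
        truth = next(t for t in default_synth.truths if t.mosaic)
        split = hm.mosaic_source_split(
            truth.mosaic, truth.yin, truth.yang, truth.statuses
        )
        assert split == (10, 2, 0)


class TestExpectedSplitNull:
    def test_single_allele_closed_form(self):
        # one derived allele is one-sided iff it hits yin or yang
        frac = hm.expected_split_null(1, reps=200_000, seed=1)
        assert frac == pytest.approx(0.546 + 0.438, abs=0.005)

    def test_degenerate_all_yin(self):
        assert hm.expected_split_null(5, p_yin=1.0, p_yang=0.0, reps=100) == 1.0

    def test_invalid_reps_raises(self):
        with pytest.raises(ValueError):
            hm.expected_split_null(5, reps=0)

    @pytest.mark.parametrize("n_derived", [2, 3, 5])
    def test_converges_to_exact_multinomial_tail(self, n_derived):
        from scipy.stats import multinomial

        p = [0.546, 0.438, 1 - 0.546 - 0.438]
        exact = 0.0
        for i in range(n_derived + 1):
            for j in range(n_derived + 1 - i):
                k = n_derived - i - j
                if max(i, j) >= 0.8 * n_derived:
                    exact += multinomial.pmf([i, j, k], n_derived, p)
        est = hm.expected_split_null(n_derived, reps=200_000, seed=2)
        assert est == pytest.approx(exact, abs=0.01)


class TestSegmentSummary:
    def _seg(self):
        return hm.SegmentSpec(
            chrom="1", window_index=0, window_start=0,
            gv_indices=tuple(range(50)), start_pos=1000, end_pos=60_000,
        )

    def test_segment_without_chs_reports_na(self):
        cfg = AnalysisConfig(min_count=100)
        haps = ["01" * 25, "10" * 25]  # two singletons
        cls = classify_segment(haps, ["R"] * 50, cfg)
        row = segment_summary(self._seg(), cls, ["R"] * 50)
        assert row["n_ch"] == 0
        assert row["max_diff"] == "NA"

    def test_planted_yinyang_segment_row(self, default_synth):
        cfg = AnalysisConfig()
        truth = default_synth.truths[0]
        haps = [truth.yin] * 500 + [truth.yang] * 300
        cls = classify_segment(haps, truth.statuses, cfg)
        row = segment_summary(self._seg(), cls, truth.statuses)
        assert row["n_yinyang_ch"] == 2
        assert row["max_diff"] >= 47

    def test_maf_sweep_matches_per_segment_recount(self, default_synth):
        # a Table-2-shaped summary: totals across MAF thresholds must agree
        # with a direct per-segment recount
        cohort = default_synth.cohort
        for maf in (0.15, 0.20, 0.25, 0.30):
            cfg = AnalysisConfig(maf_threshold=maf)
            segs = hm.build_segments(cohort, maf_threshold=maf)
            statuses_all = cohort.statuses
            n_yy = n_2ch = 0
            for seg in segs:
                haps = hm.extract_haplotypes(cohort, seg)
                st_ = [statuses_all[i] for i in seg.gv_indices]
                cls = classify_segment(haps, st_, cfg)
                rows = segment_summary(seg, cls, st_)
                assert rows["n_ch"] == len(cls.chs)
                if len(cls.chs) >= 2:
                    n_2ch += 1
                if cls.pairs:
                    n_yy += 1
            assert n_yy <= n_2ch <= len(segs)
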