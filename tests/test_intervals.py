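"""Interval algebra against brute-force base-set oracles, promoters, profiles."""

import numpy as np
import pandas as pd
import pytest

import metresponse as mr
from metresponse import intervals as iv
from conftest import random_interval_frame


def brute_union_bases(df, genome=2000):
    """Boolean base occupancy per chrom — the merge oracle."""
    out = {}
    for chrom, sub in df.groupby("chrom"):
        mask = np.zeros(genome, dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            mask[s:e] = True
        out[chrom] = mask
    return out


def brute_overlap_flags(a, b, min_overlap=1):
    flags = np.zeros(len(a), dtype=bool)
    for i, (ca, sa, ea) in enumerate(zip(a["chrom"], a["start"], a["end"])):
        for cb, sb, eb in zip(b["chrom"], b["start"], b["end"]):
            if ca == cb and min(ea, eb) - max(sa, sb) >= min_overlap:
                flags[i] = True
                break
    return flags


class TestMerge:
    def test_hand_example_with_bookend(self):
        df = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 50, 150, 300], "end": [100, 150, 200, 400]}
        )
        merged = iv.merge_intervals(df)
        assert merged.to_dict("list") == {
            "chrom": ["chr1", "chr1"], "start": [0, 300], "end": [200, 400]
        }

    def test_disjoint_unchanged(self):
        df = pd.DataFrame({"chrom": "chr1", "start": [0, 200], "end": [100, 300]})
        pd.testing.assert_frame_equal(iv.merge_intervals(df), df)

    def test_matches_base_set_oracle_on_random_instances(self, rng):
        for _ in range(200):
            df = random_interval_frame(rng, int(rng.integers(1, 25)),
                                       chroms=("chr1", "chr2"))
            merged = iv.merge_intervals(df)
            oracle = brute_union_bases(df)
            got = brute_union_bases(merged)
            assert set(oracle) == set(got)
            for chrom in oracle:
                assert (oracle[chrom] == got[chrom]).all()
            # disjoint and non-bookended within chrom
            for _, sub in merged.groupby("chrom"):
                assert (sub["start"].to_numpy()[1:] > sub["end"].to_numpy()[:-1]).all()

    def test_idempotent(self, rng):
        df = random_interval_frame(rng, 30)
        once = iv.merge_intervals(df)
        twice = iv.merge_intervals(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_max_gap_merges_near_intervals(self):
        df = pd.DataFrame({"chrom": "chr1", "start": [0, 110], "end": [100, 200]})
        assert len(iv.merge_intervals(df, max_gap=10)) == 1
        assert len(iv.merge_intervals(df, max_gap=9)) == 2

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            iv.merge_intervals(
                pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [10]})
            )


class TestIntersect:
    def test_one_base_overlap_counts(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [99], "end": [200]})
        flags, pairs = iv.intersect_intervals(a, b)
        assert flags[0] and len(pairs) == 1

    def test_bookended_is_not_overlap(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        flags, pairs = iv.intersect_intervals(a, b)
        assert not flags[0] and len(pairs) == 0

    @pytest.mark.parametrize("min_overlap", [1, 5, 20])
    def test_matches_brute_force_on_random_instances(self, rng, min_overlap):
        for _ in range(100):
            a = random_interval_frame(rng, int(rng.integers(1, 20)),
                                      chroms=("chr1", "chr2"))
            b = random_interval_frame(rng, int(rng.integers(1, 20)),
                                      chroms=("chr1", "chr2"))
            a_s = iv.sort_intervals(a)
            flags, _ = iv.intersect_intervals(a_s, b, min_overlap)
            assert (flags == brute_overlap_flags(a_s, b, min_overlap)).all()

    def test_overlap_symmetric_in_existence(self, rng):
        a = random_interval_frame(rng, 15)
        b = random_interval_frame(rng, 15)
        fa, _ = iv.intersect_intervals(a, b)
        fb, _ = iv.intersect_intervals(b, a)
        assert fa.any() == fb.any()


class TestVennPartition:
    def test_hand_partition(self):
        a = pd.DataFrame({"chrom": "c", "start": [0, 200], "end": [100, 300]})
        b = pd.DataFrame({"chrom": "c", "start": [50, 400], "end": [150, 500]})
        counts, labeled = iv.condition_overlap_partition({"A": a, "B": b})
        assert counts == {"A": 1, "B": 1, "A+B": 1}
        assert len(labeled) == 3

    def test_identical_sets_all_shared(self):
        a = pd.DataFrame({"chrom": "c", "start": [0, 200], "end": [100, 300]})
        counts, _ = iv.condition_overlap_partition({"X": a, "Y": a.copy()})
        assert counts == {"X": 0, "Y": 0, "X+Y": 2}

    def test_each_union_interval_gets_exactly_one_label(self, rng):
        sets = {
            n: random_interval_frame(rng, 12, chroms=("chr1",))
            for n in ("NT", "MET", "METCC")
        }
        counts, labeled = iv.condition_overlap_partition(sets)
        assert sum(counts.values()) == len(labeled)
        assert (labeled["label"] != "").all()

    def test_more_than_three_sets_rejected(self, rng):
        sets = {f"s{i}": random_interval_frame(rng, 3) for i in range(4)}
        with pytest.raises(ValueError):
            iv.condition_overlap_partition(sets)


class TestPromoters:
    def _genes(self):
        return pd.DataFrame(
            {
                "chrom": ["c", "c", "c"],
                "strand": ["+", "-", "+"],
                "tss": [1000, 1000, 100],
                "start": [1000, 500, 100],
                "end": [2000, 1000, 600],
            },
            index=pd.Index(["g_plus", "g_minus", "g_edge"], name="gene_id"),
        )

    def test_strand_aware_windows_and_clipping(self):
        prom = iv.define_promoters(self._genes(), upstream=500, downstream=100)
        by_name = prom.set_index("name")
        assert (by_name.loc["g_plus", "start"], by_name.loc["g_plus", "end"]) == (500, 1100)
        assert (by_name.loc["g_minus", "start"], by_name.loc["g_minus", "end"]) == (900, 1500)
        assert by_name.loc["g_edge", "start"] == 0  # clipped

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            iv.define_promoters(self._genes(), upstream=-1, downstream=100)


class TestMetaprofile:
    def test_constant_coverage_is_flat(self):
        cov = pd.DataFrame(
            {"chrom": ["c"], "start": [0], "end": [10_000], "value": [1.0]}
        )
        genes = pd.DataFrame(
            {"chrom": ["c"], "strand": ["+"], "tss": [5000]}, index=["g"]
        )
        prof = iv.tss_metaprofile(cov, genes, window=500, binsize=50)
        assert np.allclose(prof.mean, 1.0)

    def test_hand_binned_single_tss(self):
        cov = pd.DataFrame(
            {"chrom": ["c", "c", "c"], "start": [0, 990, 1010],
             "end": [990, 1010, 5000], "value": [0.0, 1.0, 0.0]}
        )
        genes = pd.DataFrame(
            {"chrom": ["c"], "strand": ["+"], "tss": [1000]}, index=["g"]
        )
        prof = iv.tss_metaprofile(cov, genes, window=50, binsize=10)
        expected = np.zeros(10)
        expected[4:6] = 1.0  # bins [-10,0) and [0,10)
        assert np.allclose(prof.mean, expected)
        assert prof.offsets[4] == -10 and prof.offsets[5] == 0

    def test_minus_strand_mirrors(self):
        # signal strictly downstream of a + TSS == upstream of a - TSS
        cov_plus = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [1000, 1010], "end": [1010, 5000],
             "value": [1.0, 0.0]}
        )
        cov_minus = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [990, 1000], "end": [1000, 5000],
             "value": [1.0, 0.0]}
        )
        gp = pd.DataFrame({"chrom": ["c"], "strand": ["+"], "tss": [1000]}, index=["g"])
        gm = pd.DataFrame({"chrom": ["c"], "strand": ["-"], "tss": [1000]}, index=["g"])
        p_plus = iv.tss_metaprofile(cov_plus, gp, window=50, binsize=10)
        p_minus = iv.tss_metaprofile(cov_minus, gm, window=50, binsize=10)
        assert np.allclose(p_plus.mean, p_minus.mean)

    def test_truncated_sites_excluded_and_counted(self):
        cov = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10_000],
                            "value": [1.0]})
        genes = pd.DataFrame(
            {"chrom": ["c", "c"], "strand": ["+", "+"], "tss": [100, 5000]},
            index=["near_edge", "ok"],
        )
        prof = iv.tss_metaprofile(cov, genes, window=500, binsize=50)
        assert prof.n_sites == 1 and prof.n_excluded == 1

    def test_window_binsize_mismatch_rejected(self):
        cov = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100],
                            "value": [1.0]})
        genes = pd.DataFrame({"chrom": ["c"], "strand": ["+"], "tss": [50]},
                             index=["g"])
        with pytest.raises(ValueError):
            iv.tss_metaprofile(cov, genes, window=55, binsize=10)


class TestBedIO:
    def test_bed_round_trip_bit_exact(self, rng, tmp_path):
        df = random_interval_frame(rng, 25, chroms=("chr1", "chr2"))
        df["name"] = [f"p{i}" for i in range(len(df))]
        df["score"] = 0
        df["strand"] = rng.choice(["+", "-"], size=len(df))
        df = iv.sort_intervals(df)
        path = tmp_path / "a.bed"
        iv.write_bed(df, path)
        back = iv.read_bed(path)
        pd.testing.assert_frame_equal(
            back[["chrom", "start", "end", "name", "strand"]],
            df[["chrom", "start", "end", "name", "strand"]],
        )
        # write again: byte-identical file
        path2 = tmp_path / "b.bed"
        iv.write_bed(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_parse_error_carries_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t100\nchr1\t50\tXYZ\n")
        with pytest.raises(iv.BedParseError, match="line 2"):
            iv.read_bed(path)

    def test_bedgraph_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [0, 10], "end": [10, 20],
             "value": [1.5, 0.0]}
        )
        path = tmp_path / "cov.bg"
        iv.write_bedgraph(df, path)
        pd.testing.assert_frame_equal(iv.read_bedgraph(path), df)
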