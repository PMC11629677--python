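import numpy as np
import pytest
from scipy import stats

import m6aipa as M
from conftest import build_feature_tables
from m6aipa import GenomicInterval
from m6aipa.cits import M6aSite
from m6aipa.matching import FeatureTable, one_sample_t
from oracles import brute_count_sites


def site(pos, strand="+", chrom="chr1"):
    return M6aSite(chrom, pos, strand, "GGACT", "p")


class TestCountM6a:
    def test_empty_site_list(self):
        assert M.count_m6a(GenomicInterval("chr1", 0, 100, "+"), []) == 0

    def test_opposite_strand_sites_not_counted(self):
        feat = GenomicInterval("chr1", 0, 100, "+")
        sites = [site(10), site(20), site(30), site(40, strand="-")]
        assert M.count_m6a(feat, sites) == 3

    def test_site_at_end_coordinate_excluded(self):
        feat = GenomicInterval("chr1", 0, 100, "+")
        assert M.count_m6a(feat, [site(100)]) == 0
        assert M.count_m6a(feat, [site(99)]) == 1

    def test_vectorized_counting_matches_brute_force(self, rng):
        feats = [
            GenomicInterval("chr1", int(s), int(s) + int(l), "+" if i % 2 else "-")
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 5000, 30), rng.integers(10, 500, 30))
            )
        ]
        sites = [
            site(int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(0, 5500, 300)
        ]
        from m6aipa.matching import count_m6a_many

        counts = count_m6a_many(feats, sites)
        for feat, got in zip(feats, counts):
            expected = brute_count_sites(
                (feat.chrom, feat.start, feat.end, feat.strand),
                [(s.chrom, s.pos, s.strand) for s in sites],
            )
            assert got == expected == M.count_m6a(feat, sites)


def table(ids, lengths, depths, counts):
    intervals = [GenomicInterval("chr1", 0, int(l), "+") for l in lengths]
    return FeatureTable(
        list(ids), intervals, np.asarray(lengths, dtype=float),
        np.asarray(depths, dtype=float), np.asarray(counts),
    )


class TestMatchExons:
    def test_tolerance_arithmetic(self, rng):
        ipas = table(["i1"], [1000], [10.0], [2])
        # 5% off in both dimensions: eligible
        exons = table(["e1"], [1050], [10.5], [1])
        pairs, unmatched = M.match_exons(ipas, exons, rng)
        assert len(pairs) == 1 and unmatched == []
        # 20% length deviation: ineligible
        exons = table(["e1"], [1200], [10.0], [1])
        pairs, unmatched = M.match_exons(ipas, exons, rng)
        assert pairs == [] and unmatched == ["i1"]

    def test_identical_exon_always_eligible(self, rng):
        ipas = table(["i1"], [800], [7.0], [0])
        exons = table(["e1"], [800], [7.0], [3])
        pairs, _ = M.match_exons(ipas, exons, rng)
        assert pairs[0].exon_id == "e1"

    def test_no_exon_reused_within_repetition(self, rng):
        ipas = table([f"i{k}" for k in range(5)], [1000] * 5, [10.0] * 5, [0] * 5)
        exons = table([f"e{k}" for k in range(3)], [1000] * 3, [10.0] * 3, [0] * 3)
        pairs, unmatched = M.match_exons(ipas, exons, rng)
        used = [p.exon_id for p in pairs]
        assert len(used) == len(set(used)) == 3
        assert len(unmatched) == 2

    def test_warning_when_many_unmatched(self, rng):
        ipas = table([f"i{k}" for k in range(10)], [1000] * 10, [10.0] * 10, [0] * 10)
        exons = table(["e0"], [5000], [10.0], [0])
        with pytest.warns(UserWarning, match="no eligible exon"):
            M.match_exons(ipas, exons, rng)


class TestRepeatMatching:
    def test_single_rep_single_pair(self):
        ipas = table(["i1"], [1000], [10.0], [4])
        exons = table(["e1"], [1000], [10.0], [1])
        res = M.repeat_matching(ipas, exons, n_reps=1, seed=0)
        assert len(res.pairs) == 1
        assert res.pairs[0].ipa_m6a_count == 4
        assert res.pairs[0].exon_m6a_count == 1

    def test_same_seed_reproduces_pairs(self):
        rng = np.random.default_rng(2)
        ipas = table([f"i{k}" for k in range(20)],
                     rng.uniform(500, 1500, 20), rng.uniform(5, 15, 20),
                     rng.poisson(3, 20))
        exons = table([f"e{k}" for k in range(100)],
                      rng.uniform(500, 1500, 100), rng.uniform(5, 15, 100),
                      rng.poisson(3, 100))
        r1 = M.repeat_matching(ipas, exons, n_reps=5, seed=11)
        r2 = M.repeat_matching(ipas, exons, n_reps=5, seed=11)
        assert r1.pairs == r2.pairs

    def test_all_pairs_satisfy_tolerances_on_synthetic_data(self, default_dataset):
        truth = default_dataset["truth"]
        expr = default_dataset["tracks"]["expression_ref"]
        ipas, exons = build_feature_tables(
            default_dataset["annotation"], truth, expr, truth.sites
        )
        res = M.repeat_matching(ipas, exons, n_reps=5, seed=3)
        assert res.pairs
        for p in res.pairs:
            assert abs(p.exon_length - p.ipa_length) <= 0.10 * p.ipa_length
            assert abs(p.exon_depth - p.ipa_depth) <= 0.10 * p.ipa_depth
        frame = res.pairs_frame()
        assert not frame.duplicated(["repetition", "exon_id"]).any()

    def test_summary_reports_six_sets(self):
        ipas = table(["i1", "i2"], [1000, 900], [10.0, 9.0], [4, 2])
        exons = table([f"e{k}" for k in range(10)], [950] * 10, [9.5] * 10, [1] * 10)
        res = M.repeat_matching(ipas, exons, n_reps=5, seed=0)
        summary = res.summary()
        assert list(summary["set"]) == ["IPA"] + [f"exon_rep{i}" for i in range(1, 6)]
        assert summary.loc[0, "mean_m6a"] == pytest.approx(3.0)


class TestStratify:
    def test_direct_binning(self):
        out = M.stratify({"x": [0, 0, 3, 13]})
        row = out.set_index("set").loc["x"]
        assert row["0"] == 0.5 and row["1-6"] == 0.25
        assert row["7-12"] == 0.0 and row[">12"] == 0.25

    def test_all_zero_counts(self):
        row = M.stratify({"x": [0, 0]}).set_index("set").loc["x"]
        assert row["0"] == 1.0

    def test_boundaries_of_middle_bin(self):
        row = M.stratify({"x": [7, 12]}).set_index("set").loc["x"]
        assert row["7-12"] == 1.0

    def test_proportions_sum_to_one(self, rng):
        counts = rng.poisson(6, 200)
        row = M.stratify({"x": counts}).set_index("set").loc["x"]
        assert row[["0", "1-6", "7-12", ">12"]].sum() == pytest.approx(1.0)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="non-integer"):
            M.stratify({"x": [0.5, 1.0]})


class TestCompareSets:
    def test_one_sample_t_matches_closed_form(self):
        reps = [0.30, 0.32, 0.28, 0.31, 0.29]
        res = one_sample_t(0.60, reps)
        expected_t = (0.60 - np.mean(reps)) / (np.std(reps, ddof=1) / np.sqrt(5))
        assert res["statistic"] == pytest.approx(expected_t)
        assert res["df"] == 4
        t_sp, p_sp = stats.ttest_1samp(reps, 0.60)
        assert res["p_value"] == pytest.approx(p_sp)

    def test_value_equal_to_rep_mean_gives_p_one(self):
        res = one_sample_t(0.30, [0.28, 0.32])
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_degenerate_variance_flagged(self):
        res = one_sample_t(0.60, [0.30, 0.30, 0.30])
        assert res["degenerate"] is True
        assert 0 < res["p_value"] < 1e-300

    def test_fewer_than_two_reps_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t(0.5, [0.3])

    def test_methods_agree_on_direction(self, default_dataset):
        truth = default_dataset["truth"]
        expr = default_dataset["tracks"]["expression_ref"]
        ipas, exons = build_feature_tables(
            default_dataset["annotation"], truth, expr, truth.sites
        )
        res = M.repeat_matching(ipas, exons, n_reps=5, seed=5)
        for method in ("paired", "six_sets", "welch"):
            out = M.compare_sets(res, method=method).set_index("quantity")
            # 3x planting rate in IPA regions: every method sees the excess
            assert out.loc["mean_m6a", "statistic"] > 0
            assert out.loc["mean_m6a", "p_value"] < 0.05
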