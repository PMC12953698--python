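"""Track normalization, promoter quantification, differential mark calls,
redistribution and meta-region matrices."""

import numpy as np
import pandas as pd
import pytest

from gc2mat import chromatin
from gc2mat.chromatin import BinnedTrack, GeneIntervals, TadSet
from gc2mat.simulate import SimulationConfig, simulate_marks_and_tads


def uniform_track(value, n_bins=100, bin_width=100, total_reads=0):
    return BinnedTrack(
        bin_width=bin_width,
        signal={"chr1": np.full(n_bins, float(value))},
        total_reads=total_reads,
    )


class TestRpkm:
    def test_formula(self):
        t = uniform_track(10, total_reads=10**6)
        out = chromatin.rpkm_bin_track(t)
        # 10 * 1e9 / (1e6 * 100) = 100
        assert out.signal["chr1"][0] == pytest.approx(100.0)
        assert out.normalization == "rpkm"

    def test_zero_bin_stays_zero(self):
        t = uniform_track(0, total_reads=1000)
        assert chromatin.rpkm_bin_track(t).signal["chr1"][0] == 0.0

    def test_doubling_reads_halves_values(self):
        t1 = uniform_track(10, total_reads=10**6)
        t2 = uniform_track(10, total_reads=2 * 10**6)
        np.testing.assert_allclose(
            chromatin.rpkm_bin_track(t1).signal["chr1"],
            2 * chromatin.rpkm_bin_track(t2).signal["chr1"],
        )

    def test_zero_total_reads_is_an_error(self):
        t = uniform_track(0)
        t.total_reads = 0
        with pytest.raises(ValueError, match="total_reads"):
            chromatin.rpkm_bin_track(t)


class TestBinarize:
    def test_uniform_track_is_all_unbound(self):
        t = uniform_track(2)
        assert not chromatin.binarize_track(t)["chr1"].any()

    def test_strong_outlier_bin_is_bound(self):
        v = np.full(100, 2.0)
        v[7] = 100.0  # 50x the mean
        t = BinnedTrack(bin_width=100, signal={"chr1": v})
        assert chromatin.binarize_track(t)["chr1"][7]

    def test_empty_track_is_all_unbound(self):
        t = uniform_track(0)
        assert not chromatin.binarize_track(t)["chr1"].any()


class TestQuantify:
    def test_uniform_signal_gives_equal_means(self):
        t = uniform_track(7, n_bins=200)
        genes = GeneIntervals(
            pd.DataFrame(
                {
                    "gene_id": ["g1"],
                    "chrom": ["chr1"],
                    "start": [5000],
                    "end": [8000],
                    "strand": ["+"],
                }
            )
        )
        q = chromatin.quantify_gene_marks(t, genes)
        assert q["promoter_mean"].iloc[0] == pytest.approx(7.0)
        assert q["body_mean"].iloc[0] == pytest.approx(7.0)

    def test_promoter_only_signal(self):
        v = np.zeros(200)
        v[49:51] = 50.0  # only the 100-bp bins around position 5000
        t = BinnedTrack(bin_width=100, signal={"chr1": v})
        genes = GeneIntervals(
            pd.DataFrame(
                {
                    "gene_id": ["g1"],
                    "chrom": ["chr1"],
                    "start": [5000],
                    "end": [15000],
                    "strand": ["+"],
                }
            )
        )
        q = chromatin.quantify_gene_marks(t, genes)
        assert q["promoter_mean"].iloc[0] > 5 * q["body_mean"].iloc[0]

    def test_overlap_weighted_mean_by_hand(self):
        # bins of 10 bp with values 1, 2, 3; interval [5, 25) overlaps
        # 5 bp of bin0, 10 bp of bin1, 5 bp of bin2:
        # (5*1 + 10*2 + 5*3) / 20 = 2.0
        t = BinnedTrack(bin_width=10, signal={"chr1": np.array([1.0, 2.0, 3.0])})
        assert chromatin._interval_mean(t, "chr1", 5, 25) == pytest.approx(2.0)

    def test_absent_chromosome_is_an_error(self):
        t = uniform_track(1)
        genes = GeneIntervals(
            pd.DataFrame(
                {
                    "gene_id": ["g1"],
                    "chrom": ["chrX"],
                    "start": [0],
                    "end": [100],
                    "strand": ["+"],
                }
            )
        )
        with pytest.raises(ValueError, match="chrX"):
            chromatin.quantify_gene_marks(t, genes)

    def test_rpkm_commutes_with_quantification(self, rng):
        v = rng.poisson(5, 300).astype(float)
        t = BinnedTrack(bin_width=100, signal={"chr1": v})
        genes = GeneIntervals(
            pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(5)],
                    "chrom": "chr1",
                    "start": [1000, 5000, 9000, 13000, 20000],
                    "end": [3000, 7500, 11000, 16000, 25000],
                    "strand": ["+", "-", "+", "-", "+"],
                }
            )
        )
        scale = 1e9 / (t.total_reads * t.bin_width)
        q_then_n = chromatin.quantify_gene_marks(t, genes)[["promoter_mean",
                                                            "body_mean"]] * scale
        n_then_q = chromatin.quantify_gene_marks(
            chromatin.rpkm_bin_track(t), genes
        )[["promoter_mean", "body_mean"]]
        np.testing.assert_allclose(q_then_n, n_then_q, atol=1e-9)


class TestDifferentialCalls:
    def test_identical_tracks_are_stable(self):
        q = pd.DataFrame({"gene_id": ["a", "b"], "promoter_mean": [50.0, 80.0],
                          "body_mean": [0.0, 0.0]})
        out = chromatin.differential_mark_call(q, q, background=10.0)
        assert (out["call"] == "stable").all()

    def test_halved_promoter_is_a_loss_at_the_boundary(self):
        wt = pd.DataFrame({"gene_id": ["a"], "promoter_mean": [101.0],
                           "body_mean": [0.0]})
        kd = pd.DataFrame({"gene_id": ["a"], "promoter_mean": [50.0],
                           "body_mean": [0.0]})
        out = chromatin.differential_mark_call(wt, kd, background=10.0)
        assert out["call"].iloc[0] == "loss"

    def test_recovery_on_synthetic_cohorts(self):
        cfg = SimulationConfig(seed=51)
        wt, kd, genes, _, truth = simulate_marks_and_tads(cfg)
        wq = chromatin.quantify_gene_marks(chromatin.rpkm_bin_track(wt), genes)
        kq = chromatin.quantify_gene_marks(chromatin.rpkm_bin_track(kd), genes)
        calls = chromatin.differential_mark_call(wq, kq)
        m = calls.merge(truth.table, on="gene_id")
        loss = m[m.true_mark_class == "loss"]
        gain = m[m.true_mark_class == "gain"]
        stable = m[m.true_mark_class.isin(["stable", "background"])]
        assert (loss["call"] == "loss").mean() >= 0.95
        assert (gain["call"] == "gain").mean() >= 0.95
        assert (stable["call"] == "loss").mean() <= 0.02

    def test_cohort_enriched_among_loss_calls(self):
        # the designed cohort must dominate loss calls (hypergeometric check)
        from gc2mat.genesets import GeneSet, hypergeometric_overlap_test

        cfg = SimulationConfig(seed=52)
        wt, kd, genes, _, truth = simulate_marks_and_tads(cfg)
        wq = chromatin.quantify_gene_marks(chromatin.rpkm_bin_track(wt), genes)
        kq = chromatin.quantify_gene_marks(chromatin.rpkm_bin_track(kd), genes)
        calls = chromatin.differential_mark_call(wq, kq)
        universe = GeneSet("all", calls["gene_id"].tolist())
        loss_calls = GeneSet(
            "loss", calls.loc[calls["call"] == "loss", "gene_id"].tolist()
        )
        cohort = GeneSet(
            "cohort",
            truth.table.loc[
                truth.table.true_mark_class == "loss", "gene_id"
            ].tolist(),
        )
        p = hypergeometric_overlap_test(loss_calls, cohort, universe)
        assert p < 1e-10


class TestRedistribution:
    def test_identical_binarizations(self):
        b = {"chr1": np.array([True, False, True])}
        out = chromatin.redistribution_summary(b, b)
        assert out["n_lost"] == out["n_gained"] == 0
        assert out["redistribution_index"] == 0.0

    def test_complete_swap_has_index_one(self):
        wt = {"chr1": np.array([True, True, False, False])}
        kd = {"chr1": np.array([False, False, True, True])}
        out = chromatin.redistribution_summary(wt, kd)
        assert out["redistribution_index"] == 1.0

    def test_hand_built_ten_bin_case(self):
        wt = {"chr1": np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], bool)}
        kd = {"chr1": np.array([1, 1, 0, 0, 1, 1, 1, 0, 0, 0], bool)}
        out = chromatin.redistribution_summary(wt, kd)
        assert (out["n_lost"], out["n_gained"]) == (2, 3)
        assert out["redistribution_index"] == pytest.approx(2 / 3)

    def test_counts_conserve_bins(self):
        rng = np.random.default_rng(0)
        wt = {"chr1": rng.random(500) < 0.2, "chr2": rng.random(300) < 0.2}
        kd = {"chr1": rng.random(500) < 0.2, "chr2": rng.random(300) < 0.2}
        out = chromatin.redistribution_summary(wt, kd)
        total = (
            out["n_lost"] + out["n_gained"]
            + out["n_stable_bound"] + out["n_stable_unbound"]
        )
        assert total == 800

    def test_binning_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            chromatin.redistribution_summary(
                {"chr1": np.zeros(3, bool)}, {"chr1": np.zeros(4, bool)}
            )


class TestMetaRegions:
    @pytest.fixture
    def toy(self):
        # toy genome: 100 kb, two TADs, six genes placed by hand; genes g0,
        # g1 inside TAD1, g2, g3 inside TAD2, g4, g5 outside: 4/6 within TADs
        track = BinnedTrack(
            bin_width=100, signal={"chr1": np.ones(1000)}
        )
        tads = TadSet(
            pd.DataFrame(
                {"chrom": "chr1", "start": [10_000, 60_000],
                 "end": [30_000, 80_000]}
            )
        )
        genes = GeneIntervals(
            pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(6)],
                    "chrom": "chr1",
                    "start": [12_000, 20_000, 62_000, 70_000, 40_000, 90_000],
                    "end": [14_000, 22_000, 64_000, 72_000, 42_000, 92_000],
                    "strand": "+",
                }
            )
        )
        values = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(6)],
                "log2fc": [3.0, 2.0, -3.0, 0.1, 0.0, 0.0],
            }
        )
        return track, tads, genes, values

    def test_within_tad_fraction_by_construction(self, toy):
        _, tads, genes, _ = toy
        assert chromatin.within_tad_fraction(genes, tads) == pytest.approx(4 / 6)

    def test_midpoint_indicators(self, toy):
        _, tads, genes, _ = toy
        inside = chromatin.within_tad_fraction(
            genes, tads, de_genes={"g0"}
        )
        outside = chromatin.within_tad_fraction(
            genes, tads, de_genes={"g4"}
        )
        assert inside == 1.0 and outside == 0.0

    def test_matrix_shape_and_cluster_sorting(self, toy):
        track, tads, genes, values = toy
        out = chromatin.tad_metaregion_matrix(
            values, tads, track, genes=genes, flank=3000, body_bins=100
        )
        assert out["matrix"].shape == (2, 30 + 100 + 30)
        clusters = out["rows"]["cluster"].tolist()
        order = {"upregulated": 0, "nontarget": 1, "downregulated": 2}
        assert clusters == sorted(clusters, key=order.get)
        assert out["within_tad_fraction"] == pytest.approx(4 / 6)

    def test_uniform_track_gives_flat_profiles(self, toy):
        track, tads, genes, values = toy
        out = chromatin.tad_metaregion_matrix(values, tads, track, genes=genes)
        np.testing.assert_allclose(out["matrix"], 1.0)


class TestIO:
    def test_bedgraph_roundtrip(self, tmp_path, rng):
        t = BinnedTrack(
            bin_width=50, signal={"chr1": rng.poisson(4, 40).astype(float)}
        )
        path = tmp_path / "t.bedgraph"
        t.write_bedgraph(path)
        back = BinnedTrack.read_bedgraph(path, bin_width=50)
        np.testing.assert_allclose(back.signal["chr1"], t.signal["chr1"])

    def test_bed_roundtrip(self, tmp_path):
        genes = GeneIntervals(
            pd.DataFrame(
                {
                    "gene_id": ["a", "b"],
                    "chrom": ["chr1", "chr2"],
                    "start": [0, 100],
                    "end": [50, 400],
                    "strand": ["+", "-"],
                }
            )
        )
        path = tmp_path / "genes.bed"
        genes.write_bed(path)
        back = GeneIntervals.read_bed(path)
        assert back.table["gene_id"].tolist() == ["a", "b"]
        assert back.table["strand"].tolist() == ["+", "-"]
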