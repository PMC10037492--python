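"""Distribution statistics: binning, relative abundance, correlations,
bin-size AIC, hot/cold spots, metagene profiles, strand bias, LOESS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from damagemap import distribution as dist
from damagemap.core_io import FeatureTrack, GenomicInterval


def _sites(positions, contig="chr1", support=None, strand="+", sample="s"):
    n = len(positions)
    return pd.DataFrame(
        {
            "contig": contig,
            "pos": np.asarray(positions, dtype=np.int64),
            "strand": strand if isinstance(strand, str) else strand,
            "base": "G",
            "sample": sample,
            "read_support": support if support is not None else np.ones(n, dtype=int),
        }
    )


def _track_from_values(values, width=100):
    """Fabricate a RelativeAbundanceTrack directly from a value vector."""
    n = len(values)
    part = dist.GenomePartition({"chr1": n * width}, width)
    df = part.bins.copy()
    df["value"] = np.asarray(values, dtype=float)
    return dist.RelativeAbundanceTrack(part, df, 1.0)


class TestBinCounts:
    def test_counts_and_cpm_rate(self):
        part = dist.GenomePartition({"chr1": 300_000}, 100_000)
        track = dist.bin_counts(_sites([10, 20, 99_999]), part)
        assert track.counts.tolist() == [3, 0, 0]
        assert track.rates[0] == pytest.approx(1e6)

    def test_empty_sample_all_zero(self):
        part = dist.GenomePartition({"chr1": 10_000}, 1_000)
        track = dist.bin_counts(_sites([]), part)
        assert (track.counts == 0).all()

    def test_random_sites_match_per_site_scan(self):
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 57_000, 400)
        support = rng.integers(1, 5, 400)
        part = dist.GenomePartition({"chr1": 57_000}, 7_000)
        track = dist.bin_counts(_sites(pos, support=support), part)
        brute = np.zeros(part.n_bins)
        for p, s in zip(pos, support):
            for i, row in part.bins.iterrows():
                if row.start <= p < row.end:
                    brute[i] += s
        assert (track.counts == brute).all()

    def test_partial_last_bin_flagged_and_counted(self):
        part = dist.GenomePartition({"chr1": 250_000}, 100_000)
        assert part.bins["partial"].tolist() == [False, False, True]
        track = dist.bin_counts(_sites([249_999]), part)
        assert track.counts.tolist() == [0, 0, 1]

    def test_rebinning_conserves_counts(self):
        rng = np.random.default_rng(2)
        pos = rng.integers(0, 200_000, 3_000)
        fine = dist.bin_counts(_sites(pos), dist.GenomePartition({"chr1": 200_000}, 1_000))
        coarse = dist.bin_counts(_sites(pos), dist.GenomePartition({"chr1": 200_000}, 2_000))
        merged = fine.counts.reshape(-1, 2).sum(axis=1)
        assert (merged == coarse.counts).all()


class TestRelativeAbundance:
    def _tracks(self, cell_counts, ndna_counts, width=1_000):
        n = len(cell_counts)
        part = dist.GenomePartition({"chr1": n * width}, width)

        def mk(counts):
            df = part.bins.copy()
            counts = np.asarray(counts, dtype=np.int64)
            df["count"] = counts
            total = counts.sum()
            df["rate"] = counts * 1e6 / total if total else 0.0
            return dist.BinTrack(part, df)

        return mk(cell_counts), mk(ndna_counts)

    def test_equal_rates_give_zero(self):
        cell, ndna = self._tracks([5, 5, 5], [5, 5, 5])
        ra = dist.relative_abundance(cell, ndna, epsilon=0.0)
        assert np.allclose(ra.values, 0.0)

    def test_doubled_rate_gives_plus_one(self):
        # rates: cell 20 vs nDNA 10 in bin0 after forcing equal totals
        cell, ndna = self._tracks([20, 10, 10], [10, 15, 15])
        cell.df["rate"] = [20.0, 10.0, 10.0]
        ndna.df["rate"] = [10.0, 15.0, 15.0]
        ra = dist.relative_abundance(cell, ndna, epsilon=0.0)
        assert ra.values[0] == pytest.approx(1.0)

    def test_pseudocount_rule(self):
        cell, ndna = self._tracks([3, 1], [0, 3])
        cell.df["rate"] = [3.0, 1.0]
        ndna.df["rate"] = [0.0, 3.0]
        ra = dist.relative_abundance(cell, ndna, epsilon=1.0)
        assert ra.values[0] == pytest.approx(2.0)  # log2((3+1)/(0+1))

    def test_both_empty_bin_is_missing_not_zero(self):
        cell, ndna = self._tracks([5, 0, 2], [1, 0, 2])
        ra = dist.relative_abundance(cell, ndna)
        assert np.isnan(ra.values[1])
        assert not np.isnan(ra.values[0])

    @given(
        st.lists(st.integers(0, 50), min_size=4, max_size=12),
        st.lists(st.integers(0, 50), min_size=4, max_size=12),
    )
    def test_swapping_samples_negates_values(self, a, b):
        n = min(len(a), len(b))
        cell, ndna = self._tracks(a[:n], b[:n])
        fwd = dist.relative_abundance(cell, ndna).values
        rev = dist.relative_abundance(ndna, cell).values
        both = ~(np.isnan(fwd) | np.isnan(rev))
        assert np.allclose(fwd[both], -rev[both])
        assert (np.isnan(fwd) == np.isnan(rev)).all()

    def test_partition_mismatch_rejected(self):
        cell, _ = self._tracks([1, 2], [1, 2])
        _, other = self._tracks([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="partition"):
            dist.relative_abundance(cell, other)


class TestCorrelate:
    def test_identical_and_negated_vectors(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        assert dist.correlate(x, x).coefficient == pytest.approx(1.0)
        assert dist.correlate(x, -x).coefficient == pytest.approx(-1.0)

    def test_matches_bruteforce_rank_correlation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=10)
        y = rng.normal(size=10)

        def ranks(v):  # average ranks for ties, built from scratch
            order = np.argsort(v, kind="mergesort")
            r = np.empty(len(v))
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                r[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return r

        rx, ry = ranks(x), ranks(y)
        want = np.corrcoef(rx, ry)[0, 1]
        got = dist.correlate(x, y).coefficient
        assert got == pytest.approx(want, abs=1e-12)

    def test_replicates_report_mean_and_sd(self):
        y = np.arange(8.0)
        reps = [y + 0.1 * np.random.default_rng(i).normal(size=8) for i in range(3)]
        res = dist.correlate(reps, y)
        assert res.coefficient_sd is not None
        assert res.coefficient > 0.8

    def test_missing_bins_dropped_and_minimum_enforced(self):
        x = np.array([1.0, np.nan, 2.0, 3.0])
        y = np.array([1.0, 5.0, 2.0, 3.0])
        assert dist.correlate(x, y).n == 3
        with pytest.raises(ValueError, match="3"):
            dist.correlate(x[:3], y[:3])  # only 2 usable pairs

    def test_open_chromatin_depletion_recovered(self, chromatin_cohort):
        """Damage generated with open-region survival < 1 must correlate
        negatively with open-chromatin coverage (relative abundance vs
        nDNA), the in-silico analog of DHS depletion."""
        genome = chromatin_cohort["genome"]
        part = dist.GenomePartition.from_genome(genome, 10_000)
        cell = dist.bin_counts(chromatin_cohort["cell_sites"], part)
        ndna = dist.bin_counts(chromatin_cohort["ndna_sites"], part)
        cell.add_feature_coverage(chromatin_cohort["open_track"], "open")
        ra = dist.relative_abundance(cell, ndna)
        res = dist.correlate(ra.df["value"], cell.df["open"])
        assert res.coefficient < 0
        assert res.pvalue < 0.01

    def test_ndna_counts_track_gc(self, chromatin_cohort):
        """Chromatin-free damage follows G availability, hence GC content."""
        genome = chromatin_cohort["genome"]
        part = dist.GenomePartition.from_genome(genome, 10_000)
        ndna = dist.bin_counts(chromatin_cohort["ndna_sites"], part).add_gc(genome)
        res = dist.correlate(ndna.df["count"].astype(float), ndna.df["gc"])
        assert res.coefficient > 0.5
        assert res.pvalue < 1e-10


class TestBinSizeEvaluation:
    def test_homogeneous_sites_prefer_wide_bins(self):
        rng = np.random.default_rng(0)
        sites = _sites(np.sort(rng.integers(0, 500_000, 2_000)))
        ev = dist.evaluate_bin_sizes(
            sites, {"chr1": 500_000}, [1_000, 2_000, 5_000, 10_000, 20_000, 50_000]
        )
        aic = ev.table["aic"].to_numpy()
        assert (np.diff(aic) < 0).all()  # flat-to-decreasing
        assert ev.best_width == 50_000  # no spurious small-width optimum

    def test_single_bin_likelihood_is_poisson_logpmf_of_total(self):
        rng = np.random.default_rng(1)
        sites = _sites(rng.integers(0, 2_000, 37))
        ev = dist.evaluate_bin_sizes(sites, {"chr1": 2_000}, [2_000, 2_000])
        assert ev.table["loglik"].iloc[0] == pytest.approx(
            float(sps.poisson.logpmf(37, 37)), abs=1e-9
        )

    def test_clustered_sites_select_width_at_or_below_cluster_scale(self):
        rng = np.random.default_rng(2)
        bg = rng.integers(0, 1_000_000, 1_500)
        hot = np.concatenate(
            [rng.integers(300_000, 320_000, 2_000), rng.integers(700_000, 720_000, 2_000)]
        )
        sites = _sites(np.sort(np.concatenate([bg, hot])))
        ev = dist.evaluate_bin_sizes(
            sites,
            {"chr1": 1_000_000},
            [2_000, 5_000, 10_000, 20_000, 50_000, 100_000, 200_000],
        )
        assert ev.best_width <= 20_000

    def test_oversized_width_skipped_with_warning(self):
        sites = _sites([10, 500, 900])
        with pytest.warns(UserWarning, match="skipped"):
            ev = dist.evaluate_bin_sizes(sites, {"chr1": 2_000}, [500, 1_000, 50_000])
        assert 50_000 not in ev.table["width"].tolist()

    def test_fewer_than_two_widths_rejected(self):
        with pytest.raises(ValueError, match="2 candidate"):
            dist.evaluate_bin_sizes(_sites([1]), {"chr1": 2_000}, [1_000])


class TestHotColdSpots:
    def test_extreme_outlier_lands_in_hot_set(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=100_000)
        values[123] = 40.0
        hot, cold = dist.hot_cold_spots(_track_from_values(values))
        hot_starts = [iv.start for iv in hot.intervals]
        assert 123 * 100 in hot_starts

    def test_uniform_values_give_empty_sets(self):
        values = np.zeros(20_000)
        hot, cold = dist.hot_cold_spots(_track_from_values(values))
        assert len(hot) == 0 and len(cold) == 0

    def test_planted_extremes_recovered_exactly(self):
        rng = np.random.default_rng(6)
        n = 100_000
        values = rng.normal(size=n)
        hot_idx = rng.choice(n, 10, replace=False)
        rest = np.setdiff1d(np.arange(n), hot_idx)
        cold_idx = rng.choice(rest, 10, replace=False)
        values[hot_idx] = 100.0
        values[cold_idx] = -100.0
        hot, cold = dist.hot_cold_spots(_track_from_values(values))
        assert sorted(iv.start // 100 for iv in hot.intervals) == sorted(hot_idx)
        assert sorted(iv.start // 100 for iv in cold.intervals) == sorted(cold_idx)

    def test_small_track_scales_thresholds_with_warning(self):
        values = np.concatenate([np.zeros(99), [5.0], [-5.0]])
        with pytest.warns(UserWarning, match="scaled"):
            hot, cold = dist.hot_cold_spots(_track_from_values(values))
        assert len(hot) == 1 and len(cold) == 1

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            dist.hot_cold_spots(_track_from_values(np.full(50, np.nan)))


class TestFractionNegative:
    def test_counts_match_direct_tally(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=500)
        track = _track_from_values(values)
        frac = dist.fraction_negative_per_contig(track)
        assert frac["chr1"] == pytest.approx((values < 0).mean())

    def test_all_positive_contig_is_zero(self):
        assert dist.fraction_negative_per_contig(
            _track_from_values(np.ones(50))
        )["chr1"] == 0.0


class TestMetagene:
    def _genes(self):
        return pd.DataFrame(
            {
                "contig": "chr1",
                "start": [10_000, 30_000],
                "end": [15_000, 35_000],
                "name": ["plusG", "minusG"],
                "strand": ["+", "-"],
            }
        )

    def test_damage_planted_upstream_of_tss_peaks_upstream(self):
        genes = self._genes()
        # plant sites in [-100, 0) upstream of each TSS
        plus_sites = np.arange(9_900, 10_000)
        minus_sites = np.arange(35_000, 35_100)  # upstream of the - gene TSS (34_999)
        sites = _sites(np.concatenate([plus_sites, minus_sites]))
        prof = dist.metagene_profile(sites, genes, "TSS", flank=500, binsize=25)
        occupied = np.flatnonzero(prof.matrix.sum(axis=0))
        want = np.flatnonzero((prof.offsets >= -100) & (prof.offsets < 0))
        assert sorted(occupied) == sorted(want)

    def test_minus_strand_gene_orientation_mirrors(self):
        genes = self._genes().iloc[[1]].reset_index(drop=True)
        # one site 200 bp upstream of the - gene TSS (genomic 34_999 + 200)
        prof = dist.metagene_profile(_sites([35_199]), genes, "TSS", 500, 25)
        (bin_idx,) = np.flatnonzero(prof.matrix[0])
        assert prof.offsets[bin_idx] == -200

    def test_uniform_damage_profile_flat_within_poisson_band(self):
        rng = np.random.default_rng(8)
        genes = pd.DataFrame(
            {
                "contig": "chr1",
                "start": np.arange(100) * 9_000 + 3_000,
                "end": np.arange(100) * 9_000 + 7_000,
                "name": [f"g{i}" for i in range(100)],
                "strand": rng.choice(["+", "-"], 100),
            }
        )
        sites = _sites(rng.integers(0, 910_000, 40_000))
        prof = dist.metagene_profile(sites, genes, "TSS", flank=1_000, binsize=25)
        per_bin = prof.matrix.sum(axis=0)
        lam = per_bin.mean()
        assert (np.abs(per_bin - lam) < 4.5 * np.sqrt(lam)).all()

    def test_flank_must_be_multiple_of_bin(self):
        with pytest.raises(ValueError, match="multiple"):
            dist.metagene_profile(_sites([1]), self._genes(), "TSS", 510, 25)


class TestStrandBias:
    def test_neutral_generator_gives_ratio_near_one(self, humanlike_genome):
        from conftest import sites_from_truth

        from damagemap import synthetic as syn

        genes = pd.DataFrame(
            {
                "contig": "chr1",
                "start": np.arange(500) * 2_000,
                "end": np.arange(500) * 2_000 + 1_500,
                "name": [f"g{i}" for i in range(500)],
                "strand": np.random.default_rng(9).choice(["+", "-"], 500),
            }
        )
        truth = syn.plant_damage(humanlike_genome, syn.DamageModel(), 20_000, seed=31)
        res = dist.ts_nts_bias(sites_from_truth(truth), genes)
        assert abs(res.ratio - 1.0) < 0.06
        assert res.pvalue > 0.05

    def test_planted_survival_recovered_with_significance(self, strand_bias_cohort):
        """ts_survival = 0.5 at 2,000 genes: pooled TS/NTS ratio within
        3 sigma of the sampling-oracle expectation, Wilcoxon p < 1e-4."""
        res = dist.ts_nts_bias(strand_bias_cohort["sites"], strand_bias_cohort["genes"])
        expected = strand_bias_cohort["expected_ratio"]
        n = strand_bias_cohort["expected_n_in_gene"]
        p_ts = expected / (1 + expected)
        sigma_ratio = np.sqrt(p_ts * (1 - p_ts) / n) / (1 - p_ts) ** 2
        assert abs(res.ratio - expected) < 3 * sigma_ratio
        assert res.pvalue < 1e-4
        assert res.n_genes > 1_500

    def test_single_gene_single_site_not_significant(self):
        genes = pd.DataFrame(
            {"contig": ["chr1"], "start": [100], "end": [600],
             "name": ["g"], "strand": ["+"]}
        )
        sites = _sites([300], strand="-")  # one TS site, zero NTS
        res = dist.ts_nts_bias(sites, genes)
        assert res.ratio == np.inf
        assert res.pvalue > 0.05

    def test_no_damage_in_any_gene_rejected(self):
        genes = pd.DataFrame(
            {"contig": ["chr1"], "start": [100], "end": [600],
             "name": ["g"], "strand": ["+"]}
        )
        with pytest.raises(ValueError, match="damage"):
            dist.ts_nts_bias(_sites([5_000]), genes)


class TestLoess:
    def test_constant_preserved(self):
        out = dist.loess_smooth(np.full(50, 3.25), span=0.4)
        assert np.allclose(out, 3.25)

    def test_linear_reproduced_exactly(self):
        x = np.arange(60, dtype=float)
        out = dist.loess_smooth(2.0 * x - 7.0, span=0.3)
        assert np.allclose(out, 2.0 * x - 7.0, atol=1e-6)

    def test_noisy_sine_rmse_below_noise_sd(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 4 * np.pi, 400)
        truth = np.sin(x)
        noisy = truth + rng.normal(0, 0.5, size=x.size)
        out = dist.loess_smooth(noisy, span=0.1)
        rmse = np.sqrt(np.mean((out - truth) ** 2))
        assert rmse < 0.5

    def test_span_validated(self):
        with pytest.raises(ValueError, match="span"):
            dist.loess_smooth(np.ones(20), span=1.5)
        with pytest.raises(ValueError, match="10 points"):
            dist.loess_smooth(np.ones(5), span=0.5)
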