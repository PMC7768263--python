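"""Metagene profiles, ranked-bin comparison, and the bootstrap TPR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rapidfoot as rf


def genes_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


class TestMetagene:
    def test_constant_track_gives_flat_profile(self):
        per_base = {"c": np.full(20_000, 2.5)}
        genes = genes_df([("g1", "c", 3000, 6000, "+"), ("g2", "c", 9000, 12_000, "-")])
        prof = rf.metagene(per_base, genes)
        assert prof.n_genes == 2
        assert len(prof.positions) == 100 + 2 * 20
        assert np.allclose(prof.mean_score, 2.5)

    def test_step_at_tss_for_plus_strand_gene(self):
        sig = np.zeros(10_000)
        sig[4000:7000] = 1.0
        genes = genes_df([("g", "c", 4000, 7000, "+")])
        prof = rf.metagene({"c": sig}, genes)
        nf = 20
        assert np.allclose(prof.mean_score[:nf], 0)  # upstream flank
        assert np.allclose(prof.mean_score[nf: nf + 100], 1)  # body
        assert np.allclose(prof.mean_score[nf + 100:], 0)

    def test_ramp_recovered_within_discretization(self):
        """A linear 0->1 ramp along each body (strands mixed) comes back
        as the same ramp on the grid."""
        sig = np.zeros(50_000)
        genes = genes_df(
            [("g1", "c", 5000, 9000, "+"), ("g2", "c", 20_000, 26_000, "-"),
             ("g3", "c", 40_000, 43_000, "+")]
        )
        for g in genes.itertuples(index=False):
            ramp = np.linspace(0, 1, g.end - g.start, endpoint=False)
            sig[g.start:g.end] = ramp if g.strand == "+" else ramp[::-1]
        prof = rf.metagene({"c": sig}, genes)
        body = prof.mean_score[20:120]
        expected = (np.arange(100) + 0.5) / 100
        assert np.max(np.abs(body - expected)) < 1.0 / 100

    def test_strand_flip_invariance_of_symmetric_signal(self):
        """A strand-symmetric signal yields the same profile if all gene
        strands are flipped."""
        rng = np.random.default_rng(0)
        raw = rng.normal(size=30_000)
        sym = raw + raw[::-1]
        genes = genes_df([("g1", "c", 5000, 8000, "+"), ("g2", "c", 12_000, 15_000, "+")])
        flipped = genes.copy()
        # mirror gene coordinates and flip strand: same signal seen reversed
        flipped["start"] = 30_000 - genes["end"]
        flipped["end"] = 30_000 - genes["start"]
        flipped["strand"] = "-"
        a = rf.metagene({"c": sym}, genes)
        b = rf.metagene({"c": sym}, flipped)
        assert np.allclose(a.mean_score, b.mean_score, atol=1e-12, equal_nan=True)

    def test_short_genes_skipped_and_counted(self):
        genes = genes_df([("tiny", "c", 100, 150, "+"), ("ok", "c", 2000, 4000, "+")])
        prof = rf.metagene({"c": np.ones(10_000)}, genes)
        assert prof.n_genes == 1 and prof.n_skipped_short == 1

    def test_no_eligible_genes_errors(self):
        with pytest.raises(ValueError, match="no eligible genes"):
            rf.metagene({"c": np.ones(1000)}, genes_df([("g", "c", 0, 10, "+")]))

    def test_fragment_track_expansion(self, tiny_track, tiny_sim):
        """OccupancyTrack input matches explicit per-base expansion."""
        frags = tiny_track.fragments
        per_base = {
            "chr1": np.repeat(
                tiny_track.scores, (frags["end"] - frags["start"]).to_numpy()
            )
        }
        genes = tiny_sim.genes.head(20)
        a = rf.metagene(tiny_track, genes)
        b = rf.metagene(per_base, genes)
        assert np.allclose(a.mean_score, b.mean_score, equal_nan=True)


class TestRankedBins:
    def test_hand_binned_means(self):
        scores = pd.DataFrame({"gene_id": list("abcdef"), "occupancy": [1, 2, 3, 4, 5, 6]})
        tpm = pd.DataFrame({"gene_id": list("abcdef"), "tpm": [10, 10, 20, 20, 30, 30]})
        out = rf.ranked_bin_comparison(scores, tpm, rf.ProfileParams(bin_size_genes=2))
        assert out["mean_tpm"].tolist() == [10, 20, 30]
        assert out["n_genes"].tolist() == [2, 2, 2]

    def test_monotone_when_expression_equals_occupancy(self):
        rng = np.random.default_rng(1)
        occ = rng.normal(size=5000)
        df = pd.DataFrame({"gene_id": [f"g{i}" for i in range(5000)], "occupancy": occ})
        tpm = pd.DataFrame({"gene_id": df["gene_id"], "tpm": occ})
        out = rf.ranked_bin_comparison(df, tpm, rf.ProfileParams(bin_size_genes=250))
        assert (np.diff(out["mean_tpm"]) > 0).all()

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(1000)], "occupancy": rng.normal(size=1000)}
        )
        tpm = pd.DataFrame(
            {"gene_id": df["gene_id"], "tpm": np.exp(df["occupancy"] + rng.normal(size=1000))}
        )
        a = rf.ranked_bin_comparison(df, tpm, rf.ProfileParams(bin_size_genes=100))
        shuffled = df.sample(frac=1, random_state=4).reset_index(drop=True)
        b = rf.ranked_bin_comparison(shuffled, tpm, rf.ProfileParams(bin_size_genes=100))
        pd.testing.assert_frame_equal(a, b)

    def test_noisy_monotone_trend_recovered(self):
        """TPM = exp(occupancy + noise): bin means rank perfectly with bin index."""
        rng = np.random.default_rng(3)
        n = 20_000
        occ = rng.normal(size=n)
        df = pd.DataFrame({"gene_id": [f"g{i:05d}" for i in range(n)], "occupancy": occ})
        tpm = pd.DataFrame(
            {"gene_id": df["gene_id"], "tpm": np.exp(occ + 0.5 * rng.normal(size=n))}
        )
        out = rf.ranked_bin_comparison(df, tpm, rf.ProfileParams(bin_size_genes=690))
        rho = stats.spearmanr(out["bin"], out["mean_tpm"]).statistic
        assert rho == pytest.approx(1.0)

    def test_empty_join_errors(self):
        a = pd.DataFrame({"gene_id": ["x"], "occupancy": [1.0]})
        b = pd.DataFrame({"gene_id": ["y"], "tpm": [1.0]})
        with pytest.raises(ValueError, match="no genes shared"):
            rf.ranked_bin_comparison(a, b)


class TestBootstrapTPR:
    def test_degenerate_all_positive(self):
        res = rf.bootstrap_tpr(11, 11, rf.BootstrapParams(n_boot=1000, seed=0))
        assert (res.ci_lower, res.ci_upper) == (1.0, 1.0)

    def test_degenerate_all_negative(self):
        res = rf.bootstrap_tpr(0, 11, rf.BootstrapParams(n_boot=1000, seed=0))
        assert (res.ci_lower, res.ci_upper) == (0.0, 0.0)

    def test_bounds_ordering(self):
        res = rf.bootstrap_tpr(8, 11, rf.BootstrapParams(n_boot=2000, seed=1))
        assert 0 <= res.ci_lower <= res.point_estimate <= res.ci_upper <= 1

    def test_deterministic_under_seed(self):
        a = rf.bootstrap_tpr(8, 11, rf.BootstrapParams(n_boot=5000, seed=9))
        b = rf.bootstrap_tpr(8, 11, rf.BootstrapParams(n_boot=5000, seed=9))
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)

    def test_converges_to_exact_binomial_quantiles(self):
        """Percentile bounds at large B match Binomial(11, 8/11) quantiles."""
        res = rf.bootstrap_tpr(8, 11, rf.BootstrapParams(n_boot=100_000, seed=2))
        lo = stats.binom.ppf(0.025, 11, 8 / 11) / 11
        hi = stats.binom.ppf(0.975, 11, 8 / 11) / 11
        assert abs(res.ci_lower - lo) < 1 / 11
        assert abs(res.ci_upper - hi) < 1 / 11
        assert lo == pytest.approx(5 / 11)


class TestExtrapolation:
    def test_reporting_scale_range(self):
        """A [0.45, 0.88] interval over 2362 detected genes reads as
        roughly 1100-2100 truly expressed at nearest-100 rounding."""
        tpr = rf.TPRResult(8 / 11, 0.45, 0.88, 8, 11)
        assert rf.extrapolate_expressed(tpr, 2362, rounding="nearest_100") == (1100, 2100)

    def test_degenerate_interval(self):
        tpr = rf.TPRResult(1.0, 1.0, 1.0, 5, 5)
        assert rf.extrapolate_expressed(tpr, 777) == (777, 777)

    def test_exact_rounding(self):
        tpr = rf.TPRResult(0.5, 0.5, 0.5, 1, 2)
        assert rf.extrapolate_expressed(tpr, 200) == (100, 100)
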