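"""Per-gene occupancy, permutation significance calls, and set algebra."""

import numpy as np
import pandas as pd
import pytest

import rapidfoot as rf

from conftest import toy_track


def genes_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


class TestGeneOccupancy:
    def test_equal_overlap_weighted_mean(self):
        track = toy_track([2.0, 4.0], starts=[0, 50], ends=[50, 100])
        genes = genes_df([("g", "c", 25, 75, "+")])
        out = rf.gene_occupancy(track, genes)
        assert out["occupancy"].iloc[0] == pytest.approx(3.0)
        assert out["n_fragments"].iloc[0] == 2

    def test_gene_inside_single_fragment(self):
        track = toy_track([-1.5, 0.5], starts=[0, 100], ends=[100, 200])
        out = rf.gene_occupancy(track, genes_df([("g", "c", 10, 60, "-")]))
        assert out["occupancy"].iloc[0] == pytest.approx(-1.5)

    def test_matches_per_base_oracle(self):
        """Weighted fragment mean equals brute-force per-base averaging."""
        rng = np.random.default_rng(9)
        bounds = np.unique(rng.integers(1, 9999, 300))
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [10_000]))
        scores = rng.normal(size=starts.size)
        track = toy_track(scores, starts=starts, ends=ends)
        per_base = np.repeat(scores, ends - starts)
        genes = []
        for i in range(100):
            a, b = sorted(rng.choice(10_000, 2, replace=False))
            if a == b:
                continue
            genes.append((f"g{i}", "c", int(a), int(b), "+"))
        out = rf.gene_occupancy(track, genes_df(genes))
        for row, (gid, _, a, b, _) in zip(out.itertuples(index=False), genes):
            assert row.occupancy == pytest.approx(per_base[a:b].mean(), abs=1e-9)

    def test_gene_outside_bounds_raises(self):
        track = toy_track([1.0], starts=[0], ends=[100])
        with pytest.raises(ValueError, match="gbad"):
            rf.gene_occupancy(track, genes_df([("gbad", "c", 50, 150, "+")]))

    def test_gene_on_absent_chromosome_flagged_absent(self):
        track = toy_track([1.0], starts=[0], ends=[100])
        out = rf.gene_occupancy(track, genes_df([("g", "chrZ", 0, 10, "+")]))
        assert np.isnan(out["occupancy"].iloc[0]) and out["n_fragments"].iloc[0] == 0


class TestCallExpressed:
    def test_constant_scores_detect_nothing(self):
        track = toy_track(np.ones(200))
        genes = genes_df([(f"g{i}", "c", i * 10, i * 10 + 10, "+") for i in range(20)])
        vals = rf.gene_occupancy(track, genes)
        calls = rf.call_expressed(vals, track, rf.CallParams(n_permutations=500, seed=0))
        assert (calls["p_value"] == 1.0).all()
        assert not (calls["fdr"] < 0.5).any()

    def test_spiked_genes_all_detected(self):
        """20 genes at score 5 over a standard-normal background are found."""
        rng = np.random.default_rng(5)
        scores = rng.normal(size=5000)
        scores[:100] = 5.0  # 20 genes x 5 fragments
        track = toy_track(scores)
        genes = genes_df(
            [(f"spike{i}", "c", i * 50, i * 50 + 50, "+") for i in range(20)]
            + [(f"null{i}", "c", 5000 + i * 50, 5000 + i * 50 + 50, "+") for i in range(80)]
        )
        vals = rf.gene_occupancy(track, genes)
        calls = rf.call_expressed(vals, track, rf.CallParams(seed=1))
        spikes = calls[calls["gene_id"].str.startswith("spike")]
        assert (spikes["fdr"] < 0.05).all()

    def test_deterministic_under_seed(self, tiny_track, tiny_sim):
        vals = rf.gene_occupancy(tiny_track, tiny_sim.genes)
        a = rf.call_expressed(vals, tiny_track, rf.CallParams(n_permutations=500, seed=3))
        b = rf.call_expressed(vals, tiny_track, rf.CallParams(n_permutations=500, seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_raising_scores_lowers_p(self):
        """Boosting one gene's fragments can only make it more significant."""
        rng = np.random.default_rng(6)
        scores = rng.normal(size=1000)
        genes = genes_df([(f"g{i}", "c", i * 100, i * 100 + 100, "+") for i in range(10)])
        track = toy_track(scores)
        vals = rf.gene_occupancy(track, genes)
        calls = rf.call_expressed(vals, track, rf.CallParams(n_permutations=2000, seed=7))
        boosted = scores.copy()
        boosted[:10] += 2.0  # fragments of g0
        track2 = toy_track(boosted)
        vals2 = rf.gene_occupancy(track2, genes)
        calls2 = rf.call_expressed(vals2, track2, rf.CallParams(n_permutations=2000, seed=7))
        assert calls2["p_value"].iloc[0] <= calls["p_value"].iloc[0]

    def test_too_few_genes_rejected(self):
        track = toy_track(np.ones(10))
        vals = pd.DataFrame({"gene_id": ["a"], "occupancy": [1.0], "n_fragments": [1]})
        with pytest.raises(ValueError, match="at least 10 genes"):
            rf.call_expressed(vals, track)


def test_bh_adjustment_matches_step_up_closed_form():
    """BH on p = [0.001, 0.01, 0.02, 0.04, 0.5]: adjusted_(i) =
    min_{j>=i} p_(j)*m/j = [0.005, 0.025, 0.1/3, 0.05, 0.5]."""
    p = np.array([0.001, 0.01, 0.02, 0.04, 0.5])
    m = len(p)
    stepup = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1])[::-1]
    from statsmodels.stats.multitest import multipletests

    adjusted = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(adjusted, stepup)
    assert np.allclose(adjusted, [0.005, 0.025, 0.1 / 3, 0.05, 0.5])


class TestSetAlgebra:
    def make_calls(self, sig, universe):
        return pd.DataFrame(
            {
                "gene_id": list(universe),
                "fdr": [0.01 if g in sig else 0.5 for g in universe],
            }
        )

    def test_detected_any_vs_all(self):
        u = ["a", "b", "c", "d"]
        reps = [self.make_calls({"a", "b"}, u), self.make_calls({"b", "c"}, u)]
        assert rf.detected_set(reps, "any") == {"a", "b", "c"}
        assert rf.detected_set(reps, "all") == {"b"}

    def test_single_replicate_all_mode(self):
        u = ["a", "b"]
        assert rf.detected_set([self.make_calls({"a"}, u)], "all") == {"a"}

    def test_differing_universes_warn_and_restrict(self):
        a = self.make_calls({"a"}, ["a", "b"])
        b = self.make_calls({"a", "c"}, ["a", "c"])
        with pytest.warns(UserWarning, match="universes differ"):
            assert rf.detected_set([a, b], "any") == {"a"}

    def test_tissue_partition_regions(self):
        sets = {"t1": {"a", "b", "c"}, "t2": {"b", "c", "d"}, "t3": {"c", "e"}}
        ts = rf.tissue_partition(sets)
        assert ts.unique == {"t1": {"a"}, "t2": {"d"}, "t3": {"e"}}
        assert ts.shared_all == {"c"}
        assert ts.venn[frozenset({"t1", "t2", "t3"})] == 1
        assert ts.venn[frozenset({"t1", "t2"})] == 1  # {b}

    def test_identical_sets(self):
        ts = rf.tissue_partition({"x": {"a", "b"}, "y": {"a", "b"}})
        assert ts.unique == {"x": set(), "y": set()}
        assert ts.shared_all == {"a", "b"}

    def test_venn_regions_sum_to_union(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(1000)]
        sets = {
            t: set(rng.choice(genes, size=400, replace=False)) for t in ("t1", "t2", "t3")
        }
        ts = rf.tissue_partition(sets)
        assert sum(ts.venn.values()) == len(set.union(*sets.values()))

    def test_set_overlap(self):
        assert rf.set_overlap({"a", "b", "c"}, {"b", "c", "d"}) == (2, pytest.approx(2 / 3))
        assert rf.set_overlap({"a"}, {"b"}) == (0, 0.0)
        assert rf.set_overlap({"a", "b"}, {"a", "b", "c"})[1] == 1.0
        assert rf.set_overlap(set(), {"a"}) == (0, None)


class TestMarkerCandidates:
    def annotation(self):
        # b: 150 bp same-strand upstream neighbor (excluded);
        # c: exactly 200 bp (retained, rule is strictly <);
        # a: far from everything.
        return genes_df(
            [
                ("up1", "c", 0, 1000, "+"),
                ("b", "c", 1150, 2000, "+"),
                ("up2", "c", 2500, 3000, "+"),
                ("cgene", "c", 3200, 4000, "+"),
                ("a", "c", 10_000, 11_000, "+"),
            ]
        )

    def test_rule_application(self):
        cands = rf.marker_candidates(
            {"a", "b", "cgene"}, [{"b"} | set()], self.annotation()
        )
        # b removed twice over (whole-animal and operon); cgene kept at 200 bp
        assert cands == {"a", "cgene"}

    def test_boundary_exactly_200bp_retained(self):
        cands = rf.marker_candidates({"cgene"}, [], self.annotation())
        assert cands == {"cgene"}

    def test_whole_animal_removal(self):
        cands = rf.marker_candidates({"a", "cgene"}, [{"a"}, set()], self.annotation())
        assert cands == {"cgene"}

    def test_minus_strand_upstream_is_rightward(self):
        genes = genes_df(
            [("m", "c", 1000, 2000, "-"), ("neigh", "c", 2100, 3000, "-")]
        )
        assert rf.marker_candidates({"m"}, [], genes) == set()
        genes2 = genes_df(
            [("m", "c", 1000, 2000, "-"), ("neigh", "c", 2200, 3000, "-")]
        )
        assert rf.marker_candidates({"m"}, [], genes2) == {"m"}

    def test_opposite_strand_neighbor_ignored_by_default(self):
        genes = genes_df(
            [("up1", "c", 0, 1000, "-"), ("g", "c", 1100, 2000, "+")]
        )
        assert rf.marker_candidates({"g"}, [], genes) == {"g"}
        assert rf.marker_candidates({"g"}, [], genes, same_strand_only=False) == set()

    def test_missing_strand_excluded_with_warning(self):
        genes = genes_df([("g", "c", 0, 100, ".")])
        with pytest.warns(UserWarning, match="lack strand"):
            assert rf.marker_candidates({"g"}, [], genes) == set()

    def test_agreement_with_brute_force_on_simulated_operons(self):
        """Planted short-gap pairs and only those fall to the operon rule."""
        from dataclasses import replace

        params = replace(rf.SimParams.tiny(seed=21), short_gap_genes=8)
        sim = rf.simulate_dataset(params)
        gaps = rf.upstream_neighbor_gaps(sim.genes)
        short = set(gaps[gaps < 200].index)
        assert len(short) == 8
        all_ids = set(sim.genes["gene_id"])
        cands = rf.marker_candidates(all_ids, [], sim.genes)
        assert all_ids - cands == short


class TestSubsetSimilarity:
    def test_identical_groups(self):
        res = rf.subset_similarity_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_separated_groups_power(self):
        rng = np.random.default_rng(10)
        res = rf.subset_similarity_test(rng.normal(0, 1, 30), rng.normal(5, 1, 30))
        assert res["p_value"] < 1e-6

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        a = rf.subset_similarity_test(x, y)
        b = rf.subset_similarity_test(y, x)
        assert a["p_value"] == pytest.approx(b["p_value"])
        assert a["t"] == pytest.approx(-b["t"])

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            rf.subset_similarity_test([1.0, 1.0], [1.0, 1.0])
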