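"""Synthetic-data generators: determinism, conservation, truth consistency."""

import numpy as np
import pandas as pd
import pytest

import oometh as om


def _cells_equal(a, b):
    if set(a.sites) != set(b.sites):
        return False
    return all(
        all(np.array_equal(x, y) for x, y in zip(a.sites[c], b.sites[c]))
        for c in a.sites
    )


class TestMethylomeSimulation:
    def test_bit_identical_given_seed(self):
        cfg = om.SimConfig(seed=5, n_cpgs=5_000, x_cpgs=1_000, cells_per_condition=3,
                           n_spiked_tiles=3)
        g1, c1, t1 = om.simulate_methylomes(cfg)
        g2, c2, t2 = om.simulate_methylomes(cfg)
        for chrom in g1.chrom_names:
            np.testing.assert_array_equal(g1.cpg_positions[chrom], g2.cpg_positions[chrom])
            np.testing.assert_array_equal(g1.latent[chrom], g2.latent[chrom])
        pd.testing.assert_frame_equal(t1.differential_tiles, t2.differential_tiles)
        assert all(
            _cells_equal(x, y) for x, y in zip(c1["A"] + c1["B"], c2["A"] + c2["B"])
        )

    def test_call_conservation(self, small_sim):
        """Methylated + unmethylated calls equal the observed CpG count."""
        _, cells, _ = small_sim
        for cell in cells["A"][:4]:
            meth, total = cell.counts()
            assert total == cell.n_sites
            assert 0 <= meth <= total

    def test_coverage_binomial_expectation(self):
        cfg = om.SimConfig(seed=7, n_chromosomes=1, n_cpgs=10_000, include_x=False,
                           cells_per_condition=20, coverage=0.2, n_spiked_tiles=0)
        _, cells, _ = om.simulate_methylomes(cfg)
        observed = np.array([c.n_sites for c in cells["A"]])
        sd = np.sqrt(10_000 * 0.2 * 0.8)
        assert abs(observed.mean() - 2_000) < 3 * sd

    def test_zero_effect_means_no_differential_tiles(self):
        cfg = om.SimConfig(seed=3, n_cpgs=5_000, x_cpgs=1_000, cells_per_condition=2,
                           effect_size=0.0)
        _, _, truth = om.simulate_methylomes(cfg)
        assert truth.differential_tiles.empty

    def test_hyper_domain_pooled_level(self):
        # enough domains that the per-domain Beta levels average out
        cfg = om.SimConfig(seed=11, n_chromosomes=2, n_cpgs=150_000, include_x=False,
                           cells_per_condition=40, coverage=0.15, n_spiked_tiles=0,
                           hyper_level=0.85)
        genome, cells, _ = om.simulate_methylomes(cfg)
        meth = total = 0
        for cell in cells["A"]:
            for chrom, (pos, m, u) in cell.sites.items():
                idx = np.searchsorted(genome.cpg_positions[chrom], pos)
                hyper = genome.latent[chrom][idx] > 0.5
                meth += m[hyper].sum()
                total += (m[hyper] + u[hyper]).sum()
        assert 0.80 <= meth / total <= 0.90

    def test_truth_consistency_at_large_n(self):
        """Pooled condition difference at spiked tiles matches the recorded effect."""
        cfg = om.SimConfig(seed=13, n_chromosomes=2, n_cpgs=30_000, include_x=False,
                           cells_per_condition=200, coverage=0.15, n_spiked_tiles=10,
                           effect_size=0.30)
        genome, cells, truth = om.simulate_methylomes(cfg)
        tiles = om.make_tiles(genome)
        qa = om.quantify_methylation(cells["A"], tiles)
        qb = om.quantify_methylation(cells["B"], tiles)
        diff = (qb.frame["fraction"] - qa.frame["fraction"]).to_numpy()
        for tid, delta in truth.differential_tiles.itertuples(index=False):
            assert diff[tid] == pytest.approx(delta, abs=0.03)

    def test_spiked_tiles_avoid_annotations(self, small_sim, small_tiles):
        genome, _, truth = small_sim
        blocked = set()
        for reg in genome.annotations:
            blocked.update(small_tiles.overlapping(reg).tolist())
        assert not blocked.intersection(truth.spiked_tile_ids.tolist())

    def test_block_coverage_mode_hits_rate(self):
        cfg = om.SimConfig(seed=17, n_chromosomes=1, n_cpgs=50_000, include_x=False,
                           cells_per_condition=10, coverage=0.2, n_spiked_tiles=0,
                           coverage_mode="blocks")
        _, cells, _ = om.simulate_methylomes(cfg)
        rate = np.mean([c.n_sites / 50_000 for c in cells["A"]])
        assert rate == pytest.approx(0.2, abs=0.05)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            om.SimConfig(seed=1, coverage=0.0)
        with pytest.raises(ValueError):
            om.SimConfig(seed=1, cells_per_condition=0)
        with pytest.raises(ValueError):
            om.SimConfig(seed=1, effect_size=1.5)
        with pytest.raises(ValueError):
            om.SimConfig(seed=None)


class TestCtSimulation:
    def test_noiseless_allelic_round_trip(self):
        table, _ = om.simulate_ct_experiment(
            paternal_fraction={"g": 0.8}, noise_sd=0.0, seed=2
        )
        wide = om.collapse_technical(table).pivot_table(
            index="sample", columns="gene", values="ct"
        )
        split = om.allelic_split(wide["g_mat"], wide["g_pat"])
        np.testing.assert_allclose(split["paternal_pct"], 80.0)

    def test_noiseless_fold_change_gives_exact_ddct(self):
        table, _ = om.simulate_ct_experiment(
            rel_expr={"g": {"A": 1.0, "B": 4.0}}, noise_sd=0.0, seed=2
        )
        _, delta = om.relative_expression(
            om.collapse_technical(table), ["Actb", "18S", "Hprt"]
        )
        means = delta.groupby("group")["delta_ct"].mean()
        assert means["B"] - means["A"] == pytest.approx(-2.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            om.simulate_ct_experiment(n_replicates=0, seed=1)
        with pytest.raises(ValueError):
            om.simulate_ct_experiment(paternal_fraction={"g": 1.0}, seed=1)
        with pytest.raises(ValueError):
            om.simulate_ct_experiment(noise_sd=-0.1, seed=1)

    def test_deterministic(self):
        t1, _ = om.simulate_ct_experiment(rel_expr={"g": 2.0}, seed=5)
        t2, _ = om.simulate_ct_experiment(rel_expr={"g": 2.0}, seed=5)
        pd.testing.assert_frame_equal(t1, t2)


class TestCloneSimulation:
    @pytest.mark.parametrize("p, expected", [(1.0, 100.0), (0.0, 0.0)])
    def test_degenerate_probabilities(self, p, expected):
        clones = om.simulate_clone_sets(20, 24, p, seed=1)
        _, total = om.clone_levels(clones)
        assert total == expected

    def test_region_total_concentrates_at_half(self):
        """24 clones x 20 CpGs at p = 0.5: total within [40, 60]% nearly always."""
        inside = sum(
            40.0 <= om.clone_levels(om.simulate_clone_sets(20, 24, 0.5, seed=s))[1] <= 60.0
            for s in range(50)
        )
        assert inside >= 48

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            om.simulate_clone_sets(0, 24, 0.5, seed=1)


class TestCountSimulation:
    def test_null_pvalues_roughly_uniform(self):
        counts, groups, _ = om.simulate_count_matrix(
            n_features=1_000, samples_per_group=(4, 4), seed=3
        )
        result = om.cpm_and_test(counts, groups)
        p = result["p_value"].to_numpy()
        from scipy import stats

        assert stats.kstest(p, "uniform").statistic < 0.1

    def test_null_feature_cpm_matches_arithmetic(self):
        counts, _, _ = om.simulate_count_matrix(
            n_features=500, baseline_mean=100.0, seed=5
        )
        mat = om.cpm(counts)
        sample = counts.columns[0]
        expected = counts[sample] / counts[sample].sum() * 1e6
        np.testing.assert_allclose(mat[sample], expected)

    def test_spiked_features_rank_high(self):
        """Fold change 8 at dispersion 0.1: spiked features land in the top decile."""
        hits = 0
        fold = {i: 8.0 for i in range(10)}
        for s in range(20):
            counts, groups, _ = om.simulate_count_matrix(
                n_features=500, dispersion=0.1, fold_changes=fold, seed=100 + s
            )
            result = om.cpm_and_test(counts, groups)
            rank = result["t"].abs().rank(ascending=False)
            hits += (rank.iloc[:10] <= 50).all()
        assert hits >= 19

    def test_validation(self):
        with pytest.raises(ValueError):
            om.simulate_count_matrix(dispersion=0.0, seed=1)
        with pytest.raises(ValueError):
            om.simulate_count_matrix(fold_changes={5000: 2.0}, seed=1)
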