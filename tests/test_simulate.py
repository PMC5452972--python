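"""Rate-profile draws, sequence evolution, and grid bookkeeping."""

import numpy as np
import pytest
import scipy.linalg
import scipy.stats

from siterates import (
    GridConfig,
    MutSelSiteProfile,
    SiteRateProfile,
    draw_profiles,
    enumerate_grid,
    evolve,
    generate_grid,
    make_balanced_tree,
    mg94_matrix,
    tree_grid,
)
from siterates.simulate import (
    HIV1_GAMMA_PARAMS,
    BENCHMARK_BRANCH_LENGTHS,
    BENCHMARK_TAXA_COUNTS,
    build_site_models,
    benchmark_uniform_design,
    simulate_replicate,
    true_rates,
)

N_CODONS = 61
UNIFORM = np.full(N_CODONS, 1.0 / N_CODONS)


class TestDrawProfiles:
    def test_constant_ds_regime(self, rng):
        profiles = draw_profiles("constant_dS", 200, rng=rng)
        assert all(p.dS == 1.0 for p in profiles)
        dn = np.array([p.dN for p in profiles])
        assert np.all((0.1 <= dn) & (dn <= 1.6))

    def test_variable_ds_regime(self, rng):
        profiles = draw_profiles("variable_dS", 200, rng=rng)
        for p in profiles:
            assert 0.5 <= p.dS <= 2.0
            assert 0.1 <= p.ratio <= 1.6
            assert p.dN == p.dS * p.ratio  # exact by construction

    def test_gamma_regime_mean(self, rng):
        # integrase setting: Gamma(shape 0.312, rate 1.027) has mean alpha/beta
        alpha, beta = HIV1_GAMMA_PARAMS["integrase"]
        n = 100_000
        profiles = draw_profiles(
            "gamma", n, {"gamma_shape": alpha, "gamma_rate": beta}, rng
        )
        ratios = np.array([p.ratio for p in profiles])
        se = np.sqrt(alpha / beta ** 2 / n)
        assert abs(ratios.mean() - alpha / beta) < 3 * se

    def test_mutsel_regimes(self, rng):
        neutral = draw_profiles("mutsel_neutral_syn", 5, rng=rng)
        assert all(isinstance(p, MutSelSiteProfile) for p in neutral)
        # neutral synonymous codons: equal fitness within each synonymous class
        from siterates.genetic_code import CODON_AA_INDEX

        for p in neutral:
            for aa in range(20):
                cls = p.fitness[CODON_AA_INDEX == aa]
                assert np.ptp(cls) < 1e-12
        biased = draw_profiles("mutsel_codon_bias", 5, rng=rng)
        spread = [np.ptp(p.fitness[CODON_AA_INDEX == 10]) for p in biased]  # Leu, 6 codons
        assert max(spread) > 0  # synonymous fitness differences exist

    def test_unknown_regime_rejected(self, rng):
        with pytest.raises(ValueError, match="regime"):
            draw_profiles("bogus", 10, rng=rng)


class TestEvolve:
    def test_zero_length_edges_copy_root(self, rng):
        tree = make_balanced_tree(4, 1.0)
        tree.edge_length = np.zeros(tree.n_nodes)  # exp(0) = identity
        qs, pis = build_site_models([SiteRateProfile(dN=0.7) for _ in range(20)])
        aln = evolve(tree, qs, rng, stationary=pis)
        assert np.all(aln.states == aln.states[0])

    def test_output_shape(self, rng):
        tree = make_balanced_tree(8, 0.2)
        profiles = draw_profiles("constant_dS", 100, rng=rng)
        qs, pis = build_site_models(profiles)
        aln = evolve(tree, qs, rng, stationary=pis)
        assert aln.states.shape == (8, 100)
        assert aln.labels == tree.leaf_labels

    def test_determinism(self):
        tree = make_balanced_tree(8, 0.2)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            profiles = draw_profiles("constant_dS", 30, rng=rng)
            qs, pis = build_site_models(profiles)
            out.append(evolve(tree, qs, rng, stationary=pis).states)
        np.testing.assert_array_equal(out[0], out[1])

    def test_cherry_joint_distribution_matches_expm_oracle(self):
        # all sites share one model: the empirical joint leaf-pair pattern
        # distribution must match pi_i [exp(Q * 2b)]_ij from a dense expm
        b = 0.3
        tree = make_balanced_tree(2, b)
        q = mg94_matrix(SiteRateProfile(dN=0.5), UNIFORM)
        n = 40_000
        rng = np.random.default_rng(1234)
        aln = evolve(tree, [q] * n, rng, stationary=[UNIFORM] * n)
        joint = np.zeros((N_CODONS, N_CODONS))
        np.add.at(joint, (aln.states[0], aln.states[1]), 1.0)
        joint /= n
        theory = UNIFORM[:, None] * scipy.linalg.expm(q * 2 * b)
        tol = 5 * np.sqrt(theory * (1 - theory) / n) + 2.0 / n
        assert np.all(np.abs(joint - theory) <= tol)

    def test_site_shuffle_shuffles_columns_identically(self, rng):
        # per-site independence: permuting (model, stream) pairs permutes
        # the realized columns exactly
        tree = make_balanced_tree(8, 0.3)
        profiles = draw_profiles("constant_dS", 25, rng=rng)
        qs, pis = build_site_models(profiles)
        fresh = lambda: np.random.default_rng(99).spawn(25)  # noqa: E731
        base = evolve(tree, qs, stationary=pis, site_rngs=fresh())
        perm = np.random.default_rng(5).permutation(25)
        streams = fresh()
        shuffled = evolve(
            tree,
            [qs[k] for k in perm],
            stationary=[pis[k] for k in perm],
            site_rngs=[streams[k] for k in perm],
        )
        np.testing.assert_array_equal(shuffled.states, base.states[:, perm])

    def test_substitution_counts_track_dn(self):
        # rank property: columns with larger true dN show more amino-acid
        # variation on a diverged tree, on average
        cfg = GridConfig(
            branch_lengths=(0.64,), taxa_counts=(64,), n_replicates=1, master_seed=8
        )
        aln, profiles, truth = simulate_replicate(cfg, 0, 0)
        aa = aln.translate().states
        distinct = np.array([np.unique(aa[:, k]).size for k in range(aa.shape[1])])
        rho = scipy.stats.spearmanr(truth, distinct).statistic
        assert rho > 0.5


class TestGrid:
    def test_benchmark_tree_grid_has_forty_trees(self):
        grid = tree_grid()
        assert len(grid) == 40
        assert len(BENCHMARK_BRANCH_LENGTHS) == 5 and len(BENCHMARK_TAXA_COUNTS) == 8
        for (b, t), tree in grid.items():
            assert tree.n_taxa == t and tree.n_edges == 2 * t - 2

    def test_uniform_design_enumerates_2500_alignments(self):
        configs = benchmark_uniform_design()
        total = sum(len(enumerate_grid(c)) for c in configs)
        assert total == 2500
        for c in configs:
            assert len(enumerate_grid(c)) == 50 * 5 * 5

    def test_single_cell_grid_and_byte_reproducibility(self, tmp_path):
        cfg = GridConfig(
            branch_lengths=(0.16,),
            taxa_counts=(4,),
            n_sites=10,
            n_replicates=1,
            master_seed=17,
        )
        reg1 = generate_grid(cfg, tmp_path / "a")
        assert len(reg1) == 1
        generate_grid(cfg, tmp_path / "b")
        f1 = (tmp_path / "a" / reg1.iloc[0]["aln_path"]).read_bytes()
        f2 = (tmp_path / "b" / reg1.iloc[0]["aln_path"]).read_bytes()
        assert f1 == f2
        t1 = (tmp_path / "a" / reg1.iloc[0]["truth_path"]).read_bytes()
        t2 = (tmp_path / "b" / reg1.iloc[0]["truth_path"]).read_bytes()
        assert t1 == t2

    def test_partial_run_rejected_unless_resumed(self, tmp_path):
        cfg = GridConfig(
            branch_lengths=(0.16,), taxa_counts=(4,), n_sites=5,
            n_replicates=1, master_seed=1,
        )
        generate_grid(cfg, tmp_path)
        with pytest.raises(FileExistsError):
            generate_grid(cfg, tmp_path)
        generate_grid(cfg, tmp_path, resume=True)  # no error

    def test_truth_files_store_rates(self, tmp_path):
        import pandas as pd

        cfg = GridConfig(
            branch_lengths=(0.04,), taxa_counts=(4,), n_sites=8,
            n_replicates=1, master_seed=2,
        )
        reg = generate_grid(cfg, tmp_path)
        truth = pd.read_csv(tmp_path / reg.iloc[0]["truth_path"], sep="\t")
        assert list(truth.columns) == ["site", "dN", "dS", "true_rate"]
        np.testing.assert_allclose(truth["true_rate"], truth["dN"] / truth["dS"])

    def test_config_validation_and_yaml_roundtrip(self, tmp_path):
        with pytest.raises(ValueError, match="gamma"):
            GridConfig(regime="gamma")
        with pytest.raises(ValueError, match="regime"):
            GridConfig(regime="nope")
        cfg = GridConfig(
            regime="gamma", gamma_shape=0.35, gamma_rate=0.249,
            taxa_counts=(16, 32, 64, 128, 256), master_seed=3,
        )
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert GridConfig.from_yaml(path) == cfg

    def test_mutsel_truth_uses_expected_dnds(self, rng):
        from siterates import expected_dnds, hky_mutation_matrix

        profiles = draw_profiles("mutsel_neutral_syn", 3, rng=rng)
        truth = true_rates(profiles)
        mu = hky_mutation_matrix()
        expected = [expected_dnds(p, mu) for p in profiles]
        np.testing.assert_allclose(truth, expected, rtol=1e-12)
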