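import math

import numpy as np
import pytest
from scipy import stats

from assemblyscape import (ScenarioConfig, assemble_communities, evolve_traits,
                           scenario_preset, simulate_landscape, simulate_scenario,
                           simulate_tree)
from assemblyscape.synthetic_data import SCENARIO_NAMES


class TestSimulateTree:
    def test_cherry_distance_two(self):
        tree = simulate_tree(2, seed=0)
        d = tree.tip_tip_distances().data
        assert d[0, 1] == pytest.approx(2.0)

    def test_reproducible_topology(self):
        a = simulate_tree(100, seed=42).__str__()
        b = simulate_tree(100, seed=42).__str__()
        assert a == b

    def test_ultrametric_unit_height(self):
        tree = simulate_tree(50, seed=7)
        heights = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
        np.testing.assert_allclose(heights, 1.0, atol=1e-9)

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1)


class TestEvolveTraits:
    def test_zero_rate_all_zero(self):
        tree = simulate_tree(20, seed=1)
        traits = evolve_traits(tree, 0.0, seed=2)
        assert (traits == 0).all()

    def test_cherry_correlation_matches_shared_path(self, tmp_path):
        """Trait correlation across replicates = shared / total path length."""
        from assemblyscape import read_newick
        p = tmp_path / "cherry.nwk"
        p.write_text("((A:0.3,B:0.3):0.7,C:1.0);\n")
        tree = read_newick(p)
        vals = np.array([evolve_traits(tree, 1.0, seed=k)[["A", "B"]].to_numpy()
                         for k in range(1000)])
        r = np.corrcoef(vals[:, 0], vals[:, 1])[0, 1]
        assert r == pytest.approx(0.7, abs=0.06)

    def test_tip_variance_matches_bm_rate(self, tmp_path):
        from assemblyscape import read_newick
        p = tmp_path / "cherry.nwk"
        p.write_text("((A:0.3,B:0.3):0.7,C:1.0);\n")
        tree = read_newick(p)
        rate = 2.5
        vals = np.array([evolve_traits(tree, rate, seed=k)["A"] for k in range(1000)])
        assert vals.var() == pytest.approx(rate * 1.0, rel=0.15)

    def test_early_burst_reduces_within_clade_variance(self):
        tree = simulate_tree(60, seed=3)
        bm = evolve_traits(tree, 1.0, seed=4, conservatism=0.0)
        eb = evolve_traits(tree, 8.0 / (1 - math.exp(-8)), seed=4, conservatism=8.0)
        # same total-variance scale, but EB concentrates divergence deep in
        # the tree: sister tips are much closer in trait than under BM
        sisters = [(a.name, b.name) for a, b in
                   ((n.children[0], n.children[1]) for n in tree.non_tips())
                   if a.is_tip() and b.is_tip()]
        d_bm = np.mean([abs(bm[x] - bm[y]) for x, y in sisters])
        d_eb = np.mean([abs(eb[x] - eb[y]) for x, y in sisters])
        assert d_eb < d_bm


class TestLandscape:
    def test_uniform_field_constant(self):
        cfg = ScenarioConfig(n_otus=10, n_sites=24, env_field="uniform", seed=1)
        frame = simulate_landscape(cfg)
        assert frame.data["env"].nunique() == 1

    def test_gradient_monotone_in_x(self):
        cfg = ScenarioConfig(n_otus=10, n_sites=30, env_field="gradient", seed=2)
        frame = simulate_landscape(cfg)
        ordered = frame.data.sort_values("x")["env"].to_numpy()
        assert np.all(np.diff(ordered) > 0)

    def test_seed_determinism(self):
        cfg = ScenarioConfig(n_otus=10, n_sites=18, env_field="patchy", seed=3)
        assert simulate_landscape(cfg).data.equals(simulate_landscape(cfg).data)

    def test_occasions_split_evenly(self):
        cfg = ScenarioConfig(n_otus=10, n_sites=24, n_occasions=6, seed=4)
        occ = simulate_landscape(cfg).data["occasion"]
        assert occ.value_counts().nunique() == 1


class TestAssembleCommunities:
    def test_read_totals_exact(self):
        cfg = ScenarioConfig(n_otus=40, n_sites=12, reads_per_sample=500, seed=5)
        table, _, _, _ = simulate_scenario(cfg)
        np.testing.assert_array_equal(table.sample_totals, 500)

    def test_config_seed_determinism(self):
        cfg = ScenarioConfig(n_otus=30, n_sites=10, seed=6)
        t1, _, _, _ = simulate_scenario(cfg)
        t2, _, _, _ = simulate_scenario(cfg)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_neutral_reduction_chi2(self):
        """No selection + full mixing -> iid multinomials from the pool
        (chi-square goodness of fit does not reject at alpha = 0.01)."""
        cfg = ScenarioConfig(n_otus=30, n_sites=40, reads_per_sample=2000,
                             dispersal_mix=1.0, selection_sigma=math.inf,
                             drift_generations=0, seed=7)
        table, _, _, truth = simulate_scenario(cfg)
        pooled = table.counts.sum(axis=0).astype(float)
        expected = truth.regional_pool.to_numpy() * pooled.sum()
        keep = expected >= 5
        obs = np.append(pooled[keep], pooled[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        stat = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(stat, len(obs) - 1)
        assert p > 0.01

    def test_strong_selection_picks_nearest_optimum(self):
        """As the niche narrows, each site is dominated by the taxon whose
        optimum maximizes the selection weight at the site's environment."""
        sigma = 0.05
        cfg = ScenarioConfig(n_otus=50, n_sites=8, reads_per_sample=2000,
                             selection_sigma=sigma, env_field="gradient",
                             env_range=1.0, bm_rate=1.0, seed=8)
        table, _, frame, truth = simulate_scenario(cfg)
        traits = truth.trait_optima.to_numpy()
        pool = truth.regional_pool.to_numpy()
        env = truth.env.to_numpy()
        for k in range(table.n_samples):
            log_w = np.log(pool) - (traits - env[k]) ** 2 / (2 * sigma ** 2)
            assert table.counts[k].argmax() == log_w.argmax()

    def test_vanishing_weights_error(self):
        cfg = ScenarioConfig(n_otus=20, n_sites=4, selection_sigma=1e-3,
                             env_field="uniform", env_level=50.0, bm_rate=1.0,
                             seed=9)
        with pytest.raises(ValueError, match="selection_sigma"):
            simulate_scenario(cfg)

    def test_mass_effect_copies_shared_community(self):
        cfg = ScenarioConfig(n_otus=25, n_sites=6, reads_per_sample=400,
                             mass_effect=1.0, seed=10)
        table, _, _, _ = simulate_scenario(cfg)
        # with mass_effect = 1 every site is the same deterministic copy
        assert np.all(table.counts == table.counts[0])


class TestScenarioPresets:
    def test_homogenizing_dispersal_full_mixing(self):
        cfg = scenario_preset("homogenizing_dispersal", seed=1)
        assert cfg.dispersal_mix == 1.0 and cfg.mass_effect > 0

    def test_variable_selection_gradient(self):
        cfg = scenario_preset("variable_selection", seed=1)
        assert cfg.env_field == "gradient"

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_preset("mystery_process")

    @pytest.mark.parametrize("name", SCENARIO_NAMES)
    def test_presets_simulate_at_desk_scale(self, name):
        cfg = scenario_preset(name, seed=2, n_sites=12, n_otus=60)
        table, tree, frame, truth = simulate_scenario(cfg)
        assert table.n_samples == 12 and truth.label == name
        assert len(list(tree.tips())) == 60
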