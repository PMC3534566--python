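import numpy as np
import pytest
from scipy import stats

from pyroclad.ctmc import MkModel, PairModel, simulate_trait
from pyroclad.dec import DecModel
from pyroclad.synthetic_data import (
    SimulationRecipe,
    load_fixture,
    make_fixture,
    simulate_correlated_traits,
    simulate_ranges,
    simulate_tree,
    write_fixture,
)
from pyroclad.treeio import parse_newick, write_newick


class TestRecipe:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationRecipe(n_tips=3)
        with pytest.raises(ValueError):
            SimulationRecipe(birth=-0.1)
        with pytest.raises(ValueError):
            SimulationRecipe(birth=0.0)


class TestSimulateTree:
    def test_tip_count_and_crown_age(self):
        t = simulate_tree(SimulationRecipe(n_tips=4, crown_age=113.0, seed=1))
        assert t.n_tips == 4
        assert t.root_age == pytest.approx(113.0, abs=1e-9)

    def test_deterministic_newick(self):
        r = SimulationRecipe(n_tips=30, crown_age=113.0, seed=5)
        assert write_newick(simulate_tree(r)) == write_newick(simulate_tree(r))

    def test_ultrametric_and_labeled(self):
        t = simulate_tree(SimulationRecipe(n_tips=25, crown_age=113.0, seed=9))
        assert all(lbl.startswith("G") for lbl in t.tip_labels)
        assert len(set(t.tip_labels)) == 25

    def test_with_extinction_still_reaches_target(self):
        t = simulate_tree(SimulationRecipe(n_tips=20, crown_age=100.0, birth=0.08,
                                           death=0.02, seed=3))
        assert t.n_tips == 20
        assert t.root_age == pytest.approx(100.0, abs=1e-9)

    def test_yule_ltt_grows_log_linearly(self):
        # pure birth: log lineage count through time is ~linear with
        # positive slope
        t = simulate_tree(SimulationRecipe(n_tips=120, crown_age=113.0, seed=13))
        node_ages = sorted(
            (float(t.ages[v]) for v in t.internal_indices()), reverse=True
        )
        times = [t.root_age - a for a in node_ages]  # time since crown
        counts = np.arange(2, 2 + len(times))
        slope, _, r, _, _ = stats.linregress(times, np.log(counts))
        assert slope > 0
        assert r > 0.95

    def test_habitat_linked_rates_return_states(self):
        tree, hab = simulate_tree(
            SimulationRecipe(n_tips=40, crown_age=113.0, seed=17,
                             habitat_birth_multiplier=4.0,
                             habitat_switch_nf=0.02),
            return_habitats=True,
        )
        assert set(hab) == set(tree.tip_labels)
        assert set(hab.values()) <= {"F", "N"}


class TestCorrelatedTraits:
    def test_deterministic(self, tree80):
        pm = PairModel(np.full(8, 0.02))
        a = simulate_correlated_traits(tree80, pm, seed=3)
        b = simulate_correlated_traits(tree80, pm, seed=3)
        assert np.array_equal(a[0], b[0])

    def test_independent_model_near_zero_association(self):
        pm = PairModel.independent(0.02, 0.02, 0.02, 0.02)
        phis = []
        for seed in range(50):
            tree = simulate_tree(SimulationRecipe(n_tips=60, crown_age=113.0, seed=500 + seed))
            s, _ = simulate_correlated_traits(tree, pm, seed=seed)
            if len(np.unique(s[:, 0])) > 1 and len(np.unique(s[:, 1])) > 1:
                phis.append(stats.pearsonr(s[:, 0], s[:, 1]).statistic)
        assert abs(np.mean(phis)) < 0.1

    def test_dependent_model_positive_association(self):
        rates = np.array([0.01, 0.01, 0.05, 0.01, 0.005, 0.10, 0.01, 0.005])
        pm = PairModel(rates, dependent=True)
        positive = 0
        n = 50
        for seed in range(n):
            tree = simulate_tree(SimulationRecipe(n_tips=60, crown_age=113.0, seed=900 + seed))
            s, _ = simulate_correlated_traits(tree, pm, seed=seed)
            tab = np.zeros((2, 2))
            for i in range(s.shape[0]):
                tab[s[i, 0], s[i, 1]] += 1
            odds = ((tab[1, 1] + 0.5) * (tab[0, 0] + 0.5)) / ((tab[1, 0] + 0.5) * (tab[0, 1] + 0.5))
            positive += int(odds > 1)
        assert positive >= 45

    def test_stationary_convergence_with_tree_height(self):
        # tip frequency of state 1 approaches the stationary pi1 as the
        # crown age grows
        q01, q10 = 0.05, 0.02
        pi1 = q01 / (q01 + q10)
        devs = []
        for crown in (10.0, 1000.0):
            freqs = []
            for seed in range(20):
                tree = simulate_tree(SimulationRecipe(n_tips=50, crown_age=crown, seed=2000 + seed))
                tips, _ = simulate_trait(tree, MkModel(q01, q10), seed=seed)
                freqs.append(tips.mean())
            devs.append(abs(np.mean(freqs) - pi1))
        assert devs[1] < devs[0]


class TestRangesSimulation:
    def test_deterministic_and_valid_tokens(self, tree80):
        m = DecModel(0.002, 0.02, 0.001, 0.001)
        a, na = simulate_ranges(tree80, m, seed=5)
        b, nb = simulate_ranges(tree80, m, seed=5)
        assert a == b and np.array_equal(na, nb)
        assert set(a) <= {"F", "N", "FN"}
        assert np.all(na > 0)  # no null ranges on the extant tree


class TestFixture:
    def test_loads_cleanly_through_treeio(self, fixture_bundle, tmp_path):
        write_fixture(fixture_bundle, tmp_path)
        loaded = load_fixture(tmp_path)
        assert loaded.tree.n_tips == 80
        assert loaded.tree.root_age == pytest.approx(113.0, abs=1e-6)
        assert set(loaded.traits.trait_names) == {"habitat", "serotiny", "soil_storage", "aril"}
        assert loaded.manifest["synthetic"] is True
        assert loaded.tree.topology_signature() == fixture_bundle.tree.topology_signature()

    def test_manifest_records_truth(self, fixture_bundle):
        man = fixture_bundle.manifest
        clade = man["planted_colonization"]["node"]
        tips = {
            fixture_bundle.tree.nodes[v].label
            for v in fixture_bundle.tree.clade_tips(clade)
        }
        assert tips == set(man["planted_colonization"]["tip_set"])
        assert all(fixture_bundle.ranges[t] in ("F", "FN") for t in tips)
        outside = set(fixture_bundle.tree.tip_labels) - tips
        assert all(fixture_bundle.ranges[t] == "N" for t in outside)

    def test_species_counts_larger_in_fireprone(self, fixture_bundle):
        fire = [c for t, c in fixture_bundle.species_counts.items()
                if fixture_bundle.ranges[t] in ("F", "FN")]
        nonfire = [c for t, c in fixture_bundle.species_counts.items()
                   if fixture_bundle.ranges[t] == "N"]
        assert np.mean(fire) > 2 * np.mean(nonfire)

    def test_reproducible(self):
        a = make_fixture(seed=777)
        b = make_fixture(seed=777)
        assert write_newick(a.tree) == write_newick(b.tree)
        assert a.ranges == b.ranges
        assert a.species_counts == b.species_counts
        for name in a.traits.trait_names:
            assert np.array_equal(a.traits.column(name), b.traits.column(name))
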