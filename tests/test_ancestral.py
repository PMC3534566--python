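import numpy as np
import pytest

from pyroclad.ancestral import (
    assign_nodes,
    assignments_from_posteriors,
    date_origin,
    lineage_timeline,
    propagate_stems,
)
from pyroclad.ctmc import MkModel
from pyroclad.mcmc_engine import McmcConfig, run_chain
from pyroclad.treeio import parse_newick


def make_assignments(tree, p_state1_by_node, threshold=0.95):
    post = {
        v: np.array([1 - p, p]) for v, p in p_state1_by_node.items()
    }
    return assignments_from_posteriors(tree, post, trait="habitat", threshold=threshold)


class TestCorrectedPosteriorRule:
    def test_full_support_passes(self, tree3):
        t = parse_newick("((A:1,B:1)1.0:1,C:2);")
        aset = make_assignments(t, {v: 0.99 for v in t.postorder()})
        internal = t.internal_indices()
        assert all(aset[v].decision == "state-1" for v in internal)

    def test_support_discounts_posterior(self):
        # 0.98 posterior x 0.95 clade support = 0.931 -> below 0.95 threshold
        t = parse_newick("((A:1,B:1)0.95:1,C:2);")
        aset = make_assignments(t, {v: 0.98 for v in t.postorder()})
        inner = [v for v in t.internal_indices() if v != t.root]
        (v,) = inner
        assert aset[v].corrected[1] == pytest.approx(0.931)
        assert aset[v].decision == "ambiguous"

    def test_unit_support_reduces_to_raw_posterior(self, tree3):
        aset = make_assignments(tree3, {v: 0.98 for v in tree3.postorder()})
        for v in tree3.internal_indices():
            assert aset[v].corrected[1] == pytest.approx(0.98)
            assert aset[v].decision == "state-1"

    def test_even_posterior_always_ambiguous(self, tree3):
        aset = make_assignments(tree3, {v: 0.5 for v in tree3.postorder()})
        assert all(a.decision == "ambiguous" for a in aset)

    def test_threshold_range_enforced(self, tree3):
        with pytest.raises(ValueError):
            make_assignments(tree3, {v: 0.9 for v in tree3.postorder()}, threshold=0.4)

    def test_raising_threshold_never_definite(self, tree3):
        probs = {v: 0.96 for v in tree3.postorder()}
        low = make_assignments(tree3, probs, threshold=0.95)
        high = make_assignments(tree3, probs, threshold=0.99)
        for v in tree3.internal_indices():
            if low[v].decision == "ambiguous":
                assert high[v].decision == "ambiguous"

    def test_root_support_is_one(self):
        t = parse_newick("((A:1,B:1)0.8:1,C:2);")
        aset = make_assignments(t, {v: 0.97 for v in t.postorder()})
        assert aset[t.root].clade_pp == 1.0
        assert aset[t.root].decision == "state-1"


class TestStemPropagation:
    def test_probability_constant_along_stem(self, tree3):
        aset = make_assignments(tree3, {v: 0.97 for v in tree3.postorder()})
        profile = propagate_stems(aset)
        inner = [v for v in tree3.internal_indices() if v != tree3.root]
        (v,) = inner  # age 1, stem spans [1, 2)
        for age in (1.0, 1.3, 1.7, 1.999):
            assert profile.probabilities_at(age)[v][1] == pytest.approx(0.97)

    def test_query_at_node_age_reads_node_assignment(self, tree3):
        probs = {v: (0.99 if tree3.ages[v] <= 1.0 else 0.6) for v in tree3.postorder()}
        aset = make_assignments(tree3, probs)
        profile = propagate_stems(aset)
        inner = [v for v in tree3.internal_indices() if v != tree3.root][0]
        assert profile.probabilities_at(tree3.ages[inner])[inner][1] == pytest.approx(0.99)

    def test_values_change_only_at_node_ages(self, fixture_bundle):
        tree = fixture_bundle.tree
        rng = np.random.default_rng(5)
        aset = make_assignments(tree, {v: rng.uniform(0, 1) for v in tree.postorder()})
        profile = propagate_stems(aset)
        node_ages = {round(float(a), 9) for a in tree.ages}
        prev = None
        for age in np.linspace(0, tree.root_age - 1e-6, 400):
            snap = {v: tuple(p) for v, p in profile.probabilities_at(age).items()}
            if prev is not None and snap != prev[1]:
                crossed = [a for a in node_ages if prev[0] < a <= age]
                assert crossed, f"profile changed away from any node age at {age}"
            prev = (age, snap)

    def test_query_beyond_root_rejected(self, tree3):
        aset = make_assignments(tree3, {v: 0.9 for v in tree3.postorder()})
        with pytest.raises(ValueError):
            propagate_stems(aset).probabilities_at(tree3.root_age + 1.0)


class TestDateOrigin:
    def test_all_ambiguous_undetected(self, tree3):
        aset = make_assignments(tree3, {v: 0.6 for v in tree3.postorder()})
        est = date_origin(aset, tree3, derived_state=1)
        assert not est.detected and est.age is None

    def test_root_passing_dates_to_root_age(self, tree3):
        aset = make_assignments(tree3, {v: 0.99 for v in tree3.postorder()})
        est = date_origin(aset, tree3, derived_state=1)
        assert est.age == pytest.approx(tree3.root_age)

    def test_single_derived_clade_dates_to_stem_top(self, fixture_bundle):
        tree = fixture_bundle.tree
        clade = fixture_bundle.manifest["planted_colonization"]["node"]
        derived = set()
        stack = [clade]
        while stack:
            v = stack.pop()
            derived.add(v)
            stack.extend(tree.nodes[v].children)
        probs = {v: (0.99 if v in derived else 0.01) for v in tree.postorder()}
        aset = make_assignments(tree, probs)
        est = date_origin(aset, tree, derived_state=1)
        parent_age = float(tree.ages[tree.nodes[clade].parent])
        assert est.age == pytest.approx(parent_age)
        assert est.node == clade

    def test_interval_passthrough(self, tree3):
        aset = make_assignments(tree3, {v: 0.99 for v in tree3.postorder()})
        est = date_origin(aset, tree3, derived_state=1,
                          age_intervals={tree3.root: (1.8, 2.3)})
        assert est.interval == (1.8, 2.3)


class TestLineageTimeline:
    def _fixture_assignments(self, bundle):
        tree = bundle.tree
        clade = bundle.manifest["planted_colonization"]["node"]
        derived = set()
        stack = [clade]
        while stack:
            v = stack.pop()
            derived.add(v)
            stack.extend(tree.nodes[v].children)
        rng = np.random.default_rng(9)
        probs = {}
        for v in tree.postorder():
            if v in derived:
                probs[v] = 0.99
            else:
                probs[v] = rng.choice([0.01, 0.5])  # mix of definite and ambiguous
        return make_assignments(tree, probs)

    def test_conservation_at_every_gridpoint(self, fixture_bundle):
        aset = self._fixture_assignments(fixture_bundle)
        tl = lineage_timeline(aset, fixture_bundle.tree, interval=10.0)
        cats = [c for c in tl.columns if c not in ("age", "n_stems")]
        assert np.allclose(tl[cats].sum(axis=1), tl["n_stems"])

    def test_present_day_counts_tips(self, fixture_bundle):
        aset = self._fixture_assignments(fixture_bundle)
        tl = lineage_timeline(aset, fixture_bundle.tree, interval=10.0)
        assert tl.loc[tl["age"] == 0.0, "n_stems"].item() == fixture_bundle.tree.n_tips

    def test_two_stems_just_below_root(self, fixture_bundle):
        aset = self._fixture_assignments(fixture_bundle)
        profile = propagate_stems(aset)
        assert len(profile.stems_at(fixture_bundle.tree.root_age - 1e-6)) == 2

    def test_totals_nondecreasing_toward_present_without_extinction(self, fixture_bundle):
        aset = self._fixture_assignments(fixture_bundle)
        tl = lineage_timeline(aset, fixture_bundle.tree, interval=10.0)
        totals = tl["n_stems"].to_numpy()  # rows run root -> present
        assert np.all(np.diff(totals) >= 0)

    def test_bad_interval_rejected(self, fixture_bundle):
        aset = self._fixture_assignments(fixture_bundle)
        with pytest.raises(ValueError):
            lineage_timeline(aset, fixture_bundle.tree, interval=0.0)

    def test_fractional_mode_conserves_mass(self, fixture_bundle):
        aset = self._fixture_assignments(fixture_bundle)
        tl = lineage_timeline(aset, fixture_bundle.tree, interval=10.0, fractional=True)
        cats = [c for c in tl.columns if c not in ("age", "n_stems")]
        assert np.allclose(tl[cats].sum(axis=1), tl["n_stems"])


class TestAssignFromTrace:
    def test_corrected_pp_matches_analytic_posterior_fixed_rates(self):
        # with clade support = 1 and frozen rates the corrected posterior is
        # the analytic marginal node posterior (within Monte-Carlo error)
        tree = parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        states = np.array([1, 0, 1, 0], dtype=np.int8)
        rates = np.array([0.3, 0.2])
        cfg = McmcConfig(iterations=42_000, burn_in=2_000, thin=10, ratedev=1.0,
                         seed=4, fixed_rates=rates)
        trace = run_chain(tree, states, MkModel(0.1, 0.1), cfg)
        aset = assign_nodes(trace, tree, trait="x", tip_states=states)
        exact_cfg = McmcConfig(iterations=300, burn_in=100, thin=100, ratedev=1.0,
                               seed=4, fixed_rates=rates, exact_node_posteriors=True)
        exact = run_chain(tree, states, MkModel(0.1, 0.1), exact_cfg)
        eset = assign_nodes(exact, tree, trait="x", tip_states=states)
        for v in tree.internal_indices():
            assert np.all(np.abs(aset[v].corrected - eset[v].corrected) < 0.03)

    def test_observed_tips_have_certain_states(self, tree3):
        states = np.array([1, 0, 1], dtype=np.int8)
        cfg = McmcConfig(iterations=2_000, burn_in=500, thin=10, ratedev=0.3, seed=1)
        trace = run_chain(tree3, states, MkModel(0.1, 0.1), cfg)
        aset = assign_nodes(trace, tree3, tip_states=states)
        for j, v in enumerate(tree3.tip_indices):
            assert aset[v].posterior[states[j]] == 1.0


class TestTimelinePlot:
    def test_plot_writes_figure(self, tree3, tmp_path):
        from pyroclad.ancestral import plot_timeline

        aset = make_assignments(tree3, {v: 0.97 for v in tree3.postorder()})
        tl = lineage_timeline(aset, tree3, interval=1.0)
        out = tmp_path / "timeline.png"
        plot_timeline(tl, path=out)
        assert out.exists() and out.stat().st_size > 0
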