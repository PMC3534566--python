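"""Seeded generators for chronograms, traits and ranges, plus a bundled
fixture shaped like the empirical use case (a ~80-genus, 113-My family with
habitat, two seed-storage traits and an ant-dispersal trait).

All generators are pure functions of (recipe, seed). The fixture is
explicitly synthetic: taxa are G001..G080 and a manifest records every true
parameter so recovery tests can compare against the simulation truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from pyroclad import ctmc
from pyroclad.dec import CLADOGENESIS, DecModel, dec_generator
from pyroclad.treeio import AMBIGUOUS, Chronogram, Node, TraitTable, write_newick


@dataclass
class SimulationRecipe:
    """Parameters of the synthetic study system.

    Defaults emulate the empirical setting: an 80-tip chronogram with a
    113-My crown age. Birth/death rates are per My; the habitat-linked
    multiplier scales the birth rate of fireprone lineages for
    diversification tests (1.0 = neutral).
    """

    n_tips: int = 80
    crown_age: float = 113.0
    birth: float = 0.033
    death: float = 0.0
    habitat_birth_multiplier: float = 1.0
    habitat_switch_nf: float = 0.01  # N -> F switch rate (joint simulation)
    habitat_switch_fn: float = 0.005  # F -> N
    root_habitat: str = "N"
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        for r in (self.birth, self.death, self.habitat_switch_nf, self.habitat_switch_fn):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.birth <= 0:
            raise ValueError("birth rate must be positive")


class _Lineage:
    __slots__ = ("parent", "habitat", "start")

    def __init__(self, parent: int, habitat: str, start: float):
        self.parent = parent
        self.habitat = habitat
        self.start = start


def _simulate_bd_once(recipe: SimulationRecipe, rng: np.random.Generator):
    """One forward birth-death run from two crown lineages; returns
    (node times, node parents, tips with habitats, stop time) or None on
    extinction."""
    times = [0.0]
    parents = [-1]
    alive = [
        _Lineage(0, recipe.root_habitat, 0.0),
        _Lineage(0, recipe.root_habitat, 0.0),
    ]
    t = 0.0
    while True:
        lam = np.array(
            [recipe.birth * (recipe.habitat_birth_multiplier if ln.habitat == "F" else 1.0) for ln in alive]
        )
        mu = np.full(len(alive), recipe.death)
        sw = np.array(
            [recipe.habitat_switch_nf if ln.habitat == "N" else recipe.habitat_switch_fn for ln in alive]
        )
        total = lam.sum() + mu.sum() + sw.sum()
        t_next = t + rng.exponential(1.0 / total)
        weights = np.concatenate([lam, mu, sw])
        pick = int(rng.choice(weights.size, p=weights / weights.sum()))
        kind, i = pick // len(alive), pick % len(alive)
        if len(alive) == recipe.n_tips and kind != 2:
            # stop just before the event that would change the tip count
            return times, parents, alive, t_next
        t = t_next
        if kind == 0:  # birth
            ln = alive[i]
            node = len(times)
            times.append(t)
            parents.append(ln.parent)
            alive[i] = _Lineage(node, ln.habitat, t)
            alive.append(_Lineage(node, ln.habitat, t))
        elif kind == 1:  # death
            alive.pop(i)
            if len(alive) == 0:
                return None
        else:  # habitat switch
            alive[i].habitat = "F" if alive[i].habitat == "N" else "N"


def _build_chronogram(times, parents, alive, T, crown_age, label_fmt="G{:03d}"):
    """Assemble a pruned, rescaled Chronogram plus the tip habitat map."""
    n_events = len(times)
    children: list[list[int]] = [[] for _ in range(n_events)]
    tip_ids = []
    for ln in alive:
        tid = len(times)
        times.append(T)
        parents.append(ln.parent)
        children.append([])
        children[ln.parent].append(tid)
        tip_ids.append(tid)
    for v in range(1, n_events):
        children[parents[v]].append(v)

    # keep only paths to surviving tips; splice single-child nodes
    keep = set(tip_ids)
    for tid in tip_ids:
        v = parents[tid]
        while v != -1:
            keep.add(v)
            v = parents[v]

    def effective_children(v):
        return [c for c in children[v] if c in keep]

    def splice(v):
        kids = effective_children(v)
        while len(kids) == 1:
            v = kids[0]
            if v in set(tip_ids):
                break
            kids = effective_children(v)
        return v

    root = splice(0)
    nodes: list[Node] = []
    habitat_of: dict[str, str] = {}
    tip_counter = [0]
    hab_by_tid = {tid: ln.habitat for tid, ln in zip(tip_ids, alive)}
    scale = crown_age / (T - times[root])

    def rec(v, parent_idx, parent_time):
        idx = len(nodes)
        bl = (times[v] - parent_time) * scale if parent_idx >= 0 else 0.0
        if v in hab_by_tid:
            tip_counter[0] += 1
            label = label_fmt.format(tip_counter[0])
            nodes.append(Node(idx, parent_idx, [], bl, label, None))
            habitat_of[label] = hab_by_tid[v]
        else:
            nodes.append(Node(idx, parent_idx, [], bl, None, None))
            for c in effective_children(v):
                c2 = splice(c) if c not in hab_by_tid else c
                child_idx = rec(c2, idx, times[v])
                nodes[idx].children.append(child_idx)
        return idx

    rec(root, -1, times[root])
    return Chronogram(nodes, 0), habitat_of


def simulate_tree(recipe: SimulationRecipe, return_habitats: bool = False):
    """Birth-death chronogram conditioned on the recipe's tip count, rescaled
    to the target crown age. With ``return_habitats`` the jointly simulated
    tip habitat states (F/N) are returned as well (used when the recipe links
    birth rates to habitat)."""
    rng = np.random.default_rng([recipe.seed % (2**31), 11])
    for _ in range(recipe.max_retries):
        out = _simulate_bd_once(recipe, rng)
        if out is None:
            continue
        times, parents, alive, T = out
        tree, habitats = _build_chronogram(list(times), list(parents), alive, T, recipe.crown_age)
        if tree.n_tips == recipe.n_tips:
            return (tree, habitats) if return_habitats else tree
    raise RuntimeError(f"tree simulation failed after {recipe.max_retries} retries (extinction too likely)")


def simulate_correlated_traits(tree: Chronogram, pair_model: ctmc.PairModel, seed: int):
    """Joint 4-state simulation of two binary traits on the tree.

    Returns (states, node_states): ``states`` has shape (n_tips, 2) aligned
    with ``tree.tip_labels``; ``node_states`` are the latent joint states at
    every node.
    """
    return ctmc.simulate_trait(tree, pair_model, seed=seed)


def simulate_ranges(tree: Chronogram, model: DecModel, seed: int):
    """Forward DEC simulation on a fixed extant tree: cladogenesis draws at
    nodes, anagenetic range evolution along branches.

    Because every lineage on the tree is extant by construction, branch
    endpoints are drawn from exp(Qt) conditional on not reaching the null
    range (the row restricted to live ranges and renormalized). Returns
    (tip range tokens, node range indices).
    """
    Q = dec_generator(model)
    names = {1: "F", 2: "N", 3: "FN"}
    rng = np.random.default_rng([seed % (2**31), 23])
    from pyroclad.ctmc import transition_probs

    Pcache: dict[float, np.ndarray] = {}

    def P(t):
        if t not in Pcache:
            Pcache[t] = transition_probs(Q, t)
        return Pcache[t]

    node_range = np.zeros(tree.n_nodes, dtype=np.int64)
    node_range[tree.root] = rng.choice([1, 2, 3], p=model.root_prior)
    start_state = np.zeros(tree.n_nodes, dtype=np.int64)  # daughter range after cladogenesis
    for v in tree.preorder():
        if v != tree.root:
            row = P(tree.nodes[v].branch_length)[start_state[v]].copy()
            row[0] = 0.0  # lineage survived: exclude the null range
            node_range[v] = rng.choice(4, p=row / row.sum())
        if not tree.nodes[v].is_tip:
            scens = CLADOGENESIS[int(node_range[v])]
            xl, xr = scens[rng.integers(len(scens))]
            for c, s in zip(tree.nodes[v].children, (xl, xr)):
                start_state[c] = s
    tips = [names[int(node_range[v])] for v in tree.tip_indices]
    return tips, node_range


def simulate_trait_given_habitat(
    tree: Chronogram,
    fire_nodes: set[int],
    q01_fire: float,
    q01_nonfire: float,
    q10: float,
    seed: int,
):
    """Simulate a binary trait whose gain rate depends on the lineage's
    habitat: branches inside ``fire_nodes`` (the planted fireprone clade) use
    ``q01_fire``, all others ``q01_nonfire``. Root starts at state 0."""
    rng = np.random.default_rng([seed % (2**31), 37])
    states = np.full(tree.n_nodes, -1, dtype=np.int64)
    states[tree.root] = 0
    for v in tree.preorder():
        if v == tree.root:
            continue
        q01 = q01_fire if v in fire_nodes else q01_nonfire
        P = ctmc.transition_probs(ctmc.MkModel(q01, q10).q_from_rates([q01, q10]), tree.nodes[v].branch_length)
        row = P[states[tree.nodes[v].parent]]
        states[v] = rng.choice(2, p=row / row.sum())
    return states[tree.tip_indices].astype(np.int8), states


@dataclass
class FixtureBundle:
    """In-memory synthetic dataset plus its ground-truth manifest."""

    tree: Chronogram
    traits: TraitTable
    ranges: dict[str, str]  # taxon -> F/N/FN
    species_counts: dict[str, int]
    manifest: dict = field(default_factory=dict)

    def range_list(self) -> list[str]:
        return [self.ranges[t] for t in self.tree.tip_labels]


def _descendant_set(tree: Chronogram, node: int) -> set[int]:
    out, stack = set(), [node]
    while stack:
        v = stack.pop()
        out.add(v)
        stack.extend(tree.nodes[v].children)
    return out


DEFAULT_FIXTURE_SEED = 777


def make_fixture(seed: int = DEFAULT_FIXTURE_SEED, out_dir: str | Path | None = None) -> FixtureBundle:
    """Build the synthetic study bundle.

    An 80-tip, 113-My pure-birth chronogram; one mid-depth clade planted as a
    non-fireprone -> fireprone colonization (its tips are F, two of them FN
    to mimic mixed genera); serotiny / soil-storage / aril traits simulated
    with habitat-dependent gain rates; species counts larger in fireprone
    lineages. Everything needed by recovery tests (the colonization node's
    tip set, all simulation rates, the seed) is recorded in the manifest.
    """
    rng = np.random.default_rng([seed % (2**31), 101])
    recipe = SimulationRecipe(n_tips=80, crown_age=113.0, birth=0.033, seed=seed)
    tree = simulate_tree(recipe)

    # plant the colonization: the internal clade closest to 18 tips among
    # mid-depth nodes (crown age 30-70 Ma), else closest overall
    def pick_clade():
        cands = []
        for v in tree.internal_indices():
            if v == tree.root:
                continue
            ntips = len(tree.clade_tips(v))
            cands.append((abs(ntips - 18) + (0 if 30 <= tree.ages[v] <= 70 else 100), v))
        return min(cands)[1]

    clade = pick_clade()
    clade_nodes = _descendant_set(tree, clade)
    clade_tip_labels = [tree.nodes[v].label for v in tree.clade_tips(clade)]

    ranges = {}
    mixed = {str(x) for x in rng.choice(clade_tip_labels, size=min(2, max(0, len(clade_tip_labels) - 2)), replace=False)}
    for lab in tree.tip_labels:
        if lab in mixed:
            ranges[lab] = "FN"
        elif lab in clade_tip_labels:
            ranges[lab] = "F"
        else:
            ranges[lab] = "N"

    trait_rates = {
        "serotiny": dict(q01_fire=0.030, q01_nonfire=0.002, q10=0.004),
        "soil_storage": dict(q01_fire=0.030, q01_nonfire=0.002, q10=0.004),
        "aril": dict(q01_fire=0.015, q01_nonfire=0.001, q10=0.004),
    }
    cols: dict[str, np.ndarray] = {}
    habitat_col = np.empty(tree.n_tips, dtype=np.int8)
    for i, lab in enumerate(tree.tip_labels):
        habitat_col[i] = {"F": 1, "N": 0, "FN": AMBIGUOUS}[ranges[lab]]
    cols["habitat"] = habitat_col
    for k, (name, pars) in enumerate(trait_rates.items()):
        tips, _ = simulate_trait_given_habitat(
            tree, clade_nodes, pars["q01_fire"], pars["q01_nonfire"], pars["q10"], seed=seed + 1000 * (k + 1)
        )
        cols[name] = tips
    traits = TraitTable(list(tree.tip_labels), cols)

    species_counts = {}
    for lab in tree.tip_labels:
        if ranges[lab] in ("F", "FN"):
            species_counts[lab] = int(1 + rng.poisson(30))
        else:
            species_counts[lab] = int(1 + rng.poisson(5))

    manifest = {
        "synthetic": True,
        "seed": int(seed),
        "recipe": {
            "n_tips": recipe.n_tips,
            "crown_age_my": recipe.crown_age,
            "birth_rate": recipe.birth,
            "death_rate": recipe.death,
        },
        "crown_age_rescaled": True,
        "planted_colonization": {
            "node": int(clade),
            "node_age_ma": float(tree.ages[clade]),
            "tip_set": sorted(clade_tip_labels),
            "direction": "N->F",
        },
        "mixed_habitat_tips": sorted(mixed),
        "trait_simulation_rates_per_my": trait_rates,
        "species_count_means": {"fireprone": 31, "nonfireprone": 6},
    }

    bundle = FixtureBundle(tree, traits, ranges, species_counts, manifest)
    if out_dir is not None:
        write_fixture(bundle, out_dir)
    return bundle


def write_fixture(bundle: FixtureBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "tree.nwk", "w") as fh:
        fh.write(write_newick(bundle.tree) + "\n")
    bundle.traits.to_frame().to_csv(out / "traits.tsv", sep="\t")
    with open(out / "ranges.tsv", "w") as fh:
        fh.write("taxon\trange\n")
        for t in bundle.tree.tip_labels:
            fh.write(f"{t}\t{bundle.ranges[t]}\n")
    with open(out / "species_counts.tsv", "w") as fh:
        fh.write("taxon\tn_species\n")
        for t in bundle.tree.tip_labels:
            fh.write(f"{t}\t{bundle.species_counts[t]}\n")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(bundle.manifest, fh, sort_keys=True)


def load_fixture(out_dir: str | Path) -> FixtureBundle:
    from pyroclad.treeio import read_newick_file, read_single_column, read_trait_table

    out = Path(out_dir)
    tree = read_newick_file(out / "tree.nwk")
    traits = read_trait_table(out / "traits.tsv")
    ranges = read_single_column(out / "ranges.tsv", "ranges", str)
    counts = read_single_column(out / "species_counts.tsv", "species counts", int)
    with open(out / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    return FixtureBundle(tree, traits, ranges, counts, manifest)
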