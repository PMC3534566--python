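"""Node-level trait assignment, stem propagation, origin dating, timelines.

The assignment rule multiplies each internal node's trait posterior by the
node's clade posterior probability (support for the node's existence in the
source tree); the product — the *corrected* posterior — must exceed a
threshold (default 0.95) for the state to be called unambiguously.

A node's probabilities are retained along its supporting stem (the branch
connecting it to its parent) until the assignment made at the next node
rootward: trait probability is treated as constant between nodes. Stems are
age intervals [node age, parent age) — a query at a node's own age reads
that node's assignment; the conservation property then holds exactly at
every age gridpoint (at age 0 the crossing stems are precisely the tips).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pyroclad.mcmc_engine import Trace
from pyroclad.treeio import AMBIGUOUS, Chronogram

DECISION_AMBIGUOUS = "ambiguous"


@dataclass
class NodeAssignment:
    """Corrected-posterior call for one node and one trait."""

    node: int
    trait: str
    age: float  # Ma
    posterior: np.ndarray  # per-state trait posterior at the node
    clade_pp: float
    decision: str  # "state-<i>" or "ambiguous"

    @property
    def corrected(self) -> np.ndarray:
        return self.posterior * self.clade_pp

    def prob(self, state: int) -> float:
        return float(self.corrected[state])


class AssignmentSet:
    """Per-node assignments for one trait on one tree."""

    def __init__(self, tree: Chronogram, trait: str, assignments: dict[int, NodeAssignment], threshold: float):
        self.tree = tree
        self.trait = trait
        self.by_node = assignments
        self.threshold = threshold

    def __getitem__(self, node: int) -> NodeAssignment:
        return self.by_node[node]

    def __iter__(self):
        return iter(self.by_node.values())

    @property
    def n_states(self) -> int:
        return next(iter(self.by_node.values())).posterior.size

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node in sorted(self.by_node):
            a = self.by_node[node]
            row = {"node": node, "age": a.age, "trait": a.trait}
            for s in range(a.posterior.size):
                row[f"P(state-{s})"] = a.posterior[s]
            row["clade_pp"] = a.clade_pp
            row["max_corrected"] = float(a.corrected.max())
            row["decision"] = a.decision
            rows.append(row)
        return pd.DataFrame(rows)

    def export_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _decide(corrected: np.ndarray, threshold: float) -> str:
    best = int(np.argmax(corrected))
    if corrected[best] > threshold:
        return f"state-{best}"
    return DECISION_AMBIGUOUS


def assign_nodes(
    trace: Trace,
    tree: Chronogram,
    trait: str = "trait",
    threshold: float = 0.95,
    tip_states: np.ndarray | None = None,
) -> AssignmentSet:
    """Corrected-posterior assignments for every node.

    Internal nodes take their state posterior from the trace tallies times
    the node's clade support (root support is 1, missing support defaults to
    1). Tips, when ``tip_states`` (aligned with ``tree.tip_labels``) is
    given, carry their observed state with probability 1; ambiguous tips take
    their tallied posterior from the trace.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    post = trace.node_posteriors()
    out: dict[int, NodeAssignment] = {}
    tip_of = {v: i for i, v in enumerate(tree.tip_indices)}
    for v in tree.postorder():
        age = float(tree.ages[v])
        if v in tip_of and tip_states is not None:
            s = int(tip_states[tip_of[v]])
            if s == AMBIGUOUS:
                p = post[v]
                if not np.isfinite(p).all():
                    p = np.full(trace.n_states, 1.0 / trace.n_states)
            else:
                p = np.zeros(trace.n_states)
                p[s] = 1.0
            pp = 1.0
        else:
            p = post[v]
            if not np.isfinite(p).all():
                raise ValueError(f"trace has no tallies for node {v}")
            pp = tree.clade_pp_or_default(v)
        corrected = p * pp
        out[v] = NodeAssignment(v, trait, age, p, pp, _decide(corrected, threshold))
    return AssignmentSet(tree, trait, out, threshold)


def assignments_from_posteriors(
    tree: Chronogram,
    posteriors: dict[int, np.ndarray],
    trait: str = "trait",
    threshold: float = 0.95,
) -> AssignmentSet:
    """Build an :class:`AssignmentSet` from explicit per-node posteriors
    (used by the DEC route and by tests with analytic posteriors)."""
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    out = {}
    for v, p in posteriors.items():
        p = np.asarray(p, dtype=float)
        pp = tree.clade_pp_or_default(v)
        out[v] = NodeAssignment(v, trait, float(tree.ages[v]), p, pp, _decide(p * pp, threshold))
    return AssignmentSet(tree, trait, out, threshold)


class StemProfile:
    """Piecewise-constant trait probabilities along every stem.

    The stem of node v spans ages [age(v), age(parent(v))) and carries v's
    corrected state probabilities; the root has no stem.
    """

    def __init__(self, assignments: AssignmentSet):
        self.assignments = assignments
        self.tree = assignments.tree

    def stems_at(self, age: float) -> list[int]:
        """Nodes whose stem crosses the query age."""
        tree = self.tree
        if age > tree.root_age + 1e-9:
            raise ValueError(f"query age {age} exceeds root age {tree.root_age}")
        out = []
        for v in tree.postorder():
            if v == tree.root:
                continue
            lo = tree.ages[v]
            hi = tree.ages[tree.nodes[v].parent]
            if lo <= age < hi:
                out.append(v)
        return out

    def probabilities_at(self, age: float) -> dict[int, np.ndarray]:
        """Corrected state probabilities of every stem crossing ``age``."""
        return {v: self.assignments[v].corrected for v in self.stems_at(age)}

    def decisions_at(self, age: float) -> dict[int, str]:
        return {v: self.assignments[v].decision for v in self.stems_at(age)}


def propagate_stems(assignments: AssignmentSet, tree: Chronogram | None = None) -> StemProfile:
    """Constant-between-nodes propagation of node probabilities along stems."""
    if tree is not None and tree is not assignments.tree:
        raise ValueError("assignments were computed on a different tree")
    missing = [v for v in assignments.tree.postorder() if v not in assignments.by_node]
    if missing:
        raise ValueError(f"assignments missing for nodes {missing}")
    return StemProfile(assignments)


@dataclass
class OriginEstimate:
    """Age of the oldest point assigned the derived state."""

    trait: str
    derived_state: int
    age: float | None  # Ma; None when undetected
    node: int | None  # oldest passing node
    interval: tuple[float, float] | None = None  # age uncertainty passthrough

    @property
    def detected(self) -> bool:
        return self.age is not None


def date_origin(
    assignments: AssignmentSet,
    tree: Chronogram,
    trait: str | None = None,
    derived_state: int = 1,
    age_intervals: dict[int, tuple[float, float]] | None = None,
) -> OriginEstimate:
    """Oldest point where the derived state's corrected probability exceeds
    the assignment threshold.

    Under stem propagation a passing node's probability extends to the top
    of its stem, so the origin age is the passing node's parent age (the
    root age when the root itself passes). ``age_intervals`` (node id ->
    (lo, hi) Ma), when supplied, is passed through for the node whose stem
    top dates the origin.
    """
    trait = trait or assignments.trait
    thr = assignments.threshold
    best_age, best_node = None, None
    for a in assignments:
        if a.prob(derived_state) > thr:
            v = a.node
            top = tree.root_age if v == tree.root else float(tree.ages[tree.nodes[v].parent])
            if best_age is None or top > best_age:
                best_age, best_node = top, v
    interval = None
    if best_node is not None and age_intervals:
        key = tree.nodes[best_node].parent if best_node != tree.root else best_node
        interval = age_intervals.get(key) or age_intervals.get(best_node)
    return OriginEstimate(trait, derived_state, best_age, best_node, interval)


def lineage_timeline(
    assignments: AssignmentSet,
    tree: Chronogram,
    interval: float = 10.0,
    fractional: bool = False,
    state_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Counts of stems per decision category at regular age gridpoints.

    Grid runs from the root age down to 0 in steps of ``interval`` My. Each
    stem crossing a gridpoint is tallied by its decision (per-state or
    ambiguous); with ``fractional`` the corrected probabilities are split
    across states instead, and residual probability goes to ``ambiguous``.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    profile = propagate_stems(assignments)
    k = assignments.n_states
    names = list(state_names) if state_names else [f"state-{s}" for s in range(k)]
    grid = np.arange(0.0, tree.root_age + 1e-9, interval)[::-1]
    rows = []
    for age in grid:
        counts = {nm: 0.0 for nm in names}
        counts["ambiguous"] = 0.0
        stems = profile.stems_at(age)
        for v in stems:
            a = assignments[v]
            if fractional:
                c = a.corrected
                for s in range(k):
                    counts[names[s]] += float(c[s])
                counts["ambiguous"] += max(0.0, 1.0 - float(c.sum()))
            else:
                if a.decision == DECISION_AMBIGUOUS:
                    counts["ambiguous"] += 1
                else:
                    counts[names[int(a.decision.split("-")[1])]] += 1
        row = {"age": float(age), "n_stems": len(stems)}
        row.update(counts)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_timeline(timeline: pd.DataFrame, path=None, ax=None):
    """Minimal stacked lineage-count plot over time (ages reversed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = [c for c in timeline.columns if c not in ("age", "n_stems")]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.stackplot(timeline["age"], [timeline[c] for c in cats], labels=cats)
    ax.set_xlim(timeline["age"].max(), 0)
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("lineages")
    ax.legend(loc="upper left", fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
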