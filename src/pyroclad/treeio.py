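"""Reading, validating and writing time-calibrated trees and trait tables.

Conventions used throughout the package:

* Branch lengths are in millions of years (My); node ages are in Ma with
  every tip at age 0 and the root at the crown age.
* Trees are rooted and ultrametric (all root-to-tip path lengths equal
  within a relative tolerance of the root age).
* Internal-node labels that parse as numbers in [0, 1] are interpreted as
  clade posterior probabilities (node support from the source tree);
  anything else is kept as a plain name.
* Binary trait states are coded 0/1 with -1 for ambiguous ("both"/NA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

ULTRAMETRIC_RTOL = 1e-6
AMBIGUOUS = -1

KNOWN_TRAITS = ("habitat", "serotiny", "soil_storage", "aril")


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally valid tree violating a chronogram invariant."""


class TraitTableError(ValueError):
    """Malformed or inconsistent trait table."""


@dataclass
class Node:
    index: int
    parent: int  # -1 for the root
    children: list[int] = field(default_factory=list)
    branch_length: float = 0.0  # My; 0 for the root
    label: str | None = None  # taxon name for tips, optional name otherwise
    clade_pp: float | None = None  # clade posterior probability, internal only

    @property
    def is_tip(self) -> bool:
        return not self.children


class Chronogram:
    """Rooted ultrametric time tree with ages in Ma (tips at 0).

    Nodes are stored in a flat list; ``postorder`` / ``preorder`` yield node
    indices. Ages are derived from branch lengths: age = root age minus the
    distance from the root.
    """

    def __init__(self, nodes: list[Node], root: int, validate: bool = True):
        self.nodes = nodes
        self.root = root
        self._index()
        if validate:
            self.validate()

    # -- construction helpers -------------------------------------------------

    def _index(self) -> None:
        n = len(self.nodes)
        order: list[int] = []
        stack = [self.root]
        seen = 0
        while stack:
            v = stack.pop()
            order.append(v)
            seen += 1
            stack.extend(self.nodes[v].children)
        if seen != n:
            raise TreeValidationError("disconnected nodes present in tree")
        self._preorder = order
        self._postorder = order[::-1]
        self.tip_indices = [i for i in self._postorder if self.nodes[i].is_tip]
        self.tip_labels = [self.nodes[i].label or "" for i in self.tip_indices]
        # depths and ages
        depth = np.zeros(n)
        for v in self._preorder:
            p = self.nodes[v].parent
            if p >= 0:
                depth[v] = depth[p] + self.nodes[v].branch_length
        self.depths = depth
        self.root_age = float(depth[self.tip_indices].max()) if self.tip_indices else 0.0
        ages = self.root_age - depth
        ages[np.abs(ages) < ULTRAMETRIC_RTOL * max(self.root_age, 1.0)] = 0.0
        self.ages = ages

    def validate(self) -> None:
        for i, nd in enumerate(self.nodes):
            if nd.is_tip:
                if not nd.label:
                    raise TreeValidationError(f"tip node {i} has no label")
            elif len(nd.children) < 2:
                raise TreeValidationError(f"internal node {i} has fewer than 2 children")
            if nd.parent < 0 and i != self.root:
                raise TreeValidationError("multiple roots")
            if nd.branch_length < 0:
                raise TreeValidationError(f"negative branch length at node {i}")
            if nd.clade_pp is not None and not (0.0 <= nd.clade_pp <= 1.0):
                raise TreeValidationError(f"clade_pp outside [0,1] at node {i}")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dupes = sorted({x for x in self.tip_labels if self.tip_labels.count(x) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        # ultrametricity
        d = self.depths[self.tip_indices]
        tol = ULTRAMETRIC_RTOL * max(self.root_age, 1.0)
        if d.max() - d.min() > tol:
            hi = self.tip_labels[int(np.argmax(d))]
            lo = self.tip_labels[int(np.argmin(d))]
            raise TreeValidationError(
                "tree is not ultrametric: root-to-tip distance "
                f"{d.max():.6g} ({hi}) vs {d.min():.6g} ({lo})"
            )

    # -- traversal -------------------------------------------------------------

    def postorder(self):
        return iter(self._postorder)

    def preorder(self):
        return iter(self._preorder)

    def internal_indices(self) -> list[int]:
        return [i for i in self._postorder if not self.nodes[i].is_tip]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def is_bifurcating(self) -> bool:
        return all(len(self.nodes[i].children) == 2 for i in self.internal_indices())

    def clade_tips(self, node: int) -> list[int]:
        """Tip indices descending from (and including, if a tip) ``node``."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.nodes[v].is_tip:
                out.append(v)
            else:
                stack.extend(self.nodes[v].children)
        return out

    def mrca(self, tip_labels: set[str]) -> int:
        """Most recent common ancestor of the named tips."""
        want = set(tip_labels)
        for v in self._postorder:
            got = {self.nodes[t].label for t in self.clade_tips(v)}
            if want <= got:
                return v
        return self.root

    def clade_pp_or_default(self, node: int, default: float = 1.0) -> float:
        if node == self.root:
            return 1.0
        pp = self.nodes[node].clade_pp
        return default if pp is None else pp

    # -- comparison ------------------------------------------------------------

    def topology_signature(self, with_lengths: bool = True, with_pp: bool = True):
        """Order-independent structural summary used for round-trip tests."""

        def rec(v: int):
            nd = self.nodes[v]
            bl = format(nd.branch_length, ".6g") if with_lengths else None
            pp = format(nd.clade_pp, ".6g") if (with_pp and nd.clade_pp is not None) else None
            if nd.is_tip:
                return (nd.label, bl)
            kids = tuple(sorted((rec(c) for c in nd.children), key=repr))
            return (kids, bl, pp)

        return rec(self.root)


# -- Newick I/O ----------------------------------------------------------------


def _label_to_clade_pp(label: str | None) -> tuple[float | None, str | None]:
    """Split an internal-node label into (clade_pp, name)."""
    if label is None or label == "":
        return None, None
    try:
        v = float(label)
    except ValueError:
        return None, label
    if 0.0 <= v <= 1.0:
        return v, None
    return None, label


def parse_newick(text: str) -> Chronogram:
    """Parse a Newick string into a validated :class:`Chronogram`.

    Internal-node labels that read as numbers in [0, 1] become clade
    posterior probabilities. Raises :class:`NewickParseError` for malformed
    input (with the character position where available) and
    :class:`TreeValidationError` for non-ultrametric or otherwise invalid
    trees.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as e:  # dendropy raises several reader error types
        pos = ""
        col = getattr(e, "col_num", None)
        line = getattr(e, "line_num", None)
        if col is not None:
            pos = f" (line {line}, column {col})"
        raise NewickParseError(f"malformed Newick{pos}: {e}") from e

    nodes: list[Node] = []
    index_of: dict[int, int] = {}
    for dnode in dtree.preorder_node_iter():
        idx = len(nodes)
        index_of[id(dnode)] = idx
        parent = index_of[id(dnode.parent_node)] if dnode.parent_node is not None else -1
        bl = float(dnode.edge.length) if dnode.edge.length is not None else 0.0
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            nd = Node(idx, parent, [], bl, label, None)
        else:
            pp, name = _label_to_clade_pp(dnode.label)
            nd = Node(idx, parent, [], bl, name, pp)
        nodes.append(nd)
        if parent >= 0:
            nodes[parent].children.append(idx)
    if not nodes:
        raise NewickParseError("empty Newick input")
    return Chronogram(nodes, root=0)


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def write_newick(tree: Chronogram) -> str:
    """Serialize a :class:`Chronogram` back to Newick.

    Round-trips topology, branch lengths (12 significant digits) and clade
    posterior probabilities through :func:`parse_newick`.
    """

    def rec(v: int) -> str:
        nd = tree.nodes[v]
        if nd.is_tip:
            s = nd.label or ""
        else:
            inner = ",".join(rec(c) for c in nd.children)
            lab = ""
            if nd.clade_pp is not None:
                lab = _fmt(nd.clade_pp)
            elif nd.label:
                lab = nd.label
            s = f"({inner}){lab}"
        if v != tree.root:
            s += f":{_fmt(nd.branch_length)}"
        return s

    return rec(tree.root) + ";"


# -- trait tables ----------------------------------------------------------------


class TraitTable:
    """Taxon-by-trait table of binary states with ambiguity.

    States are coded 0 / 1 / :data:`AMBIGUOUS` (-1). ``traits`` maps trait
    name to an ``int8`` array aligned with ``taxa``.
    """

    def __init__(self, taxa: list[str], traits: dict[str, np.ndarray]):
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise TraitTableError(f"duplicate taxon rows: {dupes}")
        self.taxa = list(taxa)
        self.traits = {k: np.asarray(v, dtype=np.int8) for k, v in traits.items()}
        for name, col in self.traits.items():
            if col.shape != (len(taxa),):
                raise TraitTableError(f"trait '{name}' length mismatch")
            bad = ~np.isin(col, [0, 1, AMBIGUOUS])
            if bad.any():
                raise TraitTableError(f"trait '{name}' contains non-binary states")
            observed = col[col != AMBIGUOUS]
            if observed.size and (not (observed == 0).any() or not (observed == 1).any()):
                warnings.warn(f"invariant trait '{name}': column lacks both 0 and 1 states")

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)

    def column(self, trait: str) -> np.ndarray:
        return self.traits[trait]

    def column_for_tree(self, trait: str, tree: Chronogram) -> np.ndarray:
        """Trait states in the tree's tip order; strict 1:1 taxon join."""
        pos = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in tree.tip_labels if t not in pos]
        if missing:
            raise TraitTableError(f"taxa on tree but missing from trait table: {missing}")
        extra = set(self.taxa) - set(tree.tip_labels)
        if extra:
            raise TraitTableError(f"taxa in trait table but not on tree: {sorted(extra)}")
        col = self.traits[trait]
        return np.array([col[pos[t]] for t in tree.tip_labels], dtype=np.int8)

    def to_frame(self) -> pd.DataFrame:
        rep = {0: "0", 1: "1", AMBIGUOUS: "both"}
        data = {name: [rep[int(x)] for x in col] for name, col in self.traits.items()}
        return pd.DataFrame(data, index=pd.Index(self.taxa, name="taxon"))


_TOKEN_MAP = {"0": 0, "1": 1, "both": AMBIGUOUS, "na": AMBIGUOUS}


def read_trait_table(path_or_buffer) -> TraitTable:
    """Read a tab-delimited trait table (taxon column + one column per trait).

    Cell tokens: ``0``, ``1``, ``both`` (ambiguous), ``NA`` (ambiguous, with a
    warning). Lines starting with ``#`` are ignored.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise TraitTableError("trait table needs a taxon column plus at least one trait column")
    taxon_col = df.columns[0]
    taxa = df[taxon_col].astype(str).tolist()
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise TraitTableError(f"duplicate taxon rows: {dupes}")
    traits: dict[str, np.ndarray] = {}
    for name in df.columns[1:]:
        vals = np.empty(len(taxa), dtype=np.int8)
        n_na = 0
        for i, raw in enumerate(df[name]):
            tok = str(raw).strip().lower()
            if tok not in _TOKEN_MAP and tok != "nan":
                raise TraitTableError(
                    f"unknown state token '{raw}' at row {i + 1} (taxon {taxa[i]}), column '{name}'"
                )
            if tok in ("na", "nan"):
                n_na += 1
                vals[i] = AMBIGUOUS
            else:
                vals[i] = _TOKEN_MAP[tok]
        if n_na:
            warnings.warn(f"trait '{name}': {n_na} NA cells treated as ambiguous")
        traits[name] = vals
    return TraitTable(taxa, traits)


def write_trait_table(table: TraitTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t")


def read_newick_file(path) -> Chronogram:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: Chronogram, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(tree) + "\n")


def read_single_column(path_or_buffer, value_name: str, cast=str) -> dict[str, object]:
    """Read a two-column TSV (taxon, value) into a dict; '#' comments ignored."""
    df = pd.read_csv(path_or_buffer, sep="\t", comment="#", dtype=str)
    if df.shape[1] != 2:
        raise TraitTableError(f"{value_name} table must have exactly two columns")
    out: dict[str, object] = {}
    for _, row in df.iterrows():
        taxon = str(row.iloc[0])
        if taxon in out:
            raise TraitTableError(f"duplicate taxon '{taxon}' in {value_name} table")
        out[taxon] = cast(row.iloc[1])
    return out
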