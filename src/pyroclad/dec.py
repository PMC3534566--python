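"""Two-area dispersal-extinction-cladogenesis (DEC) model for habitat.

Areas are F (fireprone) and N (non-fireprone, essentially rainforest);
ranges are F, N and FN, plus the absorbing null range. Anagenetic range
evolution runs along branches (dispersal adds an area, extinction removes
one); at each speciation event the parent range is inherited under the
classic DEC cladogenesis scenarios: a single-area range is copied to both
daughters, while FN splits by vicariance (F|N, N|F) or peripheral-isolate
subset sympatry (FN|F, F|FN, FN|N, N|FN), all six equiprobable.

"Unconstrained dispersal" means the two dispersal rates d_FN (range F gains
N) and d_NF (range N gains F) are estimated independently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from pyroclad import _pruning
from pyroclad.ctmc import MkModel
from pyroclad.treeio import AMBIGUOUS, Chronogram

RANGES = ("null", "F", "N", "FN")
RANGE_INDEX = {"F": 1, "N": 2, "FN": 3}
_AREAS = {"F": {"F"}, "N": {"N"}, "FN": {"F", "N"}}

# cladogenesis event sets: parent range index -> list of (left, right) range indices
CLADOGENESIS = {
    1: [(1, 1)],
    2: [(2, 2)],
    3: [(1, 2), (2, 1), (3, 1), (1, 3), (3, 2), (2, 3)],
}

RATE_BOUNDS = (1e-9, 10.0)


@dataclass
class DecModel:
    """Two-area DEC rates (per My) and root prior over {F, N, FN}."""

    d_FN: float  # dispersal: range F gains area N
    d_NF: float  # dispersal: range N gains area F
    e_F: float  # local extinction of area F
    e_N: float  # local extinction of area N
    root_prior: np.ndarray | None = None  # over (F, N, FN)

    def __post_init__(self):
        for r in (self.d_FN, self.d_NF, self.e_F, self.e_N):
            if r < 0:
                raise ValueError("DEC rates must be non-negative")
        if self.root_prior is None:
            self.root_prior = np.full(3, 1.0 / 3.0)
        else:
            self.root_prior = np.asarray(self.root_prior, dtype=float)
            if self.root_prior.shape != (3,) or abs(self.root_prior.sum() - 1.0) > 1e-9:
                raise ValueError("root prior must be a length-3 probability vector over (F, N, FN)")

    def rate_vector(self) -> np.ndarray:
        return np.array([self.d_FN, self.d_NF, self.e_F, self.e_N])

    def full_root_prior(self) -> np.ndarray:
        """Root prior over the 4-state space (null range excluded)."""
        return np.concatenate([[0.0], self.root_prior])


def dec_generator(model: DecModel) -> np.ndarray:
    """Anagenetic generator over (null, F, N, FN); rows sum to zero."""
    d_FN, d_NF, e_F, e_N = model.rate_vector()
    Q = np.zeros((4, 4))
    Q[1, 3] = d_FN  # F -> FN
    Q[2, 3] = d_NF  # N -> FN
    Q[3, 1] = e_N  # FN -> F
    Q[3, 2] = e_F  # FN -> N
    Q[1, 0] = e_F  # F -> null
    Q[2, 0] = e_N  # N -> null
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def ranges_to_indices(tip_ranges: list[str]) -> np.ndarray:
    out = np.empty(len(tip_ranges), dtype=np.int64)
    for i, r in enumerate(tip_ranges):
        if r not in RANGE_INDEX:
            raise ValueError(f"unknown tip range token '{r}' (expected F, N or FN)")
        out[i] = RANGE_INDEX[r]
    return out


def _tip_partials(tip_idx: np.ndarray) -> np.ndarray:
    tp = np.zeros((tip_idx.size, 4))
    tp[np.arange(tip_idx.size), tip_idx] = 1.0
    return tp


def _dec_partials(tree: Chronogram, P: np.ndarray, tip_partials: np.ndarray, fix: tuple | None = None):
    """Post-order DEC pruning with per-node rescaling.

    ``fix = (node, parent_range, left_range, right_range)`` restricts that
    node to a single cladogenesis scenario (used for scenario probabilities).
    Returns (partials, logscale).
    """
    n = tree.n_nodes
    partials = np.zeros((n, 4))
    for j, v in enumerate(tree.tip_indices):
        partials[v] = tip_partials[j]
    logscale = 0.0
    for v in tree.postorder():
        nd = tree.nodes[v]
        if nd.is_tip:
            continue
        if len(nd.children) != 2:
            raise ValueError(f"DEC requires a strictly bifurcating tree (polytomy at node {v})")
        cl, cr = nd.children
        dl = P[cl] @ partials[cl]
        dr = P[cr] @ partials[cr]
        vec = np.zeros(4)
        if fix is not None and fix[0] == v:
            _, r, xl, xr = fix
            w = 1.0 / len(CLADOGENESIS[r])
            vec[r] = w * dl[xl] * dr[xr]
        else:
            for r, scens in CLADOGENESIS.items():
                w = 1.0 / len(scens)
                vec[r] = w * sum(dl[x] * dr[y] for x, y in scens)
        m = vec.max()
        if m <= 0.0:
            return partials, -np.inf
        partials[v] = vec / m
        logscale += np.log(m)
    return partials, logscale


def dec_log_likelihood(tree: Chronogram, tip_ranges: list[str], model: DecModel, fix: tuple | None = None) -> float:
    """Log-likelihood of tip ranges under the DEC model.

    ``tip_ranges`` is aligned with ``tree.tip_labels`` with tokens in
    {F, N, FN}. Requires a strictly bifurcating tree.
    """
    tip_idx = ranges_to_indices(tip_ranges)
    Q = dec_generator(model)
    blens = np.array([nd.branch_length for nd in tree.nodes])
    P = _pruning.batch_transition_matrices(Q, blens)
    partials, logscale = _dec_partials(tree, P, _tip_partials(tip_idx), fix=fix)
    if not np.isfinite(logscale):
        return -np.inf
    rootL = float(model.full_root_prior() @ partials[tree.root])
    if rootL <= 0:
        return -np.inf
    return logscale + np.log(rootL)


@dataclass
class RangeReconstruction:
    """Node-level DEC reconstruction: scenario and marginal range
    probabilities plus inferred dispersal/divergence events."""

    tree: Chronogram
    scenario_probs: dict[int, dict[tuple[int, int, int], float]]  # node -> (r, xl, xr) -> p
    marginals: dict[int, np.ndarray]  # node -> P(F), P(N), P(FN)
    events: list[dict] = field(default_factory=list)
    log_likelihood: float = float("nan")

    def ml_range(self, node: int) -> str:
        return ("F", "N", "FN")[int(np.argmax(self.marginals[node]))]

    def ml_scenario(self, node: int) -> tuple[int, int, int]:
        d = self.scenario_probs[node]
        return max(d, key=d.get)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in sorted(self.marginals):
            p = self.marginals[v]
            if v in self.scenario_probs:
                r, xl, xr = self.ml_scenario(v)
                scen = f"{RANGES[r]}->{RANGES[xl]}|{RANGES[xr]}"
            else:
                scen = ""  # tip: observed range, no cladogenesis
            rows.append(
                {
                    "node": v,
                    "age": float(self.tree.ages[v]),
                    "P(F)": p[0],
                    "P(N)": p[1],
                    "P(FN)": p[2],
                    "ml_range": ("F", "N", "FN")[int(np.argmax(p))],
                    "ml_scenario": scen,
                }
            )
        return pd.DataFrame(rows)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["node", "age", "direction", "kind"])


def _detect_events(tree: Chronogram, recon: RangeReconstruction) -> list[dict]:
    """Dispersal/divergence events from the ML reconstruction.

    Cladogenetic: at a node whose ML scenario gives one daughter an area the
    other daughter lacks. Anagenetic: a node's ML marginal range contains an
    area absent from its parent's ML marginal range (dispersal on the stem).
    """
    events = []
    names = {1: "F", 2: "N", 3: "FN"}
    for v in tree.internal_indices():
        r, xl, xr = recon.ml_scenario(v)
        al, ar = _AREAS[names[xl]], _AREAS[names[xr]]
        for area in sorted(al - ar) + sorted(ar - al):
            other = "N" if area == "F" else "F"
            events.append(
                {"node": v, "age": float(tree.ages[v]), "direction": f"{other}->{area}", "kind": "cladogenetic"}
            )
    for v in tree.postorder():
        if v == tree.root or v not in recon.marginals:
            continue
        parent = tree.nodes[v].parent
        if parent not in recon.marginals:
            continue
        a_child = _AREAS[recon.ml_range(v)]
        a_parent = _AREAS[recon.ml_range(parent)]
        for area in sorted(a_child - a_parent):
            other = "N" if area == "F" else "F"
            events.append(
                {"node": v, "age": float(tree.ages[v]), "direction": f"{other}->{area}", "kind": "anagenetic"}
            )
    # one event per (node, direction); cladogenetic listed first takes precedence
    seen: set[tuple[int, str]] = set()
    unique = []
    for e in events:
        key = (e["node"], e["direction"])
        if key not in seen:
            seen.add(key)
            unique.append(e)
    return unique


_STARTS = (
    (0.01, 0.01, 0.001, 0.001),
    (0.1, 0.1, 0.01, 0.01),
    (0.001, 0.01, 0.0001, 0.0001),
    (0.01, 0.001, 0.0001, 0.0001),
    (1.0, 1.0, 0.1, 0.1),
)


def fit_dec(
    tree: Chronogram,
    tip_ranges: list[str],
    symmetric_dispersal: bool = False,
    root_prior: np.ndarray | None = None,
) -> tuple[DecModel, RangeReconstruction]:
    """Maximum-likelihood DEC fit plus node reconstruction.

    Rates are optimized in log space within [1e-9, 10] per My from five
    deterministic multi-starts (L-BFGS-B, likelihood tolerance 1e-8). Node
    scenario probabilities are obtained by fixing each cladogenesis scenario
    in turn and renormalizing the resulting tree likelihoods; marginal range
    probabilities sum scenarios by parent range.
    """
    if tree.n_tips < 4:
        raise ValueError("DEC fit needs at least 4 tips")
    idx = ranges_to_indices(tip_ranges)
    has_f = bool(((idx == 1) | (idx == 3)).any())
    has_n = bool(((idx == 2) | (idx == 3)).any())
    if not (has_f and has_n):
        raise ValueError("both areas must be represented among the tips")

    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    def unpack(x):
        if symmetric_dispersal:
            d = np.exp(x[0])
            return DecModel(d, d, np.exp(x[1]), np.exp(x[2]), root_prior)
        return DecModel(*np.exp(x), root_prior=root_prior)

    def nll(x):
        ll = dec_log_likelihood(tree, tip_ranges, unpack(x))
        return -ll if np.isfinite(ll) else 1e12

    nparam = 3 if symmetric_dispersal else 4
    best, best_val = None, np.inf
    failures = []
    for start in _STARTS:
        x0 = np.log(np.asarray(start[:nparam]))
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * nparam, options={"ftol": 1e-8, "maxiter": 500}
        )
        if res.fun < best_val:
            best, best_val = res, res.fun
        if not res.success:
            failures.append(str(res.message))
    if best is None or not np.isfinite(best_val) or best_val >= 1e12:
        raise RuntimeError(f"DEC optimization failed for all starts: {failures}")

    model = unpack(best.x)
    return model, reconstruct_ranges(tree, tip_ranges, model, log_likelihood=-best_val)


def reconstruct_ranges(
    tree: Chronogram,
    tip_ranges: list[str],
    model: DecModel,
    log_likelihood: float | None = None,
) -> RangeReconstruction:
    """Node-level reconstruction under a fixed DEC model.

    Scenario probabilities come from fixing each cladogenesis scenario in
    turn and renormalizing the tree likelihoods; marginal range
    probabilities sum scenarios by parent range. Tips carry their observed
    range with probability 1.
    """
    idx = ranges_to_indices(tip_ranges)
    if log_likelihood is None:
        log_likelihood = dec_log_likelihood(tree, tip_ranges, model)
    scenario_probs: dict[int, dict[tuple[int, int, int], float]] = {}
    marginals: dict[int, np.ndarray] = {}
    for v in tree.internal_indices():
        lls = {}
        for r, scens in CLADOGENESIS.items():
            for xl, xr in scens:
                lls[(r, xl, xr)] = dec_log_likelihood(tree, tip_ranges, model, fix=(v, r, xl, xr))
        vals = np.array(list(lls.values()))
        finite = np.isfinite(vals)
        w = np.zeros_like(vals)
        if finite.any():
            mx = vals[finite].max()
            w[finite] = np.exp(vals[finite] - mx)
            w /= w.sum()
        scenario_probs[v] = {k: float(p) for k, p in zip(lls, w)}
        marg = np.zeros(3)
        for (r, _, _), p in scenario_probs[v].items():
            marg[r - 1] += p
        marginals[v] = marg
    for j, v in enumerate(tree.tip_indices):
        marg = np.zeros(3)
        marg[idx[j] - 1] = 1.0
        marginals[v] = marg

    recon = RangeReconstruction(tree, scenario_probs, marginals, [], log_likelihood)
    recon.events = _detect_events(tree, recon)
    return recon


def ranges_to_binary(tip_ranges: list[str]) -> np.ndarray:
    """Map ranges to a binary fireproneness trait: F -> 1, N -> 0,
    FN -> ambiguous."""
    mapping = {"F": 1, "N": 0, "FN": AMBIGUOUS}
    try:
        return np.array([mapping[r] for r in tip_ranges], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"unknown tip range token {e}") from e


def habitat_as_trait(tree: Chronogram, tip_ranges: list[str], config, threshold: float = 0.95):
    """Treat habitat as a generic heritable binary trait: run the Mk MCMC
    and return corrected-posterior node assignments (state 1 = fireprone)."""
    from pyroclad.ancestral import assign_nodes
    from pyroclad.mcmc_engine import run_chain

    states = ranges_to_binary(tip_ranges)
    model = MkModel(0.1, 0.1)
    trace = run_chain(tree, states, model, config)
    return assign_nodes(trace, tree, trait="habitat", threshold=threshold, tip_states=states)


def enumerate_dec_likelihood(tree: Chronogram, tip_ranges: list[str], model: DecModel) -> float:
    """Brute-force DEC likelihood by summing over all internal-node ranges
    and cladogenesis scenarios (oracle for small trees)."""
    idx = ranges_to_indices(tip_ranges)
    Q = dec_generator(model)
    blens = np.array([nd.branch_length for nd in tree.nodes])
    P = _pruning.batch_transition_matrices(Q, blens)
    internal = tree.internal_indices()
    tip_state = {v: int(idx[j]) for j, v in enumerate(tree.tip_indices)}
    prior = model.full_root_prior()

    total = 0.0
    # assign each internal node a range in {F, N, FN} and a scenario for it
    for ranges in itertools.product((1, 2, 3), repeat=len(internal)):
        rmap = dict(zip(internal, ranges))
        per_node_options = [CLADOGENESIS[rmap[v]] for v in internal]
        for scens in itertools.product(*per_node_options):
            smap = dict(zip(internal, scens))
            p = prior[rmap[tree.root]]
            for v in internal:
                r = rmap[v]
                p *= 1.0 / len(CLADOGENESIS[r])
                cl, cr = tree.nodes[v].children
                for c, start in zip((cl, cr), smap[v]):
                    end = tip_state[c] if tree.nodes[c].is_tip else rmap[c]
                    p *= P[c][start, end]
            total += p
    return float(np.log(total)) if total > 0 else -np.inf
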