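"""Continuous-time Markov models of discrete trait evolution.

Two model families are provided:

* :class:`MkModel` — a 2-state Mk model of a single binary trait with gain
  rate ``q01`` and loss rate ``q10`` (events per My).
* :class:`PairModel` — the 4-state joint model of two binary traits used in
  correlated-evolution tests. The *dependent* variant has 8 free rates (each
  trait's gain/loss rate may depend on the state of the other trait); the
  *independent* variant ties them into 4. Simultaneous double transitions
  (00↔11, 01↔10) have rate zero in both variants.

Likelihoods are computed by Felsenstein's pruning algorithm with ambiguous
tips contributing a partial likelihood of 1 in every permitted state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm as _scipy_expm

from pyroclad import _pruning
from pyroclad.treeio import AMBIGUOUS, Chronogram

PAIR_STATES = ("00", "01", "10", "11")

# dependent-model transition order: (from-state, to-state) pairs, one per rate
PAIR_TRANSITIONS = (
    ("00", "01"),
    ("00", "10"),
    ("01", "00"),
    ("01", "11"),
    ("10", "00"),
    ("10", "11"),
    ("11", "01"),
    ("11", "10"),
)

# independent model: 4 rates (trait-1 gain/loss, trait-2 gain/loss) tied
# across the background state of the other trait.
INDEP_RATE_NAMES = ("q1_01", "q1_10", "q2_01", "q2_10")
_INDEP_TIES = {
    ("00", "10"): 0,  # trait 1 gain
    ("01", "11"): 0,
    ("10", "00"): 1,  # trait 1 loss
    ("11", "01"): 1,
    ("00", "01"): 2,  # trait 2 gain
    ("10", "11"): 2,
    ("01", "00"): 3,  # trait 2 loss
    ("11", "10"): 3,
}


def _check_prior(prior, k: int) -> np.ndarray:
    if prior is None:
        return np.full(k, 1.0 / k)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (k,) or prior.min() < 0 or abs(prior.sum() - 1.0) > 1e-9:
        raise ValueError(f"root prior must be a length-{k} probability vector")
    return prior


@dataclass
class MkModel:
    """Binary-trait Mk model: gain rate q01 and loss rate q10 (per My)."""

    q01: float
    q10: float
    root_prior: np.ndarray | None = None

    n_states = 2
    states = ("0", "1")
    rate_names = ("q01", "q10")
    n_rates = 2

    def __post_init__(self):
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be non-negative")
        self.root_prior = _check_prior(self.root_prior, 2)

    def rate_vector(self) -> np.ndarray:
        return np.array([self.q01, self.q10])

    def with_rates(self, rates) -> "MkModel":
        return MkModel(float(rates[0]), float(rates[1]), self.root_prior.copy())

    def q_from_rates(self, rates) -> np.ndarray:
        q01, q10 = float(rates[0]), float(rates[1])
        return np.array([[-q01, q01], [q10, -q10]])

    def stationary(self) -> np.ndarray:
        tot = self.q01 + self.q10
        if tot == 0:
            return np.array([0.5, 0.5])
        return np.array([self.q10, self.q01]) / tot

    def tip_partial(self, state: int) -> np.ndarray:
        if state == AMBIGUOUS:
            return np.ones(2)
        return np.eye(2)[int(state)]


@dataclass
class PairModel:
    """Joint 4-state model of two binary traits (states 00, 01, 10, 11).

    ``rates`` holds 8 values ordered as :data:`PAIR_TRANSITIONS` when
    ``dependent`` and 4 values ordered as :data:`INDEP_RATE_NAMES` otherwise.
    """

    rates: np.ndarray
    dependent: bool = True
    root_prior: np.ndarray | None = None

    n_states = 4
    states = PAIR_STATES

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        want = 8 if self.dependent else 4
        if self.rates.shape != (want,):
            raise ValueError(f"{'dependent' if self.dependent else 'independent'} PairModel needs {want} rates")
        if (self.rates < 0).any():
            raise ValueError("rates must be non-negative")
        self.root_prior = _check_prior(self.root_prior, 4)

    @property
    def rate_names(self):
        if self.dependent:
            return tuple(f"q{a}{b}" for a, b in PAIR_TRANSITIONS)
        return INDEP_RATE_NAMES

    @property
    def n_rates(self) -> int:
        return 8 if self.dependent else 4

    def rate_vector(self) -> np.ndarray:
        return self.rates.copy()

    def with_rates(self, rates) -> "PairModel":
        return PairModel(np.asarray(rates, dtype=float), self.dependent, self.root_prior.copy())

    def q_from_rates(self, rates) -> np.ndarray:
        Q = np.zeros((4, 4))
        idx = {s: i for i, s in enumerate(PAIR_STATES)}
        if self.dependent:
            for r, (a, b) in zip(rates, PAIR_TRANSITIONS):
                Q[idx[a], idx[b]] = r
        else:
            for (a, b), j in _INDEP_TIES.items():
                Q[idx[a], idx[b]] = rates[j]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    @staticmethod
    def independent(q1_01: float, q1_10: float, q2_01: float, q2_10: float, root_prior=None) -> "PairModel":
        return PairModel(np.array([q1_01, q1_10, q2_01, q2_10]), dependent=False, root_prior=root_prior)

    def tip_partial(self, state_pair) -> np.ndarray:
        """Kronecker product of the two traits' binary partials."""
        s1, s2 = int(state_pair[0]), int(state_pair[1])
        p1 = np.ones(2) if s1 == AMBIGUOUS else np.eye(2)[s1]
        p2 = np.ones(2) if s2 == AMBIGUOUS else np.eye(2)[s2]
        return np.kron(p1, p2)

    @staticmethod
    def split_state(index: int) -> tuple[int, int]:
        """4-state index -> (trait1, trait2) binary states."""
        return index // 2, index % 2


def build_rate_matrix(model) -> np.ndarray:
    """Instantaneous rate matrix Q with rows summing to zero."""
    return model.q_from_rates(model.rate_vector())


def transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """Row-stochastic transition matrix exp(Q t).

    Uses SciPy's scaling-and-squaring matrix exponential (the batched
    eigendecomposition route used inside MCMC is cross-checked against this
    in the test suite).
    """
    if t < 0:
        raise ValueError("duration t must be non-negative")
    Q = np.asarray(Q, dtype=float)
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
        raise ValueError("generator rows must sum to zero")
    P = _scipy_expm(Q * t)
    return np.clip(P, 0.0, 1.0)


def _tip_partials_matrix(model, states: np.ndarray) -> np.ndarray:
    states = np.asarray(states)
    if isinstance(model, PairModel):
        if states.ndim != 2 or states.shape[1] != 2:
            raise ValueError("PairModel needs an (n_tips, 2) state array")
        return np.array([model.tip_partial(s) for s in states])
    if states.ndim != 1:
        raise ValueError("MkModel needs an (n_tips,) state array")
    return np.array([model.tip_partial(s) for s in states])


def prune_log_likelihood(tree: Chronogram, states: np.ndarray, model, arrays: _pruning.TreeArrays | None = None) -> float:
    """Log-likelihood of tip states under the model, by post-order pruning.

    ``states`` is aligned with ``tree.tip_labels``: shape (n_tips,) for
    :class:`MkModel` (values 0/1/-1) or (n_tips, 2) for :class:`PairModel`.
    Ambiguous tips contribute partial likelihood 1 in every allowed state.
    """
    states = np.asarray(states)
    if states.shape[0] != tree.n_tips:
        raise ValueError(f"got {states.shape[0]} states for {tree.n_tips} tips")
    tip_partials = _tip_partials_matrix(model, states)
    if np.all(tip_partials == 1.0):
        warnings.warn("all tips ambiguous: likelihood is 1 (log-likelihood 0)")
    if arrays is None:
        arrays = _pruning.TreeArrays(tree)
    Q = build_rate_matrix(model)
    return _pruning.log_likelihood(arrays, Q, tip_partials, model.root_prior)


def simulate_trait(tree: Chronogram, model, seed: int | None = None, rng: np.random.Generator | None = None):
    """Forward-simulate a trait down the tree.

    Returns ``(tip_states, node_states)``: tip states aligned with
    ``tree.tip_labels`` and the latent state at every node (indexed by node
    id) for recovery tests. For :class:`PairModel`, tip states have shape
    (n_tips, 2). Identical seeds give identical output.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    Q = build_rate_matrix(model)
    k = model.n_states
    node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    node_states[tree.root] = rng.choice(k, p=model.root_prior)
    for v in tree.preorder():
        if v == tree.root:
            continue
        P = transition_probs(Q, tree.nodes[v].branch_length)
        row = P[node_states[tree.nodes[v].parent]]
        node_states[v] = rng.choice(k, p=row / row.sum())
    tips = node_states[tree.tip_indices]
    if isinstance(model, PairModel):
        tips = np.column_stack([tips // 2, tips % 2]).astype(np.int8)
    else:
        tips = tips.astype(np.int8)
    return tips, node_states
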