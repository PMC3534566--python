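"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's pruning code path: likelihoods are
computed by explicit summation over all internal-node state assignments
(and over tip states where tips are ambiguous), with per-branch transition
matrices from SciPy's matrix exponential.
"""

import itertools

import numpy as np
from scipy.linalg import expm

from pyroclad.ctmc import build_rate_matrix


def enum_markov_loglik(tree, states, model) -> float:
    """Sum over every internal-node (and ambiguous-tip) state assignment."""
    Q = build_rate_matrix(model)
    P = {
        v: expm(Q * tree.nodes[v].branch_length)
        for v in tree.preorder()
        if v != tree.root
    }
    k = model.n_states
    states = np.asarray(states)

    def tip_allowed(j):
        s = states[j]
        if k == 4:
            s1, s2 = int(s[0]), int(s[1])
            opts1 = [0, 1] if s1 == -1 else [s1]
            opts2 = [0, 1] if s2 == -1 else [s2]
            return [2 * a + b for a in opts1 for b in opts2]
        return [0, 1] if s == -1 else [int(s)]

    tip_opts = {v: tip_allowed(j) for j, v in enumerate(tree.tip_indices)}
    internal = tree.internal_indices()
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        p = model.root_prior[amap[tree.root]]
        for v in tree.preorder():
            if v == tree.root:
                continue
            s_par = amap[tree.nodes[v].parent]
            if tree.nodes[v].is_tip:
                p *= sum(P[v][s_par, s] for s in tip_opts[v])
            else:
                p *= P[v][s_par, amap[v]]
        total += p
    return float(np.log(total))


def exact_conditional_node_posteriors(tree, states, model) -> dict[int, np.ndarray]:
    """Marginal internal-node state posteriors by enumeration."""
    Q = build_rate_matrix(model)
    P = {
        v: expm(Q * tree.nodes[v].branch_length)
        for v in tree.preorder()
        if v != tree.root
    }
    k = model.n_states
    internal = tree.internal_indices()
    tip_state = {v: int(states[j]) for j, v in enumerate(tree.tip_indices)}
    post = {v: np.zeros(k) for v in internal}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        p = model.root_prior[amap[tree.root]]
        for v in tree.preorder():
            if v == tree.root:
                continue
            s_par = amap[tree.nodes[v].parent]
            if tree.nodes[v].is_tip:
                s = tip_state[v]
                p *= P[v][s_par].sum() if s == -1 else P[v][s_par, s]
            else:
                p *= P[v][s_par, amap[v]]
        total += p
        for v in internal:
            post[v][amap[v]] += p
    return {v: post[v] / total for v in internal}
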