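"""Vectorized pruning-likelihood machinery shared by the trait and DEC models.

The tree is flattened once into index arrays (postorder internal nodes,
CSR-style child lists, per-node branch lengths). Per likelihood evaluation we
compute all branch transition matrices in one batched matrix exponential and
run Felsenstein's post-order pruning with per-node rescaling so that
likelihoods of trees with hundreds of tips do not underflow.

The batched exponential uses the eigendecomposition of the generator
(``P(t) = V exp(Λt) V⁻¹``) when the eigenvector basis is well conditioned,
falling back to SciPy's scaling-and-squaring ``expm`` per branch otherwise.
A numba-compiled kernel does the pruning recursion; a pure-NumPy fallback is
used when numba is unavailable.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm as _scipy_expm

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

class TreeArrays:
    """Flat, traversal-ready representation of a :class:`Chronogram`."""

    def __init__(self, tree):
        n = tree.n_nodes
        self.n_nodes = n
        self.root = tree.root
        self.tip_indices = np.asarray(tree.tip_indices, dtype=np.int64)
        self.post_internal = np.asarray(tree.internal_indices(), dtype=np.int64)
        counts = np.zeros(n + 1, dtype=np.int64)
        for nd in tree.nodes:
            counts[nd.index + 1] = len(nd.children)
        self.child_ptr = np.cumsum(counts)
        self.child_idx = np.empty(self.child_ptr[-1], dtype=np.int64)
        for nd in tree.nodes:
            self.child_idx[self.child_ptr[nd.index] : self.child_ptr[nd.index + 1]] = nd.children
        self.branch_lengths = np.array([nd.branch_length for nd in tree.nodes], dtype=float)


def batch_transition_matrices(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """exp(Q * t) for every duration in ``ts``; shape (len(ts), k, k)."""
    Q = np.asarray(Q, dtype=float)
    ts = np.asarray(ts, dtype=float)
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        # cheap conditioning probe: V @ V^-1 must reproduce the identity
        if np.abs(V @ Vinv - np.eye(k)).max() < 1e-9:
            E = np.exp(np.multiply.outer(ts, w))
            P = np.einsum("ij,nj,jk->nik", V, E, Vinv)
            P = np.ascontiguousarray(P.real)
            np.clip(P, 0.0, None, out=P)
            return P
    except np.linalg.LinAlgError:
        pass
    # defective/ill-conditioned generator: accurate but slower route
    P = np.empty((ts.size, k, k))
    for i, t in enumerate(ts):
        P[i] = _scipy_expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    return P


def _prune_py(post_internal, child_ptr, child_idx, P, partials):
    logscale = 0.0
    for v in post_internal:
        acc = np.ones(partials.shape[1])
        for j in range(child_ptr[v], child_ptr[v + 1]):
            c = child_idx[j]
            acc *= P[c] @ partials[c]
        m = acc.max()
        if m <= 0.0 or not np.isfinite(m):
            return -np.inf
        partials[v] = acc / m
        logscale += np.log(m)
    return logscale


if _HAVE_NUMBA:

    @njit(cache=True)
    def _prune_nb(post_internal, child_ptr, child_idx, P, partials):  # pragma: no cover
        k = partials.shape[1]
        tmp = np.empty(k)
        logscale = 0.0
        for ii in range(post_internal.size):
            v = post_internal[ii]
            for s in range(k):
                partials[v, s] = 1.0
            for j in range(child_ptr[v], child_ptr[v + 1]):
                c = child_idx[j]
                for s in range(k):
                    acc = 0.0
                    for s2 in range(k):
                        acc += P[c, s, s2] * partials[c, s2]
                    tmp[s] = acc
                for s in range(k):
                    partials[v, s] *= tmp[s]
            m = 0.0
            for s in range(k):
                if partials[v, s] > m:
                    m = partials[v, s]
            if m <= 0.0:
                return -np.inf
            for s in range(k):
                partials[v, s] /= m
            logscale += np.log(m)
        return logscale

    _prune = _prune_nb
else:  # pragma: no cover
    _prune = _prune_py


def prune_partials(arrays: TreeArrays, P: np.ndarray, tip_partials: np.ndarray):
    """Post-order pruning pass.

    ``tip_partials`` has shape (n_tips, k) in the order of
    ``arrays.tip_indices``. Returns (partials, logscale): per-node rescaled
    conditional likelihoods and the accumulated log of the scaling factors.
    """
    k = tip_partials.shape[1]
    partials = np.zeros((arrays.n_nodes, k))
    partials[arrays.tip_indices] = tip_partials
    logscale = _prune(arrays.post_internal, arrays.child_ptr, arrays.child_idx, P, partials)
    return partials, logscale


def log_likelihood(arrays: TreeArrays, Q: np.ndarray, tip_partials: np.ndarray, root_prior: np.ndarray) -> float:
    P = batch_transition_matrices(Q, arrays.branch_lengths)
    partials, logscale = prune_partials(arrays, P, tip_partials)
    if not np.isfinite(logscale):
        return -np.inf
    rootL = float(root_prior @ partials[arrays.root])
    if rootL <= 0.0:
        return -np.inf
    return logscale + np.log(rootL)


def sample_node_states(arrays: TreeArrays, Q: np.ndarray, tip_partials: np.ndarray, root_prior: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One joint draw of ancestral node states given tips and rates.

    Root is drawn from prior × root partial; children are drawn pre-order
    from P[parent_state, :] × child partial. Tip entries carry the tips'
    (possibly sampled, if ambiguous) states.
    """
    P = batch_transition_matrices(Q, arrays.branch_lengths)
    partials, logscale = prune_partials(arrays, P, tip_partials)
    if not np.isfinite(logscale):
        raise ValueError("zero likelihood: cannot sample node states")
    states = np.full(arrays.n_nodes, -1, dtype=np.int64)

    def draw(w):
        c = np.cumsum(w)
        return int(np.searchsorted(c, rng.random() * c[-1], side="right"))

    states[arrays.root] = draw(root_prior * partials[arrays.root])
    order = [arrays.root]
    while order:
        v = order.pop()
        sv = states[v]
        for j in range(arrays.child_ptr[v], arrays.child_ptr[v + 1]):
            c = arrays.child_idx[j]
            states[c] = draw(P[c][sv] * partials[c])
            order.append(int(c))
    return states


def exact_node_posteriors(arrays: TreeArrays, Q: np.ndarray, tip_partials: np.ndarray, root_prior: np.ndarray) -> np.ndarray:
    """Analytic marginal node-state posteriors under fixed rates.

    Standard up-down algorithm: ``post[v] ∝ up[v] * down[v]`` where ``down``
    carries the likelihood of everything outside the clade of v.
    """
    P = batch_transition_matrices(Q, arrays.branch_lengths)
    partials, logscale = prune_partials(arrays, P, tip_partials)
    if not np.isfinite(logscale):
        raise ValueError("zero likelihood: posteriors undefined")
    k = partials.shape[1]
    down = np.zeros((arrays.n_nodes, k))
    down[arrays.root] = root_prior
    # pre-order: down[c] = P[c]^T @ (down[v] * prod_{siblings s} P[s] @ partials[s])
    stack = [arrays.root]
    while stack:
        v = stack.pop()
        kids = arrays.child_idx[arrays.child_ptr[v] : arrays.child_ptr[v + 1]]
        if kids.size == 0:
            continue
        contrib = [P[c] @ partials[c] for c in kids]
        for i, c in enumerate(kids):
            sib = down[v].copy()
            for j, other in enumerate(contrib):
                if j != i:
                    sib *= other
            dc = P[c].T @ sib
            m = dc.max()
            down[c] = dc / m if m > 0 else dc
            stack.append(int(c))
    post = partials * down
    post /= post.sum(axis=1, keepdims=True)
    return post
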