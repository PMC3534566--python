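"""Bayesian and reversible-jump MCMC over trait-model transition rates.

The sampler follows the BayesTraits-style recipe used for ancestral-state
work on chronograms:

* Metropolis-Hastings on rate values with a reflected-uniform proposal of
  half-width ``ratedev``; ``ratedev`` is tuned by short pilot chains until
  the pooled acceptance rate of rate moves falls in the 20-40% window.
* An exponential prior on every rate whose mean is itself a sampled
  hyperparameter with a uniform(0, 30) prior (the "hyperprior"), updated by
  its own Metropolis move.
* Optional reversible-jump moves over partitions of the rates into shared
  rate classes plus a zero bin. New class values are proposed from the
  exponential prior, so the prior and proposal densities cancel and the
  acceptance ratio reduces to the likelihood ratio times the forward/reverse
  choice-count ratio (all partition structures carry equal prior weight).
* At every recorded sample the internal-node states are drawn once from
  their joint conditional distribution given the tips and current rates, and
  tallied into per-node state posteriors.

Marginal likelihoods are summarized by the harmonic mean of the sampled
likelihoods, computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from pyroclad import _pruning
from pyroclad.ctmc import MkModel, PairModel, _tip_partials_matrix
from pyroclad.treeio import Chronogram

ZERO_BIN = -1


@dataclass
class McmcConfig:
    """Chain settings. Defaults are desk-scale; use ``preset("paper")`` for
    the full-scale settings (10^7 iterations, 10^4 burn-in, thin 2000)."""

    iterations: int = 100_000
    burn_in: int = 1_000
    thin: int = 20
    ratedev: float | str = "auto"
    hyperprior_upper: float = 30.0
    rj_enabled: bool = True
    seed: int = 0
    pilot_chains: int = 3
    pilot_iterations: int = 10_000
    fixed_rates: np.ndarray | None = None  # freeze rates; tally node states only
    exact_node_posteriors: bool = False  # analytic tally (fixed-rate runs)

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.ratedev != "auto" and not (isinstance(self.ratedev, (int, float)) and self.ratedev > 0):
            raise ValueError("ratedev must be 'auto' or a positive number")

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


def preset(name: str, **overrides) -> McmcConfig:
    """Named configurations: "paper" (ancestral states), "paper-correlation"
    (correlation runs), "test" (desk scale)."""
    base = {
        "paper": dict(iterations=10_000_000, burn_in=10_000, thin=2000),
        "paper-correlation": dict(iterations=5_000_000, burn_in=10_000, thin=2000),
        "test": dict(iterations=100_000, burn_in=1_000, thin=20),
    }
    if name not in base:
        raise ValueError(f"unknown preset '{name}'")
    kw = dict(base[name])
    kw.update(overrides)
    return McmcConfig(**kw)


@dataclass
class Trace:
    """Recorded MCMC samples and node-state tallies."""

    rate_names: tuple[str, ...]
    rates: np.ndarray  # (n_samples, n_rates) effective rates (zeros included)
    logL: np.ndarray  # (n_samples,)
    model_ids: list[str]  # canonical rate-partition signature per sample
    hyper_mean: np.ndarray  # (n_samples,) exponential-prior mean samples
    node_tallies: np.ndarray  # (n_nodes, n_states) state counts at records
    n_states: int
    acceptance: dict[str, tuple[int, int]]  # move -> (accepted, proposed)
    ratedev: float
    seed: int

    @property
    def n_samples(self) -> int:
        return self.logL.size

    def acceptance_rate(self, move: str = "rate") -> float:
        acc, tot = self.acceptance.get(move, (0, 0))
        return acc / tot if tot else float("nan")

    def node_posteriors(self) -> np.ndarray:
        """Per-node state posteriors (rows normalized to 1)."""
        tot = self.node_tallies.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            post = self.node_tallies / tot
        return post

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rates, columns=list(self.rate_names))
        df.insert(0, "model_id", self.model_ids)
        df["hyper_mean"] = self.hyper_mean
        df["logL"] = self.logL
        df.index.name = "sample"
        return df

    def export_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    def export_node_posteriors_tsv(self, path, tree: Chronogram | None = None) -> None:
        post = self.node_posteriors()
        rows = []
        for node in range(post.shape[0]):
            for s in range(self.n_states):
                rows.append({"node": node, "state": s, "posterior": post[node, s]})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect x into [lo, hi] (symmetric proposal under reflection)."""
    width = hi - lo
    if width <= 0:
        raise ValueError("empty reflection interval")
    y = (x - lo) % (2 * width)
    return lo + (width - abs(y - width))


def _canonical_model_id(assign: np.ndarray) -> str:
    symbols, seen = [], {}
    for a in assign:
        if a == ZERO_BIN:
            symbols.append("Z")
        else:
            if a not in seen:
                seen[a] = str(len(seen))
            symbols.append(seen[a])
    return "".join(symbols)


class _SamplerState:
    """Rate-class partition, class values and hyperparameter of one chain."""

    def __init__(self, n_rates: int, rng: np.random.Generator, upper: float, rj: bool):
        self.upper = upper
        self.hyper_mean = rng.uniform(0.0, upper)
        # start fully free: each rate its own class. Initial values are drawn
        # at the scale of ~1 change per 10 My rather than from the (broad)
        # prior so burn-in starts near plausible rates.
        self.assign = np.arange(n_rates)
        self.values = rng.exponential(0.1, size=n_rates)
        self.rj = rj

    def effective_rates(self) -> np.ndarray:
        r = np.zeros(self.assign.size)
        live = self.assign != ZERO_BIN
        r[live] = self.values[self.assign[live]]
        return r

    def log_prior_values(self, mean: float | None = None) -> float:
        m = self.hyper_mean if mean is None else mean
        if m <= 0:
            return -np.inf
        v = self.values
        return float(-v.size * np.log(m) - v.sum() / m)

    def _renumber(self):
        """Canonical class ids 0..C-1 in order of first appearance."""
        mapping, new_values = {}, []
        new_assign = np.empty_like(self.assign)
        for i, a in enumerate(self.assign):
            if a == ZERO_BIN:
                new_assign[i] = ZERO_BIN
            else:
                if a not in mapping:
                    mapping[a] = len(new_values)
                    new_values.append(self.values[a])
                new_assign[i] = mapping[a]
        self.assign = new_assign
        self.values = np.array(new_values)


def _rj_targets(state: _SamplerState, i: int) -> list:
    """Candidate reassignments of rate i: zero bin, other classes, new class."""
    a = state.assign[i]
    targets: list = []
    if a != ZERO_BIN:
        targets.append("zero")
    for c in range(state.values.size):
        if c != a:
            targets.append(c)
    members = int(np.sum(state.assign == a)) if a != ZERO_BIN else 0
    if a == ZERO_BIN or members >= 2:
        targets.append("new")
    return targets


def run_chain(tree: Chronogram, states: np.ndarray, model, config: McmcConfig, chain_index: int = 0) -> Trace:
    """Run one MCMC chain; returns a :class:`Trace`.

    ``states`` follows :func:`pyroclad.ctmc.prune_log_likelihood`'s layout.
    The chain is a pure function of (inputs, config, chain_index): identical
    seeds give identical traces. With ``config.fixed_rates`` set, rates are
    frozen and only node states are sampled (oracle mode for validating the
    tallies against analytic posteriors).
    """
    arrays = _pruning.TreeArrays(tree)
    tip_partials = _tip_partials_matrix(model, np.asarray(states))
    root_prior = model.root_prior
    rng = np.random.default_rng([config.seed % (2**31), 7919 * (chain_index + 1)])

    def loglik(rates: np.ndarray) -> float:
        Q = model.q_from_rates(rates)
        return _pruning.log_likelihood(arrays, Q, tip_partials, root_prior)

    ratedev = config.ratedev
    if config.fixed_rates is not None:
        ratedev = 1.0  # unused
    elif ratedev == "auto":
        ratedev = tune_ratedev(tree, states, model, config)

    st = _SamplerState(model.n_rates, rng, config.hyperprior_upper, config.rj_enabled)
    if config.fixed_rates is not None:
        st.assign = np.arange(model.n_rates)
        st.values = np.asarray(config.fixed_rates, dtype=float).copy()

    cur_rates = st.effective_rates()
    cur_logL = loglik(cur_rates)
    if not np.isfinite(cur_logL):
        raise RuntimeError(
            "non-finite initial likelihood; check that the data and model are compatible "
            f"(rates={cur_rates})"
        )

    n_samples = config.n_samples
    n_rates = model.n_rates
    rec_rates = np.empty((n_samples, n_rates))
    rec_logL = np.empty(n_samples)
    rec_hyper = np.empty(n_samples)
    model_ids: list[str] = []
    tallies = np.zeros((tree.n_nodes, model.n_states))
    acc = {"rate": [0, 0], "hyper": [0, 0], "rj": [0, 0]}

    p_hyper = 0.1
    p_rj = 0.2 if (config.rj_enabled and config.fixed_rates is None) else 0.0
    frozen = config.fixed_rates is not None

    rec = 0
    for it in range(1, config.iterations + 1):
        # acceptance statistics describe the equilibrium chain, not burn-in
        tally = it > config.burn_in
        if not frozen:
            u = rng.random()
            if u < p_hyper:
                # hyperparameter move: likelihood cancels
                acc["hyper"][1] += tally
                prop = _reflect(st.hyper_mean + rng.uniform(-1, 1) * config.hyperprior_upper * 0.1,
                                1e-12, config.hyperprior_upper)
                dlp = st.log_prior_values(prop) - st.log_prior_values()
                if np.log(rng.random()) < dlp:
                    st.hyper_mean = prop
                    acc["hyper"][0] += tally
            elif u < p_hyper + p_rj:
                acc["rj"][1] += tally
                i = rng.integers(n_rates)
                targets = _rj_targets(st, i)
                tgt = targets[rng.integers(len(targets))]
                old_assign = st.assign.copy()
                old_values = st.values.copy()
                if tgt == "zero":
                    st.assign[i] = ZERO_BIN
                elif tgt == "new":
                    st.values = np.append(st.values, rng.exponential(st.hyper_mean))
                    st.assign[i] = st.values.size - 1
                else:
                    st.assign[i] = tgt
                st._renumber()
                new_rates = st.effective_rates()
                new_logL = loglik(new_rates)
                n_back = len(_rj_targets(st, i))
                log_alpha = (new_logL - cur_logL) + np.log(len(targets)) - np.log(n_back)
                if np.log(rng.random()) < log_alpha:
                    cur_rates, cur_logL = new_rates, new_logL
                    acc["rj"][0] += tally
                else:
                    st.assign, st.values = old_assign, old_values
            else:
                acc["rate"][1] += tally
                if st.values.size:
                    j = rng.integers(st.values.size)
                    old = st.values[j]
                    if rng.random() < 0.05:
                        # occasional independence draw from the prior keeps the
                        # chain mobile across rate scales (prior and proposal
                        # densities cancel; acceptance is the likelihood ratio)
                        newv = rng.exponential(st.hyper_mean)
                        dlp = 0.0
                    else:
                        newv = abs(old + rng.uniform(-ratedev, ratedev))
                        dlp = -(newv - old) / st.hyper_mean  # exponential prior ratio
                    st.values[j] = newv
                    new_rates = st.effective_rates()
                    new_logL = loglik(new_rates)
                    if np.log(rng.random()) < (new_logL - cur_logL) + dlp:
                        cur_rates, cur_logL = new_rates, new_logL
                        acc["rate"][0] += tally
                    else:
                        st.values[j] = old

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0 and rec < n_samples:
            rec_rates[rec] = cur_rates
            rec_logL[rec] = cur_logL
            rec_hyper[rec] = st.hyper_mean
            model_ids.append(_canonical_model_id(st.assign))
            Q = model.q_from_rates(cur_rates)
            if config.exact_node_posteriors:
                tallies += _pruning.exact_node_posteriors(arrays, Q, tip_partials, root_prior)
            else:
                drawn = _pruning.sample_node_states(arrays, Q, tip_partials, root_prior, rng)
                tallies[np.arange(tree.n_nodes), drawn] += 1.0
            rec += 1

    return Trace(
        rate_names=tuple(model.rate_names),
        rates=rec_rates,
        logL=rec_logL,
        model_ids=model_ids,
        hyper_mean=rec_hyper,
        node_tallies=tallies,
        n_states=model.n_states,
        acceptance={k: (v[0], v[1]) for k, v in acc.items()},
        ratedev=float(ratedev),
        seed=config.seed,
    )


def tune_ratedev(tree: Chronogram, states: np.ndarray, model, config: McmcConfig, initial: float = 1.0, max_doublings: int = 20) -> float:
    """Geometric search for a proposal width with 20-40% pooled acceptance.

    Runs ``pilot_chains`` short chains per candidate value, pooling the
    rate-move acceptance fraction; the candidate is halved when acceptance is
    below 20% and doubled when above 40%. Deterministic given the seed.
    """
    ratedev = float(initial)
    history = []
    for trial in range(max_doublings):
        acc_n, tot_n = 0, 0
        for chain in range(config.pilot_chains):
            pilot = replace(
                config,
                iterations=config.pilot_iterations,
                burn_in=min(config.pilot_iterations // 10, config.pilot_iterations - 1),
                thin=max(config.pilot_iterations // 10, 1),
                ratedev=ratedev,
                seed=(config.seed + 104729 * (trial + 1)) % (2**31),
            )
            tr = run_chain(tree, states, model, pilot, chain_index=chain)
            a, t = tr.acceptance["rate"]
            acc_n += a
            tot_n += t
        rate = acc_n / tot_n if tot_n else 1.0
        history.append((ratedev, rate))
        if 0.20 <= rate <= 0.40:
            return ratedev
        ratedev = ratedev / 2 if rate < 0.20 else ratedev * 2
    raise RuntimeError(
        "ratedev tuning failed to reach the 20-40% acceptance window in "
        f"{max_doublings} adjustments (history: {history}); "
        "the data may be uninformative for this model"
    )


def harmonic_mean_logL(trace: Trace) -> float:
    """Log of the harmonic mean of sampled likelihoods (log-sum-exp form).

    log HM = log n − logsumexp(−logL_i). High-variance estimator; kept as
    the marginal-likelihood summary because it is the standard output of the
    workflow this package reproduces.
    """
    logL = np.asarray(trace.logL if isinstance(trace, Trace) else trace, dtype=float)
    if logL.size < 2:
        raise ValueError("need at least 2 recorded samples for a harmonic mean")
    return float(np.log(logL.size) - logsumexp(-logL))


def harmonic_mean_se(trace: Trace, n_blocks: int = 10) -> float:
    """Monte-Carlo standard error of the harmonic-mean log marginal
    likelihood by non-overlapping block jackknife of the trace."""
    logL = trace.logL
    if logL.size < 2 * n_blocks:
        n_blocks = max(2, logL.size // 2)
    blocks = np.array_split(logL, n_blocks)
    ests = []
    for b in range(n_blocks):
        rest = np.concatenate([blk for j, blk in enumerate(blocks) if j != b])
        ests.append(np.log(rest.size) - logsumexp(-rest))
    ests = np.asarray(ests)
    return float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((ests - ests.mean()) ** 2)))
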