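# Methods

`pyroclad` dates the origin of fire-adapted traits and fireprone habitats on
a time-calibrated, ultrametric genus-level phylogeny (a chronogram with
branch lengths in My, tips at 0 Ma). This note documents the models, the
sampler, the decision rules, the synthetic-data generator, and the numerical
choices, in enough detail to reimplement them.

## Trait models

**Binary Mk model.** A single trait evolves on the tree as a continuous-time
Markov chain on {0, 1} with gain rate `q01` and loss rate `q10` (events per
My). The generator is

    Q = [[-q01, q01], [q10, -q10]],

and the transition matrix over a branch of length t is `exp(Qt)`. Tip data
enter through Felsenstein's pruning algorithm; a tip scored "both" (a genus
with species in both states) contributes partial likelihood 1 in each state
— standard ambiguity coding rather than taxon duplication. The root is
combined with a prior over states, uniform by default and configurable to
the stationary distribution; the original analysis does not state its root
treatment, so the conservative conventional default is used.

**Joint pair model.** Correlated evolution of two binary traits uses the
4-state joint chain on {00, 01, 10, 11}. The *dependent* model has 8 free
rates — each trait's gain and loss may differ between the two backgrounds of
the other trait — while the *independent* model ties them into 4 (each
trait's rates do not depend on the other's state), so the models are nested
with 4 degrees of freedom between them. Simultaneous double transitions
(00↔11, 01↔10) have rate exactly 0 in both.

## MCMC sampler

Rates get an exponential prior whose mean is itself a sampled
hyperparameter with a uniform(0, 30) prior (the "hyperprior seeding an
exponential from a uniform 0–30"). The full-scale presets are 10^7
iterations, 10^4 burn-in, one sample per 2000 iterations (ancestral-state
runs) and 5×10^6 iterations for correlation runs; desk-scale settings are
described below.

Moves, chosen per iteration:

* **Rate update (≈70–90%).** One rate class is picked uniformly; its value
  is perturbed by a uniform window of half-width `ratedev`, reflected at 0
  (a symmetric proposal). With 5% probability the update is instead an
  independence draw from the exponential prior; because the proposal equals
  the prior, its acceptance ratio is the bare likelihood ratio. This small
  admixture is what keeps the chain mobile across rate scales — a purely
  additive window with a single global `ratedev` cannot traverse the
  small-hypermean/small-rate corner of the joint prior in finite time, which
  is detectable as bias in the flat-likelihood smoke test.
* **Hyperparameter update (10%).** The exponential-prior mean moves by a
  reflected uniform step inside (0, 30); only the prior terms enter the
  acceptance ratio, so no likelihood evaluation is needed.
* **Reversible jump (20%, optional).** The rate vector is partitioned into
  shared-value classes plus a zero bin. A randomly chosen rate is proposed
  to move to the zero bin, to another existing class, or to a fresh
  singleton class whose value is drawn from the exponential prior. All
  partition structures carry equal prior weight, and prior-draw birth
  proposals make prior and proposal densities cancel, so the acceptance
  ratio is the likelihood ratio times the forward/reverse choice-count
  ratio (Jacobian 1).

`ratedev` is tuned by short pilot chains (three chains by default),
doubling or halving geometrically until the pooled *post-burn-in* acceptance
of rate moves lands in the 20–40% window. Acceptance is deliberately not
counted during burn-in: chains started far from the posterior accept almost
everything, and tuning on whole-chain acceptance yields step sizes with
near-zero equilibrium acceptance.

At every recorded sample the internal-node states are drawn once from their
joint conditional distribution given the tips and the current rates (a
pruning pass followed by a pre-order draw) and tallied into per-node state
posteriors; an exact analytic tally (up–down algorithm) is available for
fixed-rate runs and is used as the oracle in tests.

**Marginal likelihoods** are summarized by the harmonic mean of the sampled
likelihoods, computed in log space as `log n − logsumexp(−logL_i)`. The
estimator is kept because it is what the workflow this package reproduces
used; it has well-known high variance, so a block-jackknife Monte-Carlo
standard error accompanies every estimate.

## Correlated-evolution test

The dependent and independent chains are run on the same data (the
dependent chain with reversible jump, the independent chain confined to its
4 rates). The log-Bayes factor is twice the difference of the two log
harmonic means and is compared with the upper-α χ² quantile with df = 4;
at α = 0.05 the critical value is 9.49 and significance uses a strict
"greater than".

## Ancestral assignment, stem propagation, origin dating

A node's trait posterior is multiplied by the node's clade posterior
probability (support for the node's existence in the source tree; 1 at the
root and wherever support is absent). The product — the *corrected*
posterior — must exceed 0.95 for an unambiguous call; otherwise the node is
"ambiguous". Raising the threshold can only turn definite calls ambiguous.

Each node's probabilities are retained along its supporting stem (the
branch to its parent), constant between nodes. Stems are age intervals
[node age, parent age): a query at a node's own age reads that node's
assignment, and at age 0 the crossing stems are exactly the tips, which
makes the timeline conservation property exact at every gridpoint. Origin
dating reports the *stem-top* age of the oldest passing stem — the passing
node's parent age, or the root age when the root itself passes. Node-age
uncertainty intervals, when supplied with the inputs, are passed through
unchanged (no HPD recomputation).

The lineage timeline counts stems crossing each gridpoint of a 10-My age
grid by decision category (state calls and ambiguous separately, the
conservative default); an optional fractional mode splits each stem across
states by its corrected probabilities instead.

## DEC habitat model

Two areas — F (fireprone) and N (non-fireprone/rainforest) — give ranges
{F, N, FN} plus an absorbing null range. Anagenetic events along branches:
dispersal F→FN at `d_FN`, N→FN at `d_NF` ("unconstrained" means the two are
estimated independently; a symmetric option exists), contraction FN→F at
`e_N`, FN→N at `e_F`, and single-area extinction to the null range. At each
(strictly bifurcating) node the parent range is inherited under the classic
cladogenesis event set: single-area ranges copy to both daughters; FN
splits by vicariance (F|N, N|F) or subset sympatry (FN|F, F|FN, FN|N,
N|FN), all six equiprobable. The model is time-homogeneous.

Rates are fitted by L-BFGS-B in log space within [1e-9, 10]/My from five
fixed multi-starts (likelihood tolerance 1e-8). Node scenario probabilities
come from fixing each cladogenesis scenario in turn and renormalizing the
resulting tree likelihoods; marginals sum scenarios by parent range.
Dispersal/colonization events are read out two ways and deduplicated per
(node, direction): cladogenetically (the ML scenario gives one daughter an
area the other lacks) and anagenetically (a node's ML range gains an area
its parent's ML range lacks). The alternative trait-style route maps
F→1, N→0, FN→ambiguous and reuses the Mk machinery end to end.

## Net speciation rates

The stem-group net speciation rate is R_st = log(N)/t with N the summed
extant species count of the lineage and t its stem age; the natural
logarithm is the default (base 10 available) since stem-rate estimators of
this family conventionally use ln. Habitat divergence events are nodes
where one daughter stem is fireprone and the other non-fireprone, each with
corrected probability above 0.80; both daughters share the event node's age
as their stem age. Ratios always place the fireprone side in the numerator;
ratios with a zero denominator (single-species non-fireprone lineages) are
excluded and counted. Both arithmetic and geometric means are reported.

## Synthetic data

The generator emulates the empirical setting rather than any real matrix:
an 80-tip chronogram with a 113-My crown age, binary traits under Mk/pair
models, ranges under DEC, ambiguous tips, genus-level species counts.

* **Trees.** Forward birth–death simulation from two crown lineages,
  stopped just before the event that would change the tip count away from
  the target, pruned of extinct lineages, and rescaled so the crown age
  equals the target exactly (rescaling after simulation rather than
  conditioning, for simplicity; recorded in the manifest). Birth rates may
  be habitat-linked (a fireprone multiplier with habitat switching
  simulated jointly) for diversification tests.
* **Ranges.** DEC simulation on the fixed tree with cladogenesis draws at
  nodes; branch endpoints are drawn conditional on not reaching the null
  range, since every simulated lineage is extant by construction.
* **The fixture** (seed 777, taxa G001…G080, never real genus names): one
  mid-depth clade (~15 tips, crown ~67 Ma) is planted as an N→F
  colonization, with two of its tips set to FN to mimic mixed genera;
  serotiny, soil-storage and aril traits are simulated with
  habitat-dependent gain rates (0.030/My inside the fireprone clade vs
  0.002/My outside; 0.015/0.001 for the later-arising aril trait; loss
  0.004/My); species counts are 1+Poisson(30) for fireprone tips and
  1+Poisson(5) otherwise. The manifest records every true parameter.

What the generator does *not* emulate: phylogenetic uncertainty beyond a
single support value per node (no posterior tree sets), fossil calibration
error, diversified or incomplete taxon sampling, rate variation through
time, or extinction-driven tree shape effects at the default (pure-birth)
settings. Passing tests therefore show that the inference chain recovers
known structure under its own model assumptions at desk scale — not that
those assumptions hold for any particular empirical dataset.

## Numerical choices and problem sizes

* Matrix exponentials: the public `transition_probs` uses SciPy's
  scaling-and-squaring `expm`; the sampler's hot path batches all branches
  through one eigendecomposition (`P(t) = V exp(Λt) V⁻¹`) with a cheap
  identity-reconstruction conditioning probe and a per-branch `expm`
  fallback for defective generators. The two routes agree to ~1e-13 and
  both match the 2-state closed form to 1e-12.
* Pruning rescales partials per node (log-scale accumulator), so 200-tip
  likelihoods do not underflow; the recursion is numba-compiled with a pure
  NumPy fallback.
* Ultrametricity tolerance: relative 1e-6 of the root age. Newick branch
  lengths are written to 12 significant digits.
* Chains are pure functions of (data, config, seed); pipeline TSV outputs
  are byte-identical across reruns.
* Desk-scale sizes: the default "test" preset is 1e5 iterations / 1e3
  burn-in / thin 20. Replicated calibration studies (rate recovery,
  correlation error rates) use 15k-iteration chains on 150–200-tip trees —
  chosen as the smallest scale at which the prototype runs showed clean
  null calibration and full power — and the bundled fixture is used for
  detection, timeline and determinism checks. Full-scale presets ("paper",
  "paper-correlation") retain the original settings.

## Known limitations

* The harmonic-mean marginal likelihood is noisy; log-Bayes factors near
  the 9.49 threshold should be read together with their reported MC
  standard errors. Stepping-stone estimators are out of scope by design.
* For rare, strongly clustered traits the reversible-jump chain may prefer
  an irreversible-loss (Dollo-like) explanation — root state present, gains
  zeroed — which dates the trait's origin at the root with high corrected
  posterior. This is a genuine feature of model averaging under a uniform
  root prior, visible for the fixture's aril trait.
* Tree simulation conditions on the tip count by stopping at first passage,
  which is not an exact draw from the conditioned birth–death law; for the
  rank-order and calibration properties tested here the approximation is
  immaterial.
* The DEC fit reports ML rates without confidence intervals, and scenario
  probabilities are likelihood-profile weights at the ML rates (no
  rate-uncertainty averaging).
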