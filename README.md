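# pyroclad

Dating the origin of fire-adapted traits and fireprone habitats on
time-calibrated phylogenies.

Many plant lineages carry traits — serotiny (on-plant seed storage with
fire-cued release), persistent soil seed banks with heat/smoke-cued
germination, ant-dispersed arillate seeds — whose value depends on living
in fire-prone vegetation. `pyroclad` is for evolutionary biologists who
want to ask, on a genus-level chronogram with binary trait scores: *when
did fireprone habitats and their associated seed-storage syndromes arise,
are trait and habitat evolutionarily correlated, and did lineages speciate
faster after moving into fire?* It re-implements, as a tested and seeded
pipeline, the standard inference chain for these questions:

1. **Ancestral states** — continuous-time Markov (Mk) models of binary
   traits, reversible-jump MCMC over the rates `q01`, `q10` with a
   hyperprior (exponential prior whose mean is uniform on (0, 30)),
   proposal width tuned to 20–40% acceptance. A node is called
   unambiguously when its *corrected* posterior — node trait posterior ×
   clade posterior probability — exceeds 0.95, and node probabilities are
   held constant along the supporting stem until the next node rootward.
2. **Correlated evolution** — Pagel's dependent (8-rate) vs independent
   (4-rate) joint model of a trait pair; the log-Bayes factor
   `2(log HM_dep − log HM_indep)` from harmonic-mean marginal likelihoods
   is compared with the χ² upper-5% quantile at df = 4 (9.49, strict
   inequality).
3. **Habitat biogeography** — a two-area dispersal–extinction–cladogenesis
   (DEC) model over ranges {F, N, FN} with unconstrained dispersal,
   maximum-likelihood rates, per-node inheritance-scenario probabilities,
   and read-out of rainforest→fireprone colonization events; plus the
   alternative "habitat as a heritable trait" route through the Mk
   machinery.
4. **Diversification** — stem-group net speciation rates
   `R_st = log(N)/t` compared between the fireprone and non-fireprone
   sides of each habitat-divergence event (daughters called at corrected
   probability > 0.80).
5. **Synthetic data** — seeded generators for birth–death chronograms
   (optionally with habitat-linked birth rates), Mk/pair-model traits, DEC
   ranges, and a bundled 80-tip, 113-My fixture with a planted
   rainforest→fireprone colonization and known ground truth.

Everything is deterministic given a seed; the full-scale chain settings of
the original workflow are available as the `"paper"` preset, with
desk-scale presets for development.

## Worked example

Generate the synthetic bundle and run the whole pipeline:

```bash
pyroclad simulate --seed 777 --out bundle/
pyroclad all --tree bundle/tree.nwk --traits bundle/traits.tsv \
    --ranges bundle/ranges.tsv --species-counts bundle/species_counts.tsv \
    --out-dir results/ --iterations 15000 --seed 42
```

The run writes per-stage TSVs (DEC reconstruction and events, per-trait
node assignments, origins, a 10-My lineage timeline, correlation tests,
divergence events) plus `report.txt`:

```
pyroclad pipeline report
==============================

tips: 80; root age: 113 Ma
DEC: d_FN=0.004802 d_NF=0.0004379 per My; N->F dispersal/divergence events: 1

trait origins (oldest stem-top age with corrected PP above threshold):
  habitat: 85.44 Ma
  serotiny: 66.81 Ma
  soil_storage: 66.81 Ma
  aril: 113 Ma

correlation tests (log-Bayes factor vs chi-square critical value):
  serotiny x habitat: log-BF=63.89 (crit 9.488, df 4) -> significant
  soil_storage x habitat: log-BF=6.027 (crit 9.488, df 4) -> not significant
  aril x habitat: log-BF=20.58 (crit 9.488, df 4) -> significant

divergence events: 1; mean fireprone/non-fireprone net speciation ratio: 1.362
```

Reading this: the single planted rainforest→fireprone colonization is
recovered as one N→F event; the fireprone habitat is dated to 85.4 Ma —
the stem top of the planted clade (its crown sits at 66.8 Ma), exactly
where the generator put it; the two storage traits that were simulated
with 15-fold higher gain rates inside the fireprone clade date to that
clade's crown, and serotiny and aril show significant trait–habitat
correlation (log-BF far above 9.49) while this particular soil-storage
draw does not clear the threshold. The aril origin at the root illustrates
a documented behavior of reversible-jump model averaging: for a rare,
tightly clustered trait the chain can prefer a loss-only explanation with
the state present at the root (see `docs/methods.md`). The speciation-rate
ratio of 1.36 reflects the fixture's larger species counts in fireprone
genera.

As a library, the same stages are plain functions:

```python
from pyroclad import (make_fixture, MkModel, run_chain, McmcConfig,
                      assign_nodes, date_origin)

fx = make_fixture(seed=777)
col = fx.traits.column_for_tree("serotiny", fx.tree)
trace = run_chain(fx.tree, col, MkModel(0.1, 0.1),
                  McmcConfig(iterations=15_000, burn_in=1_500, thin=15,
                             ratedev=0.05, seed=1))
aset = assign_nodes(trace, fx.tree, trait="serotiny", tip_states=col)
print(date_origin(aset, fx.tree, derived_state=1).age)
```

## Layout

```
src/pyroclad/
  treeio.py          Newick chronograms, trait tables, validation
  ctmc.py            Mk and joint pair models, pruning likelihoods, simulation
  mcmc_engine.py     RJ-MCMC, hyperprior, ratedev tuning, harmonic means
  ancestral.py       corrected posteriors, stem propagation, origins, timeline
  correlated.py      dependent vs independent test, log-Bayes factors
  dec.py             two-area DEC: generator, likelihood, fit, events
  diversification.py stem rates and sister-clade ratios
  synthetic_data.py  seeded simulators and the bundled fixture
  pipeline.py, cli.py   orchestration and the `pyroclad` command
```

`docs/methods.md` documents the models, sampler, decision rules, generator
and numerical choices in detail.
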