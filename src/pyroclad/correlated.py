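"""Pagel-style test of correlated evolution between two binary traits.

Two models are fitted by MCMC on the joint 4-state space: a *dependent*
model (8 free rates; each trait's gain/loss may depend on the other trait's
state) and an *independent* model (4 rates; nested in the dependent model).
Their marginal likelihoods are summarized by harmonic means and compared by
the log-Bayes factor, twice the difference of the two log harmonic means,
judged against the upper-alpha chi-squared quantile with degrees of freedom
equal to the parameter-count difference (4): at alpha = 0.05 the critical
value is 9.49 and significance uses a strict "greater than".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from pyroclad.ctmc import PairModel
from pyroclad.mcmc_engine import McmcConfig, Trace, harmonic_mean_logL, harmonic_mean_se, run_chain
from pyroclad.treeio import AMBIGUOUS, Chronogram

DF_PAIR = 4  # 8 dependent rates - 4 independent rates


def bf_critical_value(df: int, alpha: float) -> float:
    """Upper-``alpha`` quantile of the chi-squared distribution with ``df``
    degrees of freedom — the decision threshold for the log-Bayes factor."""
    if not (isinstance(df, (int, np.integer)) and df >= 1):
        raise ValueError("df must be an integer >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    return float(stats.chi2.ppf(1.0 - alpha, df))


@dataclass
class CorrelationTest:
    """Result of one dependent-vs-independent comparison."""

    trait_a: str
    trait_b: str
    hm_dependent: float
    hm_independent: float
    df: int
    alpha: float
    critical_value: float
    hm_se_dependent: float = float("nan")
    hm_se_independent: float = float("nan")

    @property
    def log_bayes_factor(self) -> float:
        return 2.0 * (self.hm_dependent - self.hm_independent)

    @property
    def significant(self) -> bool:
        return self.log_bayes_factor > self.critical_value

    @property
    def mc_se(self) -> float:
        """Monte-Carlo SE of the log-BF (block jackknife, both chains)."""
        return 2.0 * float(np.hypot(self.hm_se_dependent, self.hm_se_independent))


def _joint_states(states_a: np.ndarray, states_b: np.ndarray) -> np.ndarray:
    sa, sb = np.asarray(states_a, dtype=np.int8), np.asarray(states_b, dtype=np.int8)
    if sa.shape != sb.shape or sa.ndim != 1:
        raise ValueError("trait columns must be equal-length 1-D arrays")
    for name, col in (("A", sa), ("B", sb)):
        obs = col[col != AMBIGUOUS]
        if obs.size == 0 or (obs == obs[0]).all():
            raise ValueError(f"trait {name} is invariant; correlation test undefined")
    return np.column_stack([sa, sb])


def test_correlation(
    tree: Chronogram,
    states_a: np.ndarray,
    states_b: np.ndarray,
    config: McmcConfig,
    trait_a: str = "traitA",
    trait_b: str = "traitB",
    alpha: float = 0.05,
) -> CorrelationTest:
    """Run the dependent and independent chains and compare harmonic means.

    ``states_a``/``states_b`` are binary columns aligned with the tree tips
    (ambiguous allowed). The dependent chain explores the 8-rate model (with
    reversible-jump moves when enabled in ``config``); the independent chain
    is confined to the 4-rate tied model. Deterministic given ``config.seed``.
    """
    joint = _joint_states(states_a, states_b)
    dep_model = PairModel(np.full(8, 0.1), dependent=True)
    ind_model = PairModel.independent(0.1, 0.1, 0.1, 0.1)
    dep_trace = run_chain(tree, joint, dep_model, config, chain_index=0)
    ind_trace = run_chain(tree, joint, ind_model, replace(config, seed=config.seed + 1), chain_index=0)
    hm_dep = harmonic_mean_logL(dep_trace)
    hm_ind = harmonic_mean_logL(ind_trace)
    return CorrelationTest(
        trait_a=trait_a,
        trait_b=trait_b,
        hm_dependent=hm_dep,
        hm_independent=hm_ind,
        df=DF_PAIR,
        alpha=alpha,
        critical_value=bf_critical_value(DF_PAIR, alpha),
        hm_se_dependent=harmonic_mean_se(dep_trace),
        hm_se_independent=harmonic_mean_se(ind_trace),
    )


def correlation_report(tests: list[CorrelationTest]) -> pd.DataFrame:
    """Summary table of correlation tests (input order preserved)."""
    if not tests:
        raise ValueError("need at least one test to report")
    rows = []
    for t in tests:
        rows.append(
            {
                "trait_a": t.trait_a,
                "trait_b": t.trait_b,
                "log_bayes_factor": t.log_bayes_factor,
                "mc_se": t.mc_se,
                "df": t.df,
                "critical_value": t.critical_value,
                "significant": bool(t.significant),
            }
        )
    return pd.DataFrame(rows)
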