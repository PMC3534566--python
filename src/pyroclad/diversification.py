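"""Stem-group net speciation rates and sister-clade comparisons.

The stem-group net speciation rate of a lineage is R_st = log(N)/t with N
the number of extant species in the lineage and t its stem age (My); the
natural logarithm is the default and base 10 is available. Habitat
divergence events are internal nodes where one daughter stem is called
fireprone and the other non-fireprone with probability above a threshold
(default 0.80); at each event the fireprone-to-non-fireprone rate ratio is
reported with the fireprone side always in the numerator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pyroclad.ancestral import AssignmentSet
from pyroclad.treeio import Chronogram


def stem_rate(N: int, t: float, log_base: str = "natural") -> float:
    """Net speciation rate R_st = log(N)/t (per My)."""
    if not (isinstance(N, (int, np.integer)) and N >= 1):
        raise ValueError("N must be an integer >= 1")
    if t <= 0:
        raise ValueError("stem age t must be positive")
    if log_base == "natural":
        return math.log(N) / t
    if log_base in ("10", 10):
        return math.log10(N) / t
    raise ValueError("log_base must be 'natural' or '10'")


@dataclass
class DivergenceEvent:
    """A fireprone / non-fireprone split with its sister-lineage rates."""

    event_id: str
    node: int
    age: float  # Ma; stem age of both daughter lineages
    fire_tips: list[str]
    nonfire_tips: list[str]
    n_fire: int
    n_nonfire: int
    rate_fire: float
    rate_nonfire: float

    @property
    def ratio(self) -> float | None:
        """R_fire / R_nonfire; None when the non-fireprone rate is zero."""
        if self.rate_nonfire > 0:
            return self.rate_fire / self.rate_nonfire
        return None


def find_divergence_events(
    assignments: AssignmentSet,
    tree: Chronogram,
    species_counts: dict[str, int],
    threshold: float = 0.80,
    fire_state: int = 1,
    log_base: str = "natural",
) -> list[DivergenceEvent]:
    """Locate habitat divergence events and compute sister-lineage rates.

    An event is an internal node where one daughter's corrected fireprone
    probability and the other daughter's corrected non-fireprone probability
    both exceed ``threshold``. Species counts are summed over each daughter
    clade's tips; both lineages' stem age is the event node's age.
    """
    nonfire_state = 1 - fire_state
    events: list[DivergenceEvent] = []
    for v in sorted(tree.internal_indices(), key=lambda u: -tree.ages[u]):
        kids = tree.nodes[v].children
        if len(kids) != 2:
            continue
        pf = [assignments[c].prob(fire_state) for c in kids]
        pn = [assignments[c].prob(nonfire_state) for c in kids]
        fire_side = None
        if pf[0] > threshold and pn[1] > threshold:
            fire_side = 0
        elif pf[1] > threshold and pn[0] > threshold:
            fire_side = 1
        if fire_side is None:
            continue
        cf, cn = kids[fire_side], kids[1 - fire_side]
        fire_tips = [tree.nodes[t].label for t in tree.clade_tips(cf)]
        nonfire_tips = [tree.nodes[t].label for t in tree.clade_tips(cn)]
        for tip in fire_tips + nonfire_tips:
            if tip not in species_counts:
                raise KeyError(f"missing species count for tip '{tip}'")
        n_f = int(sum(species_counts[t] for t in fire_tips))
        n_n = int(sum(species_counts[t] for t in nonfire_tips))
        age = float(tree.ages[v])
        events.append(
            DivergenceEvent(
                event_id=f"D{len(events) + 1}",
                node=v,
                age=age,
                fire_tips=fire_tips,
                nonfire_tips=nonfire_tips,
                n_fire=n_f,
                n_nonfire=n_n,
                rate_fire=stem_rate(n_f, age, log_base),
                rate_nonfire=stem_rate(n_n, age, log_base),
            )
        )
    return events


def rate_ratio_summary(events: list[DivergenceEvent]) -> dict:
    """Per-event rate ratios with arithmetic and geometric means.

    Events whose non-fireprone rate is zero (single-species lineage) have an
    undefined ratio; they are excluded and counted.
    """
    if not events:
        raise ValueError("no divergence events supplied")
    ratios = [(e.event_id, e.ratio) for e in events]
    defined = [r for _, r in ratios if r is not None]
    if not defined:
        raise ValueError("all rate ratios are undefined (zero non-fireprone rates)")
    return {
        "ratios": {eid: r for eid, r in ratios if r is not None},
        "n_undefined": sum(1 for _, r in ratios if r is None),
        "mean_ratio": float(np.mean(defined)),
        "geometric_mean_ratio": float(np.exp(np.mean(np.log(defined)))),
    }


def events_frame(events: list[DivergenceEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "event": e.event_id,
                "node": e.node,
                "age": e.age,
                "N_fire": e.n_fire,
                "t_fire": e.age,
                "R_fire": e.rate_fire,
                "N_nonfire": e.n_nonfire,
                "t_nonfire": e.age,
                "R_nonfire": e.rate_nonfire,
                "ratio": e.ratio if e.ratio is not None else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["event", "node", "age", "N_fire", "t_fire", "R_fire", "N_nonfire", "t_nonfire", "R_nonfire", "ratio"],
    )
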