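"""Naive network inference over rewirings of the four core regulators.

Alternative inhibitory wirings of {pMad, Bam, Nos, Brat} (all non-self
repression edges over the fixed Dpp–receptor–pMad signaling backbone) are
screened against Wild-Type observations: for each topology the best
Wild-Type error over an exhaustive strong/weak lattice of edge strengths
(or a small global search when activation is allowed) decides acceptance
against a fitness threshold, and accepted topologies are reduced to the
parsimonious antichain — those containing no strictly smaller accepted
edge set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product as iproduct

import numpy as np

from .data import ObservationSet
from .model import (
    DEFAULT_REGULATORS,
    GermariumModel,
    NetworkTopology,
    default_parameters,
)
from .objectives import CategoryObjective, evaluate
from .scaling import ScalingConfig
from .search import screen as global_screen

logger = logging.getLogger(__name__)

DEFAULT_WT_THRESHOLD = 0.05


@dataclass
class NetworkCandidate:
    topology: NetworkTopology
    best_wt_error: float = np.inf
    accepted: bool = False
    parsimonious: bool = False

    @property
    def edge_count(self) -> int:
        return len(self.topology.edges)


def enumerate_inhibitory(max_edges: int | None = None,
                         regulators: tuple[str, ...] = DEFAULT_REGULATORS
                         ) -> list[NetworkTopology]:
    """All subsets of the 12 possible non-self repression edges among the
    four regulators (4096 without a cap), over the fixed signaling backbone."""
    possible = [(a, b, "repress") for a in regulators for b in regulators if a != b]
    cap = len(possible) if max_edges is None else max_edges
    topologies = []
    for k in range(cap + 1):
        for edges in combinations(possible, k):
            topologies.append(NetworkTopology(regulators, tuple(edges),
                                              name=f"net_{len(topologies)}"))
    return topologies


def screen_wt(topologies: list[NetworkTopology], obs_wt: ObservationSet,
              threshold: float = DEFAULT_WT_THRESHOLD,
              strong_weak: tuple[float, float] = (0.1, 10.0),
              mode: str = "lattice", budget: int = 64, seed: int = 0,
              scaling_cfg: ScalingConfig | None = None,
              max_combos: int = 4096,
              base_params=None) -> list[NetworkCandidate]:
    """Best Wild-Type error per topology; accepted iff ≤ threshold.

    ``mode='lattice'`` exhaustively samples strong/weak half-maximal
    concentrations per edge (K at strong_weak × the regulator's reference
    level φ/δ); ``mode='search'`` runs a small seeded global screen over the
    edge K values instead (used when activation is allowed).  Simulation
    failures reject that parameter point only, never the topology.
    """
    bad = [o.index for o in obs_wt if o.category != "WildType"]
    if bad:
        raise ValueError(f"screen_wt expects WildType-only observations; got {bad}")
    candidates = []
    for topo in topologies:
        params = base_params(topo) if base_params is not None else default_parameters(topo)
        model = GermariumModel(topo, params, obs_wt.region_map)
        knames = [f"K_{r}_{t}" for r, t, _ in topo.edges]
        best = np.inf
        if mode == "lattice":
            levels = []
            for (reg, tgt, _sign) in topo.edges:
                ref = params[f"phi_{reg}"] / params[f"delta_{reg}"]
                levels.append([strong_weak[0] * ref, strong_weak[1] * ref])
            combos = list(iproduct(*levels)) if knames else [()]
            if len(combos) > max_combos:
                logger.warning("truncating %d lattice combos to %d",
                               len(combos), max_combos)
                combos = combos[:max_combos]
            for combo in combos:
                pv = params.with_updates(dict(zip(knames, combo)))
                ov = evaluate(model, obs_wt, scaling_cfg, params=pv)
                if not ov.failed:
                    best = min(best, ov.values[0])
        elif mode == "search":
            if knames:
                obj = CategoryObjective(model, obs_wt, knames, scaling_cfg)
                bounds = {k: (1e-2 * params[k], 1e2 * params[k]) for k in knames}
                budget_t = max(budget, 2 * len(knames))
                sr = global_screen(obj, bounds, budget_t, seed)
                wt = sr.F[:, 0]
                best = float(np.nanmin(np.where(np.isfinite(wt), wt, np.nan)))
            else:
                ov = evaluate(model, obs_wt, scaling_cfg)
                best = ov.values[0] if not ov.failed else np.inf
        else:
            raise ValueError(f"unknown mode {mode!r}")
        candidates.append(NetworkCandidate(topo, float(best),
                                           accepted=bool(best <= threshold)))
    return candidates


def parsimony_filter(candidates: list[NetworkCandidate]) -> list[NetworkCandidate]:
    """Accepted topologies whose edge sets contain no strictly smaller
    accepted edge set (the minimal antichain under inclusion)."""
    accepted = [c for c in candidates if c.accepted]
    out = []
    for c in accepted:
        es = c.topology.edge_set()
        minimal = not any(
            other is not c and other.topology.edge_set() < es for other in accepted
        )
        c.parsimonious = minimal
        if minimal:
            out.append(c)
    return out


def candidates_to_dataframe(candidates: list[NetworkCandidate]):
    import pandas as pd

    return pd.DataFrame([
        dict(name=c.topology.name,
             edges=";".join(f"{r}-|{t}" if s == "repress" else f"{r}->{t}"
                            for r, t, s in c.topology.edges),
             edge_count=c.edge_count,
             best_wt_error=c.best_wt_error,
             accepted=c.accepted,
             parsimonious=c.parsimonious)
        for c in candidates
    ])
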