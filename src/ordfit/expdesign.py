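"""Model-based experiment design over perturbation × measurement candidates.

Candidate experiments are single and pairwise genetic perturbations (null,
heterozygous, doubled genomic content) of the species common to all
networks, combined with a choice of measured species.  For qualitative
(high/low) readouts, experiments are ranked by the variance over models of
expected predictions, by the Jaccard dissimilarity of model prediction
sets, or — for parameter refinement — by prediction variance among each
model's Representatives.  For quantitative readouts, local-sensitivity
statistics take the same discriminate/refine roles.  All per-cell objectives
are aggregated region-mean-then-sum so the four regions weigh equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product as iproduct
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import GERMLINE_REGIONS, GeneticCondition, RegionMap, condition_label
from .model import GermariumModel, ParameterVector, observable, simulate_steady
from .scaling import (
    ScalingConfig,
    min_range_and_gap,
    model_scale,
    total_variation,
)

DESIGN_SPECIES = ("Dpp", "Rec", "Mad", "Bam", "Nos", "Brat", "dMyc")
DESIGN_KINDS = ("null", "heterozygous", "doubled")


@dataclass(frozen=True)
class CandidateExperiment:
    condition: GeneticCondition
    measured: str

    @property
    def label(self) -> str:
        return f"{self.measured} in {condition_label(self.condition)}"


def enumerate_conditions(species_list: Sequence[str] = DESIGN_SPECIES,
                         kinds: Sequence[str] = DESIGN_KINDS
                         ) -> list[GeneticCondition]:
    """All single and unordered pairwise perturbations: |S|·|T| singles plus
    C(|S|,2)·|T|² pairs (7 species × 3 kinds → 210)."""
    if not species_list or not kinds:
        raise ValueError("species_list and kinds must be non-empty")
    conditions = [GeneticCondition.of((s, k))
                  for s in species_list for k in kinds]
    for s1, s2 in combinations(species_list, 2):
        for k1, k2 in iproduct(kinds, kinds):
            conditions.append(GeneticCondition.of((s1, k1), (s2, k2)))
    return conditions


def enumerate_experiments(species_perturb: Sequence[str] = DESIGN_SPECIES,
                          kinds: Sequence[str] = DESIGN_KINDS,
                          species_measure: Sequence[str] = ("pMad", "Bam", "Nos",
                                                            "Brat", "dMyc", "Dpp")
                          ) -> list[CandidateExperiment]:
    return [CandidateExperiment(c, m)
            for c in enumerate_conditions(species_perturb, kinds)
            for m in species_measure]


# ---------------------------------------------------------------------------
# qualitative predictions

def _canonical_intervals(y: np.ndarray, n_cat: int, cfg: ScalingConfig
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Fixed rank intervals tiling the output range.

    The minimum-range/minimum-gap heuristic fixes the interval width; the
    lowest interval hugs the output minimum and the intervals spread evenly
    so the highest ends at the output maximum (gaps never below the minimum
    gap).  Used for discretization, where interval placement must be anchored
    to the output scale rather than optimized away.
    """
    S = model_scale(y)
    d_min, g_min = min_range_and_gap(n_cat, S, cfg)
    base = float(y.min())
    if n_cat == 1:
        return np.array([base]), np.array([base + d_min])
    spread = float(y.max() - y.min()) - n_cat * d_min
    gap = max(spread / (n_cat - 1), g_min)
    lo = base + np.arange(n_cat) * (d_min + gap)
    return lo, lo + d_min


def qualitative_discretize(y: np.ndarray, region_map: RegionMap | None = None,
                           cfg: ScalingConfig | None = None) -> np.ndarray:
    """Expected qualitative observation: binary (0 = low, 1 = high) per region.

    Evaluates the Optimal Scaling relative error of every region labeling
    (2⁴ candidates) against the fixed canonical intervals and returns the
    labeling of minimal error; ties break toward fewer "high" regions, then
    lexicographically.
    """
    region_map = region_map or RegionMap()
    cfg = cfg or ScalingConfig()
    y = np.asarray(y, float)
    lo, hi = _canonical_intervals(y, 2, cfg)
    denom = total_variation(y) + cfg.epsilon_fraction * model_scale(y)
    regions = region_map.germline_regions
    slices = [region_map.slice0(r) for r in regions]

    best_label, best_err = None, np.inf
    for bits in iproduct((0, 1), repeat=len(regions)):
        err = 0.0
        for b, sl in zip(bits, slices):
            s = np.clip(y[sl], lo[b], hi[b])
            err += float((((y[sl] - s) / denom) ** 2).mean())
        key = (round(err, 12), sum(bits), bits)
        if best_label is None or key < (round(best_err, 12), sum(best_label),
                                        best_label):
            best_label, best_err = bits, err
    return np.asarray(best_label, int)


def prediction_ensemble(model: GermariumModel,
                        representatives: Sequence[ParameterVector],
                        experiment: CandidateExperiment,
                        region_map: RegionMap | None = None,
                        cfg: ScalingConfig | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-representative qualitative predictions and raw outputs.

    Returns (predictions (n_reps, 4) binary, raw outputs (n_reps, 17));
    failed simulations yield an all-low prediction and zero output row.
    """
    region_map = region_map or model.region_map
    preds, raws = [], []
    for pv in representatives:
        res = simulate_steady(model.with_params(pv), experiment.condition)
        if not res.ok:
            preds.append(np.zeros(len(region_map.germline_regions), int))
            raws.append(np.zeros(region_map.n_cells_germline))
            continue
        y = observable(res, experiment.measured)
        preds.append(qualitative_discretize(y, region_map, cfg))
        raws.append(y)
    return np.asarray(preds), np.asarray(raws)


def expected_prediction(predictions: np.ndarray) -> np.ndarray:
    """Per-region median of binary predictions over representatives
    (ties → low)."""
    P = np.atleast_2d(np.asarray(predictions))
    if P.shape[0] < 1:
        raise ValueError("need at least one representative")
    return (P.mean(axis=0) > 0.5).astype(int)


def _region_mean_sum(per_cell: np.ndarray, region_map: RegionMap) -> float:
    """Aggregate a per-cell statistic: mean within each region, summed."""
    return float(sum(per_cell[..., region_map.slice0(r)].mean()
                     for r in region_map.germline_regions))


def objective_expected_variance(ensembles: Mapping[str, np.ndarray],
                                region_map: RegionMap | None = None) -> float:
    """Variance over models of the expected (median) prediction, per region,
    aggregated region-mean-then-sum.  Requires ≥2 models."""
    region_map = region_map or RegionMap()
    if len(ensembles) < 2:
        raise ValueError("need at least two models to discriminate")
    expected = np.array([expected_prediction(P) for P in ensembles.values()])
    return float(expected.var(axis=0).sum())


def objective_jaccard(ensembles: Mapping[str, np.ndarray]) -> float:
    """Sum over model pairs of the Jaccard dissimilarity of prediction sets.

    Prediction sets are the unique qualitative vectors each model's
    Representatives predict (set semantics: duplicates cannot change the
    score).  Zero means all models predict the same set of outcomes; the
    maximum — the number of model pairs — means mutually exclusive sets.
    """
    names = list(ensembles)
    if len(names) < 2:
        raise ValueError("need at least two models")
    sets = {}
    for name in names:
        P = np.atleast_2d(np.asarray(ensembles[name]))
        if P.shape[0] == 0:
            raise ValueError(f"model {name!r} has no representatives")
        sets[name] = {tuple(row) for row in P}
    score = 0.0
    for a, b in combinations(names, 2):
        inter = len(sets[a] & sets[b])
        similarity = 2.0 * inter / (len(sets[a]) + len(sets[b]))
        score += 1.0 - similarity
    return score


def objective_prediction_variance(ensembles: Mapping[str, np.ndarray],
                                  region_map: RegionMap | None = None) -> float:
    """Sum over models of the per-region prediction variance among that
    model's Representatives (population variance), region-mean-summed."""
    total = 0.0
    for P in ensembles.values():
        P = np.atleast_2d(np.asarray(P, float))
        total += float(P.var(axis=0).sum())
    return total


# ---------------------------------------------------------------------------
# quantitative (sensitivity-based) designs

def quantitative_design(tables: Mapping[str, np.ndarray],
                        param_names: Sequence[str],
                        species_names: Sequence[str],
                        mode: str,
                        region_map: RegionMap | None = None) -> pd.DataFrame:
    """Sensitivity-based design table, rows = (perturbed feature, measured
    species).

    ``tables`` maps model name → sensitivities (n_reps, n_params,
    n_species, n_cells).  mode='discriminate': variance over models of the
    representative-mean sensitivity; mode='refine': sum over models of the
    variance among representatives.  Cells aggregate region-mean-then-sum;
    non-finite entries are excluded.
    """
    region_map = region_map or RegionMap()
    if mode not in ("discriminate", "refine"):
        raise ValueError("mode must be 'discriminate' or 'refine'")
    shapes = {name: t.shape[1:] for name, t in tables.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"sensitivity tables disagree on axes: {shapes}")
    n_params, n_species, _ = next(iter(shapes.values()))
    if n_params != len(param_names) or n_species != len(species_names):
        raise ValueError("axis names do not match table shape")
    if mode == "discriminate" and len(tables) < 2:
        raise ValueError("need at least two models to discriminate")

    clean = {name: np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
             for name, t in tables.items()}
    if mode == "discriminate":
        means = np.stack([t.mean(axis=0) for t in clean.values()])
        stat = means.var(axis=0)                       # (P, S, C)
    else:
        stat = sum(t.var(axis=0) for t in clean.values())

    rows = []
    for j, pname in enumerate(param_names):
        for k, sname in enumerate(species_names):
            rows.append(dict(experiment=pname, measured=sname, objective=mode,
                             score=_region_mean_sum(stat[j, k], region_map)))
    return pd.DataFrame(rows)


def design_table(scores: Mapping[CandidateExperiment, float],
                 objective: str) -> pd.DataFrame:
    rows = [dict(experiment=condition_label(e.condition), measured=e.measured,
                 objective=objective, score=s) for e, s in scores.items()]
    return pd.DataFrame(rows)


def rank_table(table: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Min–max normalize scores within each objective and sort descending."""
    if table.empty:
        raise ValueError("empty design table")
    out = table.copy()
    def _norm(g: pd.Series) -> pd.Series:
        lo, hi = g.min(), g.max()
        return (g - lo) / (hi - lo) if hi > lo else g * 0.0
    out["normalized"] = out.groupby("objective")["score"].transform(_norm)
    out = out.sort_values(["objective", "normalized"],
                          ascending=[True, False], kind="stable")
    if top_k is not None:
        out = out.groupby("objective", group_keys=False).head(top_k)
    return out.reset_index(drop=True)
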