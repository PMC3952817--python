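"""Optimal Scaling fitness estimation for ordinal observations.

Given a model output ``y`` over cells and an ordinal observation assigning
each observed cell a rank, Optimal Scaling chooses one interval per rank
(ordered, with minimum widths and gaps) and surrogate data values inside
those intervals that minimize a relative squared error to ``y``.  The
resulting minimal error is the best-case quantitative misfit of the model to
the qualitative observation: zero exactly when some rank-consistent interval
placement contains every observed model value.

Because the optimal surrogate for a fixed interval is simply the model value
clipped into the interval, the optimization reduces to placing the 2·N_cat
interval boundaries.  That reduced problem is solved here by a coarse grid
scan (when the dimension permits) refined by bounded quasi-Newton descent
from several deterministic starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .data import OrdinalObservation, RegionMap


class ScalingConfigurationError(ValueError):
    """Infeasible or invalid scaling configuration."""


@dataclass(frozen=True)
class ScalingConfig:
    """Tunables of the Optimal Scaling problem.

    epsilon_fraction
        ε as a fraction of the model output scale; keeps the relative error
        finite for flat outputs (total variation ν = 0).
    min_range_fraction_budget
        Asymptotic share ``b`` of the model scale consumed by the minimum
        interval ranges plus minimum gaps (default 0.75: for N ≥ 2 ranks the
        N minimum ranges take b·2/3 of the scale and the N−1 minimum gaps
        b·1/3, totalling b·S).
    lower_bound
        Hard floor for the lowest interval (0: concentrations non-negative).
    oracle_grid
        Per-dimension resolution of the internal coarse grid scan.
    """

    epsilon_fraction: float = 1e-6
    min_range_fraction_budget: float = 0.75
    lower_bound: float = 0.0
    oracle_grid: int = 5
    n_local_starts: int = 4

    def __post_init__(self) -> None:
        if self.epsilon_fraction <= 0:
            raise ScalingConfigurationError("epsilon_fraction must be > 0")
        if not (0 < self.min_range_fraction_budget <= 1):
            raise ScalingConfigurationError("min_range_fraction_budget must be in (0, 1]")


@dataclass(frozen=True)
class IntervalSet:
    """Ordered per-rank intervals [lower[r], upper[r]], r = 1..n_cat."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lower), np.asarray(self.upper)
        if lo.shape != hi.shape:
            raise ValueError("lower/upper length mismatch")
        if np.any(hi - lo < -1e-12):
            raise ValueError("interval with upper < lower")
        if np.any(lo[1:] - hi[:-1] < -1e-12):
            raise ValueError("intervals out of order / overlapping")

    @property
    def n_cat(self) -> int:
        return len(self.lower)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lower, float), np.asarray(self.upper, float)


@dataclass(frozen=True)
class ScalingSolution:
    """Optimized intervals, surrogate values and minimal error."""

    intervals: IntervalSet
    surrogates: np.ndarray          # per observed cell, model-output units
    error: float                    # sqrt of `inner`
    inner: float                    # sum over domains of mean per-cell error
    feasible_zero: bool


def model_scale(y: np.ndarray) -> float:
    """Scale S of a model output: range, falling back to max |y|, then 1."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("model output is empty")
    if not np.all(np.isfinite(y)):
        raise ValueError("model output contains non-finite values")
    s = float(y.max() - y.min())
    if s > 0:
        return s
    s = float(np.abs(y).max())
    return s if s > 0 else 1.0


def total_variation(y: np.ndarray) -> float:
    """Net variation ν = Σ_i |y_{i+1} − y_i| across the model geometry."""
    y = np.asarray(y, dtype=float)
    return float(np.abs(np.diff(y)).sum()) if y.size > 1 else 0.0


def min_range_and_gap(n_cat: int, S: float, cfg: ScalingConfig | None = None
                      ) -> tuple[float, float]:
    """Minimum interval range Δ_min and minimum inter-interval gap g_min.

    The heuristic reserves a fixed budget ``b`` of the model scale for the
    N_cat minimum ranges (2/3 of the budget) and the N_cat − 1 minimum gaps
    (1/3), so that N·Δ_min + (N−1)·g_min = b·S exactly for every N ≥ 2 —
    at the default b a maximum of 75% of the model scale is accounted for by
    the minimum ranges and gaps.  For N = 1 there is no gap constraint and
    g_min is returned as 0.
    """
    cfg = cfg or ScalingConfig()
    if n_cat < 1:
        raise ValueError("n_cat must be >= 1")
    if S <= 0:
        raise ValueError("model scale must be positive")
    b = cfg.min_range_fraction_budget
    d_min = (2.0 * b / 3.0) * S / n_cat
    g_min = (b / 3.0) * S / (n_cat - 1) if n_cat >= 2 else 0.0
    return d_min, g_min


def clip_surrogates(y: np.ndarray, intervals: IntervalSet, ranks: np.ndarray
                    ) -> np.ndarray:
    """Optimal surrogates for fixed intervals: y clipped into its rank's interval."""
    y = np.asarray(y, dtype=float)
    ranks = np.asarray(ranks, dtype=int)
    if ranks.min() < 1 or ranks.max() > intervals.n_cat:
        raise LookupError("cell rank without a matching interval")
    lo, hi = intervals.as_arrays()
    return np.clip(y, lo[ranks - 1], hi[ranks - 1])


def scaling_error(y: np.ndarray, s: np.ndarray, domains: Sequence[np.ndarray],
                  cfg: ScalingConfig | None = None, *,
                  nu: float | None = None, scale: float | None = None) -> float:
    """Relative error between model output ``y`` and surrogates ``s``.

    Per cell e_i = ((y_i − s_i)/(ν + ε))² with ν the total variation of the
    model output and ε = epsilon_fraction · S; the result is
    sqrt(Σ_domains mean_{i∈domain} e_i).  ``domains`` partition the observed
    cells (by region), weighting regions equally regardless of cell count.
    """
    cfg = cfg or ScalingConfig()
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y and s must be aligned")
    S = model_scale(y) if scale is None else scale
    v = total_variation(y) if nu is None else nu
    denom = v + cfg.epsilon_fraction * S
    e = ((y - s) / denom) ** 2
    inner = 0.0
    for dom in domains:
        dom = np.asarray(dom, dtype=int)
        if dom.size == 0:
            raise ValueError("empty observation domain")
        inner += float(e[dom].mean())
    return float(np.sqrt(inner))


# ---------------------------------------------------------------------------
# boundary-placement machinery

def _chain_to_bounds(V: np.ndarray, n_cat: int, lb: float, d_min: float,
                     g_min: float) -> tuple[np.ndarray, np.ndarray]:
    """Map slack vectors (m, 2·n_cat) to interval bounds (m, n_cat) each.

    Layout per row: [a0, w1, g2, w2, ..., gN, wN], all ≥ 0, where a0 lifts the
    first lower bound off ``lb``, w_r widens interval r beyond Δ_min and g_r
    widens the gap before interval r beyond g_min.
    """
    V = np.atleast_2d(V)
    m = V.shape[0]
    L = np.empty((m, n_cat))
    U = np.empty((m, n_cat))
    L[:, 0] = lb + V[:, 0]
    U[:, 0] = L[:, 0] + d_min + V[:, 1]
    for r in range(1, n_cat):
        L[:, r] = U[:, r - 1] + g_min + V[:, 2 * r]
        U[:, r] = L[:, r] + d_min + V[:, 2 * r + 1]
    return L, U


def _inner_for_bounds(L: np.ndarray, U: np.ndarray, y_obs: np.ndarray,
                      ranks0: np.ndarray, dom_masks: np.ndarray,
                      dom_sizes: np.ndarray, denom: float) -> np.ndarray:
    """Vectorized inner error for candidate bounds (m, n_cat) → (m,)."""
    lo = L[:, ranks0]                      # (m, n_obs)
    hi = U[:, ranks0]
    s = np.clip(y_obs[None, :], lo, hi)
    e = ((y_obs[None, :] - s) / denom) ** 2
    # (m, n_dom): mean error per domain
    dm = e @ dom_masks.T / dom_sizes[None, :]
    return dm.sum(axis=1)


def feasible_zero_error(y_obs: np.ndarray, ranks: np.ndarray, n_cat: int,
                        d_min: float, g_min: float, lb: float
                        ) -> tuple[bool, np.ndarray | None, np.ndarray | None]:
    """Greedy leftmost feasibility check for an exact (zero error) fit.

    Places intervals left to right as low as the constraints allow; a zero
    error assignment exists iff every observed rank's minimum model value
    stays above the running lower limit.  Returns (feasible, lower, upper)
    with the leftmost (hence smallest-span, lexicographically smallest)
    zero-error intervals when feasible.
    """
    y_obs = np.asarray(y_obs, float)
    ranks = np.asarray(ranks, int)
    L = np.empty(n_cat)
    U = np.empty(n_cat)
    prev_u = lb - g_min
    for r in range(1, n_cat + 1):
        lo_limit = max(prev_u + g_min, lb) if r > 1 else lb
        in_rank = y_obs[ranks == r]
        if in_rank.size:
            if in_rank.min() < lo_limit - 1e-12:
                return False, None, None
            L[r - 1] = lo_limit
            U[r - 1] = max(lo_limit + d_min, in_rank.max())
        else:
            L[r - 1] = lo_limit
            U[r - 1] = lo_limit + d_min
        prev_u = U[r - 1]
    return True, L, U


def solve_scaling_ranks(y_full: np.ndarray, region_ranks: dict[str, int],
                        n_cat: int, region_map: RegionMap,
                        cfg: ScalingConfig | None = None) -> ScalingSolution:
    """Optimal Scaling against per-region ranks of a full germline output.

    ``y_full`` covers all germline cells (CC excluded); the scale S and total
    variation ν are taken over the full geometry, while the error is
    evaluated only on the cells of the observed regions, with one equally
    weighted domain per region.
    """
    cfg = cfg or ScalingConfig()
    y_full = np.asarray(y_full, dtype=float)
    S = model_scale(y_full)
    nu = total_variation(y_full)
    d_min, g_min = min_range_and_gap(n_cat, S, cfg)

    regions = [r for r in region_map.germline_regions if r in region_ranks]
    if not regions:
        raise ValueError("no observed regions")
    cells, ranks, domains = [], [], []
    pos = 0
    for r in regions:
        idx = [c - 1 for c in region_map.cells(r)]
        cells.extend(idx)
        ranks.extend([region_ranks[r]] * len(idx))
        domains.append(np.arange(pos, pos + len(idx)))
        pos += len(idx)
    y_obs = y_full[np.asarray(cells)]
    return _solve_scaling_core(y_obs, np.asarray(ranks), domains, n_cat,
                               S, nu, d_min, g_min, cfg)


def solve_scaling_cells(y: np.ndarray, ranks: np.ndarray,
                        domains: Sequence[np.ndarray] | None = None,
                        n_cat: int | None = None,
                        cfg: ScalingConfig | None = None, *,
                        nu: float | None = None,
                        scale: float | None = None) -> ScalingSolution:
    """Optimal Scaling for explicit per-cell ranks (geometry-free variant).

    By default the scale and total variation are those of ``y`` itself and
    all cells form one domain; callers embedding the cells in a larger
    geometry pass ``nu``/``scale`` explicitly.
    """
    cfg = cfg or ScalingConfig()
    y = np.asarray(y, float)
    ranks = np.asarray(ranks, int)
    n_cat = int(ranks.max()) if n_cat is None else n_cat
    S = model_scale(y) if scale is None else scale
    v = total_variation(y) if nu is None else nu
    d_min, g_min = min_range_and_gap(n_cat, S, cfg)
    domains = [np.arange(y.size)] if domains is None else domains
    return _solve_scaling_core(y, ranks, domains, n_cat, S, v, d_min, g_min, cfg)


def solve_scaling(y: np.ndarray, obs: OrdinalObservation, region_map: RegionMap,
                  cfg: ScalingConfig | None = None) -> ScalingSolution:
    """Optimal Scaling of one observation against a full model output."""
    return solve_scaling_ranks(y, obs.ranks, obs.n_categories, region_map, cfg)


def _solve_scaling_core(y_obs: np.ndarray, ranks: np.ndarray,
                        domains: Sequence[np.ndarray], n_cat: int,
                        S: float, nu: float, d_min: float, g_min: float,
                        cfg: ScalingConfig) -> ScalingSolution:
    # work in units of the model scale so the solution is exactly
    # scale-invariant; bounds and surrogates are mapped back at the end
    sol = _solve_scaling_unit(y_obs / S, ranks, domains, n_cat, nu / S,
                              d_min / S, g_min / S, cfg.lower_bound / S, cfg)
    lo, hi = sol.intervals.as_arrays()
    return ScalingSolution(IntervalSet(tuple(lo * S), tuple(hi * S)),
                           sol.surrogates * S, sol.error, sol.inner,
                           sol.feasible_zero)


def _solve_scaling_unit(y_obs: np.ndarray, ranks: np.ndarray,
                        domains: Sequence[np.ndarray], n_cat: int,
                        nu: float, d_min: float, g_min: float,
                        lb: float, cfg: ScalingConfig) -> ScalingSolution:
    S = 1.0
    denom = nu + cfg.epsilon_fraction * S
    ranks0 = ranks - 1

    n_obs = y_obs.size
    dom_masks = np.zeros((len(domains), n_obs))
    for k, dom in enumerate(domains):
        dom_masks[k, np.asarray(dom, int)] = 1.0
    dom_sizes = dom_masks.sum(axis=1)
    if np.any(dom_sizes == 0):
        raise ValueError("empty observation domain")

    # exact-fit shortcut: greedy leftmost placement
    ok, L0, U0 = feasible_zero_error(y_obs, ranks, n_cat, d_min, g_min, lb)
    if ok:
        intervals = IntervalSet(tuple(L0), tuple(U0))
        s = clip_surrogates(y_obs, intervals, ranks)
        return ScalingSolution(intervals, s, 0.0, 0.0, True)

    # bounded search over slack variables
    span = max(y_obs.max() + d_min - lb, d_min)
    nv = 2 * n_cat
    bounds = [(0.0, span)] * nv

    def inner_of(V: np.ndarray) -> np.ndarray:
        L, U = _chain_to_bounds(V, n_cat, lb, d_min, g_min)
        return _inner_for_bounds(L, U, y_obs, ranks0, dom_masks, dom_sizes, denom)

    seeds = list(_seed_slacks(y_obs, ranks, n_cat, lb, d_min, g_min, span))
    if nv <= 6:  # coarse grid scan where the dimension permits
        axes = [np.linspace(0.0, span, cfg.oracle_grid)] * nv
        grid = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
        vals = inner_of(grid)
        seeds.append(grid[int(np.argmin(vals))])

    best_v, best_inner = None, np.inf
    for v0 in seeds:
        res = minimize(lambda v: float(inner_of(v[None, :])[0]), v0,
                       method="L-BFGS-B", bounds=bounds)
        if res.fun < best_inner:
            best_inner, best_v = float(res.fun), res.x

    L, U = _chain_to_bounds(best_v[None, :], n_cat, lb, d_min, g_min)
    intervals = IntervalSet(tuple(L[0]), tuple(U[0]))
    s = clip_surrogates(y_obs, intervals, ranks)
    best_inner = max(best_inner, 0.0)
    return ScalingSolution(intervals, s, float(np.sqrt(best_inner)), best_inner,
                           feasible_zero=False)


def _seed_slacks(y_obs: np.ndarray, ranks: np.ndarray, n_cat: int, lb: float,
                 d_min: float, g_min: float, span: float):
    """Deterministic starting slack vectors: rank-wise quantiles of y."""
    nv = 2 * n_cat
    # seed 1: minimal chain anchored at lb
    yield np.zeros(nv)
    # seed 2: intervals spread toward rank-wise data quantiles
    v = np.zeros(nv)
    prev_u = lb
    for r in range(1, n_cat + 1):
        in_rank = y_obs[ranks == r]
        target_lo = float(np.quantile(in_rank, 0.25)) if in_rank.size else prev_u + g_min
        target_hi = float(np.quantile(in_rank, 0.75)) if in_rank.size else target_lo + d_min
        lo_limit = lb if r == 1 else prev_u + g_min
        lo = max(lo_limit, target_lo)
        hi = max(lo + d_min, target_hi)
        if r == 1:
            v[0] = min(max(lo - lb, 0.0), span)
        else:
            v[2 * (r - 1)] = min(max(lo - lo_limit, 0.0), span)
        v[2 * (r - 1) + 1] = min(max(hi - lo - d_min, 0.0), span)
        prev_u = hi
    yield v
    # seed 3: equal spread across the data range
    v = np.zeros(nv)
    lo, hi = float(y_obs.min()), float(y_obs.max())
    width = max((hi - lo) / n_cat, d_min)
    v[0] = max(lo - lb, 0.0)
    for r in range(1, n_cat):
        v[2 * r + 1] = max(width - d_min, 0.0)
    v[1] = max(width - d_min, 0.0)
    yield v
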