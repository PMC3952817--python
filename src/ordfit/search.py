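"""Hybrid global screening and multi-start local search in log parameter space.

The global screen allocates up to 75% of its budget to a deterministic
Smolyak sparse grid on nested Chebyshev–Gauss–Lobatto (CGL) nodes — which
doubles as the support of a rough polynomial interpolant used to seed
multi-objective searches — and the remainder to a seeded Latin hypercube.
Local refinement is bounded quasi-Newton descent (L-BFGS-B, numerical
gradients) from the best screened samples; all search coordinates are log10
parameter values, so positivity and range constraints are box bounds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product as iproduct
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

logger = logging.getLogger(__name__)

GRID_FRACTION_CAP = 0.75


# ---------------------------------------------------------------------------
# nested CGL nodes and Smolyak grids (unit cube coordinates)

def cgl_nodes(level: int) -> np.ndarray:
    """Full Chebyshev–Gauss–Lobatto node set of a level, mapped to [0, 1]."""
    if level == 0:
        return np.array([0.5])
    k = np.arange(2 ** level + 1)
    return (1.0 - np.cos(np.pi * k / 2 ** level)) / 2.0


def _delta_nodes(level: int) -> np.ndarray:
    """Nodes new at ``level`` relative to ``level − 1`` (nested families)."""
    if level == 0:
        return np.array([0.5])
    if level == 1:
        return np.array([0.0, 1.0])
    k = np.arange(1, 2 ** level, 2)
    return (1.0 - np.cos(np.pi * k / 2 ** level)) / 2.0


def _multi_indices(d: int, total_max: int, total_min: int = 0):
    def rec(prefix: list[int], remaining: int, dims: int):
        if dims == 0:
            if total_max - remaining >= total_min:
                yield tuple(prefix)
            return
        for v in range(remaining + 1):
            yield from rec(prefix + [v], remaining - v, dims - 1)
    yield from rec([], total_max, d)


def sparse_grid_points(d: int, level: int) -> np.ndarray:
    """Union sparse grid of total level ``level`` in the unit cube."""
    pts: list[tuple] = []
    for mi in _multi_indices(d, level):
        for combo in iproduct(*(_delta_nodes(l) for l in mi)):
            pts.append(combo)
    arr = np.unique(np.round(np.asarray(pts, float), 12), axis=0)
    return arr


def choose_grid_level(d: int, budget: int, cap: float = GRID_FRACTION_CAP
                      ) -> int | None:
    """Largest sparse-grid level whose node count fits within cap·budget.

    Returns None (pure Latin hypercube screen) when even the level-1 grid
    (2d + 1 points) exceeds the deterministic share of the budget.
    """
    allowed = cap * budget
    best = None
    for q in range(1, 12):
        n = len(sparse_grid_points(d, q))
        if n <= allowed:
            best = q
        else:
            break
    return best


# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Evaluated global screen: grid part first, then Latin hypercube."""

    X: np.ndarray                     # (n, d) log10 parameter points
    F: np.ndarray                     # (n, m) objective values
    n_grid: int
    level: int | None
    log_lo: np.ndarray
    log_hi: np.ndarray
    names: list[str]
    budget: int
    seed: int

    @property
    def n_dim(self) -> int:
        return self.X.shape[1]

    def unit(self, X: np.ndarray | None = None) -> np.ndarray:
        X = self.X if X is None else X
        return (X - self.log_lo) / (self.log_hi - self.log_lo)

    def from_unit(self, Z: np.ndarray) -> np.ndarray:
        return self.log_lo + Z * (self.log_hi - self.log_lo)

    def best(self, rank_by=None) -> tuple[np.ndarray, np.ndarray]:
        keys = self._rank_keys(rank_by)
        i = int(np.argmin(keys))
        return self.X[i], self.F[i]

    def _rank_keys(self, rank_by=None) -> np.ndarray:
        if rank_by is None:
            return np.where(np.all(np.isfinite(self.F), axis=1),
                            np.linalg.norm(np.nan_to_num(self.F, posinf=1e300), axis=1),
                            np.inf)
        return np.array([rank_by(f) for f in self.F])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"log10_{n}" for n in self.names])
        for j in range(self.F.shape[1]):
            df[f"objective_{j}"] = self.F[:, j]
        df["from_grid"] = np.arange(len(df)) < self.n_grid
        return df

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = dict(n_grid=self.n_grid, level=self.level, names=self.names,
                    log_lo=self.log_lo.tolist(), log_hi=self.log_hi.tolist(),
                    budget=self.budget, seed=self.seed)
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @staticmethod
    def load(path: str | Path) -> "ScreenResult":
        path = Path(path)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        df = pd.read_csv(path)
        xcols = [f"log10_{n}" for n in meta["names"]]
        fcols = [c for c in df.columns if c.startswith("objective_")]
        return ScreenResult(df[xcols].to_numpy(), df[fcols].to_numpy(),
                            meta["n_grid"], meta["level"],
                            np.asarray(meta["log_lo"]), np.asarray(meta["log_hi"]),
                            meta["names"], meta["budget"], meta["seed"])


def _log_bounds(bounds: dict[str, tuple[float, float]]
                ) -> tuple[list[str], np.ndarray, np.ndarray]:
    names = list(bounds)
    lo = np.array([bounds[n][0] for n in names], float)
    hi = np.array([bounds[n][1] for n in names], float)
    if np.any(lo <= 0) or np.any(hi <= lo):
        raise ValueError("bounds must satisfy 0 < lo < hi (positive parameters)")
    return names, np.log10(lo), np.log10(hi)


def screen(objective, bounds: dict[str, tuple[float, float]], budget: int,
           seed: int, grid_cap: float = GRID_FRACTION_CAP) -> ScreenResult:
    """Deterministic sparse grid + Latin hypercube screen.

    ``objective`` maps a log10 parameter vector to a vector of objective
    values; ``bounds`` are linear (positive) parameter ranges.  At most
    ``grid_cap`` of the budget is spent deterministically; the Latin
    hypercube remainder is reproducible from ``seed``.
    """
    names, log_lo, log_hi = _log_bounds(bounds)
    d = len(names)
    if budget < 2 * d:
        raise ValueError(f"budget {budget} too small for {d} parameters")

    level = choose_grid_level(d, budget, grid_cap)
    Z_grid = sparse_grid_points(d, level) if level is not None else np.empty((0, d))
    n_lhs = budget - len(Z_grid)
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    Z_lhs = sampler.random(n_lhs) if n_lhs > 0 else np.empty((0, d))
    Z = np.vstack([Z_grid, Z_lhs])
    X = log_lo + Z * (log_hi - log_lo)

    rows = [np.atleast_1d(np.asarray(objective(x), float)) for x in X]
    F = np.vstack(rows)
    return ScreenResult(X, F, len(Z_grid), level, log_lo, log_hi, names,
                        budget, seed)


@dataclass
class LocalSolution:
    x0: np.ndarray
    x: np.ndarray
    fun: float
    converged: bool
    nit: int
    f0: float = np.nan


def multistart(screen_result: ScreenResult, objective, k_starts: int = 8,
               rank_by=None, maxiter: int = 200) -> list[LocalSolution]:
    """Bounded local refinement from the best distinct screened samples.

    ``objective`` is the scalar to minimize over log10 parameters; starts
    are the ``k_starts`` best distinct screen points under ``rank_by``
    (default: the scalar ranking stored with the screen).  Solutions are
    returned sorted by final value, so the head is never worse than the best
    screened sample.
    """
    if len(screen_result.X) == 0:
        raise ValueError("empty screen")
    keys = screen_result._rank_keys(rank_by)
    order = np.argsort(keys, kind="stable")
    starts: list[np.ndarray] = []
    seen: set[bytes] = set()
    for i in order:
        if not np.isfinite(keys[i]):
            break
        key = np.round(screen_result.X[i], 10).tobytes()
        if key in seen:
            continue
        seen.add(key)
        starts.append(screen_result.X[i])
        if len(starts) >= k_starts:
            break

    bounds = list(zip(screen_result.log_lo, screen_result.log_hi))
    solutions = []
    for x0 in starts:
        f0 = float(objective(x0))
        try:
            res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter})
            solutions.append(LocalSolution(x0, res.x, float(res.fun),
                                           bool(res.success), int(res.nit), f0))
        except Exception as err:
            logger.warning("local search failed from %s: %s", x0, err)
    if not solutions:
        logger.warning("all local searches failed; returning empty list")
    solutions.sort(key=lambda s: s.fun if np.isfinite(s.fun) else np.inf)
    # never worse than the starting sample
    for s in solutions:
        if s.fun > s.f0:
            s.x, s.fun = s.x0, s.f0
    solutions.sort(key=lambda s: s.fun if np.isfinite(s.fun) else np.inf)
    return solutions


# ---------------------------------------------------------------------------
# Smolyak polynomial interpolant over the sparse grid

def _bary_weights(nodes: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Barycentric interpolation weights, (p, n) for evaluation points z."""
    n = len(nodes)
    if n == 1:
        return np.ones((len(z), 1))
    lam = np.ones(n)
    lam[1::2] = -1.0
    lam[0] *= 0.5
    lam[-1] *= 0.5
    diff = z[:, None] - nodes[None, :]
    exact = np.isclose(diff, 0.0, atol=1e-14)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = lam[None, :] / diff
    w[np.isnan(w) | np.isinf(w)] = 0.0
    hit = exact.any(axis=1)
    w[hit] = exact[hit].astype(float)
    return w / w.sum(axis=1, keepdims=True)


class SparseGridInterpolant:
    """Smolyak combination of tensor CGL interpolants fitted to screen values."""

    def __init__(self, screen_result: ScreenResult):
        if screen_result.n_grid == 0 or screen_result.level is None:
            raise ValueError("screen has no grid part")
        self.level = screen_result.level
        self.d = screen_result.n_dim
        Z = screen_result.unit()[: screen_result.n_grid]
        F = screen_result.F[: screen_result.n_grid].copy()
        finite = np.isfinite(F)
        if not finite.all():  # penalize failed corners without poisoning the fit
            colmax = np.where(finite, F, -np.inf).max(axis=0)
            colmax = np.where(np.isfinite(colmax), colmax, 1.0)
            F = np.where(finite, F, 10.0 * np.abs(colmax) + 1.0)
        self.m = F.shape[1]
        self._values = {tuple(np.round(z, 10)): F[i] for i, z in enumerate(Z)}
        self._terms = []
        q, d = self.level, self.d
        for mi in _multi_indices(d, q, total_min=max(0, q - d + 1)):
            s = sum(mi)
            coeff = (-1) ** (q - s) * comb(d - 1, q - s)
            if coeff == 0:
                continue
            node_sets = [cgl_nodes(l) for l in mi]
            shape = tuple(len(ns) for ns in node_sets)
            V = np.empty(shape + (self.m,))
            for idx in np.ndindex(shape):
                pt = tuple(np.round([node_sets[j][idx[j]] for j in range(d)], 10))
                V[idx] = self._values[pt]
            self._terms.append((coeff, node_sets, V))

    def __call__(self, Z: np.ndarray) -> np.ndarray:
        """Predicted objectives at unit-cube points (p, d) → (p, m)."""
        Z = np.atleast_2d(Z)
        out = np.zeros((len(Z), self.m))
        for coeff, node_sets, V in self._terms:
            T = np.broadcast_to(V, (len(Z),) + V.shape).copy()
            for j in range(self.d):
                W = _bary_weights(node_sets[j], Z[:, j])  # (p, n_j)
                T = np.einsum("pn,pn...->p...", W, T)
            out += coeff * T
        return out


def interpolant_seed(screen_result: ScreenResult, target: np.ndarray,
                     n_candidates: int = 2048) -> np.ndarray:
    """Parameter point whose (interpolated) objectives are nearest a target.

    Samples the sparse-grid interpolant densely (plus all screened points at
    their true values) and returns the log10 parameter point minimizing the
    Euclidean distance to ``target`` in normalized objective space.  Falls
    back to the nearest screened sample when the screen has no usable grid.
    """
    target = np.asarray(target, float)
    F = screen_result.F
    finite = np.all(np.isfinite(F), axis=1)
    Ff = np.where(np.isfinite(F), F, np.nan)
    f_lo = np.nanmin(Ff, axis=0)
    f_hi = np.nanmax(Ff, axis=0)
    span = np.where(f_hi > f_lo, f_hi - f_lo, 1.0)

    def normalize(A: np.ndarray) -> np.ndarray:
        return (A - f_lo) / span

    tz = normalize(target)
    cand_X = [screen_result.X[finite]]
    cand_Fz = [normalize(F[finite])]
    try:
        interp = SparseGridInterpolant(screen_result)
        rng = np.random.default_rng(screen_result.seed + 1)
        Z = rng.random((n_candidates, screen_result.n_dim))
        cand_X.append(screen_result.from_unit(Z))
        cand_Fz.append(normalize(interp(Z)))
    except ValueError:
        logger.debug("no grid part; interpolant seeding falls back to screen samples")
    Xall = np.vstack(cand_X)
    Fz = np.vstack(cand_Fz)
    dist = np.linalg.norm(Fz - tz[None, :], axis=1)
    return Xall[int(np.argmin(dist))]
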