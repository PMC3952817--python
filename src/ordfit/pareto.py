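"""Pareto front tracing by a modified Normalized Normal Constraint method.

Anchor points (single-objective minimizers) define an affine normalization
of objective space and the Utopian plane through the normalized anchors.
For each point of an even lattice on that plane, a bounded local search
minimizes progress along the inward plane normal while a quadratic penalty
holds the normalized objectives on the constraint line; searches are seeded
from the sparse-grid interpolant of the global screen, both at the plane
point and at configurable fractions along the inward normal.  Surviving
solutions plus the anchors are filtered for Pareto optimality, yielding the
Representative set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .search import LocalSolution, ScreenResult, interpolant_seed, multistart

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NNCConfig:
    """Knobs of the front solver.

    n_plane_points is the lattice density per simplex edge (7 gives 7 points
    for two objectives, 28 for three); extra_start_fractions are inward
    offsets along each normal constraint used as additional search seeds,
    guarding against local minima.
    """

    n_plane_points: int = 5
    extra_start_fractions: tuple[float, ...] = (0.25, 0.5, 0.75)
    k_anchor_starts: int = 8
    penalty_weight: float = 1e4
    line_tolerance: float = 1e-6
    maxiter: int = 200
    dedupe_distance: float = 1e-6

    def __post_init__(self) -> None:
        if any(not (0 < f < 1) for f in self.extra_start_fractions):
            raise ValueError("extra_start_fractions must lie strictly in (0, 1)")


@dataclass
class ParetoSet:
    """Anchors, Utopian point and the non-dominated Representatives."""

    anchors: list[tuple[np.ndarray, np.ndarray]]      # (x_log10, objectives)
    utopian: np.ndarray
    nadir: np.ndarray
    representatives: list[tuple[np.ndarray, np.ndarray]]
    names: list[str] = field(default_factory=list)
    objective_names: list[str] = field(default_factory=list)

    def objectives(self) -> np.ndarray:
        return np.array([f for _, f in self.representatives])

    def parameters(self) -> np.ndarray:
        return np.array([x for x, _ in self.representatives])

    def normalized(self, F: np.ndarray | None = None) -> np.ndarray:
        F = self.objectives() if F is None else F
        span = np.where(self.nadir > self.utopian, self.nadir - self.utopian, 1.0)
        return (F - self.utopian) / span

    def nearest_to_utopian(self) -> tuple[np.ndarray, np.ndarray]:
        Z = self.normalized()
        i = int(np.argmin(np.linalg.norm(Z, axis=1)))
        return self.representatives[i]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"log10_{n}" for n in self.names] if self.names else \
            [f"x{j}" for j in range(self.parameters().shape[1])]
        df = pd.DataFrame(self.parameters(), columns=cols)
        onames = self.objective_names or \
            [f"objective_{j}" for j in range(self.objectives().shape[1])]
        for j, n in enumerate(onames):
            df[n] = self.objectives()[:, j]
        return df


def pareto_filter(points: np.ndarray) -> list[int]:
    """Indices of the non-dominated points (weak dominance; duplicate
    objective vectors keep their first occurrence)."""
    F = np.atleast_2d(np.asarray(points, float))
    n = len(F)
    if n == 0:
        return []
    keep = []
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)   # le[j, i]: j ≤ i
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    eq = le & le.T
    for i in range(n):
        dominated = le[:, i] & (lt[:, i] | (eq[:, i] & (np.arange(n) < i)))
        dominated[i] = False
        if not dominated.any():
            keep.append(i)
    return keep


def solve_anchors(objective, screen_result: ScreenResult,
                  k_starts: int = 8, maxiter: int = 200
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """One anchor per objective: multistart minimization of that component.

    ``objective`` maps a log10 parameter vector to the full objective
    vector.  The screen (evaluated with full vectors) supplies the starts
    for every anchor — a single global screen serves all of them.
    """
    m = screen_result.F.shape[1]
    anchors = []
    for j in range(m):
        scalar = lambda x, j=j: float(np.asarray(objective(x))[j])
        sols = multistart(screen_result, scalar, k_starts,
                          rank_by=lambda f, j=j: f[j], maxiter=maxiter)
        if not sols:
            raise RuntimeError(f"anchor search failed for objective {j}")
        x = sols[0].x
        anchors.append((x, np.asarray(objective(x), float)))
    return anchors


def nnc_points(anchors_normalized: np.ndarray, density: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Even barycentric lattice on the Utopian plane plus the inward normal.

    Returns (plane_points, normal) in normalized objective space; the normal
    is orthogonal to the plane of the anchors and points toward lower
    objectives; it is shared by every plane point.
    """
    A = np.atleast_2d(np.asarray(anchors_normalized, float))
    m = A.shape[0]
    if m < 2:
        raise ValueError("need at least two anchors")
    diffs = A[1:] - A[0]
    if np.linalg.matrix_rank(diffs, tol=1e-9) < m - 1:
        logger.warning("anchors affinely dependent; using reduced plane basis")
    # normal: unit vector orthogonal to the plane, pointing inward
    _, _, Vt = np.linalg.svd(diffs, full_matrices=True)
    normal = Vt[-1]
    if normal.sum() > 0:
        normal = -normal
    # barycentric lattice with `density` points per edge
    if density < 2:
        weights = np.full((1, m), 1.0 / m)
    else:
        combos = _compositions(density - 1, m)
        weights = np.asarray(combos, float) / (density - 1)
    plane = weights @ A
    return plane, normal


def _compositions(total: int, parts: int) -> list[tuple[int, ...]]:
    if parts == 1:
        return [(total,)]
    out = []
    for v in range(total + 1):
        out.extend((v,) + rest for rest in _compositions(total - v, parts - 1))
    return out


def solve_front(objective, screen_result: ScreenResult,
                cfg: NNCConfig | None = None,
                objective_names: list[str] | None = None) -> ParetoSet:
    """Trace the Pareto front over the screened objective space.

    For each Utopian-plane lattice point, minimizes displacement along the
    inward normal subject to a quadratic penalty keeping the normalized
    objectives on the constraint line; solutions and anchors are filtered
    for Pareto optimality and deduplicated in parameter space.
    """
    cfg = cfg or NNCConfig()
    anchors = solve_anchors(objective, screen_result,
                            cfg.k_anchor_starts, cfg.maxiter)
    FA = np.array([f for _, f in anchors])
    utopian = FA.min(axis=0)
    nadir = FA.max(axis=0)
    span = np.where(nadir > utopian, nadir - utopian, 1.0)
    m = FA.shape[1]

    def norm_f(x: np.ndarray) -> np.ndarray:
        return (np.asarray(objective(x), float) - utopian) / span

    A_norm = (FA - utopian) / span
    plane, normal = nnc_points(A_norm, cfg.n_plane_points)

    w = cfg.penalty_weight
    bounds = list(zip(screen_result.log_lo, screen_result.log_hi))
    candidates: list[tuple[np.ndarray, np.ndarray]] = list(anchors)

    for p in plane:
        # distance from the plane point to the zero crossing along the normal
        t0 = float(p @ -normal)
        targets_norm = [p] + [p + f * t0 * normal for f in cfg.extra_start_fractions]
        seeds = []
        for tz in targets_norm:
            t_raw = utopian + np.clip(tz, 0.0, None) * span
            seeds.append(interpolant_seed(screen_result, t_raw))
        seen: set[bytes] = set()
        for x0 in seeds:
            key = np.round(x0, 10).tobytes()
            if key in seen:
                continue
            seen.add(key)

            def g(x: np.ndarray) -> float:
                z = norm_f(x)
                if not np.all(np.isfinite(z)):
                    return 1e6
                dz = z - p
                t = float(dz @ normal)
                perp = dz - t * normal
                return t + w * float(perp @ perp)

            try:
                res = minimize(g, x0, method="L-BFGS-B", bounds=bounds,
                               options={"maxiter": cfg.maxiter})
            except Exception as err:
                logger.warning("NNC search failed at plane point %s: %s", p, err)
                continue
            z = norm_f(res.x)
            if np.all(np.isfinite(z)):
                candidates.append((res.x, np.asarray(objective(res.x), float)))

    # dedupe in parameter space, then Pareto filter
    unique: list[tuple[np.ndarray, np.ndarray]] = []
    for x, f in candidates:
        if all(np.linalg.norm(x - ux) >= cfg.dedupe_distance for ux, _ in unique):
            unique.append((x, f))
    Fs = np.array([f for _, f in unique])
    keep = pareto_filter(Fs)
    reps = [unique[i] for i in keep]
    if not reps:
        logger.warning("no representatives survived filtering; returning anchors")
        reps = list(anchors)
    return ParetoSet(anchors, utopian, nadir, reps, screen_result.names,
                     objective_names or [f"objective_{j}" for j in range(m)])
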