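"""Per-category fitness objectives assembled from Optimal Scaling errors.

Observations are grouped into the three data categories — WildType, Mutant,
Behavioral — and each category's objective is the square root of the sum,
over its observations, of that observation's inner scaling error (itself a
sum over observation domains of mean per-cell error).  Simulations are
cached per distinct (condition, protocol) pair within one evaluation, and
each observation receives its own independent Optimal Scaling (per-antibody
/ per-experiment intensity scales are not comparable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CATEGORIES, GeneticCondition, ObservationSet
from .model import (
    GermariumModel,
    ParameterVector,
    SimulationResult,
    _integrate,
    apply_condition,
    divide_and_shift,
    observable,
    simulate_steady,
)
from .scaling import ScalingConfig, solve_scaling


@dataclass(frozen=True)
class ObjectiveVector:
    """(E_WT, E_Mut, E_Beh) with a per-observation error breakdown."""

    values: tuple[float, float, float]
    breakdown: dict[int, float] = field(default_factory=dict)
    failed: bool = False

    def __iter__(self):
        return iter(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @staticmethod
    def failure() -> "ObjectiveVector":
        return ObjectiveVector((np.inf, np.inf, np.inf), {}, failed=True)


def evaluate(model: GermariumModel, obs_set: ObservationSet,
             scaling_cfg: ScalingConfig | None = None,
             params: ParameterVector | None = None) -> ObjectiveVector:
    """Category objectives of one parameter set against an observation set.

    One ODE integration is performed per distinct (condition, protocol)
    pair; a dynamic observation's protocol reuses its condition's steady
    state.  Any simulation failure marks the whole vector failed (infinite
    values) rather than raising, so global screens survive bad corners.
    """
    scaling_cfg = scaling_cfg or ScalingConfig()
    if params is not None:
        model = model.with_params(params)

    steady_cache: dict[GeneticCondition, SimulationResult] = {}
    dynamic_cache: dict[GeneticCondition, SimulationResult] = {}

    def get_steady(cond: GeneticCondition) -> SimulationResult:
        if cond not in steady_cache:
            steady_cache[cond] = simulate_steady(model, cond)
        return steady_cache[cond]

    def get_dynamic(cond: GeneticCondition) -> SimulationResult:
        if cond not in dynamic_cache:
            steady = get_steady(cond)
            if not steady.ok:
                dynamic_cache[cond] = steady
            else:
                p = apply_condition(model.params, cond, model.topology)
                y0 = divide_and_shift(steady, model.region_map)
                dynamic_cache[cond] = _integrate(model, p, y0, 12.0)
        return dynamic_cache[cond]

    inner = dict.fromkeys(CATEGORIES, 0.0)
    breakdown: dict[int, float] = {}
    for obs in obs_set:
        result = get_dynamic(obs.condition) if obs.dynamic else get_steady(obs.condition)
        if not result.ok:
            return ObjectiveVector.failure()
        y = observable(result, obs.species)
        sol = solve_scaling(y, obs, obs_set.region_map, scaling_cfg)
        breakdown[obs.index] = sol.error
        inner[obs.category] += sol.inner
    values = tuple(float(np.sqrt(inner[c])) for c in CATEGORIES)
    return ObjectiveVector(values, breakdown)


class CategoryObjective:
    """Callable bridge from log10 parameter vectors to category objectives.

    Maps a point ``x`` (log10 values of the free parameters, in the order of
    ``free_names``) onto the model's parameter vector and evaluates the
    three category objectives.  Results are memoized by exact ``x`` so
    anchors and front searches can share screen evaluations.
    """

    def __init__(self, model: GermariumModel, obs_set: ObservationSet,
                 free_names: list[str],
                 scaling_cfg: ScalingConfig | None = None):
        self.model = model
        self.obs_set = obs_set
        self.free_names = list(free_names)
        self.scaling_cfg = scaling_cfg or ScalingConfig()
        self._cache: dict[bytes, ObjectiveVector] = {}
        self.n_evaluations = 0
        self.n_failures = 0

    @property
    def n_dim(self) -> int:
        return len(self.free_names)

    def params_at(self, x: np.ndarray) -> ParameterVector:
        updates = {k: 10.0 ** float(v) for k, v in zip(self.free_names, x)}
        return self.model.params.with_updates(updates)

    def evaluate(self, x: np.ndarray) -> ObjectiveVector:
        key = np.asarray(x, float).tobytes()
        if key not in self._cache:
            self.n_evaluations += 1
            ov = evaluate(self.model, self.obs_set, self.scaling_cfg,
                          params=self.params_at(x))
            if ov.failed:
                self.n_failures += 1
            self._cache[key] = ov
        return self._cache[key]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.evaluate(x).as_array()

    def component(self, j: int):
        """Scalar view of objective ``j`` for single-objective search."""
        def f(x: np.ndarray) -> float:
            return float(self.evaluate(x).values[j])
        return f
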