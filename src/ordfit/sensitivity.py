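"""Relative local sensitivity of model observables by finite differences.

Sensitivities are forward-difference estimates scaled by the nominal
parameter and output values, so an entry of 1 means "a 1% parameter change
moves this output by 1%".  A floor on the nominal output guards division
where an output is identically zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .data import GeneticCondition
from .model import GermariumModel, ParameterVector, observable, simulate_steady


def local_sensitivity(model: GermariumModel, parameter: str,
                      condition: GeneticCondition = GeneticCondition.wild_type(),
                      species: Sequence[str] | None = None,
                      h_rel: float = 0.01,
                      params: ParameterVector | None = None
                      ) -> dict[str, np.ndarray]:
    """Relative sensitivity of steady-state observables to one parameter.

    S = ((y(θ(1+h)) − y(θ)) / (h·θ)) · (θ / max(y(θ), floor)) per output,
    with floor = 1e-12 × output scale.  Returns species → per-cell values;
    a failed perturbed simulation yields NaN entries (excluded downstream).
    """
    if not (0 < h_rel < 0.5):
        raise ValueError("h_rel must lie in (0, 0.5)")
    if params is not None:
        model = model.with_params(params)
    theta = model.params[parameter]
    if theta <= 0:
        raise ValueError(f"parameter {parameter} must be positive for relative steps")
    species = list(species) if species is not None else \
        list(model.topology.species) + ["Dpp"]

    base = simulate_steady(model, condition)
    pert_model = model.with_params(model.params.with_updates({parameter: theta * (1 + h_rel)}))
    pert = simulate_steady(pert_model, condition)

    out: dict[str, np.ndarray] = {}
    for s in species:
        y0 = observable(base, s)
        if not (base.ok and pert.ok):
            out[s] = np.full_like(y0, np.nan)
            continue
        y1 = observable(pert, s)
        scale = max(float(np.abs(y0).max()), 1.0)
        floor = 1e-12 * scale
        out[s] = (y1 - y0) / (h_rel * np.maximum(y0, floor))
    return out


def sensitivity_array(model: GermariumModel,
                      representatives: Sequence[ParameterVector],
                      parameters: Sequence[str],
                      species: Sequence[str],
                      condition: GeneticCondition = GeneticCondition.wild_type(),
                      h_rel: float = 0.01) -> np.ndarray:
    """Stacked sensitivities (n_reps, n_params, n_species, n_cells)."""
    n_cells = model.region_map.n_cells_germline
    out = np.empty((len(representatives), len(parameters), len(species), n_cells))
    for i, pv in enumerate(representatives):
        for j, p in enumerate(parameters):
            sens = local_sensitivity(model, p, condition, species, h_rel, params=pv)
            for k, s in enumerate(species):
                out[i, j, k] = sens[s]
    return out


def sensitivity_table(model: GermariumModel,
                      representatives: Sequence[ParameterVector],
                      parameters: Sequence[str],
                      species: Sequence[str],
                      condition: GeneticCondition = GeneticCondition.wild_type(),
                      h_rel: float = 0.01) -> pd.DataFrame:
    """Tidy per-entry table: representative, parameter, species, cell, value."""
    arr = sensitivity_array(model, representatives, parameters, species,
                            condition, h_rel)
    rows = []
    for i in range(arr.shape[0]):
        for j, p in enumerate(parameters):
            for k, s in enumerate(species):
                for c in range(arr.shape[3]):
                    rows.append((i, p, s, c + 1, arr[i, j, k, c]))
    return pd.DataFrame(rows, columns=["representative", "parameter",
                                       "species", "cell", "value"])
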