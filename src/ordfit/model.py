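"""One-dimensional compartment models of the anterior germarium.

A model is a line of 18 ODE compartments — the somatic cap cell (CC,
compartment 0) followed by 17 germline cells — carrying extracellular Dpp
(secreted by the CC only, diffusing with no-flux ends), Dpp–receptor
complexes (no receptors in the CC) and intracellular regulators.  Regulator
production is a product of Hill terms, one per incoming network edge, with
cooperativity 2; pMad production is additionally driven by the local bound
complex level through the same saturating form.

Two simulation protocols are provided: a 24 h integration from a null state
(the steady-state protocol) and a post-division protocol that shifts zone
averages posteriorly by one zone and integrates a further 12 h, over whose
trailing 6 h the phenotype output (time-averaged Brat) is evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .data import GeneticCondition, RegionMap

DEFAULT_REGULATORS = ("pMad", "Bam", "Nos", "Brat")


class ModelValidationError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkTopology:
    """A regulatory wiring: species plus signed (regulator, target) edges."""

    species: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]  # (regulator, target, sign)
    name: str = ""

    def __post_init__(self) -> None:
        for reg, tgt, sign in self.edges:
            if sign not in ("repress", "activate"):
                raise ModelValidationError(f"edge sign {sign!r} invalid")
            if reg not in self.species or tgt not in self.species:
                raise ModelValidationError(f"edge {reg}->{tgt} references unknown species")
            if reg == tgt:
                raise ModelValidationError("self-edges are excluded")
        if len(set(self.edges)) != len(self.edges):
            raise ModelValidationError("duplicate edges")

    def edges_into(self, target: str) -> list[tuple[str, str]]:
        return [(reg, sign) for reg, tgt, sign in self.edges if tgt == target]

    def without_edge(self, reg: str, tgt: str) -> "NetworkTopology":
        kept = tuple(e for e in self.edges if (e[0], e[1]) != (reg, tgt))
        return dc_replace(self, edges=kept, name=self.name + f"-no_{reg}_{tgt}")

    def edge_set(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(self.edges)


def core_topology(with_dmyc: bool = True) -> NetworkTopology:
    """Consensus chain of repressors pMad⊣Bam⊣Nos⊣Brat with Brat⊣pMad feedback.

    With ``with_dmyc`` the growth regulator dMyc is included as in the full
    germarium models (repressed by Brat, promoting pMad signaling); the bare
    four-regulator wiring is used for naive network screens.
    """
    species = DEFAULT_REGULATORS + (("dMyc",) if with_dmyc else ())
    edges = [
        ("pMad", "Bam", "repress"),
        ("Bam", "Nos", "repress"),
        ("Nos", "Brat", "repress"),
        ("Brat", "pMad", "repress"),
    ]
    if with_dmyc:
        edges += [("Brat", "dMyc", "repress"), ("dMyc", "pMad", "activate")]
    return NetworkTopology(species, tuple(edges), name="Core")


def alt1_topology(with_dmyc: bool = True) -> NetworkTopology:
    """Core without the Brat⊣pMad feedback edge."""
    t = core_topology(with_dmyc).without_edge("Brat", "pMad")
    return dc_replace(t, name="Alt1")


def piwi_topology() -> NetworkTopology:
    """Core plus a hypothetical Piwi branch.

    Piwi (with its piRNAs) is taken to sustain pMad — it represses an
    unmodeled ubiquitin ligase that degrades pMad, collapsed here to a net
    activation edge — while Bam and Brat repress Piwi.  A simplification of
    the hypothesized mechanism to the plain edge formalism.
    """
    core = core_topology()
    return NetworkTopology(
        core.species + ("Piwi",),
        core.edges + (("Bam", "Piwi", "repress"),
                      ("Brat", "Piwi", "repress"),
                      ("Piwi", "pMad", "activate")),
        name="Piwi")


def ago_topology() -> NetworkTopology:
    """Core plus a hypothetical Argonaute/miRNA branch.

    Ago stands for the combined Argonaute-1 / miR-184 function repressing
    Dpp signal transduction; Brat (as the TRIM-NHL partner) represses Ago.
    Net effect: an indirect positive feedback of Brat on pMad relief,
    expressed with plain edges.
    """
    core = core_topology()
    return NetworkTopology(
        core.species + ("Ago",),
        core.edges + (("Brat", "Ago", "repress"),
                      ("Ago", "pMad", "repress")),
        name="Ago")


#: scalar (non per-species) parameter names
SIGNALING_PARAMS = (
    "dpp_secretion",        # Dpp secretion rate at the CC [conc/h]
    "dpp_diffusion",        # diffusion coefficient [cell^2/h]
    "dpp_kon",              # receptor binding [1/(conc h)]
    "dpp_koff",             # complex dissociation [1/h]
    "dpp_internalization",  # complex internalization/degradation [1/h]
    "dpp_degradation",      # free ligand degradation [1/h]
    "receptor_total",       # receptor level per germline cell [conc]
    "k_signal",             # half-max complex level for pMad production [conc]
)


@dataclass(frozen=True)
class ParameterVector:
    """Named positive model parameters.

    Naming: ``phi_<species>`` production, ``delta_<species>`` degradation,
    ``K_<regulator>_<target>`` half-maximal concentration per edge, the
    scalar signaling parameters of :data:`SIGNALING_PARAMS`, ``dx`` cell
    spacing, ``hill_n`` (2 throughout) and ``overexpression_rate``, the
    ectopic production used by overexpression conditions.  ``ectopic`` holds
    condition-applied uniform ectopic production per species and
    ``ectopic_dpp_secretion`` uniform ectopic ligand secretion.
    """

    values: Mapping[str, float]
    ectopic: Mapping[str, float] = field(default_factory=dict)
    ectopic_dpp_secretion: float = 0.0

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ModelValidationError(f"parameter {k} = {v} must be finite and >= 0")
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "ectopic", dict(self.ectopic))

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def get(self, name: str, default: float | None = None) -> float:
        if name in self.values:
            return self.values[name]
        if default is None:
            raise KeyError(name)
        return default

    def names(self) -> list[str]:
        return sorted(self.values)

    def with_updates(self, updates: Mapping[str, float]) -> "ParameterVector":
        merged = dict(self.values)
        merged.update(updates)
        return ParameterVector(merged, self.ectopic, self.ectopic_dpp_secretion)

    def scaled(self, name: str, factor: float) -> "ParameterVector":
        return self.with_updates({name: self.values[name] * factor})


def default_parameters(topology: NetworkTopology, **overrides: float) -> ParameterVector:
    """Reference parameters giving O(1) concentrations and hour-scale kinetics.

    Every edge receives one half-maximal concentration K at half the
    regulator's reference level φ/δ = 1.  These serve as centers for the
    log-uniform search ranges; they are not fitted values.
    """
    vals: dict[str, float] = {}
    for s in topology.species:
        vals[f"phi_{s}"] = 5.0 if s == "pMad" else 1.0
        vals[f"delta_{s}"] = 1.0
    for reg, tgt, _ in topology.edges:
        vals[f"K_{reg}_{tgt}"] = 0.5
    vals.update(
        dpp_secretion=10.0,
        dpp_diffusion=2.0,
        dpp_kon=1.0,
        dpp_koff=0.1,
        dpp_internalization=1.0,
        dpp_degradation=0.5,
        receptor_total=1.0,
        k_signal=0.2,
        dx=1.0,
        hill_n=2.0,
        overexpression_rate=1.0,
    )
    vals.update(overrides)
    return ParameterVector(vals)


@dataclass(frozen=True)
class GermariumModel:
    """Topology + parameters + geometry defining the ODE system."""

    topology: NetworkTopology
    params: ParameterVector
    region_map: RegionMap = field(default_factory=RegionMap)

    @property
    def n_cells(self) -> int:
        """Germline cells (CC excluded)."""
        return self.region_map.n_cells_germline

    @property
    def state_dim(self) -> int:
        n = self.n_cells
        return (n + 1) + n + len(self.topology.species) * n

    def with_params(self, params: ParameterVector) -> "GermariumModel":
        return dc_replace(self, params=params)


@dataclass
class SimulationResult:
    """Trajectories on an hourly-resolved grid plus derived outputs."""

    t: np.ndarray                      # hours
    dpp: np.ndarray                    # (nt, n_cells+1) extracellular ligand
    complex: np.ndarray                # (nt, n_cells) bound receptor
    traj: dict[str, np.ndarray]        # species -> (nt, n_cells)
    region_map: RegionMap
    ok: bool = True
    message: str = ""

    def final(self, species: str) -> np.ndarray:
        return self.traj[species][-1]

    def trailing_mean(self, species: str, window: float = 6.0) -> np.ndarray:
        """Per-cell mean of a species over the trailing ``window`` hours."""
        mask = self.t >= self.t[-1] - window - 1e-9
        return self.traj[species][mask].mean(axis=0)


# ---------------------------------------------------------------------------

_SPECIAL_TARGETS = {
    "Dpp": "dpp_secretion",
    "Rec": "receptor_total",
    "Mad": "phi_pMad",
}


def _perturbable_param(species: str, topology: NetworkTopology) -> str:
    if species in _SPECIAL_TARGETS:
        return _SPECIAL_TARGETS[species]
    if species == "pMad":
        return "phi_pMad"
    if species in topology.species:
        return f"phi_{species}"
    raise ModelValidationError(
        f"cannot perturb {species!r}: absent from topology {topology.name!r}"
    )


def apply_condition(params: ParameterVector, condition: GeneticCondition,
                    topology: NetworkTopology) -> ParameterVector:
    """Parameters under a genetic condition.

    null → production ×0; heterozygous → ×0.5; doubled → ×2 (2× genomic
    content); overexpress → uniform ectopic production added at
    ``overexpression_rate``.  Dpp perturbations act on secretion, Rec on the
    receptor level, Mad on pMad production.
    """
    out = params
    ect = dict(params.ectopic)
    ect_dpp = params.ectopic_dpp_secretion
    factor = {"null": 0.0, "heterozygous": 0.5, "doubled": 2.0}
    # apply nulls/het/doubled first so a null+OE pair composes correctly
    for species, kind in sorted(condition.perturbations,
                                key=lambda p: p[1] == "overexpress"):
        pname = _perturbable_param(species, topology)
        if kind in factor:
            out = out.scaled(pname, factor[kind])
        else:  # overexpress
            rate = params["overexpression_rate"]
            if species == "Dpp":
                ect_dpp += rate
            elif species in ("Rec",):
                out = out.with_updates({"receptor_total": out["receptor_total"] + rate})
            else:
                target = "pMad" if species == "Mad" else species
                ect[target] = ect.get(target, 0.0) + rate
    return ParameterVector(out.values, ect, ect_dpp)


def make_rhs(model: GermariumModel, params: ParameterVector):
    """Compile the ODE right-hand side for one model + applied parameters."""
    topo = model.topology
    n = model.n_cells
    ns = len(topo.species)
    p = params

    dx2 = p["dx"] ** 2
    Dc = p["dpp_diffusion"]
    sec = p["dpp_secretion"]
    kon, koff = p["dpp_kon"], p["dpp_koff"]
    kint, deg = p["dpp_internalization"], p["dpp_degradation"]
    Rtot = p["receptor_total"]
    ksig2 = p["k_signal"] ** 2
    hn = p["hill_n"]
    ect_dpp = p.ectopic_dpp_secretion

    sp_index = {s: i for i, s in enumerate(topo.species)}
    phi = np.array([p[f"phi_{s}"] for s in topo.species])
    delta = np.array([p[f"delta_{s}"] for s in topo.species])
    ectopic = np.array([p.ectopic.get(s, 0.0) for s in topo.species])
    edges = [
        (sp_index[reg], sp_index[tgt], p[f"K_{reg}_{tgt}"] ** hn, sign == "repress")
        for reg, tgt, sign in topo.edges
    ]
    i_pmad = sp_index.get("pMad")

    nD, nC = n + 1, n

    def rhs(t: float, u: np.ndarray) -> np.ndarray:
        D = u[:nD]
        C = u[nD:nD + nC]
        X = u[nD + nC:].reshape(ns, n)
        du = np.empty_like(u)
        dD = du[:nD]
        dC = du[nD:nD + nC]
        dX = du[nD + nC:].reshape(ns, n)

        # extracellular ligand: no-flux finite-difference diffusion
        lap = np.empty(nD)
        lap[1:-1] = D[:-2] - 2.0 * D[1:-1] + D[2:]
        lap[0] = D[1] - D[0]
        lap[-1] = D[-2] - D[-1]
        Rfree = Rtot - C
        bind = kon * D[1:] * Rfree - koff * C
        dD[:] = Dc * lap / dx2 - deg * D + ect_dpp
        dD[0] += sec                    # secretion by the CC only
        dD[1:] -= bind                  # no receptors in the CC
        dC[:] = bind - kint * C

        # intracellular regulators: product of Hill terms
        fac = np.ones((ns, n))
        for ireg, itgt, Kh, repress in edges:
            Rh = X[ireg] ** hn
            if repress:
                fac[itgt] *= Kh / (Kh + Rh)
            else:
                fac[itgt] *= Rh / (Kh + Rh)
        if i_pmad is not None:
            Ch = C ** hn
            fac[i_pmad] *= Ch / (ksig2 ** (hn / 2.0) + Ch) if hn != 2.0 \
                else Ch / (ksig2 + Ch)
        dX[:] = phi[:, None] * fac - delta[:, None] * X + ectopic[:, None]
        return du

    return rhs


def _integrate(model: GermariumModel, params: ParameterVector, y0: np.ndarray,
               horizon: float, rtol: float = 1e-6, atol: float = 1e-9
               ) -> SimulationResult:
    n = model.n_cells
    ns = len(model.topology.species)
    t_eval = np.linspace(0.0, horizon, int(horizon * 4) + 1)  # 15 min grid
    rhs = make_rhs(model, params)

    # abort degenerate corners fast instead of letting the solver grind
    budget = [200_000]

    def guarded(t: float, u: np.ndarray) -> np.ndarray:
        budget[0] -= 1
        if budget[0] < 0:
            raise RuntimeError("derivative evaluation budget exceeded")
        du = rhs(t, u)
        if not np.all(np.isfinite(du)):
            raise FloatingPointError("non-finite derivative")
        return du

    try:
        sol = solve_ivp(guarded, (0.0, horizon), y0, method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        ok, msg = bool(sol.success), sol.message
    except Exception as err:  # integration blow-ups are penalized, not fatal
        ok, msg, sol = False, str(err), None
    if not ok or sol is None or not np.all(np.isfinite(sol.y)):
        empty = np.zeros((1, n))
        return SimulationResult(np.zeros(1), np.zeros((1, n + 1)), empty,
                                {s: empty.copy() for s in model.topology.species},
                                model.region_map, ok=False, message=msg)
    Y = sol.y.T
    traj = {
        s: Y[:, n + 1 + n + i * n: n + 1 + n + (i + 1) * n]
        for i, s in enumerate(model.topology.species)
    }
    return SimulationResult(sol.t, Y[:, :n + 1], Y[:, n + 1:2 * n + 1], traj,
                            model.region_map, ok=True)


def simulate_steady(model: GermariumModel,
                    condition: GeneticCondition = GeneticCondition.wild_type(),
                    horizon: float = 24.0) -> SimulationResult:
    """Integrate from a null (all-zero) state for 24 h; the final snapshot is
    the steady-state output."""
    params = apply_condition(model.params, condition, model.topology)
    y0 = np.zeros(model.state_dim)
    return _integrate(model, params, y0, horizon)


def divide_and_shift(result: SimulationResult, region_map: RegionMap | None = None
                     ) -> np.ndarray:
    """Post-division initial state: zone means shifted posteriorly by one zone.

    Each intracellular species' zone value becomes the mean of its anterior
    neighbor zone (the GSC zone keeps its own mean); extracellular ligand and
    bound complexes are untouched.  Returns a flat state vector.
    """
    rm = region_map or result.region_map
    regions = rm.germline_regions
    n = rm.n_cells_germline
    D = result.dpp[-1]
    C = result.complex[-1]
    parts = [D, C]
    for s, arr in result.traj.items():
        snap = arr[-1].copy()
        means = {r: float(arr[-1][rm.slice0(r)].mean()) for r in regions}
        for i, r in enumerate(regions):
            src = regions[i - 1] if i > 0 else r
            snap[rm.slice0(r)] = means[src]
        parts.append(snap)
    return np.concatenate(parts)


def simulate_dynamic(model: GermariumModel,
                     condition: GeneticCondition = GeneticCondition.wild_type(),
                     horizon: float = 12.0) -> SimulationResult:
    """Steady state → division/displacement shift → 12 h integration."""
    steady = simulate_steady(model, condition)
    if not steady.ok:
        return steady
    params = apply_condition(model.params, condition, model.topology)
    y0 = divide_and_shift(steady, model.region_map)
    return _integrate(model, params, y0, horizon)


def observable(result: SimulationResult, species: str) -> np.ndarray:
    """Per-germline-cell observable (17-vector; the CC never appears).

    ``Phenotype`` is the trailing-6 h mean Brat (fusome/spectrosome proxy);
    ``Dpp`` the final extracellular ligand per germline cell; any model
    species its final snapshot.
    """
    if species == "Phenotype":
        return result.trailing_mean("Brat", 6.0)
    if species == "Dpp":
        return result.dpp[-1][1:]
    if species in result.traj:
        return result.final(species)
    raise ModelValidationError(f"unknown observable {species!r}")


# ---------------------------------------------------------------------------
# topology / parameter file I/O

def topology_to_json(topology: NetworkTopology) -> dict:
    return {
        "name": topology.name,
        "species": list(topology.species),
        "edges": [{"from": r, "to": t, "sign": s} for r, t, s in topology.edges],
    }


def topology_from_json(obj: dict) -> NetworkTopology:
    return NetworkTopology(
        species=tuple(obj["species"]),
        edges=tuple((e["from"], e["to"], e["sign"]) for e in obj["edges"]),
        name=obj.get("name", ""),
    )


def default_log_bounds(params: ParameterVector, names: Sequence[str] | None = None,
                       decades: float = 2.0) -> dict[str, tuple[float, float]]:
    """Log-uniform search ranges: ``decades`` orders of magnitude either side
    of each reference value (4 total by default)."""
    names = list(names) if names is not None else [
        k for k in params.names() if k not in ("dx", "hill_n", "overexpression_rate")
    ]
    return {k: (params[k] * 10.0 ** -decades, params[k] * 10.0 ** decades)
            for k in names}
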