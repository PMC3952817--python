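"""Model-based experiment design: which measurement discriminates models?

Fits nothing — instead takes two competing wirings (Core, and Alt1 which
lacks the Brat⊣pMad feedback) with a few hand-picked parameter sets as
stand-in representatives, simulates a handful of candidate perturbation
experiments, discretizes the outputs to high/low region calls, and ranks
the experiments by three qualitative-design objectives.
"""

from ordfit.expdesign import (
    CandidateExperiment,
    enumerate_conditions,
    objective_expected_variance,
    objective_jaccard,
    objective_prediction_variance,
    prediction_ensemble,
    rank_table,
)
from ordfit.model import (
    GermariumModel,
    alt1_topology,
    core_topology,
    default_parameters,
)
import pandas as pd

models = {}
for topo in (core_topology(), alt1_topology()):
    params = default_parameters(topo)
    reps = [params,
            params.with_updates({"K_pMad_Bam": 0.2}),
            params.with_updates({"dpp_secretion": 5.0})]
    models[topo.name] = (GermariumModel(topo, params), reps)

conditions = enumerate_conditions(["Dpp", "Bam", "Nos"], ["null", "doubled"])[:8]
experiments = [CandidateExperiment(c, m) for c in conditions
               for m in ("pMad", "Brat")]
print(f"evaluating {len(experiments)} candidate experiments on "
      f"{list(models)} ...")

rows = []
for e in experiments:
    ens = {name: prediction_ensemble(m, reps, e)[0]
           for name, (m, reps) in models.items()}
    rows += [
        dict(experiment=e.condition.label, measured=e.measured,
             objective="expected_variance",
             score=objective_expected_variance(ens)),
        dict(experiment=e.condition.label, measured=e.measured,
             objective="jaccard", score=objective_jaccard(ens)),
        dict(experiment=e.condition.label, measured=e.measured,
             objective="prediction_variance",
             score=objective_prediction_variance(ens)),
    ]

ranked = rank_table(pd.DataFrame(rows), top_k=3)
print(ranked.to_string(index=False))
print()
print("Higher scores mark experiments whose predicted high/low patterns")
print("differ most between models (expected_variance, jaccard) or vary most")
print("across each model's representatives (prediction_variance, useful for")
print("refining parameters before attempting discrimination).")
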