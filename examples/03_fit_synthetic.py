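"""Calibrate a model to ordinal data with a known ground truth.

Generates ordinal observations from a two-regulator chain model, then runs
the full pipeline — global screen, anchor searches, Normalized Normal
Constraint front — over four free parameters.  Because the data were
generated by the model itself, a perfect fit (all three category objectives
zero) is attainable, and the pipeline should find it.
"""

from ordfit.synth import default_study, parameter_recovery_harness

study = default_study(rank_noise=0.0, seed=0)
print(f"study: {len(study.observations)} observations, "
      f"free parameters {study.free_names}")

report = parameter_recovery_harness(study, budget=400, k_starts=4, seed=1)
print(f"screen + local searches used {report['n_evaluations']} model "
      f"evaluations ({report['n_failures']} failed simulations tolerated)")
print(f"representatives found: {report['n_representatives']}")
print("best objectives (E_WT, E_Mut, E_Beh):",
      tuple(round(v, 6) for v in report["best_objectives"]))
print(f"log10 distance of nearest representative to the truth: "
      f"{report['nearest_log_distance']:.3f}")
print()
print("Objectives near zero mean the recovered parameters reproduce every")
print("generated rank pattern; a nonzero parameter distance at zero error")
print("reflects non-identifiability (many parameter sets fit ordinal data).")
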