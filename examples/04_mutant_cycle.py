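"""Double-mutant-cycle interaction energy, end to end.

Builds a scenario in which two mutations each destabilize the native
state and, on top of their summed effects, couple by 0.8 kcal/mol in the
double mutant.  The pipeline fits all four melts (0.5% noise) and the
cycle stage recovers the interaction energy delta = ddG_DM - (ddG_M1 +
ddG_M2) with a three-way additive/nonadditive/inconclusive call.
"""

from allokit import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    outdir="scratch/example_cycle",
    seed=5,
    bootstrap_B=60,
    scenario={
        "effect_M1": {"dG_NI": 0.8, "dGcat": -0.2},
        "effect_M2": {"dG_NI": 0.5, "dGcat": 0.1},
        "injected_delta": {"dG_NI": 0.8},
        "noise": {"melt_sd_frac": 0.005},
    },
)
report = run_pipeline(cfg)

print(report["cycles"][["property", "delta", "delta_se", "call"]].to_string(index=False))
print("\ninjected coupling on the N<=>I transition was 0.80 kcal/mol;")
print("the other properties were generated additive.")
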