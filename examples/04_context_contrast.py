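"""Full pipeline: planted replication-context enrichment, detected end to end.

Simulates a cohort in which a signature has weight 0.4 in late- and 0.1 in
early-replicating regions, partitions mutations by the inferred replication
contexts, refits exposures per (sample, context), and tests late vs early
with the signed-rank test and the rank-biserial W/R effect size.
"""

from sigcontext.pipeline import RunConfig, run_context_analysis
from sigcontext.replication import SmoothingConfig, build_profile
from sigcontext.simulate import SimulationConfig, simulate_cohort, simulate_genome, simulate_repliseq, synthetic_signatures

config = SimulationConfig(
    seed=1, n_chroms=2, chrom_length=2_000_000,
    n_samples=20, mutations_per_sample=1500,
    mixture_map={
        "late": {"SYN1": 0.4, "SYN2": 0.6},
        "early": {"SYN1": 0.1, "SYN2": 0.9},
    },
)
genome = simulate_genome(config)
signatures = synthetic_signatures(4, seed=5)
positions, values, _ = simulate_repliseq(config)
profile = build_profile(positions, values, SmoothingConfig(spar=0.2))
late = profile.context_annotation("late")
early = profile.context_annotation("early")

mutations, _ = simulate_cohort(config, genome, [late, early], signatures)
out = run_context_analysis(
    mutations, genome, [late, early], signatures,
    comparisons=[("SYN1", "late", "early")],
    config=RunConfig(seed=1),
)
row = out["comparisons"].iloc[0]
print(out["comparisons"].to_string(index=False))
print(f"\nThe signed-rank statistic W = {row['statistic']:.0f} with "
      f"p = {row['p']:.2e}; effect size W/R = {row['effect_size']:+.2f}.")
print("An effect of +1 means every sample carried more of the signature in")
print("late- than in early-replicating regions, as planted (0.4 vs 0.1).")
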