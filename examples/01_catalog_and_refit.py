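"""Build a 96-category mutation catalog and refit signature exposures.

Generates a small genome and a cohort drawn from a known two-signature
mixture, counts each sample's mutations into the 96 COSMIC trinucleotide
categories, and estimates per-signature exposure fractions.
"""

import numpy as np

from sigcontext.catalog import build_catalog, group_by_sample
from sigcontext.intervals import ContextAnnotation
from sigcontext.refit import refit_exposures
from sigcontext.simulate import SimulationConfig, simulate_cohort, simulate_genome, synthetic_signatures

config = SimulationConfig(
    seed=7, n_chroms=1, chrom_length=300_000,
    n_samples=3, mutations_per_sample=1000,
    mixture_map={"genome": {"SYN1": 0.3, "SYN2": 0.7}},
)
genome = simulate_genome(config)
signatures = synthetic_signatures(4, seed=5)
whole = ContextAnnotation.from_tuples("genome", [("chr1", 0, 300_000)], genome)
mutations, truth = simulate_cohort(config, genome, [whole], signatures)

print("planted mixture: SYN1 = 0.30, SYN2 = 0.70\n")
for sample, muts in sorted(group_by_sample(mutations).items()):
    catalog = build_catalog(muts, genome, sample_id=sample)
    exposure = refit_exposures(catalog, signatures)
    weights = {k: round(v, 3) for k, v in sorted(exposure.weights.items())}
    print(f"{sample}: {catalog.total} mutations -> exposures {weights}, "
          f"unassigned {exposure.unassigned:.3f}")

print("\nEach exposure is the fitted fraction of that sample's mutations")
print("attributed to a signature; at 1000 mutations the planted 0.3/0.7")
print("mixture is recovered to within a few percent.")
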