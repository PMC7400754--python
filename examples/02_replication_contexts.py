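"""Infer replication timing, fork direction, and speed from a synthetic wave.

Builds a Repli-seq-like signal from planted replication origins, fits the
cubic smoothing spline (spar = 0.2), and labels every 10 kb bin as
early/late (sign of the smoothed score), left/right (sign of the gradient),
and fast/slow (|gradient| vs the genome-wide median).
"""

import numpy as np

from sigcontext.replication import SmoothingConfig, build_profile
from sigcontext.simulate import SimulationConfig, simulate_repliseq

config = SimulationConfig(seed=4, n_chroms=1, chrom_length=2_000_000)
positions, values, truth = simulate_repliseq(config)
profile = build_profile(positions, values, SmoothingConfig(spar=0.2))

t = truth["chr1"]
print(f"planted origins at: {[f'{o/1e6:.2f} Mb' for o in t['origins']]}\n")
for name in ("timing", "direction", "speed"):
    labels = getattr(profile, name)["chr1"]
    counts = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
    agree = (labels == t[name]).mean()
    print(f"{name:9s}: {counts}  (agreement with planted truth: {agree:.1%})")

print("\nEarly bins sit on the positive (origin-proximal) part of the wave;")
print("a positive slope means the left-replicating strand; a shallow")
print("|gradient| means the fork covers more genome per unit time (fast).")
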