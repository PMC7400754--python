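# Methods

This note documents the models, numerical choices, and limitations behind
`sigcontext`. Empirical figures quoted here are the ones the test suite and
`scripts/acceptance.py` compute.

## Coordinates and catalogs

BED intervals are 0-based half-open; mutation positions are 1-based. The
conversion lives in exactly one function (`intervals.assign_points`): a
1-based point *p* belongs to `[start, end)` iff `start <= p−1 < end`.
Overlapping intervals of one label are merged on load, so annotated length
is order-invariant. A mutation may belong to several context labels at once;
per-context analyses are computed independently rather than forcing a
partition, because most genomic annotations overlap.

Substitutions are normalized to the pyrimidine strand: if the reference base
is a purine, the trinucleotide is reverse-complemented and the alternate
allele complemented. Category order is fixed to the canonical COSMIC layout
(substitution class slowest, then 5′ flank, then 3′ flank, each A,C,G,T), and
signature matrices are aligned by category *name*, never by position, so
both v2 and v3 COSMIC header dialects load correctly. Trinucleotides
containing N are unclassifiable and are skipped with a logged count.
Samples with fewer than 500 genome-wide substitutions are excluded before
any per-context work; the boundary (exactly 500) is retained. Per-context
fits additionally require `min_context_mutations` (default 50) classifiable
mutations — a 96-bin fit on fewer counts is dominated by sampling noise.

## Exposure refitting

The catalog is normalized to a probability vector *m*; exposures solve
min‖wᵀP − m‖², w ≥ 0, for the reference signature matrix *P*. The default
solver is greedy coordinate descent: each round evaluates, for every
signature, the optimal single-weight update, and applies the one that most
reduces the squared error, stopping when the best relative improvement falls
below 1e-3 (configurable) or after 1000 rounds. Because the objective is
exactly quadratic in one coordinate, the 1-D optimum is taken in closed form
(the vertex of the parabola, clipped at 0) — equivalent to, but exact where
a bracketing line search is approximate. Raw weights are then normalized to
fractions, fractions below the reporting cutoff (default 0.06, the
convention of the greedy-refitting tools this mirrors) are zeroed, and the
shortfall from 1 is reported as "unassigned". An exact NNLS mode
(`solver="nnls"`, via `scipy.optimize.nnls`) is available; on noiseless
mixtures the two agree to < 1e-3 per weight (measured ~4e-8), and the
acceptance script reports the observed maximum deviation.

Per-context catalogs can optionally be divided by a context-to-genome
trinucleotide abundance ratio (`catalog.trinucleotide_abundance`) before
fitting, correcting for sequence-composition differences between a
sub-genomic context and the whole genome. The default is off: on the
near-uniform synthetic genomes the correction is a no-op, and whether to
apply it to real data depends on how the reference signatures were
normalized. Burden is weight × mutations / (context length in Mb).

## MRE states (Bernoulli HMM)

Observations are bins × features binary matrices; continuous tracks are
binarized upstream (`binarize_to_bins`, any-overlap or majority rule, 10 kb
default bins — composite chromatin/replication domains are broad, so
promoter-scale bins would only add noise). Emissions are products of
independent per-feature Bernoullis (the chromHMM emission family);
transitions are first-order and homogeneous. Training is standard
Baum–Welch with per-position scaling; each chromosome of each cell type is
an independent sequence restarting from the initial distribution, and all
sequences share one parameter set ("concatenated" joint training), which is
what makes a state's interpretation portable across cell types. Decoding is
posterior-marginal argmax with ties to the lower state index.

Numerical choices: all probability parameters are floored at 1e-6 each M
step (prevents absorption at the boundary); initialization draws emissions
from the per-feature means jittered by seeded ±0.1 uniform noise, with
sticky near-uniform transitions (0.8 self-weight prior) because replication
and lamina domains span many consecutive bins; the best of `restarts`
(default 3) EM runs by final log-likelihood is kept. The per-iteration
log-likelihood trace is stored and is non-decreasing (EM guarantee; asserted
in tests). Forward-backward marginal likelihoods match brute-force path
enumeration to 1e-10 on small instances. On planted 5-state, 6-feature data
(50,000 bins) decoding recovers the planted path with adjusted Rand index
≈ 0.93. K is user-chosen; the package deliberately does not select it.

Feature enrichment of a state is fold enrichment,
P(feature | state) / P(feature); 0/0 is reported as missing. State
correspondence between two models is the row-normalized bin-overlap matrix.

## Replication timing, direction, speed

Per chromosome, the signal is fitted with a penalized cubic smoothing
spline and the gradient is the analytic derivative of the fitted spline.
The user-facing parameter is `spar` in [0, 1] with the conventional mapping
λ = r · 256^(3·spar − 1) on positions rescaled to [0, 1]; the trace ratio
r = tr(X′WX)/tr(Ω) is taken at its uniform-knots asymptote (3/16)·n⁻³,
which reproduces the classical all-knots behavior for the near-uniform bin
grids this package sees (verified against the reference smoothing-spline
implementation to three significant figures across n = 50–2000). Because
spar conventions differ across ecosystems, a direct `lam` override is
provided. Chromosomes with fewer than 4 points are skipped with a warning.

Labels are deterministic functions of the fitted curve: timing early iff
smoothed value > 0 (exact zero → late, a fixed logged convention);
direction left iff gradient > 0, right iff < 0, none at exactly 0 (such
bins are excluded from left/right contrasts); speed fast iff |gradient| is
strictly below the genome-wide median, slow otherwise (tie → slow, fixed
and logged). The speed orientation follows from geometry: a fork that moves
quickly replicates a long stretch per unit S-phase time, so its timing
curve is shallow. The median is computed after blacklist exclusion, so
artifact-prone bins do not shift the fast/slow threshold. On noiseless
synthetic waves, timing labels are exact and direction matches the planted
truth on 100% of bins more than one bump σ from any peak or valley.

## Statistics

Paired context comparisons use the Wilcoxon signed-rank statistic
W = Σ sgn(dᵢ)·Rᵢ on differences dᵢ (late − early, etc.); zero differences
are dropped before ranking and ties get average ranks (the classical
conventions; the source analyses do not state them). The effect size is the
rank-biserial correlation W/R with R the total rank sum, giving +1 when
every pair moves the same way. Rank-sum tests use exact enumeration up to
10 per group and the tie-corrected normal approximation above. Fisher's
method combines k independent p-values as −2Σln pᵢ ~ χ² with 2k df
(p = (0.5, 0.5) → 0.59657…, matched to 1e-10 against the closed form).
BH FDR is the standard step-up. Expression tertiles cut at the empirical
1/3 and 2/3 quantiles with boundary ties to the lower group. PCA is
column-centered, unscaled, with component signs fixed so the
largest-magnitude loading is positive. Reported p-values are two-sided
unless requested otherwise. Boxplot summaries use Tukey 1.5 × IQR whiskers
clipped to observed values.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (config, seed); identical seeds give
byte-identical outputs. Defaults describe a toy study: 2 chromosomes × 2 Mb
of i.i.d. sequence (GC configurable; a skewed-GC mode exercises the
abundance correction), 10 kb bins, 6 binary features from a planted 5-state
sticky HMM (self-transition 0.95, emission contrast 0.85), 4 replication
origins per chromosome as Gaussian bumps (σ = 150 kb, amplitude 2) on a −1
baseline, and cohorts of 20–50 samples × 1500–2000 mutations drawn from
per-context signature mixtures. Mutations are placed uniformly over the
genomic sites whose pyrimidine-strand trinucleotide realizes the sampled
category, inside the sampled context, so catalogs are exactly consistent
with the genome. Synthetic signatures are sparse Dirichlet draws
(concentration 0.08), i.e. nearly orthogonal — deliberately easier to
separate than real signature pairs.

Consequently, passing recovery tests shows the estimators are correct under
their own model assumptions; it does not show robustness to what real data
add: flat, collinear signatures (SBS3/SBS5/SBS8-like), mutation clustering
(kataegis), copy-number and purity distortions, chromatin-dependent
trinucleotide availability, mapping artifacts, or Repli-seq waves with
variable origin efficiency. The HMM assumes conditionally independent
binary features and homogeneous transitions; real epigenomes violate both
mildly. Expression/SV tables are simple planted monotone links and exist to
validate the statistics, not to model tumor biology.

## Problem sizes

The test suite and acceptance script use: 20 replicates × 5000-mutation
multinomial catalogs for exposure recovery (mean absolute weight error
≈ 0.007); 50,000 bins for HMM recovery; 400 bins × 2 chromosomes for
replication labeling; 50 samples × 2000 mutations for the end-to-end
contrast. These sizes make every planted effect comfortably detectable
while keeping a full run in the tens of seconds on one CPU.
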