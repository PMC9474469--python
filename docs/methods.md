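# Methods

## The analysis in one paragraph

Replicated OTU trajectories (treatment × generation × replicate) are
reduced to one series per OTU per treatment by simple averaging of
replicates at each generation; each series is rank-transformed to normal
scores; every unordered OTU pair is scored by the delay-bounded local
similarity dynamic program; significance comes from a permutation test;
pairs with p ≤ α become edges of a per-treatment network on the shared
abundance-filtered node set; and the networks are compared through
density, average path length, total/exclusive edges, and modularity.
Composition-level statistics (rarefaction, Shannon, Bray–Curtis, PCoA,
sequential PERMANOVA) run on the same tables.

## Local similarity: definitions and conventions

For series of length n and maximal delay D (default 1), the score is the
maximum over aligned contiguous runs with fixed offset |j − i| ≤ D of the
running sum of products, clipped below at zero, taken over both a
positively and a negatively accumulating table, and divided by n.
Conventions, all exercised by tests:

- **Normalization** (default `normal_scores`): value at rank r of n maps
  to Φ⁻¹(r/(n+1)); ties get averaged ranks.  A z-score and an identity
  transform are available; a constant series is an error under z-scoring
  (and maps to all zeros under normal scores).
- **Sign**: '+' if the positive table attains the maximum; ties break to '+'.
- **Delay**: the offset j − i of the maximizing run; among equal-scoring
  runs the smallest |delay| wins, then the positive delay.
- **Normalized vs raw score**: the reported `ls_score` is the run sum
  divided by n; the unnormalized run sum is kept as `raw_score` (it, not
  the normalized score, is invariant to zero-padding both series).

## Significance

p = P(LS of a permuted pair ≥ observed LS).  One series is permuted (the
two-series permutation is distributionally identical).  For n ≤ 6 the
full n! set is enumerated, identity included, so the minimal p is 1/n!.
Otherwise Monte-Carlo with p = (k+1)/(n_perm+1), n_perm = 1000 by
default.  Each pair draws its permutations from an RNG stream seeded by
(run seed, CRC32 of the two OTU ids), so results do not depend on the
order pairs are evaluated in.  The reported upper bound
min(1, p·(2D+1)) is a Bonferroni-style correction across the scanned
delay offsets — a deliberately simple, conservative stand-in for tighter
analytic tail bounds in the LSA literature, and clearly labeled as such.

With 8 generations the permutation resolution (1/1001) is fine, but the
test's power is intrinsically modest: at a latent correlation of 0.95 the
rejection rate at α = 0.01 is ≈ 0.70 before any observation noise.  This
is a property of 8-point series, not of the implementation, and it sets
the scale for the planted-recovery numbers below.

## Edge calling

Default rule: edge iff p ≤ α (α = 0.05 in the pipeline).  An inverted
rule — edge iff the p-value *upper bound* exceeds α — exists behind
`rule="inverted-upper"` because that literal reading appears in
descriptions of this workflow; it is degenerate at α = 1 (every pair
becomes an edge) and is never the default.  The α-scan reports density
across a threshold list precisely because edge counts, not any single α,
carry the comparative signal.  Raw p-values are thresholded by default;
an optional Benjamini–Hochberg mode exists but is off, mirroring common
practice in this literature.

## The synthetic generator

Per treatment, OTU k has latent log-abundance log p₀ₖ + σ_traj·zₖ(t):

- **Baseline** p₀ ~ Dirichlet(evenness·1), sorted descending so OTU ids
  are abundance-ranked, as in typical OTU tables.  Evenness (default 0.6)
  was set so ~90 of 120 OTUs clear the 1 % maximum-abundance filter at
  the default design — the scale of a rarefied rhizosphere table with
  ~190 samples at depth 3000.
- **Trajectories** zₖ are unit-variance AR(1) series (φ = 0.3).
- **Planted pairs** (ρ, lag ∈ {0,1}): the second member's z is
  ρ_eff·z_shift + √(1−ρ_eff²)·noise with ρ_eff = ρ·connectivity_scale;
  negative ρ flips the copied deviations; lag shifts by one generation.
- **Planted modules**: members load √w on a shared factor.  The factor
  trajectory is drawn once per module and shared by all treatments (one
  environmental driver; treatments differ in response strength), is
  unsmoothed (serial-passage generations are separate community
  assemblies), and is standardized to unit realized variance so the
  planted correlation is delivered at the configured strength rather
  than modulated by the luck of an 8-point draw.
- **Replicates** add lognormal noise (σ_rep = 0.5); samples are closed by
  softmax and counts drawn multinomially at fixed depth, so every sample
  sums exactly to the depth.

All randomness flows from one seeded generator in a fixed documented
order, so identical configs give byte-identical tables.

### What the generator does and does not emulate

It reproduces the design's structure (3 × 8 × 8, ~186 samples, depth
~3000, ~90 OTUs past the 1 % filter), compositional count noise, planted
pairwise/module associations with treatment-graded strength, and
treatment-graded evenness.  It does **not** model the host phenotype or
the inoculant-compositing selection loop, taxonomic phylogeny (families
are labels), overdispersion beyond lognormal-multinomial, or spurious
correlation structure beyond what compositional closure itself induces.
Consequently, passing tests demonstrate that the analysis recovers known
structure under realistic noise — not that any particular biological
conclusion from real data is correct.

### The gradient preset

`treatment_gradient_preset` plants ten strong pairs (ρ = 0.95, five with
lag 1) plus one 60-OTU association web (w = 0.95) and grades treatments:
connectivity scale (1.0, 0.9, 0.35) and evenness (0.5, 0.6, 0.72) for
three levels (formulas interpolate for 2–5 levels).  Design rationale: a
single broad web gives the first treatment a dense, *diffusely*
connected network — highest density, shortest paths, lowest modularity —
while the last treatment's network is mostly background, sparse and
fragmented (high modularity).  Distinct compact modules were tried and
rejected: they raise the dense network's modularity, the opposite of the
topology signature this preset exists to induce.  The evenness gradient
is deliberately gentle because the baseline's evenness also modulates the
background false-positive rate through compositional closure; a steep
gradient makes the background rates diverge and swamps the planted
contrast.  Validated pre-freeze on two disjoint 20-seed batches: density
ordering at every α in 19/20 and 19/20 runs, modularity and path-length
orderings in 20/20 and 20/20.

## Community statistics: numerical choices

- **Shannon** uses the natural log.
- **Rarefaction** is one multivariate-hypergeometric draw per sample; a
  sample below the target depth is an error (rarefy to the observed
  minimum to keep all samples).
- **PCoA** double-centers −½D², eigendecomposes, drops nonpositive
  eigenvalues (no Lingoes/Cailliez correction) and reports variance
  fractions over the positive eigenvalues only.
- **PERMANOVA** uses sequential (Type-I) sums of squares with generation
  before treatment then their interaction, categorical factors, QR-based
  hat matrices, free permutation of sample labels, and
  p = (#{F* ≥ F}+1)/(n_perm+1) per term.  It matches a brute-force
  enumeration oracle at n = 4, scikit-bio's one-way pseudo-F, and vegan's
  adonis2 sequential F values in the tests.  Note that with duplicated
  samples the permutation distribution has atoms — every relabeling
  preserving the group partition attains the same F — so the attainable
  p floor is the atom probability, not 1/(n_perm+1).
- **Degenerate inputs** (zero-sum samples, all-zero vectors, single-level
  factors, edgeless graphs for modularity) are hard errors with the
  offending ids in the message.

## Problem sizes used by the test suite and acceptance script

The acceptance checks run at the study scale (120 OTUs, 3 × 8 × 8
design, 1000 permutations per pair) where the property demands it
(planted recovery, gradient signature over 20 seeds, null calibration
over 2000 pairs) and at reduced scale where the property is
size-independent (end-to-end determinism at 40 OTUs; oracle equivalence
at n ≤ 8).  The permutation kernel is JIT-compiled, which keeps the full
all-pairs analysis of ~90 OTUs (≈4000 pairs × 1000 permutations) at
about a second per treatment.

## Known limitations

- Replicate summarization is the simple average only; variance-weighted
  summaries are out of scope.
- Time grids must be regular and balanced across treatments; unbalanced
  panels are an error rather than being imputed.
- The delay-offset upper bound is conservative, not an analytic tail
  approximation.
- Recall of planted ρ = 0.95 pairs at α = 0.01 is ~0.2–0.4 per
  treatment: the honest power of 8-point series (see above), recorded in
  `tests/calibration.json` from a 20-seed pre-build run.
- NetShift-style node-level rewiring scores are not implemented; only
  the global comparison properties are.
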