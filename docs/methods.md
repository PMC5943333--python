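# Methods

`riverdrift` asks a concrete riverscape-genetics question: when an instream
barrier (a weir or dam) cuts a stream population of a low-mobility fish in
two, how many generations pass before the genetic signature of that barrier
can be told apart from the background genetic structure the species already
shows?  The package answers it by space-for-time simulation — a spatially
explicit coalescent on a linear stream, with and without a barrier, scored
by the same statistics a field study would use on microsatellite genotypes.

## The simulation model

**Habitat.** A linear lattice of `n_nodes = 160` demes, 200 m apart (node 1
is the downstream end), each holding `density` diploids (3, 10 or 30 per
node, i.e. 15/50/150 per km).  Density is homogeneous, so the backward
(parent-picking) kernel equals the forward dispersal kernel.

**Dispersal.** An offspring's parent lived in the same node with
probability 1 − e, otherwise at distance d nodes (up/downstream with equal
probability) with P(d) ∝ g^d, d = 1..40.  The (e, g) pairs per density —
(0.50, 0.95), (0.25, 0.90), (0.15, 0.85) — give isolation-by-distance
regression slopes around 2.4–3.3 × 10⁻⁶ per metre, matching the empirical
scale of structure in the study system.  "Panmixia" sets e = g = 1 with
unbounded range, read as a uniform parent distribution over all 160 nodes.
Dispersal that would leave the habitat is not realized: the blocked mass is
added to the stay-put probability.  (The alternative — renormalizing the
truncated kernel over reachable nodes — weakens drift near the upstream
end and visibly under-reproduces the published edge signatures: the
above/below allelic-richness ratio comes out ≈ 0.98 instead of ≈ 0.95 and
the high-density IBD slope low; the stay-put convention is also the same
rule used at the barrier, so one convention governs all blocked dispersal.)

**Barrier.** Between nodes 125 and 126, introduced `barrier_age`
generations before sampling (backward in time, the barrier kernel applies
for the most recent T generations, the open kernel before that; the switch
is sharp).  Upstream crossings are fully blocked; downstream crossings are
multiplied by `downstream_leak` (0 = complete barrier, 0.2 = the leaky
asymmetric scenario, read as a multiplier on the kernel's crossing mass).
Blocked mass stays put.

**Coalescent.** Gene copies of the sampled diploids are traced backward
generation by generation: each lineage draws a parent node from the kernel,
then a parent gene copy uniformly among the 2 × density genes of that node;
lineages landing on the same gene merge (simultaneous multiple mergers
allowed).  Branch lengths are exact generation counts; there is no
diffusion or strong-migration approximation, which matters at these small
deme sizes (6–60 genes).  The generation loop is numba-compiled; a locus at
the highest density (TMRCA ~ tens of thousands of generations for 270
lineages) simulates in ~10 ms.

**Mutation.** Generalized stepwise model at mu = 3 × 10⁻⁴ per gene per
generation on 60 allelic states, root state 30.  A mutation moves the
repeat count by 1 + V steps, V geometric ("failures"), sign ± with equal
probability; "step variance 0.36" is read as the variance of the
step-length distribution, giving p ≈ 0.2195 from p/(1−p)² = 0.36 (a
per-mutation variance below 1 is impossible around a mean-1 step, so the
variance must describe the step-length law; the alternative reading
p = 0.36 is available via `variance_is_p`).  Steps leaving [1, 60] are
re-drawn in full.

**Sampling.** 15 diploids at each of 9 nodes (70, 80, …, 150; 135 in
total), drawn without replacement from the diploids of the 5-node (1 km)
window centred on each sample node.  At 3 diploids/node the window is
exhausted exactly; at higher densities it is subsampled.  The window is a
modelling choice exposed as `sample_window_nodes`: sampling all 15 from the
single node (possible only at 30/node) strengthens local-drift signatures —
it reproduces the published high-density allelic-richness ratio and Mantel
rate almost exactly — but cannot be applied uniformly across densities, so
the uniform 1-km window is the default and its smoothing effect should be
kept in mind when comparing absolute pooled-FST levels with the published
table (ours run ~0.01 lower).

## Statistics

All statistics operate on `AlleleMatrix` (genotypes + site/pool metadata;
Genepop I/O with a tab-separated metadata sidecar).

- **He** is Nei's unbiased estimator (2n/(2n−1))(1 − Σp²); the plug-in
  version is biased downward at small n.  **Ho** is the heterozygote
  fraction.
- **FIS and FST** are Weir–Cockerham (1984) variance-component estimators;
  multilocus values are ratios of summed components, and negative estimates
  are reported as computed.  The FST permutation test shuffles individuals
  between the two pools (default 45 000 permutations when requested).
- **Jost's D** uses Nei–Chesser unbiased Hs/Ht; loci combine by harmonic
  mean when all per-locus values are positive, otherwise by arithmetic mean
  (a harmonic mean across signs is undefined — this fallback is the one
  numerical liberty taken).
- **Allelic richness** is hypergeometric rarefaction,
  Ar = Σ_a [1 − C(N−N_a, g)/C(N, g)].  For simulated pools the rarefaction
  size is the full pooled gene count (pools are equal-sized by design), and
  the above/below ratio is reported as above/below (< 1 when the upstream
  pool is poorer).
- **HWE** is the Monte-Carlo exact probability test: genotype tables are
  generated by random pairing of the observed allele multiset and scored by
  their Levene conditional probability.
- **LD-Ne** is the Burrows-Δ r² method with a 2% rare-allele threshold,
  the sample-size bias adjustment (1/S + 3.19/S² for S ≥ 30, the
  small-sample variant below), and the random-mating quadratic inversion.
  Point estimate only; jackknife CIs are out of scope.
- **Heterozygosity excess** (bottleneck test): per locus, equilibrium
  coalescent samples under SMM or TPM (70% single-step, multi-step variance
  30, i.e. geometric p = 5/6) are conditioned on the observed allele count
  by bisecting theta and rejection-sampling matching replicates (budget
  200 × iters per locus); the standardized differences feed a one-tailed
  Wilcoxon signed-rank across loci, plus the 0.1-binned mode-shift
  indicator (needs ≥ 5 polymorphic loci).
- **Barrier detection** is the paired exact Wilcoxon signed-rank over
  per-locus FST values (cross-barrier vs same-design background pair
  below the barrier), one-sided.  The exact null is computed by dynamic
  programming over sign assignments (valid with tied ranks) up to 25
  pairs, normal approximation beyond; zero differences are dropped.
- **Ritland kinship** uses whole-sample reference frequencies and
  (k−1)-weighted locus averaging; the autocorrelogram's null permutes
  individual locations (10 000 by default), with a central 95% envelope.
- **IBD regression** linearizes pairwise site FST as FST/(1−FST) against
  river distance in metres; the Mantel statistic is the regression slope,
  one-tailed for a positive association, permuting site identities.

## The experiment grid

`ScenarioGrid`/`run_grid` reproduce the study design: scenarios {panmixia,
ibd, ibd_asym} × densities {3, 10, 30 per node} × barrier ages {none, 5,
10, 15, 20, 25, 50, 100} × {8, 20} loci, 50 replicates per cell by
default.  Replicate seeds derive deterministically from (master seed,
scenario, density, age, replicate), so any replicate is reproducible in
isolation.  Per replicate: cross-position pooled FST (nodes 130/140/150 vs
100/110/120), background FST (100/110/120 vs 70/80/90), per-locus versions
feeding the detection Wilcoxon, pooled allelic richness above/below, and
the 9-node IBD slope and Mantel p.  "Detected" means p < 0.05 (the
conventional level; configurable).  Wright's back-calculation
Ne = Nt/(1−FST) uses Nt = 35 nodes × density for the above-barrier
segment.

## The synthetic fixture generator

`make_empirical_fixture` emulates only the *shape* of an empirical
microsatellite survey: pool sizes, locus count, and per-locus expected
heterozygosities (frequencies are drawn by sharpening a Dirichlet draw
until the frequency-He matches the target within ±0.02, then genotypes are
sampled under Hardy–Weinberg).  It carries no genealogy, no linkage, no
spatial autocorrelation, and no mutation-model allele-size structure, so
tests built on it validate estimator arithmetic and null calibration —
not the population-genetic realism of the simulator, which is exercised
separately against closed-form coalescent expectations and forward
Wright–Fisher oracles.

## Problem sizes and numerical choices

Simulation-backed package tests use 25 replicates per grid cell (75 for
the barrier-detection power cells, whose rates sit close to the 50%
threshold), with tolerances widened accordingly where the source permits;
the acceptance script uses the study's 50.  Mantel tests use 999
permutations in the suite and 10 000 in the acceptance script.  Monte-Carlo
p-values are add-one corrected.  The coalescent raises after 10⁷
generations without an MRCA; mutation re-draws are bounded at 1000
attempts.  Degenerate inputs (monomorphic pools, all-tied Wilcoxon, FST = 1
pairs in the IBD linearization) are flagged or excluded with warnings
rather than silently propagated.

## Known limitations

- Absolute pooled cross-position FST under the IBD scenarios runs
  ~0.012–0.017 against the published 0.027–0.029, and Mantel significance
  rates run correspondingly higher, under the uniform 1-km sampling
  window (see Sampling above).  Slopes, panmixia controls, allelic-richness
  ratios and the Ne back-calculations reproduce the published values.
- Under panmixia with a 15-generation-old complete barrier, the paired
  per-locus Wilcoxon detects the barrier in ~60% of replicates at 15
  ind/km but only ~44% at 50 ind/km.  The latter is consistent with first
  principles — two isolated panmictic segments of 350 and 1250 diploids
  reach E[FST] ≈ 0.014 in 15 generations, and 8 loci rarely deliver the
  ~7/8 concordant differences the exact Wilcoxon needs — but falls short
  of the >50% detection the original study reports for both densities.
- The LD-Ne estimator and the bottleneck test are point re-implementations
  of the published methods' defaults, not full re-implementations of the
  original programs (no CIs, no jackknife, fixed random-mating model).
- One-dimensional habitat only; no selection, recombination within loci,
  overlapping generations, or temporally varying density.
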