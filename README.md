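# riverdrift

Spatially explicit coalescent simulation and microsatellite statistics for
detecting the genetic effects of instream barriers (weirs, dams) on
low-mobility stream fish.

Artificial barriers split stream populations into an upstream and a
downstream fragment.  In species that already show fine-scale
isolation-by-distance (IBD), genetic differentiation across a barrier can
look exactly like background spatial structure — so "FST across the barrier
is significant" is not evidence of a barrier effect.  `riverdrift`
implements the space-for-time simulation approach to this problem: a
generation-by-generation backward coalescent on a linear lattice of stream
demes, with a barrier insertable at a known age, scored by the statistics a
microsatellite field study actually uses, so that observed cross-barrier
contrasts can be compared against simulated expectations for known
effective densities and barrier ages.

## What's in the box

- **`riverdrift.sim`** — the simulator: 160-node linear habitat (200 m
  spacing), truncated geometric dispersal kernel (emigration rate *e*,
  decay *g*, max 40 nodes), per-node diploid density, an optional barrier
  between nodes 125/126 (complete, or leaky downstream at rate 0.2)
  introduced *T* generations before sampling, and generalized stepwise
  mutation (mu = 3×10⁻⁴, step variance 0.36, 60 allelic states).
- **`riverdrift.stats`** — Nei unbiased He/Ho, Weir–Cockerham FIS and
  pairwise FST (variance components, permutation tests), Jost's D,
  hypergeometric rarefied allelic richness, effective inbreeding
  Fe = 1 − He_focal/He_ref, Monte-Carlo exact HWE test, LD-based Ne
  (Burrows r², 2% rare-allele threshold), heterozygosity-excess bottleneck
  test under SMM/TPM with mode-shift indicator, exact paired Wilcoxon
  barrier-detection test, Ritland kinship autocorrelograms and
  FST/(1−FST)-vs-distance Mantel regression.
- **`riverdrift.experiment`** — the scenario grid (panmixia / IBD / IBD +
  asymmetric leak × densities 15/50/150 per km × barrier ages × 8/20 loci,
  50 replicates), summary tables and detection power curves.
- **`riverdrift.genotypes` / `riverdrift.genepop`** — the `AlleleMatrix`
  container, Genepop 2/3-digit I/O with a metadata sidecar, site pooling,
  and a synthetic fixture generator calibrated to target heterozygosities.
- A `riverdrift` CLI with `simulate`, `stats`, `spatial`, `experiment` and
  `fixtures` subcommands.

## Worked example

Simulate one no-barrier data set under isolation-by-distance at 50
diploids per km and score it the way the barrier analysis would:

```python
import riverdrift as rd
from riverdrift.experiment import scenario_lattice, replicate_statistics

cfg = scenario_lattice("ibd", density=10)        # 10 diploids/node = 50/km
matrix = rd.simulate_dataset(cfg, rd.SampleDesign(), rd.MutationConfig(),
                             n_loci=8, seed=42)  # 135 diploids, 9 nodes
print(replicate_statistics(matrix, mantel_permutations=9999, mantel_seed=42))
```

```
       cross_fst: 0.007355     # pooled FST, nodes 130/140/150 vs 100/110/120
  background_fst: 0.02457      # pooled FST, nodes 100/110/120 vs 70/80/90
      wilcoxon_p: 0.8086       # paired per-locus test: cross > background?
        ar_above: 5.125        # rarefied allelic richness above / below
        ar_below: 5.25
       ibd_slope: 4.921e-06    # FST/(1-FST) per metre over the 9 nodes
        mantel_p: 0.0001       # one-tailed Mantel test of that slope
```

With no barrier, the cross-position FST (0.007) is nothing special against
the background (0.025) — the detection test is far from significant
(p = 0.81) — while the IBD signal itself is strong (slope ≈ 4.9×10⁻⁶ per m,
Mantel p = 10⁻⁴).  This is the core message of the analysis: in a
structured population, a barrier must raise differentiation *above* the IBD
background before it is detectable.

The effective inbreeding coefficient from a pair of pooled expected
heterozygosities (above-barrier 0.396 vs downstream reference 0.472):

```python
>>> from riverdrift.stats.diversity import effective_inbreeding
>>> round(effective_inbreeding(0.396, 0.472), 3)
0.161
```

Full grid runs from the shell:

```sh
riverdrift experiment --seed 1 --replicates 50 --out results/
riverdrift simulate --scenario ibd --density 50 --barrier-age 20 --loci 8 --seed 7 --out sim.gen
```

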