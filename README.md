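# domscan

Population-genomic scans for multi-population crop-domestication cohorts.

Perennial crops such as avocado were domesticated several times from
distinct wild lineages.  Resolving that history from resequencing data
takes a chain of analyses: purify the cohort of recent hybrids using
admixture proportions, measure within-group diversity (π) and
between-group divergence (Weir–Cockerham F<sub>ST</sub>) in genomic
windows, scan each group for selective sweeps with a composite likelihood
ratio, test whether candidate gene sets overlap more than chance allows,
date group splits from cross-coalescence-rate curves, and quantify genic
hemizygosity from structural variants.  `domscan` implements this chain as
a tested, reusable Python library (with a thin CLI) for population
geneticists who want each step to be verifiable rather than welded inside
a one-off pipeline, together with a structured-coalescent cohort simulator
so that every stage can be exercised against known ground truth without
any external data.

## The statistics at the core

- **Diversity**: per-site π = k(n−k)/C(n,2) for derived count k among n
  haplotypes; window values are sums over SNPs divided by the full window
  width.
- **Divergence**: per-site Weir & Cockerham (1984) variance components
  (a, b, c) with θ̂ = a/(a+b+c); windowed F<sub>ST</sub> is the arithmetic
  mean of per-SNP θ̂ (PLINK convention), with empirical top-1% outlier
  windows.
- **Sweeps**: the SweepFinder/SweeD composite likelihood.  A lineage at
  distance d from a sweep of strength α escapes with probability
  p<sub>e</sub> = 1 − e<sup>−αd</sup>; the sweep-distorted spectrum mixes
  hypergeometric down-projections of the background SFS over the binomial
  number of escapees, and CLR(x) = 2[max<sub>α</sub> Σ<sub>s</sub> ln
  P(j<sub>s</sub> | d<sub>s</sub>, α) − Σ<sub>s</sub> ln
  p<sub>bg</sub>(j<sub>s</sub>)] ≥ 0.
- **Enrichment**: overlap of flagged gene sets tested by label permutation
  over a fixed universe (p = (b+1)/(N+1), N = 10,000 by default),
  cross-checked against the exact hypergeometric tail.
- **Hemizygosity**: a gene is hemizygous when a single ≥4-read indel SV
  affects ≥20% of its merged coding region.
- **Split times**: rCCR = 2λ<sub>01</sub>/(λ<sub>00</sub>+λ<sub>11</sub>);
  the time at rCCR = 0.5 converts to years as t/μ with μ = 5.4×10⁻⁹ per
  site per year and a 7-year generation time.

Model details, numerical choices and limitations: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a two-group cohort (10 Guatemalan + 5 Lowland diploids, 1 Mb,
θ = 0.0035) with one hard sweep planted in the Guatemalan group at
chr1:495,000 (footprint 50 kb, intensity s = 0.05), then run the scans:

```python
import numpy as np
from domscan.simulate import SimulationConfig, SweepSpec, simulate_cohort
from domscan.variant_io import tile_windows, classify_accessions
from domscan.popgen import window_pi, mean_fst, empirical_top_cutoff
from domscan.sweep import scan_genome

cfg = SimulationConfig(
    chrom_lengths={"chr1": 1_000_000},
    samples={"Guatemalan": 10, "Lowland": 5, "Mexican": 0},
    sweeps=[SweepSpec("Guatemalan", "chr1", 495_000, radius=50_000, s=0.05)],
)
matrix, truth = simulate_cohort(cfg, seed=1)

windows = tile_windows(cfg.chrom_lengths, 10_000)
window_pi(matrix, windows, "Guatemalan")
print(f"mean windowed pi: {np.mean([w.values['pi'] for w in windows]):.5f}")
print(f"mean Fst L vs G: {mean_fst(matrix, 'Lowland', 'Guatemalan'):.4f}")

scan_genome(matrix, "Guatemalan", windows)
threshold, top = empirical_top_cutoff(windows, "CLR", 0.01)
print(f"top-1% CLR threshold: {threshold:.1f}")
for w in top:
    print(f"  {w.chrom}:{w.start}-{w.end}  CLR={w.values['CLR']:.1f}")

profiles = [("Lyon",  {"Guatemalan": 83.78, "Mexican": 16.22, "Lowland": 0.0}),
            ("Bacon", {"Guatemalan": 37.69, "Mexican": 62.31, "Lowland": 0.0})]
for p in classify_accessions(profiles):
    print(f"{p.accession}: {p.assigned_group}")
```

Output:

```
mean windowed pi: 0.00329
mean Fst L vs G: 0.0811
top-1% CLR threshold: 249.3
  chr1:490000-500000  CLR=249.3
Lyon: Guatemalan
Bacon: admixed
```

The mean π sits at the simulated θ ≈ 0.0035 (slightly below here because
the sweep trough removes variation), the two groups separated 44 kyr ago
show modest divergence, the single top-1% window is exactly the one
containing the planted sweep center — its CLR of 249 dwarfs the neutral
genome — and the two accessions classify by the strict Q<sub>i</sub> > 80%
rule: one into the Guatemalan group, one as a hybrid.

The same operations are available from a shell via `domscan qc`,
`domscan classify`, `domscan pi`, `domscan fst`, `domscan clr`,
`domscan smooth`, `domscan outliers`, `domscan enrich shared`,
`domscan hemizygosity`, `domscan rccr` and `domscan simulate`
(see `domscan --help`).

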