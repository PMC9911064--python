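# Methods

`domscan` packages the statistical core of a resequencing-cohort
domestication analysis: cohort QC and ancestry purification, windowed
diversity and divergence, a composite-likelihood sweep scan, permutation
enrichment of gene sets, structural-variant-based genic hemizygosity, and
split-time estimation from cross-coalescence-rate curves.  Every stage is
verifiable against a structured-coalescent simulator that emits cohorts
with machine-readable ground truth.

## Coordinates and QC

All internal coordinates are 0-based half-open; the 1-based conventions of
VCF and GFF3 are converted at the I/O boundary.  Site QC follows the
bcftools-style expression `QUAL < 20 || DP > 32`: both inequalities are
strict, a record missing its depth annotation passes the depth clause
(the expression cannot evaluate it), and a negative depth is an error.
Sample-level QC removes individuals whose missing-call fraction reaches
50% (ingroup) or 75% (outgroup); both cutoffs are strict
(keep iff fraction < cutoff).  Window tiling keeps partial terminal
windows (bedtools-compatible) and removes only windows lying entirely
inside merged assembly-gap intervals; remaining windows carry their gap
fraction so densities can renormalise.

Ancestry classification assigns an accession to its majority group iff the
maximum admixture proportion Qi strictly exceeds 0.80, otherwise
"admixed"; a user-supplied exclusion list (e.g. near-relatives of an
over-sampled cultivar) maps to "excluded".  Q-matrix rows are accepted as
fractions (row sum in [0.99, 1.01]) or percentages (sum in [99, 101]);
anything else is an error rather than a guess, because published tables
mix the two scales.

## Diversity and divergence

Per-site nucleotide diversity is the unbiased pairwise estimator
pi = k(n-k) / C(n,2) for derived count k among n non-missing haplotypes.
Window pi divides the summed per-site values by the **full window width**;
no callable-site mask is assumed, which matches the VCFtools-style
windowed convention.  Windows without SNPs report 0.

Per-site Fst is the Weir & Cockerham (1984) two-population moment
estimator, theta_hat = a / (a + b + c), computed from sample sizes, allele
frequencies and observed heterozygosity of diploid genotypes.  "Mean Fst
per window" is the arithmetic mean of the defined per-SNP estimates — the
PLINK windowed convention — and negative per-site values are retained, not
truncated.  Sites monomorphic overall or with fewer than two genotyped
diploids in either population are undefined and excluded from means.
Empirical outlier sets take the ceil(q*W) highest-valued of the W valued
windows genome-wide; ties at the threshold are all included and logged.

## The sweep scan

The scan implements the SweepFinder/SweeD composite-likelihood model.  The
background site frequency spectrum is estimated genome-wide per population
(unfolded by default, with REF treated as ancestral — exact in the
simulator, an explicit logged assumption on real data; a folded mode is
provided).  With missing data, sites are hypergeometrically down-projected
to a common sample size, chosen as the largest n attained by at least half
of the polymorphic sites; sites below it are dropped with a log entry.

The sweep spectrum uses the star-genealogy approximation.  A lineage at
distance d from a sweep of strength alpha escapes with probability
p_e = 1 - exp(-alpha d).  Conditional on b of n lineages escaping, the
sample behaves like a pre-sweep sample of b+1 lineages (the b escapees
plus the swept ancestor), with counts drawn from the hypergeometric
projection of the background to b+1; the swept ancestor carries the
derived allele with probability i/(b+1), contributing n-b+i-1 copies
today, else i copies.  The mixture over Binomial(n, p_e) values of b is
renormalised over polymorphic classes.  The CLR at a test position is
twice the log ratio of the alpha-maximised composite likelihood to the
background likelihood, clamped at >= 0 because the alpha grid contains the
null sentinel (alpha = infinity).  The grid uses 40 log-spaced strengths
spanning escape half-distances from 100 bp to 10 Mb.

Numerics: for genome scans the per-site log-likelihood ratio is
precomputed on a 1024-point grid of t = alpha*d (log-spaced on
[1e-6, 30]) and linearly interpolated; beyond t = 30 the spectrum is
background to < 1e-6 total variation and the contribution is exactly
zero.  `sweep_site_prob` always evaluates the exact mixture — the table is
a scan-path optimisation only.  The scan evaluates one CLR per
non-overlapping 10-kb window at the window midpoint.

Loess smoothing for genome-wide visualisation is Cleveland's tricube-
weighted local regression (degree 2 by default, span 0.5 per chromosome),
with unvalued/gap windows assigned 0 before fitting; chromosomes with
fewer than 5 windows are returned unsmoothed with a warning.  The
degree-1 mode reproduces the classic lowess of standard statistical
packages to ~1e-14, which is how the implementation is cross-checked.

## Gene sets and permutation enrichment

Sweep gene sets take every gene within 5 kb (inclusive) of a top-window
test position; Fst gene sets take every gene whose span overlaps a top
window (half-open).  The shared-gene test permutes flagged labels over the
common gene universe with both set sizes fixed — distributionally
identical to hypergeometric sampling of the overlap, which is the exact
oracle used in tests — and reports p = (b+1)/(N+1) over N permutations
(default 10,000), which cannot be zero.  The gene universe is a parameter
(default: all genes in the supplied annotation), because enrichment
against different universes answers different questions.

## Genic hemizygosity

Indel SVs (DEL/INS) with at least 4 supporting reads are retained; other
SV classes are skipped with a warning.  A gene is hemizygous when a
*single* SV affects >= 20% of its merged CDS length: for deletions the
overlap of the deleted span with the CDS, for insertions the inserted
length provided the breakpoint falls inside the CDS.  A point insertion
cannot "overlap" a fraction of the CDS, so the inserted-length rule is an
interpretation, exposed via parameters along with per-event versus
cumulative accounting (per-event is the default).  Both thresholds are
inclusive; genes without CDS are never flagged.

## Cross-coalescence split times

rCCR = 2*lambda01 / (lambda00 + lambda11) per epoch; undefined epochs
(zero denominator) are skipped.  The split-time point estimate is the
first transition, scanning from the most recent epoch into the past, where
rCCR rises through 0.5, located by linear interpolation between epoch
*midpoints* (epochs are half-open intervals; the midpoint is the natural
representative).  Non-monotone curves use the first crossing with a
warning.  Scaled times convert to years as t / mu_per_year with
mu = 5.4e-9 per site per year, and rates to diploid effective sizes as
Ne = 1 / (2 lambda mu_gen) with a 7-year generation time.  Note the
crossing convention (first crossing, midpoint interpolation) is a
documented choice; other tools may use the left boundary or the last
crossing.

## The synthetic cohort generator

The generator emulates the cohort structure the analyses assume, not any
particular dataset:

- **Demography.** Three populations with topology
  ((Lowland, Guatemalan), Mexican), default diploid sample sizes 3
  Mexican / 5 Lowland / 10 Guatemalan.  Diploid Ne defaults to 23,148 so
  that theta = 4 Ne mu = 0.0035 per site at mu = 3.78e-8 per generation
  (5.4e-9 per year x 7-year generations); splits default to 6,286
  generations (44 kyr) and 185,714 generations (1.3 Myr).  No migration.
- **Linkage.** Independent 1-kb segments: exact single-genealogy
  coalescent within a segment, free recombination between segments.  This
  is deliberate: window statistics see realistic variance while every
  segment's genealogy remains exact and cheap.  Real linkage decays
  continuously, so LD-based statistics are out of the generator's scope.
- **Mutations.** Poisson on branches under infinite sites; the ancestral
  allele is always REF, enabling unfolded spectra; position collisions
  within a segment are dropped.
- **Sweeps.** The star-approximation capture process: at a recent time
  (default 0.05 * 2Ne generations, the duration scale of a strong hard
  sweep) every lineage of the swept population escapes independently with
  probability f(d) = s + (1-s) min(1, d/r), and all non-escaping lineages
  merge instantly into the swept ancestor.  f gives full capture at the
  center (factor s, default 0.05) and recovers linearly to neutral at the
  footprint radius r.  A burst of instantaneous capture — rather than a
  permanent rescaling of Ne — is what produces the U-shaped frequency
  spectrum (excess singletons and high-frequency derived alleles) on top
  of the diversity trough; a time-constant Ne rescaling would thin SNPs
  without changing the conditional spectrum and would be invisible to a
  frequency-based scan.
- **Hybrids.** Admixed accessions copy, independently per segment and per
  haplotype, one haplotype from a source population drawn with the
  specified proportions; the per-segment sources are recorded as truth.
- **SV sets.** Deletions/insertions planted over synthetic gene models
  with configured CDS fractions straddling the 20% rule and configured
  read supports straddling the 4-read rule; the truth flag applies both
  rules jointly.
- **Rate curves.** Piecewise-constant lambda curves in MSMC2 output units
  over 32 log-spaced epochs (1 kyr - 10 Myr): lambda00 = lambda11 =
  1/(2 Ne mu_gen), lambda01 = 0 for epochs younger than the split and
  equal to lambda00 above it.  The generator reports both the requested
  split and the crossing its own discretised step implies under midpoint
  interpolation; epoch discretisation bounds the agreement between the
  two (about half an epoch width, i.e. a few percent at 32 epochs across
  four decades).  Noisy mode multiplies every rate by lognormal(0, sigma)
  noise (sigma = 0.1 in the standard checks).

Everything is driven by one `numpy` Generator seed: identical seeds give
byte-identical VCF/GFF3/SV/curve files.

### What passing tests do and do not show

The simulator reproduces the *statistical* structure the methods assume —
neutral spectra, split-driven divergence, sweep-shaped distortions,
rule-based SV truth — under idealised conditions: no sequencing error, no
missing data unless injected, free recombination between segments, exact
ancestral polarisation, panmictic constant-size populations.  Passing the
suite therefore demonstrates correctness of the estimators and detection
machinery under the model, not robustness to misspecification on real
data (background selection, population growth, reference bias, phasing
and polarisation error).

## Problem sizes in the standard checks

The verification suite runs on desk-scale genomes chosen to keep the
statistics well-resolved: sweep power uses 20 replicates of a 12 x 1 Mb
genome (10 diploids, theta = 0.0035, five planted sweeps with s = 0.05
and r = 50 kb, centers at window midpoints); diversity calibration uses
1-2 Mb neutral cohorts; spectrum correctness uses 10^6-draw Monte-Carlo
simulations of the capture process; permutation p-values are checked
against exact hypergeometric tails on enumerable universes.  The
acceptance script (`scripts/acceptance.py`) re-runs a scaled version of
the same computations from scratch.

## Known limitations

- The scan assumes correctly polarised alleles in unfolded mode; the
  folded mode exists precisely because real polarisation is unreliable.
- The composite likelihood treats SNPs as independent; no correction for
  linkage is attempted (standard for this scan family).
- Physical distance stands in for recombination distance.
- The permutation test treats genes as exchangeable units; gene length
  and clustering are not modelled (the hypergeometric equivalence is
  exact only under that exchangeability).
- Cross-coalescence curves are consumed, never inferred: the upstream HMM
  and its biases are out of scope.
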