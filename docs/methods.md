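# Methods

## Simulation model

Each replicate is an independent neutral coalescent sample with
recombination, generated by msprime and reduced to a binary haplotype
matrix (0 = ancestral, 1 = derived) with continuous site positions in
[0, 1).  Mutations follow the infinite-sites convention (binary model on a
continuous genome), so every site carries exactly one derived allele and
sites fixed in the full sample are discarded.  The locus is parameterized
by the scaled rates θ = 4N₀μl and ρ = 4N₀rl; the defaults θ = ρ = 20,
l = 50 kb, N₀ = 10⁴ are the study conditions used throughout and
correspond to μ = r = 10⁻⁸ per site per generation.  Samples are haploid
genomes (ms semantics); all statistics are defined on haplotypes, and the
default sampling design takes 100 discovery plus 100 disjoint typing
haplotypes per population.  `reuse_discovery_as_typing` types the
discovery haplotypes themselves, the variant in which the typed SFS is
truncated sharply at the threshold frequency.

Demographies are expressed as a generic description — diploid deme sizes,
a scaled migration matrix in 4N₀m units, and a time-ordered backward event
list (splits and size changes, times in 4N₀ generations) — which is
de-scaled into engine units at simulation time.  Four constructors cover
the study's models:

* **Island** (2 or 3 demes).  The stated 4N₀m is interpreted by default in
  the ms `-I` convention: the *total* scaled immigration per deme, divided
  equally among the other demes, so the three-deme model at 0.3 has
  per-pair entries of 0.15.  A `pairwise` convention flag applies the
  stated value to every pair instead; the two readings coincide for two
  demes, which is why the two-island baselines are unaffected by the
  choice.
* **Stepping stone** (3 demes in a line).  Per-pair entry 4N₀m between
  adjacent demes only; the middle deme's total immigration is therefore
  twice the edge demes'.
* **Serial split.**  Backwards in time, deme III merges into II at t₂ and
  II into I at t₁.  The one-generation founder bottleneck is implemented
  literally: a size change to f·N₀ one generation (1/(4N₀) scaled units)
  before the merge.  At the default parameters its coalescent effect is
  numerically negligible (an extra coalescence probability of order
  1/(2f·N₀) for one generation) but it is retained for fidelity to the
  stated model.

Per-replicate seeds are derived from the master seed through a
counter-based `SeedSequence` scheme, so any replicate can be regenerated
in isolation and results do not depend on execution order.

## Ascertainment

Discovery operates on the per-population discovery panels only.  In every
scheme a site must segregate in the panel(s) consulted — a site invisible
to a panel cannot be "discovered" — and the minor-allele-frequency filter
keeps sites with folded frequency ≥ threshold (ties kept; a strictness
flag switches to >).  Markers are then drawn uniformly without replacement
from the candidates; replicates with fewer candidates than the marker
count (default 50) are recorded as excluded for that (scheme, threshold)
cell, never truncated, and exclusion fractions are reported per cell so
conditioning-induced selection of deep-genealogy replicates stays visible.

The independent-panel scheme needs one genuine design decision.  Its rule
— "a site with low MAF in any population is eliminated" — is ambiguous
about sites a panel cannot see at all (absent, or fixed derived).  The
default here is panel-local: a panel only vetoes sites it observes as
variable below the threshold, and discovery requires passing in at least
one panel.  This choice is what gives the scheme its characteristic
behaviour across demographies — strong downward F_ST bias when migration
keeps diverged variants visible at low frequency in neighbouring panels,
a slight upward bias under a recent serial split where post-split variants
are entirely absent from other panels, and workable candidate counts
throughout.  The alternative reading (`unseen_vetoes=True`), in which
absence anywhere eliminates the site, keeps only ancestral variation
shared by all panels: measured under the default study conditions it
leaves a mean of ~7 candidate sites per split-model replicate at threshold
0.10 (never ≥50 in 2,000 replicates), so the scheme would exclude
essentially every replicate once populations are diverged.  Both variants
are implemented and tested; the strict one satisfies the textbook nesting
property (its candidates are a subset of every other scheme's).

## Summary statistics

π̂_w and π̂_b are mean pairwise Hamming differences within and between
populations over the site set, computed from per-site derived counts:
π̂_w = Σ d(n−d) / C(n,2) and π̂_b = Σ [d_A(n_B−d_B) + d_B(n_A−d_A)] /
(n_A n_B).  These identities are verified against brute-force pair
enumeration in the tests.  Values are totals over the site set, not
per-bp: every downstream use is a ratio.  F̂_ST = 1 − π̂_w/π̂_b with π̂_w
the unweighted mean of the two within-population values (deme sizes are
equal in every model here, so weighting is immaterial); replicates with
π̂_b = 0 are flagged undefined and dropped from cell means with a count.
Note the estimator is not exactly zero for identical populations at
finite n: π̂_w excludes self-pairs while π̂_b does not, giving −1/(n−1)
for two copies of the same haplotype multiset.

Bias per (scheme, threshold, pair) cell is aggregated as the difference
between the mean typing F̂_ST and the mean re-sequencing F̂_ST over the
cell's usable replicates; the re-sequencing baseline uses the *typing*
haplotypes at all segregating sites, so the comparison differs only in
site selection, never in samples.  Because both means run over the same
replicates, the difference of means equals the mean of paired differences;
both are stored.  Relative diversity is the ratio of the mean typing π to
the mean π of 50 markers drawn uniformly from all segregating sites of
the replicate (no panel conditioning or MAF filter) — an unbiased
per-site-average control, so departures from 1 isolate the ascertainment
effect from the 50-marker subsampling.  Monte-Carlo standard errors
accompany each quantity (delta method for the ratios).

## PCA

The structure-inference experiment pools, across replicates of a
three-population demography, every candidate site at a 5% panel-frequency
filter (no fixed-size marker draw), for the no-ascertainment control and
each scheme over the same replicates.  Columns are normalized
EIGENSTRAT-style — centered by the allele frequency p among typing rows
and scaled by √(p(1−p)), without the diploid factor-of-2 since units are
haploid — and columns fixed among typing rows are dropped with a count.
Scores are row projections onto the top right-singular vectors;
eigenvalues are those of the row covariance; signs are fixed by making
each component's largest-magnitude loading positive.

Cluster recovery is summarized by a separation ratio: the distance between
two populations' centroids in the leading components, divided by the mean
within-population RMS spread of *all* populations — a common scale for
the whole score plot.  The shared denominator matters: under
single-population ascertainment the discovery population's spread inflates
while the other two populations' centroids converge, and a pair-local
denominator would mask the collapse by deflating the discovery-population
pairs' ratios at the same time.  Ratios well above 1 mean distinct
clusters.  The default pools R = 100 replicates; the qualitative ordering
(all pairs separated without ascertainment and under the merged panel,
the unascertained pair collapsing toward each other under the
single-population scheme) is stable across R from a handful to hundreds
of replicates, though all ratios grow with the pooled site count.

## Problem sizes and numerical choices

The factorial experiment shares one simulation per replicate across all
(scheme, threshold) cells, so scheme contrasts are paired.  The bundled
tests and the acceptance script run at desk scale — 1,000 replicates for
the two-island F̂_ST baselines (MC standard error ≈ 0.004), 400–500
replicates for directional and monotonicity checks, 10,000 cheap
panmictic replicates for the neutral-theory moment checks, R = 100 for
PCA — with three-standard-error tolerances computed from the runs
themselves; the library defaults to the study-scale 10,000 replicates.
Threshold sweeps default to {0, 0.01, 0.025, 0.05, 0.075, 0.1, 0.15,
0.2}; the grid is configuration, not a claim about any particular study.
Ties at the MAF threshold are kept; marker draws and baseline draws use
per-(replicate, cell) derived seeds.  Degenerate inputs are result states,
not errors: zero-site replicates, excluded marker selections, undefined
F̂_ST, empty PCA candidate sets, and zero within-population spread (a
large sentinel ratio) are all flagged and counted.

## What the generator does and does not emulate

The synthetic data are neutral, equilibrium (or piecewise-constant)
coalescent samples with uniform mutation and recombination, phased and
error-free, with known ancestral states and a single biallelic mutation
per site.  Real SNP-array pipelines add genotyping error, missingness,
unphased diploid genotypes, ancestral-state misidentification, selection,
and array-design heuristics (spacing, GC content, tag-SNP selection) that
are out of scope here.  Passing tests therefore demonstrate the *logic*
of ascertainment bias under the modelled histories — directions,
orderings, and magnitudes of the distortions — not quantitative
predictions for any particular array or species.

## Known limitations

* The independent-panel default resolves a genuine ambiguity (documented
  above); analyses sensitive to it should report both variants.
* π̂_w weighting across a pair is unweighted; unequal deme sizes would
  need the sample-size-weighted form.
* PCA separation ratios depend on the pooled site count; only ratio
  orderings, not absolute values, are meaningful across configurations.
* No ascertainment-bias *correction* is provided; the package measures
  bias, it does not undo it.
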