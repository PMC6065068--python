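# Methods

## The demographic model

The world is a raster of square demes (default 50 x 50 km) over an
Iberia-like polygon of 209 land demes; an `18 x 13` grid with a diagonal
southeastern cut and an irregular northern coastline.  Two layers occupy each
deme: the invading focal species and the resident donor species.  The donor
initially occupies the northern 45% of grid rows (a stand-in for its
reconstructed glacial range; the true presence-probability map is not
shipped, and the mask is user-overridable via YAML).  The focal species
starts at carrying capacity in one southwestern source deme and the
simulation runs 10,000 generations (20 ky at 2 y/generation) to sampling.

Per generation, each deme updates by joint-density Lotka-Volterra growth
with both competition coefficients equal to 1:

    N_i' = N_i + G * N_i * (1 - (N_f + N_d) / K_i),

then a fraction `M` of each layer emigrates, split equally among the layer's
habitable neighbours (4-neighbourhood; the donor is confined to its initial
range; coastal demes lose nothing to sea).  Because `K_focal = 2 K_donor`,
the invader deterministically excludes the resident wherever both co-occur;
the exact interaction equations of the original two-layer simulator are not
published, and this is the simplest model satisfying every stated
constraint (replacement complete at sampling under all parameter sets).

Growth is deterministic and real-valued.  Emigrant packets are
*stochastically rounded* to whole individuals (floor + Bernoulli on the
fraction): without rounding, the philopatric mitochondrial setting
(`M = 0.005`, `K = 250`) sends ~0.3 individuals per edge per generation and
a sub-individual cutoff would freeze the wave; with it, colonization
proceeds by discrete founders at a realistic speed.  Abundances below one
individual are truncated to zero, which defines donor extinction and the
front position.  All remaining randomness lives in the coalescent stage.

Parameter sets (`par1`..`par8`) cross `K_G/K_T` in {1000/500, 10000/5000},
`M` in {0.2, 0.02} and bidirectional admixture `A` in {0.005, 0.03} at
`G = 0.5`.  The mitochondrial mode quarters the carrying capacities
(250/125), sets `M = 0.005` (female philopatry) and uses asymmetric
admixture (0.025 donor-to-focal vs 0.001; male-biased colonization).

## Backward ancestry tracing

Sampled lineages (2 per individual for nuclear markers, 1 for mtDNA) start
in the focal layer at the sample demes and walk backward one generation at a
time.  The event order within a backward generation is fixed for
reproducibility: (1) admixture switch — in a co-occupied deme a lineage in
layer *i* has its parent in layer *j* with probability
`A_(j->i) * N_j / (N_i + N_j)` (relative-density scaling; the alternative,
absolute contact numbers, is not adopted because it makes the switch
probability exceed 1 at these parameter values); (2) migration — the
parental deme is drawn proportionally to the inflow masses recorded by the
forward pass, including the stay-at-home mass; (3) coalescence — co-located
lineages of the same marker merge pairwise with probability `1/(cN)`
(`c = 2` nuclear, `1` mtDNA), at most one merger per marker per generation
(mergers are rare at these densities).  A lineage's ancestry is the layer it
occupies at generation 0; merged lineages share ancestry.  Markers are
independent — no recombination within a marker, no linkage between markers,
no sequence evolution, and no pre-divergence ancestral mixing (the species
split predates the simulation by far).

The tracing kernel is a single numba-compiled loop vectorized across all
markers of a replicate (10,000 generations x 40,000 lineage-walks in ~10 s),
which is what makes the desk-scale study feasible on one CPU.

### What the model does and does not reproduce

Mean introgression rises with the admixture rate and falls with migration,
reproducing the reference ordering par4 > par3 > par2 > par1; low migration
also yields the northward within-transect gradients, because slowly mixing
northern lineages repeatedly traverse the former contact front on their way
back to the source.  Two caveats are structural.  First, the marginal
per-haplotype introgression probability is invariant to a joint rescaling of
`K_G` and `K_T` under this kernel (the switch probability depends only on
density ratios, and coalescence — the only K-sensitive ingredient — provably
does not move marginal means, a property the test suite checks directly).
The printed K-ordering of the reference table (par5 > par1) therefore cannot
arise here except through front stochasticity, and is not asserted.  Second,
re-derived interaction equations can only be expected to match printed mean
percentages to first order; the scaled-reproduction test uses a factor-of-two
band chosen a priori, plus the exact orderings, as its criterion.

## Scale choices

The reference analysis used 50,000 markers x 100 replicates per set; this
package's tests and acceptance script run 2,000 markers x 10 replicates per
set (the smallest scale that resolves per-locality means and the 5% frequency
grid cleanly) and 400-1,000 mitochondrial replicates, with one forward
history per parameter set and independent coalescent replicates on it.
Observed maxima of the frequency spectrum are tail statistics and scale with
the number of simulated markers, so desk-scale maxima sit at or below the
printed ones; the outlier bound (no low-admixture marker above 80%) is
one-sided and unaffected.

## Scan statistics

**Frequency spectrum and sign threshold.**  Marker frequency is counted over
the 20 sampled haplotypes (the individual-dosage variant is also reported);
the grid step is 5% because every reference threshold is a multiple of 5.
Tail proportions use `>= f` (boundary inclusive).  The sign threshold is the
minimum grid frequency at which the empirical tail proportion strictly
exceeds the simulated tail in at least `ceil(q * n_reps)` replicates; ties
count against qualification, which can only raise the threshold
(conservative).  The global threshold is the maximum over parameter sets.

**RND/RNDmin.**  An informative site is a position with no missing state
across the three species panels and at least one difference among them (the
source analysis does not define the term; this definition is recorded in
output metadata).  `RND(h) = Dxy(h, donor panel) / Dxy(donor, outgroup)`,
the denominator averaged over all donor x outgroup pairs per window; windows
need >= 50 informative sites (>= 100 for planted power tracts) and are
dropped on a zero denominator.  Windows are non-overlapping, 0-based
half-open, anchored at 0.  Calibration sweeps the threshold over observed
RNDmin values; a window counts as truly introgressed only when a truth tract
covers it entirely (partially overlapped windows are excluded, as are truth
frequencies above 65%, the range the reference local-ancestry method could
see); the largest threshold with FDR <= 10% is selected.  On the clean
synthetic genomes, fully covered windows separate almost perfectly from the
background, so power is high for all tract lengths and the monotonicity
check is non-strict; the low power values of the original study reflect
real-data noise that the generator deliberately omits.

**Dating.**  Tract lengths under a single admixture pulse are exponential
with mean `1/(rt)`; the estimator inverts the pooled arithmetic mean tract
length with `r = 1e-8` per bp per generation and 2-year generations.  IBS
tracts are runs of identity between consecutive mismatches (interior length
= distance between flanking mismatches - 1); terminal runs are censored and
excluded from binning by default; tracts intersecting masked regions are
discarded.  Binning uses `[(3/2)^n, (3/2)^(n+1))`; the two minimum-length
filters (300 bp, 10 kb) are alternatives, never combined silently.  The
demographic fitting that consumes these histograms is out of scope.

**Sequence statistics.**  FST is Hudson's `1 - Hw/Hb` per site, averaged
genome-wide as a ratio of means, negatives untruncated (the estimator and
averaging are recorded in metadata since the reference names neither).  The
exact Hardy-Weinberg test conditions on allele counts and sums probabilities
no larger than the observed configuration's.  The gene filter cascade
applies, in order: triallelic-site masking; discard on HWE distortion at
p < 0.01 in either parental species (paralogy guard — the whole alignment is
discarded, the stricter reading); removal of sequences > 50% missing;
exclusion of donor-origin focal haplotypes; masking of sites with < 4
informative haplotypes in either species or no outgroup information; and
rejection below 100 comparable codons or on a premature stop.  dN/dS uses
Nei-Gojobori site/difference counting (changes to stops counted
non-synonymous, multi-step codons averaged over minimal pathways) with
Jukes-Cantor correction; gene values average defined pairwise ratios, and
pairs with `p >= 3/4` or `dS = 0` are excluded and counted.

**Landscape.**  Relative position is `|pos - L/2|/(L/2)` (centre) or
distance/arm-length (centromere; undefined on a zero-length arm).  Levan
arm-ratio cutoffs 1.7/3/7 separate metacentric, submetacentric,
subtelocentric and acrocentric chromosomes (the reference cites the
classification without printing thresholds).  SNP subsampling is greedy
left-to-right at >= 50 kb, deterministic and seedless; the centromere-style
binned analysis requires an explicit bin width (none is stated anywhere, so
none is defaulted).

## Synthetic data

Sequences are generated site-independently on the tree
`((focal, donor), outgroup)`: branch mutation probabilities solve the
pairwise targets (focal-donor uncorrected distance 0.0069; within-species
diversity as star phylogenies with `pi/2` private mutations per haplotype,
0.0014 focal / 0.0022 donor; donor-outgroup distance defaults to twice
focal-donor, a configurable choice as no value is printed).  Planted tracts
copy the donor consensus plus `pi_donor/4` noise (a shallow coalescence
inside the donor tree), onto haplotype sets chosen by pattern: uniform,
northern-only, mtDNA-like (none of the 10 southern, >= 2 northern), or
outlier (> 80%).  Frequencies are realized exactly.  What passing tests on
these data do **not** show: robustness to linkage disequilibrium, incomplete
lineage sorting, phasing error, or missing data — the generator has none of
them.

## Numerical conventions

Coordinates are 0-based half-open throughout; BED/TSV/FASTA/VCF output is
plain text.  All stochastic components take explicit integer seeds;
sub-seeds derive from `numpy.random.SeedSequence` with CRC-based keys and
stay below 2^31.  Backward-sampling cumulative distributions are float32;
the kernel guards the upper boundary by skipping zero-mass slots.  The exact
Spearman p enumerates all `n!` rank permutations up to n = 10 (cached
permutation matrix); Mann-Whitney uses the exact small-sample distribution
when tie-free.  The HWE enumeration works in log space.

## Known limitations

No habitat heterogeneity, long-distance dispersal, density-dependent
admixture, within-marker recombination, or selection; the landscape module
consumes recombination tracks rather than estimating them; ELAI-style local
ancestry inference is represented by its dosage output contract (and by
simulator truth), not re-implemented.  Real-data results of the original
study (per-individual proportions of 1.38-2.44%, 139 outlier regions, the
rho = 0.74 centre-distance correlation) depend on the sequenced genomes and
are anchors for orders of magnitude only, not targets the synthetic pipeline
reproduces.
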