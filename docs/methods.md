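# Methods

This note documents the models, estimators and numerical choices behind
`hybridscan`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Forward simulation of hybrid populations (`simulate`)

The generator produces mosaic diploid genomes under a Wright–Fisher
admixture-pulse model. Generation 0 consists of N pure parental diploids,
parent-1 (P1, the "malinche-like" parent) with probability `admix_p`. Each
subsequent generation: (i) parents are drawn with replacement with
probability proportional to fitness — the product over planted
incompatibility pairs of the 3×3 fitness-matrix entry for the individual's
two-locus ancestry genotype; mating is random with selfing allowed; (ii)
each gamete receives Poisson(L Morgans) crossovers per linkage group at
uniform positions, with no interference, on a uniform map (default
1 cM/378 kb, the genome-wide average for the motivating system); (iii)
optionally, a Binomial(N, m) number of individuals is replaced by pure
parental migrants. Coordinates are 0-based, half-open (BED convention); a
marker at position x takes the ancestry of the segment containing x.
Haplotypes are stored as (first ancestry, breakpoint list) with strictly
alternating ancestry, which makes the segment-tiling invariant structural.

Demographic scenarios re-express coalescent-style parameters in forward
time through the parental effective size (default Ne = 10,500): a
migration rate 4Nm becomes a per-generation migrant fraction 4Nm/(4Ne), and
burst windows given in units of t/4N become generation windows t·4Ne before
the present. A bottleneck multiplies the hybrid population size by
`bottleneck_fraction` for the whole post-admixture epoch, matching the
scenario in which the hybrid population is founded small.

What the generator does **not** emulate: sequence-level mutation (markers
are perfect ancestry readouts before read noise), recombination-rate
variation along the genome, interference, sex chromosomes, age structure,
assortative mating, and linked background selection. Passing tests
therefore demonstrate correctness of the estimators under the stated model,
not robustness to, e.g., recombination-map misspecification — the dating
module in particular inherits the uniform-map assumption and will
underestimate ages where the true map is longer than assumed.

Read sampling: per marker, read depth ~ Poisson(depth); each read picks one
haplotype uniformly and reports its parental allele flipped with that
parent's error rate (defaults 0.04 for P1, 0.05 for P2 templates — the
empirical wrong-parent call rates of the motivating data set). The
probability a read reports P1 at dosage d is (d/2)(1−e₁) + (1−d/2)e₂.

## Ancestry HMM (`hmm`)

Three hidden states per marker (hom-P1, het, hom-P2). Emissions are
binomial in the P1-read count with success probabilities 1−deltapar2, ½,
deltapar1; binomial coefficients cancel in normalisation and zero-read
markers are state-uninformative. The per-read error parameters
(deltapar1 = 0.05 for P2/birchmanni tracts, deltapar2 = 0.04 for
P1/malinche) are taken 1:1 from the wrong-parent call rates measured in
parental panels.

Transitions treat each haplotype as a two-state ancestry chain. Over an
inter-marker gap of d bp a haplotype switches ancestry with probability
q(d) = 1 − exp(−λd), λ = morgans_per_bp × rfac × (recRate / 24 Morgans).
`recRate = 240` is an expected genome-wide ancestry-junction count
calibrated on a 24-chromosome, one-Morgan-per-chromosome genome (one
crossover per chromosome per meiosis × an a-priori ≥10 generations of
admixture); dividing by the 24-Morgan reference converts it to junctions
per Morgan independently of the map actually analysed, and `rfac = 3` is
the published tuning scalar (the largest value that does not induce
breakpoints in parental individuals). The diploid transition matrix is the
product chain of the two haplotypes: hom↔het costs one switch, hom↔hom a
double switch (probability q²). The exact transition algebra of the
original MSG implementation is not published; this construction preserves
the parameters' documented roles and their qualitative behaviour (more
breakpoints with larger rfac, none on parental input at the defaults).

Forward–backward is run per linkage group with per-step normalisation
(scaled algorithm); posteriors are validated against brute-force path
enumeration in the test suite. The two-pass scheme runs naive priors
(⅓, ⅓, ⅓), sets the priors to the population-mean posterior state
frequencies, and reruns — the learned priors estimate the population's
genotype composition (e.g. ≈(0.49, 0.42, 0.09) for a malinche-major zone).

Post-processing follows the published rules: hard calls require the
maximum posterior to exceed 0.95 (strictly), markers missing or ambiguous
in more than 15% of individuals are dropped, and adjacent markers are
thinned unless some individual's posterior moved by at least 0.1 relative
to the last *kept* marker (first marker of each group always kept; the
last-kept comparison, rather than nearest-neighbour, is what makes the
thinned set describe every ±0.1 ancestry change). Individuals are hybrids
iff their hybrid index (proportion P1 over called markers) lies in
[0.10, 0.90]; hybrids outside mean ± 2.576·sd of the hybrid-index
distribution are excluded as ancestry outliers. The interval uses the
distribution's sd, not the SE of the mean: an SE-based band excludes
essentially every individual once n is large, which is clearly not the
intended (published) behaviour of removing a handful of outliers.

## Cross-chromosome LD scan (`ld`)

R between two markers is the Pearson correlation of unphased ancestry
dosages over pairwise-complete individuals — the composite-LD estimator;
under random union of gametes the dosage correlation equals the gametic
(haplotype) correlation. Within-chromosome pairs are excluded from scans.
A permutation-exact property worth knowing: under the null, E[R²] is
exactly 1/(n−1) for this estimator, independent of the dosage
distribution. With n = 170 individuals that is ≈0.0059; reports of
unlinked-R² levels near 1/(2n) correspond to estimators with ~2n effective
units and are not reachable by a dosage Pearson correlation.

Significance: a proportional-odds ordinal regression of the second
marker's dosage (genome order; a symmetric orientation average is
available) on the first, fitted on the 3×3 contingency table by BFGS with
an L2 penalty on the slope equivalent to a Gaussian prior with sd 2.5 —
the conventional weakly-informative default for ordered-logit
stabilisation. The penalty keeps the slope finite under complete
separation while leaving near-null fits essentially untouched. t =
slope/SE with SE from the observed information (central-difference Hessian
of the penalised likelihood), and p two-sided from Student t with
n_complete − 2 df. Degenerate tables (constant outcome, singular
information) fall back to an exact permutation test on |R| with the
add-one estimator p = (1 + #{|R*| ≥ |R|})/(B+1); ties count as exceedances,
so the permutation p is exact but conservative for small n where discrete
dosage tables collide.

The effective number of independent markers M_eff uses the Li–Ji spectral
construction: with eigenvalues λᵢ of the marker correlation matrix,
M_eff = Σᵢ [ I(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋) ], reported unrounded (the ceiling is
used where a marker count is needed). Permutation FDR calibration samples
⌈M_eff⌉ markers, permutes genotypes within columns independently in each
population (preserving marginal dosage frequencies exactly), counts joint
positives at each threshold, and divides the mean by the observed joint
count. Demographic FDR re-simulates both populations under bottleneck /
migration scenarios, estimates each population's marginal false-positive
rate at the joint threshold, takes the joint rate as their product (the
populations are independent), scales by the effective number of
cross-chromosome tests and divides by the observed positive count. The
bounded-FDR property test calibrates the joint threshold so the *neutral*
expected FDR is 5% (mirroring the permutation-calibration step of the
original analysis) and then requires the demographic scenarios to stay at
or below 15%.

The conspecific-excess test compares the fraction of positive-R pairs
among joint-significant pairs to same-size draws (without replacement)
from the genomic background (pairs non-significant in both populations).

## LD blocks (`blocks`)

Significant markers on a chromosome are clustered left-to-right: a focal
marker joins the current cluster iff its pairwise p-value with the
cluster's last member is below the significance threshold, else it starts
a new cluster. Block intervals span first to last member; single-marker
blocks take the marker's unit BED interval. Partner region pairs from two
populations are intersected requiring overlap on *both* sides. The
misassembly check flags a block-edge marker when its maximum
cross-chromosome R² exceeds its maximum same-chromosome R² within 300 kb;
markers with no neighbour in the radius are excluded from the denominator.

## Dating (`dating`)

D for a marker pair is half the dosage covariance (diploid composite-D:
cov(x, y) = 2D_g under random union, so D̂ = cov/2 estimates the gametic
disequilibrium), computed over a minor-parent-informative marker subset
(tagged markers in synthetic data; the caller supplies the autapomorphic
subset on real data) and paired with map distance x in Morgans. The
exponential D = a·exp(−Tx) is fitted by Levenberg–Marquardt with
a₀ = max D and T₀ = 1/mean(x) (robust for exponentials); negative fitted T
is clipped to 0 with a warning. Distances are capped by default at desk
scale (≈1.5 Mb ≈ 0.04 M) because the per-generation decay factor is
1 − c(x) with Haldane's c, and the e^(−Tx) approximation is accurate to
~2% only for small x. CIs bootstrap individuals (recomputing points and
refitting); `fit_decay` alone can only bootstrap points, so the
individual-level bootstrap lives in `estimate_age`.

## Two-locus selection and ABC (`bdm`)

Ancestry genotypes at a locus are coded by the number of "M" (P1) alleles.
Three fitness matrices: variant A penalises every genotype with ≥1 M at
locus 1 and ≥1 B at locus 2 (four cells at 1−s) — the combinations never
tested by selection when the derived M allele arose at locus 1 against a B
background at locus 2; variant B is the mirror; ALL_HYBRID penalises
everything but the two parental double homozygotes (co-evolution /
selection against hybrid phenotypes). Selection is equal across penalised
cells.

One generation iterates: selection reweighting → gamete production with
recombination fraction ½ (for unlinked loci the two alleles of a gamete
are independent draws within the individual, so phase never enters and
nine unphased classes suffice) → drift as a multinomial sample of 2N
gametes over the four gamete classes (an N = ∞ flag skips drift) → random
union of gametes. The admixture-pulse initial state is gametes M-M at
frequency p and B-B at 1−p — maximal initial LD, the configuration a
hybrid-zone founding event produces. Neutrally, gamete-level D halves each
generation exactly.

Pair sets: each of n_pairs locus pairs is assigned variant A or B by a
fair coin (the two BDM orderings are equally likely a priori), iterated T
generations, and multinomially sampled at that pair's sample size. Summary
statistics (averaged over pairs): the major-parent double-homozygote
frequency, the pooled minor-parent homozygote×heterozygote frequency (both
orientations), and the mean ancestry proportion. The kernel is compiled
with numba; drift and sampling use sequential binomial decompositions of
the multinomials.

ABC: parameters are drawn from independent uniform priors — s ∈ (0, 0.1),
population-specific admixture proportion and age windows, N ∈ (50, 5000) —
summary statistics are normalised by their prior-predictive sd, and the
tolerance fraction of draws nearest in Euclidean distance is accepted.
Accepted parameters are logit-transformed to their prior support,
adjusted by a local-linear regression on the (normalised) statistics
shifted to the observed values, and back-transformed — preventing
out-of-support adjusted draws. The MAP is the mode of a Gaussian KDE with
Silverman bandwidth on a 512-point grid; credible intervals are 2.5/97.5
percentiles of the adjusted draws. Zero-variance statistics are dropped
from the regression; a fully degenerate accepted set skips adjustment with
a warning.

Posterior predictive checks draw parameter vectors from the joint
(adjusted) posterior, simulate pairs until the requested number passes the
same significance rule applied to data (conspecific sign and ordinal
p < 0.013 by default), and report per-class deviations of observed
genotype frequencies from random-mating (product Hardy–Weinberg)
expectations, with orientation-symmetric classes collapsed (MM_MB with
MB_MM, etc.). An attempt cap guards rules that cannot be satisfied.

## Divergence (`divergence`)

Consumes externally computed per-region counts (divergent sites, aligned
length, optionally synonymous/nonsynonymous classes as pass-through
columns). Divergence is count/length. Single-marker regions are widened to
their nearest flanking markers (one-sided at group edges). The comparison
is one-sided (candidates > background), matching the directional
hypothesis: observed mean with a with-replacement bootstrap CI over
candidate regions, against a null distribution of same-size
without-replacement background draws; both mean and median are reported.

## Problem sizes and reproducibility

Desk-scale defaults used by the acceptance script and tests, chosen once
as a realistic miniature of the study conditions: 4–10 linkage groups of
7.5–9.5 Mb, markers every 40 kb–1 Mb, populations of N = 800–3000 with
samples of 143–170, ABC at 10⁵ simulations × 48 pairs with tolerance 0.5%
(the test suite uses 3×10⁴ × 30 pairs at 1%), demographic-null rate
estimation from two replicates of 780 cross-chromosome pairs per
population. All randomness flows from a single seed via
`numpy.random.SeedSequence`; stage seeds are derived deterministically, so
identical seeds give byte-identical numeric outputs.

## Known limitations

- The uniform-map assumption biases age estimates wherever the true
  recombination map deviates; no correction is applied.
- The ordinal-regression p-value is well calibrated in the bulk but the
  permutation fallback is conservative for small samples (tied discrete
  tables); both are exact only under exchangeability.
- One-directional BDM variants (A/B) purge the incompatible alleles under
  sustained strong selection, so planted-pair LD is transient — detection
  power peaks at intermediate ages and the end-to-end recovery fixtures
  use the symmetric ALL_HYBRID variant for a stable signal.
- The forward-time demographic nulls stand in for coalescent simulations
  of the same scenarios; they reproduce the qualitative bounded-FDR
  behaviour, not exact coalescent FDR values.
- s and N are partially confounded in the ABC posterior at small N, where
  drift mimics weak selection; the regression adjustment narrows but does
  not remove this ridge.
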