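# hybridscan

Genome-wide mapping of hybrid incompatibilities from ancestry linkage
disequilibrium in natural hybrid zones.

When two recently diverged species hybridise, selection against
Bateson–Dobzhansky–Muller (BDM) incompatibilities — negative epistatic
interactions between alleles that evolved in separate lineages — removes
particular combinations of parental ancestry from hybrid genomes. After
tens of generations of admixture, this leaves a detectable footprint:
*unlinked* genomic regions whose local ancestries are correlated across
individuals, with same-parent ("conspecific") combinations
over-represented. `hybridscan` implements the full analysis chain needed to
find and interpret that footprint, for users studying replicate hybrid
populations with shallow-sequencing ancestry data (the motivating system is
a pair of swordtail fish hybrid zones, but nothing is fish-specific):

- **Forward simulation** of admixed diploid populations: Wright–Fisher
  reproduction from an admixture pulse at proportion *p*, Poisson
  crossovers on a uniform map (default 1 cM/378 kb), planted two-locus
  incompatibilities with selection coefficient *s*, optional bottlenecks
  and migration, and shallow-read sampling with per-parent error rates.
- **Ancestry calling**: a three-state (hom-P1 / het / hom-P2) hidden Markov
  model over allele-specific read counts with binomial emissions,
  distance-dependent transitions, two-pass (learned) priors, ambiguity
  filtering, marker thinning and hybrid classification.
- **LD scanning**: the ancestry correlation R between dosage vectors of
  marker pairs on *different* chromosomes, with p-values from a
  ridge-stabilised proportional-odds ordinal regression (t = slope/SE,
  Student t with n−2 df) or an exact permutation test; effective number of
  independent markers by eigenvalue spectral decomposition; permutation and
  demographic-simulation FDR calibration; joint two-population
  significance; block clustering and cross-population interval
  intersection; a misassembly check comparing local vs cross-chromosome LD.
- **Hybrid-zone dating** from admixture LD decay: D(x) = a·exp(−T·x) with
  D half the dosage covariance and x the map distance in Morgans, fitted by
  nonlinear least squares with bootstrap CIs.
- **Selection inference**: the two-locus selection → gamete (c = ½) →
  drift (multinomial sampling of 2N gametes) → random-union recursion for
  the nine ancestry genotype classes; rejection ABC with local-linear
  regression adjustment over (s, N, T, p); posterior predictive checks of
  genotype-frequency deviations from random-mating expectations.
- **Divergence resampling**: per-site divergence of candidate LD regions
  vs same-size draws from the genomic background.

## Worked example

Dating a simulated hybrid zone (`examples/03_date_hybrid_zone.py`):

```
simulated pulse age:  40 generations
estimated age T_hat:  39.8 generations
bootstrap 95% CI:     35.3 - 43.7
amplitude a_hat:      0.182  (ancestry covariance at x = 0)
R^2 decays below 0.5 at ~332 kb
```

The exponential decay constant of pairwise disequilibrium with map distance
recovers the simulated pulse age; the distance at which windowed R² falls
below 0.5 shrinks as ln 2 / (2T) Morgans, so older zones show tighter LD.
Inferring selection strength by ABC (`examples/04_abc_selection_strength.py`,
truth s = 0.03):

```
MAP s = 0.0370   (95% credible interval 0.0244 - 0.0676)
MAP N = 3549
```

Each script in `examples/` demonstrates one capability end to end
(simulation + genotyping, the planted-pair LD scan, dating, ABC,
divergence resampling) and prints a line explaining what the numbers mean.
A thin CLI covers the file-based stages:

```bash
hybridscan simulate --scenario zone.yaml --map markers.bed --out-genotypes geno.tsv
hybridscan genotype --reads reads.tsv --map markers.bed --out-genotypes calls.tsv
hybridscan ld --genotypes geno.tsv --out scan.tsv
hybridscan age --genotypes geno.tsv --map markers.bed --out age.json
```

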