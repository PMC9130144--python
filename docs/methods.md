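# Methods

This note records the statistical conventions, the simulator's assumptions,
and the design choices made where several defensible options existed. It
states nothing that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

Genotypes are unordered pairs of positive integer allele codes per
individual × locus; `0/0` is missing, and a half-missing pair is promoted
to fully missing. GenePop files are accepted in 2- or 3-digit coding
(auto-detected per file, mixed widths rejected), `POP` separators are
case-insensitive, and the comma after the individual ID is required.
Haplotype alignments require equal lengths over {A,C,G,T,N,-}; sequences
are uppercased on read. Membership matrices must row-sum to 1 within 1e-4
on input and are renormalised to 1e-6 or better after validation.

Haplotype collapsing treats a distinct fully-resolved sequence as a
haplotype. A sequence with N/gap sites joins a resolved haplotype only if
it matches exactly one of them at its resolved sites; otherwise it is
excluded with a logged warning. This is deterministic and conservative —
an ambiguous read never invents a new haplotype and never picks among
several compatible ones.

## Estimators

* **He** uses Nei's unbiased form (2n/(2n−1))(1 − Σp²), the convention of
  the classical microsatellite summary tools.
* **Allelic richness** is hypergeometric rarefaction to g genes (El
  Mousadik & Petit). The default g is twice the smallest genotyped sample
  over the groups and loci being compared, so every table cell is defined;
  g is exposed because rarefaction depth dominates the scale of A_R
  (depth 2 confines A_R to [1, 2], which is what per-location tables with
  singleton samples force).
* **F_IS / F_ST** are Weir–Cockerham variance-component estimators; the
  multilocus value is the ratio of components summed over alleles and loci.
  F_IS significance permutes alleles among individuals within the group
  (two-sided on |f|); pairwise-θ significance shuffles individuals between
  the two groups, both with the +1 permutation correction. BY (any
  dependence) FDR is applied across groups/pairs. 10,000 permutations is
  the default; calibration experiments use 199 to keep 200-fixture runs
  fast, which only coarsens, never biases, the null p-values.
* **Exact HWE tests** condition on allele counts. The full array space is
  enumerated when it contains ≤ 20,000 genotype arrays; otherwise the null
  is sampled by uniformly random re-pairings of the 2n genes. Those
  re-pairings *are* the conditional null distribution, so draws are i.i.d.
  and the standard error is plain binomial — this replaces the classical
  switch-based Markov chain, which needs dememorisation and batch-means
  error estimates for the same target. One-sided heterozygote
  excess/deficiency tests use the total heterozygote count as score under
  the same null. Fisher's combination reports χ² = −2Σln p with df = 2k; a
  zero p (an enumeration/permutation proxy) propagates as χ² = ∞, combined
  p = 0. Elsewhere a permutation zero is reported as 1/(n_perm+1).
* **LD** is a genotypic contingency G-test between the two loci's genotype
  classes, with p from permuting one locus's genotypes across individuals.
* **Null alleles** use the closed-form Chakraborty and Brookfield-1
  estimators with the disregard rule: fewer than 15 genotyped individuals
  or both estimates under 8%. (The randomisation-based allele-size
  diagnostics of dedicated software are out of scope.)
* **Private-allele Nm**: p̄(1) is the mean in-home-group frequency of
  alleles seen in exactly one group; the Barton–Slatkin log-linear
  regressions at reference sizes 10/25/50 (ln p(1) = a·ln Nm + b with
  (−0.505, −2.44), (−0.576, −2.655), (−0.612, −2.585)) give three
  estimates, and the size-corrected value interpolates linearly between
  the bracketing reference sizes at the observed mean sample size (nearest
  segment beyond [10, 50], floored at 0). `migrants_over_horizon`
  converts migrants/generation to a horizon count, nm·horizon/gen_time.
* **AMOVA**: for genotype data the default decomposition is gene-level —
  locus-by-locus over allele copies, components summed over loci — which
  makes Φ_ST the direct F_ST analogue; on island-model fixtures it tracks
  multilocus θ to within ~0.005. An individual-level variant partitioning
  squared allele-mismatch distances between individuals is available
  (`level="individual"`); it is the natural distance-matrix formulation
  (and the one the brute-force oracle checks) but sits systematically
  above θ (~+0.06 at θ≈0.2) because it omits the within-individual gene
  level from the denominator. Haplotype AMOVA uses pairwise site
  differences. Negative components are reported as estimated, with
  percentages shown both raw and after truncating negatives to zero.
  Permutation schemes are the standard component-specific ones:
  individuals among populations (Φ_ST), individuals among populations
  within groups (Φ_SC), whole populations among groups (Φ_CT).
* **ΔK** is |L̄(K+1) − 2L̄(K) + L̄(K−1)|/sd(L(K)), undefined at the ends,
  infinite when sd = 0; the argmax is reported alongside the full table
  rather than auto-selected, since K selection should triangulate several
  estimators. The **MMMM** estimators count, per replicate, clusters in
  which some sampling location's mean (or median) membership reaches the
  threshold (default 0.8), then take the median/max across replicates.
  Even-replicate medians are reported as-is with a rounded companion.
* **Bootstrap representativeness**: S subsamples of the captive size m are
  drawn *without* replacement from the M wild individuals (m > M/2 makes
  with-replacement duplicates dominate; a `replace=True` flag exists for
  sensitivity). The 2.5/97.5 band uses order statistics by default;
  interpolated ("linear") quantiles are available and are used in the
  coverage calibration, where the nominal 95% level itself is under test
  (at S=100 the order-statistic band covers ≈93%, the interpolated one
  ≈95%). Replicates on which a statistic is undefined are redrawn and
  counted.

## Simulator

Forward-time Wright–Fisher, chosen over a coalescent because captive
founding and reproductive skew are forward-time mechanisms. D demes of
diploid size N; each offspring draws its two parents from its own deme with
probability 1−m, from one uniformly chosen other deme with probability m
(recorded migrant convention: Nm = N·m immigrants per deme per
generation, under which F_ST ≈ 1/(1+4Nm) at equilibrium). Microsatellites
mutate ±1 repeat with probability mu per transmitted allele, reflecting at
state 1 so codes stay GenePop-positive; initial allele states are uniform
on [10, 30], giving standing variation that drifts toward
migration-mutation balance. Missingness is uniform at random — the
simplest null; no locus- or deme-specific dropout is modelled. mtDNA is
one maternally inherited sequence per individual, each deme starting from
its own random ancestor, with finite-sites mutation and female migration
m_f (default m). Generation time is a labelling constant only — horizon
conversions take it as an argument.

The captive generator draws f founders without replacement from the source
demes, designates n_females of them as breeding females, gives each sex
Dirichlet(skew) parental weights, and produces offspring by Mendelian
draws; offspring mtDNA copies the mother's haplotype. Small `skew`
concentrates reproduction (the "one dominant breeder" scenario);
`n_females=1` forces a single maternal lineage.

What the simulator does *not* emulate: selection, age structure and
overlapping generations (relevant to a species maturing at 18–25 years),
spatial landscape/watershed geometry, allele-size homoplasy constraints,
and genotyping artefacts (stutter, allelic dropout). Passing tests
therefore demonstrate correctness of the estimators and the qualitative
founder-effect mechanics, not calibration to any real dataset.

## Calibration experiments (study conditions)

`rerepop.experiments` fixes the problem sizes used by the acceptance
checks: island-model recovery at D=8, N=50, 4Nm=4, mu=1e-4, G=10N over 20
seeds (mean θ within ±50% of 0.2); type-I error of the F_IS/LD/θ
permutation tests on 200 null fixtures each (Dirichlet allele frequencies,
allele-wise i.i.d. genotypes — exact HWE and linkage equilibrium), bound
0.07 at nominal 0.05; bootstrap-band coverage over 200 meta-replications
(95% ± 4 points); and the founder-effect scenario at D=6 diverged demes
(m=0.002, G=80), f=9, one breeding female, 88 offspring over 50 seeds —
expected pattern: exactly one captive haplotype, Hd/π/ANAPL below the wild
band, Ho above it. These scales keep each experiment in the tens of
seconds to ~2 minutes on one CPU while leaving the binomial noise well
inside the tolerance bands.

## Known limitations

* The Genepop reference implementation of the private-allele method could
  not be cross-run here; the regression coefficients and the interpolation
  rule are validated against hand computation (p̄(1)=0.065 at reference
  size 10 ⇒ Nm≈1.79) rather than against the binary.
* The HWE Monte Carlo draws independent re-pairings rather than running
  the switch chain; results agree with enumeration (tested to 3 SE) but
  chain-specific diagnostics (number of switches) are not reproduced.
* AMOVA assumes every population is non-empty at shared loci; loci absent
  from a population are skipped at the gene level rather than imputed.
* With S=100 bootstrap replicates the band's percentile granularity is
  1/100; order-statistic and interpolated bands can differ at that scale.
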