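# Methods

`mpqtl` implements the statistical pipeline used to dissect virus
resistance in an eight-founder *Drosophila melanogaster* advanced-intercross
panel (DSPR-style recombinant inbred lines, RILs), together with a
simulator that generates panels with the same statistical structure so
that every stage can be validated by parameter recovery.  This note
records the models, the numerical choices, and what the synthetic data do
and do not establish.

## The vial-level mixed model

All phenotype modelling starts from the vial-level linear mixed model

    y_ijk = beta + date_i + RIL_j + eps_ijk

where `y_ijk` is the phenotype of vial *k* of RIL *j* injected on day *i*
(mean survival day of DCV-infected flies, or the proportion of
sigma-virus-infected flies — analysed untransformed in both cases),
`date_i ~ N(0, s2_date)`, `RIL_j ~ N(0, s2_RIL)` and
`eps ~ N(0, s2_resid)`.  The single-day repeatability is

    R = s2_RIL / (s2_RIL + s2_resid)

deliberately excluding the between-day variance.  QTL enter as fixed
effects: either a two-level allele class or the founder genotype
probabilities / resistant probability at the peak.

**Estimation.**  REML (default) or ML, via Henderson's mixed-model
equations.  The coefficient matrix is ordered (fixed effects, dates,
RILs); the RIL block is diagonal and absorbed by a Schur complement, so
one likelihood evaluation costs `O(n + n_RIL * (p + n_date)^2)`.  The two
variance ratios are profiled out of the residual variance and maximised
with Nelder–Mead from a coarse log-scale grid start (bounds e^-18..e^10 on
the ratios; a ratio pinned at the lower bound is reported as a zero
variance component).  On balanced designs the estimates agree with
expected-mean-square closed forms to ~1e-8 (tested); on unbalanced
single-factor designs they agree with `statsmodels` `MixedLM` (tested).
A constant response is detected up front and returned as a degenerate fit
(all variances zero) rather than being pushed through the optimiser.

**Repeatability CI.**  Profile likelihood on R: the ratio
`gamma_RIL = R/(1-R)` is fixed, the date ratio and residual variance are
re-profiled, and the 95% bound solves a chi-square(1) threshold by Brent's
method.  If the profile is too flat to bracket a bound (tiny designs), a
parametric bootstrap (default 1,000 refits) supplies the missing side.

**BLUPs.**  The RIL solutions of the mixed-model equations are the
empirical BLUPs — shrunken, date-corrected RIL deviations that sum to ~0.
"Corrected" BLUPs come from the same fit with the QTL fixed term included,
so downstream scans see the phenotype net of a known locus.

**Variance decomposition (Bayesian).**  The proportion of between-RIL
variance explained by a QTL is the relative drop in the posterior median
of `s2_RIL` between the baseline model and the model with the QTL fixed
effect.  Both are fitted with a conjugate Gibbs sampler: flat prior on
fixed effects, inverse-gamma(0.001, 0.001) on each variance; defaults
13,000 iterations, 3,000 burn-in, thinning 10 (all configurable).  Chains
with effective sample size below 100 for `s2_RIL` are flagged, and
negative proportions (sampling noise around zero) are reported as-is with
a flag rather than truncated.  Tests use shorter chains (2,500–5,000
iterations), which keep the Monte Carlo error of the proportion well
inside the ±0.10 recovery tolerance at the tested sizes.

**Joint effect sizes.**  All mapped QTL enter one REML model as per-RIL
resistant probabilities (0 → susceptible allele, 1 → resistant), so a
coefficient is the trait change across the allele swap.  Wald 95%
intervals and two-sided p-values are reported, plus the per-coefficient
Wald chi-square given all other loci (the type II test used to declare
QTL effects independent).  Covariate pairs with |r| > 0.99 are flagged.

## Genome scans

At each 10-kb grid position the RIL BLUP is regressed on the eight founder
genotype probabilities.  Because the probabilities sum to one, the design
holds at most seven independent founder columns beyond the intercept; rank
is decided numerically (SVD with a relative tolerance), so a founder
absent at a position simply reduces `df_num` — no column is special-cased.
The model-comparison F is converted to

    LOD = (n/2) * log10(RSS0 / RSS1)

with RSS0 from the null design (intercept plus any covariate, e.g. the
founder probabilities at an already-mapped QTL, included in both models so
the LOD measures the position's increment).  Perfect fits are capped at a
finite LOD; a constant phenotype scores 0 everywhere.

**Permutation significance.**  Phenotypes are permuted across RIL labels
while genotypes — and genotype-linked covariates — stay with the genomes,
preserving LD structure under the null.  The genomewide maximum LOD is
recorded per permutation (2,000 by default for main scans, 1,000 for
interaction scans); the alpha-level threshold is the
`ceil(alpha * n_perm)`-th largest maximum and p-values use the add-one
convention `(r+1)/(n_perm+1)` (so an observation beyond all 2,000 nulls
reports p = 1/2001, printed as < 0.0005).  Internally each position is
reduced once to an orthonormal basis of its founder columns residualised
against the null design; a permutation then costs one matrix product, and
the resulting thresholds are exact least squares, not an approximation.
Calibration is verified by simulation: under a no-QTL panel the 0.05
threshold is exceeded by the true scan at the nominal rate (binomial 95%
band, 200 replicates).

**Interval refinement.**  The LOD profile is recomputed locally around a
peak (window ±1 Mb by default, same 10-kb grid — no sub-grid
interpolation).  Two supports are reported: the 95% Bayesian credible
interval (smallest contiguous run of grid steps, grown outward from the
peak, holding ≥95% of the normalised 10^LOD mass; profiles with more than
one mode above peak−2 are logged) and the 2-LOD drop interval (outermost
positions within 2 LOD of the peak).  Ties for the peak go to the lowest
(arm, position); a peak on the window edge triggers a warning.

**Mapping resolution caveat.**  Neighbouring grid positions separated by
no informative recombination event are *identical* designs; the argmax
within such a block is decided by noise (or by the lowest-position tie
rule when exactly tied).  Recovery tolerances of ±2 grid steps therefore
presuppose enough RILs that recombination breaks the local block, which
holds at the 600-RIL scale used in the recovery experiments.

## Founder-allele classes

At a mapped QTL, RILs are hard-assigned to the founder whose probability
is ≥0.95 (configurable); ambiguous RILs are excluded — the computable
analogue of genotyping ambiguous lines directly, which software cannot do.
Represented founders are ranked by mean BLUP and the ranked list is cut at
each of the k−1 points; each cut is scored by a two-group one-way ANOVA F
and the best cut is the two-class (resistant/susceptible) partition.  Ties
in F go to the smaller resistant class (conservative minor-allele
designation).  Whether the high or the low end of the trait is "resistant"
is explicit (`higher_is_resistant`): survival days → high, infection
proportion → low.  The ranked-cut search is the analysis; an exhaustive
all-bipartition maximiser exists only in the test suite as an oracle and
upper bound.  A RIL's resistant probability is the summed genotype
probability of resistant-class founders, so resistant + susceptible
probabilities are exactly 1.

Linkage disequilibrium between two QTL is tested by Fisher's exact test on
the 2×2 cross-classification of hard-assigned allele classes; tables with
an empty margin report p = 1 with a degeneracy flag.

## Epistasis

Two detectors.  (1) *Pairwise*: the vial-level model with both QTL classes
and their product, fitted by ML with random date and RIL retained; the
interaction is judged by a 1-df likelihood-ratio test.  The test is
reported only when all four joint genotype classes hold ≥10 RILs
(configurable); rare-allele QTL are skipped with the reason recorded —
with, say, 18 resistant lines at one locus the joint classes cannot all
reach 10.  (2) *Modifier scan*: at every grid position an OLS model on
BLUPs with the known QTL (as continuous resistant probability, configurable
to a two-level class), the local founder probabilities, and their products
is compared with the same model lacking the products; the interaction LOD
is the log10 likelihood ratio, zero by construction when the products are
linearly dependent on the main effects.  Founder columns with less than 5
expected carriers at a position are pooled before forming products (rank
handles the df).  OLS on BLUPs is heteroscedasticity-naive by design —
faithful to the estimator this pipeline reproduces rather than optimal.
Genomewide interaction significance uses the same permutation machinery,
re-fitting both models per permutation.

## The panel simulator

The simulator emulates the construction of the mapping panel, not any
particular dataset:

- **Intercross.**  A census of `2 * (2 * n_ril)` individuals (configurable
  mating pairs), founded by equal numbers of eight homozygous founder
  lines, random-mates for 50 generations.  Crossovers per arm per meiosis
  are Poisson with mean the arm's genetic length in Morgans, positions
  uniform, genetic↔physical linear within an arm.  The X is treated as an
  autosome for mosaic purposes.
- **Balanced transmission.**  Pairing is random but each pair leaves
  exactly two offspring, and each parent passes *complementary* gametes
  (one crossover realisation, opposite phases) to them.  Every allele copy
  at every locus is transmitted exactly once per generation, so founder
  frequencies are conserved exactly — there is no pedigree or Mendelian
  drift, only randomisation of mosaic structure.  This is the idealised
  limit of equal-contribution laboratory maintenance and is what makes the
  panel's design property (each founder ≈ 12.5% of every genome, on
  average) hold at simulable census sizes; a finite census with multinomial
  family sizes would drift by several percentage points over 50
  generations.
- **Inbreeding.**  Each RIL is founded from one sampled individual and
  inbred by resampling gamete pairs from itself until genomewide
  heterozygosity falls below 1% (typically ~6 rounds), then one haplotype
  is retained.  This fixes a homozygous mosaic about twice as fast as
  sib-pair inbreeding with the same qualitative junction structure, and
  makes the zero-generation limit exact: with no intercrossing every RIL
  is one unbroken founder haplotype.
- **Emission.**  Genotype probabilities are unit vectors on the true
  founder by default; an optional `blur` mixes rows with the uniform
  distribution to emulate residual haplotype-inference uncertainty.
- **Phenotypes.**  Planted QTL assign founder-class effects (plus optional
  interaction terms) from the *true* mosaic; vials then follow the mixed
  model above, with vials batched ~50 per injection day and replicate
  vials of a RIL always on different days.  The sigma assay forms a latent
  vial infection probability on the linear probability scale, clips to
  [0, 1], and draws a binomial infected count over 20 flies — so sigma
  values are proportions in multiples of 1/20, and the binomial stage adds
  variance beyond `s2_resid`.
- **Defaults.**  DCV-like trait scale: `beta = 10` days, `s2_RIL = 3.0`,
  `s2_resid = 0.9` (single-day repeatability ≈ 0.77), `s2_date = 0.5`;
  20 flies per vial, 50 vials per day.  The five-arm genome uses
  release-5-scale physical lengths and a ~2.87-Morgan map.  The intercross
  census is exposed in the config because the real population's census is
  not part of the panel's published description.

**What the synthetic data do not emulate:** genotype-probability
uncertainty patterns of a real haplotype HMM (blur is a crude stand-in),
segregation distortion and residual heterozygosity, X-specific dosage and
recombination, selection during inbreeding, and fly-level death-time
distributions (vials are simulated at the vial mean directly unless
fly-level records are supplied).  Recovery tests therefore certify the
estimators under the assumed generative model, not robustness to these
real-data features.

## Problem sizes used in the recovery suite

Chosen once as desk-scale renderings of the study conditions: founder
balance at the full 600-RIL, five-arm scale; permutation calibration on a
1,000-position, two-arm genome with 150 RILs, 200 permutations and 200
phenotype replicates over four independent panels (thresholds are
genotype-conditional, so redrawing phenotypes on a fixed panel is the
standard conditional-inference framing); major-QTL recovery (5v3 split,
5.2-unit effect, ~78% of between-RIL variance) and modifier recovery
(sign-reversing interaction) on fixed 600-RIL panels with phenotype
redraws; repeatability coverage at 100 RILs × 2 vials for R = 0.77 and
0.74.  Full-scale defaults (2,000 main-scan permutations, 13,000 MCMC
iterations) remain the library defaults.

## Known limitations

- The mixed model is Gaussian throughout; sigma proportions are analysed
  untransformed, so vial-level variance is mildly heteroscedastic near the
  [0, 1] boundary.  This mirrors the estimator being reproduced.
- Effect-size p-values are Wald/normal rather than posterior tail
  probabilities; with hundreds of RILs the difference is negligible, and
  the Bayesian route is reserved for the variance decomposition where the
  posterior-median contrast is the estimand.
- The scan machinery assumes probability rows sum to one (readers
  renormalise within 1e-6 and reject beyond); it does not model
  per-position genotype uncertainty beyond what the probabilities encode.
- No multi-QTL model search: the procedure is single scans plus covariate
  rescans, as in the analysis it implements.
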