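# Methods

`dfemix` infers the distribution of fitness effects (DFE) of spontaneous
mutations from a mutation-accumulation (MA) backcross design: MA lines are
crossed to their unmutated ancestor, producing haploid recombinant lines
(RLs) that each carry a random ~50% subset of the parental mutations.  With
genotypes at every known mutation and a growth-rate phenotype per RL, the
effects of individual mutations become estimable as random effects drawn
from a parametric DFE.

## Data model

For one cross (or a merged set of crosses), the data are a phenotype vector
**y** (n_b observations), a 0/1 mutation matrix **M** (n_b × n_m), a 0/1
two-level fixed-effect matrix **F** (mating type and markers for
introgressed non-focal-background chromosomal regions), a plate index per
observation, and an MA-line index per observation (merged analyses fit one
overall mean per MA line).  The phenotype is modelled as

    y_i = ybar_{line(i)} + g_i + Σ_j F_ij f_j + p_{plate(i)} + ε_i,

with plate effects p ~ Normal(0, V_p), residuals ε ~ Normal(0, V_e), and
g_i the genotypic value — the sum of the effects of the mutations the
observation carries.

Two DFE families are implemented.

**Multicategory (point-mass) model.** Each mutation belongs to one of n_c
categories; category 0 has effect 0, category k ≥ 1 has a free effect e_k
and frequency q_k (q_0 = 1 − Σ q_k).  The likelihood combines the
per-mutation assignment probabilities, the multinomial probability of the
category counts, plate-effect densities, and the per-observation residual
densities.  Both category-probability terms are retained in the default
likelihood; `include_assignment_term=False` switches to the count-only
variant for sensitivity analysis (the two differ in how strongly the
frequency vector is informed by the assignments; posterior modes of q are
unaffected, concentration is).

**Two-sided (reflected) gamma model.** Each mutation has a side indicator
(0 = deleterious, 1 = beneficial) with side frequencies (q_0, q_1) and a
positive magnitude drawn from that side's gamma distribution; the sign is
applied by side.  Each side's gamma is parameterized by its **mean** and
**shape** (the rate is shape/mean); variants tie the means and/or shapes
across sides (`same`/`different`).  The likelihood adds the gamma density
of each active magnitude and the binomial probability of the side counts to
the shared terms.

## Sampler

A Metropolis–Hastings sampler proposes one scalar variable per iteration,
cycling deterministically through the variable blocks (assignments or
sides, effects or magnitudes, frequencies, fixed effects, plate effects,
plate variance, per-line means, residual variance).  Proposals are additive
normal deviates, additive uniform deviates for frequencies, deterministic
flips for discrete labels, and log-scale walks for variances; all are
symmetric, so the Hastings correction is 1 except for the side flip (next
paragraph).  Proposal scales are tuned multiplicatively toward 25%
acceptance during burn-in and frozen afterwards.  Likelihood changes are
computed incrementally from maintained sufficient statistics, with a full
recomputation every 2×10⁶ proposals to eliminate floating-point drift; unit
tests verify the maintained value equals an independent from-scratch
evaluation at the end of every chain.

**Side flips redraw the magnitude.**  A literal flip that re-activates the
mutation's stored magnitude for the other side deadlocks: once the stored
value is incompatible with the data, the flip can never be accepted and the
stored value is never updated (we observed mutations with simulated
|effect| ≈ 0.2–0.3 frozen on the wrong side for entire chains).  The
sampler therefore redraws the newly active magnitude from the destination
side's current gamma distribution at each flip proposal.  Because that
gamma density appears in both the target and the proposal, it cancels in
the acceptance ratio; the stationary distribution is exactly the model
posterior, and side switching becomes ergodic.

**Priors.** Phenotypes are standardized internally to zero mean and unit
SD, making the priors literal: category effects uniform in ±0.5 phenotypic
SD, gamma means uniform in (0, 0.5 SD), gamma shapes uniform in (0.1, 100),
frequencies uniform in (0, 1).  Fixed effects, plate effects and per-line
means take flat improper priors.  Variances take the scale-invariant 1/V
prior, which pairs with the symmetric log-scale walk without a Jacobian
term.  Estimates are rescaled to original phenotype units for reporting;
the stored log likelihood is adjusted to the original data scale so BIC
values are comparable across models.

**Initialization.** Multicategory: all mutations in category 0, effects 0,
equal frequencies.  Gamma: random sides, magnitudes drawn from the initial
gamma (mean 0.05 SD, shape 1), q_0 = 0.5.  Shared: per-line means 0 (the
standardized sample mean), V_e = 1 (the standardized sample variance),
V_p = 0.1.  Magnitudes are floored at 1e-12 to keep log terms finite; with
shapes ≥ 0.1 the truncated mass is negligible.

**Schedules.** The default desk-scale schedule is 10⁶ burn-in and 10⁷
sampling proposals thinned every 10³ (10,000 draws; about 1.5–2 minutes for
40 mutations × 10,000 observations on one CPU).  Published-scale schedules
(10⁸–10⁹ burn-in, ~10⁹–5×10⁹ sampling, thin 10⁴) are plain configuration
values.  Chains are bit-reproducible for a fixed seed and configuration.

## Posterior summaries

Parameter estimates are posterior modes from a Gaussian KDE (Silverman
bandwidth, argmax on a 512-point grid; histogram fallback available);
95% credible intervals use ranked draws with a nearest-rank rule
(lower = ⌊0.025 n⌋+1-th, upper = ⌈0.975 n⌉-th sorted value).  For
multicategory chains, category labels are exchangeable, so summaries
relabel the nonzero categories per draw by ascending effect; the
permutation-null analysis deliberately keeps raw labels, whose mode
distribution is symmetric about zero under the null.  BIC uses
k·log(n) − 2·log(L̂) with L̂ the maximum sampled log likelihood and a
parameter count that includes per-mutation latent variables (the category
assignment; twice the number of mutations for the gamma models); ΔBIC < −10
is reported as strong evidence.  Permutation nulls shuffle phenotypes among
observations within plates without replacement (a with-replacement variant
is available).  Per-mutation effects under the gamma model are posterior
means of the signed effect, accompanied by the raw carrier/non-carrier
growth difference computed within MA line; the bootstrap test of mean
squared effects between annotation classes resamples mutations with
replacement within class, with a two-sided p from sign crossings, doubled
and capped at 1.

## Synthetic data

The generator draws each genotype independently with transmission
probability 0.5 (free recombination — adequate because the inference
conditions on genotypes), effects from either DFE family, optional
two-level fixed effects and plate effects, and Gaussian residuals with
V_e = 1, so effects are in residual-SD units (close to phenotypic-SD units
for small-effect scenarios).  Growth curves for the rate-extraction stage
are logistic, sampled every 12 h over 12–96 h, with multiplicative
log-normal noise.

The four parameter-recovery scenarios (two-, three- and four-category
point masses and a two-sided gamma; 40 mutations × 10,000 observations
each) are the samplers' validation surface.  For these scenarios the
harness assigns category/side counts at their exact expected proportions
(shuffled) rather than drawing them multinomially: with only 40 mutations
the composition noise (SD ≈ 0.06 for a frequency of 0.2) would otherwise
dominate the comparison between posterior modes and the nominal DFE, and
the check is meant to measure sampler fidelity, not multinomial sampling
noise.  The general generator keeps random label drawing.  Note that for
the gamma scenario the realized magnitudes are still 30 + 10 random gamma
draws, so posterior modes track the realized sample (e.g. a realized
negative-side mean of 0.62 for a nominal 0.5); recovery is judged within
2 posterior SDs, which comfortably covers this.

What the synthetic data do not emulate: linkage between mutation sites,
genotyping error, KASP assay dropout structure, plate-edge effects, or
non-Gaussian growth noise.  Passing recovery tests therefore demonstrates
correctness of the inference under its own assumptions, not robustness to
those real-data features.

## Growth rates, QC, and the mixed-model test

**Growth rates.**  Maximum growth rate per well is the largest OLS slope of
ln(absorbance) on time over all contiguous windows of 5–8 readings on the
12-h grid, keeping windows with R² ≥ 0.75 (exclusion is strictly R² <
0.75).  A flat window is defined to have R² = 0 (no growth signal) and so
never qualifies; windows containing nonpositive or missing absorbance are
invalidated individually.  Slope ties break to the earliest start, then the
fewest points.  If no window qualifies the rate is missing, not an error.

**Genotype QC.**  Fixed stage order: drop invariant mutations; drop
mutations perfectly (anti-)concordant with the mating-type or
introgressed-region markers (evaluated on pairwise-complete calls, with
no-evidence mutations retained); set missing calls of listed
single-working-primer mutations to the nonamplified allele; drop lines with
>10% missing or >5% heterozygous calls (strict); recode surviving
heterozygous calls as missing (haploid organism); impute, first from
identical-haplotype lines of the same mating reaction (strict identity at
all co-called sites; conflicting donors leave the cell missing), then from
the genome-order adjacent mutation when r² > 0.7 (strict), never across
chromosomes, using the phase implied by the sign of D; with two qualifying
neighbours the higher-r² one wins, ties going upstream.  r² values are
computed once on the step-2 input so fills do not cascade.  Every stage's
counts reconcile in the QC report.

**Mixed-model test.**  The directional relationship between growth rate and
mutation count is tested by a likelihood-ratio test (1 df) between nested
linear mixed models fitted by ML (not REML — the models differ in a fixed
effect), with mating type and region markers as fixed factors and MA line,
haplotype and plate as variance components (statsmodels MixedLM with a
constant grouping and one variance component per factor; single-level
factors are dropped with a warning, covering within-cross analyses where
the MA-line factor is degenerate).  Optimizer fallbacks (lbfgs → bfgs → cg)
guard against spurious non-convergence; negative statistics beyond the
1e-8 tolerance are clipped to zero with a warning.  Calibration of the
asymptotic chi-square reference was verified on a replicate-rich null
design (60 haplotypes × 4 replicates); with ~2 replicates per haplotype the
variance components are weakly identified and the test becomes
anticonservative — a known finite-sample property of mixed-model LRTs, so
p-values near the threshold deserve caution in sparse designs.

## Validation problem sizes

The test suite runs the three recovery scenarios at the desk schedule
(≈90–110 s each), prior-recovery with 10⁴ thinned draws, a 50-replicate
permutation null at a reduced size (1,000 observations, 10 plates, shorter
chains), 500 null mixed-model datasets for type-I error, and exhaustive
small-instance oracle comparisons for both likelihoods.  These sizes were
chosen so the whole suite completes comfortably on a single CPU while
keeping every check at full statistical strength.

## Known limitations

* The four-category model is generated and fittable, but its label
  switching between the three free classes is not resolved beyond per-draw
  effect sorting; component-wise summaries can remain ambiguous.
* Side-flip acceptance collapses to near zero once the two gamma sides are
  well separated (redraws from the opposite side are data-incompatible);
  assignments are then effectively frozen at their burn-in values.  This is
  a mixing, not a correctness, concern, and only for datasets where side
  membership is unambiguous anyway.
* The LD imputation is deterministic single-neighbour; no genotype
  likelihoods or multi-site haplotype models.
* Convergence diagnostics are limited to acceptance rates and trace export;
  no R-hat gating is applied.
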