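# Methods

## The evaluation model

`ssgwas` implements single-step genomic BLUP (ssGBLUP) for one trait at a
time in a pedigreed population where only a subset of animals is
genotyped, and the windowed-variance genome scan that falls out of it by
backsolving SNP effects.

The direct animal model is

    y = Xb + Vu + Wp + e,
    var(u) = H s2_a,   var(p) = I s2_p,   var(e) = I s2_e,

where `b` collects the systematic effects (sex, dam-age class, optional
slaughterhouse factor and an age-in-days covariate for post-weaning
traits), `u` the additive breeding values of **all** pedigree
individuals, and `p` a random herd-year-season (hys) effect grouping
records by herd and calving quarter. For a weaning-weight-type trait the
maternal model adds the dam's additive maternal effect `m`:

    y = Xb + Zu + Tm + Wp + e,
    var([u; m]) = [[s2_a, s_am], [s_am, s2_m]] (x) H,

with `T` mapping each record to its dam (a record whose dam is unknown
is rejected) and `s_am` the direct-maternal covariance, typically
negative for weaning weight.

`H` blends the pedigree numerator relationship matrix `A` with the
marker-based `G`; only its inverse is ever formed:

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

on the genotyped block. `A^-1` is built sparsely by Henderson's rules
with Mendelian-sampling variances that account for parental inbreeding
(inbreeding by the Meuwissen-Luo recursion); `A22` is the exact
genotyped-by-genotyped block of `A`, obtained indirectly from one sparse
factorization of `A^-1` (one solve per genotyped column) so the full
dense `A` is never formed — pedigrees are routinely 10^5-10^6 animals
while the genotyped set is thousands. `G` is VanRaden's first method,
`G = ZZ' / sum_i 2 p_i (1 - p_i)` with dosages centered at twice the
observed post-QC allele frequency (the only computable base-population
frequency) and missing dosages mean-imputed (null after centering). The
raw `G` is always exactly singular when frequencies are observed in the
same sample (column centering makes the vector of ones a null vector),
so by default it is blended,
`G_b = (1-w) G + w A22` with `w = 0.05`; `w = 0` is supported and is the
configuration in which the algebraic identities below are exact. An
off-by-default option rescales `G` to match `A22`'s mean diagonal and
off-diagonal before blending.

Genotype QC applies, in fixed order: individual call rate >= 0.95, SNP
missingness <= 5%, minor-allele frequency >= 0.01, autosomes only. The
individual call-rate rule is common practice; the defaults are all
exposed in `RunConfig`.

## REML

Variance components are estimated by restricted maximum likelihood: an
EM warm-up (default 100 rounds in the run configuration, mirroring
common practice with AI-REML software; the validation runs use 2-3
because AI converges in about ten iterations at these problem sizes)
followed by average-information (AI) updates with step-halving whenever
a step leaves the parameter space, and an EM fallback step when the AI
matrix is not invertible. Components are floored at 1e-8 of the
phenotypic variance; convergence is declared when the largest relative
parameter change drops below `ai_tol`. Standard errors come from the
inverse AI matrix at convergence.

The implementation writes the mixed-model equations in unscaled form,
`C = W'R^-1 W + blockdiag(0, K0^-1 (x) K^-1)` per random term, so `C^-1`
is directly the prediction-error covariance. Every trace the EM and AI
updates need then reduces to `tr(K^-1 C^{ab})` over the inverse blocks
of each term; these are computed **exactly** by a dense Cholesky
inversion of `C` each round. That is a deliberate desk-scale choice: at
the few-thousand-equation sizes this package targets it is exact and
takes a few seconds, where large national evaluations would need
selected inversion or sampling. The REML log-likelihood (used for the
monotonicity checks and reported with fits) is evaluated from the same
factorization via `log|C|`, sparse log-determinants of `H^-1`, and
`y'Py`.

Derived parameters: `h2 = s2_a / (s2_a [+ s2_m] + s2_p + s2_e)`,
`h2_mat` analogous, `r_a,mat = s_am / sqrt(s2_a s2_m)`. The phenotypic
denominator deliberately **excludes** the direct-maternal covariance;
with the covariance included, published weaning-weight component tables
do not reproduce their own printed heritabilities (0.483 vs 0.400 on the
worked example in the tests), while excluding it reproduces all printed
values.

## From GEBVs to windows

For the genotyped animals, GEBVs are a linear transform of marker
effects, so the effects are recovered by backsolving

    g_hat = Z' G^-1 u_hat / sum_i 2 p_i (1 - p_i),

which equals the projection `Z'(ZZ')^-1 u_hat` exactly when `G` is the
unblended marker matrix (this identity is a test; it requires a
full-rank `G`, hence centering at external/base-population frequencies —
with blending the backsolve uses the blended `G^-1` that actually
entered `H`). Each
SNP's variance contribution is `2 p_i (1 - p_i) g_hat_i^2`; windows are
fixed, non-overlapping 1-Mb bins indexed `floor((bp-1)/10^6)` per
chromosome, and a window's statistic is its summed contribution as a
percent of the genome-wide sum (so percentages add to 100 by
construction). An alternative statistic — the variance across genotyped
animals of the window's summed marker breeding values — is available as
`window_stat="bv_variance"`. Windows at or above the reporting threshold
(default 0.5%, compared on raw unrounded values) are merged into regions
when consecutive; the cross-trait table pools significant windows over
traits, merges the pooled set, and marks each trait where one of its own
significant windows falls inside, flagging regions marked by two or more
traits as pleiotropic. Coordinates are 1-based inclusive internally and
in the TSV reports (matching PLINK .map conventions); the BED export is
the single 0-based half-open conversion point.

SNP-effect p-values are deliberately not computed; the windowed share of
additive variance is the association measure.

## The synthetic-data generator

The generator provides ground truth for every stage. It builds a
discrete-generation random-mating pedigree (founders plus `g`
generations, sires and dams drawn from the previous generation, most
recent generations genotyped), gene-drops biallelic SNPs through it
(founder frequencies uniform on [0.05, 0.5]; one allele per parent,
independent per SNP), and generates phenotypes from exactly the effect
structure the models fit. Genetic effects are marker-determined: a dense
polygenic background of small normal effects on every SNP plus planted
QTL *windows*, each spreading its variance share evenly over the
segregating SNPs of one 1-Mb window. Marker-determined effects make the
marker-based `G` the correct covariance among genotyped animals — with
a marker-independent polygenic term, ssGBLUP fits show a genuine
downward bias in `s2_a` that is a property of the mismatch, not of the
estimator. For the maternal model, per-SNP effects are drawn bivariate
so the direct and maternal values have the configured covariance. The
realized (co)variances are rescaled to hit the configured components
exactly across non-founders.

What the generator does **not** emulate: linkage disequilibrium beyond
cosegregation (SNPs are transmitted independently), selection or
assortative mating, genotyping error, and multi-breed structure. Passing
tests therefore demonstrate the machinery's correctness and calibration
under the model's own assumptions, not performance on LD-rich real chip
data, where windows capture QTL through many linked markers.

Default magnitudes echo a weaning-weight-like beef trait (mean 285,
additive variance 900, hys 400, residual 950, maternal 300 with
correlation -0.7 where enabled). The default genome is 10 autosomes of
100 Mb (cattle-like autosome lengths).

## Validation regimes and problem sizes

The replicated validation runs (tests and `scripts/acceptance.py`) use:

- direct model: 240 founders + 4 x 500 offspring (2,000 records), the
  last two generations (1,000 animals) genotyped for 3,000 SNPs, true
  h2 = 0.4, one QTL window at 5% of the additive variance; 5 replicates.
- maternal model: 200 founders + 4 x 400 offspring (1,600 records), the
  last generation genotyped for 1,000 SNPs, r_a,mat = -0.7, no QTL;
  5 replicates.

These sizes keep a full replicate (simulation, relationship matrices,
REML with exact dense traces, backsolving, window scan) at roughly 10-20
seconds, so the whole validation battery runs in minutes on one CPU.

A known calibration limit, documented deliberately: with 1,000 genotyped
animals and 3,000 unlinked markers, the backsolving projection has rank
1,000 < 3,000 and GEBV accuracy is ~0.78, so the *estimated* share of a
QTL window planted at 5% of `s2_a` is pulled toward the noise floor —
its sampling distribution has median near 0.9% but substantial mass
below the 0.5% reporting threshold. The detection-power check in the
test suite asserts a 90% detection rate and fails honestly at this data
size (~70-80% measured); detection rates and window shares are reported
as computed. On LD-rich data at real-study sizes the same machinery
concentrates far more variance in causal windows.

## Numerical choices

- Fixed-effect identifiability by reference-level dropping (first factor
  keeps all levels and absorbs the intercept; later factors drop their
  first level). AI-REML software often uses a generalized inverse
  instead; contrasts, not raw levels, are comparable across the two.
- Covariates centered at the sample mean (conditioning only; breeding
  values unchanged).
- Minor allele defined from post-QC sample frequencies; ties at 0.5
  broken by lexicographic allele order, for determinism.
- MME solving: sparse LU is the default and the oracle; Jacobi-
  preconditioned CG is available for larger systems (residual tolerances
  1e-10 / 1e-8).
- Missing-parent sentinel is 0 after renumbering; pedigree renumbering
  is a Kahn topological sort, and cycles are reported with an individual
  on the cycle.

## Known limitations

Unknown-parent groups / metafounders are not implemented (a limitation
for real evaluations with incomplete pedigrees). Single trait only —
the natural extension to multi-trait evaluation with per-trait marker
weighting is out of scope. No APY or other large-scale `G` inverse, and
no iterative SNP reweighting.
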