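# Methods

## Scientific setting

Feed conversion ratio (FCR, g dry-matter feed per g gain) cannot be
recorded per fish when families are communally fed, so family-tank
designs record it per tank while growth and tissue composition are
recorded per fish.  Feeding a diet enriched in the heavy stable isotopes
¹⁵N and ¹³C for a fixed window turns each fish's tissues into a record
of its own metabolism: the atom percent excess (APE) of a tissue over
its pre-experiment baseline is proportional to the fraction of that
tissue's nutrients deposited during the window.  Scaled to final weight
and expressed per gram of gain this yields individual indicator ratios

    IFCR = FW · APE / (FW − IW),      IFER = 1 / IFCR,

which proxy individual feed conversion and feed efficiency.  The
package implements the full analysis chain around these traits:
phenotype derivation, genomic relationship matrices, restricted
maximum-likelihood (REML) variance components, and a predictive
tank-level regression — plus a synthetic-data generator that emulates
the family-tank experiment so every stage can be validated by parameter
recovery.

## Phenotype derivation (`isofeed.isotopes`)

Isotope-ratio mass spectrometry reports per-mil delta values against
international standards (air for N, R = 0.003676; VPDB for C,
R = 0.0112372).  Conversion to atom percent uses

    atom% = (δ + 1000) / (δ + 1000 + 1000/R) · 100,

which is strictly monotone and inverted exactly for round-trip checks.
In this formula the divisor term is the standard's isotope *ratio* R,
not a per-mil value, although the conventional notation writes it with
the same symbol as delta.  APE subtracts the baseline IA% (defaults
0.370% for ¹⁵N and 1.087% for ¹³C in all tissues; a per-tissue override
exists because measured baselines differ slightly, e.g. 1.082% for
adipose ¹³C, but the indicator-ratio convention uses the single carbon
value).

Growth traits are WG = FW − IW and RG = WG/FW·100.  Records are set
missing when a weight is absent, when RG < 6.4% (abnormal development)
or when RG > 49% (growth unmatched by the isotope profile, i.e. a
phenotyping error); both thresholds are strict inequalities and the
filter is idempotent.  A separate absolute-gain threshold (≈1.3 g) is
redundant with the RG rule at these weights and is not applied.  Fish
excluded by the filters are also excluded from the tank gain sum used
for FCR = FI/ΣWG; a switch (`include_filtered_in_fcr`) restores them
for sensitivity analysis.  APE slightly below zero (within 3 baseline
SDs) is retained with a warning flag as measurement noise; below that
it flags the record invalid.

Tank dry-matter intake supports the waste-collection arithmetic
FI = (fed − waste/(1 − leaching)) · DM-fraction, with the leaching
correction exposed as an input because collection protocols
parameterize it differently.

## Relationship matrices (`isofeed.grm`)

The individual matrix is VanRaden method 1: Z = M − 2P columnwise,
G = ZZ′ / (2·Σⱼ pⱼ(1−pⱼ)).  Missing dosages are mean-imputed to 2pⱼ
(zero deviation).  Allele frequencies default to the observed full
sample; the simulator additionally records its true base frequencies,
on which the expected full-sib relationship is 0.5 and between-family
relationship 0.  (With sample frequencies every row of G sums to zero
exactly, so between-family values are necessarily negative — the
validation checks therefore use base frequencies.)

The tank-level matrix averages deviations over each tank's members,
T_tj = (1/n_t)·Σᵢ (M_ij − 2pⱼ), G_T = TT′, then rescales by a single
scalar so that mean(diag(G_T)) = 1.0 exactly; the scalar is kept as
metadata.  Only G_T is rescaled; G keeps its VanRaden denominator.
Replicate tanks of one full-sib family share the family mean genotype,
so their rows of G_T are nearly identical — this near-duplication is
what identifies tank-level genetic variance separately from the tank
residual.  QC (MAF and call-rate thresholds) is applied before either
matrix is formed.

## Mixed models (`isofeed.reml`)

Two bivariate Gaussian model families:

* **Tank level** — y per tank, fixed trait-specific intercept plus
  sampling day (linear covariate 1–5 by default; a factor switch
  exists), random genetic tank effect ~ N(0, T₀ ⊗ G_T) and tank
  residual ~ N(0, R ⊗ I) with R *diagonal* across traits.  The ratio
  h_t² = σ²_a/(σ²_a+σ²_e) is the fraction of between-tank variance
  explained by genetics.
* **Individual level** — additive genomic effect ~ N(0, G₀ ⊗ G), common
  tank environment ~ N(0, T ⊗ I), residual full 2×2, giving
  h² = σ²_a/(σ²_a+σ²_t+σ²_e) and c² = σ²_t/(same).

The day covariate applies to both traits of a pair.  The restricted
log-likelihood is evaluated densely: V = Σₖ Cₖ ⊗ ZₖKₖZₖ′, Cholesky
factorization, with the log|X′X| correction so the value is invariant
to full-rank reparameterizations of the fixed design.  Variances are
parameterized on the log scale and cross-trait correlations through
atanh, so the search space is unconstrained while every candidate
covariance matrix stays positive definite; boundary contact is declared
at |r| > 1−10⁻⁶ (reported as ±1.0 with a flag) or variance below
10⁻⁸ of the phenotypic variance.  Maximization is Nelder–Mead from two
admissible starts (even and 80/20 variance splits), taking the better
optimum; convergence tolerances are 10⁻⁹ on the objective and 10⁻⁶ on
parameters, both configurable.  A 10⁻⁸ ridge guards numerically
semi-definite relationship matrices and is recorded in the fit message.
Standard errors come from the finite-difference observed information in
the component parameterization and are omitted with a warning when the
information matrix is indefinite (routine at boundaries); ratio and
correlation SEs use the delta method.

Significance of the genetic term uses LR = 2(logL₁ − logL₀) against
χ²(1), with negative values from numerical noise clamped to zero.  The
genetic effect is declared significant when LR *exceeds* the critical
value.  Because the null places the variance on the boundary, the χ²(1)
reference is conservative (the asymptotic null is a 50:50 mixture of a
point mass at zero and χ²(1)); the plain χ²(1) convention is kept for
comparability with standard practice in this literature.

Validated against independent estimators: a dense grid search over the
profiled variance ratio agrees to 10⁻³ on ≤30-record instances, and
with an identity relationship on balanced groups the REML ratio equals
the one-way ANOVA intraclass estimator.

## Tank regression (`isofeed.regression`)

OLS of tank FCR on sampling day plus candidate tank-mean covariates
(FI, mean RG/WG, mean atom% per tissue), through statsmodels.  Leave-
one-out prediction uses the exact hat-matrix identity e₍t₎ = e_t/(1−h_tt);
PRESS = Σe₍t₎², R̂² = 1 − PRESS/SS_tot, bias = mean leave-one-out
prediction error (the in-sample mean residual, identically zero with an
intercept, is also reported).  Backward elimination removes, at each
step, the covariate whose removal most reduces PRESS, never touching
day, stopping when no removal helps; ties go to the first-listed
column, so the procedure is deterministic in column order.  Covariates
enter on their raw scale (no standardization).  Pairwise interaction
products are available behind a flag, off by default.  A per-covariate
report of p-values accompanies the scan for reference, but the stopping
rule is pure PRESS minimization.

## Synthetic data (`isofeed.simulate`)

The generator emulates the family-tank design: 23 full-sib families ×
2 tanks × 50 fish and 51,543 SNPs by default, a 12-day enriched window
(diet 2.7 atom% ¹⁵N, 2.0 atom% ¹³C), tanks assigned to sampling days
1–5 round-robin with small additive day effects on growth.

Five latent additive traits per fish: growth potential (g), tissue
turnover rate for muscle/liver/adipose (fraction of tissue exchanged
over the window), and an intake deviation (g).  Founder genotypes are
drawn in Hardy–Weinberg proportions at frequencies uniform on the MAF
range, offspring by Mendelian transmission at unlinked loci.  Breeding
values are per-SNP effects with cross-trait correlations from the
configured genetic covariance; after forming u = Z_c·B each latent's
realized sample variance is rescaled to its target exactly, so
GRM-based REML estimates an unbiased target by construction
(correlations are matched in expectation only).

Growth is linear over the window (endpoints are all that is analysed):
WG = mean gain + day effect + breeding value + tank effect + residual.
Initial weight is drawn correlated with gain (Gaussian copula,
r = 0.8): bigger fish grow more, which keeps relative gain inside the
physiological range so the growth filters fire at error-like rates
(≈0.5–1% of fish) rather than flagging genuinely fast-growing small
fish.  The copula leaves the WG distribution — and hence the configured
heritability — untouched.

Isotope kinetics are single-compartment endpoint mixing: the new-
nutrient fraction f = clamp((WG + turnover·FW)/FW, 0, 1−10⁻⁶), and the
recorded atom% is IA + f·(diet − IA) plus measurement noise truncated
at ±3σ, finally clipped strictly below the diet level — so simulated
values always lie between baseline minus 3σ and diet enrichment, and
equilibrium is never reached.  A configuration whose deterministic mean
implies f ≥ 1 is rejected outright (the experiment's validity requires
staying away from isotopic equilibrium); the clamp only absorbs
stochastic tails.

Individual intake is gain cost + size-proportional turnover cost +
genetic intake deviation:

    FI_i = 0.45·WG_i + 0.53·turnover_i·FW_i + dev_i,

observable only as the tank sum (exact conservation; optional
tank-level recording noise, off by default).  The default coefficients
were chosen so that simulated tank FCR means ≈0.69 with CV ≈2–4% and is
predominantly growth-driven — fast-growing tanks dilute the
size-proportional cost over more gain — reproducing the strongly
favourable FCR–growth relationship of real family-tank data
(tank correlation of FCR with mean RG ≈ −0.5 under the defaults).

The within-tank decomposition of individual feed intake is an
assumption, not an inference about real fish: only tank totals are ever
observable, so any individual split consistent with the totals would
fit the data.  Recovery tests exercise what the real analysis can see.

### What the generator does not emulate

* Growth curves, feeding bouts, leaching dynamics, mortality, water
  quality; only endpoint weights and intake totals matter downstream.
* Adipose carbon turns over more slowly than new-tissue deposition in
  real fish (measured adipose atom% sits well below the muscle value);
  the shared single-compartment formula bounds every tissue's new
  fraction below by RG/100, so simulated adipose enrichment runs higher
  than observed.  Relative orderings across tissues are preserved.
* Isotope atom% variances are growth-dominated, so the simulated
  heritabilities of atom% traits track the growth heritability more
  closely than the lower tissue-specific values seen in real data.
* Linkage: loci are unlinked, so relationship estimates have less
  sampling variance than equal-sized real SNP panels.

Passing recovery tests therefore demonstrates the estimators are
correct for the stated generative model at the stated sizes — not that
real data meet those assumptions.

## Problem sizes

Validation studies run at a deliberately desk-scale design chosen as
the package's standard validation condition: 8 families × 2 tanks × 25
fish and 1,000 SNPs, 50 replicates for parameter recovery (tank-level
genetic correlation −0.8; heritabilities 0.1/0.3/0.5), 10 replicates
for the |r_g| = 1 boundary demonstration; REML-vs-grid agreement on
24-record instances; PRESS identity on 100 random datasets of 15–45
tanks.  The analysis drivers under `analysis/` use 10 families × 2
tanks × 20 fish with 2,000 SNPs.

## Known limitations

* The tank-level phenotypic FCR–growth correlation under default
  settings (≈−0.5) is weaker than reported from real experiments
  (≈−0.8); with only tank totals observable the generator cannot be
  pinned tighter without asserting unobservable individual structure.
* Nelder–Mead is derivative-free and robust near boundaries but slower
  than average-information REML; fits at a few hundred individuals take
  seconds.  The optimization contract (tolerances, two starts) is in
  `reml_fit` and any maximizer honouring it could be substituted.
* Standard errors are unavailable exactly where estimates hit the
  parameter-space boundary, which is also where they would be least
  interpretable; boundary flags are reported instead.
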