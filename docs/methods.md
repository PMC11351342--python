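# Methods

`mrmediate` implements a complete two-sample Mendelian-randomization (MR)
workflow on GWAS summary statistics — instrument selection, a suite of
causal-effect estimators, sensitivity diagnostics, and a two-step
product-of-coefficients mediation layer — together with a synthetic-data
generator that produces whole studies with known causal structure, so
every stage can be validated against ground truth.

## Model and assumptions

MR treats genetic variants as instrumental variables for an exposure X.
A variant j with exposure association β̂Xj (SE σXj) and outcome
association β̂Yj (SE σYj) provides a ratio estimate β̂Yj/β̂Xj of the causal
effect, valid under the three instrument conditions: association with X,
independence from confounders, and no pathway to the outcome other than
through X (exclusion restriction).  Binary outcomes are analysed on the
log-odds scale throughout; odds ratios are exp-transformed at reporting
time only.

### Instrument selection

1. genome-wide significance on the exposure, p < 5×10⁻⁸ (strict `<`);
2. LD clumping: greedy in ascending p (position, then SNP-id tie-break),
   accepting a SNP only if every accepted SNP on the same chromosome
   within 10,000 kb has pairwise r² < 0.001;
3. exclusion of instruments associated with the outcome at p < 5×10⁻⁸;
4. exclusion of instruments linked to listed confounder traits through an
   offline lookup table (case-insensitive substring matching), a local
   stand-in for web-catalogue queries;
5. strength filter: per-SNP F = R²(N−K−1)/(K(1−R²)) with K = 1 and
   R² = t²/(t²+n−2) from the per-SNP t-statistic (the standard
   summary-data approximation; callers may supply their own `r2_snp`);
   instruments with F > 10 are retained.

### Estimators

* **Wald ratio** (single instrument): βY/βX with first-order SE σY/|βX|;
  a second-order delta-method SE is available by flag.
* **IVW**: weighted regression of βY on βX through the origin with
  weights 1/σY². The fixed-effect SE is (Σ βX²/σY²)^(−1/2); the
  multiplicative random-effects SE inflates it by max(1, √(Q/(n−1))).
  The pipeline reports random-effects IVW when the Cochran-Q p-value is
  below α (policy `auto_by_q`; `fixed`/`random` force either).
* **MR-Egger**: same weighted regression with a free intercept after
  orienting all βX ≥ 0; the intercept estimates average directional
  pleiotropy. SEs carry the same multiplicative inflation, floored at 1;
  inference uses t with n−2 df.
* **Weighted median**: ratio estimates ordered, the estimate interpolated
  at standardized cumulative weight 0.5; consistent when instruments
  carrying more than half the weight are valid. SE by seeded parametric
  bootstrap (default 1000 draws of both βX and βY from their sampling
  distributions).
* **Simple / weighted mode**: Gaussian-kernel density mode of the ratio
  estimates, bandwidth 0.9·min(sd, mad)·n^(−1/5) scaled by a
  `bandwidth_factor` (default 1), evaluated on a 2048-point grid;
  the weighted variant weights kernels by inverse ratio variance.
  The bandwidth acts on the ratio estimates themselves — a bandwidth
  derived from the ratio SEs would not track the spread of the density
  being maximized. A zero-spread (point-mass) input falls back to the
  weighted median of the ratios.

p-values are two-sided normal except MR-Egger (t, n−2 df).

### Sensitivity diagnostics

Cochran's Q about the fixed-effect IVW fit (χ², n−1 df) — the fixed fit
is used regardless of the reporting model, the standard definition;
the MR-Egger intercept test for directional pleiotropy; leave-one-out
IVW with flags for SNPs whose removal flips the α-level verdict; and the
Steiger directionality test: per-SNP r² = t²/(t²+n−2) summed on each
side, aggregate correlations compared via Fisher's z with SE
√(1/(nX−3)+1/(nY−3)). Verdicts: `true` (exposure side explains more,
p < 0.05), `false` (reversed, p < 0.05), `uncertain` otherwise. For
binary traits this r² is an observed-scale approximation, recorded in
the result so liability-scale values can be substituted. Funnel and
scatter outputs are plot-ready tables; no figures are rendered.

### Two-step mediation

Step 1 (exposure → mediator) passes when IVW p < α AND 2SLS p < α (the
dual criterion; 2SLS runs on individual-level data when available —
always the case for synthetic studies — and is waived with a log note
otherwise) AND the Egger-intercept p ≥ α. Step 2 (mediator → outcome,
the mediator's own instruments) passes when the Wald/IVW p < α AND the
Q-test p ≥ α AND the Steiger verdict is `true`. For survivors the
indirect effect is b1·b2 with Sobel SE S = √(b1²s2² + b2²s1²),
Z = b1·b2/S, and a symmetric 95% CI b1·b2 ± 1.96·S; a mediator passes
finally when Sobel p < α. The proportion mediated b1·b2/total is
reported unconstrained (it may exceed 1 or be negative when signs
oppose). An additive compatibility form of S (b1·s2 + b2·s1) exists
behind an explicit flag for comparison with legacy reports; it is not a
valid standard error (it does not transform correctly under rescaling)
and is never the default.

Two pipeline-level choices deserve emphasis, both adopted because the
alternatives are self-defeating in a mediation design:

* the outcome-association exclusion in step 1 screens the exposure's
  instruments against the **disease outcome**, not against the mediator:
  a strongly caused mediator is genome-wide associated with the very
  instruments that carry the signal, and excluding them both deletes the
  effect under test and induces a selection artifact in the Egger
  intercept;
* step-2 instrument selection removes SNPs that are genome-wide
  instruments of the **exposure**: such SNPs reach the outcome through
  every other mediator, so keeping them contaminates step 2 with
  spurious heterogeneity. Step 2 therefore runs on the mediator's own
  instruments.

Mediators are processed with failure isolation: an error in one mediator
marks it failed and the scan continues. Multiple testing is nominal
p < α across mediators by default, mirroring common screening practice;
a Benjamini–Hochberg mode (`multiple_testing="bh"`, applied across the
Sobel p-values of screen survivors) is available as a clearly-labelled
extension.

## Synthetic studies

The generator simulates one population and assigns three disjoint
sub-cohorts to the exposure, mediator and outcome GWAS roles (an
`overlap_frac` knob exists for robustness experiments). Genotypes are
Binomial(2, MAF) dosages, MAF uniform on (0.1, 0.5); optional LD blocks
are produced by thresholding equicorrelated latent Gaussians per
haplotype, with the latent correlation calibrated numerically
(bivariate-normal orthant probabilities, bisection) so the dosage r²
hits the requested value to about ±0.05. Allele pairs are drawn from the
non-palindromic set, since simulated studies share a strand.

The structural model is

    X   = Σ aj Gj + εx                      (instrument block)
    Mk  = θ1k X + Σ bkj Gkj + Σ γkj Gj + εm (own SNPs; pleiotropy)
    L   = δ X + Σ θ2k Mk + Σ gy,kj Gkj      (liability)
    Y   = threshold(L) at the target prevalence

Effect magnitudes are uniform on (0.5, 1.5) before exact variance
scaling, and positive (effect-allele coding is arbitrary, so orienting
effects trait-increasing loses no generality while making directional
pleiotropy meaningful). All phenotypic variances are 1, so `exposure_h2`
and `own_h2` are variance fractions. Infeasible combinations (negative
residual variance) are fatal with an explanation. One integer seed
drives everything through spawned child generators; identical seeds give
bit-identical cohorts.

The binary outcome thresholds a liability with a **logistic** residual —
exactly a logistic link — so the per-SNP logistic GWAS estimates sit on
the same log-odds scale as θ2, up to the small noncollapsibility
attenuation of marginalizing the other liability components (measured by
the test suite at roughly 2% under the default presets; a probit
liability is available by option). Default prevalence is 0.05 with a
case-cohort of 20,000, giving per-SNP outcome SEs of realistic
magnitude. Per-SNP GWAS scans are vectorized: closed-form simple OLS for
continuous traits and a simultaneous 2×2 Newton–Raphson logistic solver
across SNPs for binary traits (validated against statsmodels `Logit` in
the unit suite). 2SLS is the textbook two-stage estimator with the
residual variance taken about the *actual* exposure (the proper 2SLS
variance); stage-1 multiple R² is reported as instrument relevance.

Defaults — n = 20,000 per cohort, 50 instruments, exposure h² = 0.2 —
give per-instrument F statistics spanning roughly 20–200, comfortably
above the F > 10 rule, resembling the strongly-instrumented exposures
(e.g. telomere length) this design targets. Scenario presets:

| preset | θ1 | θ2 | δ | other |
|---|---|---|---|---|
| `null` | 0 | 0 | 0 | |
| `mediated` | 0.4 | 0.5 | 0 | indirect 0.2 |
| `direct_only` | 0 | 0 | 0.3 | |
| `pleiotropic` | 0.4 | 0.5 | 0 | directional γ = 0.04 on 30% of instruments |
| `heterogeneous` | 0.4 | 0.5 | 0 | own-SNP liability effects sd 0.15 |
| `reverse` | 0.5 (M→X) | 0 | 0 | instruments act on the mediator |

The packaged 10-mediator screening fixture (fixed internal seed, part of
its definition) wires three genuine mediators, two pure-pleiotropy traits
(constant direct effect of every exposure instrument, θ1 = 0 — the Egger
intercept estimand is then exactly the per-SNP direct effect), two
mediators with heterogeneous step-2 instruments, and three nulls; the
two-step screen recovers exactly the three genuine mediators.

### What the generator does not emulate

Realistic allele-frequency spectra and genome maps, population
stratification and other confounding, sample relatedness, assortative
mating, and sex-specific effects are all absent; LD is block-equicorrelated
rather than map-based. Passing tests therefore demonstrate the internal
correctness and calibration of the statistical machinery under the stated
generative model, not robustness to the full messiness of real GWAS.

## Numerical choices

* Harmonization: palindromic (A/T, C/G) SNPs are dropped by default; the
  `infer_by_eaf` policy orients them by allele frequency only when both
  sides lie outside [0.42, 0.58] (window 0.08, the common two-sample
  convention); palindromic SNPs with missing frequency are always
  dropped. Validation warns, rather than rejects, when a reported
  p-value disagrees with |beta/se| by more than two-fold — public GWAS
  rounding breaks exact agreement.
* Degenerate inputs are errors, not silent results: single-record Egger
  or median, zero exposure betas, rank-deficient 2SLS designs,
  infeasible variance budgets. Monomorphic SNPs get flagged placeholder
  records (eaf 0/1, beta 0, uninformative SE).
* Greedy clumping breaks p-value ties by position, then SNP id, so
  results are reproducible across platforms.
* Report tables are written with `%.12g` formatting; fixed-seed reruns
  are byte-identical.

## Benchmark sizes

The operating-characteristic benchmarks in `mrmediate.evaluation` use
1000 replicates for null calibration and 200 for recovery, robustness
and concordance (100 per arm for directionality), at the default cohort
sizes above; these sizes make the Monte-Carlo error small relative to
each acceptance band while keeping a full run in the minutes range on a
single core.

## Known limitations

Per-SNP R² from t-statistics is an approximation (exact only for
standardized traits); binary-trait Steiger r² is observed-scale; the
weighted-median and mode SEs are bootstrap-based and hence seeded;
MR-PRESSO-style outlier correction, multivariable MR, and bootstrap
mediation CIs are out of scope.
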