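# Methods

This note documents the statistical procedures implemented in
`overyield`, the assumptions behind them, the design of the synthetic
generator, and the numerical and calibration choices that were genuinely
open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Additive partitioning

The partition operates per plot on the *S* sown species with expected
relative yields equal to the sown proportions (1/*S* under equal-density
sowing; the field is explicit so unequal designs are representable).
Monoculture yields *Mᵢ* are arithmetic means over all monoculture plots
of a species, across blocks, so that the reference integrates over
block-to-block soil differences.  Conventions:

* **Species sown but absent at harvest** keep *Yᵢ* = 0 and stay in the
  partition (ΔRYᵢ = −RYₑ,ᵢ).  Dropping them would bias NE upward and
  break the sown-composition bookkeeping.
* **Monocultures** are reported with NE = CE = SE = 0 and excluded from
  the greater-than-zero tests; a biodiversity effect is undefined
  without a mixture.
* **Species extinct pool-wide** are flagged inactive and removed from
  all computations (`drop_inactive`), with sown proportions renormalized
  over the surviving species.  The *declared* sown richness of the
  original design (1/2/6/9) remains the model covariate; renormalization
  only affects expected relative yields.
* A plot in which every sown species died returns an all-negative
  partition (NE = −Σ pᵢMᵢ), not an error.
* The signed square-root transform is sign(y)·√|y|: odd, monotone, and
  variance-stabilizing for effects that take either sign.

The grand-mean test fits an OLS ANOVA of the transformed effect on
block + log₂(sown richness) + mixture identity over mixture plots and
tests F = n·ȳ²/MS_resid on (1, residual df).  The residual stratum
after mixture identity is the error term; with duplicated mixture
identities this is the replicate-to-replicate stratum.  The alternative
— a mixture-identity error stratum — is not implemented; the choice is
recorded in the report metadata (`error_stratum` column).

**Limitation (shared reference).**  All plots divide by the same
estimated *M̂ᵢ*.  The ratio estimator inflates E[1/M̂] by roughly
CV²/n_mono, and the shared denominator correlates errors across plots,
so with few monoculture replicates the residual-based grand-mean test is
anticonservative in absolute terms.  This is a property of the ratio
pipeline, not of the test; the calibration study below therefore uses
the true monoculture means (§5).

## 2. CWM decomposition and variance attribution

CWM weights are realized biomass proportions among species present at
harvest (absent species carry weight 0, since pᵢ is defined from
biomass).  Species pool means are unweighted across the plots where a
species was measured.  A present species without a trait value raises an
error by default; an explicit `missing="renormalize"` policy reweights
over the measured species and warns.  Community-level root traits (RLD,
SRL) have no species-level values and bypass the decomposition.

The attribution fits three sequential ANOVAs (order: block → richness →
mixture identity) to the specific, fixed, and adjustment components and
extracts the Type-I richness SS from each.  Because richness precedes
mixture identity, its Type-I SS is unaffected by the identity term.
All three shares are normalized by the **total SS of the specific CWM**
— not each response's own total — so they are commensurable and the
covariation share defined by
specific% − fixed% − adjust% closes an exact identity (it is negative
when composition and adjustment trend oppositely).  Richness enters as
log₂(sown richness) by default, consistent with the log-scale richness
covariate of the mixed models; a categorical coding is exposed.
Sequential sums of squares are computed by incremental least squares,
which remains well-defined under the deliberate aliasing of richness
within mixture identity; a richness term fully aliased with earlier
terms raises a design error naming the term.

## 3. Two-order mixed-model comparison

Responses are modeled with two crossed random intercepts (block, mixture
identity) fitted by maximum likelihood; each fixed term added to the
sequence is assessed by a 1-df likelihood-ratio test.  Identity
predictors are 0/1 sown-presence indicators, one focal species at a
time.  Transforms follow the conventions above: signed √ for NE/CE/SE,
plain √ for community biomass, RLD, and SRL.  Verdicts at α = 0.05 with
a marginal band at 0.10 (both configurable):

* identity significant ⇔ p < α in **both** orders;
* richness neutralized ⇔ p(model 1) < 0.10 and p(model 2) ≥ α.

If every mixture identity has a single plot the mixture random factor is
confounded with the residual and is dropped with a warning.  REML,
small-sample df corrections, richness × identity interactions, and
multiple-testing corrections across the response × species grid are
deliberately out of scope.

The fitter profiles the fixed effects and the residual variance out of
the marginal likelihood analytically and optimizes the remaining one or
two log variance ratios by Nelder–Mead with an explicit OLS boundary
check (γ → 0).  A single fit on an 85-plot design takes ~10 ms, which
makes the 1000-replicate calibration studies feasible; the test suite
cross-checks the maximized log-likelihoods against statsmodels MixedLM
(ML, variance components) and a variance-ratio grid.  Likelihood-ratio
statistics are clipped at zero.

## 4. The synthetic generator

The generator reproduces the statistical structure the analysis modules
assume, with these default study conditions:

* **Pool and design.**  Nine species (five grasses, two forbs, two
  legumes); one tall grass (`Arr.ela`, monoculture mean 350 g m⁻²) is
  dominant; a grass (`Phl.pra`) and a forb (`Ant.syl`) are extinct
  (inactive), leaving seven analyzable species.  85 plots: 7
  monocultures, 46 two-species plots (all 21 active pairs twice + 4
  single-replicate pairs with an extinct partner), 24 six-species plots
  (12 balanced compositions twice; every species appears in exactly 16),
  8 nine-species plots (full pool).  Four blocks, sizes 21–22;
  replicates of an identity land in distinct blocks.
* **Biomass.**  Mixture yield per active sown species:
  Yᵢ = pᵢ·μᵢ·(1 + ce·log₂S + se·1[dominant])·b(block)·ε with mean-one
  lognormal noise (CV 0.2), mean-one lognormal block factors (log-SD
  0.1), monoculture CV 0.2; defaults ce = 0.25, se = 0.5.  Proportions
  are 1/S over the *active* sown species: after 15 seasons survivors
  occupy the ground left by extinct neighbours, which keeps expected
  relative yields internally consistent with the analysis convention.
  A uniform proportional gain yields pure complementarity (all ΔRY
  equal ⇒ SE = 0 exactly); the dominance boost yields a mix of selection
  and complementarity.  Ground-truth NE/CE/SE are obtained by passing
  the noise-free yields through the partitioning code itself against the
  true μᵢ.
* **Traits.**  Species trait means follow the observed ranges for
  mesophilic grassland dominants (heights 12–46 cm, SLA 17–30 mm² mg⁻¹,
  leaf N 16–41 mg g⁻¹, AMF colonization 11–87%, with the legumes
  N-rich and highly mycorrhizal).  Plasticity defaults: height
  +1.5 cm per log₂ richness (plants grow taller in mixtures); small
  negative slopes for leaf N, leaf P, and AMF colonization; zero for
  SLA and leaf K.  Additive Gaussian noise and block intercepts; AMF
  clipped to [0, 100] and concentrations to ≥ 0 (a mild nonlinearity at
  the margins).
* **Soil and root variables.**  Linear in log₂ richness with a
  dominant-presence shift and additive Gaussian block/noise terms;
  defaults make pH fall (−0.08 per log₂S, −0.05 with the dominant) and
  organic C, total N, available P and K, and RLD rise, SRL fall.
* **Determinism.**  One `numpy` Generator seeded from the configuration
  drives design, biomass, and trait generation in a fixed order;
  identical configuration and seed give bit-identical output tables.
* **Not emulated.**  Temporal dynamics (the 15-year trajectory appears
  only as a static endpoint), spatial autocorrelation, plant–soil
  feedback loops, weed invasion, and any causal ordering between soil
  change and trait change — the generator imposes a configurable causal
  template, not a claim about the real system.  Passing recovery tests
  therefore demonstrate correctness of the estimators under these
  conditions, not robustness to everything field data can do.

## 5. Calibration and recovery study design

The Monte-Carlo studies in the test suite and the acceptance script use
these scenarios and sizes (chosen as the package's own design):

* **Null calibration (1000 replicates, 85-plot design).**  The per-term
  LRT rates are measured on the soil-pH response under the
  all-effects-zero configuration: an additive, homoscedastic Gaussian
  response that satisfies the mixed model's assumptions, so the nominal
  5% level is the correct yardstick.  NE is unsuitable for this purpose:
  its noise variance is several-fold larger in plots containing the
  high-yield dominant, a violation aligned with the identity regressor
  that turns the study into a robustness test.  The grand-mean F test of
  NE is calibrated with the partition computed against the **true**
  monoculture means and with the biomass block factor off — the ANOVA
  conditions on blocks as fixed, so random block factors on biomass
  would make the conditional null false (and the shared estimated
  reference would do the same through ratio bias).  Both choices select
  the scenario in which the tested null is exactly true.
* **Neutralization recovery (200 replicates each).**  Identity-only
  scenario: pH shifted −0.15 by dominant presence (≈3 residual SD), no
  richness slope; expected verdict `neutralized = True`.  Richness-only
  scenario: pH slope −0.08 per log₂ richness, no identity shift;
  expected `neutralized = False`.  A yield-based response is not used
  here because a fixed per-capita dominance boost produces an identity
  effect scaling as 1/S, which induces a genuine residual richness trend
  after identity — not a clean identity-only null.
* **Plasticity and covariation.**  Zero plasticity leaves the
  adjustment share at its noise floor (richness has 1 df, so the
  expected share is ≈ σ²_adj·χ²₁ / SS_total — well under 2% at the
  default noise).  The anticorrelated scenario (height plasticity
  −3 cm per log₂S against the rising weight of the tall dominant)
  produces a negative covariation share: if the fixed and adjustment
  slopes are +a and −b, the shares scale as (a−b)², a², b², and the
  covariation term −2ab < 0.
* **Slope recovery (100 replicates).**  The complementarity slope is
  re-estimated as the regression of CE/(Σ pᵢM̂ᵢ) on log₂S with the
  estimated reference; the shared-reference ratio bias is constant in S
  and lands in the intercept, leaving the slope approximately unbiased.

## 6. Numerical conventions and edge cases

* Partition identities hold to ≤1e-13 relative; tolerances asserted at
  1e-9.
* Sown proportions must sum to 1 within 1e-6 per plot.
* `cwm` on a plot with zero total biomass is an error (undefined), as is
  `ztransform` of a constant vector (zero variance).
* Grand-mean F on identically zero effects returns F = 0, p = 1 rather
  than 0/0.
* A saturated ANOVA (zero residual df) and a single represented richness
  level raise design errors instructing the caller to change terms.
* Optimizer: Nelder–Mead on log variance ratios, xatol 2e-3 / fatol
  1e-7, bounds via clipping to e⁻¹⁵…e¹⁰, OLS corner always evaluated; a
  second start at smaller ratios fires only when the first fails to beat
  OLS.

## 7. Known limitations

* With one monoculture replicate per species (the default design), the
  estimated-reference partition carries a positive relative-yield bias
  of order CV² and dataset-level correlated errors; grand means of SE
  can take either sign at a single seed even when the generative
  selection effect is positive.  More monoculture replicates shrink
  this.
* ML (not REML) variance estimates are biased low in small samples; the
  LRT calibration shows the practical effect at this design size is
  within the nominal band, but p-values near the threshold should not be
  over-read.
* The two-order procedure tests one focal species at a time and applies
  no multiplicity correction across the response × species grid, by
  design.
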